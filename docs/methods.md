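# Methods

## Signal model and analysis chain

Recordings are two-channel resting-state field potentials — motor-cortex ECoG
("MCx") and subthalamic LFP ("STN") — sampled at 256 Hz after hardware
band-pass filtering (0.3–100 Hz) in the acquisition setting the package
emulates. Analysis operates on three 30-s artifact-free epochs per recording.
Time intervals are half-open `[start, end)` seconds with sample index
`floor(t·fs)`, which removes boundary double-counting throughout.

**Epoch selection.** Visual artifact screening is replaced by an amplitude
rule: a sample is an artifact when |x − median| exceeds `k` robust SDs
(1.4826·MAD) on any channel; the earliest `n` non-overlapping clean windows on
a 1-s grid are taken. `k = 6` by default — no principled threshold exists for
visual criteria, so `k` is exposed in the configuration and the epoch rule is
deliberately conservative (a single bad sample disqualifies a window).

**Spectra.** Power spectra average Hann-windowed periodograms over
non-overlapping 1-s windows (window length exactly `fs` samples ⇒ 1 Hz bins).
Per-window mean removal is the only detrending; the acquisition high-pass
makes stronger detrending redundant. Scaling is density-per-1-Hz-bin with
Hann window-power compensation, so summed power tracks signal variance
(Parseval). Normalization divides by the summed power over the inclusive bins
5–45 and 55–95 Hz; 46–54 Hz is excluded as the 50 Hz mains region. Band means
are arithmetic means over inclusive integer bins; low β = 13–20 Hz and high
β = 21–30 Hz partition total β = 13–30 Hz without overlap.

**Imaginary coherence.** Auto- and cross-spectra are averaged over the same
1-s Hann windows, pooled across all epochs before the ratio is formed
(maximizing estimator degrees of freedom), and |Im C(f)| is reported.
Nonnegative magnitudes are reported because the sign of Im C merely encodes
lead/lag direction. Zero-power bins yield 0 with a warning. Operands are
canonicalized internally so icoh(x, y) and icoh(y, x) are bit-identical.
With W windows the squared-coherence bias floor is ≈ 1/W; at the default 90
windows independent channels average |Im C| ≈ 0.03, which is why the worked
example calls 0.24 clearly non-null.

**Bursts.** Burst analysis z-scores each epoch (population SD) to remove
between-subject amplitude differences, computes 10-cycle complex Morlet power
at each integer frequency of the target band (grid defined 1–128 Hz; bands
above 100 Hz warn because 128 Hz is Nyquist at 256 Hz) and averages across
band frequencies into one envelope sample per input sample. The detection
threshold is the linear-interpolation 75th percentile of envelope samples
pooled over *all* recordings of a region — one common threshold for all MCx
and another for all STN signals, spanning subjects, groups and weeks (the
maximal reading; per-week pooling is available through the same function by
changing the pool). Bursts are maximal strictly-supra-threshold runs lasting
≥ 100 ms (inclusive); runs touching an epoch edge are discarded rather than
truncated, avoiding downward-biased durations. "Long" bursts are strictly
longer than 350 ms. Burst amplitude is the per-burst peak envelope averaged
over bursts — the envelope-peak convention of the β-burst literature; the
mean envelope per burst is also stored.

## Synthetic data: what it emulates, what it does not

The generator provides ground truth for every downstream stage:

* **Background**: white noise shaped in the frequency domain to 1/f^a
  (default a = 1, flat below 0.5 Hz), unit SD, plus an optional 50 Hz mains
  sinusoid (gain 0.3). Exactly controllable: the average periodogram slope
  over 5–45 Hz recovers `a` within ±0.3 over 20 realizations.
* **Bursts**: Poisson counts per sub-band (default 8/min each in 13–20 and
  21–30 Hz), gamma durations (shape 3, scale 0.08 s ⇒ mean 240 ms, clipped to
  0.1–2 s), integer carrier frequency, amplitude ~N(2.5, 0.5)·background-SD,
  cosine-tapered (Tukey) envelope. Non-overlap is enforced by resampling
  collisions with a 0.2 s minimum gap (up to 200 draws; an event that cannot
  be placed is dropped, which only matters at extreme rates). No empirical
  burst-duration distribution is available to match; gamma is a modelling
  choice.
* **Coupling**: one shared 13–30 Hz band-limited source added to both
  channels, delayed by `coupling_lag_ms` (default 10 ms) at STN. A shared
  *lagged* source guarantees genuinely imaginary coherence, not merely real
  coherence.
* **Cohorts**: groups follow the empty-vector / low-titre / high-titre design
  (default 6 subjects each, weeks 2, 3, 4, 6, 8) through week-wise severity
  multipliers that scale burst rate strongly and amplitude/duration mildly
  (raw burst amplitude in vivo changes far less than burst incidence, and the
  amplitude screen in epoch selection must not confuse disease severity with
  artifact). Behaviour, TH⁺ count and striatal OD are drawn from an explicit
  linear-Gaussian path model (latent cortical β burden → STN burden →
  endpoints; default standardized coefficients 0.65/0.7/0.6/0.55, residual SD
  0.5) so maximum-likelihood recovery has a closed-form truth.
  `simulate_endpoint_table` exposes this generative path model directly for
  large-n recovery studies; `simulate_cohort` additionally renders one
  recording per subject-week. All randomness descends from one root seed with
  deterministic per-subject child streams; identical configuration + seed is
  bit-reproducible.

Not emulated: biophysical basal-ganglia dynamics, spike activity, movement or
anaesthesia artifacts, non-stationary 1/f slopes, and electrode artifacts.
Passing tests therefore demonstrate correctness of the *analysis* under the
stated statistical structure, not robustness to every pathology of real
recordings.

A practical interaction worth knowing when validating detection against
injected events: with a pooled percentile threshold at quantile q, ground
truth and detection can only coincide exactly when injected events occupy
slightly more than a fraction 1−q of the samples — the threshold then falls at
the foot of the burst taper, between background and event amplitudes. The
recovery fixtures use a ~28% duty cycle with ≥ 0.9 s gaps, amplitude 10
(SNR ≥ 10) and durations 150–600 ms; there, wavelet smearing (which widens
detected bursts) and taper shrink (which narrows them) cancel to within
50 ms per edge. At realistic sparse rates the same rule legitimately detects
background β fluctuations as bursts — as it does in real data — so exact
count agreement is not a meaningful expectation outside that regime.

## Path models

Models are observed-variable recursive path models; every node is a measured
quantity (no latent factors). `fit` minimizes
F = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p with Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ, free
parameters being edge coefficients, all variances and exogenous covariances.
Listwise deletion is applied first; S uses ddof = 1. Variables are rescaled to
unit sample variance internally (the fit function and every index reported
are invariant under diagonal rescaling; raw cohort tables mix variances
spanning many orders of magnitude, which otherwise ill-conditions both the
optimizer and the finite-difference Hessian) and estimates are mapped back.
Optimization is L-BFGS-B from the per-equation OLS solution (for recursive
models with free residuals that start *is* the ML solution up to polish);
non-convergence with a non-vanishing gradient raises.

Reported: χ² = (n−1)·F, df = p(p+1)/2 − q,
RMSEA = √(max(χ²−df, 0)/(df·(n−1))) (0 when df = 0), AIC = χ² + 2q (the
differences between models are what matter), CFI against the independence
baseline, and SRMR. Standard errors come from the numerical Hessian of F
(acov = 2/(n−1)·H⁻¹). Standardized coefficients are S = b·sd(from)/sd(to);
their confidence intervals use a delta method through the full parameter
vector, S(θ) = b·√(Σ_ff(θ)/Σ_tt(θ)) — simply rescaling the raw CI by the SD
ratio ignores the sampling variability of the scale factors and over-covers
(the textbook case: a standardized simple-regression slope has SE
(1−r²)/√n, not √(1−r²)/√n).

Longitudinal repeated measures enter as subject-week rows; RMSEA is reported
as the misfit summary for that structure rather than adopting a random-effects
likelihood. The ICS/ICSF criteria sometimes quoted for such models have no
published formula; CFI and SRMR are reported instead and `SEMResults` carries
everything needed to plug in a user-supplied index.

The correlated-endpoint multiplicity rule is
α_adj = 1 − (1−α)^(1/m^(1−r̄)): at r̄ = 0 it reduces to the Šidák level
(≈ Bonferroni), at r̄ = 1 fully redundant tests leave α untouched. It is a
pluggable function, not baked into any fitting path.

**Composite score.** Candidate features are first mean-normalized per group
and cumulative-summed over weeks (so a feature constantly at its group mean
maps to 1, 2, 3, …). The neurodegeneration target is the mean of
min–max-normalized TH⁺-cell loss and striatal-OD loss, each expressed as
1 − value/control-group mean — this composite is a package definition, made
explicit because no canonical one exists. Forward selection adds, at each
step, the feature whose non-negative-least-squares weight vector
(renormalized to sum to 1) minimizes RMSE; selection stops when the
improvement falls below 1% *of the intercept-only baseline RMSE* — a
target-scale criterion, because a relative-to-current-RMSE rule keeps
admitting spurious features once the fit reaches the noise floor. An
exhaustive-subset mode (≤ 12 candidates) is provided for cross-checking.

**Behaviour–degeneration curves.** Behaviour scores are z-normalized per
group and tercile-decoded into normal/moderate/severe; "preserved" means the
normal class. P(preserved) versus neurodegeneration percentage is fitted per
group by logistic regression with a weak ridge penalty (λ = 10⁻³, centred
parameterization) so the curve stays defined under perfect separation — the
regime the data approximate when motor function collapses at a sharp
threshold; the fitted midpoint then lands mid-gap. Terciles and the logistic
form are package choices where no cut points or functional form are
prescribed; both are monotone and exposed.

## I/O conventions

CSV recordings use the dialect `time_s,MCx,STN` with a `# fs_hz=… subject=…`
metadata comment line and full float precision (exact round trips). EDF files
are standard 16-bit EDF with 1-s records; the physical range is rounded to 4
significant digits so the 8-character header field reproduces the value used
for scaling, bounding round-trip error by one quantization step. The EDF
writer/reader is a minimal implementation of the fixed-layout format; an
independent EDF reader is used as a cross-check in the test suite. Recording
length must be a whole number of seconds for EDF (records are 1 s).

## Problem sizes

Defaults are sized so a full verification run completes comfortably on one
CPU: recovery fixtures use three 30-s epochs at 256 Hz; cohort demonstrations
use 3–6 subjects per group over 2–5 weeks of 120-s recordings; path-model
recovery uses 100 replicates of n = 200 subject-rows via the endpoint-table
fast path; statistical calibration uses 500 null simulations. All are
package choices that can be scaled up through the same configuration objects.

## Known limitations

* The SEM layer assumes linear-Gaussian relations and complete cases;
  repeated measures are not modelled with random effects.
* The burst threshold convention (pooled percentile) makes burst statistics
  cohort-relative: adding recordings changes the threshold, hence all burst
  features. This mirrors the common-threshold design it implements.
* The artifact rule is amplitude-only; physiological artifacts with normal
  amplitudes (chewing rhythms, slow drift within the band) pass it.
* Human mode consumes a precomputed feature table; EEG source reconstruction
  of cortical time series is out of scope.
* Wavelet envelope edges limit burst-timing resolution to roughly the
  wavelet's temporal SD (53–76 ms across 21–30 Hz at 10 cycles); sub-50 ms
  edge accuracy is only achievable in the favorable threshold regime
  described above.
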