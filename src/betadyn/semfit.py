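"""Path models over the longitudinal feature table.

The models are observed-variable recursive path models (no latent factors):
every node is a measured feature, behaviour score or histology endpoint.
``PathModel`` is the model object; ``PathModel.fit`` minimizes the maximum-
likelihood covariance discrepancy

    F_ML = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over free path coefficients, residual variances and exogenous covariances,
and returns a :class:`SEMResults` with chi-square, RMSEA, AIC, CFI, SRMR,
standard errors and standardized coefficients (S = b * sd(from)/sd(to)).

Also here: the correlated-endpoint "adjusted Bonferroni" rule, the
mean-normalized cumulative-sum feature transform, the non-negative
forward-selection composite score, and the logistic behaviour-versus-
neurodegeneration curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModel",
    "SEMResults",
    "AdjustedBonferroni",
    "adjusted_bonferroni",
    "cumulative_features",
    "CompositeScoreModel",
    "CompositeScoreResults",
    "BehaviorDegenerationModel",
    "LogisticCurve",
]


# ---------------------------------------------------------------------------
# ML path-model fit

class PathModel:
    """Directed acyclic path model among observed variables.

    Parameters
    ----------
    edges
        ``(from, to)`` pairs, one free coefficient each.
    variables
        Optional explicit variable order; defaults to order of appearance.
    """

    def __init__(self, edges: Sequence[tuple[str, str]], variables: Sequence[str] | None = None):
        self.edges = [tuple(e) for e in edges]
        if not self.edges:
            raise ValueError("path model needs at least one edge")
        seen: list[str] = []
        for a, b in self.edges:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        self.variables = list(variables) if variables is not None else seen
        missing = [v for v in seen if v not in self.variables]
        if missing:
            raise ValueError(f"edge variables missing from variable list: {missing}")
        self._check_acyclic()
        self.endogenous = sorted({b for _, b in self.edges})
        self.exogenous = [v for v in self.variables if v not in self.endogenous]

    @classmethod
    def from_text(cls, text: str) -> "PathModel":
        """Parse a model file with one ``from -> to`` edge per line."""
        edges = []
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "->" not in line:
                raise ValueError(f"cannot parse model line {line!r}; expected 'from -> to'")
            a, b = (t.strip() for t in line.split("->", 1))
            edges.append((a, b))
        return cls(edges)

    def _check_acyclic(self) -> None:
        order: list[str] = []
        temp: set[str] = set()
        perm: set[str] = set()
        children = {v: [b for a, b in self.edges if a == v] for v in self.variables}

        def visit(v: str) -> None:
            if v in perm:
                return
            if v in temp:
                raise ValueError(f"path model contains a cycle through {v!r}")
            temp.add(v)
            for c in children[v]:
                visit(c)
            temp.discard(v)
            perm.add(v)
            order.append(v)

        for v in self.variables:
            visit(v)

    # -- parameter bookkeeping ------------------------------------------------

    def _param_names(self) -> list[str]:
        names = [f"{b}~{a}" for a, b in self.edges]
        names += [f"var({v})" for v in self.variables]
        names += [f"cov({a},{b})" for a, b in combinations(self.exogenous, 2)]
        return names

    def _implied_cov(self, theta: np.ndarray) -> np.ndarray:
        p = len(self.variables)
        idx = {v: i for i, v in enumerate(self.variables)}
        ne = len(self.edges)
        B = np.zeros((p, p))
        for k, (a, b) in enumerate(self.edges):
            B[idx[b], idx[a]] = theta[k]
        psi = np.zeros((p, p))
        psi[np.arange(p), np.arange(p)] = theta[ne:ne + p]
        for k, (a, b) in enumerate(combinations(self.exogenous, 2)):
            psi[idx[a], idx[b]] = psi[idx[b], idx[a]] = theta[ne + p + k]
        inv = np.linalg.inv(np.eye(p) - B)
        return inv @ psi @ inv.T

    def _start_values(self, S: np.ndarray) -> np.ndarray:
        idx = {v: i for i, v in enumerate(self.variables)}
        coefs = []
        resid = dict(zip(self.variables, np.diag(S)))
        for v in self.endogenous:
            parents = [a for a, b in self.edges if b == v]
            pi = [idx[a] for a in parents]
            Sp = S[np.ix_(pi, pi)]
            sv = S[pi, idx[v]]
            beta = np.linalg.solve(Sp, sv)
            resid[v] = max(S[idx[v], idx[v]] - float(sv @ beta), 1e-6)
            for a, b in zip(parents, beta):
                coefs.append(((a, v), float(b)))
        coef_map = dict(coefs)
        theta = [coef_map[(a, b)] for a, b in self.edges]
        theta += [resid[v] for v in self.variables]
        theta += [S[idx[a], idx[b]] for a, b in combinations(self.exogenous, 2)]
        return np.array(theta)

    # -- fitting --------------------------------------------------------------

    def fit(self, data: pd.DataFrame, maxiter: int = 500) -> "SEMResults":
        """Maximum-likelihood fit to the sample covariance (listwise deletion).

        Internally the variables are rescaled to unit sample variance — the
        fit function, chi-square and all fit indices are invariant under
        diagonal rescaling, and the optimizer is far better conditioned when
        cell counts and normalized powers differ by orders of magnitude.
        Estimates are mapped back to the raw scale afterwards.
        """
        df = data[self.variables].dropna()
        n = len(df)
        q = len(self._param_names())
        if n <= q:
            raise ValueError(f"n={n} must exceed the {q} free parameters")
        sds = df.std(ddof=1)
        if (sds <= 0).any():
            bad = list(sds.index[sds <= 0])
            raise ValueError(f"constant variables: {bad}")
        zdf = df / sds
        S = np.atleast_2d(np.cov(zdf.to_numpy().T, ddof=1))
        eigs = np.linalg.eigvalsh(S)
        if eigs[0] <= 1e-10 * eigs[-1]:
            raise ValueError("sample covariance is not positive definite "
                             "(collinear variables)")
        _, logdet_S = np.linalg.slogdet(S)
        p = len(self.variables)
        ne = len(self.edges)

        def objective(theta: np.ndarray) -> float:
            sigma = self._implied_cov(theta)
            try:
                c = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return 1e10
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            inv = np.linalg.inv(sigma)
            return float(logdet + np.trace(S @ inv) - logdet_S - p)

        x0 = self._start_values(S)
        bounds = [(None, None)] * ne + [(1e-8, None)] * p
        bounds += [(None, None)] * (len(x0) - ne - p)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
        if not res.success and np.linalg.norm(res.jac) > 1e-4:
            raise RuntimeError(
                f"ML fit did not converge in {maxiter} iterations "
                f"(|grad| = {np.linalg.norm(res.jac):.3g}): {res.message}")

        theta = res.x
        fmin = max(objective(theta), 0.0)
        chi2 = (n - 1) * fmin
        dof = p * (p + 1) // 2 - q
        rmsea = 0.0 if dof == 0 else float(np.sqrt(max(chi2 - dof, 0.0) / (dof * (n - 1))))
        aic = chi2 + 2 * q

        # baseline (independence) model for CFI
        f_base = float(np.sum(np.log(np.diag(S))) - logdet_S)
        chi2_base = (n - 1) * f_base
        dof_base = p * (p - 1) // 2
        denom = max(chi2_base - dof_base, chi2 - dof, 0.0)
        cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - dof, 0.0) / denom

        sigma = self._implied_cov(theta)
        d = np.sqrt(np.diag(S))
        resid = (S - sigma) / np.outer(d, d)
        iu = np.triu_indices(p)
        srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

        se, acov = self._standard_errors(objective, theta, n)
        se_std = self._standardized_se(theta, acov)
        names = self._param_names()

        # map the unit-variance solution back to raw scale: edge b_raw =
        # b_z * sd(to)/sd(from); variances scale by sd^2, covariances by the
        # product of sds. On the standardized problem the edge coefficients
        # are exactly S = b_raw * sd(from)/sd(to).
        scale = np.concatenate([
            [sds[b] / sds[a] for a, b in self.edges],
            [sds[v] ** 2 for v in self.variables],
            [sds[a] * sds[b] for a, b in combinations(self.exogenous, 2)],
        ])
        std_coef = pd.Series(theta[:ne], index=[f"{b}~{a}" for a, b in self.edges])
        raw_cov = np.cov(df.to_numpy().T, ddof=1)
        return SEMResults(
            model=self,
            params=pd.Series(theta * scale, index=names),
            se=pd.Series(se * scale, index=names),
            standardized=std_coef,
            standardized_se=se_std,
            chi2=float(chi2), df=int(dof), rmsea=rmsea, aic=float(aic),
            cfi=float(cfi), srmr=srmr, n=n, converged=True,
            sample_cov=pd.DataFrame(np.atleast_2d(raw_cov), index=self.variables,
                                    columns=self.variables),
        )

    @staticmethod
    def _standard_errors(objective, theta: np.ndarray, n: int
                         ) -> tuple[np.ndarray, np.ndarray | None]:
        """SEs from the numerical Hessian of F_ML: acov = (2/(n-1)) H^-1."""
        k = theta.size
        h = 1e-4 * (1.0 + np.abs(theta))
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = objective(theta + ei + ej)
                fpm = objective(theta + ei - ej)
                fmp = objective(theta - ei + ej)
                fmm = objective(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            acov = 2.0 / (n - 1) * np.linalg.inv(H)
            var = np.clip(np.diag(acov), 0.0, None)
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix; standard errors unavailable")
            return np.full(k, np.nan), None
        return np.sqrt(var), acov

    def _standardized_se(self, theta: np.ndarray, acov: np.ndarray | None) -> pd.Series:
        """Delta-method SEs of the standardized coefficients.

        S_edge(theta) = b * sqrt(Sigma_ff / Sigma_tt) with the variances taken
        from the model-implied covariance, so the sampling variability of the
        scale factors propagates (scaling the raw SE by the SD ratio alone
        overstates the uncertainty of S).
        """
        names = [f"{b}~{a}" for a, b in self.edges]
        if acov is None:
            return pd.Series(np.nan, index=names)
        idx = {v: i for i, v in enumerate(self.variables)}

        def s_vec(th: np.ndarray) -> np.ndarray:
            sigma = self._implied_cov(th)
            return np.array([
                th[k] * np.sqrt(sigma[idx[a], idx[a]] / sigma[idx[b], idx[b]])
                for k, (a, b) in enumerate(self.edges)])

        h = 1e-5 * (1.0 + np.abs(theta))
        G = np.zeros((len(self.edges), theta.size))
        for j in range(theta.size):
            e = np.zeros(theta.size); e[j] = h[j]
            G[:, j] = (s_vec(theta + e) - s_vec(theta - e)) / (2 * h[j])
        var = np.clip(np.einsum("ij,jk,ik->i", G, acov, G), 0.0, None)
        return pd.Series(np.sqrt(var), index=names)


@dataclass
class SEMResults:
    """ML path-model estimates with fit indices, statsmodels-results style."""

    model: PathModel
    params: pd.Series
    se: pd.Series
    standardized: pd.Series
    standardized_se: pd.Series
    chi2: float
    df: int
    rmsea: float
    aic: float
    cfi: float
    srmr: float
    n: int
    converged: bool
    sample_cov: pd.DataFrame

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.se, "upper": self.params + z * self.se})

    def standardized_conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Delta-method CI for the standardized coefficients."""
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "lower": self.standardized - z * self.standardized_se,
            "upper": self.standardized + z * self.standardized_se,
        })

    def summary(self) -> str:
        lines = [
            "Path model (ML covariance-structure fit)",
            "=" * 72,
            f"n = {self.n}   free parameters = {len(self.params)}   df = {self.df}",
            f"chi2 = {self.chi2:.4f}   RMSEA = {self.rmsea:.4f}   AIC = {self.aic:.2f}",
            f"CFI = {self.cfi:.4f}   SRMR = {self.srmr:.4f}",
            "-" * 72,
            f"{'parameter':<28}{'estimate':>10}{'std err':>10}{'z':>8}{'P>|z|':>9}{'S':>8}",
            "-" * 72,
        ]
        pv = self.pvalues
        zv = self.zvalues
        for name in self.params.index:
            s = f"{self.standardized[name]:8.3f}" if name in self.standardized.index else " " * 8
            lines.append(
                f"{name:<28}{self.params[name]:>10.4f}{self.se[name]:>10.4f}"
                f"{zv[name]:>8.2f}{pv[name]:>9.4f}{s}")
        lines.append("=" * 72)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "chi2": self.chi2,
            "df": self.df,
            "rmsea": self.rmsea,
            "aic": self.aic,
            "cfi": self.cfi,
            "srmr": self.srmr,
            "estimates": self.params.to_dict(),
            "se": self.se.to_dict(),
            "standardized": self.standardized.to_dict(),
            "standardized_se": self.standardized_se.to_dict(),
            "p_values": self.pvalues.to_dict(),
        }


# ---------------------------------------------------------------------------
# Correlated-endpoint Bonferroni adjustment

@dataclass(frozen=True)
class AdjustedBonferroni:
    alpha_adjusted: float
    significant: tuple[bool, ...]


def adjusted_bonferroni(
    p_values: Sequence[float],
    mean_abs_correlation: float,
    alpha: float = 0.05,
) -> AdjustedBonferroni:
    """alpha_adj = 1 - (1 - alpha)^(1 / m^(1 - rbar)).

    The correction weakens as the average absolute correlation rbar between the
    tested endpoints rises: rbar = 0 reduces to the Sidak/Bonferroni level,
    rbar = 1 (fully redundant tests) leaves alpha untouched.
    """
    p_values = list(p_values)
    if not p_values:
        raise ValueError("p_values must be nonempty")
    r = float(mean_abs_correlation)
    if not 0.0 <= r <= 1.0:
        raise ValueError("mean_abs_correlation must lie in [0, 1]")
    m = len(p_values)
    alpha_adj = 1.0 - (1.0 - alpha) ** (1.0 / m ** (1.0 - r))
    return AdjustedBonferroni(alpha_adj, tuple(p < alpha_adj for p in p_values))


# ---------------------------------------------------------------------------
# Cumulative-sum feature transform

def cumulative_features(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    group_col: str = "group",
    subject_col: str = "subject",
    week_col: str = "week",
) -> pd.DataFrame:
    """Per group: divide each feature by its group mean, then cumulative-sum
    across weeks in chronological order within each subject.

    Subjects missing any week are dropped (with a warning naming them). A
    feature whose group mean is zero cannot be mean-normalized and is
    rejected.
    """
    df = table.copy()
    weeks = sorted(df[week_col].unique())
    complete = df.groupby(subject_col)[week_col].nunique() == len(weeks)
    dropped = complete.index[~complete].tolist()
    if dropped:
        warnings.warn(f"dropping subjects with incomplete weeks: {dropped}")
        df = df[df[subject_col].isin(complete.index[complete])]
    df = df.sort_values([subject_col, week_col]).reset_index(drop=True)
    for col in feature_cols:
        means = df.groupby(group_col)[col].transform("mean")
        if np.any(means == 0):
            bad = df.loc[means == 0, group_col].unique().tolist()
            raise ValueError(f"group mean of {col!r} is zero in groups {bad}")
        df[col] = df[col] / means
        df[col] = df.groupby(subject_col)[col].cumsum()
    return df


# ---------------------------------------------------------------------------
# Composite neurodegeneration score

@dataclass
class CompositeScoreResults:
    selected_features: list[str]
    weights: pd.Series  # non-negative, sum to 1
    rmse: float
    baseline_rmse: float
    per_group_rmse: dict[str, float]
    history: list[tuple[str, float]] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Composite score (non-negative weights, sum = 1)", "-" * 48]
        for f, w in self.weights.items():
            lines.append(f"  {f:<32}{w:8.3f}")
        lines.append(f"RMSE = {self.rmse:.4f} (baseline {self.baseline_rmse:.4f})")
        for g, r in self.per_group_rmse.items():
            lines.append(f"  RMSE[{g}] = {r:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "weights": self.weights.to_dict(),
            "rmse": self.rmse,
            "baseline_rmse": self.baseline_rmse,
            "per_group_rmse": self.per_group_rmse,
        }


class CompositeScoreModel:
    """Weighted non-negative combination of candidate features fitting a target.

    Forward selection: at each step the feature whose NNLS weight vector
    (renormalized to sum 1) minimizes RMSE joins the model; selection stops
    when the RMSE improvement falls below ``tol`` of the intercept-only
    baseline RMSE (a target-scale criterion, so a model already at the noise
    floor does not keep absorbing spurious features). ``method='exhaustive'``
    searches all subsets instead (candidate menu capped at 12 features).
    """

    def __init__(self, features: pd.DataFrame, target: pd.Series | np.ndarray,
                 groups: pd.Series | None = None):
        self.X = features.astype(float)
        self.y = np.asarray(target, dtype=float)
        self.groups = None if groups is None else np.asarray(groups)
        if self.X.shape[0] != self.y.size:
            raise ValueError("features and target length mismatch")
        if self.X.shape[1] == 0:
            raise ValueError("need at least one candidate feature")
        if all(self.X[c].std() == 0 for c in self.X.columns):
            raise ValueError("all candidate features are constant")

    def _rmse_for(self, cols: list[str]) -> tuple[float, np.ndarray]:
        A = self.X[cols].to_numpy()
        w, _ = optimize.nnls(A, self.y)
        if w.sum() == 0:
            return float("inf"), w
        w = w / w.sum()
        return float(np.sqrt(np.mean((self.y - A @ w) ** 2))), w

    def fit(self, tol: float = 0.01, method: str = "forward",
            max_features: int | None = None) -> CompositeScoreResults:
        baseline = float(np.sqrt(np.mean((self.y - self.y.mean()) ** 2)))
        cols = list(self.X.columns)
        if method == "exhaustive":
            if len(cols) > 12:
                raise ValueError("exhaustive search capped at 12 candidate features")
            best: tuple[float, list[str], np.ndarray] | None = None
            for k in range(1, len(cols) + 1):
                for sub in combinations(cols, k):
                    r, w = self._rmse_for(list(sub))
                    if best is None or r < best[0] - 1e-12:
                        best = (r, list(sub), w)
            assert best is not None
            rmse, selected, w = best
            history = [("+".join(selected), rmse)]
        elif method == "forward":
            selected: list[str] = []
            w = np.array([])
            rmse = baseline
            history = []
            limit = max_features or len(cols)
            while len(selected) < limit:
                trials = [(self._rmse_for(selected + [c]), c)
                          for c in cols if c not in selected]
                (best_rmse, best_w), best_col = min(trials, key=lambda t: t[0][0])
                if baseline > 0 and (rmse - best_rmse) / baseline < tol:
                    break
                selected.append(best_col)
                w, rmse = best_w, best_rmse
                history.append((best_col, rmse))
                if rmse == 0:
                    break
            if not selected:
                # forced single best feature so the result is never empty
                (rmse, w), col = min(
                    [(self._rmse_for([c]), c) for c in cols], key=lambda t: t[0][0])
                selected = [col]
                history.append((col, rmse))
        else:
            raise ValueError(f"unknown method {method!r}")

        weights = pd.Series(w, index=selected)
        per_group: dict[str, float] = {}
        if self.groups is not None:
            pred = self.X[selected].to_numpy() @ w
            for g in np.unique(self.groups):
                m = self.groups == g
                per_group[str(g)] = float(np.sqrt(np.mean((self.y[m] - pred[m]) ** 2)))
        return CompositeScoreResults(selected, weights, rmse, baseline, per_group, history)


# ---------------------------------------------------------------------------
# Behaviour-versus-neurodegeneration curves

@dataclass(frozen=True)
class LogisticCurve:
    """P(preserved motor function) = 1 / (1 + exp(-(a + b * degeneration)))."""

    group: str
    midpoint: float  # degeneration % at which P = 0.5
    slope: float  # b; negative when function is lost with degeneration
    n: int

    def predict(self, degeneration_pct: np.ndarray) -> np.ndarray:
        x = np.asarray(degeneration_pct, dtype=float)
        a = -self.slope * self.midpoint
        return 1.0 / (1.0 + np.exp(-(a + self.slope * x)))


def _decode_behavior(z: np.ndarray) -> np.ndarray:
    """Tercile-cut z-scored behaviour into 0=normal, 1=moderate, 2=severe."""
    q1, q2 = np.quantile(z, [1 / 3, 2 / 3])
    cls = np.ones(z.size, dtype=int)
    cls[z <= q1] = 0
    cls[z > q2] = 2
    return cls


def _penalized_logistic(x: np.ndarray, y01: np.ndarray, ridge: float = 1e-3
                        ) -> tuple[float, float]:
    """MLE of logit P(y=1) = a + b*(x - xbar) with a weak ridge penalty.

    The penalty keeps the fit defined under perfect separation (where the
    unpenalized MLE diverges); it barely moves estimates otherwise.
    """
    xc = x - x.mean()

    def nll(th):
        a, b = th
        eta = a + b * xc
        return float(np.sum(np.logaddexp(0.0, -eta) * y01
                            + np.logaddexp(0.0, eta) * (1 - y01))
                     + ridge * (a * a + b * b))

    res = optimize.minimize(nll, np.array([0.0, -0.1]), method="BFGS")
    a, b = res.x
    return float(a - b * x.mean()) , float(b)  # de-centred intercept, slope


class BehaviorDegenerationModel:
    """Monotone logistic link between neurodegeneration and preserved function.

    Behaviour scores (higher = worse deficit) are z-normalized per group and
    tercile-decoded into normal / moderate / severe; "preserved" means the
    normal class. A logistic curve of P(preserved) against neurodegeneration
    percentage is fitted per group.
    """

    def __init__(self, degeneration_pct, behavior, groups=None):
        self.x = np.asarray(degeneration_pct, dtype=float)
        self.behavior = np.asarray(behavior, dtype=float)
        if groups is None:
            groups = np.full(self.x.size, "all")
        self.groups = np.asarray(groups)
        if not (self.x.size == self.behavior.size == self.groups.size):
            raise ValueError("inputs must be equal length")

    def fit(self) -> dict[str, LogisticCurve]:
        curves: dict[str, LogisticCurve] = {}
        for g in np.unique(self.groups):
            m = self.groups == g
            beh = self.behavior[m]
            if beh.std() == 0:
                raise ValueError(
                    f"group {g}: behaviour has a single class; curve unidentifiable")
            z = (beh - beh.mean()) / beh.std()
            cls = _decode_behavior(z)
            preserved = (cls == 0).astype(float)
            if preserved.min() == preserved.max():
                raise ValueError(
                    f"group {g}: behaviour has a single class; curve unidentifiable")
            a, b = _penalized_logistic(self.x[m], preserved)
            midpoint = -a / b if b != 0 else float("nan")
            curves[str(g)] = LogisticCurve(str(g), float(midpoint), float(b), int(m.sum()))
        return curves

    def bootstrap_slope_ci(self, group: str, n_boot: int = 200, seed: int = 0,
                           alpha: float = 0.05) -> tuple[float, float]:
        """Percentile bootstrap CI for the slope of one group's curve."""
        rng = np.random.default_rng(seed)
        m = self.groups == group
        x, beh = self.x[m], self.behavior[m]
        slopes = []
        for _ in range(n_boot):
            idx = rng.integers(0, x.size, x.size)
            bs = beh[idx]
            if bs.std() == 0:
                continue
            z = (bs - bs.mean()) / bs.std()
            preserved = (_decode_behavior(z) == 0).astype(float)
            if preserved.min() == preserved.max():
                continue
            _, b = _penalized_logistic(x[idx], preserved)
            slopes.append(b)
        if len(slopes) < max(20, n_boot // 4):
            raise ValueError("too few valid bootstrap resamples")
        lo, hi = np.quantile(slopes, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
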