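"""Behavioural and imaging indices.

Cylinder-test forelimb-asymmetry scoring for hemiparkinsonian rodents and the
SPECT specific-binding ratio used to quantify striatal dopamine-transporter
density in patients. Both are closed-form transforms of pre-scored counts;
video scoring and image segmentation happen upstream and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PawCounts", "RegionUptake", "cylinder_index", "specific_binding"]


@dataclass(frozen=True)
class PawCounts:
    """Wall-touch counts from one cylinder-test trial.

    ``ipsi`` and ``contra`` are single-paw touches ipsilateral/contralateral to
    the lesioned hemisphere; ``both`` counts simultaneous two-paw touches.
    """

    ipsi: int
    contra: int
    both: int

    def __post_init__(self) -> None:
        for name in ("ipsi", "contra", "both"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.ipsi + self.contra + self.both


@dataclass(frozen=True)
class RegionUptake:
    """Semi-quantitative SPECT tracer uptake for a striatal region.

    ``occipital_counts`` is the occipital-cortex reference value; it must be
    positive for the binding ratio to be defined.
    """

    region_counts: float
    occipital_counts: float


def cylinder_index(pc: PawCounts) -> float:
    """Forepaw-use preference as a percentage.

    ``100 * (ipsi + 0.5 * both) / (ipsi + contra + both)``. 50% means symmetric
    forepaw use; values above 50% indicate ipsilateral preference (the motor
    deficit readout in a unilateral lesion model).
    """
    if pc.total <= 0:
        raise ValueError("cylinder trial has zero wall touches")
    return 100.0 * (pc.ipsi + 0.5 * pc.both) / pc.total


def specific_binding(ru: RegionUptake) -> float:
    """DAT specific-binding ratio: (region - occipital) / occipital."""
    if ru.occipital_counts <= 0:
        raise ValueError("occipital reference counts must be positive")
    return (ru.region_counts - ru.occipital_counts) / ru.occipital_counts
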