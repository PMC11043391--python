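"""IHC H-scores from intensity-category distributions.

Tumour cells are graded into four staining-intensity categories —
negative (0), weak (1+), moderate (2+), strong (3+) — separately for the
nucleus and the cytoplasm.  The H-score weighs the category percentages:

    H = %1+ + 2 * %2+ + 3 * %3+

and therefore lies in [0, 300], reaching 300 only when every cell is 3+.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .highcontent import wilcoxon_rank_sum

__all__ = [
    "IntensityDistribution",
    "HScore",
    "h_score",
    "counts_to_percentages",
    "compare_groups",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class IntensityDistribution:
    """Percent of tumour cells at intensity 0 / 1+ / 2+ / 3+ in one compartment."""

    compartment: str  # "nucleus" or "cytoplasm"
    pct0: float
    pct1: float
    pct2: float
    pct3: float

    def __post_init__(self) -> None:
        if self.compartment not in ("nucleus", "cytoplasm"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        pcts = (self.pct0, self.pct1, self.pct2, self.pct3)
        if any(p < 0 for p in pcts):
            raise ValueError("percentages must be non-negative")
        if abs(sum(pcts) - 100.0) > _SUM_TOL:
            raise ValueError(f"percentages sum to {sum(pcts)}, expected 100")


@dataclass(frozen=True)
class HScore:
    value: float
    compartment: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 300.0:
            raise ValueError(f"H-score {self.value} outside [0, 300]")


def h_score(dist: IntensityDistribution) -> HScore:
    """Percentage-weighted intensity score, out of 300."""
    value = dist.pct1 + 2.0 * dist.pct2 + 3.0 * dist.pct3
    return HScore(value=value, compartment=dist.compartment)


def counts_to_percentages(counts, compartment: str) -> IntensityDistribution:
    """Build an intensity distribution from raw cell counts per category."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (4,):
        raise ValueError("expected four category counts (0, 1+, 2+, 3+)")
    if (c < 0).any() or c.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    pct = c / c.sum() * 100.0
    return IntensityDistribution(compartment, *pct)


def compare_groups(scores_a: list[HScore], scores_b: list[HScore]) -> float:
    """Two-sided rank-sum p comparing H-score values between two groups."""
    if not scores_a or not scores_b:
        raise ValueError("both groups must be non-empty")
    return wilcoxon_rank_sum(
        [s.value for s in scores_a], [s.value for s in scores_b]
    )
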