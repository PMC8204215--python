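"""Study statistics: exact 2x2 tests, Mann-Whitney U, Bland-Altman agreement.

The analyses mirror a small-animal device study: angiographic occlusion
grades are dichotomised (grade 1 = fully occluded = GOOD; any residual
filling = BAD), group contrasts use Fisher's exact test (two-sided,
probability-ordering convention) and the Mann-Whitney U test (exact
permutation enumeration for the small samples involved), the gap-threshold
rule is evaluated as a 2x2 prediction-vs-outcome table, and agreement between
two gap-measurement modalities is summarised with Bland-Altman bias and 95%
limits of agreement (bias +- 1.96 SD of the paired differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .coverage import Occlusion, predict_occlusion
from .exceptions import InputError
from .io import CaseRecord

__all__ = [
    "Outcome",
    "ContingencyTable2x2",
    "AgreementResult",
    "ThresholdResult",
    "dichotomize_dsa",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "bland_altman",
    "plot_bland_altman",
    "group_summary",
    "threshold_predictivity",
]


class Outcome(str, Enum):
    GOOD = "GOOD"  # fully occluded
    BAD = "BAD"  # any residual filling


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise InputError("contingency table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement between two paired measurements (mm^2)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_pairs: int


@dataclass(frozen=True)
class ThresholdResult:
    """Gap-threshold rule evaluated against the dichotomised outcome."""

    table: ContingencyTable2x2  # rows: predicted RESIDUAL/OCCLUDED, cols: BAD/GOOD
    fisher_p: float
    misclassified: int
    n: int


def dichotomize_dsa(grade: int) -> Outcome:
    """Collapse a 3-level angiographic occlusion grade to GOOD (1) vs BAD (2-3)."""
    if grade not in (1, 2, 3):
        raise InputError(f"DSA grade must be in {{1, 2, 3}}, got {grade}")
    return Outcome.GOOD if grade == 1 else Outcome.BAD


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    margin-fixed tables no more probable than the observed one."""
    arr = table.as_array()
    if arr.sum() < 1:
        raise InputError("all-zero table")
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(min(p, 1.0))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U1 = sum over pairs of [1 if a > b, 0.5 if tie] (group-a wins)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "exact_permutation",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns ``(U, two-sided p)``.

    ``exact_permutation`` enumerates every relabelling of the pooled sample
    (total n <= 12) and reports the doubled smaller tail probability of U,
    capped at 1 — valid under ties.  ``normal_approx`` uses the tie-corrected
    normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    u = _u_statistic(a, b)

    if method == "normal_approx":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return u, float(res.pvalue)
    if method != "exact_permutation":
        raise InputError(f"unknown method {method!r}")
    pooled = np.concatenate([a, b])
    n = pooled.size
    if n > 12:
        raise InputError(f"exact permutation limited to total n <= 12, got {n}")
    n_a = a.size
    us = []
    idx = np.arange(n)
    for pick in combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(pick)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    lo = float((us <= u + 1e-12).mean())
    hi = float((us >= u - 1e-12).mean())
    return u, min(1.0, 2.0 * min(lo, hi))


def bland_altman(pairs: Iterable[tuple[float, float]]) -> AgreementResult:
    """Bias and 95% limits of agreement of paired measurements.

    bias = mean(m1 - m2); limits = bias +- 1.96 * sample SD (n-1 denominator).
    """
    diffs = np.array([m1 - m2 for m1, m2 in pairs], dtype=float)
    if diffs.size < 2:
        raise InputError("Bland-Altman needs at least 2 pairs")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n_pairs=diffs.size,
    )


def plot_bland_altman(pairs: Sequence[tuple[float, float]], path) -> AgreementResult:
    """Standard Bland-Altman plot (pair means vs differences) saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    arr = np.asarray(pairs, dtype=float)
    means, diffs = arr.mean(axis=1), arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, color="k")
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of paired measurements (mm$^2$)")
    ax.set_ylabel("difference (mm$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return res


def group_summary(cases: Sequence[CaseRecord]) -> dict:
    """Per-device mean implant count and herniation proportion."""
    if not cases:
        raise InputError("empty case list")
    out: dict[str, dict] = {}
    for device in sorted({c.device for c in cases}):
        grp = [c for c in cases if c.device == device]
        out[device] = {
            "n": len(grp),
            "mean_implants": float(np.mean([c.n_implants for c in grp])),
            "herniation_proportion": float(np.mean([c.herniation for c in grp])),
        }
    return out


def threshold_predictivity(
    cases: Sequence[CaseRecord], threshold_mm2: float = 1.0
) -> ThresholdResult:
    """Evaluate the largest-gap threshold rule against 180-day outcome.

    Only cases with a measured gap (NGID) are eligible.  The 2x2 table has
    rows (predicted RESIDUAL, predicted OCCLUDED) and columns (BAD, GOOD).
    """
    eligible = [c for c in cases if c.largest_gap_mm2 is not None]
    if not eligible:
        raise InputError("no cases with a measured largest gap")
    counts = np.zeros((2, 2), dtype=int)
    miss = 0
    for c in eligible:
        pred = predict_occlusion(c.largest_gap_mm2, threshold_mm2)
        outcome = dichotomize_dsa(c.dsa_180d)
        i = 0 if pred is Occlusion.RESIDUAL else 1
        j = 0 if outcome is Outcome.BAD else 1
        counts[i, j] += 1
        if (pred is Occlusion.RESIDUAL) != (outcome is Outcome.BAD):
            miss += 1
    table = ContingencyTable2x2(*counts.ravel().tolist())
    return ThresholdResult(
        table=table,
        fisher_p=fisher_exact_2x2(table),
        misclassified=miss,
        n=len(eligible),
    )
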