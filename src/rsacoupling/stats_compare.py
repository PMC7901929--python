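"""Group comparisons of the coupling indices.

Paired index triples (Px, Pxl, Pxk) over epochs are compared with the
Friedman test for repeated measures; independent groups (e.g. sleep stages)
with the Kruskal-Wallis test.  Pairwise follow-ups — Wilcoxon signed-rank
for paired columns, rank-sum for independent groups — are Bonferroni
corrected, with significance stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .svr_coupling import CouplingResult

logger = logging.getLogger(__name__)

__all__ = ["PairwiseComparison", "ComparisonReport",
           "compare_indices", "compare_groups", "stars_for"]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for(p_adjusted: float) -> str:
    """Significance stars from an adjusted p-value (ns above 0.05)."""
    for thr, mark in _STAR_THRESHOLDS:
        if p_adjusted < thr:
            return mark
    return "ns"


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    p_raw: float
    p_adjusted: float
    significant: bool
    stars: str


@dataclass
class ComparisonReport:
    test_name: str
    statistic: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "pairwise": [
                {"pair": list(pc.pair), "p_raw": pc.p_raw,
                 "p_adjusted": pc.p_adjusted,
                 "significant": pc.significant, "stars": pc.stars}
                for pc in self.pairwise
            ],
        }


def _bonferroni(pairs: list[tuple[tuple[str, str], float]]
                ) -> list[PairwiseComparison]:
    m = len(pairs)
    out = []
    for pair, p_raw in pairs:
        p_adj = min(1.0, p_raw * m)
        out.append(PairwiseComparison(
            pair=pair, p_raw=float(p_raw), p_adjusted=float(p_adj),
            significant=bool(p_adj < 0.05), stars=stars_for(p_adj),
        ))
    return out


def compare_indices(
    results: list[CouplingResult] | np.ndarray,
    which: tuple[str, ...] = ("Px", "Pxl", "Pxk"),
) -> ComparisonReport:
    """Friedman test across paired index columns over epochs.

    Accepts either CouplingResult objects or a (n_epochs, n_indices) array in
    the column order of ``which``.  Epochs with a non-finite entry are
    dropped; at least 10 complete rows are required.  Pairwise Wilcoxon
    signed-rank follow-ups are Bonferroni corrected.
    """
    if len(which) < 2:
        raise ValueError("need at least two indices to compare")
    if isinstance(results, np.ndarray):
        mat = np.asarray(results, dtype=float)
        if mat.shape[1] != len(which):
            raise ValueError("column count does not match 'which'")
    else:
        mat = np.array([[getattr(r, w) for w in which] for r in results],
                       dtype=float)
    keep = np.all(np.isfinite(mat), axis=1)
    if np.any(~keep):
        logger.info("dropping %d incomplete epochs", int((~keep).sum()))
        mat = mat[keep]
    if mat.shape[0] < 10:
        raise ValueError(f"need >= 10 complete epochs, got {mat.shape[0]}")

    if np.all(mat == mat[:, [0]]):
        # every row fully tied: no rank differences (scipy's tie correction
        # degenerates to 0/0 here)
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(
            *(mat[:, j] for j in range(mat.shape[1])))
    pairs = []
    for i, j in itertools.combinations(range(len(which)), 2):
        d = mat[:, i] - mat[:, j]
        if np.allclose(d, 0):
            p_raw = 1.0
        else:
            p_raw = stats.wilcoxon(mat[:, i], mat[:, j]).pvalue
        pairs.append(((which[i], which[j]), p_raw))
    return ComparisonReport(
        test_name="friedman", statistic=float(stat), p_value=float(p),
        pairwise=_bonferroni(pairs),
    )


def compare_groups(values_by_group: dict[str, np.ndarray]) -> ComparisonReport:
    """Kruskal-Wallis across independent groups with rank-sum follow-ups."""
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for name, v in groups.items():
        if len(v) < 5:
            raise ValueError(f"group {name!r} has fewer than 5 values")
    stat, p = stats.kruskal(*groups.values())
    pairs = []
    for a, b in itertools.combinations(groups, 2):
        p_raw = stats.mannwhitneyu(groups[a], groups[b],
                                   alternative="two-sided").pvalue
        pairs.append(((a, b), p_raw))
    return ComparisonReport(
        test_name="kruskal_wallis", statistic=float(stat), p_value=float(p),
        pairwise=_bonferroni(pairs),
    )
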