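"""Second-level (group) statistics across subjects.

Per-subject effect estimates (brain scores, gains, importances) are tested
against zero with two-sided Wilcoxon signed-rank tests across subjects;
p-values over voxels/channels/times are corrected jointly with the
Benjamini/Hochberg false discovery rate; uncertainty is summarized as the
standard error of the mean (SEM) across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .data import ScoreMap

__all__ = [
    "wilcoxon_vs_zero",
    "fdr_bh",
    "GroupResult",
    "group_map",
]


def wilcoxon_vs_zero(values: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for a one-sample test.

    Zero differences are dropped (Wilcoxon's original rule). The exact
    null distribution is used for n ≤ 25 without ties, the tie-corrected
    normal approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    nz = values[values != 0]
    if nz.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "approx" if (nz.size > 25 or has_ties) else "exact"
    res = sp_stats.wilcoxon(
        nz, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.pvalue)


def fdr_bh(
    pvalues: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini/Hochberg step-up: returns (adjusted p, rejection mask)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class GroupResult:
    """Across-subject summary per target location."""

    mean: np.ndarray
    sem: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    tested: np.ndarray  # False where any subject was degenerate
    shape: tuple

    def n_significant(self) -> int:
        return int(self.significant.sum())


def group_map(
    score_maps: list[ScoreMap], q: float = 0.05
) -> GroupResult:
    """Wilcoxon-vs-zero + joint BH FDR over all locations of a score map.

    All subjects must share the target grid. Locations degenerate in any
    subject are excluded from testing (p = 1, never significant) but keep
    their across-subject mean/SEM. For MEG maps the correction pools
    space and time jointly.
    """
    if len(score_maps) < 2:
        raise ValueError("group statistics require at least 2 subjects")
    shape = score_maps[0].scores.shape
    for sm in score_maps:
        if sm.scores.shape != shape:
            raise ValueError("score maps must share one target grid")
    data = np.stack([sm.scores.reshape(-1) for sm in score_maps])
    degen = np.stack(
        [sm.degenerate.reshape(-1) for sm in score_maps]
    ).any(axis=0)
    n_subj, n_loc = data.shape
    mean = data.mean(axis=0)
    sem = data.std(axis=0, ddof=1) / np.sqrt(n_subj)
    p = np.ones(n_loc)
    tested = ~degen
    for i in np.nonzero(tested)[0]:
        p[i] = wilcoxon_vs_zero(data[:, i])
    p_adj = np.ones(n_loc)
    significant = np.zeros(n_loc, dtype=bool)
    if tested.any():
        adj, rej = fdr_bh(p[tested], q=q)
        p_adj[tested] = adj
        significant[tested] = rej
    return GroupResult(
        mean=mean.reshape(shape), sem=sem.reshape(shape),
        p=p.reshape(shape), p_adj=p_adj.reshape(shape),
        significant=significant.reshape(shape),
        tested=tested.reshape(shape), shape=shape,
    )
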