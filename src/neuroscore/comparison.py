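"""Gain decomposition, layer profiles, and convergence across checkpoints.

The gain ΔR of a higher-level embedding M1 over a lower-level embedding M2
is the elementwise difference of their brain scores on the same targets,
R_M1 − R_M2; it attributes predictive signal to the representational level
added by M1. Convergence is the per-subject Pearson correlation between a
family of checkpoints' average brain scores and their language accuracy
(or training step): positive correlations indicate that models converge
toward brain-like representations as they learn, negative ones divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ModelCard, ScoreMap
from .extraction import middle_layers

__all__ = [
    "DeltaMap",
    "gain",
    "average_scores",
    "build_comparison_table",
    "convergence",
    "layer_profile",
    "residualize_embedding",
]


@dataclass
class DeltaMap:
    """Elementwise brain-score difference R_M1 − R_M2 for one subject."""

    subject_id: int
    values: np.ndarray
    degenerate: np.ndarray
    card_m1: ModelCard
    card_m2: ModelCard


def gain(score_m1: ScoreMap, score_m2: ScoreMap) -> DeltaMap:
    """ΔR = R_M1 − R_M2 on identical targets of the same subject."""
    if score_m1.subject_id != score_m2.subject_id:
        raise ValueError("gain requires score maps of the same subject")
    if score_m1.scores.shape != score_m2.scores.shape:
        raise ValueError("gain requires score maps on the same target grid")
    return DeltaMap(
        subject_id=score_m1.subject_id,
        values=score_m1.scores - score_m2.scores,
        degenerate=score_m1.degenerate | score_m2.degenerate,
        card_m1=score_m1.card,
        card_m2=score_m2.card,
    )


def average_scores(
    smap: ScoreMap | DeltaMap,
    mask: np.ndarray | None = None,
    time_indices: np.ndarray | None = None,
) -> float:
    """Masked mean score across spatial (and temporal) dimensions.

    Degenerate targets are excluded. ``time_indices`` restricts a MEG map
    to a subsampled time axis (e.g. ten samples regularly spread over the
    epoch) before averaging.
    """
    values = smap.values if isinstance(smap, DeltaMap) else smap.scores
    keep = ~smap.degenerate
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape[:mask.ndim]:
            raise ValueError("mask shape does not match the score map")
        keep = keep & (mask if mask.ndim == values.ndim else mask[:, None])
    if time_indices is not None:
        if values.ndim != 2:
            raise ValueError("time_indices applies to channels × times maps")
        sel = np.zeros(values.shape[1], dtype=bool)
        sel[np.asarray(time_indices, int)] = True
        keep = keep & sel[None, :]
    if not keep.any():
        raise ValueError("empty mask: nothing to average")
    return float(values[keep].mean())


def build_comparison_table(
    score_maps: list[ScoreMap],
    mask: np.ndarray | None = None,
    time_indices: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per (embedding, subject) with the spatially averaged score.

    The averaging settings (mask / time subsampling) are recorded in the
    table attrs so downstream analyses know what was averaged.
    """
    rows = []
    for sm in score_maps:
        c = sm.card
        rows.append(dict(
            subject_id=sm.subject_id, name=c.name, task=c.task,
            n_layers=c.n_layers, dim=c.dim, n_heads=c.n_heads,
            training_step=c.training_step, accuracy_top1=c.accuracy_top1,
            layer_index=c.layer_index, layer_position=c.layer_position,
            score=average_scores(sm, mask=mask, time_indices=time_indices),
        ))
    table = pd.DataFrame(rows)
    table.attrs["mask"] = None if mask is None else np.asarray(mask)
    table.attrs["time_indices"] = time_indices
    return table


def _constant(v: np.ndarray) -> bool:
    # tolerance absorbs pairwise-summation noise on literally equal values
    return v.std() <= 1e-12 * max(1.0, float(np.abs(v).max()))


def convergence(
    table: pd.DataFrame, key: str = "accuracy_top1"
) -> pd.DataFrame:
    """Per-subject Pearson r between average brain score and ``key``.

    ``key`` is ``accuracy_top1`` (language performance) or
    ``training_step``. Constant scores or keys yield r = 0 with a
    degenerate flag rather than NaN.
    """
    if key not in ("accuracy_top1", "training_step"):
        raise ValueError("key must be accuracy_top1 or training_step")
    out = []
    for subj, grp in table.groupby("subject_id", sort=True):
        x = grp[key].to_numpy(dtype=float)
        y = grp["score"].to_numpy(dtype=float)
        if _constant(x) or _constant(y) or len(x) < 2:
            out.append(dict(subject_id=subj, r=0.0, degenerate=True))
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            out.append(dict(subject_id=subj, r=r, degenerate=False))
    return pd.DataFrame(out)


def layer_profile(table: pd.DataFrame) -> tuple[pd.DataFrame, int, bool]:
    """Mean score per layer and whether the best layer is a middle layer.

    Returns ``(profile, best_layer, best_is_middle)`` where profile has one
    row per layer_index with the mean score across subjects (and steps).
    """
    prof = (
        table.groupby("layer_index", sort=True)["score"]
        .mean()
        .reset_index()
    )
    best = int(prof.loc[prof["score"].idxmax(), "layer_index"])
    n_layers = int(table["n_layers"].iloc[0])
    try:
        in_middle = best in middle_layers(n_layers)
    except ValueError:
        in_middle = False
    return prof, best, in_middle


def residualize_embedding(
    values_m1: np.ndarray,
    values_m2: np.ndarray,
    train_mask: np.ndarray,
) -> np.ndarray:
    """Optional orthogonalization: remove M2's span from M1.

    Least-squares projection of M1 onto M2 is fitted on the training words
    only and subtracted everywhere, giving the part of M1 not linearly
    explained by M2. Not used by default; raw score differences are the
    primary comparison.
    """
    X = np.asarray(values_m2, float)
    Y = np.asarray(values_m1, float)
    B, *_ = np.linalg.lstsq(X[train_mask], Y[train_mask], rcond=None)
    return Y - X @ B
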