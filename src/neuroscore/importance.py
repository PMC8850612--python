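"""Random-forest prediction of brain scores and permutation importance.

Which property of a language model makes its embeddings brain-like? A
random forest is fitted, for each subject separately, from seven model
properties — training task (causal vs masked), number of attention heads,
number of layers, dimensionality, training step, top-1 language accuracy,
and layer position — to the model's average brain score, evaluated with a
Pearson R under 5-fold cross-validation across models. The permutation
importance ΔR of a property is the mean decrease in held-out R when that
property's column is shuffled (50 repetitions) within the held-out fold,
averaged across folds: ΔR ≈ 0 for properties that do not matter, positive
for those that do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .stats import wilcoxon_vs_zero

__all__ = [
    "FEATURES",
    "ImportanceResult",
    "build_property_table",
    "fit_importance",
    "rank_and_compare",
]

#: Model properties fed to the forest, in canonical order.
FEATURES = [
    "task",
    "n_heads",
    "n_layers",
    "dim",
    "training_step",
    "accuracy_top1",
    "layer_position",
]


@dataclass
class ImportanceResult:
    """Per-subject permutation importances and forest fit quality."""

    subject_id: int
    fit_r: float  # CV Pearson R of the forest itself
    delta_r: pd.Series  # mean held-out R decrease per feature
    degenerate: bool = False


def build_property_table(comparison_table: pd.DataFrame) -> pd.DataFrame:
    """PropertyTable: the seven features + per-subject average score.

    Input is the (embedding, subject) comparison table; the categorical
    task is encoded as a binary indicator (masked = 1, causal = 0).
    """
    df = comparison_table.copy()
    if df["score"].isna().any():
        raise ValueError("PropertyTable requires a score for every row")
    df["task"] = (df["task"] == "masked").astype(float)
    return df[["subject_id", *FEATURES, "score"]]


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator):
    order = rng.permutation(n)
    return np.array_split(order, n_folds)


def fit_importance(
    table: pd.DataFrame,
    n_trees: int = 500,
    n_repeats: int = 50,
    n_folds: int = 5,
    seed: int = 0,
) -> list[ImportanceResult]:
    """Permutation feature importance, one result per subject.

    Per subject: a RandomForestRegressor is fitted on each of ``n_folds``
    CV training splits (rows = embeddings); fit quality is the Pearson R
    between held-out scores and predictions pooled over folds. For each
    feature, the column is shuffled within the held-out fold
    ``n_repeats`` times and the mean decrease in held-out R, averaged
    across folds, is reported.
    """
    results = []
    for subj, grp in table.groupby("subject_id", sort=True):
        X = grp[FEATURES].to_numpy(dtype=float)
        y = grp["score"].to_numpy(dtype=float)
        n = len(y)
        if n < 2 * n_folds:
            raise ValueError(
                f"subject {subj}: {n} rows cannot support {n_folds} folds"
            )
        if np.std(y) == 0:
            results.append(ImportanceResult(
                subject_id=subj, fit_r=0.0,
                delta_r=pd.Series(0.0, index=FEATURES), degenerate=True,
            ))
            continue
        rng = np.random.default_rng([seed, int(subj)])
        folds = _fold_indices(n, n_folds, rng)
        drops = np.zeros((n_folds, len(FEATURES)))
        truth_all, pred_all = [], []
        for f, test in enumerate(folds):
            train = np.setdiff1d(np.arange(n), test)
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
            )
            forest.fit(X[train], y[train])
            base_pred = forest.predict(X[test])
            truth_all.append(y[test])
            pred_all.append(base_pred)
            base_r = _pearson(y[test], base_pred)
            # batch all shuffled copies into one predict call per feature
            for j in range(len(FEATURES)):
                stacked = np.tile(X[test], (n_repeats, 1, 1))
                for rep in range(n_repeats):
                    stacked[rep, :, j] = rng.permutation(stacked[rep, :, j])
                preds = forest.predict(
                    stacked.reshape(-1, len(FEATURES))
                ).reshape(n_repeats, -1)
                rs = np.array(
                    [_pearson(y[test], p) for p in preds]
                )
                drops[f, j] = base_r - rs.mean()
        fit_r = _pearson(np.concatenate(truth_all), np.concatenate(pred_all))
        results.append(ImportanceResult(
            subject_id=subj, fit_r=fit_r,
            delta_r=pd.Series(drops.mean(axis=0), index=FEATURES),
        ))
    return results


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rank_and_compare(
    results: list[ImportanceResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order features by mean ΔR and test adjacent pairs across subjects.

    Returns ``(ranking, pairs)``: ranking has one row per feature with the
    across-subject mean and SEM of ΔR; pairs holds the Wilcoxon signed-rank
    p-value for each adjacent pair in the ranking (no pairs for a single
    feature).
    """
    mat = pd.DataFrame(
        {r.subject_id: r.delta_r for r in results}
    ).T  # subjects × features
    order = mat.mean(axis=0).sort_values(ascending=False).index
    n = mat.shape[0]
    ranking = pd.DataFrame({
        "feature": order,
        "mean_delta_r": mat[order].mean(axis=0).to_numpy(),
        "sem": mat[order].std(axis=0, ddof=1).to_numpy() / np.sqrt(n),
    })
    pairs = []
    for a, b in zip(order, order[1:]):
        diff = (mat[a] - mat[b]).to_numpy()
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = wilcoxon_vs_zero(diff)
        pairs.append(dict(top=a, runner_up=b, p=p))
    return ranking, pd.DataFrame(pairs)
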