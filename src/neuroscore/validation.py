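"""Ground-truth recovery studies on synthetic data.

Every analysis stage of the package is validated by planting a known
structure with the synthetic generator and measuring whether the pipeline
recovers it: ridge weights against the closed form, brain scores against
noise-free and pure-noise limits, FIR delay recovery, noise-ceiling
behaviour, gain decomposition, convergence, and permutation-importance
recovery, plus the calibration of the group-level false discovery rate
under a full null. The study sizes here are deliberately compact — a few
hundred words, tens of channels — which is ample for the planted effects
being recovered; each function documents its own conditions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sp_stats

from .comparison import average_scores, build_comparison_table, convergence, gain
from .data import BrainRecording
from .encoding import (
    DEFAULT_ALPHAS,
    DEFAULT_DELAYS,
    CVScheme,
    fir_delay_profile,
    ridge_closed_form,
    ridge_fit,
)
from .importance import build_property_table, fit_importance
from .simulate import canonical_embeddings, make_brain, make_embedding_family, make_stimuli
from .stats import group_map, wilcoxon_vs_zero
from . import encoding as enc

__all__ = [
    "ridge_oracle_check",
    "recovery_study",
    "null_calibration",
    "fir_delay_study",
    "ceiling_study",
    "gain_study",
    "convergence_study",
    "importance_study",
    "synthetic_property_table",
]


def _stimuli(seed: int, short: bool = True, n_subjects: int = 1):
    """Default study stream: 25 sentences = 5 blocks of 5.

    ``short`` uses 4–6-word sentences to keep scoring loops fast; the
    full 9–15-word protocol is exercised where word-level statistics
    matter.
    """
    rng_span = (4, 6) if short else (9, 15)
    return make_stimuli(n_sentences=25, words_per_sentence=rng_span,
                        n_subjects=n_subjects, seed=seed)


# ---------------------------------------------------------------------------
# Ridge oracle
# ---------------------------------------------------------------------------

def explicit_loo_curve(X, Y, alphas) -> np.ndarray:
    """Brute-force LOO oracle: refit ridge without each sample in turn."""
    n = X.shape[0]
    out = np.zeros((len(alphas), Y.shape[1]))
    for a, lam in enumerate(alphas):
        errs = np.zeros((n, Y.shape[1]))
        for i in range(n):
            m = np.ones(n, dtype=bool)
            m[i] = False
            W = ridge_closed_form(X[m], Y[m], lam)
            errs[i] = (Y[i] - X[i] @ W) ** 2
        out[a] = errs.mean(axis=0)
    return out


def ridge_oracle_check(n_instances: int = 50, seed: int = 0) -> dict:
    """Max deviations of ridge_fit from the closed form and explicit LOO.

    Random instances with n_words ≤ 30, o ≤ 8, n_targets ≤ 6.
    """
    rng = np.random.default_rng(seed)
    max_w = 0.0
    max_loo = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 31))
        o = int(rng.integers(2, 9))
        t = int(rng.integers(1, 7))
        X = rng.standard_normal((n, o))
        Y = X @ rng.standard_normal((o, t)) + rng.standard_normal((n, t))
        fit = ridge_fit(X, Y)
        oracle = explicit_loo_curve(X, Y, DEFAULT_ALPHAS)
        max_loo = max(max_loo, float(np.abs(fit.loo_mse - oracle).max()))
        for j in range(t):
            ref = ridge_closed_form(X, Y[:, [j]], fit.alpha_per_target[j])
            max_w = max(max_w, float(np.abs(fit.W[:, j] - ref[:, 0]).max()))
    return {"max_weight_error": max_w, "max_loo_error": max_loo}


# ---------------------------------------------------------------------------
# Brain-score recovery and null level
# ---------------------------------------------------------------------------

def recovery_study(seed: int = 0) -> dict:
    """fMRI brain scores at SNR → ∞, SNR 1, and on pure noise.

    One subject, 20 channels (half responsive), 25 sentences of 9–15
    words, compositional generator. Returns mean scores over responsive
    channels (and over all channels for the null).
    """
    st = _stimuli(seed, short=False)
    emb = canonical_embeddings(st, dim=8, seed=seed)["compositional"]
    cv = CVScheme(seed=seed)
    out = {}
    recs, truth = make_brain(st, emb, n_subjects=1, n_channels=20,
                             snr=np.inf, seed=seed)
    sm = enc.brain_score_fmri(emb, recs[0], st, cv)
    out["noise_free_mean"] = float(sm.scores[truth.responsive_mask].mean())
    recs1, truth1 = make_brain(st, emb, n_subjects=1, n_channels=20,
                               snr=1.0, seed=seed)
    sm1 = enc.brain_score_fmri(emb, recs1[0], st, cv)
    out["snr1_mean"] = float(sm1.scores[truth1.responsive_mask].mean())
    rng = np.random.default_rng([seed, 77])
    null_rec = BrainRecording(
        subject_id=0, modality="fmri",
        data=rng.standard_normal(recs[0].data.shape), tr=2.0,
    )
    smn = enc.brain_score_fmri(emb, null_rec, st, cv)
    out["null_mean"] = float(smn.scores.mean())
    out["null_se"] = float(
        smn.scores.std(ddof=1) / np.sqrt(smn.scores.size)
    )
    return out


# ---------------------------------------------------------------------------
# Group-level FDR calibration under the full null
# ---------------------------------------------------------------------------

def null_calibration(
    n_replicates: int = 200,
    n_subjects: int = 20,
    n_locations: int = 200,
    seed: int = 0,
) -> dict:
    """Empirical FDR of group_map on pure-noise recordings.

    Each replicate scores ``n_subjects`` independent white-noise
    recordings against a fixed embedding and runs the Wilcoxon + BH group
    analysis over ``n_locations`` voxels; under the full null every
    discovery is false, so the false-discovery proportion is 1 whenever
    anything is selected.
    """
    st = _stimuli(seed, short=True)
    emb = canonical_embeddings(st, dim=6, seed=seed)["compositional"]
    cv = CVScheme(seed=seed)
    n_scans = int(np.ceil((st.end_time() + 12.0) / 2.0))
    fdp = np.zeros(n_replicates)
    all_scores = np.empty((n_replicates, n_subjects, n_locations))
    for rep in range(n_replicates):
        maps = []
        for subj in range(n_subjects):
            rng = np.random.default_rng([seed, 11, rep, subj])
            rec = BrainRecording(
                subject_id=subj, modality="fmri",
                data=rng.standard_normal((n_scans, n_locations)), tr=2.0,
            )
            sm = enc.brain_score_fmri(emb, rec, st, cv)
            maps.append(sm)
            all_scores[rep, subj] = sm.scores
        g = group_map(maps, q=0.05)
        fdp[rep] = 1.0 if g.n_significant() > 0 else 0.0
    flat = all_scores.reshape(-1, n_locations)
    loc_mean = flat.mean(axis=0)
    loc_se = flat.std(axis=0, ddof=1) / np.sqrt(flat.shape[0])
    z = loc_mean / loc_se
    return {
        "empirical_fdr": float(fdp.mean()),
        "fdr_mc_se": float(fdp.std(ddof=1) / np.sqrt(n_replicates)),
        "frac_locations_beyond_3se": float((np.abs(z) > 3).mean()),
        "grand_mean_score": float(flat.mean()),
        "grand_se": float(flat.mean(axis=1).std(ddof=1)
                          / np.sqrt(flat.shape[0])),
    }


# ---------------------------------------------------------------------------
# FIR delay recovery
# ---------------------------------------------------------------------------

def fir_delay_study(n_seeds: int = 40, snr: float = 10.0,
                    seed: int = 0) -> dict:
    """Recover the planted hemodynamic delay from FIR weight norms.

    For each run a one-hot kernel delay d ∈ {2,4,6,8,10} s is planted and
    the delay block with the largest ridge weight norm (summed over CV
    folds) is read off.
    """
    st = _stimuli(seed, short=True)
    emb = canonical_embeddings(st, dim=6, seed=seed)["compositional"]
    cv = CVScheme(seed=seed)
    hits = 0
    for k in range(n_seeds):
        delay = DEFAULT_DELAYS[k % len(DEFAULT_DELAYS)]
        recs, _ = make_brain(
            st, emb, n_subjects=1, n_channels=10, snr=snr,
            kernel=("onehot", delay), seed=seed * 1000 + k + 1,
        )
        _, fits = enc.brain_score_fmri(emb, recs[0], st, cv,
                                       return_fits=True)
        prof = np.sum([fir_delay_profile(f, emb.dim) for f in fits],
                      axis=0)
        if DEFAULT_DELAYS[int(np.argmax(prof))] == delay:
            hits += 1
    return {"hit_rate": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# Noise ceiling behaviour
# ---------------------------------------------------------------------------

def ceiling_study(n_seeds: int = 30, seed: int = 0) -> dict:
    """Identical-subject exactness and gain from larger templates.

    Part 1: four subjects with literally identical recordings — the
    ceiling must be 1 everywhere. Part 2: paired over seeds, the ceiling
    of a noisy subject from a 6-subject template vs a 1-subject template;
    a sign test checks the positive direction.
    """
    st = _stimuli(seed, short=True, n_subjects=7)
    emb = canonical_embeddings(st, dim=6, seed=seed)["compositional"]
    cv = CVScheme(seed=seed)
    recs, _ = make_brain(st, emb, n_subjects=1, n_channels=10, snr=1.0,
                         seed=seed)
    idents = [
        BrainRecording(subject_id=i, modality="fmri",
                       data=recs[0].data.copy(), tr=recs[0].tr)
        for i in range(4)
    ]
    c = enc.noise_ceiling(idents, 0, st, cv)
    max_dev = float(np.abs(c.scores - 1.0).max())

    wins = 0
    diffs = []
    for k in range(n_seeds):
        recs_k, truth_k = make_brain(
            st, emb, n_subjects=7, n_channels=10, snr=0.5,
            seed=seed * 1000 + k + 1,
        )
        cv_k = CVScheme(seed=k)
        few = enc.noise_ceiling(recs_k[:2], 0, st, cv_k)
        many = enc.noise_ceiling(recs_k, 0, st, cv_k)
        resp = truth_k.responsive_mask
        d = many.scores[resp].mean() - few.scores[resp].mean()
        diffs.append(float(d))
        wins += int(d > 0)
    sign_p = float(sp_stats.binomtest(
        wins, n_seeds, 0.5, alternative="greater"
    ).pvalue)
    return {
        "identical_max_dev": max_dev,
        "wins": wins,
        "n_seeds": n_seeds,
        "sign_test_p": sign_p,
        "mean_ceiling_gain": float(np.mean(diffs)),
    }


# ---------------------------------------------------------------------------
# Gain decomposition
# ---------------------------------------------------------------------------

def gain_study(n_subjects: int = 20, seed: int = 0) -> dict:
    """Group-level gain of the compositional over the lexical embedding.

    Brain responses are generated from the compositional level at SNR 1;
    both embeddings are scored per subject and the per-subject average
    gains are tested against zero with a Wilcoxon signed-rank test.
    """
    st = _stimuli(seed, short=True)
    levels = canonical_embeddings(st, dim=6, seed=seed)
    cv = CVScheme(seed=seed)
    recs, truth = make_brain(
        st, levels["compositional"], n_subjects=n_subjects, n_channels=12,
        snr=1.0, seed=seed,
    )
    gains = []
    for rec in recs:
        s_comp = enc.brain_score_fmri(levels["compositional"], rec, st, cv)
        s_lex = enc.brain_score_fmri(levels["lexical"], rec, st, cv)
        gains.append(average_scores(gain(s_comp, s_lex),
                                    mask=truth.responsive_mask))
    gains = np.asarray(gains)
    return {
        "mean_gain": float(gains.mean()),
        "wilcoxon_p": wilcoxon_vs_zero(gains),
        "n_subjects": n_subjects,
    }


# ---------------------------------------------------------------------------
# Convergence across checkpoints
# ---------------------------------------------------------------------------

def convergence_study(n_seeds: int = 20, n_steps: int = 10,
                      seed: int = 0) -> dict:
    """Recover the planted accuracy → brain-score link.

    Per seed: a 10-checkpoint × 3-representation family (word-embedding
    layer + two contextual layers) with a linear mixing curve; responses
    generated from the deepest final-checkpoint embedding; convergence is
    the per-subject correlation between average brain score and planted
    accuracy. A shuffled-accuracy null is computed alongside.
    """
    st = _stimuli(seed, short=True)
    cv = CVScheme(seed=seed)
    rs, null_rs = [], []
    for k in range(n_seeds):
        fam_seed = seed * 1000 + k + 1
        family, truth = make_embedding_family(
            st, dim=6, n_layers=2, n_steps=n_steps, seed=fam_seed,
        )
        generator = next(
            e for e in family
            if e.card.training_step == n_steps - 1
            and e.card.layer_index == 2
        )
        recs, _ = make_brain(st, generator, n_subjects=1, n_channels=12,
                             snr=1.0, seed=fam_seed)
        maps = [enc.brain_score_fmri(e, recs[0], st, cv) for e in family]
        table = build_comparison_table(maps)
        rs.append(float(convergence(table, "accuracy_top1")["r"].iloc[0]))
        rng = np.random.default_rng([seed, 13, k])
        y = table.groupby("training_step")["score"].mean().to_numpy()
        acc = truth.accuracy_curve.copy()
        rng.shuffle(acc)
        null_rs.append(float(np.corrcoef(acc, y)[0, 1]))
    rs = np.asarray(rs)
    null_rs = np.asarray(null_rs)
    return {
        "median_r": float(np.median(rs)),
        "null_mean": float(null_rs.mean()),
        "null_se": float(null_rs.std(ddof=1) / np.sqrt(n_seeds)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Permutation-importance recovery
# ---------------------------------------------------------------------------

def synthetic_property_table(
    n_rows: int = 45,
    subjects=(0,),
    seed: int = 0,
    noise: float = 0.0,
):
    """Random model properties with a score that is a pure function of
    the planted accuracy (plus optional noise); all other properties are
    drawn independently."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for subj in subjects:
        for i in range(n_rows):
            acc = float(rng.uniform(0, 0.5))
            rows.append(dict(
                subject_id=subj,
                task=str(rng.choice(["causal", "masked"])),
                n_heads=int(rng.choice([4, 8])),
                n_layers=int(rng.choice([4, 8, 12])),
                dim=int(rng.choice([128, 256, 512])),
                training_step=int(rng.integers(0, 4_500_000)),
                accuracy_top1=acc,
                layer_position=float(rng.uniform(0, 1)),
                score=0.1 * np.sin(6 * acc) + 0.3 * acc
                + noise * rng.standard_normal(),
            ))
    return build_property_table(pd.DataFrame(rows))


def importance_study(n_seeds: int = 40, seed: int = 0) -> dict:
    """Accuracy must dominate when the score is a function of accuracy.

    Per seed, one subject with 45 models; the forest's permutation
    importances are ranked. Reports how often accuracy ranks first and
    the across-seed mean ± SE of an independent feature's ΔR (n_heads).
    """
    top = 0
    indep = []
    for k in range(n_seeds):
        table = synthetic_property_table(seed=seed * 1000 + k + 1)
        res = fit_importance(table, n_trees=100, n_repeats=50,
                             seed=seed * 1000 + k + 1)[0]
        if res.delta_r.idxmax() == "accuracy_top1":
            top += 1
        indep.append(res.delta_r["n_heads"])
    indep = np.asarray(indep)
    return {
        "accuracy_top_rate": top / n_seeds,
        "n_seeds": n_seeds,
        "independent_delta_r_mean": float(indep.mean()),
        "independent_delta_r_se": float(indep.std(ddof=1)
                                        / np.sqrt(n_seeds)),
    }
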