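"""End-to-end orchestration of the synthetic study.

``run(config, outdir)`` executes the full sequence —
simulate → extract → score → ceiling → compare → importance → report —
on synthetic data with planted ground truth, writing TSV/HDF5 artifacts
and a JSON manifest (config, seeds, content hashes) so any run is
reproducible bit-identically from (config, seed). Stages consume the
artifacts of earlier stages and fail with a dependency error naming the
missing stage if run out of order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import build_comparison_table, convergence, gain, layer_profile
from .data import write_arrays, write_stimuli
from .encoding import CVScheme, brain_score_fmri, noise_ceiling
from .importance import build_property_table, fit_importance, rank_and_compare
from .simulate import canonical_embeddings, make_brain, make_embedding_family, make_stimuli
from .stats import group_map

__all__ = ["RunConfig", "run", "DependencyError"]


class DependencyError(RuntimeError):
    """A pipeline stage was asked to run before its inputs exist."""


@dataclass
class RunConfig:
    """Parameters of one synthetic end-to-end run."""

    seed: int = 0
    modality: str = "fmri"
    n_sentences: int = 30
    n_subjects: int = 6
    n_channels: int = 40
    dim: int = 12
    n_layers: int = 3
    n_steps: int = 6
    snr: float = 1.0
    responsive_fraction: float = 0.5
    shared_noise_fraction: float = 0.3
    n_folds: int = 5
    stages: tuple = (
        "simulate", "extract", "score", "ceiling",
        "compare", "importance", "report",
    )
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    art: dict = {}
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "hashes": {},
        "stages": [],
    }
    cv = CVScheme(n_folds=config.n_folds, seed=config.seed)

    def need(key: str, stage: str):
        if key not in art:
            raise DependencyError(
                f"stage {stage!r} needs artifact {key!r}; run its "
                "producing stage first"
            )
        return art[key]

    for stage in config.stages:
        if stage == "simulate":
            stimuli = make_stimuli(
                n_sentences=config.n_sentences,
                n_subjects=config.n_subjects, seed=config.seed,
            )
            family, fam_truth = make_embedding_family(
                stimuli, dim=config.dim, n_layers=config.n_layers,
                n_steps=config.n_steps, seed=config.seed,
            )
            levels = canonical_embeddings(
                stimuli, dim=config.dim, seed=config.seed
            )
            recordings, brain_truth = make_brain(
                stimuli, levels["compositional"],
                n_subjects=config.n_subjects,
                n_channels=config.n_channels,
                responsive_fraction=config.responsive_fraction,
                snr=config.snr, modality=config.modality,
                shared_noise_fraction=config.shared_noise_fraction,
                seed=config.seed,
            )
            art.update(stimuli=stimuli, family=family,
                       fam_truth=fam_truth, levels=levels,
                       recordings=recordings, brain_truth=brain_truth)
            write_stimuli(stimuli, outdir / "stimuli.tsv")
            write_arrays(outdir / "arrays.h5", stimuli=stimuli,
                         embeddings=family + list(levels.values()),
                         recordings=recordings, mode="w")
            manifest["hashes"]["brain"] = [
                _hash_array(r.data) for r in recordings
            ]
        elif stage == "extract":
            # embeddings for this study come from the planted family;
            # stage kept for provider-based runs and dependency checking
            need("stimuli", stage)
            need("family", stage)
        elif stage == "score":
            stimuli = need("stimuli", stage)
            recordings = need("recordings", stage)
            embeddings = need("family", stage) + list(
                need("levels", stage).values()
            )
            maps = {}
            for emb in embeddings:
                for rec in recordings:
                    maps[(emb.card.key(), rec.subject_id)] = brain_score_fmri(
                        emb, rec, stimuli, cv
                    )
            art["score_maps"] = maps
            manifest["hashes"]["scores"] = _hash_array(np.concatenate(
                [m.scores for m in maps.values()]
            ))
        elif stage == "ceiling":
            stimuli = need("stimuli", stage)
            recordings = need("recordings", stage)
            ceilings = {
                rec.subject_id: noise_ceiling(
                    recordings, rec.subject_id, stimuli, cv
                )
                for rec in recordings
            }
            art["ceilings"] = ceilings
            pd.DataFrame({
                "subject_id": list(ceilings),
                "ceiling": [
                    float(c.scores[~c.degenerate].mean())
                    for c in ceilings.values()
                ],
            }).to_csv(outdir / "ceiling.tsv", sep="\t", index=False)
        elif stage == "compare":
            maps = need("score_maps", stage)
            levels = need("levels", stage)
            recordings = need("recordings", stage)
            family = need("family", stage)
            fam_maps = [
                maps[(emb.card.key(), rec.subject_id)]
                for emb in family for rec in recordings
            ]
            table = build_comparison_table(fam_maps)
            table.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
            conv = convergence(table, "accuracy_top1")
            conv.to_csv(outdir / "convergence.tsv", sep="\t", index=False)
            profile, best, in_middle = layer_profile(table)
            profile.to_csv(outdir / "layer_profile.tsv", sep="\t",
                           index=False)
            gains = [
                gain(maps[(levels["compositional"].card.key(), r.subject_id)],
                     maps[(levels["lexical"].card.key(), r.subject_id)])
                for r in recordings
            ]
            art.update(table=table, convergence=conv, gains=gains,
                       best_layer=best, best_in_middle=in_middle)
        elif stage == "importance":
            table = need("table", stage)
            prop = build_property_table(table)
            results = fit_importance(prop, n_trees=100, seed=config.seed)
            ranking, pairs = rank_and_compare(results)
            ranking.to_csv(outdir / "importance.tsv", sep="\t", index=False)
            art.update(importance=results, ranking=ranking,
                       importance_pairs=pairs)
        elif stage == "report":
            maps = need("score_maps", stage)
            levels = need("levels", stage)
            recordings = need("recordings", stage)
            comp_maps = [
                maps[(levels["compositional"].card.key(), r.subject_id)]
                for r in recordings
            ]
            grp = group_map(comp_maps)
            pd.DataFrame({
                "mean": grp.mean.reshape(-1),
                "sem": grp.sem.reshape(-1),
                "p": grp.p.reshape(-1),
                "p_adj": grp.p_adj.reshape(-1),
                "significant": grp.significant.reshape(-1),
            }).to_csv(outdir / "group_map.tsv", sep="\t", index=False)
            art["group"] = grp
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["stages"].append(stage)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    art["manifest"] = manifest
    return art
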