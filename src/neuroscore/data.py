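"""Domain containers for word-level encoding analyses.

The central objects are:

* :class:`StimulusSet` — the ordered word stream a subject read, with
  onset/duration timing, sentence and block structure (blocks of five
  consecutive sentences are the cross-validation unit), and per-sentence
  subject assignment.
* :class:`EmbeddingMatrix` — one activation vector per word, extracted from
  a (toy) network layer, together with a :class:`ModelCard` recording the
  architecture/training provenance of that layer.
* :class:`BrainRecording` — one subject's responses, either fMRI (scan grid
  × voxels at a fixed TR) or MEG (word epochs × channels × peri-word times).
* :class:`ScoreMap` — per-target cross-validated Pearson brain scores.

Stimulus metadata and model cards travel as TSV; all numeric arrays travel
in a single HDF5 container with a fixed group layout (``/stimuli``,
``/embeddings/<key>``, ``/brain/<subject>``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "ModelCard",
    "EmbeddingMatrix",
    "BrainRecording",
    "ProjectionOperator",
    "ScoreMap",
    "SchemaError",
    "AlignmentError",
    "read_stimuli",
    "write_stimuli",
    "read_arrays",
    "write_arrays",
]

STIMULUS_COLUMNS = [
    "word_id",
    "token",
    "onset",
    "duration",
    "sentence_id",
    "block_id",
    "run_id",
    "subject_ids",
]


class SchemaError(ValueError):
    """Tabular input violates the stimulus schema."""


class AlignmentError(ValueError):
    """Arrays do not align with the stimulus word list."""


def _parse_subjects(cell) -> frozenset[int]:
    if isinstance(cell, frozenset):
        return cell
    if isinstance(cell, (set, list, tuple)):
        return frozenset(int(s) for s in cell)
    cell = str(cell).strip()
    if not cell or cell == "-":
        return frozenset()
    return frozenset(int(s) for s in cell.split(","))


@dataclass(frozen=True)
class StimulusSet:
    """Ordered word stream with sentence/block structure.

    ``words`` holds one row per word with the columns in
    :data:`STIMULUS_COLUMNS`; ``subject_ids`` is a frozenset of the subjects
    who saw that word's sentence. Word indexing is 0-based, onsets are
    seconds from run start, time intervals are half-open ``[start, end)``.
    """

    words: pd.DataFrame

    def __post_init__(self):
        object.__setattr__(self, "words", validate_stimuli(self.words))

    # -- convenience views ------------------------------------------------
    def __len__(self) -> int:
        return len(self.words)

    @property
    def tokens(self) -> np.ndarray:
        return self.words["token"].to_numpy()

    @property
    def onsets(self) -> np.ndarray:
        return self.words["onset"].to_numpy(dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return self.words["duration"].to_numpy(dtype=float)

    @property
    def word_ids(self) -> np.ndarray:
        return self.words["word_id"].to_numpy(dtype=int)

    @property
    def sentence_ids(self) -> np.ndarray:
        return self.words["sentence_id"].to_numpy(dtype=int)

    @property
    def block_ids(self) -> np.ndarray:
        return self.words["block_id"].to_numpy(dtype=int)

    @property
    def run_ids(self) -> np.ndarray:
        return self.words["run_id"].to_numpy(dtype=int)

    def sentences(self) -> list[int]:
        """Sentence ids in presentation order."""
        return list(dict.fromkeys(self.words["sentence_id"]))

    def blocks(self) -> list[int]:
        """Block ids in presentation order."""
        return list(dict.fromkeys(self.words["block_id"]))

    def sentence_words(self, sentence_id: int) -> pd.DataFrame:
        return self.words[self.words["sentence_id"] == sentence_id]

    def subjects(self) -> set[int]:
        out: set[int] = set()
        for s in self.words["subject_ids"]:
            out |= s
        return out

    def sentences_of_subject(self, subject_id: int) -> list[int]:
        seen = self.words[[subject_id in s for s in self.words["subject_ids"]]]
        return list(dict.fromkeys(seen["sentence_id"]))

    def end_time(self) -> float:
        last = self.words.iloc[-1]
        return float(last["onset"] + last["duration"])


def validate_stimuli(
    df: pd.DataFrame,
    min_words: int | None = None,
    max_words: int | None = None,
) -> pd.DataFrame:
    """Validate a stimulus table; returns a normalized copy.

    Checks required columns, strictly increasing onsets within each run,
    contiguity of sentences and blocks in presentation order, ≤5 sentences
    per block, and (if given) per-sentence word-count bounds.
    """
    missing = [c for c in STIMULUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df.reset_index(drop=True).copy()
    df["subject_ids"] = [_parse_subjects(c) for c in df["subject_ids"]]

    for run_id, grp in df.groupby("run_id", sort=False):
        onsets = grp["onset"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(onsets) <= 0)[0]
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise SchemaError(
                f"onsets not strictly increasing in run {run_id} at row {row}"
            )

    for col in ("sentence_id", "block_id"):
        ids = df[col].to_numpy()
        seen: set = set()
        prev = None
        for v in ids:
            if v != prev:
                if v in seen:
                    raise SchemaError(f"{col} {v} is not contiguous")
                seen.add(v)
                prev = v

    sent_block = df.groupby("sentence_id", sort=False)["block_id"].nunique()
    if (sent_block > 1).any():
        bad = sent_block[sent_block > 1].index[0]
        raise SchemaError(f"sentence {bad} spans multiple blocks")
    per_block = df.groupby("block_id", sort=False)["sentence_id"].nunique()
    if (per_block > 5).any():
        bad = per_block[per_block > 5].index[0]
        raise SchemaError(f"block {bad} holds more than 5 sentences")

    if min_words is not None or max_words is not None:
        counts = df.groupby("sentence_id", sort=False).size()
        if min_words is not None and (counts < min_words).any():
            bad = counts[counts < min_words].index[0]
            raise SchemaError(f"sentence {bad} has fewer than {min_words} words")
        if max_words is not None and (counts > max_words).any():
            bad = counts[counts > max_words].index[0]
            raise SchemaError(f"sentence {bad} has more than {max_words} words")
    return df


@dataclass(frozen=True)
class ModelCard:
    """Provenance of one extracted representation.

    ``layer_index`` 0 is the non-contextual word-embedding layer;
    ``layer_position`` is relative depth in [0, 1] (0 = embedding layer,
    1 = last layer). ``n_layers`` counts contextual layers stacked on the
    embedding layer, so a model exposes ``n_layers + 1`` representations.
    """

    task: str = "causal"
    n_layers: int = 1
    dim: int = 128
    n_heads: int = 4
    training_step: int = 0
    accuracy_top1: float = 0.0
    layer_index: int = 0
    name: str = ""

    def __post_init__(self):
        if self.task not in ("causal", "masked", "visual"):
            raise ValueError(
                f"task must be causal|masked|visual, got {self.task!r}"
            )
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 <= self.accuracy_top1 <= 1.0:
            raise ValueError("accuracy_top1 must lie in [0, 1]")
        if not 0 <= self.layer_index <= self.n_layers:
            raise ValueError("layer_index out of range")

    @property
    def layer_position(self) -> float:
        """Relative depth: layer_index / (total layers − 1)."""
        total = self.n_layers + 1
        if total == 1:
            return 0.0
        return self.layer_index / (total - 1)

    def key(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class EmbeddingMatrix:
    """words × dim activation matrix aligned to a StimulusSet."""

    values: np.ndarray
    word_ids: np.ndarray
    card: ModelCard

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.word_ids = np.asarray(self.word_ids, dtype=np.int64)
        if self.values.ndim != 2:
            raise AlignmentError("embedding values must be 2-D (words × dim)")
        if self.values.shape[0] != self.word_ids.shape[0]:
            raise AlignmentError(
                f"{self.values.shape[0]} rows vs {self.word_ids.shape[0]} word ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise AlignmentError("embedding values must be finite")

    @property
    def n_words(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def check_aligned(self, stimuli: StimulusSet) -> None:
        if not np.array_equal(self.word_ids, stimuli.word_ids):
            raise AlignmentError(
                f"embedding rows ({self.n_words}) do not align with the "
                f"stimulus word list ({len(stimuli)})"
            )


@dataclass
class BrainRecording:
    """One subject's responses in fMRI (scan grid) or MEG (epoch) mode."""

    subject_id: int
    modality: str  # "fmri" | "meg"
    data: np.ndarray
    tr: float | None = None  # fMRI: repetition time, seconds
    times: np.ndarray | None = None  # MEG: epoch time axis, seconds
    word_ids: np.ndarray | None = None  # MEG: epoch alignment
    labels: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.modality == "fmri":
            if self.data.ndim != 2:
                raise AlignmentError("fMRI data must be scans × voxels")
            if self.tr is None or self.tr <= 0:
                raise ValueError("fMRI recording requires a positive TR")
        elif self.modality == "meg":
            if self.data.ndim != 3:
                raise AlignmentError("MEG data must be words × channels × times")
            if self.times is None:
                raise ValueError("MEG recording requires an epoch time axis")
            self.times = np.asarray(self.times, dtype=np.float64)
            if self.times.shape[0] != self.data.shape[2]:
                raise AlignmentError(
                    f"time axis length {self.times.shape[0]} does not match "
                    f"data time dimension {self.data.shape[2]}"
                )
            if not (self.times.min() <= 0.0 <= self.times.max()):
                raise AlignmentError("MEG epoch axis must cover word onset t=0")
            if self.word_ids is not None:
                self.word_ids = np.asarray(self.word_ids, dtype=np.int64)
                if self.word_ids.shape[0] != self.data.shape[0]:
                    raise AlignmentError("word_ids do not match epoch count")
        else:
            raise ValueError(f"modality must be fmri|meg, got {self.modality!r}")

    @property
    def n_targets(self) -> int:
        return self.data.shape[1]

    @property
    def n_scans(self) -> int:
        if self.modality != "fmri":
            raise ValueError("n_scans is an fMRI property")
        return self.data.shape[0]

    @property
    def scan_onsets(self) -> np.ndarray:
        return np.arange(self.n_scans) * float(self.tr)


@dataclass
class ProjectionOperator:
    """Linear sensors → sources map applied before correlation scoring."""

    matrix: np.ndarray  # m sources × n sensors
    labels: list[str] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise AlignmentError("projection matrix must be 2-D")

    def check_compatible(self, n_sensors: int) -> None:
        if self.matrix.shape[1] != n_sensors:
            raise AlignmentError(
                f"projection expects {self.matrix.shape[1]} sensors, "
                f"recording has {n_sensors}"
            )


@dataclass
class ScoreMap:
    """Cross-validated Pearson brain scores for one subject and embedding.

    ``scores`` is (n_voxels,) for fMRI or (n_channels, n_times) for MEG.
    ``degenerate`` flags targets whose score is undefined (zero variance in
    truth or prediction in some fold); those entries hold 0.
    """

    subject_id: int
    scores: np.ndarray
    card: ModelCard
    modality: str
    degenerate: np.ndarray = None  # type: ignore[assignment]
    fold_of_block: dict[int, int] = field(default_factory=dict)
    times: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.scores.shape, dtype=bool)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if self.degenerate.shape != self.scores.shape:
            raise AlignmentError("degenerate mask shape mismatch")
        ok = self.degenerate | (np.abs(self.scores) <= 1.0 + 1e-12)
        if not ok.all():
            raise ValueError("scores outside [-1, 1] without degenerate flag")


# ---------------------------------------------------------------------------
# TSV / HDF5 plumbing
# ---------------------------------------------------------------------------

def write_stimuli(stimuli: StimulusSet, path: str | Path) -> None:
    df = stimuli.words.copy()
    df["subject_ids"] = [
        ",".join(str(s) for s in sorted(ss)) if ss else "-"
        for ss in df["subject_ids"]
    ]
    df.to_csv(path, sep="\t", index=False)


def read_stimuli(path: str | Path) -> StimulusSet:
    """Read and validate a stimulus TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_ids": str})
    return StimulusSet(df)


def _card_to_attrs(card: ModelCard) -> dict:
    return dataclasses.asdict(card)


def _card_from_attrs(attrs) -> ModelCard:
    kwargs = {f.name: attrs[f.name] for f in dataclasses.fields(ModelCard)}
    kwargs["task"] = str(kwargs["task"])
    kwargs["name"] = str(kwargs["name"])
    for k in ("n_layers", "dim", "n_heads", "training_step", "layer_index"):
        kwargs[k] = int(kwargs[k])
    kwargs["accuracy_top1"] = float(kwargs["accuracy_top1"])
    return ModelCard(**kwargs)


def write_arrays(
    path: str | Path,
    *,
    stimuli: StimulusSet | None = None,
    embeddings: Iterable[EmbeddingMatrix] = (),
    recordings: Iterable[BrainRecording] = (),
    mode: str = "a",
) -> None:
    """Write containers into the fixed HDF5 layout.

    Layout: ``/embeddings/<card-key>`` (values + word_ids + card attrs),
    ``/brain/<subject>`` (data + axes). Embeddings are checked against
    ``stimuli`` alignment when stimuli are given.
    """
    with h5py.File(path, mode) as f:
        for emb in embeddings:
            if stimuli is not None:
                emb.check_aligned(stimuli)
            grp = f.require_group("embeddings").create_group(emb.card.key())
            grp.create_dataset("values", data=emb.values)
            grp.create_dataset("word_ids", data=emb.word_ids)
            for k, v in _card_to_attrs(emb.card).items():
                grp.attrs[k] = v
        for rec in recordings:
            grp = f.require_group("brain").create_group(str(rec.subject_id))
            grp.attrs["modality"] = rec.modality
            grp.attrs["subject_id"] = rec.subject_id
            grp.create_dataset("data", data=rec.data)
            if rec.modality == "fmri":
                grp.attrs["tr"] = rec.tr
            else:
                grp.create_dataset("times", data=rec.times)
                if rec.word_ids is not None:
                    grp.create_dataset("word_ids", data=rec.word_ids)


def read_arrays(
    path: str | Path,
) -> tuple[list[EmbeddingMatrix], list[BrainRecording]]:
    """Read every embedding and recording from an HDF5 container."""
    embeddings: list[EmbeddingMatrix] = []
    recordings: list[BrainRecording] = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.get("embeddings", {})):
            grp = f["embeddings"][key]
            embeddings.append(
                EmbeddingMatrix(
                    values=grp["values"][()],
                    word_ids=grp["word_ids"][()],
                    card=_card_from_attrs(grp.attrs),
                )
            )
        for key in sorted(f.get("brain", {}), key=lambda s: int(s)):
            grp = f["brain"][key]
            modality = str(grp.attrs["modality"])
            recordings.append(
                BrainRecording(
                    subject_id=int(grp.attrs["subject_id"]),
                    modality=modality,
                    data=grp["data"][()],
                    tr=float(grp.attrs["tr"]) if modality == "fmri" else None,
                    times=grp["times"][()] if "times" in grp else None,
                    word_ids=grp["word_ids"][()] if "word_ids" in grp else None,
                )
            )
    return embeddings, recordings


def cards_to_table(cards: Sequence[ModelCard]) -> pd.DataFrame:
    rows = []
    for c in cards:
        row = dataclasses.asdict(c)
        row["layer_position"] = c.layer_position
        rows.append(row)
    return pd.DataFrame(rows)
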