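"""Synthetic stimuli, embedding families, and multi-subject brain responses.

The generator emulates the structure of a rapid serial visual presentation
reading experiment: sentences of 9–15 words shown one word at a time with
a mean word duration of 351 ms (floored at 300 ms), 300 ms blanks between
words, 5 s blanks between sentences, and sentences grouped into blocks of
five consecutive sentences (the cross-validation unit).

Embedding families emulate checkpoints of language models at increasing
training amounts: at step t the activations are a mixture
``(1−α_t)·noise + α_t·signal``, where the signal nests three levels —
word-form (visual-like) features, a word-identity lookup (lexical), and a
causal decaying average of the lexical vectors over the sentence so far
(compositional) — mixed toward the compositional level with layer depth.
The planted "language accuracy" of a checkpoint follows the mixing curve,
so convergence analyses have a known ground truth.

Brain responses are produced by a shared linear forward model G from a
designated embedding: in fMRI mode the word features are binned onto a TR
grid and passed through an FIR kernel (one-hot at a known delay by
default, so delay-recovery tests have an exact target; a smooth option
exists); in MEG mode a latency kernel places the response at a known
peri-word time. Only a configurable fraction of channels is responsive;
per-subject noise is scaled to an exact signal-to-noise ratio, and an
optional noise component shared across subjects induces inter-subject
correlation beyond the common signal. Every generator is a pure function
of (config, seed) and returns the ground truth it used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BrainRecording, EmbeddingMatrix, ModelCard, StimulusSet
from .extraction import visual_embedding
import pandas as pd

__all__ = [
    "GroundTruth",
    "make_stimuli",
    "make_embedding_family",
    "canonical_embeddings",
    "make_brain",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GroundTruth:
    """Exactly what the generator used, recorded for recovery tests."""

    seed: int
    forward_map: np.ndarray | None = None  # o × n_channels
    responsive_mask: np.ndarray | None = None
    accuracy_curve: np.ndarray | None = None  # planted acc per step
    mix_curve: np.ndarray | None = None  # signal fraction α per step
    kernel: tuple | None = None  # ("onehot", delay_s) | ("smooth", weights)
    latency: float | None = None  # MEG response latency, seconds
    snr: float | None = None
    shared_noise_fraction: float = 0.0
    components: dict = field(default_factory=dict)  # named signal matrices


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

def _make_vocabulary(rng: np.random.Generator, size: int) -> list[str]:
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    vocab = set()
    while len(vocab) < size:
        length = int(rng.integers(2, 10))
        vocab.add("".join(rng.choice(letters, size=length)))
    return sorted(vocab)


def make_stimuli(
    n_sentences: int = 40,
    words_per_sentence: tuple[int, int] = (9, 15),
    word_duration_mean: float = 0.351,
    word_duration_floor: float = 0.300,
    word_duration_max: float = 1.400,
    gap: float = 0.300,
    inter_sequence_gap: float = 5.0,
    block_size: int = 5,
    n_subjects: int = 1,
    sentences_per_subject: int | None = None,
    vocabulary_size: int = 250,
    seed: int = 0,
    run_id: int = 0,
) -> StimulusSet:
    """Generate a word stream with sentence/block structure and timing.

    Word durations are drawn from a shifted gamma with the requested mean
    and floor, clipped at ``word_duration_max``; tokens are sampled from a
    Zipf-like distribution over a pseudo-word vocabulary so word types
    repeat. If ``sentences_per_subject`` is None every subject sees every
    sentence; otherwise each subject is assigned a random subset.
    """
    lo, hi = words_per_sentence
    if not (1 <= lo <= hi):
        raise ConfigError("invalid words_per_sentence range")
    if sentences_per_subject is not None and sentences_per_subject > n_sentences:
        raise ConfigError(
            f"sentences_per_subject ({sentences_per_subject}) exceeds "
            f"n_sentences ({n_sentences})"
        )
    if word_duration_mean <= word_duration_floor:
        raise ConfigError("word_duration_mean must exceed the floor")
    rng = np.random.default_rng(seed)
    vocab = _make_vocabulary(rng, vocabulary_size)
    # Zipf-ish token frequencies so word types repeat across sentences
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    probs = 1.0 / ranks
    probs /= probs.sum()

    shape = 2.0  # gamma shape for the duration excess over the floor
    scale = (word_duration_mean - word_duration_floor) / shape

    if sentences_per_subject is None:
        assignments = [set(range(n_subjects)) for _ in range(n_sentences)]
    else:
        assignments = [set() for _ in range(n_sentences)]
        for subj in range(n_subjects):
            chosen = rng.choice(
                n_sentences, size=sentences_per_subject, replace=False
            )
            for s in chosen:
                assignments[s].add(subj)

    rows = []
    t = 0.0
    word_id = 0
    for s in range(n_sentences):
        n_words = int(rng.integers(lo, hi + 1))
        tokens = rng.choice(vocab, size=n_words, p=probs)
        for i, tok in enumerate(tokens):
            dur = float(np.clip(
                word_duration_floor + rng.gamma(shape, scale),
                word_duration_floor, word_duration_max,
            ))
            rows.append(dict(
                word_id=word_id, token=str(tok), onset=round(t, 6),
                duration=round(dur, 6), sentence_id=s,
                block_id=s // block_size, run_id=run_id,
                subject_ids=frozenset(assignments[s]),
            ))
            word_id += 1
            t += dur + (gap if i < n_words - 1 else inter_sequence_gap)
    return StimulusSet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Embedding families with planted structure
# ---------------------------------------------------------------------------

def _standardize(M: np.ndarray) -> np.ndarray:
    std = M.std(axis=0)
    std[std == 0] = 1.0
    return (M - M.mean(axis=0)) / std


def _lexical_matrix(
    stimuli: StimulusSet, dim: int, seed: int
) -> np.ndarray:
    """Word-identity lookup: one Gaussian vector per word type."""
    rng_type: dict[str, np.ndarray] = {}
    rng = np.random.default_rng([seed, 101])
    rows = []
    for tok in stimuli.tokens:
        key = tok.casefold()
        if key not in rng_type:
            rng_type[key] = rng.standard_normal(dim)
        rows.append(rng_type[key])
    return np.stack(rows)


def _compositional_matrix(
    stimuli: StimulusSet, lexical: np.ndarray, decay: float = 0.7
) -> np.ndarray:
    """Causal decaying average of lexical vectors over the sentence so far."""
    out = np.empty_like(lexical)
    sent = stimuli.sentence_ids
    acc = np.zeros(lexical.shape[1])
    norm = 0.0
    prev_sent = None
    for i in range(lexical.shape[0]):
        if sent[i] != prev_sent:
            acc = np.zeros(lexical.shape[1])
            norm = 0.0
            prev_sent = sent[i]
        acc = decay * acc + lexical[i]
        norm = decay * norm + 1.0
        out[i] = acc / norm
    return out


def signal_levels(
    stimuli: StimulusSet, dim: int, seed: int,
    decay: float = 0.7, visual_weight: float = 0.3,
) -> dict[str, np.ndarray]:
    """The three nested signal levels, column-standardized.

    ``lexical`` blends word-identity vectors with a projection of the
    word-form features (so lexical embeddings implicitly carry visual
    information, as word embeddings do); ``compositional`` is the causal
    decaying average of the lexical vectors within each sentence.
    """
    visual = _standardize(
        visual_embedding(stimuli, dim=dim, seed=seed).values
    )
    ident = _lexical_matrix(stimuli, dim, seed)
    lexical = _standardize(
        np.sqrt(1 - visual_weight) * _standardize(ident)
        + np.sqrt(visual_weight) * visual
    )
    compositional = _standardize(
        _compositional_matrix(stimuli, lexical, decay)
    )
    return {"visual": visual, "lexical": lexical,
            "compositional": compositional}


def canonical_embeddings(
    stimuli: StimulusSet, dim: int = 16, seed: int = 0, decay: float = 0.7,
) -> dict[str, EmbeddingMatrix]:
    """Noise-free visual / lexical / compositional embeddings with cards."""
    levels = signal_levels(stimuli, dim, seed, decay)
    cards = {
        "visual": ModelCard(task="visual", dim=dim, n_layers=1, n_heads=0,
                            layer_index=0, name="visual"),
        "lexical": ModelCard(task="causal", dim=dim, n_layers=2, n_heads=4,
                             layer_index=0, accuracy_top1=0.45,
                             name="word-embedding"),
        "compositional": ModelCard(task="causal", dim=dim, n_layers=2,
                                   n_heads=4, layer_index=2,
                                   accuracy_top1=0.45, name="compositional"),
    }
    return {
        k: EmbeddingMatrix(levels[k], stimuli.word_ids, cards[k])
        for k in levels
    }


def make_embedding_family(
    stimuli: StimulusSet,
    dim: int = 16,
    n_layers: int = 3,
    n_steps: int = 10,
    signal_mix_curve: np.ndarray | None = None,
    require_monotone: bool = True,
    accuracy_max: float = 0.45,
    n_heads: int = 4,
    decay: float = 0.7,
    layer_mix: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[EmbeddingMatrix], GroundTruth]:
    """Checkpoints × layers of a toy language model family.

    Layer l's signal interpolates lexical → compositional with depth
    (``layer_mix`` overrides the default linear ramp; layer 0 is the pure
    word-identity lookup, the deepest layer the pure compositional level).
    Checkpoint t mixes that signal with fresh noise at fraction ``α_t``
    given by ``signal_mix_curve`` (default: linear 0 → 1 over steps), and
    its planted top-1 accuracy is ``accuracy_max · α_t``.
    """
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    if signal_mix_curve is None:
        alphas = (np.linspace(0, 1, n_steps) if n_steps > 1
                  else np.ones(1))
    else:
        alphas = np.asarray(signal_mix_curve, dtype=float)
        if alphas.shape != (n_steps,):
            raise ConfigError("signal_mix_curve length must equal n_steps")
        if (alphas < 0).any() or (alphas > 1).any():
            raise ConfigError("signal_mix_curve values must lie in [0, 1]")
        if require_monotone and (np.diff(alphas) < 0).any():
            raise ConfigError("signal_mix_curve must be non-decreasing")
    if layer_mix is None:
        betas = (np.linspace(0, 1, n_layers + 1) if n_layers > 0
                 else np.zeros(1))
    else:
        betas = np.asarray(layer_mix, dtype=float)
        if betas.shape != (n_layers + 1,):
            raise ConfigError("layer_mix length must equal n_layers + 1")

    levels = signal_levels(stimuli, dim, seed, decay)
    layer_signals = [
        _standardize(
            (1 - b) * levels["lexical"] + b * levels["compositional"]
        ) if 0 < b else levels["lexical"]
        for b in betas
    ]
    layer_signals = [
        levels["compositional"] if b == 1 else sig
        for b, sig in zip(betas, layer_signals)
    ]

    acc = accuracy_max * alphas
    family: list[EmbeddingMatrix] = []
    rng = np.random.default_rng([seed, 202])
    for t in range(n_steps):
        for l in range(n_layers + 1):
            noise = rng.standard_normal((len(stimuli), dim))
            values = (1 - alphas[t]) * noise + alphas[t] * layer_signals[l]
            card = ModelCard(
                task="causal", n_layers=n_layers, dim=dim, n_heads=n_heads,
                training_step=t, accuracy_top1=float(acc[t]), layer_index=l,
                name=f"family-{n_layers}x{dim}",
            )
            family.append(
                EmbeddingMatrix(values, stimuli.word_ids, card)
            )
    truth = GroundTruth(
        seed=seed, accuracy_curve=acc, mix_curve=alphas,
        components={**levels,
                    "layer_signals": layer_signals, "layer_mix": betas},
    )
    return family, truth


# ---------------------------------------------------------------------------
# Brain responses
# ---------------------------------------------------------------------------

def _scaled_noise(
    rng: np.random.Generator, shape: tuple, target_std: np.ndarray
) -> np.ndarray:
    """White noise rescaled per channel to an exact standard deviation."""
    raw = rng.standard_normal(shape)
    axes = tuple(i for i in range(len(shape)) if i != 1)
    std = raw.std(axis=axes, keepdims=True)
    std[std == 0] = 1.0
    return raw / std * np.reshape(target_std, std.shape)


def make_brain(
    stimuli: StimulusSet,
    generator: EmbeddingMatrix,
    n_subjects: int = 4,
    n_channels: int = 60,
    responsive_fraction: float = 0.5,
    snr: float = 1.0,
    modality: str = "fmri",
    tr: float = 2.0,
    kernel: tuple = ("onehot", 6.0),
    latency: float = 0.4,
    meg_times: np.ndarray | None = None,
    shared_noise_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[BrainRecording], GroundTruth]:
    """Multi-subject responses from a shared linear forward model.

    fMRI mode: word features are summed into TR bins, shifted through the
    FIR ``kernel`` (``("onehot", d)`` places all response at delay d
    seconds; ``("smooth", weights)`` spreads it over delays 2,4,...  s),
    and projected through G into the responsive channels. MEG mode: the
    projected features appear at the epoch sample nearest ``latency``
    (zero before onset, so the signal is causal).

    Per-subject noise is rescaled so the responsive-channel variance ratio
    equals ``snr`` exactly (``snr=np.inf`` → noise-free);
    ``shared_noise_fraction`` of the noise variance on responsive channels
    is common to all subjects.
    """
    if not 0 < responsive_fraction <= 1:
        raise ConfigError("responsive_fraction must lie in (0, 1]")
    if snr <= 0:
        raise ConfigError("snr must be positive")
    if not 0 <= shared_noise_fraction <= 1:
        raise ConfigError("shared_noise_fraction must lie in [0, 1]")
    generator.check_aligned(stimuli)
    rng = np.random.default_rng([seed, 303])
    o = generator.dim
    n_resp = max(1, int(round(responsive_fraction * n_channels)))
    responsive = np.zeros(n_channels, dtype=bool)
    responsive[rng.choice(n_channels, size=n_resp, replace=False)] = True
    G = rng.standard_normal((o, n_channels)) / np.sqrt(o)
    G[:, ~responsive] = 0.0

    features = _standardize(generator.values)

    if modality == "fmri":
        from .encoding import bin_words  # local import avoids cycles

        max_delay = 10.0
        n_scans = int(np.ceil((stimuli.end_time() + max_delay + tr) / tr))
        binned = bin_words(features, stimuli.onsets, n_scans, tr)
        kind = kernel[0]
        if kind == "onehot":
            delay = float(kernel[1])
            k = delay / tr
            if abs(k - round(k)) > 1e-9:
                raise ConfigError("onehot kernel delay must be a TR multiple")
            weights = {int(round(k)): 1.0}
        elif kind == "smooth":
            w = np.asarray(kernel[1], dtype=float)
            weights = {i + 1: float(w[i]) for i in range(w.size)}
        else:
            raise ConfigError(f"unknown kernel kind {kind!r}")
        drive = np.zeros_like(binned)
        for shift, wgt in weights.items():
            if shift < n_scans:
                drive[shift:] += wgt * binned[: n_scans - shift]
        signal = drive @ G  # n_scans × n_channels
        shape = (n_scans, n_channels)
    elif modality == "meg":
        if meg_times is None:
            meg_times = np.round(np.arange(-0.5, 2.0 + 1e-9, 0.1), 10)
        meg_times = np.asarray(meg_times, dtype=float)
        amp = features @ G  # words × channels
        t_idx = int(np.argmin(np.abs(meg_times - latency)))
        if meg_times[t_idx] < 0:
            raise ConfigError("latency must map to a post-onset sample")
        signal = np.zeros((len(stimuli), n_channels, meg_times.size))
        signal[:, :, t_idx] = amp
        shape = signal.shape
    else:
        raise ConfigError(f"modality must be fmri|meg, got {modality!r}")

    axes = tuple(i for i in range(signal.ndim) if i != 1)
    sig_var = signal.var(axis=axes)
    # noise floor for silent channels: median responsive signal variance
    floor = np.median(sig_var[responsive]) if responsive.any() else 1.0
    if floor == 0:
        floor = 1.0
    noise_var = np.where(responsive, sig_var, floor)
    noise_var = noise_var / snr if np.isfinite(snr) else np.zeros_like(
        noise_var
    )
    if not np.isfinite(snr):
        noise_var[:] = 0.0
        # silent channels still need *some* content to be "pure noise"
        noise_var[~responsive] = floor

    shared_std = np.sqrt(shared_noise_fraction * noise_var) * responsive
    indiv_std = np.sqrt(noise_var - shared_std**2)
    shared = _scaled_noise(np.random.default_rng([seed, 404]), shape,
                           shared_std)

    recordings = []
    for subj in range(n_subjects):
        sub_rng = np.random.default_rng([seed, 505, subj])
        noise = _scaled_noise(sub_rng, shape, indiv_std)
        data = signal + shared + noise
        if modality == "fmri":
            rec = BrainRecording(subject_id=subj, modality="fmri",
                                 data=data, tr=tr)
        else:
            rec = BrainRecording(subject_id=subj, modality="meg", data=data,
                                 times=meg_times, word_ids=stimuli.word_ids)
        recordings.append(rec)

    truth = GroundTruth(
        seed=seed, forward_map=G, responsive_mask=responsive,
        kernel=kernel if modality == "fmri" else None,
        latency=latency if modality == "meg" else None,
        snr=snr, shared_noise_fraction=shared_noise_fraction,
        components={"signal": signal, "features": features},
    )
    return recordings, truth
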