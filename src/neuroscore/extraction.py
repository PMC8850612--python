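"""Causal activation extraction and toy embedding providers.

Real language transformers are out of scope here; what matters for the
analysis pipeline is the *extraction protocol*: activations are taken in a
causal way, one vector per word per layer, with the word's context limited
to the current sentence so far plus the three preceding sentences of the
stream ("THE CAT IS ON" is the context for "ON"). The toy providers below
honour that contract exactly — layer 0 is a deterministic, non-contextual
word-embedding lookup, deeper layers integrate causal context
progressively — so causality and layer-0 context-independence can be
tested exhaustively.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np

from .data import EmbeddingMatrix, ModelCard, StimulusSet

__all__ = [
    "tokenize",
    "causal_contexts",
    "extract",
    "ToyContextualProvider",
    "toy_contextual_provider",
    "toy_visual_provider",
    "visual_embedding",
    "middle_layers",
]


def tokenize(token: str) -> str:
    """Toy tokenization: whitespace-delimited tokens, case-folded."""
    return token.strip().casefold()


def _token_rng(token: str, seed: int) -> np.random.Generator:
    # stable across processes (no reliance on Python's randomized hash)
    digest = hashlib.sha256(f"{seed}:{token}".encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence(list(words)))


def causal_contexts(
    stimuli: StimulusSet, n_context_sentences: int = 3
) -> list[list[str]]:
    """Per-word causal token sequences.

    For word i of sentence s, the sequence holds all words of the (at most)
    ``n_context_sentences`` sentences preceding s in presentation order,
    followed by the words of s up to and including word i. Contexts never
    include future words and never cross run boundaries; words at the start
    of a run simply get shorter contexts.
    """
    tokens = [tokenize(t) for t in stimuli.tokens]
    sent = stimuli.sentence_ids
    runs = stimuli.run_ids
    # sentence spans in presentation order, per run
    spans: list[tuple[int, int, int, int]] = []  # (run, sent, start, stop)
    start = 0
    for i in range(1, len(tokens) + 1):
        if i == len(tokens) or sent[i] != sent[start] or runs[i] != runs[start]:
            spans.append((runs[start], sent[start], start, i))
            start = i
    span_of_sentence = {(r, s): (a, b) for r, s, a, b in spans}
    order = [(r, s) for r, s, _, _ in spans]
    pos_in_order = {key: k for k, key in enumerate(order)}

    contexts: list[list[str]] = []
    for i in range(len(tokens)):
        key = (runs[i], sent[i])
        k = pos_in_order[key]
        ctx: list[str] = []
        for prev in order[max(0, k - n_context_sentences):k]:
            if prev[0] != runs[i]:  # run boundary: drop earlier sentences
                ctx = []
                continue
            a, b = span_of_sentence[prev]
            ctx.extend(tokens[a:b])
        a, _ = span_of_sentence[key]
        ctx.extend(tokens[a:i + 1])
        contexts.append(ctx)
    return contexts


@dataclass
class ToyContextualProvider:
    """Deterministic stand-in for a trained causal transformer.

    Layer 0 is a seeded hash-based lookup: a unit-norm Gaussian vector per
    word type, independent of context. Layer l (1..n_layers) is a
    normalized causal exponential mixture of the layer-(l−1) vectors over
    the token sequence, with a decay that flattens with depth so deeper
    layers integrate longer contexts.
    """

    dim: int = 16
    n_layers: int = 3
    mixing_rate: float = 0.7
    seed: int = 0
    task: str = "causal"
    n_heads: int = 4
    training_step: int = 0
    accuracy_top1: float = 0.0

    def lookup(self, token: str) -> np.ndarray:
        v = _token_rng(tokenize(token), self.seed).standard_normal(self.dim)
        return v / np.linalg.norm(v)

    def _decay(self, layer: int) -> float:
        # depth-increasing context integration: rho -> mixing_rate at the top
        return self.mixing_rate ** (self.n_layers / layer)

    def layers(self, tokens: list[str]) -> np.ndarray:
        """Activations for the FINAL token: (n_layers+1, dim)."""
        if not tokens:
            raise ValueError("empty token sequence")
        base = np.stack([self.lookup(t) for t in tokens])  # T × dim
        T = base.shape[0]
        out = np.empty((self.n_layers + 1, self.dim))
        out[0] = base[-1]
        prev = base
        for l in range(1, self.n_layers + 1):
            rho = self._decay(l)
            cur = np.empty_like(prev)
            # causal prefix mixture, normalized per position
            acc = np.zeros(self.dim)
            norm = 0.0
            for j in range(T):
                acc = rho * acc + prev[j]
                norm = rho * norm + 1.0
                cur[j] = acc / norm
            cur /= np.maximum(
                np.linalg.norm(cur, axis=1, keepdims=True), 1e-12
            )
            out[l] = cur[-1]
            prev = cur
        return out

    def card(self, layer_index: int) -> ModelCard:
        return ModelCard(
            task=self.task, n_layers=self.n_layers, dim=self.dim,
            n_heads=self.n_heads, training_step=self.training_step,
            accuracy_top1=self.accuracy_top1, layer_index=layer_index,
            name=f"toy-{self.task}-{self.n_layers}x{self.dim}",
        )


def toy_contextual_provider(
    dim: int = 16, n_layers: int = 3, mixing_rate: float = 0.7, seed: int = 0,
) -> ToyContextualProvider:
    return ToyContextualProvider(
        dim=dim, n_layers=n_layers, mixing_rate=mixing_rate, seed=seed
    )


def extract(
    provider: ToyContextualProvider,
    stimuli: StimulusSet,
    n_context_sentences: int = 3,
) -> list[EmbeddingMatrix]:
    """One EmbeddingMatrix per layer, rows aligned to the word stream."""
    contexts = causal_contexts(stimuli, n_context_sentences)
    n_rep = provider.n_layers + 1
    values = np.empty((n_rep, len(contexts), provider.dim))
    for i, ctx in enumerate(contexts):
        acts = provider.layers(ctx)
        if acts.shape != (n_rep, provider.dim):
            raise ValueError(
                f"provider dimensionality drift: got {acts.shape}, "
                f"expected {(n_rep, provider.dim)}"
            )
        values[:, i] = acts
    return [
        EmbeddingMatrix(values[l], stimuli.word_ids, provider.card(l))
        for l in range(n_rep)
    ]


def _wordform_features(token: str, dim: int, seed: int) -> np.ndarray:
    """Deterministic word-form descriptor emulating a character-recognition
    embedding: token length plus signed hashed character-bigram counts."""
    token = tokenize(token)
    feats = np.zeros(dim)
    feats[0] = len(token)
    padded = f"^{token}$"
    for a, b in zip(padded, padded[1:]):
        digest = hashlib.sha256(f"{seed}:{a}{b}".encode()).digest()
        bucket = 1 + int.from_bytes(digest[:4], "little") % (dim - 1)
        sign = 1.0 if digest[4] % 2 else -1.0
        feats[bucket] += sign
    return feats


def visual_embedding(
    stimuli: StimulusSet, dim: int = 16, seed: int = 0
) -> EmbeddingMatrix:
    """Toy visual embedding: word-form descriptors per word."""
    values = np.stack(
        [_wordform_features(t, dim, seed) for t in stimuli.tokens]
    )
    card = ModelCard(task="visual", n_layers=1, dim=dim, n_heads=0,
                     layer_index=0, name="toy-visual")
    return EmbeddingMatrix(values, stimuli.word_ids, card)


# the visual provider has no context dependence, so the callable form
# just closes over (dim, seed)
def toy_visual_provider(dim: int = 16, seed: int = 0):
    return lambda stimuli: visual_embedding(stimuli, dim=dim, seed=seed)


def middle_layers(n_layers: int) -> list[int]:
    """Middle-layer indices: integers l with n/2 ≤ l ≤ 3n/4.

    Bounds are inclusive over integer layer indices; a 12-layer model gives
    {6, 7, 8, 9}. Raises for models too shallow to have a middle layer.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    lo = math.ceil(n_layers / 2)
    hi = math.floor(3 * n_layers / 4)
    if hi < lo:
        raise ValueError(f"a {n_layers}-layer model has no middle layers")
    return list(range(lo, hi + 1))
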