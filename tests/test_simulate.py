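"""Synthetic generators: structure, determinism, planted ground truth."""

import numpy as np
import pytest

from neuroscore import make_brain, make_embedding_family, make_stimuli
from neuroscore.simulate import (
    ConfigError,
    _compositional_matrix,
    signal_levels,
)

from conftest import assert_within_se


class TestMakeStimuli:
    def test_block_arithmetic(self):
        st = make_stimuli(n_sentences=10, seed=0)
        assert st.blocks() == [0, 1]
        counts = st.words.groupby("block_id")["sentence_id"].nunique()
        assert (counts == 5).all()

    def test_determinism(self):
        a = make_stimuli(seed=5)
        b = make_stimuli(seed=5)
        assert a.words.drop(columns="subject_ids").equals(
            b.words.drop(columns="subject_ids")
        )
        assert list(a.words["subject_ids"]) == list(b.words["subject_ids"])

    def test_word_duration_mean(self):
        # Monte-Carlo check of the configured sampler over ~1e4 words
        st = make_stimuli(n_sentences=900, seed=1)
        d = st.durations
        assert len(d) >= 10_000
        se = d.std() / np.sqrt(len(d))
        assert_within_se(d.mean(), se, target=0.351)
        assert d.min() >= 0.300 and d.max() <= 1.400

    def test_sentence_lengths_and_gaps(self):
        st = make_stimuli(n_sentences=20, seed=2)
        counts = st.words.groupby("sentence_id").size()
        assert counts.between(9, 15).all()
        # within-sentence gap is 300 ms; sentences separated by 5 s
        w = st.words
        same = w["sentence_id"].to_numpy()[:-1] == w["sentence_id"].to_numpy()[1:]
        gaps = w["onset"].to_numpy()[1:] - (
            w["onset"].to_numpy()[:-1] + w["duration"].to_numpy()[:-1]
        )
        np.testing.assert_allclose(gaps[same], 0.300, atol=1e-6)
        np.testing.assert_allclose(gaps[~same], 5.0, atol=1e-6)

    def test_oversubscribed_subjects_rejected(self):
        with pytest.raises(ConfigError):
            make_stimuli(n_sentences=10, n_subjects=2,
                         sentences_per_subject=11)

    def test_partial_assignment(self):
        st = make_stimuli(n_sentences=10, n_subjects=3,
                          sentences_per_subject=4, seed=3)
        for subj in range(3):
            assert len(st.sentences_of_subject(subj)) == 4


class TestEmbeddingFamily:
    def test_alpha_zero_independent_of_lexical(self, stimuli):
        family, truth = make_embedding_family(
            stimuli, dim=8, n_layers=2, n_steps=3,
            signal_mix_curve=np.array([0.0, 0.5, 1.0]), seed=3,
        )
        lex = truth.components["lexical"]
        first = [e for e in family if e.card.training_step == 0]
        rs = []
        for emb in first:
            for j in range(emb.dim):
                r = np.corrcoef(emb.values[:, j], lex[:, j])[0, 1]
                rs.append(r)
        rs = np.asarray(rs)
        # under independence |r| is O(1/sqrt(n_words)); 3 SE bounds it
        se = 1.0 / np.sqrt(len(stimuli))
        assert np.abs(rs).mean() < 3 * se
        assert_within_se(np.mean(rs), se)

    def test_alpha_one_layer0_is_lookup(self, stimuli):
        family, _ = make_embedding_family(
            stimuli, dim=8, n_layers=2, n_steps=1,
            signal_mix_curve=np.array([1.0]), seed=3,
        )
        layer0 = next(e for e in family if e.card.layer_index == 0)
        tokens = [t.casefold() for t in stimuli.tokens]
        seen = {}
        for i, tok in enumerate(tokens):
            if tok in seen:
                np.testing.assert_allclose(
                    layer0.values[i], layer0.values[seen[tok]], atol=1e-12
                )
            seen[tok] = i

    def test_deepest_layer_is_decaying_average(self, stimuli):
        family, truth = make_embedding_family(
            stimuli, dim=8, n_layers=3, n_steps=1,
            signal_mix_curve=np.array([1.0]), seed=4,
        )
        deepest = next(e for e in family if e.card.layer_index == 3)
        # recompute the mixture directly from the lexical component
        comp = _compositional_matrix(stimuli, truth.components["lexical"])
        comp = (comp - comp.mean(0)) / comp.std(0)
        r = np.corrcoef(deepest.values.ravel(), comp.ravel())[0, 1]
        assert r > 0.99

    def test_planted_accuracy_follows_curve(self, stimuli):
        curve = np.array([0.0, 0.2, 0.9])
        family, truth = make_embedding_family(
            stimuli, dim=4, n_layers=1, n_steps=3,
            signal_mix_curve=curve, accuracy_max=0.5, seed=0,
        )
        np.testing.assert_allclose(truth.accuracy_curve, 0.5 * curve)
        for e in family:
            assert e.card.accuracy_top1 == 0.5 * curve[e.card.training_step]

    def test_non_monotone_curve_rejected(self, stimuli):
        with pytest.raises(ConfigError):
            make_embedding_family(
                stimuli, n_steps=3,
                signal_mix_curve=np.array([0.5, 0.2, 1.0]),
            )

    def test_cards_complete(self, stimuli):
        family, _ = make_embedding_family(
            stimuli, dim=4, n_layers=2, n_steps=2, seed=1
        )
        assert len(family) == 2 * 3
        for e in family:
            assert e.card.dim == 4 and e.card.n_layers == 2


class TestMakeBrain:
    def test_noise_free_signal_exact(self, stimuli, embeddings):
        recs, truth = make_brain(
            stimuli, embeddings["compositional"], n_subjects=2,
            n_channels=12, snr=np.inf, seed=5,
        )
        resp = truth.responsive_mask
        np.testing.assert_array_equal(
            recs[0].data[:, resp], truth.components["signal"][:, resp]
        )
        # silent channels still carry noise so they are not constant
        assert recs[0].data[:, ~resp].std() > 0

    def test_nonresponsive_channels_pure_noise(self, stimuli, embeddings):
        recs, truth = make_brain(
            stimuli, embeddings["compositional"], n_subjects=1,
            n_channels=12, snr=2.0, seed=6,
        )
        from neuroscore.encoding import bin_words

        n_scans = recs[0].n_scans
        drive = bin_words(
            truth.components["features"], stimuli.onsets, n_scans, 2.0
        )
        silent = recs[0].data[:, ~truth.responsive_mask]
        rs = [
            np.corrcoef(drive[:, j], silent[:, c])[0, 1]
            for j in range(drive.shape[1])
            for c in range(silent.shape[1])
        ]
        se = 1.0 / np.sqrt(n_scans)
        assert np.abs(np.mean(rs)) < 3 * se / np.sqrt(len(rs) / 4)
        assert np.abs(rs).max() < 5 * se

    def test_achieved_snr(self, embeddings, stimuli):
        recs, truth = make_brain(
            stimuli, embeddings["compositional"], n_subjects=1,
            n_channels=10, snr=4.0, seed=7,
        )
        resp = truth.responsive_mask
        sig = truth.components["signal"][:, resp]
        noise = recs[0].data[:, resp] - sig
        achieved = sig.var(axis=0) / noise.var(axis=0)
        assert np.all(np.abs(achieved / 4.0 - 1) < 0.10)

    def test_determinism(self, stimuli, embeddings):
        a, _ = make_brain(stimuli, embeddings["lexical"], n_subjects=2,
                          n_channels=8, seed=9)
        b, _ = make_brain(stimuli, embeddings["lexical"], n_subjects=2,
                          n_channels=8, seed=9)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_shared_noise_induces_intersubject_correlation(
        self, stimuli, embeddings
    ):
        recs, truth = make_brain(
            stimuli, embeddings["compositional"], n_subjects=6,
            n_channels=10, snr=1.0, shared_noise_fraction=0.5, seed=10,
        )
        resp = np.nonzero(truth.responsive_mask)[0]
        sig = truth.components["signal"]
        rs = []
        for i in range(6):
            for j in range(i + 1, 6):
                for c in resp:
                    ni = recs[i].data[:, c] - sig[:, c]
                    nj = recs[j].data[:, c] - sig[:, c]
                    rs.append(np.corrcoef(ni, nj)[0, 1])
        mean_r = np.mean(rs)
        se = np.std(rs) / np.sqrt(len(rs))
        assert mean_r > 3 * se  # positive at 3 SE

    def test_meg_signal_causal(self, stimuli, embeddings):
        recs, truth = make_brain(
            stimuli, embeddings["lexical"], n_subjects=1, n_channels=8,
            modality="meg", snr=np.inf, latency=0.4, seed=11,
        )
        rec = recs[0]
        pre = rec.times < 0
        assert np.all(rec.data[:, truth.responsive_mask][:, :, pre] == 0)

    @pytest.mark.parametrize("kwargs", [
        dict(responsive_fraction=0.0),
        dict(responsive_fraction=1.5),
        dict(snr=-1.0),
        dict(shared_noise_fraction=2.0),
    ])
    def test_config_errors(self, stimuli, embeddings, kwargs):
        with pytest.raises(ConfigError):
            make_brain(stimuli, embeddings["lexical"], n_subjects=1,
                       n_channels=4, **kwargs)


def test_signal_levels_are_standardized(stimuli):
    levels = signal_levels(stimuli, dim=6, seed=0)
    for mat in levels.values():
        np.testing.assert_allclose(mat.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(mat.std(axis=0), 1, atol=1e-10)
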