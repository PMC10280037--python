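"""Pretext task: batch structure, NCE loss oracles, training behaviour."""

import numpy as np
import pytest

from pulsepair.contrastive import (ContrastiveConfig, PairBatch, chance_loss,
                                   make_pair_batches, nce_loss,
                                   nce_loss_and_grad, pair_accuracy, train_ssl)
from pulsepair.encoder import build_encoder
from pulsepair.signals import Segment

from conftest import make_segment


def brute_force_nce(z, tau):
    """Independent oracle: explicit per-query softmax cross-entropy."""
    n = z.shape[0]
    losses = []
    for j in range(n):
        partner = j + 1 if j % 2 == 0 else j - 1
        cand = [i for i in range(n) if i != j]
        logits = np.array([z[j] @ z[i] / tau for i in cand])
        p = np.exp(logits - logits.max())
        p /= p.sum()
        losses.append(-np.log(p[cand.index(partner)]))
    return float(np.mean(losses))


def make_segments(n_patients, per_patient, rng, prefix="p"):
    segs = []
    for i in range(n_patients):
        for k in range(per_patient):
            segs.append(Segment(f"{prefix}{i}", f"{prefix}{i}_r", k,
                                rng.normal(size=(800, 2))))
    return segs


class TestNceLoss:
    @pytest.mark.parametrize("n_pairs", [2, 4, 8])
    @pytest.mark.parametrize("tau", [0.1, 1.0])
    def test_matches_brute_force_on_random_batches(self, n_pairs, tau, rng):
        for _ in range(20):
            z = rng.normal(size=(2 * n_pairs, 32))
            assert nce_loss(z, tau) == pytest.approx(
                brute_force_nce(z, tau), abs=1e-6)

    def test_identical_embeddings_give_ln3(self):
        z = np.ones((4, 16))
        for tau in (0.1, 1.0, 7.0):
            assert nce_loss(z, tau) == pytest.approx(np.log(3), abs=1e-9)

    def test_two_cluster_hand_computation(self):
        z = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1]])
        expected = -np.log(np.e / (np.e + 2))
        assert nce_loss(z, 1.0) == pytest.approx(expected, abs=1e-9)

    def test_single_pair_has_zero_loss(self, rng):
        assert nce_loss(rng.normal(size=(2, 8)), 0.5) == pytest.approx(0, abs=1e-9)

    def test_invariant_to_swapping_other_pairs(self, rng):
        z = rng.normal(size=(8, 16))
        # permuting whole pairs relabels the negatives but not the loss
        perm = np.array([2, 3, 0, 1, 6, 7, 4, 5])
        assert nce_loss(z, 0.3) == pytest.approx(nce_loss(z[perm], 0.3), abs=1e-9)

    def test_high_temperature_limit_is_chance(self, rng):
        z = rng.normal(size=(16, 32)) * 3
        assert nce_loss(z, 1e6) == pytest.approx(chance_loss(8), abs=1e-4)

    def test_gradient_matches_finite_differences(self, rng):
        z = rng.normal(size=(6, 4))
        _, g = nce_loss_and_grad(z.copy(), 0.7)
        eps = 1e-6
        for i, j in [(0, 0), (3, 2), (5, 3)]:
            zp, zm = z.copy(), z.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (nce_loss(zp, 0.7) - nce_loss(zm, 0.7)) / (2 * eps)
            assert g[i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_bad_inputs_rejected(self, rng):
        z = rng.normal(size=(4, 8))
        with pytest.raises(ValueError):
            nce_loss(z, 0.0)
        z[0, 0] = np.nan
        with pytest.raises(ValueError):
            nce_loss(z, 1.0)


class TestPairBatches:
    def test_structural_contract(self, rng):
        segs = make_segments(10, 7, rng)
        batches = make_pair_batches(segs, 4, rng)
        assert len(batches) == 2  # 10 patients // 4 pairs
        for b in batches:
            assert len(b.segments) == 8
            assert len(set(b.pseudo_patient_ids)) == 4
            for j in range(4):
                assert (b.segments[2 * j].pseudo_patient_id
                        == b.segments[2 * j + 1].pseudo_patient_id)

    def test_admission_discharge_never_paired(self, rng):
        segs = []
        for phase in ("admission", "discharge"):
            for k in range(3):
                segs.append(Segment("p0", f"p0_{phase}", k,
                                    rng.normal(size=(800, 2)),
                                    pseudo_patient_id=f"p0:{phase}"))
        segs += make_segments(4, 3, rng, prefix="q")
        for b in make_pair_batches(segs, 3, rng):
            for j in range(b.n_pairs):
                a, c = b.segments[2 * j], b.segments[2 * j + 1]
                assert a.pseudo_patient_id == c.pseudo_patient_id
                # the two phases stay in separate pairs
                assert not (a.recording_id.endswith("admission")
                            and c.recording_id.endswith("discharge"))

    def test_single_segment_patients_skipped_with_warning(self, rng):
        segs = make_segments(5, 2, rng)
        segs.append(Segment("lonely", "lonely_r", 0, rng.normal(size=(800, 2))))
        with pytest.warns(UserWarning, match="single segment"):
            batches = make_pair_batches(segs, 2, rng)
        for b in batches:
            assert "lonely" not in b.pseudo_patient_ids

    def test_too_few_patients_rejected(self, rng):
        with pytest.raises(ValueError, match="pseudo-patients"):
            make_pair_batches(make_segments(3, 3, rng), 4, rng)

    def test_seeded_determinism(self):
        segs = make_segments(8, 4, np.random.default_rng(0))
        a = make_pair_batches(segs, 3, np.random.default_rng(5))
        b = make_pair_batches(segs, 3, np.random.default_rng(5))
        assert [x.pseudo_patient_ids for x in a] == [x.pseudo_patient_ids for x in b]

    def test_mismatched_pair_rejected(self, rng):
        s1 = make_segment(rng.normal(size=(800, 2)), "a")
        s2 = make_segment(rng.normal(size=(800, 2)), "b")
        with pytest.raises(ValueError, match="pseudo-patient"):
            PairBatch([s1, s2], ["a"])


class TestPairAccuracy:
    def _one_hot_batch(self, n_pairs):
        segs, pids = [], []
        rng = np.random.default_rng(0)
        for i in range(n_pairs):
            pids.append(f"p{i}")
            for k in range(2):
                segs.append(Segment(f"p{i}", f"p{i}_r", k,
                                    rng.normal(size=(800, 2))))
        return PairBatch(segs, pids)

    def test_oracle_embeddings_give_perfect_retrieval(self, monkeypatch):
        batch = self._one_hot_batch(4)
        model = build_encoder("small")

        def fake_forward(x, train=False, stage=None):
            z = np.zeros((x.shape[0], 32))
            for i in range(x.shape[0]):
                z[i, i // 2] = 1.0  # one-hot patient codes
            return z
        monkeypatch.setattr(model, "forward", fake_forward)
        assert pair_accuracy(model, [batch]) == 1.0

    def test_untrained_encoder_near_chance(self, rng):
        # N=8: chance 1/15; identical-architecture untrained embeddings are
        # weakly correlated, so allow 3 binomial SEs around chance
        segs = make_segments(64, 4, rng)
        model = build_encoder("small", seed=1)
        batches = make_pair_batches(segs, 8, rng)
        acc = pair_accuracy(model, batches)
        n_queries = sum(2 * b.n_pairs for b in batches)
        p = 1 / 15
        se = np.sqrt(p * (1 - p) / n_queries)
        assert acc < p + 5 * se

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            pair_accuracy(build_encoder("small"), [])


class TestTraining:
    def test_zero_epochs_returns_initialization(self, rng):
        segs = make_segments(6, 3, rng)
        cfg = ContrastiveConfig(batch_pairs=2, epochs=0, seed=4)
        model, hist = train_ssl(segs, "small", cfg)
        init = build_encoder("small", head="projection", seed=4)
        a, b = model.state(), init.state()
        assert all(np.array_equal(a[k], b[k]) for k in a)
        assert len(hist) == 0

    def test_seeded_runs_identical(self, rng):
        segs = make_segments(8, 3, rng)
        cfg = ContrastiveConfig(batch_pairs=3, epochs=2, seed=9)
        _, h1 = train_ssl(segs, "small", cfg)
        _, h2 = train_ssl(segs, "small", cfg)
        assert h1["loss"].tolist() == h2["loss"].tolist()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ContrastiveConfig(temperature=0.0)
        with pytest.raises(ValueError):
            ContrastiveConfig(batch_pairs=1)
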