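"""Training, prediction, persistence and split discipline."""

import json

import numpy as np
import pytest

import peakboost as pb
from conftest import constant_target_pairs


def keys(pairs):
    return {r.peptide.key for r, _ in pairs}


class TestSplit:
    def test_split_sizes_and_disjoint(self, small_library):
        pairs, _ = small_library
        train, test = pb.train_test_split_by_peptide(pairs, 0.2, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert not (keys(train) & keys(test))

    def test_split_deterministic(self, small_library):
        pairs, _ = small_library
        a = pb.train_test_split_by_peptide(pairs, 0.2, seed=123)
        b = pb.train_test_split_by_peptide(pairs, 0.2, seed=123)
        assert [r.spec_id for r, _ in a[1]] == [r.spec_id for r, _ in b[1]]

    def test_split_no_leakage_many_seeds(self, small_library):
        pairs, _ = small_library
        for seed in range(100):
            train, test = pb.train_test_split_by_peptide(pairs, 0.3, seed=seed)
            assert not (keys(train) & keys(test))
            assert len(train) + len(test) == len(pairs)

    def test_split_two_records(self):
        pairs, _ = pb.generate_dataset(pb.DEFAULT_RULES["HCD"], 2, seed=0)
        train, test = pb.train_test_split_by_peptide(pairs, 0.5, seed=0)
        assert len(train) == 1 and len(test) == 1

    def test_split_too_few(self):
        pairs, _ = pb.generate_dataset(pb.DEFAULT_RULES["HCD"], 1, seed=0)
        with pytest.raises(pb.PeptideError):
            pb.train_test_split_by_peptide(pairs, 0.5, seed=0)


class TestTraining:
    def test_constant_target_recovery(self, constant_model):
        model, train_pairs = constant_model
        heldout = constant_target_pairs(n=20, seed=99)
        for record, _ in heldout:
            pred = pb.predict_peptide(model, record.peptide)
            np.testing.assert_allclose(pred.b, -2.0, atol=1e-3)
            np.testing.assert_allclose(pred.y, -2.0, atol=1e-3)
            np.testing.assert_allclose(pred.linear_b, 0.25, atol=1e-3)

    def test_empty_training_set(self):
        with pytest.raises(pb.PeptideError):
            pb.train_model([], "HCD")

    def test_training_deterministic(self, noise_free_hcd):
        pairs, _ = pb.generate_dataset(noise_free_hcd, 40, seed=17)
        cfg = pb.TrainingConfig(n_rounds=40, seed=17)
        m1 = pb.train_model(pairs, "HCD", cfg)
        m2 = pb.train_model(pairs, "HCD", cfg)
        probe = pb.generate_peptides(10, seed=4, flavor="HCD")
        assert pb.models.prediction_digest(m1, probe) == pb.models.prediction_digest(
            m2, probe
        )

    def test_heldout_pcc_on_learnable_task(self, tiny_model):
        model, pairs = tiny_model
        fresh, _ = pb.generate_dataset(pb.noise_free(pb.DEFAULT_RULES["HCD"]), 30, seed=909)
        res = pb.evaluate_model(model, fresh)
        assert res.median_pcc >= 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            pb.TrainingConfig(n_rounds=0)
        with pytest.raises(ValueError):
            pb.TrainingConfig(test_fraction=1.5)


class TestPrediction:
    def test_vector_lengths_and_determinism(self, tiny_model):
        model, _ = tiny_model
        p = pb.Peptide("ACDEK", charge=2)
        pred = pb.predict_peptide(model, p)
        assert pred.b.shape == pred.y.shape == (4,)
        pred2 = pb.predict_peptide(model, p)
        np.testing.assert_array_equal(pred.b, pred2.b)
        np.testing.assert_array_equal(pred.y, pred2.y)

    def test_linear_space_floor_maps_to_zero(self, tiny_model):
        model, _ = tiny_model
        p = pb.Peptide("ACDEFGHIK", charge=2)
        pred = pb.predict_peptide(model, p)
        floor = np.log2(model.epsilon)
        at_floor = pred.b <= floor + 1e-9
        assert np.all(pred.linear_b[at_floor] == 0.0)
        above = ~at_floor
        np.testing.assert_allclose(pred.linear_b[above], 2.0 ** pred.b[above])

    def test_batch_order_independence_and_rejects(self, tiny_model):
        model, _ = tiny_model
        peps = pb.generate_peptides(30, seed=40, flavor="HCD")
        records = [pb.PeptideRecord(f"r{i}", p) for i, p in enumerate(peps)]
        preds_fwd, rej_fwd = pb.predict_batch(model, records)
        preds_rev, rej_rev = pb.predict_batch(model, records[::-1])
        assert rej_fwd == rej_rev == []
        assert set(preds_fwd) == set(preds_rev)
        for sid in preds_fwd:
            np.testing.assert_array_equal(preds_fwd[sid].b, preds_rev[sid].b)

    def test_batch_reject_reported_not_fatal(self, constant_model):
        # a peptide already carrying a clashing N-term mod cannot take the
        # model flavor's label; for the unlabeled HCD flavor, force a clash
        # via a TMT model instead
        pairs, _ = pb.generate_dataset(pb.DEFAULT_RULES["TMT"], 30, seed=2)
        model = pb.train_model(pairs, "TMT", pb.TrainingConfig(n_rounds=20, seed=2))
        good = pb.PeptideRecord("good", pb.Peptide("ACDEK", charge=2))
        bad = pb.PeptideRecord(
            "bad", pb.Peptide("ACDEK", ((0, "iTRAQ4plex"),), charge=2)
        )
        preds, rejects = pb.predict_batch(model, [good, bad])
        assert set(preds) == {"good"}
        assert len(rejects) == 1 and rejects[0][0] == "bad"


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        model, _ = tiny_model
        pb.save_model(model, tmp_path / "m")
        loaded = pb.load_model(tmp_path / "m")
        assert loaded.flavor.name == model.flavor.name
        peps = pb.generate_peptides(50, seed=8, flavor="HCD")
        for p in peps:
            a = pb.predict_peptide(model, p)
            b = pb.predict_peptide(loaded, p)
            np.testing.assert_array_equal(a.b, b.b)
            np.testing.assert_array_equal(a.y, b.y)

    def test_corrupt_archive(self, tiny_model, tmp_path):
        model, _ = tiny_model
        pb.save_model(model, tmp_path / "m")
        (tmp_path / "m" / "b.json").write_text("not a booster")
        with pytest.raises(pb.PeptideError, match="corrupt"):
            pb.load_model(tmp_path / "m")

    def test_missing_archive(self, tmp_path):
        with pytest.raises(pb.PeptideError, match="model archive"):
            pb.load_model(tmp_path / "nope")

    def test_schema_version_mismatch(self, tiny_model, tmp_path):
        model, _ = tiny_model
        pb.save_model(model, tmp_path / "m")
        manifest = json.loads((tmp_path / "m" / "manifest.json").read_text())
        manifest["schema_version"] = "pb-0"
        (tmp_path / "m" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(pb.PeptideError, match="schema"):
            pb.load_model(tmp_path / "m")


def test_more_training_data_does_not_hurt(noise_free_hcd):
    """Median held-out PCC is non-decreasing in training-set size (one seed,
    modest sizes; the trend is what matters)."""
    eval_pairs, _ = pb.generate_dataset(noise_free_hcd, 40, seed=500)
    medians = []
    for n in (30, 120):
        pairs, _ = pb.generate_dataset(noise_free_hcd, n, seed=77)
        model = pb.train_model(pairs, "HCD", pb.TrainingConfig(n_rounds=80, seed=1))
        medians.append(pb.evaluate_model(model, eval_pairs).median_pcc)
    assert medians[1] >= medians[0] - 0.02
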