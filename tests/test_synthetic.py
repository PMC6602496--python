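"""Synthetic generator: determinism, ground-truth structure, dataset export."""

import dataclasses

import numpy as np
import pytest

import peakboost as pb
from peakboost.synthetic import SeriesProfile, SyntheticFragmentationRules


class TestGeneratePeptides:
    def test_tryptic_and_deterministic(self):
        a = pb.generate_peptides(100, seed=7)
        b = pb.generate_peptides(100, seed=7)
        assert a == b
        assert len(a) == 100
        assert all(p.sequence[-1] in "KR" for p in a)
        assert all(p.charge in (2, 3) for p in a)
        lengths = {len(p.sequence) for p in a}
        assert lengths <= set(range(7, 23))

    def test_flavor_labels_applied(self):
        for p in pb.generate_peptides(20, seed=1, flavor="TMT"):
            assert (0, "TMT6plex") in p.modifications
            for i, aa in enumerate(p.sequence, start=1):
                if aa == "K":
                    assert (i, "TMT6plex") in p.modifications

    def test_phospho_flavor_carries_phospho(self):
        for p in pb.generate_peptides(20, seed=2, flavor="iTRAQphospho"):
            assert any(name == "Phospho" for _, name in p.modifications)
            assert (0, "iTRAQ4plex") in p.modifications

    def test_invalid_range(self):
        with pytest.raises(pb.PeptideError):
            pb.generate_peptides(5, (10, 5))


def symmetric_rules():
    prof = SeriesProfile(0.5, 0.25, 1.0)
    return SyntheticFragmentationRules(
        flavor="HCD", b_profile=prof, y_profile=prof,
        proline_y_boost=1.0, proline_b_suppression=1.0, b1_suppression=1.0,
        basicity_weight_b=0.3, basicity_weight_y=0.3,
        noise_sigma=0.0, dropout=0.0, contaminant_rate=0.0,
    )


class TestGroundTruth:
    def test_normalized_to_one(self, hcd_rules):
        for p in pb.generate_peptides(10, seed=5, flavor="HCD"):
            b, y = pb.ground_truth_intensities(hcd_rules, p)
            assert b.sum() + y.sum() == pytest.approx(1.0)
            assert (b > 0).all() and (y > 0).all()

    def test_homopolymer_symmetry(self):
        b, y = pb.ground_truth_intensities(symmetric_rules(), pb.Peptide("AAAAAAA"))
        np.testing.assert_allclose(b, y)

    def test_proline_boosts_y(self, hcd_rules):
        with_p = pb.Peptide("ACDPEFK", charge=2)
        without = pb.Peptide("ACDAEFK", charge=2)
        n = 7
        cleavage = 3  # between D and P -> y_{n-3} = y4
        _, y_p = pb.ground_truth_intensities(hcd_rules, with_p)
        _, y_a = pb.ground_truth_intensities(hcd_rules, without)
        ratio_at = y_p[n - cleavage - 1] / y_a[n - cleavage - 1]
        # the boosted position gains relative to its no-proline counterpart
        other = [i for i in range(n - 1) if i != n - cleavage - 1]
        assert ratio_at > max(y_p[other] / y_a[other])

    def test_label_shift_changes_low_b_ions(self):
        rules = dataclasses.replace(symmetric_rules(), label_b_shift=2.0)
        plain = pb.Peptide("AAAAAAK", charge=2)
        labeled = pb.apply_flavor_labels(plain, pb.get_flavor("TMT"))
        b0, _ = pb.ground_truth_intensities(rules, plain)
        b1, _ = pb.ground_truth_intensities(rules, labeled)
        # before normalization b1..b3 doubled: ratio structure shows it
        assert (b1[:3] / b0[:3]).mean() > (b1[3:] / b0[3:]).mean()

    def test_distinct_flavor_profiles(self):
        p = pb.Peptide("ACDEFGHIK", charge=2)
        profiles = {
            fl: np.concatenate(pb.ground_truth_intensities(rules, p))
            for fl, rules in pb.DEFAULT_RULES.items()
        }
        names = list(profiles)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not np.allclose(profiles[a], profiles[b])


class TestSimulateSpectrum:
    def test_deterministic(self, hcd_rules):
        p = pb.Peptide("ACDEFGHIK", charge=2)
        s1 = pb.simulate_spectrum(hcd_rules, p, seed=12)
        s2 = pb.simulate_spectrum(hcd_rules, p, seed=12)
        np.testing.assert_array_equal(s1.mz, s2.mz)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_full_dropout_leaves_only_contaminants(self, hcd_rules):
        rules = dataclasses.replace(hcd_rules, dropout=1.0, contaminant_rate=3.0)
        p = pb.Peptide("ACDEFGHIK", charge=2)
        spec = pb.simulate_spectrum(rules, p, seed=3)
        frag_mz = {round(f.mz, 4) for f in pb.theoretical_fragments(p)}
        assert not frag_mz & {round(m, 4) for m in spec.mz}

    def test_zero_noise_recovers_truth(self, noise_free_hcd):
        p = pb.Peptide("ACDEFGHIK", charge=2)
        spec = pb.simulate_spectrum(noise_free_hcd, p, seed=0)
        tb, ty = pb.extract_targets(p, spec)
        gb, gy = pb.ground_truth_targets(noise_free_hcd, p)
        np.testing.assert_allclose(tb.values, gb, atol=1e-12)
        np.testing.assert_allclose(ty.values, gy, atol=1e-12)


class TestGenerateDataset:
    def test_unique_keys_and_determinism(self, hcd_rules):
        pairs, truth = pb.generate_dataset(hcd_rules, 50, seed=9)
        keys = {r.peptide.key for r, _ in pairs}
        assert len(keys) == len(pairs) == 50
        assert set(truth) == {r.spec_id for r, _ in pairs}
        pairs2, _ = pb.generate_dataset(hcd_rules, 50, seed=9)
        for (r1, s1), (r2, s2) in zip(pairs, pairs2):
            assert r1 == r2
            np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_msp_round_trip_preserves_targets(self, tmp_path, noise_free_hcd):
        pairs, _ = pb.generate_dataset(noise_free_hcd, 20, seed=14)
        path = tmp_path / "lib.msp"
        pb.write_msp(pairs, path)
        back, rejects = pb.read_msp_library(path)
        assert rejects == []
        for (r0, s0), (r1, s1) in zip(pairs, back):
            t0 = pb.extract_targets(r0.peptide, s0)
            t1 = pb.extract_targets(r1.peptide, s1)
            np.testing.assert_allclose(t0[0].values, t1[0].values, atol=1e-6)
            np.testing.assert_allclose(t0[1].values, t1[1].values, atol=1e-6)

    def test_flavors_share_seed_but_not_truth(self):
        pa, _ = pb.generate_dataset(pb.DEFAULT_RULES["HCD"], 5, seed=4)
        pb_, _ = pb.generate_dataset(pb.DEFAULT_RULES["TMT"], 5, seed=4)
        # same seed, different flavor: ground-truth generators differ
        ga = pb.ground_truth_intensities(pb.DEFAULT_RULES["HCD"], pa[0][0].peptide)
        gb = pb.ground_truth_intensities(pb.DEFAULT_RULES["TMT"], pa[0][0].peptide)
        assert not np.allclose(np.concatenate(ga), np.concatenate(gb))


def test_rules_validation():
    prof = SeriesProfile(0.5, 0.2, 1.0)
    with pytest.raises(pb.PeptideError):
        SyntheticFragmentationRules("x", prof, prof, dropout=1.5)
    with pytest.raises(pb.PeptideError):
        SeriesProfile(0.5, -0.1, 1.0)
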