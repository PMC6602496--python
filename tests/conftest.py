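"""Shared fixtures: small synthetic libraries and a tiny trained model.

Everything is generated programmatically and seeded; session scope keeps the
expensive pieces (model training) to one fit per run.
"""

import numpy as np
import pytest

import peakboost as pb


@pytest.fixture(scope="session")
def hcd_rules():
    return pb.DEFAULT_RULES["HCD"]


@pytest.fixture(scope="session")
def noise_free_hcd(hcd_rules):
    return pb.noise_free(hcd_rules)


@pytest.fixture(scope="session")
def small_library(hcd_rules):
    """100 noisy HCD-flavored peptide/spectrum pairs with ground truth."""
    return pb.generate_dataset(hcd_rules, 100, seed=7)


@pytest.fixture(scope="session")
def tmt_library():
    """60 TMT-flavored pairs (labeled peptides) for modification round-trips."""
    return pb.generate_dataset(pb.DEFAULT_RULES["TMT"], 60, seed=13)


@pytest.fixture(scope="session")
def tiny_model(noise_free_hcd):
    """A small but competent model on noise-free HCD data (150 peptides)."""
    pairs, _ = pb.generate_dataset(noise_free_hcd, 150, seed=3)
    cfg = pb.TrainingConfig(n_rounds=120, seed=3)
    return pb.train_model(pairs, "HCD", cfg), pairs


def constant_target_pairs(n=60, seed=5):
    """Length-3 tryptic peptides whose 4 fragments all carry equal intensity.

    With 4 fragments at equal intensity the TIC-normalized value is exactly
    0.25 everywhere, so every log2 target is exactly -2.
    """
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHILMNPQSTVWY")
    pairs = []
    seen = set()
    while len(pairs) < n:
        seq = "".join(rng.choice(aas, size=2)) + ("K" if rng.random() < 0.5 else "R")
        charge = int(rng.choice([2, 3]))
        p = pb.Peptide(seq, charge=charge)
        if p.key in seen:
            continue
        seen.add(p.key)
        frags = pb.theoretical_fragments(p)
        spec_id = f"const{len(pairs):03d}"
        spec = pb.ObservedSpectrum(
            identifier=spec_id,
            precursor_mz=500.0,
            precursor_charge=charge,
            mz=np.array([f.mz for f in frags]),
            intensity=np.full(len(frags), 100.0),
        )
        pairs.append((pb.PeptideRecord(spec_id, p), spec))
    return pairs


@pytest.fixture(scope="session")
def constant_model():
    pairs = constant_target_pairs()
    cfg = pb.TrainingConfig(n_rounds=120, max_depth=3, seed=5)
    model = pb.train_model(pairs, "HCD", cfg)
    return model, pairs
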