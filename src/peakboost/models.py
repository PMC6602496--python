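"""Per-ion-series gradient-boosted tree regressors, one pair per model flavor.

A trained model holds two boosters (b and y series) fit on pooled
(feature vector → log2 target) pairs over all training peptides, with early
stopping on an internal peptide-disjoint validation slice. Models persist as a
directory archive: a JSON manifest (flavor, feature schema version, training
configuration, seed, epsilon, summary) plus one serialized booster per series.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import xgboost as xgb

from .annotation import AnnotationConfig, extract_targets
from .chem import (
    DEFAULT_REGISTRY,
    FragmentConfig,
    ModificationRegistry,
    Peptide,
    PeptideError,
    theoretical_fragments,
)
from .features import FEATURE_SCHEMA_VERSION, encode_peptide_matrix
from .flavors import ModelFlavor, apply_flavor_labels, get_flavor
from .io import ObservedSpectrum, PeptideRecord, PredictedPeaks

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "Prediction",
    "train_test_split_by_peptide",
    "train_model",
    "predict_peptide",
    "predict_batch",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

SERIES = ("b", "y")


@dataclass(frozen=True)
class TrainingConfig:
    """Gradient-boosting hyperparameters and split discipline."""

    n_rounds: int = 200
    max_depth: int = 8
    learning_rate: float = 0.1
    early_stopping_rounds: int = 20
    test_fraction: float = 0.1  # internal early-stopping validation slice
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_rounds, self.max_depth, self.early_stopping_rounds) <= 0:
            raise ValueError("rounds, depth and early-stopping rounds must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test fraction must be in (0, 1)")


@dataclass
class Prediction:
    """Predicted target vectors for one peptide, in log2 and linear space."""

    peptide: Peptide
    b: np.ndarray
    y: np.ndarray
    linear_b: np.ndarray
    linear_y: np.ndarray

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.b, self.y])

    def to_peaks(
        self, registry: ModificationRegistry = DEFAULT_REGISTRY
    ) -> PredictedPeaks:
        frags = theoretical_fragments(self.peptide, FragmentConfig(), registry=registry)
        frags = [f for f in frags if f.charge == 1]
        linear = np.concatenate([self.linear_b, self.linear_y])
        return PredictedPeaks(
            peptide=self.peptide, fragments=tuple(frags), linear_intensity=linear
        )


@dataclass
class TrainedModel:
    flavor: ModelFlavor
    boosters: dict[str, xgb.Booster]
    n_trees: dict[str, int]
    schema_version: str
    config: TrainingConfig
    epsilon: float
    training_summary: dict

    def predict_matrix(self, series: str, X: np.ndarray) -> np.ndarray:
        dm = xgb.DMatrix(X)
        return self.boosters[series].predict(
            dm, iteration_range=(0, self.n_trees[series])
        )


def _pair_key(record: PeptideRecord):
    return record.peptide.key


def train_test_split_by_peptide(
    pairs: Sequence[tuple[PeptideRecord, ObservedSpectrum]],
    test_fraction: float,
    seed: int,
) -> tuple[list, list]:
    """Deterministic peptide-keyed split: no (sequence, mods, charge) key
    appears in both partitions."""
    if len(pairs) < 2:
        raise PeptideError("need at least 2 records to split")
    if not (0 < test_fraction < 1):
        raise PeptideError("test fraction must be in (0, 1)")
    keys = sorted({_pair_key(r) for r, _ in pairs})
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_test = max(1, int(round(test_fraction * len(keys))))
    if n_test >= len(keys):
        n_test = len(keys) - 1
    test_keys = set(map(tuple, keys[:n_test]))
    train = [p for p in pairs if _pair_key(p[0]) not in test_keys]
    test = [p for p in pairs if _pair_key(p[0]) in test_keys]
    return train, test


def _assemble_training_arrays(
    pairs: Sequence[tuple[PeptideRecord, ObservedSpectrum]],
    flavor: ModelFlavor,
    ann_cfg: AnnotationConfig,
    registry: ModificationRegistry,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    X_blocks, yb_blocks, yy_blocks = [], [], []
    for record, spec in pairs:
        pep = apply_flavor_labels(record.peptide, flavor, registry)
        tb, ty = extract_targets(pep, spec, ann_cfg, registry)
        X_blocks.append(encode_peptide_matrix(pep, registry=registry))
        yb_blocks.append(tb.values)
        yy_blocks.append(ty.values)
    X = np.concatenate(X_blocks)
    return X, {"b": np.concatenate(yb_blocks), "y": np.concatenate(yy_blocks)}


def train_model(
    pairs: Sequence[tuple[PeptideRecord, ObservedSpectrum]],
    flavor: ModelFlavor | str,
    cfg: TrainingConfig = TrainingConfig(),
    ann_cfg: AnnotationConfig | None = None,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> TrainedModel:
    """Fit b- and y-series boosters on an annotated training set.

    The flavor's fixed labels are applied to every peptide (idempotent;
    clashes raise). Early stopping uses a peptide-disjoint internal validation
    slice of size ``cfg.test_fraction``. Squared-error objective on the log2
    targets; fully reproducible under a fixed seed (single-threaded hist
    training).
    """
    if isinstance(flavor, str):
        flavor = get_flavor(flavor)
    if not pairs:
        raise PeptideError("empty training set")
    if ann_cfg is None:
        ann_cfg = AnnotationConfig(tolerance=flavor.tolerance_da)

    if len(pairs) >= 10:
        fit_pairs, val_pairs = train_test_split_by_peptide(
            pairs, cfg.test_fraction, cfg.seed
        )
    else:  # too small for a validation slice: train on everything, no early stop
        fit_pairs, val_pairs = list(pairs), []

    X_fit, y_fit = _assemble_training_arrays(fit_pairs, flavor, ann_cfg, registry)
    evals_X = None
    if val_pairs:
        evals_X, evals_y = _assemble_training_arrays(val_pairs, flavor, ann_cfg, registry)

    params = {
        "objective": "reg:squarederror",
        "max_depth": cfg.max_depth,
        "eta": cfg.learning_rate,
        "seed": cfg.seed,
        "nthread": 1,
        "tree_method": "hist",
        "verbosity": 0,
    }
    boosters: dict[str, xgb.Booster] = {}
    n_trees: dict[str, int] = {}
    val_rmse: dict[str, float] = {}
    for series in SERIES:
        dtrain = xgb.DMatrix(X_fit, label=y_fit[series])
        kwargs: dict = {}
        if evals_X is not None:
            dval = xgb.DMatrix(evals_X, label=evals_y[series])
            kwargs = {
                "evals": [(dval, "val")],
                "early_stopping_rounds": cfg.early_stopping_rounds,
                "verbose_eval": False,
            }
        booster = xgb.train(params, dtrain, num_boost_round=cfg.n_rounds, **kwargs)
        best = getattr(booster, "best_iteration", None)
        n_trees[series] = (best + 1) if best is not None else cfg.n_rounds
        if evals_X is not None:
            pred = booster.predict(dval, iteration_range=(0, n_trees[series]))
            val_rmse[series] = float(np.sqrt(np.mean((pred - evals_y[series]) ** 2)))
        boosters[series] = booster

    summary = {
        "n_training_pairs": len(pairs),
        "n_fit": len(fit_pairs),
        "n_validation": len(val_pairs),
        "n_rows": int(X_fit.shape[0]),
        "validation_rmse": val_rmse,
    }
    return TrainedModel(
        flavor=flavor,
        boosters=boosters,
        n_trees=n_trees,
        schema_version=FEATURE_SCHEMA_VERSION,
        config=cfg,
        epsilon=ann_cfg.epsilon,
        training_summary=summary,
    )


def _linearize(values: np.ndarray, epsilon: float) -> np.ndarray:
    """Map log2 predictions to linear space; the floor maps to exactly 0."""
    floor = np.log2(epsilon)
    linear = np.power(2.0, values)
    linear[values <= floor + 1e-9] = 0.0
    return linear


def predict_peptide(
    model: TrainedModel,
    p: Peptide,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
    apply_labels: bool = True,
) -> Prediction:
    """Predict (b, y) log2 target vectors and linear intensities for a peptide.

    The model flavor's fixed labels are applied automatically when absent
    (set ``apply_labels=False`` to predict on the peptide exactly as given).
    Predictions are clipped to the training target range
    [log2(epsilon), 0].
    """
    if model.schema_version != FEATURE_SCHEMA_VERSION:
        raise PeptideError(
            f"model schema {model.schema_version!r} does not match "
            f"encoder schema {FEATURE_SCHEMA_VERSION!r}"
        )
    if apply_labels:
        p = apply_flavor_labels(p, model.flavor, registry)
    X = encode_peptide_matrix(p, registry=registry)
    floor = float(np.log2(model.epsilon))
    out = {}
    for series in SERIES:
        vals = np.clip(model.predict_matrix(series, X), floor, 0.0).astype(float)
        out[series] = vals
    return Prediction(
        peptide=p,
        b=out["b"],
        y=out["y"],
        linear_b=_linearize(out["b"], model.epsilon),
        linear_y=_linearize(out["y"], model.epsilon),
    )


def predict_batch(
    model: TrainedModel,
    records: Iterable[PeptideRecord],
    registry: ModificationRegistry = DEFAULT_REGISTRY,
    progress: Callable[[int], None] | None = None,
) -> tuple[dict[str, Prediction], list[tuple[str, str]]]:
    """Predict for every valid record; returns (predictions by spec_id, rejects).

    Per-record failures (label clashes, residues outside the alphabet that
    slipped past upstream validation) are collected as (spec_id, reason), never
    fatal. Results are keyed by spec_id and therefore order-independent.
    """
    predictions: dict[str, Prediction] = {}
    rejects: list[tuple[str, str]] = []
    for i, record in enumerate(records):
        try:
            predictions[record.spec_id] = predict_peptide(model, record.peptide, registry)
        except (PeptideError, ValueError) as exc:
            rejects.append((record.spec_id, str(exc)))
        if progress is not None:
            progress(i + 1)
    return predictions, rejects


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.json"


def save_model(model: TrainedModel, path) -> None:
    """Write a portable model archive directory.

    Layout: ``manifest.json`` plus ``b.json`` / ``y.json`` (xgboost's JSON
    booster serialization).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "peakboost-model",
        "flavor": model.flavor.name,
        "schema_version": model.schema_version,
        "config": asdict(model.config),
        "epsilon": model.epsilon,
        "n_trees": model.n_trees,
        "training_summary": model.training_summary,
    }
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=2))
    for series in SERIES:
        model.boosters[series].save_model(str(path / f"{series}.json"))


def load_model(path) -> TrainedModel:
    """Load a model archive; raises on corrupt archives or schema mismatch."""
    path = Path(path)
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise PeptideError(f"not a model archive (no {_MANIFEST}): {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise PeptideError(f"corrupt model manifest in {path}: {exc}") from None
    if manifest.get("format") != "peakboost-model":
        raise PeptideError(f"not a model archive: {path}")
    if manifest["schema_version"] != FEATURE_SCHEMA_VERSION:
        raise PeptideError(
            f"model archive {path} was trained with feature schema "
            f"{manifest['schema_version']!r}; current encoder is "
            f"{FEATURE_SCHEMA_VERSION!r}"
        )
    boosters = {}
    for series in SERIES:
        booster = xgb.Booster()
        booster_path = path / f"{series}.json"
        if not booster_path.exists():
            raise PeptideError(f"model archive {path} missing {series}.json")
        try:
            booster.load_model(str(booster_path))
        except xgb.core.XGBoostError as exc:
            raise PeptideError(f"corrupt booster {booster_path}: {exc}") from None
        boosters[series] = booster
    return TrainedModel(
        flavor=get_flavor(manifest["flavor"]),
        boosters=boosters,
        n_trees={k: int(v) for k, v in manifest["n_trees"].items()},
        schema_version=manifest["schema_version"],
        config=TrainingConfig(**manifest["config"]),
        epsilon=float(manifest["epsilon"]),
        training_summary=manifest["training_summary"],
    )


def prediction_digest(model: TrainedModel, peptides: Iterable[Peptide]) -> str:
    """SHA-256 digest of predictions over peptides; a reproducibility probe."""
    h = hashlib.sha256()
    for p in peptides:
        pred = predict_peptide(model, p)
        h.update(pred.concatenated().tobytes())
    return h.hexdigest()
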