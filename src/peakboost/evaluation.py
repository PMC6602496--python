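"""Pearson-correlation evaluation of predicted versus observed spectra.

The score for one spectrum is the Pearson correlation coefficient (PCC)
between the predicted and observed log2 target vectors with the b and y
series concatenated (floored, unmatched positions included). Spectra whose
concatenated vector is constant on either side have no defined PCC; they are
excluded from medians and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationConfig, extract_targets
from .chem import DEFAULT_REGISTRY, ModificationRegistry, Peptide, PeptideError
from .flavors import relabel_for_flavor
from .io import ObservedSpectrum, PeptideRecord
from .models import Prediction, TrainedModel, predict_peptide

__all__ = [
    "spectrum_pcc",
    "EvaluationResult",
    "evaluate_model",
    "cross_evaluate",
    "mirror_pair_export",
]


def spectrum_pcc(
    pred: tuple[np.ndarray, np.ndarray],
    obs: tuple[np.ndarray, np.ndarray],
) -> float:
    """PCC between concatenated [b; y] vectors; NaN when either is constant.

    Symmetric and invariant to positive affine rescaling of either side.
    """
    pb, py = (np.asarray(v, dtype=float) for v in pred)
    ob, oy = (np.asarray(v, dtype=float) for v in obs)
    if pb.shape != ob.shape or py.shape != oy.shape:
        raise PeptideError(
            f"prediction/observation length mismatch: "
            f"b {pb.shape} vs {ob.shape}, y {py.shape} vs {oy.shape}"
        )
    x = np.concatenate([pb, py])
    y = np.concatenate([ob, oy])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class EvaluationResult:
    """Per-spectrum scores plus distribution summaries."""

    scores: pd.DataFrame  # columns: spec_id, pcc, charge, length
    n_undefined: int

    @property
    def median_pcc(self) -> float:
        return float(self.scores["pcc"].median())

    def summary(self) -> dict:
        pcc = self.scores["pcc"]
        five = {
            "min": float(pcc.min()),
            "q1": float(pcc.quantile(0.25)),
            "median": float(pcc.median()),
            "q3": float(pcc.quantile(0.75)),
            "max": float(pcc.max()),
        }
        per_charge = {
            int(z): float(g["pcc"].median())
            for z, g in self.scores.groupby("charge")
        }
        return {
            "n_scored": int(len(self.scores)),
            "n_undefined": self.n_undefined,
            **five,
            "per_charge_median": per_charge,
        }


def evaluate_model(
    model: TrainedModel,
    eval_set: Sequence[tuple[PeptideRecord, ObservedSpectrum]],
    ann_cfg: AnnotationConfig | None = None,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
    relabel: bool = False,
) -> EvaluationResult:
    """Score every spectrum in an evaluation set against model predictions.

    Targets are extracted from each peptide as annotated in the set; with
    ``relabel`` the peptide is shown to the model with the model's own label
    chemistry (existing labels stripped first), which is how mismatched
    model/dataset combinations are evaluated.
    """
    if not eval_set:
        raise PeptideError("empty evaluation set")
    if ann_cfg is None:
        ann_cfg = AnnotationConfig(tolerance=model.flavor.tolerance_da)
    rows = []
    n_undefined = 0
    for record, spec in eval_set:
        pep = record.peptide
        tb, ty = extract_targets(pep, spec, ann_cfg, registry)
        pred_pep = relabel_for_flavor(pep, model.flavor, registry) if relabel else pep
        pred = predict_peptide(model, pred_pep, registry)
        r = spectrum_pcc((pred.b, pred.y), (tb.values, ty.values))
        if np.isnan(r):
            n_undefined += 1
            continue
        rows.append(
            {
                "spec_id": record.spec_id,
                "pcc": r,
                "charge": pep.charge,
                "length": len(pep.sequence),
            }
        )
    scores = pd.DataFrame(rows, columns=["spec_id", "pcc", "charge", "length"])
    return EvaluationResult(scores=scores, n_undefined=n_undefined)


def cross_evaluate(
    models: Mapping[str, TrainedModel],
    eval_sets: Mapping[str, Sequence[tuple[PeptideRecord, ObservedSpectrum]]],
    ann_cfg: AnnotationConfig | None = None,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Median-PCC matrix: rows = models, columns = evaluation datasets.

    Every model is applied to every dataset, including mismatched
    combinations; each model sees the peptides relabeled with its own label
    chemistry. Matched cells are the ones whose row and column names agree.
    """
    matrix = pd.DataFrame(
        index=list(models), columns=list(eval_sets), dtype=float
    )
    for mname, model in models.items():
        for dname, eval_set in eval_sets.items():
            res = evaluate_model(model, eval_set, ann_cfg, registry, relabel=True)
            matrix.loc[mname, dname] = res.median_pcc
    return matrix


def mirror_pair_export(
    model: TrainedModel,
    p: Peptide,
    spectrum: ObservedSpectrum,
    ann_cfg: AnnotationConfig | None = None,
    registry: ModificationRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Aligned predicted/observed fragment table for mirror plotting.

    One row per singly charged b/y fragment with both intensity columns
    max-normalized to 1; unmatched observed positions are 0.
    """
    if ann_cfg is None:
        ann_cfg = AnnotationConfig(tolerance=model.flavor.tolerance_da)
    pred = predict_peptide(model, p, registry)
    pep = pred.peptide  # possibly label-completed
    tb, ty = extract_targets(pep, spectrum, ann_cfg, registry)
    peaks = pred.to_peaks(registry)

    obs_linear = {}
    for series, tv in (("b", tb), ("y", ty)):
        lin = np.power(2.0, tv.values)
        lin[~tv.matched_mask] = 0.0
        obs_linear[series] = lin

    rows = []
    pred_lin = np.asarray(peaks.linear_intensity)
    for frag, plin in zip(peaks.fragments, pred_lin):
        rows.append(
            {
                "series": frag.series,
                "index": frag.index,
                "mz": frag.mz,
                "predicted": plin,
                "observed": obs_linear[frag.series][frag.index - 1],
            }
        )
    df = pd.DataFrame(rows)
    for col in ("predicted", "observed"):
        top = df[col].max()
        if top > 0:
            df[col] = df[col] / top
    return df.sort_values(["series", "index"]).reset_index(drop=True)


def plot_mirror(df: pd.DataFrame, path, title: str = "") -> None:
    """Render a mirror plot (predicted up, observed down) to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    colors = {"b": "#1f77b4", "y": "#d62728"}
    for _, row in df.iterrows():
        c = colors[row["series"]]
        ax.vlines(row["mz"], 0, row["predicted"], color=c, lw=1.2)
        ax.vlines(row["mz"], 0, -row["observed"], color=c, lw=1.2, alpha=0.6)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("m/z")
    ax.set_ylabel("relative intensity (up: predicted, down: observed)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_score_boxes(results: Mapping[str, EvaluationResult], path) -> None:
    """Boxplots of per-spectrum PCC distributions, one box per model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 * max(4, len(results)), 4))
    ax.boxplot(
        [res.scores["pcc"] for res in results.values()],
        tick_labels=list(results),
        showfliers=False,
    )
    ax.set_ylabel("per-spectrum PCC")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
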