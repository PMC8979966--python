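"""Scoring screen calls against activation-based ground truth.

A variant counts as a true (cognate) interaction when it activates more
than 10% of cognate T cells on average in the coculture assay (strict
inequality).  Besides the classical confusion-matrix quantities this
module reports the validated-call rate — the fraction of screen-positive
calls confirmed by the orthogonal assay — because that precision-style
number is the "specificity" convention used when benchmarking this kind
of screen against a handful of validated interactions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn import metrics as _skm


@dataclass
class GroundTruthTable:
    """Per-variant activation fraction and the binary cognate label."""

    table: pd.DataFrame  # index variant_id; columns activation_fraction, cognate
    threshold: float = 0.10

    @classmethod
    def from_activation(
        cls, activation: Mapping[str, float], threshold: float = 0.10
    ) -> "GroundTruthTable":
        return label_ground_truth(activation, threshold)

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = 0.10) -> "GroundTruthTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
        if not {"variant_id", "activation_fraction"} <= set(df.columns):
            raise ValueError("truth TSV needs columns variant_id, activation_fraction")
        activation = dict(zip(df["variant_id"], df["activation_fraction"].astype(float)))
        return label_ground_truth(activation, threshold)

    @property
    def cognate(self) -> set[str]:
        return set(self.table.index[self.table["cognate"]])

    @property
    def variants(self) -> set[str]:
        return set(self.table.index)

    def save(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


def label_ground_truth(
    activation: Mapping[str, float], threshold: float = 0.10
) -> GroundTruthTable:
    """Binary cognate labels from mean activation fractions (strict ``>``)."""
    for v, frac in activation.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"activation fraction for {v!r} out of [0, 1]: {frac}")
    df = pd.DataFrame(
        {
            "activation_fraction": pd.Series(dict(activation), dtype=float),
            "cognate": pd.Series({v: f > threshold for v, f in activation.items()}),
        }
    )
    df.index.name = "variant_id"
    return GroundTruthTable(table=df.sort_index(), threshold=threshold)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else math.nan


@dataclass
class PerformanceReport:
    """Confusion matrix plus the derived rates for one screen."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # TP / (TP + FN)
    specificity: float  # TN / (TN + FP)
    validated_call_rate: float  # TP / (TP + FP): fraction of calls that validate
    n_calls: int
    roc_points: list[tuple[float, float]] | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "validated_call_rate": self.validated_call_rate,
            "sensitivity_pct": _fmt_pct(self.sensitivity),
            "validated_call_rate_pct": _fmt_pct(self.validated_call_rate),
            "n_calls": self.n_calls,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.roc_points is not None:
            d["roc_points"] = [[float(a), float(b)] for a, b in self.roc_points]
        return d

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _fmt_pct(x: float) -> str:
    return "nan%" if math.isnan(x) else f"{100.0 * x:.1f}%"


def screen_performance(
    calls: Iterable[str], truth: GroundTruthTable
) -> PerformanceReport:
    """Confusion matrix of a call set against the activation ground truth.

    Every called variant must carry a truth label.  ``validated_call_rate``
    is computed on the called set (TP / calls); ``specificity`` is the
    classical TN / (TN + FP) over all labeled variants.
    """
    calls = set(calls)
    unlabeled = calls - truth.variants
    if unlabeled:
        raise ValueError(f"called variant(s) without a truth label: {sorted(unlabeled)}")
    cognate = truth.cognate
    tp = len(calls & cognate)
    fp = len(calls - cognate)
    fn = len(cognate - calls)
    tn = len(truth.variants - cognate - calls)
    return PerformanceReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        validated_call_rate=_safe_div(tp, len(calls)),
        n_calls=len(calls),
    )


def roc_curve(
    scores: Mapping[str, float], truth: GroundTruthTable
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and trapezoid AUC from a variant score map.

    Scores are swept descending with ties grouped; needs at least one
    cognate and one non-cognate labeled variant.  Scores here are typically
    the mean normalized enrichment ratios of the experimental arm.
    """
    variants = [v for v in scores if v in truth.variants]
    missing = set(scores) - truth.variants
    if missing:
        raise ValueError(f"scored variant(s) without a truth label: {sorted(missing)}")
    y = np.array([truth.table.loc[v, "cognate"] for v in variants], dtype=bool)
    s = np.array([scores[v] for v in variants], dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC needs at least one cognate and one non-cognate variant")
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return [(float(a), float(b)) for a, b in zip(fpr, tpr)], auc


def plot_roc(
    points: Iterable[tuple[float, float]], path: str | Path, auc: float | None = None
) -> None:
    """Write a ROC plot to an image file (matplotlib, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = list(points)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([p[0] for p in pts], [p[1] for p in pts], marker="o", lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("False-positive rate (1 - specificity)")
    ax.set_ylabel("True-positive rate (sensitivity)")
    if auc is not None:
        ax.set_title(f"AUC = {auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "GroundTruthTable",
    "PerformanceReport",
    "label_ground_truth",
    "plot_roc",
    "roc_curve",
    "screen_performance",
]
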