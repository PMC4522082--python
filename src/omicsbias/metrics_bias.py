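"""Confusion metrics with NaN semantics, the diagnostic index β, and the
rule-based classification of the three diagnostic biases.

A biased kernel classifier on skewed omics data can print a "reasonable"
accuracy that is really just the majority-count ratio.  The bias report
combines the Gram-matrix structure, the accuracy's relation to that ratio,
and the sensitivity/specificity gap into one of five verdicts:

* overfitting — identity-like Gram: every test sample gets the majority
  label, accuracy collapses to the majority ratio, specificity to 0.
* underfitting — constant (flat) Gram: no discrimination, accuracy ≈ 0.5.
* explicit label skew — normal Gram but accuracy ≈ majority ratio with a
  large sensitivity/specificity gap.
* implicit label skew — normal Gram, accuracy clearly above the majority
  ratio, yet the sensitivity/specificity gap persists (the deceptive case).
* none — no bias signature.

Any 0/0 ratio (e.g. NPR when nothing is predicted negative) is NaN, not an
error, and NaN propagates through fold averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import LabelCounts

BIAS_TYPES = ("overfitting", "explicit_label_skew", "implicit_label_skew",
              "underfitting", "none")

# Rule thresholds: the verbal criteria "close to the majority-count ratio"
# and "imbalanced sensitivity and specificity" made numeric.  Configurable
# per call.
DELTA_SPECIFICITY = 0.05
DELTA_ACCURACY = 0.025
DELTA_RANDOM = 0.10
DELTA_GAP = 0.30


@dataclass
class DiagnosticMetrics:
    """Confusion counts and the derived ratios (possibly NaN)."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppr: float = field(init=False)
    npr: float = field(init=False)

    def __post_init__(self):
        def ratio(num, den):
            return num / den if den > 0 else math.nan

        total = self.tp + self.fp + self.tn + self.fn
        self.accuracy = ratio(self.tp + self.tn, total)
        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.ppr = ratio(self.tp, self.tp + self.fp)
        self.npr = ratio(self.tn, self.tn + self.fn)


@dataclass
class BiasReport:
    """Bias verdict plus the quantitative evidence behind it."""

    bias_type: str
    evidence: dict


def confusion_metrics(y_true, y_pred) -> DiagnosticMetrics:
    """Score ±1 predictions against ±1 truth; +1 is the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    for arr in (y_true, y_pred):
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError("labels must be -1 or +1")
    return DiagnosticMetrics(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def diagnostic_index(accuracy: float, sensitivity: float,
                     specificity: float) -> float:
    """β = −log₂(a) − log₂((s + p)/2); 0 is perfect, large flags bias.

    Reported to 4 decimals in output tables; s + p = 0 yields +inf.
    """
    if not 0 < accuracy <= 1:
        raise ValueError("accuracy must be in (0, 1]")
    for v, name in ((sensitivity, "sensitivity"), (specificity, "specificity")):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    sp = (sensitivity + specificity) / 2.0
    if sp == 0:
        return math.inf
    return -math.log2(accuracy) - math.log2(sp)


def majority_ratio(counts: LabelCounts) -> float:
    """Majority-count ratio: the deceptive accuracy floor of a biased model."""
    if counts.total == 0:
        raise ValueError("empty label set")
    return counts.majority_count / counts.total


def classify_bias(metrics: DiagnosticMetrics, counts: LabelCounts,
                  gram_structure: str, alpha_report=None,
                  delta_spec: float = DELTA_SPECIFICITY,
                  delta_acc: float = DELTA_ACCURACY,
                  delta_rand: float = DELTA_RANDOM,
                  delta_gap: float = DELTA_GAP) -> BiasReport:
    """Apply the bias rule cascade to aggregated metrics.

    ``metrics`` should be aggregated over an evaluation scheme (mean
    accuracy etc.); ``gram_structure`` is the structure of the training
    Gram matrix; ``alpha_report`` optionally supplies the signed-weight
    tallies for the evidence record.
    """
    ratio = majority_ratio(counts)
    a, s, p = metrics.accuracy, metrics.sensitivity, metrics.specificity
    gap = abs(s - p) if not (math.isnan(s) or math.isnan(p)) else math.nan
    sp_ok = not math.isnan(a)
    beta = diagnostic_index(a, s, p) if (
        sp_ok and a > 0 and not math.isnan(gap)) else math.nan

    bias = "none"
    if gram_structure == "identity_like" and not math.isnan(p) \
            and p <= delta_spec and abs(a - ratio) <= delta_acc:
        bias = "overfitting"
    elif gram_structure == "flat_like" and sp_ok and a <= 0.5 + delta_rand:
        bias = "underfitting"
    elif gram_structure == "normal" and not math.isnan(gap) and gap >= delta_gap:
        # a large sensitivity/specificity gap on a normal Gram is label
        # skew; accuracy at-or-below ~the majority ratio is the explicit
        # (deceptive-accuracy) form, accuracy clearly above it the
        # implicit form
        if a <= ratio + delta_acc:
            bias = "explicit_label_skew"
        else:
            bias = "implicit_label_skew"

    evidence = {
        "gram_structure": gram_structure,
        "majority_ratio": ratio,
        "accuracy_gap_to_majority": a - ratio if sp_ok else math.nan,
        "sens_spec_gap": gap,
        "beta": beta,
    }
    if alpha_report is not None:
        evidence["alpha_sign_counts"] = (alpha_report.n_positive_sign,
                                         alpha_report.n_negative_sign)
        evidence["bias_sign"] = alpha_report.bias_sign
    return BiasReport(bias_type=bias, evidence=evidence)


def aggregate(fold_metrics: list) -> dict:
    """Mean ± std of each metric across folds; NaN in any fold propagates.

    Returns ``{metric: (mean, std)}`` with the population std (ddof 0 is
    not used; ddof 1 matches the ± std convention of k-fold tables).
    """
    if not fold_metrics:
        raise ValueError("no folds to aggregate")
    out = {}
    for name in ("accuracy", "sensitivity", "specificity", "ppr", "npr"):
        vals = np.array([getattr(f, name) for f in fold_metrics], dtype=float)
        if np.isnan(vals).any():
            out[name] = (math.nan, math.nan)
        else:
            std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            out[name] = (float(vals.mean()), std)
    return out


def mean_metrics(fold_metrics: list) -> DiagnosticMetrics:
    """Pool fold confusion counts into one DiagnosticMetrics whose ratio
    fields are then overwritten with the per-fold means (the convention the
    bias rules are calibrated to)."""
    pooled = DiagnosticMetrics(
        tp=sum(f.tp for f in fold_metrics),
        fp=sum(f.fp for f in fold_metrics),
        tn=sum(f.tn for f in fold_metrics),
        fn=sum(f.fn for f in fold_metrics),
    )
    agg = aggregate(fold_metrics)
    for name in ("accuracy", "sensitivity", "specificity", "ppr", "npr"):
        setattr(pooled, name, agg[name][0])
    return pooled
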