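"""Evaluation schemes (k-fold CV, LOOCV, Monte-Carlo half splits) and the
experiment runner: data → classifier → per-fold metrics → bias report.

All randomness flows from the scheme seed, so equal seeds reproduce
identical reports.  The positive class is mapped to the majority-count
type by default (labels are flipped if needed), matching the convention
under which an all-majority prediction shows sensitivity 1 and
specificity 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import dca_svm, lssvm, metrics_bias
from .data_model import ExpressionDataset, label_counts, standardize_samples
from .dca import DCAParams
from .kernels import KernelSpec, classify_gram, gram, rbf2_bandwidth


@dataclass(frozen=True)
class EvalScheme:
    """kfold (k disjoint folds), loocv, or monte_carlo half splits.

    monte_carlo ``split_mode``: "fixed_half" draws exactly ⌈n/2⌉ training
    samples per repetition; "bernoulli_half" gives each sample an
    independent fair coin (repetitions with an empty side are redrawn).
    """

    kind: str = "kfold"
    k: int = 5
    reps: int = 500
    train_fraction: float = 0.5
    split_mode: str = "fixed_half"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("kfold", "loocv", "monte_carlo"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.kind == "monte_carlo":
            if self.reps < 1:
                raise ValueError("reps must be >= 1")
            if self.split_mode not in ("fixed_half", "bernoulli_half"):
                raise ValueError(f"unknown split_mode {self.split_mode!r}")


@dataclass
class ExperimentResult:
    """Aggregated metrics, per-fold detail, and the bias verdict."""

    aggregate: dict               # metric -> (mean, std)
    fold_metrics: list
    bias_report: metrics_bias.BiasReport
    alpha_reports: list
    gram_structure: str
    scheme: EvalScheme
    classifier: str
    flipped_labels: bool = False


def split_indices(scheme: EvalScheme, n: int):
    """Materialize the (train_idx, test_idx) pairs for ``n`` samples."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(scheme.seed)
    if scheme.kind == "kfold":
        if n < scheme.k:
            raise ValueError(f"n={n} is smaller than k={scheme.k}")
        perm = rng.permutation(n)
        folds = np.array_split(perm, scheme.k)
        return [(np.sort(np.setdiff1d(perm, f)), np.sort(f)) for f in folds]
    if scheme.kind == "loocv":
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in idx]
    splits = []
    n_train = math.ceil(n * scheme.train_fraction)
    for _ in range(scheme.reps):
        if scheme.split_mode == "fixed_half":
            perm = rng.permutation(n)
            tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        else:
            while True:
                mask = rng.random(n) < scheme.train_fraction
                if 0 < mask.sum() < n:
                    break
            tr, te = np.nonzero(mask)[0], np.nonzero(~mask)[0]
        splits.append((tr, te))
    return splits


def _resolve_kernel(spec: KernelSpec, X_train: np.ndarray) -> KernelSpec:
    """rbf2 sets its bandwidth to the total variation of the training set."""
    if spec.family == "rbf2":
        return KernelSpec("rbf2", bandwidth_sq=rbf2_bandwidth(X_train))
    return spec


def run_experiment(X: ExpressionDataset, classifier_spec, scheme: EvalScheme,
                   C: float = 1.0, dca_params: DCAParams | None = None,
                   map_majority_positive: bool = True,
                   stratified: bool = False) -> ExperimentResult:
    """Evaluate one classifier under one scheme and classify its bias.

    ``classifier_spec`` is a :class:`~omicsbias.kernels.KernelSpec` for a
    plain LS-SVM or the string ``"dca_svm"`` for the composed pipeline.
    """
    counts = label_counts(X.labels)
    labels = X.labels.copy()
    flipped = False
    if map_majority_positive and counts.majority_label == -1:
        labels = -labels
        counts = label_counts(labels)
        flipped = True

    Z = standardize_samples(X).values
    n = Z.shape[1]
    is_dca = isinstance(classifier_spec, str)
    if is_dca and classifier_spec != "dca_svm":
        raise ValueError(f"unknown classifier {classifier_spec!r}")

    splits = split_indices(scheme, n)
    if stratified and scheme.kind == "kfold":
        splits = _stratified_kfold(scheme, labels)

    fold_metrics, alpha_reports = [], []
    for fold_no, (tr, te) in enumerate(splits):
        ytr, yte = labels[tr], labels[te]
        if len(set(ytr.tolist())) < 2:
            raise ValueError(
                f"fold {fold_no}: training split contains a single class; "
                "use a stratified scheme or larger folds"
            )
        try:
            if is_dca:
                model = dca_svm.fit(Z[:, tr], ytr, params=dca_params, C=C,
                                    assume_standardized=True)
                pred = dca_svm.predict(model, Z[:, te],
                                       assume_standardized=True)
                alpha_reports.append(
                    lssvm.signed_alpha_report(model.lssvm_model))
            else:
                spec = _resolve_kernel(classifier_spec, Z[:, tr])
                model = lssvm.fit(Z[:, tr], ytr, spec, C=C)
                pred = lssvm.predict(model, Z[:, te])
                alpha_reports.append(lssvm.signed_alpha_report(model))
        except Exception as exc:
            raise RuntimeError(f"classifier failed on fold {fold_no}: {exc}"
                               ) from exc
        fold_metrics.append(metrics_bias.confusion_metrics(yte, pred))

    # Gram structure of the full training Gram (the bias fingerprint)
    if is_dca:
        full = dca_svm.fit(Z, labels, params=dca_params, C=C,
                           assume_standardized=True)
        structure = gram(full.lssvm_model.spec,
                         full.train_true_signals).structure
    else:
        spec = _resolve_kernel(classifier_spec, Z)
        structure = gram(spec, Z).structure

    agg = metrics_bias.aggregate(fold_metrics)
    mean = metrics_bias.mean_metrics(fold_metrics)
    report = metrics_bias.classify_bias(
        mean, counts, structure,
        alpha_report=alpha_reports[0] if alpha_reports else None)
    return ExperimentResult(
        aggregate=agg, fold_metrics=fold_metrics, bias_report=report,
        alpha_reports=alpha_reports, gram_structure=structure,
        scheme=scheme,
        classifier="dca_svm" if is_dca else classifier_spec.family,
        flipped_labels=flipped,
    )


def _stratified_kfold(scheme: EvalScheme, labels: np.ndarray):
    """Per-class round-robin fold assignment (deterministic given seed)."""
    rng = np.random.default_rng(scheme.seed)
    assign = np.empty(labels.size, dtype=int)
    for cls in (-1, 1):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % scheme.k
    all_idx = np.arange(labels.size)
    return [(all_idx[assign != f], all_idx[assign == f])
            for f in range(scheme.k)]
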