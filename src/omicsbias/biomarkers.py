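"""Phenotype separation: gaussianizing transform for count data, DCA true
signals, two-sample t-test ranking, and top-k biomarker coordinate export.

Count (negative-binomial) data are first pushed toward normality with
Y = E(log(X+1)) / var(log(X+1)): log-transform, center each sample column
by its mean, and divide element-wise by that column's variance.  DCA then
denoises, and a classic pooled-variance two-sample t-test ranks features
by p-value.  No multiple-testing correction drives the ranking; a
Benjamini–Hochberg column is attached for information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import dca
from .data_model import ExpressionDataset


@dataclass
class BiomarkerRanking:
    """Features ordered by ascending p-value, plus the true-signal matrix
    the coordinates are read from."""

    feature_ids: list
    p_values: np.ndarray
    t_statistics: np.ndarray
    adjusted_p: np.ndarray
    order: np.ndarray             # ranked positions into the original rows
    true_signals: np.ndarray      # p x n denoised matrix (original row order)
    sample_ids: list
    labels: np.ndarray


def gaussianize(ds: ExpressionDataset, mode: str = "variance"
                ) -> ExpressionDataset:
    """Approximate-normality transform for non-negative count data.

    Pass-through when the dataset is already tagged normal.  ``mode``
    "variance" divides the column-centered log counts by the column
    variance (the literal reading); "std" divides by the standard
    deviation (ordinary z-scoring).
    """
    if ds.distribution_tag == "normal":
        return ds
    if mode not in ("variance", "std"):
        raise ValueError(f"unknown mode {mode!r}")
    X = ds.values
    if (X < 0).any():
        raise ValueError("gaussianize requires non-negative values")
    L = np.log(X + 1.0)
    mean = L.mean(axis=0, keepdims=True)
    var = L.var(axis=0, ddof=1, keepdims=True)
    bad = np.nonzero(var.ravel() == 0)[0]
    if bad.size:
        raise ValueError(
            f"sample {ds.sample_ids[bad[0]]!r} has zero log-count variance"
        )
    denom = var if mode == "variance" else np.sqrt(var)
    return ds.with_values((L - mean) / denom, distribution_tag="normal")


def rank_biomarkers(ds: ExpressionDataset,
                    dca_params: dca.DCAParams | None = None,
                    equal_var: bool = True) -> BiomarkerRanking:
    """Gaussianize (if counts), denoise with DCA, rank features by the
    two-sample t-test between the +1 and −1 classes.

    Features with zero pooled variance get p = 1 and t = 0.
    """
    pos = ds.labels == 1
    neg = ds.labels == -1
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    work = gaussianize(ds) if ds.distribution_tag != "normal" else ds
    res = dca.transform(work.values, dca_params)
    Y = res.true_signals
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(Y[:, pos], Y[:, neg], axis=1,
                               equal_var=equal_var)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    order = np.lexsort((np.arange(p.size), p))
    adj = multipletests(p, method="fdr_bh")[1]
    return BiomarkerRanking(
        feature_ids=[ds.feature_ids[i] for i in order],
        p_values=p[order],
        t_statistics=t[order],
        adjusted_p=adj[order],
        order=order,
        true_signals=Y,
        sample_ids=list(ds.sample_ids),
        labels=ds.labels.copy(),
    )


def export_top_k(ranking: BiomarkerRanking, k: int = 3) -> pd.DataFrame:
    """k × n table of true-signal coordinates for the top-k biomarkers,
    with a final ``label`` row — the input for external 3-D scatter plots."""
    if k < 0 or k > len(ranking.feature_ids):
        raise ValueError(f"k={k} outside [0, {len(ranking.feature_ids)}]")
    rows = ranking.true_signals[ranking.order[:k]]
    df = pd.DataFrame(rows, index=ranking.feature_ids[:k],
                      columns=ranking.sample_ids)
    df.loc["label"] = ranking.labels
    if k == 0:
        df = df.iloc[0:0]
    return df
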