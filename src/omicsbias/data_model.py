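"""Expression-matrix container, delimited-text I/O, and sample-wise scaling.

The universal input is a features × samples matrix: continuous intensities
for gene/protein array data (approximately normal after upstream
normalization) or non-negative integer counts for RNA-Seq/miRNA-Seq data
(approximately negative binomial).  Labels are binary phenotypes coded
−1/+1, with +1 conventionally assigned to the majority-count class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_TAGS = ("normal", "negative_binomial", "unknown")


@dataclass
class ExpressionDataset:
    """A features × samples expression matrix with identifiers and labels.

    Parameters
    ----------
    values : ndarray of shape (p, n)
        Expression values; rows are features, columns are samples.
    feature_ids : list of str, length p
    sample_ids : list of str, length n
    labels : ndarray of int, length n
        Phenotype labels in {−1, +1}.
    distribution_tag : {"normal", "negative_binomial", "unknown"}
        Declared generative family; drives e.g. the gaussianizing transform.
    """

    values: np.ndarray
    feature_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    labels: np.ndarray = None
    distribution_tag: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (features x samples) matrix")
        p, n = self.values.shape
        if not self.feature_ids:
            self.feature_ids = [f"f{i}" for i in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(n)]
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")
        if self.labels is None:
            raise ValueError("labels are required")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (n,):
            raise ValueError(
                f"labels length {self.labels.size} does not match sample count {n}"
            )
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be -1 or +1")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        if self.distribution_tag not in VALID_TAGS:
            raise ValueError(f"unknown distribution_tag {self.distribution_tag!r}")
        if self.distribution_tag == "negative_binomial":
            v = self.values
            if (v < 0).any():
                raise ValueError("count data must be non-negative")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, distribution_tag: str | None = None):
        """Return a copy sharing identifiers/labels but with new values."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            distribution_tag=distribution_tag or self.distribution_tag,
        )


@dataclass(frozen=True)
class LabelCounts:
    """Class counts with the majority-count convention (ties resolve to +1)."""

    n_positive: int
    n_negative: int

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative

    @property
    def majority_label(self) -> int:
        return 1 if self.n_positive >= self.n_negative else -1

    @property
    def majority_count(self) -> int:
        return max(self.n_positive, self.n_negative)


def label_counts(labels) -> LabelCounts:
    """Count −1/+1 labels and identify the majority-count class."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be -1 or +1")
    return LabelCounts(
        n_positive=int(np.sum(labels == 1)), n_negative=int(np.sum(labels == -1))
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(path, labels_path, distribution_tag="unknown") -> ExpressionDataset:
    """Read a delimited expression matrix and a sample → label map.

    The matrix file has feature ids in the first column and sample ids in
    the header; the labels file has two columns (sample id, label) where a
    label token is "+1"/"1"/"-1".  Every sample column must have a label.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     float_precision="round_trip")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in expression matrix: {exc}")
    lab = pd.read_csv(labels_path, sep=_sniff_sep(labels_path), header=None,
                      comment="#", dtype=str)
    if lab.shape[1] < 2:
        raise ValueError(f"{labels_path}: expected two columns (sample id, label)")
    mapping = {}
    for sid, tok in zip(lab.iloc[:, 0], lab.iloc[:, 1]):
        tok = str(tok).strip()
        if tok in ("+1", "1"):
            mapping[str(sid)] = 1
        elif tok == "-1":
            mapping[str(sid)] = -1
        else:
            raise ValueError(f"{labels_path}: unknown label token {tok!r}")
    sample_ids = [str(c) for c in df.columns]
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples missing a label: {missing}")
    labels = np.array([mapping[s] for s in sample_ids], dtype=int)
    return ExpressionDataset(
        values=values,
        feature_ids=[str(i) for i in df.index],
        sample_ids=sample_ids,
        labels=labels,
        distribution_tag=distribution_tag,
    )


def write_expression(ds: ExpressionDataset, path, labels_path, sep="\t"):
    """Write the matrix and label files in the format read_expression expects."""
    df = pd.DataFrame(ds.values, index=ds.feature_ids, columns=ds.sample_ids)
    df.to_csv(path, sep=sep, float_format="%.17g")
    lab = pd.DataFrame({"sample": ds.sample_ids,
                        "label": ["%+d" % y for y in ds.labels]})
    lab.to_csv(labels_path, sep=sep, header=False, index=False)


# ---------------------------------------------------------------------------
# Scaling primitives


def standardize_samples(ds: ExpressionDataset, axis="samples") -> ExpressionDataset:
    """Scale each sample (column) to zero mean and unit variance.

    Variance uses the p−1 denominator.  ``axis="features"`` switches to
    row-wise scaling for the equivalent per-feature reading.
    """
    X = ds.values
    ax = 0 if axis == "samples" else 1
    mean = X.mean(axis=ax, keepdims=True)
    sd = X.std(axis=ax, ddof=1, keepdims=True)
    bad = np.nonzero(sd.ravel() == 0)[0]
    if bad.size:
        ids = ds.sample_ids if axis == "samples" else ds.feature_ids
        raise ValueError(
            f"constant {axis[:-1]} cannot be standardized: {ids[bad[0]]!r}"
        )
    return ds.with_values((X - mean) / sd, distribution_tag="unknown")


def q3_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Divide each sample by its upper-quartile scale factor s = Q3/1000."""
    X = ds.values
    q3 = np.percentile(X, 75, axis=0)
    bad = np.nonzero(q3 <= 0)[0]
    if bad.size:
        raise ValueError(
            f"sample {ds.sample_ids[bad[0]]!r} has non-positive 75th percentile"
        )
    return ds.with_values(X / (q3 / 1000.0))


def cpm_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Adjust all counts in each sample to reads per million (column sum 1e6)."""
    X = ds.values
    colsum = X.sum(axis=0)
    bad = np.nonzero(colsum <= 0)[0]
    if bad.size:
        raise ValueError(f"sample {ds.sample_ids[bad[0]]!r} has zero total count")
    return ds.with_values(X * (1e6 / colsum))
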