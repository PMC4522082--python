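"""Kernel functions, Gram matrices, and Gram-structure diagnostics.

High-throughput profiling amplifies expression levels exponentially, so
pairwise sample distances are large even after per-sample standardization.
Under a Gaussian kernel with a small bandwidth this collapses the Gram
matrix to (approximately) the identity — the fingerprint of the
overfitting bias — while an ill-chosen sigmoid-type kernel can collapse it
to a constant matrix, the fingerprint of the underfitting bias.  The
structure classifier below detects both degeneracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

KERNEL_FAMILIES = ("linear", "rbf", "rbf2", "quad", "mlp")

#: off-diagonal magnitude below which a Gram matrix counts as identity-like
EPS_IDENTITY = 1e-8
#: entry range below which a Gram matrix counts as flat (constant)
EPS_FLAT = 1e-8

#: rbf2 bandwidth averages squared distances over all ordered pairs (i, j),
#: including the zero i = j terms, divided by (m-1)^2
RBF2_INCLUDES_DIAGONAL = True


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its bandwidth (Gaussian families only).

    family : {"linear", "rbf", "rbf2", "quad", "mlp"}
    bandwidth_sq : σ² for the Gaussian exp(−‖x−x′‖²/2σ²); default 1.
    """

    family: str
    bandwidth_sq: float | None = None

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family in ("rbf", "rbf2"):
            bw = 1.0 if self.bandwidth_sq is None else float(self.bandwidth_sq)
            if bw <= 0:
                raise ValueError("bandwidth_sq must be positive")
            object.__setattr__(self, "bandwidth_sq", bw)
        elif self.bandwidth_sq is not None:
            raise ValueError(f"{self.family!r} kernel takes no bandwidth")


@dataclass
class GramMatrix:
    """An evaluated m×m kernel matrix with structure annotations."""

    values: np.ndarray
    spec: KernelSpec
    structure: str = "normal"
    max_offdiag: float = np.nan
    min_entry: float = np.nan


@dataclass(frozen=True)
class DistanceSummary:
    """Five-number summary of pairwise squared sample distances."""

    min_sq: float
    quartiles_sq: tuple
    max_sq: float


def kernel_value(spec: KernelSpec, x, x2) -> float:
    """Evaluate k(x, x′) for one pair of equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError("sample vectors have mismatched lengths")
    if spec.family in ("rbf", "rbf2"):
        d2 = float(np.sum((x - x2) ** 2))
        return float(np.exp(-d2 / (2.0 * spec.bandwidth_sq)))
    dot = float(x @ x2)
    if spec.family == "linear":
        return dot
    if spec.family == "quad":
        return (1.0 + dot) ** 2
    return float(np.tanh(dot - 1.0))  # mlp


def rbf2_bandwidth(X_samples: np.ndarray) -> float:
    """Adaptive bandwidth: total variation of the m training samples.

    σ² = (1/(m−1)²) Σ_{i,j} ‖x_i − x_j‖² over ordered pairs, the i = j
    terms contributing zero.  ``X_samples`` holds samples as columns.
    """
    X = np.asarray(X_samples, dtype=float)
    m = X.shape[1]
    if m < 2:
        raise ValueError("rbf2 bandwidth needs at least 2 samples")
    d2 = pdist(X.T, metric="sqeuclidean")
    total = 2.0 * float(d2.sum())  # ordered pairs double each unordered one
    sigma_sq = total / (m - 1) ** 2
    if sigma_sq == 0:
        raise ValueError("all samples identical; rbf2 bandwidth is zero")
    return sigma_sq


def _pairwise_kernel(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    # A, B: samples as columns
    if spec.family in ("rbf", "rbf2"):
        d2 = cdist(A.T, B.T, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * spec.bandwidth_sq))
    G = A.T @ B
    if spec.family == "linear":
        return G
    if spec.family == "quad":
        return (1.0 + G) ** 2
    return np.tanh(G - 1.0)


def gram(spec: KernelSpec, X_rows: np.ndarray, X_cols: np.ndarray | None = None):
    """Evaluate the kernel over two sample sets (columns = samples).

    With one argument, returns a square annotated :class:`GramMatrix`;
    with two, returns the rectangular cross-kernel block as an ndarray.
    """
    A = np.asarray(X_rows, dtype=float)
    if X_cols is not None:
        B = np.asarray(X_cols, dtype=float)
        if A.shape[0] != B.shape[0]:
            raise ValueError("sample sets have mismatched feature counts")
        return _pairwise_kernel(spec, A, B)
    K = _pairwise_kernel(spec, A, A)
    K = (K + K.T) / 2.0  # enforce exact symmetry against float noise
    gm = GramMatrix(values=K, spec=spec)
    gm.structure = classify_gram(gm)
    return gm


def classify_gram(K, eps_identity: float = EPS_IDENTITY,
                  eps_flat: float = EPS_FLAT) -> str:
    """Classify a square Gram matrix as identity_like, flat_like, or normal.

    identity_like: all off-diagonal magnitudes below ``eps_identity`` and the
    diagonal within ``eps_identity`` of 1 (Gaussian kernel collapse).
    flat_like: entry range below ``eps_flat`` — a constant matrix, covering
    the all-ones sigmoid collapse.
    """
    V = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("Gram matrix must be square")
    off = V - np.diag(np.diag(V))
    max_offdiag = float(np.max(np.abs(off))) if V.shape[0] > 1 else 0.0
    min_entry = float(V.min())
    if isinstance(K, GramMatrix):
        K.max_offdiag = max_offdiag
        K.min_entry = min_entry
    if max_offdiag < eps_identity and np.max(np.abs(np.diag(V) - 1.0)) < eps_identity:
        return "identity_like"
    if float(V.max()) - min_entry < eps_flat:
        return "flat_like"
    return "normal"


def distance_summary(X_samples: np.ndarray) -> DistanceSummary:
    """Summarize ‖x_i − x_j‖² over all unordered sample pairs i < j."""
    X = np.asarray(X_samples, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d2 = pdist(X.T, metric="sqeuclidean")
    q = np.percentile(d2, (25, 50, 75))
    return DistanceSummary(
        min_sq=float(d2.min()),
        quartiles_sq=(float(q[0]), float(q[1]), float(q[2])),
        max_sq=float(d2.max()),
    )
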