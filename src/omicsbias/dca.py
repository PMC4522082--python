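"""Derivative component analysis (DCA): wavelet-domain low-rank denoising.

Each sample (column) is decomposed with a J-level discrete wavelet
transform; the per-level coefficient matrices are then denoised by
replacing each with its per-column mean plus a low-rank PCA reconstruction
of the column-centered matrix; the inverse transform yields "true
signals" of the original shape.  The finest detail levels (j ≤ τ), which
carry mostly system noise, are reconstructed from a fixed small number of
components (first PC by default); coarser details and the approximation
keep enough components to explain a target fraction of variance (95 % by
default), preserving global structure.

The transform uses the periodized boundary so that level-j coefficient
length is exactly ⌈p/2^j⌉ and reconstruction is lossless when every
component is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .data_model import ExpressionDataset


@dataclass(frozen=True)
class DCAParams:
    """Tunable controls of the transform.

    wavelet : orthogonal discrete wavelet name (default "db8")
    level_J : decomposition depth (default 7); requires p ≥ 2^J
    cutoff_tau : finest levels 1..τ use the fixed-rank rule (default 2)
    detail_components_m : rank for levels j ≤ τ (default 1, first PC)
    tail_variability_rho : variance fraction kept at levels j > τ and the
        approximation (default 0.95); ρ = 1 keeps everything (lossless)
    """

    wavelet: str = "db8"
    level_J: int = 7
    cutoff_tau: int = 2
    detail_components_m: int = 1
    tail_variability_rho: float = 0.95

    def __post_init__(self):
        if not 1 <= self.cutoff_tau <= self.level_J:
            raise ValueError("need 1 <= cutoff_tau <= level_J")
        if not 0 < self.tail_variability_rho <= 1:
            raise ValueError("tail_variability_rho must be in (0, 1]")
        if self.detail_components_m < 1:
            raise ValueError("detail_components_m must be >= 1")
        if self.wavelet not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {self.wavelet!r}")


@dataclass
class WaveletStack:
    """Per-level DWT coefficient matrices for a p×n input.

    details[j-1] is cD_j of shape (⌈p/2^j⌉, n); approximation is cA_J.
    """

    details: list
    approximation: np.ndarray
    original_length: int

    @property
    def level_J(self) -> int:
        return len(self.details)


@dataclass
class DCAResult:
    """True-signal matrix X* (same shape as input) plus the ranks used."""

    true_signals: np.ndarray
    params: DCAParams
    per_level_rank: list = field(default_factory=list)


def _as_matrix(X):
    if isinstance(X, ExpressionDataset):
        return X.values
    return np.asarray(X, dtype=float)


def decompose(X, params: DCAParams) -> WaveletStack:
    """Column-wise J-level DWT with periodized boundary."""
    M = _as_matrix(X)
    if M.ndim != 2:
        raise ValueError("input must be a 2-D (features x samples) matrix")
    p = M.shape[0]
    if p < 2 ** params.level_J:
        raise ValueError(
            f"feature count {p} is too short for a {params.level_J}-level "
            f"transform (need p >= {2 ** params.level_J})"
        )
    with warnings.catch_warnings():
        # depth beyond pywt's filter-length heuristic is intentional:
        # periodization keeps halving exactly
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(M, params.wavelet, mode="periodization",
                              level=params.level_J, axis=0)
    cA = coeffs[0]
    details = list(reversed(coeffs[1:]))  # details[j-1] = cD_j (finest first)
    return WaveletStack(details=details, approximation=cA, original_length=p)


def reconstruct(stack: WaveletStack, params: DCAParams) -> np.ndarray:
    """Inverse DWT of a coefficient stack, trimmed to the original length."""
    coeffs = [stack.approximation] + list(reversed(stack.details))
    out = pywt.waverec(coeffs, params.wavelet, mode="periodization", axis=0)
    return out[: stack.original_length]


def pca_reconstruct(M: np.ndarray, m: int | None = None,
                    rho: float | None = None, center_axis: str = "columns"):
    """Low-rank denoise one coefficient matrix.

    Returns ``(mean term + rank-m approximation of the centered matrix,
    rank used)``.  Exactly one of ``m`` (fixed rank) or ``rho`` (smallest
    rank whose cumulative variance fraction reaches ρ) must be given.
    Centering is per column (per sample) by default; ``center_axis="rows"``
    switches to per-feature means.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("PCA reconstruction needs a matrix with >= 2 samples")
    if (m is None) == (rho is None):
        raise ValueError("give exactly one of m or rho")
    ax = 0 if center_axis == "columns" else 1
    mean = M.mean(axis=ax, keepdims=True)
    Mc = M - mean
    W, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return mean + Mc, 0  # centered matrix is zero; nothing to keep
    if m is None:
        frac = np.cumsum(var) / total
        m = int(np.searchsorted(frac, rho - 1e-12) + 1)
    m = int(min(m, s.size))
    approx = (W[:, :m] * s[:m]) @ Vt[:m]
    return mean + approx, m


def _denoise_stack(stack: WaveletStack, params: DCAParams,
                   keep_bases: bool = False):
    ranks, new_levels, bases = [], [], []
    levels = list(stack.details) + [stack.approximation]
    for j, M in enumerate(levels, start=1):
        is_detail = j <= stack.level_J
        if is_detail and j <= params.cutoff_tau:
            rec, r = pca_reconstruct(M, m=params.detail_components_m)
        else:
            rec, r = pca_reconstruct(M, rho=params.tail_variability_rho)
        new_levels.append(rec)
        ranks.append(r)
        if keep_bases:
            Mc = M - M.mean(axis=0, keepdims=True)
            W, s, _ = np.linalg.svd(Mc, full_matrices=False)
            bases.append(W[:, :r].copy())
    denoised = WaveletStack(details=new_levels[:-1],
                            approximation=new_levels[-1],
                            original_length=stack.original_length)
    return denoised, ranks, bases


def transform(X, params: DCAParams | None = None) -> DCAResult:
    """Full DCA: decompose, denoise every level, invert.

    Detail levels j ≤ τ use the fixed rank ``detail_components_m``; levels
    j > τ and the approximation use the ``tail_variability_rho`` rule.
    """
    params = params or DCAParams()
    stack = decompose(X, params)
    denoised, ranks, _ = _denoise_stack(stack, params)
    return DCAResult(true_signals=reconstruct(denoised, params),
                     params=params, per_level_rank=ranks)


def fit_transform_bases(X, params: DCAParams | None = None):
    """Like :func:`transform`, but also return the per-level principal
    score bases (left singular vectors) for inductive out-of-sample use."""
    params = params or DCAParams()
    stack = decompose(X, params)
    denoised, ranks, bases = _denoise_stack(stack, params, keep_bases=True)
    res = DCAResult(true_signals=reconstruct(denoised, params),
                    params=params, per_level_rank=ranks)
    return res, bases


def apply_bases(X_new, params: DCAParams, bases: list) -> np.ndarray:
    """Inductive transform: project new samples' centered wavelet
    coefficients onto the frozen training bases at each level and invert."""
    stack = decompose(X_new, params)
    levels = list(stack.details) + [stack.approximation]
    new_levels = []
    for M, W in zip(levels, bases):
        mean = M.mean(axis=0, keepdims=True)
        Mc = M - mean
        new_levels.append(mean + W @ (W.T @ Mc))
    denoised = WaveletStack(details=new_levels[:-1],
                            approximation=new_levels[-1],
                            original_length=stack.original_length)
    return reconstruct(denoised, params)
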