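"""Least-squares SVM: training as one linear system, prediction, and the
signed-support-vector-weight report used in label-skewness analysis.

The LS-SVM replaces the C-SVM's inequality constraints with equalities, so
the dual collapses to the (m+1)×(m+1) linear system

    [ 0   1ᵀ          ] [ b ]   [ 0 ]
    [ 1   K + (1/C) I ] [ α ] = [ y ]

whose solution satisfies Σ α_i = 0.  The decision rule for a new sample is
sign(Σ α_i k(x_i, x′) + b).  All α are generically nonzero (no sparsity);
the sign of y_i attached to |α_i| marks which class each support vector
weight serves, which is the quantity that skews under imbalanced labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .kernels import GramMatrix, KernelSpec, gram

#: |alpha| above this counts as a support-vector weight in reports
SUPPORT_TOL = 1e-12


@dataclass
class LSSVMModel:
    """Trained LS-SVM: dual coefficients plus the data needed to predict."""

    alphas: np.ndarray
    bias: float
    train_samples: np.ndarray  # features x m, standardized
    train_labels: np.ndarray
    spec: KernelSpec
    penalty: float = 1.0

    @property
    def ridge(self) -> float:
        return 1.0 / self.penalty


@dataclass(frozen=True)
class SignedAlphaReport:
    """|α_i| carrying the class sign of sample i, plus sign tallies."""

    signed_alphas: np.ndarray
    n_positive_sign: int
    n_negative_sign: int
    bias_sign: int  # -1, 0, +1


def solve_dual(K: np.ndarray, y: np.ndarray, C: float):
    """Solve the LS-SVM saddle system for (alphas, bias).

    Falls back to least squares with a warning when the system is singular
    or numerically unusable (e.g. the non-PSD sigmoid kernel).
    """
    m = K.shape[0]
    A = np.zeros((m + 1, m + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(m) / C
    rhs = np.concatenate(([0.0], y.astype(float)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
            sol = scipy.linalg.solve(A, rhs, assume_a="sym")
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("non-finite solution")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgWarning, ValueError):
        warnings.warn(
            "LS-SVM system is singular or ill-conditioned; "
            "using least-squares fallback",
            RuntimeWarning,
            stacklevel=2,
        )
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return sol[1:], float(sol[0])


def train(K, y, C: float = 1.0, train_samples=None) -> LSSVMModel:
    """Train an LS-SVM from a precomputed Gram matrix and ±1 labels."""
    if isinstance(K, GramMatrix):
        spec = K.spec
        Kv = K.values
    else:
        spec = KernelSpec("linear")
        Kv = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=int)
    if Kv.ndim != 2 or Kv.shape[0] != Kv.shape[1]:
        raise ValueError("Gram matrix must be square")
    if y.shape != (Kv.shape[0],):
        raise ValueError("label length does not match Gram size")
    if C <= 0:
        raise ValueError("penalty C must be positive")
    alphas, bias = solve_dual(Kv, y, C)
    return LSSVMModel(
        alphas=alphas,
        bias=bias,
        train_samples=None if train_samples is None
        else np.asarray(train_samples, dtype=float),
        train_labels=y,
        spec=spec,
        penalty=float(C),
    )


def fit(X_train: np.ndarray, y, spec: KernelSpec, C: float = 1.0) -> LSSVMModel:
    """Train directly from standardized training samples (columns)."""
    K = gram(spec, X_train)
    return train(K, y, C=C, train_samples=X_train)


def decision_values(model: LSSVMModel, X_new: np.ndarray) -> np.ndarray:
    """Pre-sign decision values Σ α_i k(x_i, x′) + b for each test column."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.size == 0:
        return np.zeros(0)
    if model.train_samples is None:
        raise ValueError("model was trained without stored samples")
    if X_new.shape[0] != model.train_samples.shape[0]:
        raise ValueError("feature-length mismatch with training samples")
    Kx = gram(model.spec, model.train_samples, X_new)  # m x n_new
    return model.alphas @ Kx + model.bias


def predict(model: LSSVMModel, X_new: np.ndarray) -> np.ndarray:
    """Classify test samples; a decision value of exactly 0 maps to +1."""
    f = decision_values(model, X_new)
    return np.where(f >= 0, 1, -1).astype(int)


def signed_alpha_report(model: LSSVMModel) -> SignedAlphaReport:
    """Attach class signs to |α_i| and tally them, mirroring the weight-
    distribution analysis that exposes label-skewness bias."""
    signed = np.abs(model.alphas) * model.train_labels
    nz = np.abs(model.alphas) > SUPPORT_TOL
    return SignedAlphaReport(
        signed_alphas=signed,
        n_positive_sign=int(np.sum(nz & (model.train_labels == 1))),
        n_negative_sign=int(np.sum(nz & (model.train_labels == -1))),
        bias_sign=int(np.sign(model.bias)),
    )
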