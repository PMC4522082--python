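"""Synthetic expression-data generators with the statistical structure the
bias analysis targets: normal intensities or negative-binomial counts,
configurable label skew, a planted class signal, and a control that
installs the large pairwise sample distances produced by the exponential
signal amplification of high-throughput profiling.

Presets mirror the class-count geometry of the benchmark cohorts the
framework was developed against (breast-cancer gene array 13 vs 34,
protein array 78 vs 72, kidney RNA-Seq 68 vs 475, glioma RNA-Seq
18 vs 516, glioma miRNA-Seq 18 vs 512), with the feature count scaled to
2048 by default — enough for a 7-level wavelet transform while keeping
simulations fast; the majority class is always labeled +1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import ExpressionDataset, standardize_samples
from .kernels import distance_summary

#: default feature count (power of two >= 2^7 for the DCA depth)
DEFAULT_P = 2048


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator controls.

    distribution : "normal" (array-like intensities) or
        "negative_binomial" (sequencing-like counts)
    n_majority, n_minority : class sizes; majority is labeled +1
    p : feature count
    n_informative : leading features carrying the class signal
    effect_size : mean shift in noise-SD units (normal) or log2-fold
        change of the count mean (negative binomial)
    nb_dispersion : NB size parameter r (variance μ + μ²/r)
    nb_mean : median count mean; per-feature means are log-normal around it
    baseline_sd : SD of the per-feature baseline shared by all samples.
        Real expression profiles share a strong per-feature baseline
        (housekeeping genes high, others low), which makes samples highly
        correlated after per-sample standardization — the regime in which
        sigmoid-type kernels saturate to a constant Gram matrix.
    amplification : extra per-feature scale on the signal block (0 = off)
    seed : RNG seed
    """

    distribution: str = "normal"
    n_majority: int = 40
    n_minority: int = 10
    p: int = DEFAULT_P
    n_informative: int = 32
    effect_size: float = 1.5
    nb_dispersion: float = 2.0
    nb_mean: float = 100.0
    nb_mean_log_sd: float = 1.0
    baseline_sd: float = 2.0
    amplification: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.distribution not in ("normal", "negative_binomial"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if min(self.n_majority, self.n_minority) < 1:
            raise ValueError("class counts must be >= 1")
        if not 0 <= self.n_informative <= self.p:
            raise ValueError("need 0 <= n_informative <= p")
        if self.nb_dispersion <= 0 or self.nb_mean <= 0:
            raise ValueError("NB mean and dispersion must be positive")
        if self.amplification < 0:
            raise ValueError("amplification must be non-negative")


PRESETS = {
    "breastibc_like": SyntheticSpec(distribution="normal",
                                    n_majority=34, n_minority=13),
    "hcc_like": SyntheticSpec(distribution="normal",
                              n_majority=78, n_minority=72),
    "kidney_like": SyntheticSpec(distribution="negative_binomial",
                                 n_majority=475, n_minority=68),
    "lgg_rnaseq_like": SyntheticSpec(distribution="negative_binomial",
                                     n_majority=516, n_minority=18),
    "lgg_mirnaseq_like": SyntheticSpec(distribution="negative_binomial",
                                       n_majority=512, n_minority=18,
                                       p=1024),
}


def preset(name: str) -> SyntheticSpec:
    """Look up a named cohort-shaped generator spec."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def _nb_draw(rng, mean, size, r):
    # numpy's negative_binomial(n, p) has mean n(1-p)/p; p = r/(r+mu)
    pvec = r / (r + mean)
    return rng.negative_binomial(r, pvec, size=size)


def generate(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw one dataset; the majority class is +1 and column order is a
    seeded shuffle of the two class blocks."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_majority + spec.n_minority
    labels = np.concatenate([np.ones(spec.n_majority, dtype=int),
                             -np.ones(spec.n_minority, dtype=int)])
    order = rng.permutation(n)
    labels = labels[order]
    k = spec.n_informative

    if spec.distribution == "normal":
        baseline = spec.baseline_sd * rng.standard_normal(spec.p)
        X = baseline[:, None] + rng.standard_normal((spec.p, n))
        if k:
            shift = np.where(labels == 1, spec.effect_size / 2.0,
                             -spec.effect_size / 2.0)
            X[:k] += shift
        if spec.amplification:
            X[:k] *= 1.0 + spec.amplification
        tag = "normal"
    else:
        base_mu = spec.nb_mean * np.exp(
            spec.nb_mean_log_sd * rng.standard_normal(spec.p))
        mu = np.tile(base_mu[:, None], (1, n))
        if k:
            fold = 2.0 ** spec.effect_size
            mu[:k, labels == 1] *= fold
        if spec.amplification:
            mu[:k] *= 1.0 + spec.amplification
        X = _nb_draw(rng, mu, (spec.p, n), spec.nb_dispersion).astype(float)
        tag = "negative_binomial"

    return ExpressionDataset(
        values=X,
        feature_ids=[f"g{i}" for i in range(spec.p)],
        sample_ids=[f"s{j}" for j in range(n)],
        labels=labels,
        distribution_tag=tag,
    )


def amplify_to_min_distance(ds: ExpressionDataset, target_min_sq: float,
                            max_p: int = 2 ** 15,
                            seed: int = 12345) -> ExpressionDataset:
    """Grow the feature count until, after per-sample standardization, the
    minimum pairwise squared distance reaches ``target_min_sq``.

    For near-independent noise the squared distance between standardized
    samples grows linearly with dimension, so doubling p (by appending
    noise features drawn to match the distribution tag) drives the minimum
    distance past any finite target; the result is verified with
    :func:`~omicsbias.kernels.distance_summary` before returning.
    """
    if target_min_sq <= 0:
        return ds
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = ds.values
    for i in range(ds.n_samples):
        for j in range(i + 1, ds.n_samples):
            if np.array_equal(X[:, i], X[:, j]):
                raise ValueError(
                    f"samples {ds.sample_ids[i]!r} and {ds.sample_ids[j]!r} "
                    "are identical; the target distance is unreachable"
                )
    rng = np.random.default_rng(seed)
    current = ds
    while True:
        z = standardize_samples(current)
        if distance_summary(z.values).min_sq >= target_min_sq:
            return current
        p = current.n_features
        if 2 * p > max_p:
            raise ValueError(
                f"cannot reach min squared distance {target_min_sq} "
                f"within max_p={max_p}"
            )
        if current.distribution_tag == "negative_binomial":
            extra = _nb_draw(rng, 100.0, (p, current.n_samples), 2.0
                             ).astype(float)
        else:
            extra = rng.standard_normal((p, current.n_samples))
        current = ExpressionDataset(
            values=np.vstack([current.values, extra]),
            feature_ids=list(current.feature_ids)
            + [f"pad{p}_{i}" for i in range(p)],
            sample_ids=list(current.sample_ids),
            labels=current.labels.copy(),
            distribution_tag=current.distribution_tag,
        )


def skewed_signal_fixture(n_minority: int = 16, skew: int = 4, p: int = 256,
                          signal_scale: float = 0.06,
                          noise_scale: float = 1.0, smooth_w: int = 8,
                          n_waves: int = 3, seed: int = 0) -> ExpressionDataset:
    """A 1:``skew`` imbalanced dataset with a smooth (low-frequency) class
    signal buried in high-frequency measurement noise.

    Each sample is ``x = c·A·s + ε`` with ``c = ±1`` the class, ``s`` a sum
    of slow sinusoids over the feature index, and ``ε`` high-pass white
    noise (white noise minus its ``smooth_w``-point moving average,
    rescaled to unit SD) — noise uncorrelated across adjacent features,
    as left by per-feature measurement error once the smooth profile is
    removed.  The class signal concentrates in coarse wavelet levels while
    the noise lives in the fine ones, so wavelet-domain low-rank denoising
    recovers the class structure that the raw linear kernel — at the
    default signal-to-noise ratio, under skewed labels — turns into a
    majority-favoring classifier.
    """
    from scipy.ndimage import uniform_filter1d

    rng = np.random.default_rng(seed)
    n_majority = n_minority * skew
    n = n_majority + n_minority
    labels = np.concatenate([np.ones(n_majority, dtype=int),
                             -np.ones(n_minority, dtype=int)])
    labels = labels[rng.permutation(n)]
    t = np.arange(p) / p
    s = np.zeros(p)
    for f in range(1, n_waves + 1):
        s += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    s /= np.sqrt(np.mean(s ** 2))  # unit RMS
    eps = rng.standard_normal((p, n))
    eps -= uniform_filter1d(eps, size=smooth_w, axis=0)
    eps /= eps.std()
    X = noise_scale * eps + signal_scale * np.outer(s, labels)
    return ExpressionDataset(
        values=X,
        feature_ids=[f"g{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n)],
        labels=labels,
        distribution_tag="normal",
    )
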