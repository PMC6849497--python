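"""Gaussian naive Bayes over the 6-D power features.

Per class, each feature is modelled as an independent Gaussian with the
class's sample mean and sample standard deviation; priors are empirical
class frequencies. The posterior

    p(C_k | F) = p(C_k) * prod_i p(F_i | C_k) / p(F_1..F_n)

is computed in log space with a log-sum-exp evidence: the raw product of
six densities underflows easily (gyro-power SDs are in the thousands),
and log-space normalisation leaves the posterior invariant to any
common positive scaling of the likelihoods. The explicit ``evidence``
function mirrors the total-probability denominator directly and exists
for inspection and testing; ``posterior`` never multiplies raw
densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .features import N_FEATURES
from .knn import TrainingSet
from .signals import CLASS_ORDER, MotionClass, ParameterError

__all__ = [
    "ClassStats",
    "Posterior",
    "FittingError",
    "fit_gaussian_nb",
    "gaussian_likelihood",
    "log_gaussian_likelihood",
    "evidence",
    "posterior",
    "nb_classify",
]

#: Relative variance floor: sigma is floored at 1e-6 x the global
#: (pooled) SD of the feature, and absolutely at 1e-12, so constant
#: features cannot produce infinite densities.
SIGMA_FLOOR_REL = 1e-6
SIGMA_FLOOR_ABS = 1e-12

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class FittingError(ValueError):
    """Training data cannot support the model (e.g. a class with < 2 points)."""


@dataclass(frozen=True)
class ClassStats:
    """Fitted per-class Gaussians and priors.

    ``classes`` lists the fitted classes in enumeration order; row k of
    ``means``/``sds`` holds the six per-feature parameters of class k,
    ``priors[k]`` its empirical frequency. ``sigma_floor`` records the
    per-feature floor actually applied.
    """

    classes: tuple[MotionClass, ...]
    priors: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    sigma_floor: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "priors", np.asarray(self.priors, dtype=float))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(self, "sigma_floor", np.asarray(self.sigma_floor, dtype=float))
        K = len(self.classes)
        if self.priors.shape != (K,) or self.means.shape != (K, N_FEATURES) \
                or self.sds.shape != (K, N_FEATURES):
            raise ParameterError("inconsistent ClassStats shapes")
        if abs(float(self.priors.sum()) - 1.0) > 1e-9:
            raise ParameterError("priors must sum to 1")
        if np.any(self.priors < 0):
            raise ParameterError("priors must be non-negative")
        if np.any(self.sds <= 0):
            raise ParameterError("all standard deviations must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class Posterior:
    """Per-class posterior probabilities, summing to 1."""

    classes: tuple[MotionClass, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (len(self.classes),):
            raise ParameterError("posterior shape mismatch")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12) or abs(p.sum() - 1) > 1e-9:
            raise ParameterError("posterior entries must lie in [0,1] and sum to 1")

    def __getitem__(self, c: MotionClass) -> float:
        return float(self.probs[self.classes.index(c)])

    def top(self) -> MotionClass:
        """Maximum-posterior class; ties go to the earlier enumeration member."""
        best = np.max(self.probs)
        tied = [c for c, p in zip(self.classes, self.probs) if p == best]
        return min(tied, key=lambda c: CLASS_ORDER[c])


def fit_gaussian_nb(train: TrainingSet) -> ClassStats:
    """Fit per-class feature means/SDs and empirical priors.

    Sample statistics use the n-1 denominator; every class needs at
    least 2 training points. SDs are floored (see module constants) so
    degenerate, zero-variance features keep a proper density.
    """
    classes = train.classes
    y = np.asarray(train.y, dtype=object)
    global_sd = np.std(train.X, axis=0, ddof=1) if len(train) > 1 else np.zeros(N_FEATURES)
    floor = np.maximum(SIGMA_FLOOR_REL * global_sd, SIGMA_FLOOR_ABS)

    priors, means, sds = [], [], []
    for c in classes:
        Xc = train.X[y == c]
        if Xc.shape[0] < 2:
            raise FittingError(
                f"class {c.value!r} has {Xc.shape[0]} training point(s); need >= 2"
            )
        priors.append(Xc.shape[0] / len(train))
        means.append(Xc.mean(axis=0))
        sds.append(np.maximum(Xc.std(axis=0, ddof=1), floor))
    return ClassStats(
        classes=classes,
        priors=np.asarray(priors),
        means=np.asarray(means),
        sds=np.asarray(sds),
        sigma_floor=floor,
    )


def gaussian_likelihood(x: float, mu: float, sigma: float) -> float:
    """Normal density (1/(σ√(2π))) · exp(−((x−μ)/σ)²/2)."""
    if not sigma > 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    z = (x - mu) / sigma
    return math.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))


def log_gaussian_likelihood(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI


def _log_joint(f: np.ndarray, stats: ClassStats) -> np.ndarray:
    """log[ p(C_k) * prod_i p(F_i = f_i | C_k) ] for every class k."""
    f = np.asarray(f, dtype=float)
    if f.shape != (N_FEATURES,):
        raise ParameterError(f"feature vector must have shape ({N_FEATURES},)")
    log_lik = log_gaussian_likelihood(f[None, :], stats.means, stats.sds).sum(axis=1)
    return np.log(stats.priors) + log_lik


def evidence(f: np.ndarray, stats: ClassStats) -> float:
    """Total probability of the feature vector: Σ_k p(C_k) Π_i p(F_i | C_k).

    Evaluated through the log-domain joint for numerical robustness;
    strictly positive. This is the normalising denominator of the
    posterior.
    """
    return float(np.exp(logsumexp(_log_joint(f, stats))))


def posterior(f: np.ndarray, stats: ClassStats) -> Posterior:
    """Per-class posterior probabilities of a feature vector.

    Computed as prior x joint likelihood over the six features,
    normalised by the evidence — entirely in log space, so the result is
    exact up to floating point even where the raw densities underflow.
    """
    log_joint = _log_joint(f, stats)
    probs = np.exp(log_joint - logsumexp(log_joint))
    probs = probs / probs.sum()  # exact renormalisation
    return Posterior(classes=stats.classes, probs=probs)


def nb_classify(f: np.ndarray, stats: ClassStats) -> MotionClass:
    """Maximum-posterior class; ties go to the earlier enumeration member."""
    log_joint = _log_joint(f, stats)
    best = np.max(log_joint)
    tied = [c for c, lj in zip(stats.classes, log_joint) if lj == best]
    return min(tied, key=lambda c: CLASS_ORDER[c])
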