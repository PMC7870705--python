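"""Maximum-likelihood inference of pollen transmission efficiency.

Genotype counts ``(n_TT, n_TG, n_GG)`` from a selfed family are
multinomial with class probabilities ``((1-f)(1-k), (1-f)k + f(1-k), f k)``.
At the default female transmission ``f = 0.5`` the heterozygote class
probability is constant (1/2), so conditional on the number of
homozygotes ``m = n_TT + n_GG`` the count ``n_GG`` is binomial(m, k) and
the MLE has the closed form ``k_hat = n_GG / (n_TT + n_GG)``.  The same
conditioning makes the Clopper-Pearson interval exact for ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import SegregationCounts, TransmissionModel, expected_selfing_freqs

__all__ = ["MLEResult", "LRTResult", "NotIdentifiableError", "loglik_k", "mle_k", "ci_k", "lrt_k"]


class NotIdentifiableError(ValueError):
    """Raised when the data carry no information about k (no homozygotes at f=0.5)."""


@dataclass(frozen=True)
class MLEResult:
    """Point estimate and confidence interval for the transmission efficiency k."""

    k_hat: float
    loglik_at_max: float
    ci_low: float
    ci_high: float
    ci_method: str
    ci_level: float
    informative_n: int
    boundary: bool = False
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "k_hat": self.k_hat,
            "loglik_at_max": self.loglik_at_max,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "informative_n": self.informative_n,
            "boundary": self.boundary,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a null transmission efficiency k0."""

    statistic: float
    p: float
    k0: float
    k_hat: float
    boundary_null: bool = False
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p": self.p,
            "k0": self.k0,
            "k_hat": self.k_hat,
            "boundary_null": self.boundary_null,
            "flags": list(self.flags),
        }


def loglik_k(k: float, counts: SegregationCounts, f: float = 0.5) -> float:
    """Multinomial log-likelihood of the genotype counts at transmission k.

    Zero counts contribute nothing (the 0*log(0) convention); a positive
    count in a zero-probability class returns ``-inf`` rather than
    raising.
    """
    freqs = expected_selfing_freqs(TransmissionModel(k=k, f=f)).as_array()
    n = counts.as_array()
    total = 0.0
    for ni, pi in zip(n, freqs):
        if ni == 0:
            continue
        if pi <= 0.0:
            return -math.inf
        total += ni * math.log(pi)
    return total


def _point_estimate(counts: SegregationCounts, f: float) -> float:
    """MLE of k: closed form at f = 0.5, numerical maximization otherwise."""
    if f == 0.5:
        if counts.informative_n == 0:
            raise NotIdentifiableError(
                "k is not identifiable: no homozygous plants observed "
                "(at f = 0.5 the heterozygote count carries no information about k)"
            )
        return counts.n_GG / counts.informative_n
    if counts.total == 0:
        raise NotIdentifiableError("k is not identifiable from an empty family")
    res = optimize.minimize_scalar(
        lambda k: -loglik_k(k, counts, f=f),
        bounds=(1e-12, 1 - 1e-12),
        method="bounded",
        options={"xatol": 1e-12},
    )
    k_hat = float(res.x)
    # Snap to an exact boundary when the optimum sits against it.
    for edge in (0.0, 1.0):
        if abs(k_hat - edge) < 1e-9 and loglik_k(edge, counts, f=f) >= loglik_k(
            k_hat, counts, f=f
        ):
            k_hat = edge
    return k_hat


def mle_k(
    counts: SegregationCounts,
    f: float = 0.5,
    ci_method: str = "exact_binomial",
    ci_level: float = 0.95,
) -> MLEResult:
    """Maximum-likelihood estimate of the pollen transmission efficiency.

    At ``f = 0.5`` the estimate is the closed form
    ``k_hat = n_GG / (n_TT + n_GG)``; for other values of ``f`` the
    likelihood is maximized numerically.  Boundary estimates (0 or 1)
    are returned exactly and flagged, with one-sided confidence
    intervals.

    Raises
    ------
    NotIdentifiableError
        If ``f = 0.5`` and the family contains no homozygous plants.
    """
    m = counts.informative_n
    k_hat = _point_estimate(counts, f)
    boundary = k_hat in (0.0, 1.0)
    low, high, ci_flags = _ci_k(counts, level=ci_level, method=ci_method, f=f, k_hat=k_hat)
    return MLEResult(
        k_hat=k_hat,
        loglik_at_max=loglik_k(k_hat, counts, f=f),
        ci_low=low,
        ci_high=high,
        ci_method=ci_method,
        ci_level=ci_level,
        informative_n=m,
        boundary=boundary,
        flags=tuple(ci_flags),
    )


def ci_k(
    counts: SegregationCounts,
    level: float = 0.95,
    method: str = "exact_binomial",
    f: float = 0.5,
) -> tuple[float, float]:
    """Confidence interval for k by exact binomial or profile-likelihood inversion.

    ``exact_binomial`` is the Clopper-Pearson interval for ``n_GG``
    successes out of ``n_TT + n_GG`` trials — exact at every sample size
    because, conditional on the homozygote total, ``n_GG`` is binomial
    with success probability ``k`` when ``f = 0.5``.  ``profile_lrt``
    inverts the likelihood-ratio test at the chi-square(1) cutoff.
    """
    if method == "exact_binomial" and f != 0.5:
        raise ValueError("exact_binomial intervals require f = 0.5")
    if counts.informative_n == 0 and f == 0.5:
        raise NotIdentifiableError("k is not identifiable: no homozygous plants observed")
    low, high, _ = _ci_k(counts, level=level, method=method, f=f, k_hat=None)
    return low, high


def _ci_k(
    counts: SegregationCounts,
    level: float,
    method: str,
    f: float,
    k_hat: float | None,
) -> tuple[float, float, list[str]]:
    flags: list[str] = []
    if method == "exact_binomial":
        if f != 0.5:
            raise ValueError("exact_binomial intervals require f = 0.5")
        m = counts.informative_n
        x = counts.n_GG
        alpha = 1.0 - level
        low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, m - x + 1))
        high = 1.0 if x == m else float(stats.beta.ppf(1 - alpha / 2, x + 1, m - x))
        if x == 0 or x == m:
            flags.append("one_sided_boundary")
        return low, high, flags
    if method == "profile_lrt":
        if k_hat is None:
            k_hat = counts.n_GG / counts.informative_n if f == 0.5 else None
        if k_hat is None:
            raise ValueError("profile_lrt requires the MLE; call via mle_k for f != 0.5")
        cutoff = stats.chi2.ppf(level, df=1)
        ll_max = loglik_k(k_hat, counts, f=f)

        def deviance_minus_cutoff(k: float) -> float:
            return 2.0 * (ll_max - loglik_k(k, counts, f=f)) - cutoff

        eps = 1e-12
        if k_hat <= 0.0 or deviance_minus_cutoff(eps) < 0:
            low = 0.0
            if k_hat <= 0.0:
                flags.append("one_sided_boundary")
        else:
            low = float(optimize.brentq(deviance_minus_cutoff, eps, k_hat))
        if k_hat >= 1.0 or deviance_minus_cutoff(1 - eps) < 0:
            high = 1.0
            if k_hat >= 1.0:
                flags.append("one_sided_boundary")
        else:
            high = float(optimize.brentq(deviance_minus_cutoff, k_hat, 1 - eps))
        return low, high, flags
    raise ValueError(f"unknown CI method {method!r}")


def lrt_k(counts: SegregationCounts, k0: float, f: float = 0.5) -> LRTResult:
    """Likelihood-ratio test of H0: k = k0 against the unrestricted MLE.

    The statistic is ``2 [l(k_hat) - l(k0)]`` referred to chi-square(1).
    When ``k0`` lies on the boundary of the parameter space (0 or 1) the
    null distribution is the half-half mixture of a point mass at zero
    and chi-square(1), so the p-value is halved.  A null value
    incompatible with the data (infinite deviance) gives p = 0, flagged.
    """
    if not (0.0 <= k0 <= 1.0):
        raise ValueError(f"k0 must lie in [0, 1], got {k0}")
    boundary_null = k0 in (0.0, 1.0)
    k_hat = _point_estimate(counts, f)
    ll_max = loglik_k(k_hat, counts, f=f)
    ll0 = loglik_k(k0, counts, f=f)
    flags: list[str] = []
    if math.isinf(ll0):
        return LRTResult(
            statistic=math.inf,
            p=0.0,
            k0=k0,
            k_hat=k_hat,
            boundary_null=boundary_null,
            flags=("null_incompatible",),
        )
    statistic = max(0.0, 2.0 * (ll_max - ll0))
    p = float(stats.chi2.sf(statistic, df=1))
    if boundary_null:
        p = 1.0 if statistic == 0.0 else p / 2.0
        flags.append("boundary_null_mixture")
    return LRTResult(
        statistic=statistic,
        p=p,
        k0=k0,
        k_hat=k_hat,
        boundary_null=boundary_null,
        flags=tuple(flags),
    )
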