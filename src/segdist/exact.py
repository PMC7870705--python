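"""Exact significance tests for segregation and complementation analysis.

Two readings of "does this transgenic family segregate like the
non-transgenic control" are provided: the Fisher-Freeman-Halton exact
test of independence on the 2xC contingency table of the two families'
genotype counts (the primary reading), and an exact multinomial
goodness-of-fit of one family's counts against fixed expected
proportions.  Both define the two-sided p-value as the total null
probability of outcomes no more probable than the one observed, with a
small relative tolerance absorbing floating-point ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .core import GenotypeFreqs, SegregationCounts

__all__ = [
    "ContingencyTable2xC",
    "ExactTestResult",
    "freeman_halton_2xc",
    "multinomial_exact_gof",
    "chi2_gof",
]

#: Relative tolerance for treating two table probabilities as tied.
TIE_RTOL = 1e-7

#: Largest family size accepted for full multinomial enumeration.
MAX_ENUMERATION_N = 200


@dataclass(frozen=True)
class ContingencyTable2xC:
    """A 2-row contingency table of genotype counts (rows = populations)."""

    counts: tuple[tuple[int, ...], tuple[int, ...]]
    row_labels: tuple[str, str] = ("row1", "row2")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape[0] != 2 or arr.ndim != 2:
            raise ValueError(f"expected a 2xC table, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integers")
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if arr.sum() == 0:
            raise ValueError("grand total must be positive")
        object.__setattr__(
            self, "counts", tuple(tuple(int(x) for x in row) for row in arr)
        )

    @classmethod
    def from_rows(
        cls, row1, row2, labels: tuple[str, str] = ("row1", "row2")
    ) -> "ContingencyTable2xC":
        return cls(counts=(tuple(row1), tuple(row2)), row_labels=labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class ExactTestResult:
    """Outcome of an exact (or asymptotic) significance test."""

    p: float
    method: str
    statistic: float | None = None
    tables_enumerated: int | None = None
    reps: int | None = None
    mc_se: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")

    def to_dict(self) -> dict:
        out = {"p": self.p, "method": self.method}
        for name in ("statistic", "tables_enumerated", "reps", "mc_se"):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        if self.flags:
            out["flags"] = list(self.flags)
        return out


def _log_table_prob(row1: np.ndarray, col_totals: np.ndarray, n: int, r1: int) -> float:
    """Log multivariate-hypergeometric probability of a 2xC table with fixed margins,
    parameterized by its first row."""
    return float(
        np.sum(gammaln(col_totals + 1))
        - np.sum(gammaln(row1 + 1))
        - np.sum(gammaln(col_totals - row1 + 1))
        + gammaln(r1 + 1)
        + gammaln(n - r1 + 1)
        - gammaln(n + 1)
    )


def _enumerate_first_rows(col_totals: np.ndarray, r1: int):
    """Yield every first row (as an array) compatible with the fixed margins."""
    c = len(col_totals)

    def rec(j: int, remaining: int, prefix: list[int]):
        if j == c - 1:
            if 0 <= remaining <= col_totals[j]:
                yield np.array(prefix + [remaining], dtype=np.int64)
            return
        suffix_cap = int(col_totals[j + 1 :].sum())
        lo = max(0, remaining - suffix_cap)
        hi = min(int(col_totals[j]), remaining)
        for x in range(lo, hi + 1):
            yield from rec(j + 1, remaining - x, prefix + [x])

    yield from rec(0, r1, [])


def freeman_halton_2xc(table: ContingencyTable2xC) -> ExactTestResult:
    """Fisher-Freeman-Halton exact test of independence for a 2xC table.

    Conditional on the observed margins, each table has a multivariate
    hypergeometric probability; the two-sided p-value is the sum over
    all tables whose probability does not exceed the observed table's
    (within a relative tie tolerance).  For 2x2 tables this reduces to
    the classical two-sided Fisher exact test.

    A degenerate table (an all-zero row, or a single nonempty column)
    admits only one outcome and returns p = 1 with a warning flag.
    """
    arr = table.as_array()
    col_totals = arr.sum(axis=0)
    keep = col_totals > 0
    arr = arr[:, keep]
    col_totals = col_totals[keep]
    row_totals = arr.sum(axis=1)
    n = int(arr.sum())
    if (row_totals == 0).any() or arr.shape[1] < 2:
        return ExactTestResult(
            p=1.0,
            method="freeman_halton_enumeration",
            tables_enumerated=1,
            flags=("degenerate_margin",),
        )
    r1 = int(row_totals[0])
    log_p_obs = _log_table_prob(arr[0], col_totals, n, r1)
    cutoff = log_p_obs + math.log1p(TIE_RTOL)
    total = 0.0
    n_tables = 0
    for row1 in _enumerate_first_rows(col_totals, r1):
        n_tables += 1
        lp = _log_table_prob(row1, col_totals, n, r1)
        if lp <= cutoff:
            total += math.exp(lp)
    return ExactTestResult(
        p=min(1.0, total),
        method="freeman_halton_enumeration",
        tables_enumerated=n_tables,
    )


def _as_count_array(counts) -> np.ndarray:
    if isinstance(counts, SegregationCounts):
        return counts.as_array()
    arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim != 1 or (arr < 0).any():
        raise ValueError("counts must be a 1-D array of nonnegative integers")
    return arr


def _as_prob_array(probs, n_classes: int) -> np.ndarray:
    if isinstance(probs, GenotypeFreqs):
        arr = probs.as_array()
    else:
        arr = np.asarray(probs, dtype=float)
    if arr.shape != (n_classes,):
        raise ValueError(f"expected {n_classes} class probabilities, got shape {arr.shape}")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must be nonnegative and sum to 1")
    return arr


def _multinomial_logpmf(x: np.ndarray, n: int, log_p: np.ndarray) -> float:
    mask = x > 0
    return float(
        gammaln(n + 1) - np.sum(gammaln(x + 1)) + np.sum(x[mask] * log_p[mask])
    )


def multinomial_exact_gof(
    counts,
    probs,
    method: str = "enumerate",
    reps: int = 100_000,
    seed: int | None = None,
) -> ExactTestResult:
    """Exact multinomial goodness-of-fit test against fixed class proportions.

    The p-value is the null probability of all outcomes whose
    multinomial probability does not exceed the observed outcome's
    (relative tie tolerance ``TIE_RTOL``).  ``method="enumerate"``
    enumerates every composition of n (allowed for n <= 200);
    ``method="monte_carlo"`` estimates the same tail by seeded
    simulation and reports the replicate count and standard error.
    """
    x = _as_count_array(counts)
    p = _as_prob_array(probs, len(x))
    n = int(x.sum())
    if (p == 0).any() and (x[p == 0] > 0).any():
        return ExactTestResult(p=0.0, method="multinomial_enumeration", tables_enumerated=0,
                               flags=("impossible_outcome",))
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
    log_obs = _multinomial_logpmf(x, n, log_p)
    cutoff = log_obs + math.log1p(TIE_RTOL)
    if method == "enumerate":
        if n > MAX_ENUMERATION_N:
            raise ValueError(
                f"full enumeration is limited to n <= {MAX_ENUMERATION_N} "
                f"(got n = {n}); use method='monte_carlo'"
            )
        total = 0.0
        n_outcomes = 0
        for outcome in _compositions(n, len(x)):
            n_outcomes += 1
            lp = _multinomial_logpmf(outcome, n, log_p)
            if lp <= cutoff:
                total += math.exp(lp)
        return ExactTestResult(
            p=min(1.0, total),
            method="multinomial_enumeration",
            tables_enumerated=n_outcomes,
        )
    if method == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo requires an explicit seed for reproducibility")
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, p, size=reps)
        lps = (
            gammaln(n + 1)
            - gammaln(draws + 1).sum(axis=1)
            + np.where(draws > 0, draws * log_p, 0.0).sum(axis=1)
        )
        hits = int(np.count_nonzero(lps <= cutoff))
        p_hat = hits / reps
        se = math.sqrt(max(p_hat * (1 - p_hat), 1e-300) / reps)
        return ExactTestResult(
            p=p_hat, method="multinomial_monte_carlo", reps=reps, mc_se=se
        )
    raise ValueError(f"unknown method {method!r}")


def _compositions(n: int, c: int):
    """Yield all c-part compositions of n as integer arrays."""
    if c == 1:
        yield np.array([n], dtype=np.int64)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, c - 1):
            yield np.concatenate(([first], rest))


def chi2_gof(counts, probs) -> ExactTestResult:
    """Pearson chi-square goodness-of-fit against fixed class proportions.

    Asymptotic cross-check for the exact tests; df = classes - 1.
    """
    x = _as_count_array(counts)
    p = _as_prob_array(probs, len(x))
    expected = x.sum() * p
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive for the chi-square test")
    statistic, pvalue = stats.chisquare(x, f_exp=expected)
    return ExactTestResult(
        p=float(pvalue), method="chi2_asymptotic", statistic=float(statistic)
    )
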