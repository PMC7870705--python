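"""Deterministic genetic models for gametophytic pollen-sterility loci.

A gametophytic sterility allele acts in the haploid pollen grain that
carries it: in a heterozygote, roughly half the pollen aborts and the
allele is under-transmitted through the male side.  The central parameter
is the pollen transmission efficiency ``k`` — the probability that a
functional (surviving, competing) pollen grain drawn at random carries the
sterile allele.  Mendelian transmission corresponds to ``k = 0.5``;
a fully penetrant sterility allele gives ``k = 0``.

This module holds the pure, closed-form pieces of that model: expected
genotype frequencies in selfed and backcross progenies under distorted
transmission, two-locus coupling-phase gamete frequencies, expected
pollen fertility under transgene rescue, and the map between ``k`` and
the per-grain abortion probability ``sigma``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransmissionModel",
    "SegregationCounts",
    "GenotypeFreqs",
    "PollenViabilityModel",
    "TransgeneInsertion",
    "TransgeneSpec",
    "TwoLocusModel",
    "expected_selfing_freqs",
    "expected_backcross_freqs",
    "two_locus_pollen_transmission",
    "expected_pollen_fertility",
    "sigma_from_k",
    "k_from_sigma",
]

_FREQ_TOL = 1e-12


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class TransmissionModel:
    """Transmission efficiencies of a sterile allele through each gamete class.

    Parameters
    ----------
    k
        Probability that a functional pollen grain carries the sterile
        allele.  ``0.5`` is Mendelian; ``0`` means the allele never
        transmits through pollen.
    f
        Transmission through female gametes.  Embryo sacs are unaffected
        by pollen-acting sterility alleles, so this defaults to the
        Mendelian ``0.5``.
    """

    k: float
    f: float = 0.5

    def __post_init__(self) -> None:
        _check_prob(self.k, "k")
        _check_prob(self.f, "f")


@dataclass(frozen=True)
class SegregationCounts:
    """Genotype counts at a marker linked to a sterility locus in a selfed family.

    ``TT`` is homozygous for the cultivated (functional) allele, ``TG``
    heterozygous, and ``GG`` homozygous for the wild-species (sterile)
    allele.
    """

    n_TT: int
    n_TG: int
    n_GG: int

    def __post_init__(self) -> None:
        for name in ("n_TT", "n_TG", "n_GG"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
            object.__setattr__(self, name, int(value))

    @property
    def total(self) -> int:
        return self.n_TT + self.n_TG + self.n_GG

    @property
    def informative_n(self) -> int:
        """Number of homozygous plants; with ``f = 0.5`` only these carry
        information about ``k``."""
        return self.n_TT + self.n_GG

    def as_array(self) -> np.ndarray:
        return np.array([self.n_TT, self.n_TG, self.n_GG], dtype=np.int64)


@dataclass(frozen=True)
class GenotypeFreqs:
    """Expected genotype proportions (TT, TG, GG) in a progeny family."""

    p_TT: float
    p_TG: float
    p_GG: float

    def __post_init__(self) -> None:
        for name in ("p_TT", "p_TG", "p_GG"):
            _check_prob(getattr(self, name), name)
        total = self.p_TT + self.p_TG + self.p_GG
        if abs(total - 1.0) > _FREQ_TOL:
            raise ValueError(f"genotype frequencies must sum to 1, got {total!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_TT, self.p_TG, self.p_GG], dtype=float)


@dataclass(frozen=True)
class PollenViabilityModel:
    """Per-grain abortion model for pollen carrying a sterile allele.

    ``sigma`` is the probability that a grain carrying an unrescued
    sterile allele aborts; ``rescue_efficiency`` is the probability that
    a transgene copy present in the same grain restores viability.
    Both default to 1 (fully penetrant abortion, fully effective rescue).
    """

    sigma: float = 1.0
    rescue_efficiency: float = 1.0

    def __post_init__(self) -> None:
        _check_prob(self.sigma, "sigma")
        _check_prob(self.rescue_efficiency, "rescue_efficiency")


@dataclass(frozen=True)
class TransgeneInsertion:
    """One transgene insertion locus in a T1 plant.

    ``zygosity`` is ``"hemizygous"`` (single-copy T0 transformant) or
    ``"homozygous"``.  ``r`` is the recombination fraction to the
    sterility locus; ``None`` means unlinked (independent assortment).
    For a linked hemizygous insertion, ``phase`` says which homolog the
    transgene sits on: ``"coupling"`` with the sterile allele or
    ``"repulsion"`` (on the functional-allele homolog).
    """

    zygosity: str
    r: float | None = None
    phase: str = "coupling"

    def __post_init__(self) -> None:
        if self.zygosity not in ("hemizygous", "homozygous"):
            raise ValueError(
                f"zygosity must be 'hemizygous' or 'homozygous', got {self.zygosity!r}"
            )
        if self.r is not None:
            r = float(self.r)
            if not (0.0 <= r <= 0.5):
                raise ValueError(f"recombination fraction r must lie in [0, 0.5], got {r}")
            object.__setattr__(self, "r", r)
        if self.phase not in ("coupling", "repulsion"):
            raise ValueError(f"phase must be 'coupling' or 'repulsion', got {self.phase!r}")

    def transmission_prob(self, with_sterile_allele: bool) -> float:
        """P(gamete carries this transgene | gamete's allele at the sterility locus)."""
        if self.zygosity == "homozygous":
            return 1.0
        if self.r is None:
            return 0.5
        same = self.phase == "coupling"
        if with_sterile_allele == same:
            return 1.0 - self.r
        return self.r


@dataclass(frozen=True)
class TransgeneSpec:
    """The set of transgene insertions segregating in a plant."""

    insertions: tuple[TransgeneInsertion, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "insertions", tuple(self.insertions))


@dataclass(frozen=True)
class TwoLocusModel:
    """Two linked gametophytic sterility loci in a double heterozygote.

    ``kA`` and ``kB`` are the single-locus transmission efficiencies,
    ``r`` the recombination fraction between the loci, and ``phase``
    whether the two sterile alleles sit on the same homolog
    (``"coupling"``) or opposite homologs (``"repulsion"``).  The
    ``viability_rule`` sets how the two loci combine in a gamete that
    carries both sterile alleles: ``"multiplicative"`` (independent
    action) or ``"minimum"`` (the more severe locus dominates).
    """

    kA: float
    kB: float
    r: float
    phase: str = "coupling"
    viability_rule: str = "multiplicative"

    def __post_init__(self) -> None:
        _check_prob(self.kA, "kA")
        _check_prob(self.kB, "kB")
        r = float(self.r)
        if not (0.0 <= r <= 0.5):
            raise ValueError(f"recombination fraction r must lie in [0, 0.5], got {r}")
        object.__setattr__(self, "r", r)
        if self.phase not in ("coupling", "repulsion"):
            raise ValueError(f"phase must be 'coupling' or 'repulsion', got {self.phase!r}")
        if self.viability_rule not in ("multiplicative", "minimum"):
            raise ValueError(
                "viability_rule must be 'multiplicative' or 'minimum', "
                f"got {self.viability_rule!r}"
            )


def expected_selfing_freqs(model: TransmissionModel) -> GenotypeFreqs:
    """Expected genotype frequencies in a selfed family under distorted transmission.

    With male transmission ``k`` and female transmission ``f`` of the
    sterile allele,

        P(TT) = (1-f)(1-k),  P(TG) = (1-f)k + f(1-k),  P(GG) = f k.

    At ``f = 0.5`` this is ``((1-k)/2, 1/2, k/2)``: a half-heterozygous
    family whose homozygote split is governed entirely by ``k``.  At
    ``k = 0`` the family segregates 1:1:0 — the hallmark of a fully
    penetrant gametophytic sterility allele.
    """
    k, f = model.k, model.f
    return GenotypeFreqs(
        p_TT=(1.0 - f) * (1.0 - k),
        p_TG=(1.0 - f) * k + f * (1.0 - k),
        p_GG=f * k,
    )


def expected_backcross_freqs(
    model: TransmissionModel, pollen_parent_is_het: bool = True
) -> tuple[float, float]:
    """Expected (TT, TG) frequencies in a backcross to the homozygous cultivated parent.

    When the heterozygote is the pollen parent, P(TG) equals the male
    transmission ``k``; when it is the seed parent, P(TG) equals ``f``.
    """
    p_het = model.k if pollen_parent_is_het else model.f
    return (1.0 - p_het, p_het)


def two_locus_pollen_transmission(model: TwoLocusModel) -> np.ndarray:
    """Transmission frequencies of the four pollen haplotypes of a double heterozygote.

    Haplotypes are ordered ``(++, +s, s+, ss)`` where ``+`` is the
    functional and ``s`` the sterile allele at locus A then locus B.
    Meiotic frequencies follow the linkage phase (coupling parentals are
    ``++`` and ``ss``); each haplotype is then weighted by its relative
    viability among functional pollen.  Per locus the sterile allele
    contributes a factor ``2k`` and the functional allele ``2(1-k)``
    (so Mendelian loci contribute factor 1), combined by the model's
    viability rule, and the result is renormalized.
    """
    r = model.r
    if model.phase == "coupling":
        meiotic = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
    else:
        meiotic = np.array([r / 2, (1 - r) / 2, (1 - r) / 2, r / 2])

    def locus_factor(k: float, sterile: bool) -> float:
        return 2.0 * k if sterile else 2.0 * (1.0 - k)

    weights = np.empty(4)
    for i, (a_sterile, b_sterile) in enumerate(
        [(False, False), (False, True), (True, False), (True, True)]
    ):
        fa = locus_factor(model.kA, a_sterile)
        fb = locus_factor(model.kB, b_sterile)
        if model.viability_rule == "multiplicative":
            weights[i] = fa * fb
        else:
            weights[i] = min(fa, fb)
    weighted = meiotic * weights
    total = weighted.sum()
    if total <= 0.0:
        raise ValueError("no pollen haplotype has positive transmission under this model")
    return weighted / total


def expected_pollen_fertility(
    het_loci: int | list | tuple,
    viability: PollenViabilityModel | None = None,
    transgenes: TransgeneSpec | None = None,
) -> float:
    """Expected fraction of fertile pollen for a heterozygous, possibly rescued plant.

    The plant is heterozygous at ``het_loci`` independent sterility loci
    (pass an int, or a list of locus labels).  Each pollen grain draws
    one allele per locus (meiotic 1/2 each) and each transgene insertion
    per its zygosity and linkage; a grain carrying one or more sterile
    alleles aborts with probability ``sigma`` per unrescued sterile
    allele, where a transgene copy present in the grain rescues with
    probability ``rescue_efficiency``.

    For one locus with fully penetrant abortion this gives the classic
    dosage series: no transgene -> 0.5 (semi-sterility), one hemizygous
    unlinked insertion -> 0.75, a homozygous insertion -> 1.0.
    """
    if viability is None:
        viability = PollenViabilityModel()
    if transgenes is None:
        transgenes = TransgeneSpec()
    n_loci = het_loci if isinstance(het_loci, (int, np.integer)) else len(het_loci)
    if n_loci < 0:
        raise ValueError("number of heterozygous loci must be nonnegative")

    linked = [ins for ins in transgenes.insertions if ins.r is not None]
    if len(linked) > 1:
        raise ValueError("at most one transgene insertion may be linked to the locus")
    if linked and n_loci != 1:
        raise ValueError("transgene linkage is only defined for a single sterility locus")

    sigma = viability.sigma
    rescue = viability.rescue_efficiency
    fertility = 0.0
    # Exact enumeration over gamete classes: allele pattern x transgene pattern.
    for alleles in itertools.product([False, True], repeat=n_loci):
        n_sterile = sum(alleles)
        p_alleles = 0.5**n_loci if n_loci else 1.0
        with_sterile = bool(alleles[0]) if n_loci == 1 else any(alleles)
        for present in itertools.product([False, True], repeat=len(transgenes.insertions)):
            p_tg = 1.0
            for ins, here in zip(transgenes.insertions, present):
                p_here = ins.transmission_prob(with_sterile)
                p_tg *= p_here if here else 1.0 - p_here
            # Rescue succeeds if any present copy works; copies act independently.
            n_copies = sum(present)
            p_rescued = 1.0 - (1.0 - rescue) ** n_copies if n_copies else 0.0
            p_abort_per_allele = sigma * (1.0 - p_rescued)
            p_viable = (1.0 - p_abort_per_allele) ** n_sterile
            fertility += p_alleles * p_tg * p_viable
    return fertility


def sigma_from_k(k: float) -> float:
    """Abortion probability implied by an observed transmission efficiency.

    When surviving pollen grains compete equally, a per-grain abortion
    probability ``sigma`` yields ``k = (1 - sigma) / (2 - sigma)``;
    inverting gives ``sigma = (1 - 2k) / (1 - k)``.  Only reduced
    transmission (``k <= 0.5``) maps onto an abortion model.
    """
    k = float(k)
    if not (0.0 <= k <= 0.5):
        raise ValueError(
            "k must lie in [0, 0.5]: enhanced transmission (k > 0.5) cannot be "
            "expressed as pollen abortion and is not modeled by this map"
        )
    return (1.0 - 2.0 * k) / (1.0 - k)


def k_from_sigma(sigma: float) -> float:
    """Transmission efficiency implied by a per-grain abortion probability."""
    sigma = _check_prob(sigma, "sigma")
    return (1.0 - sigma) / (2.0 - sigma)
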