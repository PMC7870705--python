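"""Seeded generators for selfed, backcross, mapping, and transgene-rescue populations.

Every generator is a pure function of its arguments: a single root seed
is combined with a fixed per-stage label to derive independent named
substreams, so identical calls are bit-reproducible and adding one
simulation stage never perturbs another's draws.

The generators reproduce the statistical structure the analysis modules
assume: multinomial genotype counts in selfed T1 families under
distorted male transmission, per-plant marker genotypes from a selfing
meiosis with per-interval recombination (no interference), and
gamete-level transgene rescue in complementation T1 families.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GenotypeFreqs,
    SegregationCounts,
    TransgeneInsertion,
    TransmissionModel,
    expected_selfing_freqs,
    sigma_from_k,
)
from .inference import mle_k
from .mapping import MarkerMap, RecombinantRecord

__all__ = [
    "SimulationConfig",
    "ComplementationSample",
    "simulate_selfing_counts",
    "simulate_backcross_counts",
    "simulate_marker_population",
    "simulate_complementation_t1",
    "expected_complementation_freqs",
    "expected_rescued_k",
    "recovery_experiment",
]

_DESIGNS = ("selfing_T1", "backcross", "mapping_population", "complementation_T1")


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: root seed plus a stable hash of the stage label."""
    if seed < 0:
        raise ValueError("seed must be a nonnegative integer")
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass(frozen=True)
class SimulationConfig:
    """Declarative description of one simulated population.

    ``design`` selects the generator; ``params`` holds its keyword
    arguments (model parameters such as k, f, rescue, marker map
    settings).  The same config always produces bit-identical output.
    """

    seed: int
    n_plants: int
    design: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ValueError(f"design must be one of {_DESIGNS}, got {self.design!r}")
        if self.n_plants <= 0:
            raise ValueError("n_plants must be positive")

    def run(self):
        if self.design == "selfing_T1":
            return simulate_selfing_counts(n=self.n_plants, seed=self.seed, **self.params)
        if self.design == "backcross":
            return simulate_backcross_counts(n=self.n_plants, seed=self.seed, **self.params)
        if self.design == "mapping_population":
            return simulate_marker_population(n=self.n_plants, seed=self.seed, **self.params)
        return simulate_complementation_t1(n=self.n_plants, seed=self.seed, **self.params)


def simulate_selfing_counts(
    k: float, n: int, seed: int, f: float = 0.5
) -> SegregationCounts:
    """Multinomial genotype counts for a selfed T1 family of size n."""
    if n <= 0:
        raise ValueError("family size n must be positive")
    probs = expected_selfing_freqs(TransmissionModel(k=k, f=f)).as_array()
    draw = _rng(seed, "selfing_counts").multinomial(n, probs)
    return SegregationCounts(n_TT=int(draw[0]), n_TG=int(draw[1]), n_GG=int(draw[2]))


def simulate_backcross_counts(k: float, n: int, seed: int) -> tuple[int, int]:
    """(n_TT, n_TG) counts for a backcross with the heterozygote as pollen parent."""
    if n <= 0:
        raise ValueError("family size n must be positive")
    if not (0.0 <= k <= 1.0):
        raise ValueError(f"k must lie in [0, 1], got {k}")
    n_tg = int(_rng(seed, "backcross_counts").binomial(n, k))
    return (n - n_tg, n_tg)


def _draw_gametes(
    rng: np.random.Generator,
    size: int,
    seg_r: np.ndarray,
    locus_segments: tuple[int, int] | None,
    allow_double_crossover: bool,
) -> np.ndarray:
    """Haplotype matrix (size x positions); 0 = cultivated, 1 = wild chromosome."""
    n_seg = len(seg_r)
    starts = rng.integers(0, 2, size=size)
    cross = rng.random((size, n_seg)) < seg_r
    if locus_segments is not None and not allow_double_crossover:
        # Condition the two sub-intervals flanking the locus on not both
        # recombining: renormalize over {none, left-only, right-only}.
        sL, sR = locus_segments
        rL, rR = seg_r[sL], seg_r[sR]
        w = np.array([(1 - rL) * (1 - rR), rL * (1 - rR), (1 - rL) * rR])
        w = w / w.sum()
        pick = rng.choice(3, size=size, p=w)
        cross[:, sL] = pick == 1
        cross[:, sR] = pick == 2
    parity = np.concatenate(
        [np.zeros((size, 1), dtype=np.int64), np.cumsum(cross, axis=1)], axis=1
    )
    return (starts[:, None] + parity) % 2


def simulate_marker_population(
    marker_map: MarkerMap,
    locus_position: float,
    k: float,
    n: int,
    seed: int,
    allow_double_crossover: bool = True,
) -> list[RecombinantRecord]:
    """Selfed mapping population with marker genotypes and pollen phenotypes.

    ``locus_position`` is given in marker-index coordinates: a value of
    2.4 places the locus 40% of the way (in recombination fraction)
    through the interval between the third and fourth markers.  Each
    plant is formed from one female gamete (undistorted) and one male
    gamete subject to viability selection at the locus so the wild
    allele transmits with probability ``k``.  Phenotypes follow the
    gametophytic model (heterozygous at the locus -> SS, homozygous
    cultivated -> N); homozygous-wild plants, absent under the 1:1:0
    model, are excluded by redrawing.
    """
    if marker_map.rec_fractions is None:
        raise ValueError("marker_map must carry rec_fractions to simulate recombination")
    if n <= 0:
        raise ValueError("population size n must be positive")
    if not (0.0 <= k <= 1.0):
        raise ValueError(f"k must lie in [0, 1], got {k}")
    m = len(marker_map)
    if not (0.0 < locus_position < m - 1) or float(locus_position).is_integer():
        raise ValueError(
            "locus_position must lie strictly between two adjacent markers "
            f"(0 < pos < {m - 1}, non-integer); got {locus_position}"
        )
    j = int(np.floor(locus_position))
    theta = locus_position - j
    rj = marker_map.rec_fractions[j]
    r_left = theta * rj
    r_right = (rj - r_left) / (1.0 - 2.0 * r_left) if r_left < 0.5 else 0.0
    seg_r = np.array(
        list(marker_map.rec_fractions[:j])
        + [r_left, r_right]
        + list(marker_map.rec_fractions[j + 1 :])
    )
    locus_pos_idx = j + 1  # column index of the locus in the position axis
    locus_segments = (j, j + 1)

    rng_f = _rng(seed, "mapping_female")
    rng_m = _rng(seed, "mapping_male")
    rng_pair = _rng(seed, "mapping_pairing")

    if k <= 0.5:
        accept = np.array([1.0, k / (1.0 - k) if k < 1.0 else 1.0])
    else:
        accept = np.array([(1.0 - k) / k, 1.0])

    def draw_male(rng: np.random.Generator, want: int) -> np.ndarray:
        out = []
        got = 0
        while got < want:
            batch = max(want * 2, 64)
            g = _draw_gametes(rng, batch, seg_r, locus_segments, allow_double_crossover)
            u = rng.random(batch)
            keep = u < accept[g[:, locus_pos_idx]]
            g = g[keep]
            out.append(g)
            got += len(g)
        return np.concatenate(out)[:want]

    records: list[RecombinantRecord] = []
    needed = n
    plant_idx = 0
    while needed > 0:
        females = _draw_gametes(rng_f, needed, seg_r, locus_segments, allow_double_crossover)
        males = draw_male(rng_m, needed)
        rng_pair.random(needed)  # reserved stream; keeps pairing stage stable
        genotypes = females + males  # 0 = TT, 1 = het, 2 = GG per position
        ok = genotypes[:, locus_pos_idx] != 2
        if not allow_double_crossover:
            # Also exclude plant-level double crossovers flanking the
            # locus (one gamete recombining left of it, the other
            # right), which hide the locus genotype from every marker.
            visible = (
                genotypes[:, locus_pos_idx] == genotypes[:, locus_pos_idx - 1]
            ) | (genotypes[:, locus_pos_idx] == genotypes[:, locus_pos_idx + 1])
            ok &= visible
        for row in genotypes[ok]:
            plant_idx += 1
            locus_geno = row[locus_pos_idx]
            phenotype = "SS" if locus_geno == 1 else "N"
            marker_calls = np.delete(row, locus_pos_idx)
            calls = tuple("THG"[g] for g in marker_calls)
            records.append(
                RecombinantRecord(
                    plant_id=f"p{plant_idx:05d}", calls=calls, phenotype=phenotype
                )
            )
        needed = n - len(records)
    return records


@dataclass(frozen=True)
class ComplementationSample:
    """A simulated transgene-rescue T1 family.

    ``counts`` are the genotype counts at the sterility locus;
    ``plants`` has one row per plant with its locus genotype and the
    number of transgene copies it inherited.
    """

    counts: SegregationCounts
    plants: pd.DataFrame


def _gamete_classes(insertion: TransgeneInsertion | None):
    """Joint P(allele, transgene) classes for one gamete; allele 1 = sterile."""
    classes = []
    for allele in (0, 1):
        p_allele = 0.5
        if insertion is None:
            classes.append((allele, 0, p_allele))
            continue
        p_tg = insertion.transmission_prob(with_sterile_allele=bool(allele))
        if p_tg > 0.0:
            classes.append((allele, 1, p_allele * p_tg))
        if p_tg < 1.0:
            classes.append((allele, 0, p_allele * (1.0 - p_tg)))
    return classes


def expected_rescued_k(
    k: float,
    rescue: float = 1.0,
    zygosity: str = "hemizygous",
    linkage_r: float | None = None,
    phase: str = "coupling",
) -> float:
    """Marginal male transmission of the sterile allele under transgene rescue.

    Exact enumeration over male gamete classes: a sterile-allele gamete
    carrying the transgene is viable with probability
    ``rescue + (1 - rescue)(1 - sigma)``; without it, ``1 - sigma``,
    where ``sigma`` is implied by the base transmission ``k``.
    """
    sigma = sigma_from_k(k)
    insertion = TransgeneInsertion(zygosity=zygosity, r=linkage_r, phase=phase)
    num = 0.0
    den = 0.0
    for allele, tg, p in _gamete_classes(insertion):
        if allele == 0:
            viable = 1.0
        elif tg:
            viable = rescue + (1.0 - rescue) * (1.0 - sigma)
        else:
            viable = 1.0 - sigma
        den += p * viable
        if allele == 1:
            num += p * viable
    return num / den


def expected_complementation_freqs(
    k: float,
    rescue: float = 1.0,
    zygosity: str = "hemizygous",
    linkage_r: float | None = None,
    phase: str = "coupling",
) -> GenotypeFreqs:
    """Expected T1 genotype frequencies at the sterility locus under rescue."""
    k_eff = expected_rescued_k(k, rescue, zygosity, linkage_r, phase)
    return expected_selfing_freqs(TransmissionModel(k=k_eff))


def simulate_complementation_t1(
    k: float,
    rescue: float,
    zygosity: str,
    n: int,
    seed: int,
    linkage_r: float | None = None,
    phase: str = "coupling",
) -> ComplementationSample:
    """Transgene-rescue T1 family simulated at the gamete level.

    The transgene segregates Mendelianly from its own insertion locus
    (hemizygous or homozygous in the T0 parent, optionally linked to the
    sterility locus at recombination fraction ``linkage_r``).  A male
    gamete carrying the sterile allele is viable if it also carries the
    transgene and rescue succeeds (probability ``rescue``), and
    otherwise survives abortion with probability ``1 - sigma`` where
    ``sigma`` is implied by the base transmission ``k``.  Female gametes
    are unselected.
    """
    if n <= 0:
        raise ValueError("family size n must be positive")
    if not (0.0 <= rescue <= 1.0):
        raise ValueError(f"rescue must lie in [0, 1], got {rescue}")
    sigma = sigma_from_k(k)
    insertion = TransgeneInsertion(zygosity=zygosity, r=linkage_r, phase=phase)
    classes = _gamete_classes(insertion)
    alleles = np.array([c[0] for c in classes])
    tgs = np.array([c[1] for c in classes])
    probs = np.array([c[2] for c in classes])

    rng_f = _rng(seed, "complementation_female")
    rng_m = _rng(seed, "complementation_male")

    f_idx = rng_f.choice(len(classes), size=n, p=probs)
    f_allele, f_tg = alleles[f_idx], tgs[f_idx]

    m_allele = np.empty(n, dtype=np.int64)
    m_tg = np.empty(n, dtype=np.int64)
    got = 0
    while got < n:
        batch = max((n - got) * 2, 64)
        idx = rng_m.choice(len(classes), size=batch, p=probs)
        a, t = alleles[idx], tgs[idx]
        u = rng_m.random(batch)
        rescued = (a == 1) & (t == 1) & (u < rescue)
        u2 = rng_m.random(batch)
        survives = (a == 0) | rescued | (u2 < (1.0 - sigma))
        a, t = a[survives], t[survives]
        take = min(len(a), n - got)
        m_allele[got : got + take] = a[:take]
        m_tg[got : got + take] = t[:take]
        got += take

    genotype_code = f_allele + m_allele  # 0 TT, 1 TG, 2 GG
    copies = f_tg + m_tg
    plants = pd.DataFrame(
        {
            "genotype": np.array(["TT", "TG", "GG"])[genotype_code],
            "transgene_copies": copies,
        }
    )
    counts = SegregationCounts(
        n_TT=int(np.count_nonzero(genotype_code == 0)),
        n_TG=int(np.count_nonzero(genotype_code == 1)),
        n_GG=int(np.count_nonzero(genotype_code == 2)),
    )
    return ComplementationSample(counts=counts, plants=plants)


def recovery_experiment(
    k_grid,
    n: int,
    reps: int,
    seed: int,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Estimator-validation table: bias, RMSE and CI coverage per true k.

    For each ``k_true`` on the grid, ``reps`` selfed families of size
    ``n`` are simulated and the MLE with its exact binomial interval is
    computed; one row per grid point reports mean estimate, bias, RMSE
    and empirical CI coverage.  Deterministic under the root seed.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100 for stable summaries")
    rows = []
    for gi, k_true in enumerate(k_grid):
        k_hats = np.empty(reps)
        covered = np.empty(reps, dtype=bool)
        for rep in range(reps):
            counts = simulate_selfing_counts(
                k=k_true, n=n, seed=int(_rng(seed, f"recovery_{gi}_{rep}").integers(2**31))
            )
            fit = mle_k(counts, ci_level=ci_level)
            k_hats[rep] = fit.k_hat
            covered[rep] = fit.ci_low <= k_true <= fit.ci_high
        rows.append(
            {
                "k_true": float(k_true),
                "mean_k_hat": float(k_hats.mean()),
                "bias": float(k_hats.mean() - k_true),
                "rmse": float(np.sqrt(np.mean((k_hats - k_true) ** 2))),
                "ci_coverage": float(covered.mean()),
                "n": n,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
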