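"""Recombinant-based delimitation of a gametophytic sterility locus.

High-resolution mapping of a pollen-sterility locus rests on a simple
constraint: under the 1:1:0 gametophytic model a semi-sterile (SS) plant
is heterozygous at the locus and a normally fertile (N) plant is
homozygous for the cultivated allele.  Each recombinant plant therefore
confines the locus to the maximal run of markers whose genotype call
matches the call implied by its pollen phenotype; intersecting these
per-plant constraints yields the candidate interval between two flanking
markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerMap",
    "RecombinantRecord",
    "CandidateInterval",
    "ConflictingRecombinantsError",
    "breakpoint_intervals",
    "delimit_locus",
    "recombinant_yield",
    "estimate_recombinant_fraction",
    "render_graphical_genotypes",
]

GENOTYPE_CODES = ("T", "H", "G")
MISSING = None


class ConflictingRecombinantsError(ValueError):
    """Raised when recombinant constraints admit no locus position.

    Signals a phenotyping or genotyping error, or a second segregating
    locus inside the screened window.
    """

    def __init__(self, message: str, plants: list[str]):
        super().__init__(message)
        self.plants = list(plants)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered markers along the screened window.

    ``positions_bp`` (physical) and ``rec_fractions`` (per adjacent
    interval) are optional; positions must strictly increase along the
    order.
    """

    names: tuple[str, ...]
    positions_bp: tuple[float, ...] | None = None
    rec_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        names = tuple(self.names)
        if len(names) < 2:
            raise ValueError("a marker map needs at least two markers")
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        object.__setattr__(self, "names", names)
        if self.positions_bp is not None:
            pos = tuple(float(p) for p in self.positions_bp)
            if len(pos) != len(names):
                raise ValueError("positions_bp must match the number of markers")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("positions_bp must strictly increase along the marker order")
            object.__setattr__(self, "positions_bp", pos)
        if self.rec_fractions is not None:
            rf = tuple(float(r) for r in self.rec_fractions)
            if len(rf) != len(names) - 1:
                raise ValueError("rec_fractions must have one entry per adjacent interval")
            if any(not (0.0 <= r <= 0.5) for r in rf):
                raise ValueError("recombination fractions must lie in [0, 0.5]")
            object.__setattr__(self, "rec_fractions", rf)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _normalize_phenotype(label: str) -> str:
    """Map a phenotype label to the binary N/SS classification.

    Three-way sterile-pollen morphology labels (e.g. ``S22A_SS``) are
    accepted and collapse to SS for constraint purposes.
    """
    text = str(label).strip()
    if text.upper() == "N":
        return "N"
    if text.upper().endswith("SS"):
        return "SS"
    raise ValueError(f"unknown pollen phenotype label {label!r} (expected N or *SS)")


@dataclass(frozen=True)
class RecombinantRecord:
    """One plant's ordered marker genotype calls plus its pollen phenotype."""

    plant_id: str
    calls: tuple[str | None, ...]
    phenotype: str

    def __post_init__(self) -> None:
        calls = []
        for c in self.calls:
            if c is None or (isinstance(c, str) and c.strip() in ("", "-", ".", "NA")):
                calls.append(None)
                continue
            code = str(c).strip().upper()
            if code not in GENOTYPE_CODES:
                raise ValueError(
                    f"plant {self.plant_id}: unknown genotype code {c!r} "
                    f"(expected one of {GENOTYPE_CODES} or a missing token)"
                )
            calls.append(code)
        if sum(c is not None for c in calls) < 2:
            raise ValueError(f"plant {self.plant_id}: needs at least two non-missing calls")
        object.__setattr__(self, "calls", tuple(calls))
        object.__setattr__(self, "phenotype", _normalize_phenotype(self.phenotype))

    @property
    def implied_locus_call(self) -> str:
        """Genotype the plant must carry at the locus: H if SS, T if N."""
        return "H" if self.phenotype == "SS" else "T"


@dataclass(frozen=True)
class CandidateInterval:
    """Candidate locus interval between two flanking markers.

    An open side means the locus lies strictly beyond that flanking
    marker (the marker itself is excluded by a constraining plant); a
    closed side means the interval is bounded only by the end of the
    map.
    """

    left: str
    right: str
    left_open: bool
    right_open: bool
    supporting_plants: tuple[str, ...] = ()
    length_bp: float | None = None

    def to_dict(self) -> dict:
        out = {
            "left": self.left,
            "right": self.right,
            "left_open": self.left_open,
            "right_open": self.right_open,
            "supporting_plants": list(self.supporting_plants),
        }
        if self.length_bp is not None:
            out["length_bp"] = self.length_bp
        return out


def _check_record(record: RecombinantRecord, marker_map: MarkerMap) -> None:
    if len(record.calls) != len(marker_map):
        raise ValueError(
            f"plant {record.plant_id}: {len(record.calls)} calls but map has "
            f"{len(marker_map)} markers"
        )


def breakpoint_intervals(
    record: RecombinantRecord, marker_map: MarkerMap
) -> list[tuple[str, str]]:
    """Marker intervals containing the plant's recombination breakpoints.

    A breakpoint is localized between the two flanking *non-missing*
    calls that differ; missing calls widen the interval conservatively.
    """
    _check_record(record, marker_map)
    observed = [(i, c) for i, c in enumerate(record.calls) if c is not None]
    if not observed:
        raise ValueError(f"plant {record.plant_id}: all genotype calls are missing")
    out = []
    for (i_prev, c_prev), (i_next, c_next) in zip(observed, observed[1:]):
        if c_prev != c_next:
            out.append((marker_map.names[i_prev], marker_map.names[i_next]))
    return out


def _excluded_markers(record: RecombinantRecord) -> set[int]:
    """Marker indices positively excluded (non-missing, non-matching call)."""
    implied = record.implied_locus_call
    return {
        i for i, c in enumerate(record.calls) if c is not None and c != implied
    }


def _allowed_intervals(record: RecombinantRecord, n: int) -> list[tuple[float, float]]:
    """Open intervals of locus positions compatible with the plant.

    Positions are continuous marker-index coordinates (the locus sits at
    or between markers).  Each maximal run of calls matching the
    phenotype-implied genotype allows the open interval between the
    nearest positively excluding markers on either side; the map ends
    (sentinels at -0.5 and n-0.5) bound runs with no excluding flank.
    Missing calls never tighten a constraint.
    """
    implied = record.implied_locus_call
    intervals: list[tuple[float, float]] = []
    prev_excl = -0.5
    in_run = False
    for i, c in enumerate(record.calls):
        if c is None:
            continue
        if c == implied:
            in_run = True
        else:
            if in_run:
                intervals.append((prev_excl, float(i)))
                in_run = False
            prev_excl = float(i)
    if in_run:
        intervals.append((prev_excl, n - 0.5))
    return intervals


def delimit_locus(
    records: list[RecombinantRecord], marker_map: MarkerMap
) -> CandidateInterval:
    """Intersect per-plant constraints to delimit the sterility locus.

    Each plant confines the locus to the span where its genotype call
    matches its phenotype-implied call (H for SS, T for N), open out to
    the nearest positively excluding marker on each side (the
    breakpoint may fall anywhere in that gap, including between the
    locus and the flanking marker).  The locus must lie in the
    intersection of these per-plant regions; the result is reported as
    the interval between the tightest excluding flanks (open) or the
    map ends (closed).  ``supporting_plants`` are the recombinants
    whose calls set a flanking marker.

    Raises :class:`ConflictingRecombinantsError` when the constraints
    are incompatible, naming the plants involved — a signal of
    phenotyping/genotyping error or a second segregating locus.
    """
    if not records:
        raise ValueError("delimit_locus requires at least one recombinant record")
    n = len(marker_map)
    current: list[tuple[float, float]] = [(-0.5, n - 0.5)]
    seen: list[RecombinantRecord] = []
    for record in records:
        _check_record(record, marker_map)
        allowed = _allowed_intervals(record, n)
        if not allowed:
            raise ConflictingRecombinantsError(
                f"plant {record.plant_id} has no marker call matching its phenotype-"
                f"implied genotype {record.implied_locus_call!r}",
                plants=[record.plant_id],
            )
        nxt = [
            (max(lo1, lo2), min(hi1, hi2))
            for lo1, hi1 in current
            for lo2, hi2 in allowed
            if max(lo1, lo2) < min(hi1, hi2)
        ]
        if not nxt:
            culprits = [r.plant_id for r in seen] + [record.plant_id]
            raise ConflictingRecombinantsError(
                "conflicting recombinants: constraints admit no locus position "
                f"(plants {', '.join(culprits)}); check phenotyping/genotyping or "
                "consider a second locus",
                plants=culprits,
            )
        current = nxt
        seen.append(record)

    lo = min(iv[0] for iv in current)
    hi = max(iv[1] for iv in current)

    # A homozygous-wild call strictly inside the candidate span
    # contradicts the 1:1:0 model (the sterile allele cannot have been
    # transmitted by both gametes at the locus).
    g_plants = sorted(
        {
            r.plant_id
            for r in records
            if any(c == "G" and lo < i < hi for i, c in enumerate(r.calls))
        }
    )
    if g_plants:
        raise ConflictingRecombinantsError(
            "genotype G observed inside the candidate interval, impossible under "
            f"the 1:1:0 gametophytic model (plants {', '.join(g_plants)})",
            plants=g_plants,
        )

    left_open = lo > -0.5
    right_open = hi < n - 0.5
    left_idx = int(lo) if left_open else 0
    right_idx = int(hi) if right_open else n - 1
    exclusions = [(_excluded_markers(r), r.plant_id) for r in records]
    supporting = tuple(
        pid
        for excl, pid in exclusions
        if (left_open and left_idx in excl) or (right_open and right_idx in excl)
    )
    length_bp = None
    if marker_map.positions_bp is not None:
        length_bp = marker_map.positions_bp[right_idx] - marker_map.positions_bp[left_idx]
    return CandidateInterval(
        left=marker_map.names[left_idx],
        right=marker_map.names[right_idx],
        left_open=left_open,
        right_open=right_open,
        supporting_plants=supporting,
        length_bp=length_bp,
    )


def recombinant_yield(n_screened: int, r_plant: float) -> float:
    """Expected number of recombinant plants in a screen.

    ``r_plant`` is the per-plant probability of carrying at least one
    breakpoint in the screened interval; the expectation is simply
    ``n_screened * r_plant``.
    """
    if not (0.0 <= r_plant <= 1.0):
        raise ValueError(f"r_plant must lie in [0, 1], got {r_plant}")
    if n_screened < 0:
        raise ValueError("n_screened must be nonnegative")
    return n_screened * r_plant


def estimate_recombinant_fraction(
    n_recombinant: int, n_screened: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Per-plant recombinant fraction with an exact binomial (Clopper-Pearson) CI."""
    from scipy import stats

    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not (0 <= n_recombinant <= n_screened):
        raise ValueError("n_recombinant must lie in [0, n_screened]")
    x, m = n_recombinant, n_screened
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, m - x + 1))
    high = 1.0 if x == m else float(stats.beta.ppf(1 - alpha / 2, x + 1, m - x))
    return x / m, low, high


def render_graphical_genotypes(
    records: list[RecombinantRecord], marker_map: MarkerMap
) -> str:
    """Plain-text graphical genotype table: one row per plant, one column per marker."""
    width = max(len(n) for n in marker_map.names)
    id_width = max([len(r.plant_id) for r in records] + [len("plant")])
    lines = [
        " ".join(["plant".ljust(id_width)]
                 + [n.rjust(width) for n in marker_map.names] + ["phen"])
    ]
    for r in records:
        cells = [(c if c is not None else "-").rjust(width) for c in r.calls]
        lines.append(" ".join([r.plant_id.ljust(id_width)] + cells + [r.phenotype]))
    return "\n".join(lines)
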