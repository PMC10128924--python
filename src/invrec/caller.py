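"""Parental-origin assignment and CO/NCOGC event calling.

Each offspring chromosome is reduced to an *origin vector*: the parent of
origin (P1/P2/UNKNOWN) at every unmasked panel site.  After dropping
UNKNOWN sites the vector is run-length segmented and scanned left to
right:

* a short interior run flanked on both sides by the other origin is a
  noncrossover gene conversion (NCOGC) if its genomic span does not
  exceed ``max_ncogc_span``;
* an origin switch that persists is a crossover (CO), reported with a
  flanking-marker uncertainty interval ``(left_flank, right_flank]``;
* an interior run too wide to be a conversion tract is a double CO (both
  boundary COs are reported);
* switches without enough supporting sites are left unresolved rather
  than called, guarding against isolated genotyping errors.

Support rules (shared verbatim with the brute-force test oracle): at a CO
boundary the background-side (left) flank run is supported if it has at
least ``min_support_co`` sites or is the first run of the informative
region; the departure-side (right) run must itself have at least
``min_support_co`` sites.  Conversion tracts have no support requirement
but single-site tracts carry a ``low_support`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import MarkerPanel

log = logging.getLogger(__name__)

P1: int = 0
P2: int = 1
UNKNOWN: int = -1

_ORIGIN_NAME = {P1: "P1", P2: "P2", UNKNOWN: "UNKNOWN"}

MISSING_ALLELE = b"."


class UninformativeOffspringError(ValueError):
    """Raised when an origin vector has no informative (non-UNKNOWN) site."""


@dataclass
class OffspringObservation:
    """Observed alleles of one offspring, aligned 1:1 with all panel sites.

    ``alleles`` uses dtype S1; ``b"."`` (or empty) marks a missing call.
    ``y_coverage`` is chrY coverage normalized to autosomal coverage and
    is used to flag nondisjunction in male-expected offspring.
    """

    offspring_id: str
    alleles: np.ndarray
    y_coverage: float | None = None
    selection_class: str = "nonrecombinant"  # or "recombinant"

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype="S1")
        if self.y_coverage is not None and self.y_coverage < 0:
            raise ValueError("y_coverage must be >= 0")


@dataclass
class OriginVector:
    """Per-site parental-origin calls aligned to the unmasked panel sites."""

    offspring_id: str
    calls: np.ndarray  # int8 in {P1, P2, UNKNOWN}
    n_conflicts: int = 0  # observed alleles matching neither parent

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class RecombinationEvent:
    """A called CO or NCOGC with its flanking-marker uncertainty interval.

    ``left_flank``/``right_flank`` are the nearest informative sites of the
    surrounding origin; the event lies in ``(left_flank, right_flank]``.
    ``inner_start``/``inner_end`` delimit the switched sites themselves.
    For an NCOGC, ``converted_sites`` lists the converted site positions.
    """

    offspring_id: str
    event_class: str  # "CO" | "NCOGC"
    left_flank: int
    right_flank: int
    inner_start: int
    inner_end: int
    n_support: int
    converted_sites: tuple[int, ...] | None = None
    flags: tuple[str, ...] = ()
    excluded: bool = False

    def __post_init__(self):
        if self.event_class not in ("CO", "NCOGC"):
            raise ValueError(f"bad event class {self.event_class!r}")
        if not (self.left_flank < self.inner_start <= self.right_flank):
            raise ValueError("event interval must satisfy left < inner <= right")
        if self.n_support < 1:
            raise ValueError("n_support must be >= 1")

    @property
    def midpoint(self) -> float:
        """Midpoint of the uncertainty interval; the point used for binning."""
        return (self.left_flank + self.right_flank) / 2.0

    def key(self) -> tuple:
        """Canonical tuple for comparisons (oracle equivalence tests)."""
        return (
            self.event_class,
            int(self.left_flank),
            int(self.inner_start),
            int(self.inner_end),
            int(self.right_flank),
            int(self.n_support),
        )


@dataclass
class UnresolvedBoundary:
    """An origin switch with insufficient support to call; logged, not called."""

    offspring_id: str
    left_flank: int
    right_flank: int
    reason: str


@dataclass
class CallResult:
    offspring_id: str
    events: list[RecombinationEvent]
    unresolved: list[UnresolvedBoundary] = field(default_factory=list)

    @property
    def cos(self) -> list[RecombinationEvent]:
        return [e for e in self.events if e.event_class == "CO"]

    @property
    def ncogcs(self) -> list[RecombinationEvent]:
        return [e for e in self.events if e.event_class == "NCOGC"]


@dataclass
class NdjCall:
    offspring_id: str
    is_nondisjunction: bool | None  # None when Y coverage is unavailable
    y_coverage: float | None
    threshold: float


@dataclass
class JackpotGroup:
    """NCOGCs with byte-identical converted-site sets in >= 2 offspring.

    Identical tracts in different individuals are best explained by a
    single pre-meiotic (germline mitotic) conversion propagated to
    several gametes.
    """

    converted_sites: tuple[int, ...]
    offspring_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.offspring_ids)


def assign_parental_origin(obs: OffspringObservation, panel: MarkerPanel) -> OriginVector:
    """Call P1/P2/UNKNOWN at each unmasked panel site.

    A site is P1 if the observed allele equals the P1 allele, P2 if it
    equals the P2 allele, and UNKNOWN if missing or matching neither
    parent (non-parental alleles are counted as conflicts and logged).
    """
    if len(obs.alleles) != panel.n_sites:
        raise ValueError(
            f"observation length {len(obs.alleles)} does not match panel "
            f"({panel.n_sites} sites)"
        )
    idx = panel.unmasked_index
    a = obs.alleles[idx]
    calls = np.full(len(idx), UNKNOWN, dtype=np.int8)
    calls[a == panel.allele_p1[idx]] = P1
    calls[a == panel.allele_p2[idx]] = P2
    missing = (a == MISSING_ALLELE) | (a == b"")
    conflicts = int(((calls == UNKNOWN) & ~missing).sum())
    if conflicts:
        log.debug("%s: %d non-parental alleles set to UNKNOWN", obs.offspring_id, conflicts)
    return OriginVector(obs.offspring_id, calls, n_conflicts=conflicts)


def _runs(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length segmentation: (origins, start_idx, end_idx) per run."""
    change = np.flatnonzero(np.diff(calls) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, len(calls) - 1]
    return calls[starts], starts, ends


def call_events(
    vec: OriginVector,
    panel: MarkerPanel,
    min_support_co: int = 2,
    max_ncogc_span: int = 10_000,
) -> CallResult:
    """Segment an origin vector into CO and NCOGC calls.

    ``max_ncogc_span`` (bp, on the switched sites themselves) separates
    conversion tracts from double COs; the default 10 kb is generous
    relative to the ~400 bp tracts expected in *D. melanogaster* while
    still far below typical double-CO separations.
    """
    if min_support_co < 1:
        raise ValueError("min_support_co must be >= 1")
    if max_ncogc_span < 0:
        raise ValueError("max_ncogc_span must be >= 0")
    keep = vec.calls != UNKNOWN
    if not keep.any():
        raise UninformativeOffspringError(
            f"offspring {vec.offspring_id!r}: no informative site"
        )
    calls = vec.calls[keep]
    pos = panel.unmasked_positions[keep]

    origins, r_start, r_end = _runs(calls)
    nruns = len(origins)
    rlen = r_end - r_start + 1

    events: list[RecombinationEvent] = []
    unresolved: list[UnresolvedBoundary] = []

    j = 0  # boundary index: boundary j lies between runs j and j+1
    while j < nruns - 1:
        # Tract candidate: run j+1 is interior (a following run exists to
        # revert to) and its genomic span fits a conversion tract.
        interior = (j + 1) < (nruns - 1)
        span = int(pos[r_end[j + 1]] - pos[r_start[j + 1]])
        if interior and span <= max_ncogc_span:
            flags = ("low_support",) if rlen[j + 1] == 1 else ()
            events.append(
                RecombinationEvent(
                    offspring_id=vec.offspring_id,
                    event_class="NCOGC",
                    left_flank=int(pos[r_end[j]]),
                    right_flank=int(pos[r_start[j + 2]]),
                    inner_start=int(pos[r_start[j + 1]]),
                    inner_end=int(pos[r_end[j + 1]]),
                    n_support=int(rlen[j + 1]),
                    converted_sites=tuple(int(p) for p in pos[r_start[j + 1] : r_end[j + 1] + 1]),
                    flags=flags,
                )
            )
            j += 2
            continue
        # Single boundary: CO candidate.  Left run is background-side,
        # right run is the departure.
        left_ok = rlen[j] >= min_support_co or j == 0
        right_ok = rlen[j + 1] >= min_support_co
        lf = int(pos[r_end[j]])
        rf = int(pos[r_start[j + 1]])
        if left_ok and right_ok:
            events.append(
                RecombinationEvent(
                    offspring_id=vec.offspring_id,
                    event_class="CO",
                    left_flank=lf,
                    right_flank=rf,
                    inner_start=rf,
                    inner_end=int(pos[r_end[j + 1]]),
                    n_support=int(rlen[j + 1]),
                )
            )
        else:
            reason = "short_departure_run" if not right_ok else "short_left_flank"
            unresolved.append(UnresolvedBoundary(vec.offspring_id, lf, rf, reason))
            log.debug("%s: unresolved switch at (%d, %d]: %s", vec.offspring_id, lf, rf, reason)
        j += 1

    return CallResult(vec.offspring_id, events, unresolved)


def detect_nondisjunction(
    obs: OffspringObservation, y_cov_threshold: float = 0.1
) -> NdjCall:
    """Flag nondisjunction from missing Y-chromosome coverage.

    Male-expected offspring lacking Y coverage received both maternal X
    chromatids (X nondisjunction).  The decision is a strict less-than on
    the normalized Y coverage; coverage exactly at the threshold is not
    flagged.  Missing coverage yields an undetermined (None) status.
    """
    if obs.y_coverage is None:
        return NdjCall(obs.offspring_id, None, None, y_cov_threshold)
    return NdjCall(
        obs.offspring_id,
        bool(obs.y_coverage < y_cov_threshold),
        float(obs.y_coverage),
        y_cov_threshold,
    )


def find_jackpots(events) -> list[JackpotGroup]:
    """Group NCOGCs with exactly equal converted-site sets across offspring.

    Only groups of size >= 2 (distinct offspring) are reported; these are
    pre-meiotic jackpot candidates.
    """
    by_tract: dict[tuple[int, ...], list[str]] = {}
    for e in events:
        if e.event_class != "NCOGC":
            continue
        if e.converted_sites is None:
            raise ValueError("NCOGC event lacks converted_sites")
        by_tract.setdefault(tuple(sorted(e.converted_sites)), []).append(e.offspring_id)
    groups = []
    for tract, ids in sorted(by_tract.items()):
        uniq = tuple(dict.fromkeys(ids))
        if len(uniq) >= 2:
            groups.append(JackpotGroup(tract, uniq))
    return groups


def restrict_to_selected_interval(
    events, interval: tuple[int, int], selection_class: str
) -> list[RecombinationEvent]:
    """Flag COs outside the phenotypically selected interval as excluded.

    In a recombinant-selected cross, COs recovered wholly outside the
    selected interval rode along with the selected event and were not
    themselves selected for; counting them would bias frequencies.  They
    are retained with ``excluded=True`` rather than dropped.  NCOGCs are
    never excluded by this rule, and nonrecombinant-selected offspring
    are unaffected.
    """
    start, end = interval
    if start >= end:
        raise ValueError("interval must satisfy start < end")
    out = []
    for e in events:
        excluded = e.excluded
        if selection_class == "recombinant" and e.event_class == "CO":
            # uncertainty interval (left_flank, right_flank]; disjoint from
            # [start, end] iff entirely proximal or distal of it
            if e.right_flank < start or e.left_flank >= end:
                excluded = True
        out.append(
            RecombinationEvent(
                offspring_id=e.offspring_id,
                event_class=e.event_class,
                left_flank=e.left_flank,
                right_flank=e.right_flank,
                inner_start=e.inner_start,
                inner_end=e.inner_end,
                n_support=e.n_support,
                converted_sites=e.converted_sites,
                flags=e.flags,
                excluded=excluded,
            )
        )
    return out
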