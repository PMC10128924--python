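"""Scoring caller output against simulator ground truth.

Recovery is only well-defined for events the marker panel can resolve in
principle, so the scorer distinguishes *resolvable* truth from the rest:

* a CO is resolvable when at least ``min_support_co`` unmasked markers
  flank it on each side, none of those flank markers is inside a
  conversion tract, and no second CO either shares its informative gap
  (no unmasked marker between them: the pair is invisible) or is
  separated from it by markers spanning at most ``max_ncogc_span`` (the
  pair is by construction indistinguishable from a conversion tract);
* a conversion tract is detectable when it covers at least one unmasked
  marker, an unmasked marker exists on each side outside the tract, and
  no CO or second tract falls between its flanking markers.

A called CO matches a truth CO when its flanking-marker interval
contains the true breakpoint; a called NCOGC matches a tract when the
converted-site set equals the tract's covered markers.  Calls explained
by *no* truth at all (including unresolvable truth and close-CO pairs)
are spurious.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caller import CallResult
from .panel import MarkerPanel
from .sim import SimulatedOffspring


@dataclass
class RecoverySummary:
    n_co_true: int = 0
    n_co_resolvable: int = 0
    n_co_recovered: int = 0
    n_tract_true: int = 0
    n_tract_detectable: int = 0
    n_tract_recovered: int = 0
    n_spurious: int = 0
    missed: list[tuple[str, str, object]] = field(default_factory=list)
    spurious: list[tuple[str, tuple]] = field(default_factory=list)

    @property
    def co_recovery(self) -> float:
        return self.n_co_recovered / self.n_co_resolvable if self.n_co_resolvable else float("nan")

    @property
    def tract_recovery(self) -> float:
        return self.n_tract_recovered / self.n_tract_detectable if self.n_tract_detectable else float("nan")


def _tracts_of(off: SimulatedOffspring) -> list[tuple[int, int]]:
    tracts = list(off.product.tracts)
    if off.product.jackpot_tract is not None:
        tracts.append(off.product.jackpot_tract)
    return tracts


def score_recovery(
    offspring: list[SimulatedOffspring],
    results: dict[str, CallResult],
    panel: MarkerPanel,
    min_support_co: int = 2,
    max_ncogc_span: int = 10_000,
) -> RecoverySummary:
    """Compare called events with simulator truth, offspring by offspring.

    ``results`` maps offspring id to its :class:`CallResult`.
    Nondisjunction offspring (no meiotic product) are skipped.
    """
    P = panel.unmasked_positions
    s = RecoverySummary()
    for off in offspring:
        if off.product is None:
            continue
        res = results[off.offspring_id]
        cos = sorted(off.product.co_positions)
        tracts = _tracts_of(off)
        covered_sets = []
        for (a, b) in tracts:
            i0 = int(np.searchsorted(P, a, side="left"))
            i1 = int(np.searchsorted(P, b, side="right"))
            covered_sets.append((i0, i1, tuple(int(p) for p in P[i0:i1])))

        called_cos = [e for e in res.events if e.event_class == "CO"]
        called_nco = [e for e in res.events if e.event_class == "NCOGC"]

        # ---- truth COs ----
        for k, x in enumerate(cos):
            s.n_co_true += 1
            lc = int(np.searchsorted(P, x, side="right"))  # markers <= x
            rc = len(P) - lc
            resolvable = lc >= min_support_co and rc >= min_support_co
            if resolvable:
                # a second CO with no marker between them is jointly
                # invisible; with intervening markers spanning at most
                # max_ncogc_span the pair mimics a conversion tract
                for j, x2 in enumerate(cos):
                    if j == k:
                        continue
                    a, b = sorted((x, x2))
                    i0 = int(np.searchsorted(P, a, side="right"))
                    i1 = int(np.searchsorted(P, b, side="right"))
                    between = P[i0:i1]
                    if len(between) == 0 or between[-1] - between[0] <= max_ncogc_span:
                        resolvable = False
                        break
            if resolvable:
                flank = list(P[lc - min_support_co : lc]) + list(P[lc : lc + min_support_co])
                if any(a <= m <= b for m in flank for (a, b) in tracts):
                    resolvable = False
            if not resolvable:
                continue
            s.n_co_resolvable += 1
            if any(e.left_flank <= x < e.right_flank for e in called_cos):
                s.n_co_recovered += 1
            else:
                s.missed.append((off.offspring_id, "CO", x))

        # ---- truth tracts ----
        for (a, b), (i0, i1, covered) in zip(tracts, covered_sets):
            s.n_tract_true += 1
            if not covered:
                continue
            detectable = i0 > 0 and i1 < len(P)
            if detectable:
                lfm, rfm = int(P[i0 - 1]), int(P[i1])
                if any(lfm <= x < rfm for x in cos):
                    detectable = False
                for (i0b, i1b, covb) in covered_sets:
                    if covb and (i0b, i1b) != (i0, i1) and i0b <= i1 and i1b >= i0:
                        detectable = False
                # adjacent tracts merging into one run
                for (i0b, i1b, covb) in covered_sets:
                    if covb and (i0b, i1b) != (i0, i1) and (i0b == i1 or i1b == i0):
                        detectable = False
            if not detectable:
                continue
            s.n_tract_detectable += 1
            if any(e.converted_sites == covered for e in called_nco):
                s.n_tract_recovered += 1
            else:
                s.missed.append((off.offspring_id, "NCOGC", (a, b)))

        # ---- spurious calls ----
        pair_sets = set()
        for j in range(len(cos)):
            for k in range(j + 1, len(cos)):
                x1, x2 = cos[j], cos[k]
                i0 = int(np.searchsorted(P, x1, side="right"))
                i1 = int(np.searchsorted(P, x2, side="right"))
                pair_sets.add(tuple(int(p) for p in P[i0:i1]))
        tract_sets = {cov for (_, _, cov) in covered_sets if cov}
        for e in called_cos:
            ok = any(e.left_flank <= x < e.right_flank for x in cos)
            if not ok:  # CO-looking edge of a tract touching a region end
                ok = any(
                    (e.left_flank < a <= e.right_flank) or (e.left_flank <= b < e.right_flank)
                    for (a, b) in tracts
                )
            if not ok:
                s.n_spurious += 1
                s.spurious.append((off.offspring_id, e.key()))
        for e in called_nco:
            if e.converted_sites not in tract_sets and e.converted_sites not in pair_sets:
                s.n_spurious += 1
                s.spurious.append((off.offspring_id, e.key()))
    return s
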