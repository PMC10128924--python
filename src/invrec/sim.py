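"""Forward simulation of meiosis in an inversion heterozygote.

The simulator is both the package's synthetic-data generator and its
scientific model of how a heterozygous paracentric inversion distorts
what is recovered in offspring:

* Meiotic DSBs land uniformly on the chromosome.  Each DSB is resolved
  as a crossover (CO) with a position-dependent probability, as a
  noncrossover gene conversion (NCOGC) tract with a constant probability,
  or invisibly (intersister repair).  Keeping the NCOGC probability
  position-independent encodes the central observation that inversion
  breakpoints alter repair *outcome*, not DSB formation: conversions are
  generated evenly while COs are suppressed.
* CO suppression outside the inversion is distance dependent: zero
  within ``suppression_radius`` of a breakpoint, rising linearly to the
  unsuppressed rate at ``suppression_full_distance`` (per side — the
  distal side defaults to a much longer ramp, reflecting the combined
  telomere + breakpoint suppression seen on real distal segments).
* Inside the inversion COs still form (``p_co_intra``, calibrated so
  that roughly 12% of pre-selection chromatids carry a single
  intra-inversion CO), but a transmitted chromatid carrying an odd
  number of intra-inversion COs would be acentric/dicentric; such
  candidates are rejected and the meiosis redrawn (polar-body
  elimination).  Offspring therefore never carry a single
  intra-inversion CO, and the surviving pool is enriched for
  conversion-bearing chromatids — Sturtevant's transmission distortion.
* The DSB count per transmitted-chromatid candidate is, by default,
  *regulated*: ``floor(mean)`` plus a Bernoulli remainder.  Meiotic DSB
  numbers are tightly controlled, and an underdispersed count is what
  couples CO and NCOGC numbers through fate competition; with an exactly
  Poisson count the per-chromatid CO and NCOGC counts would be
  independent and elimination could not enrich conversions.

The simulation is single-transmitted-chromatid: one candidate product
per meiosis, with rejection, rather than full four-strand bookkeeping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .caller import MISSING_ALLELE, OffspringObservation
from .panel import MarkerPanel

log = logging.getLogger(__name__)

#: dm6 chrX length (bp)
CHRX_LENGTH = 23_542_271
#: dl-49 inversion breakpoints (bp, dm6).  The proximal breakpoint is
#: reported as an interval; the upper bound is used as the default point.
DL49_DISTAL = 4_897_260
DL49_PROXIMAL = 13_427_212

#: Approximate dm6 coordinates of the phenotypic marker loci used to
#: select recombinants (y, cv, wy = IP3K2, f).
DEFAULT_MARKERS: dict[str, int] = {
    "y": 253_000,
    "cv": 5_796_000,
    "wy": 13_135_000,
    "f": 17_432_000,
}


@dataclass(frozen=True)
class InversionCrossModel:
    """Parameters of an inversion-heterozygote cross on one chromosome.

    Defaults emulate the *dl-49* X-chromosome cross: dm6 chrX length and
    breakpoints, ~400 bp conversion tracts, per-chromatid DSB mean 1.42
    with CO fraction 0.47 (unsuppressed map length ~67 cM for the whole
    X; ~0.75 conversion tracts per transmitted chromatid).
    """

    chrom: str = "chrX"
    chrom_length: int = CHRX_LENGTH
    breakpoint_distal: int = DL49_DISTAL
    breakpoint_proximal: int = DL49_PROXIMAL
    inversion_active: bool = True
    dsb_mean: float = 1.42
    dsb_count_model: str = "regulated"  # "regulated" (underdispersed) | "poisson"
    p_co: float = 0.47
    p_nco: float = 0.53
    p_co_intra: float = 0.246
    tract_mean: float = 400.0
    suppression_radius: int = 500_000
    suppression_full_distance: int = 3_000_000
    suppression_full_distance_distal: int = 10_000_000
    ndj_rate: float = 0.0
    jackpot_prob: float = 0.0
    jackpot_clone_mean: float = 3.0
    max_rejection_attempts: int = 100_000

    def __post_init__(self):
        if not (0 < self.breakpoint_distal < self.breakpoint_proximal < self.chrom_length):
            raise ValueError("need 0 < distal < proximal < chromosome length")
        for name in ("p_co", "p_nco", "p_co_intra", "ndj_rate", "jackpot_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_co + self.p_nco > 1.0 + 1e-12 or self.p_co_intra + self.p_nco > 1.0 + 1e-12:
            raise ValueError("CO + NCO resolution probabilities exceed 1")
        if self.tract_mean <= 0 or self.dsb_mean < 0:
            raise ValueError("tract_mean and dsb_mean must be positive")
        if self.dsb_count_model not in ("regulated", "poisson"):
            raise ValueError("dsb_count_model must be 'regulated' or 'poisson'")
        if self.suppression_radius < 0 or self.suppression_full_distance <= self.suppression_radius:
            raise ValueError("need 0 <= radius < full distance")

    @property
    def inversion_length(self) -> int:
        return self.breakpoint_proximal - self.breakpoint_distal

    def is_intra_inversion(self, positions) -> np.ndarray:
        x = np.asarray(positions)
        return (x > self.breakpoint_distal) & (x < self.breakpoint_proximal)


@dataclass(frozen=True)
class SelectionScheme:
    """Phenotypic selection rule for collected offspring.

    ``select`` names the marker pair; an offspring is *recombinant* when
    the transmitted chromatid has different parental origins at the two
    marker loci.  ``mode`` keeps recombinants, nonrecombinants, or all
    offspring (None).  Nondisjunction offspring phenotypically mimic
    recombinants when ``ndj_mimics_recombinant`` (the cross-2 scenario:
    they could not be told apart until sequencing).
    """

    markers: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    select: tuple[str, str] = ("y", "f")
    mode: str | None = None  # "recombinant" | "nonrecombinant" | None
    ndj_mimics_recombinant: bool = True

    def __post_init__(self):
        if self.mode not in (None, "recombinant", "nonrecombinant"):
            raise ValueError("mode must be 'recombinant', 'nonrecombinant' or None")
        for name in self.select:
            if name not in self.markers:
                raise ValueError(f"unknown marker {name!r}")

    @property
    def interval(self) -> tuple[int, int]:
        a = self.markers[self.select[0]]
        b = self.markers[self.select[1]]
        return (min(a, b), max(a, b))


@dataclass(frozen=True)
class MeioticProduct:
    """Ground truth for one transmitted chromatid.

    ``co_positions``: breakpoints x (switch between x and x+1).
    ``tracts``: conversion tracts (start, end), 1-based inclusive, that
    flip the local origin to the other homolog.
    """

    base_origin: int
    co_positions: tuple[int, ...]
    tracts: tuple[tuple[int, int], ...]
    attempts: int = 1
    jackpot_tract: tuple[int, int] | None = None


@dataclass
class SimulatedOffspring:
    offspring_id: str
    observation: OffspringObservation
    product: MeioticProduct | None  # None for nondisjunction offspring
    is_ndj: bool
    jackpot_id: int | None = None


def suppression_factor(model: InversionCrossModel, distance, distal_side: bool = False):
    """CO suppression multiplier f(d) for distance d from a breakpoint.

    f = 0 within ``suppression_radius``, rising linearly to 1 at the
    side's full-recovery distance; monotone non-decreasing in d.
    """
    d = np.asarray(distance, dtype=float)
    full = model.suppression_full_distance_distal if distal_side else model.suppression_full_distance
    f = (d - model.suppression_radius) / (full - model.suppression_radius)
    return np.clip(f, 0.0, 1.0)


def suppression_profile(model: InversionCrossModel, positions) -> np.ndarray:
    """f(d) at chromosome positions outside the inversion (NaN inside).

    Distance is measured to the nearest breakpoint; the distal side uses
    its own (longer) ramp.  Intra-inversion CO formation is governed
    separately by ``p_co_intra``.
    """
    x = np.asarray(positions, dtype=float)
    if (x < 1).any() or (x > model.chrom_length).any():
        raise ValueError("positions outside chromosome")
    out = np.full(x.shape, np.nan)
    distal = x <= model.breakpoint_distal
    proximal = x >= model.breakpoint_proximal
    out[distal] = suppression_factor(model, model.breakpoint_distal - x[distal], distal_side=True)
    out[proximal] = suppression_factor(model, x[proximal] - model.breakpoint_proximal, distal_side=False)
    return out


def co_probability(model: InversionCrossModel, positions) -> np.ndarray:
    """Per-DSB probability of CO resolution at each position."""
    x = np.asarray(positions)
    if not model.inversion_active:
        return np.full(x.shape, model.p_co)
    p = np.empty(x.shape, dtype=float)
    intra = model.is_intra_inversion(x)
    p[intra] = model.p_co_intra
    f = suppression_profile(model, x[~intra])
    p[~intra] = model.p_co * f
    return p


def _draw_dsb_count(model: InversionCrossModel, rng: np.random.Generator) -> int:
    if model.dsb_count_model == "poisson":
        return int(rng.poisson(model.dsb_mean))
    base = int(math.floor(model.dsb_mean))
    frac = model.dsb_mean - base
    return base + int(rng.random() < frac)


def _draw_tract(model: InversionCrossModel, x: int, rng: np.random.Generator) -> tuple[int, int]:
    length = int(rng.geometric(1.0 / model.tract_mean))
    offset = int(rng.integers(0, length))
    start = max(1, x - offset)
    end = min(model.chrom_length, start + length - 1)
    return (start, end)


def simulate_meiosis(model: InversionCrossModel, rng) -> MeioticProduct:
    """Draw one transmitted chromatid (with polar-body rejection).

    ``rng`` is a numpy Generator or a seed.  Identical (model, seed)
    pairs give identical output.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for attempt in range(1, model.max_rejection_attempts + 1):
        n = _draw_dsb_count(model, rng)
        base = int(rng.integers(0, 2))
        if n == 0:
            return MeioticProduct(base, (), (), attempts=attempt)
        xs = rng.integers(1, model.chrom_length + 1, size=n)
        u = rng.random(n)
        pco = co_probability(model, xs)
        is_co = u < pco
        is_nco = (~is_co) & (u < pco + model.p_nco)
        co_pos = tuple(int(x) for x in np.sort(xs[is_co]))
        if model.inversion_active:
            n_intra = int(model.is_intra_inversion(np.array(co_pos)).sum()) if co_pos else 0
            if n_intra % 2 == 1:
                continue  # acentric/dicentric product: eliminated
        tracts = tuple(_draw_tract(model, int(x), rng) for x in xs[is_nco])
        return MeioticProduct(base, co_pos, tracts, attempts=attempt)
    raise RuntimeError(
        f"no transmissible chromatid in {model.max_rejection_attempts} attempts"
    )


def origin_at(product: MeioticProduct, positions) -> np.ndarray:
    """Parental origin (0/1) of the transmitted chromatid at positions."""
    pos = np.asarray(positions, dtype=np.int64)
    co = np.asarray(product.co_positions, dtype=np.int64)
    orig = (product.base_origin + np.searchsorted(co, pos, side="left")) % 2
    covered = np.zeros(pos.shape, dtype=bool)
    tracts = list(product.tracts)
    if product.jackpot_tract is not None:
        tracts.append(product.jackpot_tract)
    for s, e in tracts:
        covered |= (pos >= s) & (pos <= e)
    orig = orig.astype(np.int8)
    orig[covered] ^= 1
    return orig


def is_phenotypically_recombinant(product: MeioticProduct, scheme: SelectionScheme) -> bool:
    a, b = scheme.select
    o = origin_at(product, [scheme.markers[a], scheme.markers[b]])
    return bool(o[0] != o[1])


def _render_observation(
    offspring_id: str,
    origins: np.ndarray,
    panel: MarkerPanel,
    y_coverage: float,
    selection_class: str,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> OffspringObservation:
    alleles = np.where(origins == 0, panel.allele_p1, panel.allele_p2)
    n = len(alleles)
    if missing_rate > 0:
        miss = rng.random(n) < missing_rate
        alleles = np.where(miss, MISSING_ALLELE, alleles)
    if error_rate > 0:
        flip = rng.random(n) < error_rate
        other = np.where(origins == 0, panel.allele_p2, panel.allele_p1)
        alleles = np.where(flip & (alleles != MISSING_ALLELE), other, alleles)
    return OffspringObservation(
        offspring_id=offspring_id,
        alleles=alleles,
        y_coverage=y_coverage,
        selection_class=selection_class,
    )


def simulate_cross(
    model: InversionCrossModel,
    panel: MarkerPanel,
    scheme: SelectionScheme | None,
    n_offspring: int,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed=None,
    jackpot_clone_sizes: tuple[int, ...] = (),
) -> list[SimulatedOffspring]:
    """Simulate offspring until ``n_offspring`` pass phenotypic selection.

    Nondisjunction offspring are injected at ``model.ndj_rate``; they
    carry both maternal homologs (rendered as an arbitrary per-site
    collapse of the heterozygous genotype) and essentially no Y
    coverage.  Pre-meiotic jackpot clones — identical conversion tracts
    shared by several offspring — are injected either from the explicit
    ``jackpot_clone_sizes`` or at ``model.jackpot_prob`` clones per
    collected offspring with mean clone size ``model.jackpot_clone_mean``.
    """
    rng = np.random.default_rng(seed)
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    mode = scheme.mode if scheme is not None else None

    collected: list[tuple[str, MeioticProduct | None, bool]] = []
    attempts = 0
    max_attempts = max(10_000, 2_000 * n_offspring)
    while len(collected) < n_offspring:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"selection scheme not satisfied after {max_attempts} meioses"
            )
        if model.ndj_rate > 0 and rng.random() < model.ndj_rate:
            pheno_recomb = scheme.ndj_mimics_recombinant if scheme else False
            if mode is None or (mode == "recombinant") == pheno_recomb:
                collected.append(("ndj", None, pheno_recomb))
            continue
        product = simulate_meiosis(model, rng)
        if scheme is not None:
            pheno_recomb = is_phenotypically_recombinant(product, scheme)
        else:
            pheno_recomb = False
        if mode is None or (mode == "recombinant") == pheno_recomb:
            collected.append(("meiosis", product, pheno_recomb))

    # pre-meiotic jackpot clones
    sizes = [int(k) for k in jackpot_clone_sizes]
    if not sizes and model.jackpot_prob > 0:
        n_clones = int(rng.poisson(model.jackpot_prob * n_offspring))
        extra = max(model.jackpot_clone_mean - 2.0, 0.0)
        sizes = [2 + int(rng.poisson(extra)) for _ in range(n_clones)]
    jackpot_of: dict[int, tuple[int, tuple[int, int]]] = {}
    if sizes:
        if panel.n_unmasked == 0:
            raise ValueError("cannot place jackpot tracts on an empty panel")
        pool = [i for i, (kind, _, _) in enumerate(collected) if kind == "meiosis"]
        for cid, k in enumerate(sizes):
            if k < 2:
                raise ValueError("jackpot clone size must be >= 2")
            if k > len(pool):
                raise ValueError("jackpot clone larger than available offspring")
            anchor = int(rng.choice(panel.unmasked_positions))
            length = int(rng.geometric(1.0 / model.tract_mean))
            offset = int(rng.integers(0, length))
            start = max(1, anchor - offset)
            end = min(model.chrom_length, start + length - 1)
            members = rng.choice(len(pool), size=k, replace=False)
            chosen = [pool[m] for m in members]
            for i in sorted(chosen, reverse=True):
                pool.remove(i)
            for i in chosen:
                jackpot_of[i] = (cid, (start, end))

    offspring: list[SimulatedOffspring] = []
    width = max(4, len(str(n_offspring)))
    for i, (kind, product, pheno_recomb) in enumerate(collected):
        oid = f"off{i + 1:0{width}d}"
        sel_class = "recombinant" if pheno_recomb else "nonrecombinant"
        if kind == "ndj":
            origins = rng.integers(0, 2, size=panel.n_sites).astype(np.int8)
            ycov = float(rng.uniform(0.0, 0.02))
            obs = _render_observation(
                oid, origins, panel, ycov, sel_class, error_rate, missing_rate, rng
            )
            offspring.append(SimulatedOffspring(oid, obs, None, True))
            continue
        jid = None
        if i in jackpot_of:
            jid, tract = jackpot_of[i]
            product = replace(product, jackpot_tract=tract)
        origins = origin_at(product, panel.positions)
        ycov = float(max(0.0, rng.normal(1.0, 0.15)))
        obs = _render_observation(
            oid, origins, panel, ycov, sel_class, error_rate, missing_rate, rng
        )
        offspring.append(SimulatedOffspring(oid, obs, product, False, jackpot_id=jid))
    return offspring


def synthetic_panel(
    chrom: str = "chrX",
    chrom_length: int = CHRX_LENGTH,
    mean_spacing: float = 367.0,
    low_density_region: tuple[int, int] | None = (1, DL49_DISTAL),
    low_density_spacing: float = 81_540.0,
    seed=None,
) -> MarkerPanel:
    """Generate a diagnostic panel with realistic marker density.

    Sites follow a Poisson process at ``1/mean_spacing`` per bp, except
    inside ``low_density_region`` where the rate drops to
    ``1/low_density_spacing`` — emulating the distal segment of the real
    cross where shared ancestry leaves almost no diagnostic SNVs.
    Alleles are drawn uniformly with P1 != P2 at every site.
    """
    rng = np.random.default_rng(seed)
    if mean_spacing <= 0 or low_density_spacing <= 0:
        raise ValueError("spacings must be positive")
    positions: list[int] = []
    x = 0.0
    lo, hi = low_density_region if low_density_region is not None else (0, 0)
    while True:
        spacing = low_density_spacing if (low_density_region and lo <= x + 1 <= hi) else mean_spacing
        x += rng.exponential(spacing)
        if x >= chrom_length:
            break
        positions.append(int(math.ceil(x)))
    pos = np.unique(np.asarray(positions, dtype=np.int64))
    bases = np.array([b"A", b"C", b"G", b"T"])
    i1 = rng.integers(0, 4, size=len(pos))
    i2 = (i1 + rng.integers(1, 4, size=len(pos))) % 4
    return MarkerPanel(
        chrom=chrom,
        chrom_length=chrom_length,
        positions=pos,
        allele_p1=bases[i1],
        allele_p2=bases[i2],
    )


def expected_map_length(model: InversionCrossModel, interval: tuple[int, int], n_grid: int = 20_001) -> float:
    """Analytic expected map length (cM) of an interval, pre-rejection.

    Exact for ``inversion_active=False``; with the inversion on, the
    rejection step perturbs realized rates slightly (intra-inversion COs
    are transmitted only in pairs), so treat this as the generation-rate
    map length.
    """
    a, b = interval
    if not (0 < a < b <= model.chrom_length):
        raise ValueError("bad interval")
    grid = np.linspace(a, b, n_grid)
    mean_c = float(co_probability(model, grid.astype(np.int64)).mean())
    return 100.0 * model.dsb_mean * mean_c * (b - a) / model.chrom_length


def scaled_to_map_length(
    model: InversionCrossModel, interval: tuple[int, int], target_cM: float
) -> InversionCrossModel:
    """Rescale ``dsb_mean`` so the interval's expected map length hits target."""
    current = expected_map_length(model, interval)
    if current <= 0:
        raise ValueError("interval has zero expected map length")
    return replace(model, dsb_mean=model.dsb_mean * target_cM / current)


def intra_inversion_single_co_probability(model: InversionCrossModel) -> float:
    """P(exactly one intra-inversion CO on a pre-selection chromatid)."""
    a = model.inversion_length / model.chrom_length * model.p_co_intra
    if model.dsb_count_model == "poisson":
        lam = model.dsb_mean * a
        return lam * math.exp(-lam)
    base = int(math.floor(model.dsb_mean))
    frac = model.dsb_mean - base

    def p1(n: int) -> float:
        return n * a * (1 - a) ** (n - 1) if n >= 1 else 0.0

    return (1 - frac) * p1(base) + frac * p1(base + 1)


def calibrated_p_co_intra(model: InversionCrossModel, target: float = 0.12) -> float:
    """p_co_intra giving a target single-intra-inversion-CO probability.

    The ~12% default target reproduces the classical compound-X estimate
    of single-CO frequency within *dl-49* heterozygotes.
    """
    lo, hi = 0.0, min(1.0, 1.0 - model.p_nco)
    for _ in range(200):
        mid = (lo + hi) / 2
        p = intra_inversion_single_co_probability(replace(model, p_co_intra=mid))
        if p < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
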