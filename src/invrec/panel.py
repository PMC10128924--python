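"""Diagnostic SNV marker panels.

A diagnostic panel is the set of positions at which two (isogenized,
effectively haploid) parental lines carry different single-nucleotide
alleles.  At such sites the parental origin of an offspring chromosome is
directly readable from its genotype, which is what makes crossover and
gene-conversion breakpoint mapping possible.

Positions are 1-based base pairs throughout (VCF convention); window
arithmetic is done in 0-based half-open genomic space (see
:mod:`invrec.io` for the converters used at the BED boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

VALID_BASES = (b"A", b"C", b"G", b"T")


def _as_allele_array(alleles) -> np.ndarray:
    arr = np.asarray(alleles, dtype="S1")
    bad = ~np.isin(arr, VALID_BASES)
    if bad.any():
        raise ValueError(
            f"alleles must be single nucleotides A/C/G/T; offending values "
            f"{np.unique(arr[bad])}"
        )
    return arr


def _check_increasing(positions: np.ndarray, what: str) -> None:
    if len(positions) > 1 and not (np.diff(positions) > 0).all():
        raise ValueError(f"{what}: positions must be strictly increasing")


@dataclass(frozen=True)
class ParentalCallSet:
    """Homozygous/hemizygous single-nucleotide calls for one parental line.

    Parameters
    ----------
    chrom:
        Chromosome identifier.
    positions:
        1-based positions, strictly increasing.
    alleles:
        Single-nucleotide allele per position (one call per site; the
        parental stocks are isogenized and males are hemizygous for chrX,
        so a single allele fully describes each site).
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.int64))
        object.__setattr__(self, "alleles", _as_allele_array(self.alleles))
        if len(self.positions) != len(self.alleles):
            raise ValueError("positions and alleles must have equal length")
        _check_increasing(self.positions, "ParentalCallSet")
        if (self.positions < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")

    @classmethod
    def from_pairs(cls, chrom: str, pairs) -> "ParentalCallSet":
        """Build from an iterable of ``(position, allele)`` pairs."""
        pairs = sorted(pairs)
        pos = [p for p, _ in pairs]
        alle = [a for _, a in pairs]
        return cls(chrom, np.array(pos, dtype=np.int64), np.array(alle, dtype="S1"))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered diagnostic SNV sites on one chromosome.

    ``allele_p1 != allele_p2`` at every site.  Masked sites are excluded
    from event calling but retained for density reporting.
    """

    chrom: str
    chrom_length: int
    positions: np.ndarray
    allele_p1: np.ndarray
    allele_p2: np.ndarray
    masked: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.int64))
        object.__setattr__(self, "allele_p1", _as_allele_array(self.allele_p1))
        object.__setattr__(self, "allele_p2", _as_allele_array(self.allele_p2))
        if self.masked is None:
            object.__setattr__(self, "masked", np.zeros(len(self.positions), dtype=bool))
        else:
            object.__setattr__(self, "masked", np.asarray(self.masked, dtype=bool))
        n = len(self.positions)
        if not (len(self.allele_p1) == len(self.allele_p2) == len(self.masked) == n):
            raise ValueError("panel arrays must have equal length")
        _check_increasing(self.positions, "MarkerPanel")
        if n and (self.positions > self.chrom_length).any():
            raise ValueError("panel positions exceed chromosome length")
        if (self.allele_p1 == self.allele_p2).any():
            raise ValueError("diagnostic sites require allele_p1 != allele_p2")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_unmasked(self) -> int:
        return int((~self.masked).sum())

    @property
    def unmasked_index(self) -> np.ndarray:
        return np.flatnonzero(~self.masked)

    @property
    def unmasked_positions(self) -> np.ndarray:
        return self.positions[~self.masked]

    def mean_spacing(self, start: int | None = None, end: int | None = None) -> float:
        """Mean inter-site spacing (bp) over ``[start, end]`` (all sites)."""
        pos = self.positions
        if start is not None or end is not None:
            lo = start if start is not None else 0
            hi = end if end is not None else self.chrom_length
            pos = pos[(pos >= lo) & (pos <= hi)]
        if len(pos) < 2:
            return float("nan")
        return float(np.mean(np.diff(pos)))

    def masked_spans(self) -> list[tuple[int, int]]:
        """Contiguous runs of masked sites as (first_pos, last_pos) intervals."""
        spans: list[tuple[int, int]] = []
        idx = np.flatnonzero(self.masked)
        if len(idx) == 0:
            return spans
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.r_[idx[0], idx[breaks + 1]]
        ends = np.r_[idx[breaks], idx[-1]]
        for s, e in zip(starts, ends):
            spans.append((int(self.positions[s]), int(self.positions[e])))
        return spans

    def swapped(self) -> "MarkerPanel":
        """The same panel with the P1/P2 roles exchanged."""
        return replace(self, allele_p1=self.allele_p2.copy(), allele_p2=self.allele_p1.copy())


@dataclass(frozen=True)
class DensityProfile:
    """SNV counts in sliding windows tiling ``[0, chrom_length)``.

    Windows are ``[start, start+window)`` in 0-based half-open coordinates,
    at step ``step`` (overlapping when step < window).
    """

    chrom: str
    chrom_length: int
    window: int
    step: int
    starts: np.ndarray
    counts: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


def build_diagnostic_panel(
    p1: ParentalCallSet, p2: ParentalCallSet, chrom_length: int
) -> MarkerPanel:
    """Intersect two parental call sets into a diagnostic panel.

    The panel contains exactly the positions where both parents have a
    call and the alleles differ.  Sites where either parent lacks a call
    are dropped: without both alleles the site cannot assign parental
    origin.
    """
    if p1.chrom != p2.chrom:
        raise ValueError(f"chromosome mismatch: {p1.chrom!r} vs {p2.chrom!r}")
    common, i1, i2 = np.intersect1d(p1.positions, p2.positions, return_indices=True)
    a1 = p1.alleles[i1]
    a2 = p2.alleles[i2]
    diff = a1 != a2
    n_shared_identical = int((~diff).sum())
    if n_shared_identical:
        log.debug("dropped %d shared sites with identical alleles", n_shared_identical)
    panel = MarkerPanel(
        chrom=p1.chrom,
        chrom_length=int(chrom_length),
        positions=common[diff],
        allele_p1=a1[diff],
        allele_p2=a2[diff],
    )
    if len(panel) == 0:
        log.warning("diagnostic panel for %s is empty (no discordant sites)", p1.chrom)
    return panel


def snv_density_windows(panel: MarkerPanel, window: int = 50_000, step: int = 25_000) -> DensityProfile:
    """Count panel sites (masked included) per sliding window.

    Default 50 kb windows with 25 kb overlap.  A site at 1-based position
    ``p`` belongs to window ``[a, a+window)`` iff ``a <= p-1 < a+window``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0 or step > window:
        raise ValueError("step must satisfy 0 < step <= window")
    starts = np.arange(0, panel.chrom_length, step, dtype=np.int64)
    pos0 = panel.positions - 1  # 0-based
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, np.minimum(starts + window, panel.chrom_length), side="left")
    counts = (hi - lo).astype(np.int64)
    return DensityProfile(
        chrom=panel.chrom,
        chrom_length=panel.chrom_length,
        window=int(window),
        step=int(step),
        starts=starts,
        counts=counts,
    )


def mask_low_density(
    panel: MarkerPanel, profile: DensityProfile, min_sites_per_window: int
) -> MarkerPanel:
    """Mask panel sites falling in any window below a density threshold.

    A site is masked if *any* window containing it holds fewer than
    ``min_sites_per_window`` sites (conservative: whole low-density spans
    are removed from event calling, the way sparse regions where short
    conversion tracts are undetectable must be excluded from frequency
    comparisons).  Masking is cumulative with any existing mask, hence
    monotone in the threshold.
    """
    if profile.chrom != panel.chrom or profile.chrom_length != panel.chrom_length:
        raise ValueError("density profile does not match panel")
    masked = panel.masked.copy()
    low = np.flatnonzero(profile.counts < min_sites_per_window)
    pos0 = panel.positions - 1
    for w in low:
        a = profile.starts[w]
        i = np.searchsorted(pos0, a, side="left")
        j = np.searchsorted(pos0, a + profile.window, side="left")
        masked[i:j] = True
    n_new = int(masked.sum() - panel.masked.sum())
    if n_new:
        log.info("masked %d low-density sites (threshold %d)", n_new, min_sites_per_window)
    return replace(panel, masked=masked)
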