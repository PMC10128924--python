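"""File formats: VCF in; TSV/BED-like tables in and out.

Coordinate conventions
----------------------
All in-memory positions are 1-based base pairs (VCF convention).  The
BED-like event table is 0-based half-open; because a CO/NCOGC
uncertainty interval is the half-open 1-based interval
``(left_flank, right_flank]``, its BED representation is numerically
``[left_flank, right_flank)`` — the same two integers.  The explicit
converters below are used at every boundary and are mutually inverse.

TSV dialect: tab-separated, one header line, ``.`` for missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .caller import MISSING_ALLELE, OffspringObservation, RecombinationEvent
from .panel import DensityProfile, MarkerPanel, ParentalCallSet

log = logging.getLogger(__name__)

MISSING = "."


def vcf_to_internal(pos: int) -> int:
    """1-based VCF position -> internal position (also 1-based; identity)."""
    return int(pos)


def internal_to_bed_start(pos: int) -> int:
    """1-based position -> 0-based BED start of that base."""
    return int(pos) - 1


def bed_start_to_internal(start: int) -> int:
    """0-based BED start -> 1-based position of that base."""
    return int(start) + 1


class FormatError(ValueError):
    """A malformed record, reported with its file and line number."""


def _rows(path) -> "list[tuple[int, list[str]]]":
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append((i, line.split("\t")))
    return out


# ---------------------------------------------------------------- VCF in


def read_vcf_calls(path, chrom: str | None = None) -> ParentalCallSet:
    """Read one parental line's homozygous/hemizygous SNV calls from VCF.

    Keeps biallelic SNVs only; indels/MNVs, heterozygous and missing
    genotypes are skipped with logged counts (the parental stocks are
    isogenized, so a confident call is a single allele).  Hom-ref calls
    record the REF base.  Without a sample column the ALT allele is
    taken as the call.
    """
    from cyvcf2 import VCF

    positions: list[int] = []
    alleles: list[bytes] = []
    skipped = {"non_snv": 0, "het_or_missing": 0, "multiallelic": 0, "other_chrom": 0, "dup": 0}
    vcf = VCF(str(path))
    the_chrom = chrom
    for v in vcf:
        if chrom is not None and v.CHROM != chrom:
            skipped["other_chrom"] += 1
            continue
        if the_chrom is None:
            the_chrom = v.CHROM
        elif v.CHROM != the_chrom:
            raise FormatError(f"{path}: multiple chromosomes ({the_chrom}, {v.CHROM}); pass chrom=")
        if not v.is_snp:
            skipped["non_snv"] += 1
            continue
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.gt_types):
            gt = v.gt_types[0]
            if gt == 0:  # hom-ref
                allele = v.REF
            elif gt == 3:  # hom-alt
                allele = v.ALT[0]
            else:  # het or unknown
                skipped["het_or_missing"] += 1
                continue
        else:
            allele = v.ALT[0]
        pos = vcf_to_internal(v.POS)
        if positions and pos <= positions[-1]:
            skipped["dup"] += 1
            continue
        positions.append(pos)
        alleles.append(allele.encode())
    dropped = {k: n for k, n in skipped.items() if n}
    if dropped:
        log.info("%s: skipped records %s", path, dropped)
    if not positions:
        log.warning("%s: no usable SNV calls", path)
    return ParentalCallSet(
        the_chrom or (chrom or ""),
        np.array(positions, dtype=np.int64),
        np.array(alleles, dtype="S1"),
    )


def read_calls_tsv(path) -> ParentalCallSet:
    """Read (chrom, pos, allele) calls from TSV."""
    rows = _rows(path)
    if not rows:
        log.warning("%s: empty call set", path)
        return ParentalCallSet("", np.array([], dtype=np.int64), np.array([], dtype="S1"))
    start = 1 if rows[0][1][0].lower() in ("chrom", "chr") else 0
    chrom, positions, alleles = None, [], []
    for ln, f in rows[start:]:
        try:
            c, p, a = f[0], int(f[1]), f[2]
        except (IndexError, ValueError) as e:
            raise FormatError(f"{path}:{ln}: bad call record: {e}") from None
        if chrom is None:
            chrom = c
        elif c != chrom:
            raise FormatError(f"{path}:{ln}: multiple chromosomes")
        positions.append(p)
        alleles.append(a.encode())
    return ParentalCallSet(chrom, np.array(positions), np.array(alleles, dtype="S1"))


# ------------------------------------------------------------- panel TSV


def write_panel_tsv(panel: MarkerPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom_length={panel.chrom_length}\n")
        fh.write("chrom\tpos\tallele_p1\tallele_p2\tmasked\n")
        for p, a1, a2, m in zip(panel.positions, panel.allele_p1, panel.allele_p2, panel.masked):
            fh.write(f"{panel.chrom}\t{p}\t{a1.decode()}\t{a2.decode()}\t{int(m)}\n")


def read_panel_tsv(path) -> MarkerPanel:
    chrom_length = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#chrom_length="):
                chrom_length = int(line.strip().split("=", 1)[1])
            if not line.startswith("#"):
                break
    if chrom_length is None:
        raise FormatError(f"{path}: missing '#chrom_length=' header")
    rows = _rows(path)
    chrom, pos, a1, a2, masked = None, [], [], [], []
    for ln, f in rows[1:]:  # skip column header
        try:
            c, p, x1, x2, m = f[0], int(f[1]), f[2], f[3], bool(int(f[4]))
        except (IndexError, ValueError) as e:
            raise FormatError(f"{path}:{ln}: bad panel record: {e}") from None
        chrom = chrom or c
        pos.append(p)
        a1.append(x1.encode())
        a2.append(x2.encode())
        masked.append(m)
    return MarkerPanel(
        chrom or "",
        chrom_length,
        np.array(pos, dtype=np.int64),
        np.array(a1, dtype="S1"),
        np.array(a2, dtype="S1"),
        np.array(masked, dtype=bool),
    )


def write_density_bedgraph(profile: DensityProfile, path) -> None:
    """Density profile as BEDGRAPH-style TSV (0-based half-open windows)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsnv_count\n")
        for a, c in zip(profile.starts, profile.counts):
            b = min(int(a) + profile.window, profile.chrom_length)
            fh.write(f"{profile.chrom}\t{a}\t{b}\t{c}\n")


# ------------------------------------------------------ genotype matrix


def write_genotype_matrix(panel: MarkerPanel, observations, path) -> None:
    """Sites as rows, offspring as columns; '.' for missing calls."""
    obs = list(observations)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(o.offspring_id for o in obs) + "\n")
        cols = [o.alleles for o in obs]
        for i, p in enumerate(panel.positions):
            vals = [(c[i] or MISSING_ALLELE).decode() for c in cols]
            fh.write(f"{panel.chrom}\t{p}\t" + "\t".join(vals) + "\n")


def read_genotype_matrix(path) -> tuple[str, np.ndarray, dict[str, np.ndarray]]:
    """Read a genotype matrix -> (chrom, positions, {offspring: alleles})."""
    rows = _rows(path)
    if not rows:
        log.warning("%s: empty genotype matrix", path)
        return ("", np.array([], dtype=np.int64), {})
    ln0, header = rows[0]
    if len(header) < 3 or header[0] != "chrom":
        raise FormatError(f"{path}:{ln0}: expected 'chrom\\tpos\\t<ids...>' header")
    ids = header[2:]
    chrom, positions = None, []
    cols: list[list[bytes]] = [[] for _ in ids]
    for ln, f in rows[1:]:
        if len(f) != 2 + len(ids):
            raise FormatError(f"{path}:{ln}: expected {2 + len(ids)} fields, got {len(f)}")
        try:
            p = int(f[1])
        except ValueError:
            raise FormatError(f"{path}:{ln}: bad position {f[1]!r}") from None
        chrom = chrom or f[0]
        positions.append(p)
        for j, v in enumerate(f[2:]):
            cols[j].append(v.encode() if v else MISSING_ALLELE)
    return (
        chrom or "",
        np.array(positions, dtype=np.int64),
        {oid: np.array(col, dtype="S1") for oid, col in zip(ids, cols)},
    )


def observations_from_matrix(
    panel: MarkerPanel,
    matrix: dict[str, np.ndarray],
    positions: np.ndarray,
    coverage: dict[str, float] | None = None,
    selection: dict[str, str] | None = None,
) -> list[OffspringObservation]:
    """Align a genotype matrix with a panel into observations."""
    if len(positions) != panel.n_sites or not np.array_equal(positions, panel.positions):
        raise ValueError("genotype matrix positions do not match the panel")
    out = []
    for oid, alleles in matrix.items():
        out.append(
            OffspringObservation(
                offspring_id=oid,
                alleles=alleles,
                y_coverage=(coverage or {}).get(oid),
                selection_class=(selection or {}).get(oid, "nonrecombinant"),
            )
        )
    return out


def write_coverage_tsv(rows, path) -> None:
    """rows: iterable of (offspring_id, y_coverage, selection_class)."""
    with open(path, "w") as fh:
        fh.write("offspring\tchry_normalized_coverage\tselection_class\n")
        for oid, cov, sel in rows:
            c = MISSING if cov is None else f"{cov:.4f}"
            fh.write(f"{oid}\t{c}\t{sel}\n")


def read_coverage_tsv(path) -> tuple[dict[str, float], dict[str, str]]:
    coverage: dict[str, float] = {}
    selection: dict[str, str] = {}
    for ln, f in _rows(path)[1:]:
        try:
            oid, cov, sel = f[0], f[1], f[2]
        except IndexError:
            raise FormatError(f"{path}:{ln}: expected 3 fields") from None
        if cov != MISSING:
            try:
                coverage[oid] = float(cov)
            except ValueError:
                raise FormatError(f"{path}:{ln}: bad coverage {cov!r}") from None
        selection[oid] = sel
    return coverage, selection


# ---------------------------------------------------------- events BED


_EVENT_COLS = (
    "chrom\tstart\tend\tclass\toffspring\tn_support\tinner_start\tinner_end"
    "\tconverted\tflags\texcluded"
)


def write_events_bed(events, path, chrom: str) -> None:
    """Events as BED-like TSV; start/end are the 0-based half-open
    rendering of the flanking-marker uncertainty interval."""
    with open(path, "w") as fh:
        fh.write(_EVENT_COLS + "\n")
        for e in events:
            conv = ",".join(str(p) for p in e.converted_sites) if e.converted_sites else MISSING
            flags = ",".join(e.flags) if e.flags else MISSING
            fh.write(
                f"{chrom}\t{e.left_flank}\t{e.right_flank}\t{e.event_class}\t"
                f"{e.offspring_id}\t{e.n_support}\t{e.inner_start}\t{e.inner_end}\t"
                f"{conv}\t{flags}\t{int(e.excluded)}\n"
            )


def read_events_bed(path) -> list[RecombinationEvent]:
    rows = _rows(path)
    if not rows:
        log.warning("%s: empty event table", path)
        return []
    events = []
    for ln, f in rows[1:]:
        try:
            conv = None if f[8] == MISSING else tuple(int(x) for x in f[8].split(","))
            flags = () if f[9] == MISSING else tuple(f[9].split(","))
            events.append(
                RecombinationEvent(
                    offspring_id=f[4],
                    event_class=f[3],
                    left_flank=int(f[1]),
                    right_flank=int(f[2]),
                    inner_start=int(f[6]),
                    inner_end=int(f[7]),
                    n_support=int(f[5]),
                    converted_sites=conv,
                    flags=flags,
                    excluded=bool(int(f[10])),
                )
            )
        except (IndexError, ValueError) as e:
            raise FormatError(f"{path}:{ln}: bad event record: {e}") from None
    return events
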