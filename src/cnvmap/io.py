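"""Readers and writers for every external format the pipeline touches.

Canonical internal tables are plain TSV with fixed headers; any line
starting with ``#`` is a provenance/comment line and is skipped on read,
so write-then-read round-trips are exact.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, is_autosome, normalize_chrom

log = logging.getLogger("cnvmap")

SOURCES = ("penncnv", "birdseye", "canary")
VALID_CN = frozenset({0, 1, 3, 4, 5, 6})


class ParseError(ValueError):
    """Malformed input record; the message names the offending line."""


@dataclass(frozen=True)
class CNVCall:
    """One caller observation of a non-diploid segment in one sample.

    Normal diploid state (cn = 2) is never stored as a call.
    """

    sample_id: str
    interval: GenomicInterval
    cn: int
    num_probes: int
    confidence: float | None = None
    source: str = "penncnv"

    def __post_init__(self):
        if self.cn not in VALID_CN:
            raise ValueError(f"invalid copy state cn={self.cn} (diploid cn=2 is not a call)")
        if self.num_probes < 1:
            raise ValueError(f"num_probes must be >= 1, got {self.num_probes}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class CNPGenotypeTable:
    """Integer copy-number genotypes at predefined polymorphic loci.

    ``genotypes`` is a (loci x samples) integer matrix with entries 0..6
    (2 = diploid).
    """

    loci: list[tuple[str, GenomicInterval]]
    genotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.genotypes.shape != (len(self.loci), len(self.sample_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.loci)} loci x {len(self.sample_ids)} samples"
            )
        if self.genotypes.size and (
            self.genotypes.min() < 0 or self.genotypes.max() > 6
        ):
            raise ValueError("CNP genotypes must be integers in 0..6")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def allelic_mask(self) -> np.ndarray:
        """Loci where at least one sample deviates from diploid."""
        if self.genotypes.size == 0:
            return np.zeros(len(self.loci), dtype=bool)
        return (self.genotypes != 2).any(axis=1)

    def biallelic_deletion_mask(self) -> np.ndarray:
        """Loci whose genotypes are confined to {0,1,2} with >=1 carrier."""
        if self.genotypes.size == 0:
            return np.zeros(len(self.loci), dtype=bool)
        pure = (self.genotypes <= 2).all(axis=1)
        return pure & self.allelic_mask()

    def subset(self, mask: np.ndarray) -> "CNPGenotypeTable":
        idx = np.flatnonzero(mask)
        return CNPGenotypeTable(
            [self.loci[i] for i in idx], self.genotypes[idx], list(self.sample_ids)
        )


@dataclass(frozen=True)
class GeneModel:
    """One transcript model in refFlat style (genomic coordinates)."""

    gene_id: str
    symbol: str
    strand: str
    tx: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    coding: bool = True

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if not self.tx.contains(ex):
                raise ValueError(f"exon {ex} outside tx {self.tx} of {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons of {self.gene_id} unsorted or overlapping")
            prev_end = ex.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class ReferenceSVSet:
    """A reference structural-variant panel with alt-allele frequencies."""

    name: str
    records: list[tuple[GenomicInterval, list[float]]] = field(default_factory=list)

    def __post_init__(self):
        for iv, afs in self.records:
            for f in afs:
                if not (0.0 <= f <= 1.0):
                    raise ValueError(f"allele frequency {f} outside [0,1] in {self.name}")


@dataclass
class SNPGenotypeMatrix:
    """Allele-dosage matrix (snps x samples); missing entries are NaN."""

    snps: list[tuple[str, str, int]]  # (snp_id, chrom, pos)
    genotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.snps), len(self.sample_ids)):
            raise ValueError("SNP matrix shape does not match snps x samples")
        g = self.genotypes[~np.isnan(self.genotypes)]
        if g.size and not np.isin(g, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")


# ---------------------------------------------------------------------------
# PennCNV rawcnv text
# ---------------------------------------------------------------------------

_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>[\d,]+)-(?P<end>[\d,]+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)\s+"
    r"startsnp=\S+\s+endsnp=\S+"
)


def parse_penncnv_rawcnv(text_lines) -> list[CNVCall]:
    """Parse PennCNV ``rawcnv`` report lines into calls.

    Lines look like::

        chr11:111478291-111677695 numsnp=150 length=199,404 state5,cn=3 S01 startsnp=rsA endsnp=rsB

    Coordinates are taken verbatim; a ``cn=2`` record is rejected (normal
    diploid is never a call). Malformed lines raise :class:`ParseError`
    naming the line number.
    """
    calls: list[CNVCall] = []
    for lineno, raw in enumerate(text_lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _RAWCNV_RE.match(line)
        if m is None:
            raise ParseError(f"malformed rawcnv line {lineno}: {line!r}")
        cn = int(m.group("cn"))
        if cn == 2:
            raise ParseError(f"rawcnv line {lineno}: cn=2 record is not a CNV call")
        try:
            interval = GenomicInterval(
                m.group("chrom"),
                int(m.group("start").replace(",", "")),
                int(m.group("end").replace(",", "")),
            )
        except ValueError as exc:
            raise ParseError(f"rawcnv line {lineno}: {exc}") from exc
        calls.append(
            CNVCall(
                sample_id=m.group("sample"),
                interval=interval,
                cn=cn,
                num_probes=int(m.group("numsnp").replace(",", "")),
                confidence=None,
                source="penncnv",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Call tables (TSV)
# ---------------------------------------------------------------------------

CALL_COLUMNS = ["sample", "chrom", "start", "end", "cn", "num_probes", "confidence"]


def read_call_tsv(path, source: str) -> list[CNVCall]:
    """Read a caller-agnostic call table.

    Non-autosome rows are dropped with a logged count (the analysis is
    restricted to the 22 autosomes); an ``end <= start`` row is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    calls: list[CNVCall] = []
    dropped = 0
    for row in df.itertuples(index=False):
        if not is_autosome(row.chrom):
            dropped += 1
            continue
        conf = None if pd.isna(row.confidence) else float(row.confidence)
        calls.append(
            CNVCall(
                sample_id=str(row.sample),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                cn=int(row.cn),
                num_probes=int(row.num_probes),
                confidence=conf,
                source=source,
            )
        )
    if dropped:
        log.warning("%s: dropped %d non-autosome rows", path, dropped)
    return calls


def write_call_tsv(calls, path, header_lines=()) -> None:
    rows = [
        {
            "sample": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "cn": c.cn,
            "num_probes": c.num_probes,
            "confidence": "" if c.confidence is None else repr(c.confidence),
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    _write_tsv(df, path, header_lines)


def _write_tsv(df: pd.DataFrame, path, header_lines=()) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference SV sets (VCF or BED+AF TSV)
# ---------------------------------------------------------------------------


def read_reference_sv(path, name: str | None = None) -> ReferenceSVSet:
    """Load a reference SV panel from VCF or from a BED+AF TSV.

    VCF records need a resolvable end coordinate (INFO/END or reference
    span); records without one are skipped with a warning. Multi-allelic
    records retain every alternate-allele frequency.

    The TSV flavour has columns ``chrom  start  end  af`` where ``af`` is a
    comma-separated list of alternate-allele frequencies.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    if path.suffix in (".vcf", ".gz") or _looks_like_vcf(path):
        return _read_reference_vcf(path, name)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        if not is_autosome(row.chrom):
            continue
        afs = [float(x) for x in str(row.af).split(",") if x != ""]
        records.append((GenomicInterval(row.chrom, int(row.start), int(row.end)), afs))
    return ReferenceSVSet(name, records)


def _looks_like_vcf(path: Path) -> bool:
    try:
        with open(path) as fh:
            return fh.readline().startswith("##fileformat=VCF")
    except (OSError, UnicodeDecodeError):
        return False


def _read_reference_vcf(path: Path, name: str) -> ReferenceSVSet:
    import pysam

    records = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if not is_autosome(rec.chrom):
                continue
            end = rec.info.get("END", rec.stop)
            if end is None or end <= rec.start:
                skipped += 1
                continue
            af = rec.info.get("AF")
            if af is None:
                afs = []
            elif isinstance(af, (tuple, list)):
                afs = [float(x) for x in af]
            else:
                afs = [float(af)]
            records.append((GenomicInterval(rec.chrom, rec.start, int(end)), afs))
    if skipped:
        log.warning("%s: skipped %d records without a resolvable end", path, skipped)
    return ReferenceSVSet(name, records)


def write_reference_sv_tsv(refset: ReferenceSVSet, path, header_lines=()) -> None:
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "af": ",".join(repr(f) for f in afs),
        }
        for iv, afs in refset.records
    ]
    _write_tsv(pd.DataFrame(rows, columns=["chrom", "start", "end", "af"]), path, header_lines)


# ---------------------------------------------------------------------------
# Global map table
# ---------------------------------------------------------------------------

MAP_COLUMNS = [
    "chrom", "start", "end", "id", "type", "states", "frequency_pct", "novel", "ref_matches",
]


def write_map_tsv(map_loci, path, header_lines=()) -> None:
    """Write the global map with BED-compatible leading columns.

    Round-trips losslessly through :func:`read_map_tsv`.
    """
    rows = []
    for m in map_loci:
        rows.append(
            {
                "chrom": m.interval.chrom,
                "start": m.interval.start,
                "end": m.interval.end,
                "id": m.id,
                "type": m.map_type,
                "states": ",".join(str(s) for s in sorted(m.states_present)),
                "frequency_pct": repr(m.frequency_pct),
                "novel": int(m.novel),
                "ref_matches": ";".join(
                    f"{k}:{repr(v)}" for k, v in sorted(m.ref_matches.items())
                ),
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=MAP_COLUMNS), path, header_lines)


def read_map_tsv(path) -> list:
    from .mapbuild import MapLocus

    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"chrom": str, "ref_matches": str, "states": str}
    )
    loci = []
    for row in df.itertuples(index=False):
        matches = {}
        if isinstance(row.ref_matches, str) and row.ref_matches:
            for part in row.ref_matches.split(";"):
                k, v = part.rsplit(":", 1)
                matches[k] = float(v)
        loci.append(
            MapLocus(
                id=str(row.id),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                map_type=str(row.type),
                states_present=frozenset(int(s) for s in str(row.states).split(",")),
                frequency_pct=float(row.frequency_pct),
                carrier_samples=frozenset(),
                ref_matches=matches,
                novel=bool(int(row.novel)),
            )
        )
    return loci


# ---------------------------------------------------------------------------
# CNP genotype table (rows = loci, columns = samples)
# ---------------------------------------------------------------------------


def read_cnp_tsv(path) -> CNPGenotypeTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    fixed = ["locus_id", "chrom", "start", "end"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in fixed]
    loci = [
        (str(r.locus_id), GenomicInterval(r.chrom, int(r.start), int(r.end)))
        for r in df.itertuples(index=False)
    ]
    genotypes = df[sample_ids].to_numpy(dtype=int)
    return CNPGenotypeTable(loci, genotypes, sample_ids)


def write_cnp_tsv(table: CNPGenotypeTable, path, header_lines=()) -> None:
    data = {
        "locus_id": [lid for lid, _ in table.loci],
        "chrom": [iv.chrom for _, iv in table.loci],
        "start": [iv.start for _, iv in table.loci],
        "end": [iv.end for _, iv in table.loci],
    }
    for j, sid in enumerate(table.sample_ids):
        data[sid] = table.genotypes[:, j] if table.genotypes.size else []
    _write_tsv(pd.DataFrame(data), path, header_lines)


# ---------------------------------------------------------------------------
# SNP genotype matrix
# ---------------------------------------------------------------------------


def read_snp_tsv(path) -> SNPGenotypeMatrix:
    """SNP dosage TSV: columns snp_id, chrom, pos then one column per sample.

    Missing genotypes are empty cells or ``NA``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    fixed = ["snp_id", "chrom", "pos"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in fixed]
    snps = [
        (str(r.snp_id), normalize_chrom(r.chrom), int(r.pos))
        for r in df.itertuples(index=False)
    ]
    genotypes = df[sample_ids].to_numpy(dtype=float)
    return SNPGenotypeMatrix(snps, genotypes, sample_ids)


def write_snp_tsv(matrix: SNPGenotypeMatrix, path, header_lines=()) -> None:
    data = {
        "snp_id": [s[0] for s in matrix.snps],
        "chrom": [s[1] for s in matrix.snps],
        "pos": [s[2] for s in matrix.snps],
    }
    for j, sid in enumerate(matrix.sample_ids):
        col = matrix.genotypes[:, j] if matrix.genotypes.size else np.array([])
        data[sid] = ["" if np.isnan(x) else int(x) for x in col]
    _write_tsv(pd.DataFrame(data), path, header_lines)


# ---------------------------------------------------------------------------
# BED and refFlat
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """BED3/BED6; only the first three columns are used; non-autosomes dropped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: BED line with <3 fields: {line!r}")
            if not is_autosome(parts[0]):
                continue
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_refflat(path) -> list[GeneModel]:
    """refFlat-like TSV: geneName, name, chrom, strand, txStart, txEnd,
    exonCount, exonStarts, exonEnds (exon lists comma-separated, possibly
    with a trailing comma as in UCSC dumps). Non-coding transcripts are
    recognised by an ``NR_``/``XR_`` accession prefix."""
    genes = []
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=[
            "geneName", "name", "chrom", "strand", "txStart", "txEnd",
            "exonCount", "exonStarts", "exonEnds",
        ],
        header=0,
        dtype={"chrom": str},
    )
    for row in df.itertuples(index=False):
        if not is_autosome(row.chrom):
            continue
        starts = [int(x) for x in str(row.exonStarts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exonEnds).rstrip(",").split(",")]
        if len(starts) != len(ends) or len(starts) != int(row.exonCount):
            raise ParseError(f"{path}: exon list mismatch for {row.name}")
        exons = tuple(
            GenomicInterval(row.chrom, s, e) for s, e in zip(starts, ends)
        )
        genes.append(
            GeneModel(
                gene_id=str(row.name),
                symbol=str(row.geneName),
                strand=str(row.strand),
                tx=GenomicInterval(row.chrom, int(row.txStart), int(row.txEnd)),
                exons=exons,
                coding=not str(row.name).startswith(("NR_", "XR_")),
            )
        )
    return genes


def write_refflat(genes, path, header_lines=()) -> None:
    rows = [
        {
            "geneName": g.symbol,
            "name": g.gene_id,
            "chrom": g.tx.chrom,
            "strand": g.strand,
            "txStart": g.tx.start,
            "txEnd": g.tx.end,
            "exonCount": g.n_exons,
            "exonStarts": ",".join(str(e.start) for e in g.exons) + ",",
            "exonEnds": ",".join(str(e.end) for e in g.exons) + ",",
        }
        for g in genes
    ]
    _write_tsv(pd.DataFrame(rows), path, header_lines)


# ---------------------------------------------------------------------------
# CNVR tables
# ---------------------------------------------------------------------------

CNVR_COLUMNS = [
    "chrom", "start", "end", "id", "type", "carriers", "frequency_pct", "states", "samples",
]


@dataclass
class CNVRLite:
    """A CNVR row read back from disk (member calls are not persisted)."""

    locus_id: str
    interval: GenomicInterval
    cnvr_type: str
    carrier_count: int
    frequency_pct: float | None
    states_present: frozenset
    carrier_samples: frozenset


def write_cnvr_tsv(regions, path, header_lines=()) -> None:
    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "id": r.locus_id,
                "type": r.cnvr_type,
                "carriers": r.carrier_count,
                "frequency_pct": "" if r.frequency_pct is None else repr(r.frequency_pct),
                "states": ",".join(str(s) for s in sorted(r.states_present)),
                "samples": ",".join(sorted(r.carrier_samples)),
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=CNVR_COLUMNS), path, header_lines)


def read_cnvr_tsv(path) -> list[CNVRLite]:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"chrom": str, "states": str, "samples": str},
    )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CNVRLite(
                locus_id=str(row.id),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                cnvr_type=str(row.type),
                carrier_count=int(row.carriers),
                frequency_pct=None if pd.isna(row.frequency_pct) else float(row.frequency_pct),
                states_present=frozenset(
                    int(s) for s in str(row.states).split(",") if s not in ("", "nan")
                ),
                carrier_samples=frozenset(
                    s for s in str(row.samples).split(",") if s not in ("", "nan")
                ),
            )
        )
    return out
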