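"""Gene-level annotation of map loci.

Covers gene overlap with disruption-span labels ("txStart-Intron4",
"Exon6-Exon7", ...), the functional deletion/duplication filter, disease
and inheritance tallies, and generic gene-set fold-enrichment.

Exon and intron numbers are 1-based in TRANSCRIPT orientation: on the
minus strand "txStart" denotes the transcription start at the higher
genomic coordinate and exon 1 is the genomically last exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, reciprocal_overlap_fraction, shared_bases
from .io import GeneModel

log = logging.getLogger("cnvmap")

INHERITANCE_MODES = ("AD", "AR", "Mito", "Unk")


@dataclass
class GeneOverlap:
    locus_id: str
    gene_id: str
    symbol: str
    span_label: str
    whole_gene: bool
    exons_hit: frozenset  # 1-based, transcript orientation


@dataclass(frozen=True)
class DiseaseRecord:
    gene_id: str
    phenotype: str
    inheritance: str  # AD | AR | Mito | Unk
    icd_class: str | None = None

    def __post_init__(self):
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"inheritance must be one of {INHERITANCE_MODES}")


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # query genes in the set
    m: int  # query size
    K: int  # set size
    N: int  # background size
    fold: float
    p: float
    p_adj: float | None = None


# ---------------------------------------------------------------------------
# Span labelling
# ---------------------------------------------------------------------------


def _genomic_position_label(pos: int, gene: GeneModel) -> tuple[str, int]:
    """("exon"|"intron", genomic 1-based index) for a position inside tx."""
    for i, ex in enumerate(gene.exons):
        if ex.start <= pos < ex.end:
            return "exon", i + 1
        if pos < ex.start:
            return "intron", i  # between genomic exons i and i+1
    return "intron", gene.n_exons  # past last exon (inside tx tail)


def _to_transcript_label(kind: str, genomic_idx: int, gene: GeneModel) -> str:
    n = gene.n_exons
    if gene.strand == "+":
        idx = genomic_idx
    else:
        idx = (n - genomic_idx + 1) if kind == "exon" else (n - genomic_idx)
    return f"{kind.capitalize()}{idx}"


def span_label(locus: GenomicInterval, gene: GeneModel) -> str:
    """Disruption-span label, 5'->3' in transcript orientation.

    A locus covering the whole transcript is "txStart-txEnd"; a boundary
    beyond the transcript on the transcript-start side is labelled
    "txStart" (resp. "txEnd"), otherwise "ExonK" / "IntronK" at the exon
    or intron in which the boundary falls.
    """
    if locus.contains(gene.tx):
        return "txStart-txEnd"
    # genomic-left and genomic-right endpoint labels
    if locus.start <= gene.tx.start:
        left = "GTXSTART"
    else:
        left = _to_transcript_label(*_genomic_position_label(locus.start, gene), gene)
    if locus.end >= gene.tx.end:
        right = "GTXEND"
    else:
        right = _to_transcript_label(
            *_genomic_position_label(locus.end - 1, gene), gene
        )
    if gene.strand == "+":
        five, three = left, right
        five = "txStart" if five == "GTXSTART" else five
        three = "txEnd" if three == "GTXEND" else three
    else:
        five, three = right, left
        five = "txStart" if five == "GTXEND" else five
        three = "txEnd" if three == "GTXSTART" else three
    return f"{five}-{three}"


def exons_hit(locus: GenomicInterval, gene: GeneModel) -> frozenset:
    """1-based transcript-orientation indices of exons sharing >=1 bp."""
    hit = set()
    n = gene.n_exons
    for i, ex in enumerate(gene.exons):
        if shared_bases(locus, ex) > 0:
            hit.add(i + 1 if gene.strand == "+" else n - i)
    return frozenset(hit)


def overlap_genes(locus_id: str, locus: GenomicInterval, genes, mode: str = "any"):
    """Genes overlapped by a locus.

    ``mode="any"`` returns every gene sharing >=1 bp (used for disruption
    labelling); ``mode="reciprocal50"`` applies the 50% reciprocal-overlap
    criterion (used for map-level genic tallies).
    """
    if mode not in ("any", "reciprocal50"):
        raise ValueError(f"mode must be 'any' or 'reciprocal50', got {mode!r}")
    out = []
    for g in genes:
        if shared_bases(locus, g.tx) == 0:
            continue
        if mode == "reciprocal50":
            fa, fb = reciprocal_overlap_fraction(locus, g.tx)
            if not (fa >= 0.5 and fb >= 0.5):
                continue
        out.append(
            GeneOverlap(
                locus_id=locus_id,
                gene_id=g.gene_id,
                symbol=g.symbol,
                span_label=span_label(locus, g),
                whole_gene=locus.contains(g.tx),
                exons_hit=exons_hit(locus, g),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Functional filter
# ---------------------------------------------------------------------------


def _passes_deletion_rule(ov: GeneOverlap) -> bool:
    return len(ov.exons_hit) > 0


def _passes_duplication_rule(ov: GeneOverlap, locus, gene: GeneModel) -> bool:
    if ov.whole_gene:
        return True
    internal = gene.tx.contains(locus)
    return internal and len(ov.exons_hit) > 0


def functional_filter(overlaps, locus_types: dict, loci: dict, genes_by_id: dict):
    """Keep functionally relevant events; discard all intronic ones.

    Deletions are kept when they hit at least one exon. Duplications are
    kept when they cover an entire gene or are internal to the gene body
    and hit an exon (potential frame disruption). Mixed loci pass if
    either rule passes. ``locus_types`` maps locus_id -> DEL/DUP/MIX,
    ``loci`` maps locus_id -> interval, ``genes_by_id`` maps gene_id ->
    :class:`GeneModel`.
    """
    kept = []
    for ov in overlaps:
        ltype = locus_types[ov.locus_id]
        locus = loci[ov.locus_id]
        gene = genes_by_id[ov.gene_id]
        if len(ov.exons_hit) == 0 and not ov.whole_gene:
            continue  # wholly intronic
        if ltype == "DEL":
            ok = _passes_deletion_rule(ov)
        elif ltype == "DUP":
            ok = _passes_duplication_rule(ov, locus, gene)
        else:  # MIX carries both event kinds
            ok = _passes_deletion_rule(ov) or _passes_duplication_rule(ov, locus, gene)
        if ok:
            kept.append(ov)
    return kept


# ---------------------------------------------------------------------------
# Disease tallies
# ---------------------------------------------------------------------------


def read_disease_tsv(path) -> list[DiseaseRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DiseaseRecord(
            gene_id=str(r.gene),
            phenotype=str(r.phenotype),
            inheritance=str(r.inheritance),
            icd_class=None
            if "icd_class" not in df.columns or pd.isna(r.icd_class)
            else str(r.icd_class),
        )
        for r in df.itertuples(index=False)
    ]


def read_icd_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(r.phenotype): str(r.icd_class) for r in df.itertuples(index=False)}


def tally_diseases(overlaps, disease_table, icd_map: dict | None = None):
    """Percentage breakdowns of phenotypes hit, by ICD class and by
    inheritance mode.

    Counting is per (gene, phenotype) record: a gene with two phenotypes of
    different inheritance contributes to both. Phenotypes missing from
    ``icd_map`` are counted under "unclassified" with a warning. Returns a
    dict with ``by_inheritance``, ``by_icd`` (class -> percent, two
    decimals, deterministic ordering) and the raw ``n_records``.
    """
    icd_map = icd_map or {}
    genes_hit = {ov.gene_id for ov in overlaps} | {ov.symbol for ov in overlaps}
    records = [d for d in disease_table if d.gene_id in genes_hit]
    inh_counts: dict[str, int] = {}
    icd_counts: dict[str, int] = {}
    for d in records:
        inh_counts[d.inheritance] = inh_counts.get(d.inheritance, 0) + 1
        icd = d.icd_class or icd_map.get(d.phenotype)
        if icd is None:
            log.warning("phenotype %r has no ICD class; counted as unclassified", d.phenotype)
            icd = "unclassified"
        icd_counts[icd] = icd_counts.get(icd, 0) + 1
    n = len(records)

    def pct(counts):
        return {
            k: round(100.0 * v / n, 2) if n else 0.0
            for k, v in sorted(counts.items())
        }

    return {"n_records": n, "by_inheritance": pct(inh_counts), "by_icd": pct(icd_counts)}


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------


def enrichment_test(query_genes, gene_set, background, set_name: str = "") -> EnrichmentResult:
    """Hypergeometric fold-enrichment of a gene set in a query list.

    fold = (k/m)/(K/N); p is the hypergeometric upper tail P(X >= k).
    Both query and set must be subsets of the background.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes)
    gset = set(gene_set)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    if not gset <= background:
        raise ValueError("gene set must be a subset of the background")
    N, m, K = len(background), len(query), len(gset)
    k = len(query & gset)
    fold = (k / m) / (K / N) if (m and K) else 0.0
    p = float(stats.hypergeom.sf(k - 1, N, K, m)) if k > 0 else 1.0
    return EnrichmentResult(set_name=set_name, k=k, m=m, K=K, N=N, fold=fold, p=min(1.0, p))


def enrichment_tests(query_genes, gene_sets: dict, background, adjust: bool = True):
    """Run :func:`enrichment_test` per set with optional Benjamini-Hochberg."""
    results = [
        enrichment_test(query_genes, gset, background, set_name=name)
        for name, gset in sorted(gene_sets.items())
    ]
    if adjust and results:
        adj = stats.false_discovery_control([r.p for r in results], method="bh")
        for r, pa in zip(results, adj):
            r.p_adj = float(pa)
    return results


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
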