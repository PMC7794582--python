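"""CNV-SNP linkage disequilibrium and taggability.

Deletion loci whose cohort genotypes fit a single deletion allele
(CN in {0,1,2}) are tested against flanking SNPs inside distance windows.
r2 is computed from EM-estimated two-locus haplotype frequencies on
unphased genotypes (the standard 3x3-table EM), falling back to the
squared genotype correlation if the EM degenerates.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np
from scipy import stats

from .intervals import GenomicInterval
from .io import CNPGenotypeTable, SNPGenotypeMatrix

EM_TOL = 1e-8
EM_MAX_ITER = 1000
DEFAULT_WINDOWS = (200_000, 500_000, 1_000_000, 2_000_000, 3_000_000)
TAG_R2 = 0.8  # inclusive "strong LD" threshold


@dataclass
class BiallelicDeletion:
    """A deletion locus modellable as a single allele; dosage = 2 - CN."""

    locus_id: str
    interval: GenomicInterval
    dosage: np.ndarray  # per-sample deletion-allele count, NaN for missing
    carrier_count: int


@dataclass
class LDResult:
    locus_id: str
    snp_id: str
    r2: float
    distance: int  # bp to nearest breakpoint; 0 inside the locus
    window: int
    tag: bool  # r2 >= 0.8


def select_biallelic_deletions(
    cnp_table: CNPGenotypeTable, min_carriers: int = 4
) -> list[BiallelicDeletion]:
    """Polymorphic bi-allelic deletions with at least ``min_carriers``
    carrier individuals (CN < 2); any CN > 2 genotype excludes a locus."""
    out = []
    for i, (lid, iv) in enumerate(cnp_table.loci):
        g = cnp_table.genotypes[i]
        if (g > 2).any():
            continue
        carriers = int((g < 2).sum())
        if carriers < min_carriers:
            continue
        out.append(
            BiallelicDeletion(
                locus_id=lid,
                interval=iv,
                dosage=(2 - g).astype(float),
                carrier_count=carriers,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Two-locus EM r2
# ---------------------------------------------------------------------------


def _genotype_table(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    t = np.zeros((3, 3))
    for x, y in zip(a, b):
        t[int(x), int(y)] += 1
    return t


def em_haplotype_freqs(table: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """EM estimate of haplotype frequencies (h11, h10, h01, h00) from a 3x3
    unphased genotype count table (rows: dosage at locus A, cols: at B).

    Only the double heterozygote is phase-ambiguous; sample allele
    frequencies are preserved by every EM step. Returns ``None`` when the
    iteration fails to converge.
    """
    n = table.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    a_dos = (table.sum(axis=1) * np.arange(3)).sum()
    b_dos = (table.sum(axis=0) * np.arange(3)).sum()
    pA = a_dos / (2 * n)
    pB = b_dos / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus")
    # fixed haplotype contributions from unambiguous genotypes
    c11 = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    c10 = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    c01 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    c00 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    ndh = table[1, 1]  # double heterozygotes
    h11, h10, h01, h00 = pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)
    for _ in range(max_iter):
        cis = h11 * h00
        trans = h10 * h01
        w = 0.5 if (cis + trans) == 0 else cis / (cis + trans)
        new = np.array(
            [
                (c11 + w * ndh) / (2 * n),
                (c10 + (1 - w) * ndh) / (2 * n),
                (c01 + (1 - w) * ndh) / (2 * n),
                (c00 + w * ndh) / (2 * n),
            ]
        )
        delta = np.max(np.abs(new - np.array([h11, h10, h01, h00])))
        h11, h10, h01, h00 = new
        if delta < tol:
            return h11, h10, h01, h00
    return None


def _r2_from_haps(h11, h10, h01, h00) -> float:
    pA = h11 + h10
    pB = h11 + h01
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return 0.0
    d = h11 - pA * pB
    return min(1.0, d * d / denom)


def em_r2(dosage_a, dosage_b) -> float:
    """Haplotype-based r2 between two dosage vectors in {0,1,2}.

    Missing entries are dropped pairwise; both loci must be polymorphic on
    the complete pairs. Symmetric in its arguments and invariant under
    allele relabeling (dosage -> 2 - dosage at either locus).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no complete genotype pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic locus")
    table = _genotype_table(a, b)
    haps = em_haplotype_freqs(table)
    if haps is None:  # EM degenerate: squared genotype correlation fallback
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)
    return float(_r2_from_haps(*haps))


# ---------------------------------------------------------------------------
# Windows, tag-SNPs, summaries
# ---------------------------------------------------------------------------


def snp_distance(deletion_interval: GenomicInterval, pos: int) -> int:
    """Distance from a SNP to the nearest locus breakpoint; 0 inside."""
    if deletion_interval.start <= pos < deletion_interval.end:
        return 0
    if pos < deletion_interval.start:
        return deletion_interval.start - pos
    return pos - deletion_interval.end


def snps_in_window(deletion: BiallelicDeletion, snps, window: int):
    """Candidate SNPs within ``window`` bp of the nearer breakpoint
    (inclusive; SNPs inside the deletion have distance 0).

    ``snps`` is an iterable of (snp_id, chrom, pos); returns
    ``[(snp_id, distance), ...]``.
    """
    out = []
    for snp_id, chrom, pos in snps:
        if chrom != deletion.interval.chrom:
            continue
        d = snp_distance(deletion.interval, pos)
        if d <= window:
            out.append((snp_id, d))
    return out


def ld_scan(
    deletions, snp_matrix: SNPGenotypeMatrix, window: int, kept_snp_ids=None
) -> list[LDResult]:
    """r2 of every (deletion, candidate SNP) pair inside one window."""
    snp_index = {s[0]: i for i, s in enumerate(snp_matrix.snps)}
    results: list[LDResult] = []
    for deletion in deletions:
        for snp_id, dist in snps_in_window(deletion, snp_matrix.snps, window):
            if kept_snp_ids is not None and snp_id not in kept_snp_ids:
                continue
            row = snp_matrix.genotypes[snp_index[snp_id]]
            try:
                r2 = em_r2(deletion.dosage, row)
            except ValueError:
                continue  # monomorphic / no complete pairs
            results.append(
                LDResult(
                    locus_id=deletion.locus_id,
                    snp_id=snp_id,
                    r2=r2,
                    distance=dist,
                    window=window,
                    tag=r2 >= TAG_R2,
                )
            )
    return results


def find_tag_snp(deletion: BiallelicDeletion, snp_matrix: SNPGenotypeMatrix, window: int):
    """The SNP with maximal r2 to the deletion within the window.

    Ties break by smaller distance, then lower genomic position. Returns
    ``(snp_id, r2)`` or ``None`` when no polymorphic candidate exists.
    """
    snp_index = {s[0]: i for i, s in enumerate(snp_matrix.snps)}
    pos_by_id = {s[0]: s[2] for s in snp_matrix.snps}
    best = None  # (-r2, distance, pos, snp_id)
    for snp_id, dist in snps_in_window(deletion, snp_matrix.snps, window):
        row = snp_matrix.genotypes[snp_index[snp_id]]
        try:
            r2 = em_r2(deletion.dosage, row)
        except ValueError:
            continue
        key = (-r2, dist, pos_by_id[snp_id], snp_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[3], -best[0]


def taggability_summary(results, thresholds=(0.5, 0.8)):
    """Taggability of the deletion set.

    Per threshold: the proportion of deletions whose best candidate SNP
    reaches that r2. Also reports per-deletion counts of SNPs in strong LD
    (r2 >= 0.8): the maximum and the median. Empty input yields a zeroed
    summary.
    """
    best: dict[str, float] = {}
    strong_counts: dict[str, int] = {}
    for r in results:
        best[r.locus_id] = max(best.get(r.locus_id, 0.0), r.r2)
        strong_counts.setdefault(r.locus_id, 0)
        if r.r2 >= TAG_R2:
            strong_counts[r.locus_id] += 1
    n = len(best)
    props = {
        t: (sum(1 for v in best.values() if v >= t) / n if n else 0.0)
        for t in thresholds
    }
    counts = list(strong_counts.values())
    return {
        "n_deletions": n,
        "proportion_tagged": props,
        "strong_snp_count_max": max(counts) if counts else 0,
        "strong_snp_count_median": float(median(counts)) if counts else 0.0,
    }


def spearman_trend(x, y):
    """Classical Spearman rho with tie-corrected two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def trend_tests(results, deletion_props: dict):
    """The four monotone-trend checks of the LD analysis.

    ``deletion_props`` maps locus_id to a dict with keys ``length`` and
    ``snp_density``. Returns a dict of (rho, p) for: r2 vs distance over
    pairs, best r2 vs deletion length, strong-LD SNP count vs deletion
    length, and best r2 vs local SNP density.
    """
    pairs_r2 = [r.r2 for r in results]
    pairs_d = [r.distance for r in results]
    best: dict[str, float] = {}
    strong: dict[str, int] = {}
    for r in results:
        best[r.locus_id] = max(best.get(r.locus_id, 0.0), r.r2)
        strong.setdefault(r.locus_id, 0)
        if r.r2 >= TAG_R2:
            strong[r.locus_id] += 1
    ids = sorted(best)
    lengths = [deletion_props[i]["length"] for i in ids]
    density = [deletion_props[i]["snp_density"] for i in ids]
    return {
        "r2_vs_distance": spearman_trend(pairs_r2, pairs_d),
        "r2_vs_length": spearman_trend([best[i] for i in ids], lengths),
        "tag_count_vs_length": spearman_trend([strong[i] for i in ids], lengths),
        "r2_vs_snp_density": spearman_trend([best[i] for i in ids], density),
    }


def gwas_cross(results, gwas_snp_table, r2_min: float = 0.5):
    """Deletion x GWAS-SNP pairs exceeding ``r2_min`` (strict).

    ``gwas_snp_table`` maps snp_id -> trait (or is an iterable of
    (snp_id, trait)). Returns ``[(locus_id, snp_id, r2, trait), ...]``.
    """
    if not isinstance(gwas_snp_table, dict):
        gwas_snp_table = {sid: trait for sid, trait in gwas_snp_table}
    return [
        (r.locus_id, r.snp_id, r.r2, gwas_snp_table[r.snp_id])
        for r in results
        if r.snp_id in gwas_snp_table and r.r2 > r2_min
    ]
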