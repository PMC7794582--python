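"""CNV region (CNVR) construction and dataset summaries.

Per-sample adjacent calls are first re-merged (the HMM caller splits large
events), then calls from all samples are clustered by transitive >=1 bp
overlap into non-overlapping population loci. Each locus carries a type
(loss / gain / mixed), a carrier count and a carrier frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import mean, median

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, union_span
from .io import CNVCall


@dataclass
class CNVRegion:
    """A population CNV locus: union of transitively overlapping calls."""

    locus_id: str
    interval: GenomicInterval
    members: list[CNVCall]
    cnvr_type: str  # loss | gain | mixed
    carrier_count: int
    frequency_pct: float | None = None
    states_present: frozenset = field(default_factory=frozenset)

    @property
    def carrier_samples(self) -> frozenset:
        return frozenset(c.sample_id for c in self.members)

    @property
    def is_singleton(self) -> bool:
        return self.carrier_count == 1


def classify_cnvr(members) -> str:
    """loss if every state < 2, gain if every state > 2, else mixed."""
    states = [c.cn if isinstance(c, CNVCall) else int(c) for c in members]
    if not states:
        raise ValueError("cannot classify a locus with no members")
    if max(states) < 2:
        return "loss"
    if min(states) > 2:
        return "gain"
    return "mixed"


def locus_length(interval: GenomicInterval) -> tuple[int, float]:
    """Length in bp and in kb (3 decimals) under the half-open convention."""
    return interval.length, interval.length_kb


def compute_frequency(carrier_count: int, n_samples: int) -> float:
    """Carrier frequency in percent, reported to 2 decimals.

    A locus with no carriers cannot exist, so ``carrier_count = 0`` is an
    error. A singleton in a 102-sample cohort yields 0.98.
    """
    if not (1 <= carrier_count <= n_samples):
        raise ValueError(
            f"carrier_count must be in [1, n_samples], got {carrier_count}/{n_samples}"
        )
    return round(100.0 * carrier_count / n_samples, 2)


def merge_adjacent(calls_one_sample, gap_frac: float = 0.2) -> list[CNVCall]:
    """Re-join same-state calls the caller split into fragments.

    Input: calls of one sample on one chromosome, sorted by start.
    Consecutive calls with identical copy state merge when the inter-call
    gap is at most ``gap_frac`` times the length of the would-be merged
    span. Probe counts are summed and the minimum confidence kept.
    """
    calls = list(calls_one_sample)
    if not calls:
        return []
    samples = {c.sample_id for c in calls}
    chroms = {c.interval.chrom for c in calls}
    if len(samples) > 1 or len(chroms) > 1:
        raise ValueError("merge_adjacent expects calls of one sample on one chromosome")
    for a, b in zip(calls, calls[1:]):
        if b.interval.start < a.interval.start:
            raise ValueError("calls must be sorted by start")
    out = [calls[0]]
    for nxt in calls[1:]:
        cur = out[-1]
        gap = nxt.interval.start - cur.interval.end
        span = max(cur.interval.end, nxt.interval.end) - cur.interval.start
        if nxt.cn == cur.cn and gap <= gap_frac * span:
            confs = [c.confidence for c in (cur, nxt) if c.confidence is not None]
            out[-1] = replace(
                cur,
                interval=GenomicInterval(
                    cur.interval.chrom,
                    cur.interval.start,
                    max(cur.interval.end, nxt.interval.end),
                ),
                num_probes=cur.num_probes + nxt.num_probes,
                confidence=min(confs) if confs else None,
            )
        else:
            out.append(nxt)
    return out


def merge_adjacent_all(calls, gap_frac: float = 0.2) -> list[CNVCall]:
    """Apply :func:`merge_adjacent` per (sample, chromosome) group."""
    groups: dict[tuple, list[CNVCall]] = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.interval.chrom), []).append(c)
    out: list[CNVCall] = []
    for key in sorted(groups):
        grp = sorted(groups[key], key=lambda c: (c.interval.start, c.interval.end))
        out.extend(merge_adjacent(grp, gap_frac))
    return out


def build_cnvrs(calls, n_samples: int | None = None) -> list[CNVRegion]:
    """Cluster calls into non-overlapping population loci.

    The partition is the transitive closure of >=1 bp overlap; each locus
    spans the union (min start, max end) of its members. Ids are
    ``CNVR_<chrom>_<rank>`` with rank assigned by (chrom, start, end).
    When ``n_samples`` is given, carrier frequencies are attached.
    """
    by_chrom: dict[int, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom_order, []).append(c)
    regions: list[CNVRegion] = []
    for chrom_order in sorted(by_chrom):
        chrom_calls = sorted(
            by_chrom[chrom_order], key=lambda c: (c.interval.start, c.interval.end)
        )
        clusters: list[list[CNVCall]] = []
        cluster_end = None
        for c in chrom_calls:
            if cluster_end is None or c.interval.start >= cluster_end:
                clusters.append([c])
                cluster_end = c.interval.end
            else:
                clusters[-1].append(c)
                cluster_end = max(cluster_end, c.interval.end)
        for rank, members in enumerate(clusters, start=1):
            interval = union_span([m.interval for m in members])
            carriers = {m.sample_id for m in members}
            freq = (
                compute_frequency(len(carriers), n_samples)
                if n_samples is not None
                else None
            )
            regions.append(
                CNVRegion(
                    locus_id=f"CNVR_{interval.chrom}_{rank}",
                    interval=interval,
                    members=members,
                    cnvr_type=classify_cnvr(members),
                    carrier_count=len(carriers),
                    frequency_pct=freq,
                    states_present=frozenset(m.cn for m in members),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# Summaries and distribution comparisons
# ---------------------------------------------------------------------------


@dataclass
class DatasetSummary:
    n_calls: int
    n_loci: int
    length_stats_by_class: dict  # class -> {"mean": .., "median": .., "n": ..}
    calls_per_individual: dict  # sample_id -> count
    mean_calls_per_individual: float
    del_dup_ratio: float | None
    carrier_rate_pct: float
    genome_coverage_bp: int


def summarize(calls, regions, n_samples: int | None = None) -> DatasetSummary:
    """Cohort-level summary of a call set and its loci.

    ``carrier_rate_pct`` is the percentage of samples with at least one
    call; ``genome_coverage_bp`` is the total locus length (loci are
    non-overlapping by construction).
    """
    calls = list(calls)
    regions = list(regions)
    per_sample: dict[str, int] = {}
    for c in calls:
        per_sample[c.sample_id] = per_sample.get(c.sample_id, 0) + 1
    if n_samples is None:
        n_samples = len(per_sample)
    stats_by_class: dict[str, dict] = {}
    for cls in ("loss", "gain", "mixed", "all"):
        lens = [
            r.interval.length
            for r in regions
            if cls == "all" or r.cnvr_type == cls
        ]
        stats_by_class[cls] = {
            "mean": float(mean(lens)) if lens else 0.0,
            "median": float(median(lens)) if lens else 0.0,
            "n": len(lens),
        }
    n_del = sum(1 for c in calls if c.cn < 2)
    n_dup = sum(1 for c in calls if c.cn > 2)
    return DatasetSummary(
        n_calls=len(calls),
        n_loci=len(regions),
        length_stats_by_class=stats_by_class,
        calls_per_individual=per_sample,
        mean_calls_per_individual=(len(calls) / n_samples) if n_samples else 0.0,
        del_dup_ratio=(n_del / n_dup) if n_dup else None,
        carrier_rate_pct=round(100.0 * len(per_sample) / n_samples, 2)
        if n_samples
        else 0.0,
        genome_coverage_bp=sum(r.interval.length for r in regions),
    )


def compare_distributions(sample_a, sample_b, test: str):
    """Two-sided two-sample comparison.

    ``test`` is one of ``rank-sum`` (Wilcoxon rank-sum / Mann-Whitney,
    exact for small untied samples), ``ks`` (two-sample
    Kolmogorov-Smirnov) or ``chi2`` (chi-square test of homogeneity of a
    2 x k count table passed as two count vectors). Returns
    ``(statistic, p_value)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if test == "rank-sum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if test == "ks":
        res = stats.ks_2samp(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "chi2":
        table = np.vstack([a, b])
        if np.allclose(table.sum(axis=0) * 0, 0) and (table.sum() == 0):
            raise ValueError("empty contingency table")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    raise ValueError(f"unknown test {test!r}; expected rank-sum, ks or chi2")
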