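"""Global CNV map: merge validated CNVRs with allelic genotyped CNP loci,
match against reference SV panels, drop frequency-based false positives,
flag novel loci and correlate frequencies with a reference panel."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .intervals import (
    GenomicInterval,
    reciprocal_overlap_fraction,
    shared_bases,
    union_span,
)
from .io import CNPGenotypeTable, ReferenceSVSet
from .regions import CNVRegion, compute_frequency


@dataclass
class MapLocus:
    """One entry of the global CNV map."""

    id: str
    interval: GenomicInterval
    map_type: str  # DEL | DUP | MIX
    states_present: frozenset
    frequency_pct: float
    carrier_samples: frozenset = field(default_factory=frozenset)
    ref_matches: dict = field(default_factory=dict)
    novel: bool = False


def _map_type(states) -> str:
    if all(s < 2 for s in states):
        return "DEL"
    if all(s > 2 for s in states):
        return "DUP"
    return "MIX"


@dataclass
class _Contribution:
    """One mergeable unit: a vCNVR or an allelic CNP locus."""

    id: str
    interval: GenomicInterval
    states: frozenset
    carriers: frozenset


def _cnp_contributions(cnps: CNPGenotypeTable) -> list[_Contribution]:
    out = []
    allelic = cnps.allelic_mask()
    for i, (lid, iv) in enumerate(cnps.loci):
        if not allelic[i]:
            continue
        g = cnps.genotypes[i]
        carriers = frozenset(
            s for s, cn in zip(cnps.sample_ids, g) if cn != 2
        )
        states = frozenset(int(cn) for cn in g if cn != 2)
        out.append(_Contribution(lid, iv, states, carriers))
    return out


def union_merge(vcnvrs, allelic_cnps: CNPGenotypeTable | None, n_samples: int) -> list[MapLocus]:
    """Merge validated CNVRs and allelic CNP loci into map loci.

    Units overlapping by >=1 base (transitively) collapse into one locus
    spanning their union; the id concatenates contributing ids in
    positional order (e.g. ``CNVR_1_31_CNP118``); the frequency is
    recomputed as the fraction of samples carrying any non-diploid state at
    the locus; the type is derived from the combined states.
    """
    units: list[_Contribution] = []
    for r in vcnvrs:
        base = r.base if hasattr(r, "base") else r  # accept ValidatedCNVR or CNVRegion
        units.append(
            _Contribution(
                base.locus_id, base.interval, frozenset(base.states_present),
                frozenset(base.carrier_samples),
            )
        )
    if allelic_cnps is not None:
        units.extend(_cnp_contributions(allelic_cnps))

    by_chrom: dict[int, list[_Contribution]] = {}
    for u in units:
        by_chrom.setdefault(u.interval.chrom_order, []).append(u)
    loci: list[MapLocus] = []
    for chrom_order in sorted(by_chrom):
        group = sorted(by_chrom[chrom_order], key=lambda u: (u.interval.start, u.interval.end))
        clusters: list[list[_Contribution]] = []
        cluster_end = None
        for u in group:
            if cluster_end is None or u.interval.start >= cluster_end:
                clusters.append([u])
                cluster_end = u.interval.end
            else:
                clusters[-1].append(u)
                cluster_end = max(cluster_end, u.interval.end)
        for members in clusters:
            interval = union_span([m.interval for m in members])
            carriers = frozenset().union(*(m.carriers for m in members))
            states = frozenset().union(*(m.states for m in members))
            loci.append(
                MapLocus(
                    id="_".join(m.id for m in members),
                    interval=interval,
                    map_type=_map_type(states),
                    states_present=states,
                    frequency_pct=compute_frequency(len(carriers), n_samples)
                    if carriers
                    else 0.0,
                    carrier_samples=carriers,
                )
            )
    return loci


def match_reference(locus: MapLocus, refset: ReferenceSVSet, f: float = 0.5):
    """Summed alt-allele frequency of the best-matching reference record.

    Candidate records must pass reciprocal overlap >= ``f`` (inclusive) in
    both directions; the best record maximises the product of the two
    overlap fractions. Returns ``None`` when nothing matches.
    """
    best = None
    best_score = -1.0
    for iv, afs in refset.records:
        if shared_bases(locus.interval, iv) == 0:
            continue
        fa, fb = reciprocal_overlap_fraction(locus.interval, iv)
        if fa >= f and fb >= f:
            score = fa * fb
            if score > best_score:
                best_score = score
                best = afs
    if best is None:
        return None
    return float(sum(best))


def attach_reference_matches(loci, refsets, f: float = 0.5) -> list[MapLocus]:
    """Populate ``ref_matches`` for every locus against every panel."""
    out = []
    for locus in loci:
        matches = {}
        for rs in refsets:
            m = match_reference(locus, rs, f)
            if m is not None:
                matches[rs.name] = m
        out.append(replace(locus, ref_matches=matches))
    return out


def drop_false_positives(loci, refsets, freq_threshold: float = 90.0) -> list[MapLocus]:
    """Remove likely false positives: frequency above the threshold AND
    absent (no reciprocal-overlap match) from every provided panel.

    Without reference panels absence cannot be assessed, so an empty
    ``refsets`` leaves the input unchanged.
    """
    refsets = list(refsets)
    if not refsets:
        return list(loci)
    kept = []
    for locus in loci:
        if locus.frequency_pct > freq_threshold:
            if not any(match_reference(locus, rs) is not None for rs in refsets):
                continue
        kept.append(locus)
    return kept


def find_novel(loci, refsets, f: float = 0.5) -> list[MapLocus]:
    """Flag and return novel loci.

    A locus is novel when, in every panel, no record shares at least a
    fraction ``f`` (inclusive) of the LOCUS's own length -- a one-sided
    criterion, unlike the reciprocal rule used for frequency matching.
    Sets ``novel`` on every input locus in place of the returned copies.
    """
    novel_loci = []
    for i, locus in enumerate(loci):
        known = False
        for rs in refsets:
            for iv, _ in rs.records:
                if shared_bases(locus.interval, iv) / locus.interval.length >= f:
                    known = True
                    break
            if known:
                break
        loci[i] = replace(locus, novel=not known)
        if not known:
            novel_loci.append(loci[i])
    return novel_loci


def frequency_correlation(paired_freqs):
    """Pearson correlation between map and reference frequencies.

    ``paired_freqs`` is an iterable of (map_frequency, reference_frequency)
    for matched loci. Returns ``(r, (ci_low, ci_high), p)`` with a
    Fisher-z 95% confidence interval and a two-sided p-value.
    """
    pairs = np.asarray(list(paired_freqs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (map, reference) frequency pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the frequency vectors")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)
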