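"""Sample-, call- and SNP-level quality control.

Thresholds default to the array-CNV conventions: samples are dropped when
any intensity-quality metric or the per-sample call count is out of range;
calls are dropped by probe support, confidence, length and overlap with
blacklist regions; SNPs by MAF, call rate and an exact Hardy-Weinberg test.
All threshold comparisons are strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, shared_bases
from .io import CNVCall, SNPGenotypeMatrix


@dataclass(frozen=True)
class SampleQCMetrics:
    sample_id: str
    lrr_sd: float = 0.0
    waviness: float = 0.0
    baf_drift: float = 0.0
    call_count: int = 0
    qc_contrast: float | None = None

    def __post_init__(self):
        for name in ("lrr_sd", "waviness", "baf_drift"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.call_count < 0:
            raise ValueError("call_count must be non-negative")


@dataclass
class FilterConfig:
    """QC thresholds; defaults are the standard two-caller array settings."""

    min_probes_by_source: dict = field(
        default_factory=lambda: {"penncnv": 10, "birdseye": 3}
    )
    min_len_bp: int = 1_000
    max_len_bp: int = 3_000_000
    birdseye_min_confidence: float = 5.0
    canary_min_confidence: float = 0.1
    exclusion_regions: list = field(default_factory=list)
    snp_maf_min: float = 0.01
    snp_callrate_min: float = 0.95
    snp_hwe_p_min: float = 1e-4
    max_sample_calls: int = 100
    max_waviness: float = 0.05
    max_lrr_sd: float = 0.4
    max_baf_drift: float = 0.0125
    max_qc_contrast: float = 0.4

    def __post_init__(self):
        if self.min_len_bp >= self.max_len_bp:
            raise ValueError("min_len_bp must be below max_len_bp")
        if self.min_len_bp <= 0:
            raise ValueError("length thresholds must be positive")


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------


def filter_samples(metrics_list, config: FilterConfig | None = None):
    """Partition samples into kept and excluded (with reasons).

    A sample is excluded when ANY of the following holds (strict
    comparisons): qc_contrast > 0.4, call_count > 100, waviness > 0.05,
    lrr_sd > 0.4, baf_drift > 0.0125.

    Returns ``(kept_ids, excluded)`` where ``excluded`` maps sample_id to
    the list of machine-readable reason codes that fired.
    """
    config = config or FilterConfig()
    seen = set()
    kept: list[str] = []
    excluded: dict[str, list[str]] = {}
    for m in metrics_list:
        if m.sample_id in seen:
            raise ValueError(f"duplicate sample_id {m.sample_id!r}")
        seen.add(m.sample_id)
        reasons = []
        if m.qc_contrast is not None and m.qc_contrast > config.max_qc_contrast:
            reasons.append("qc_contrast")
        if m.call_count > config.max_sample_calls:
            reasons.append("call_count")
        if m.waviness > config.max_waviness:
            reasons.append("waviness")
        if m.lrr_sd > config.max_lrr_sd:
            reasons.append("lrr_sd")
        if m.baf_drift > config.max_baf_drift:
            reasons.append("baf_drift")
        if reasons:
            excluded[m.sample_id] = reasons
        else:
            kept.append(m.sample_id)
    return kept, excluded


# ---------------------------------------------------------------------------
# Call-level filtering
# ---------------------------------------------------------------------------


def _call_drop_reason(call: CNVCall, config: FilterConfig, exclusion_by_chrom) -> str | None:
    min_probes = config.min_probes_by_source.get(call.source)
    if min_probes is not None and call.num_probes < min_probes:
        return "num_probes"
    if call.source == "birdseye" and call.confidence is not None:
        if call.confidence < config.birdseye_min_confidence:
            return "confidence"
    if call.source == "canary" and call.confidence is not None:
        if not (call.confidence > config.canary_min_confidence):
            return "confidence"
    if call.interval.length < config.min_len_bp:
        return "too_short"
    if call.interval.length > config.max_len_bp:
        return "too_long"
    for region in exclusion_by_chrom.get(call.interval.chrom, ()):
        if shared_bases(call.interval, region) > 0:
            return "exclusion_region"
    return None


def filter_calls(calls, config: FilterConfig | None = None):
    """Remove low-quality calls; returns the kept calls (idempotent)."""
    kept, _ = filter_calls_verbose(calls, config)
    return kept


def filter_calls_verbose(calls, config: FilterConfig | None = None):
    """Like :func:`filter_calls` but also returns ``[(call, reason)]`` for
    dropped calls; each drop carries exactly one reason code (first match
    in a fixed order: probes, confidence, length, exclusion region)."""
    config = config or FilterConfig()
    excl: dict[str, list[GenomicInterval]] = {}
    for region in config.exclusion_regions:
        excl.setdefault(region.chrom, []).append(region)
    kept, dropped = [], []
    for call in calls:
        reason = _call_drop_reason(call, config, excl)
        if reason is None:
            kept.append(call)
        else:
            dropped.append((call, reason))
    return kept, dropped


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_p(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity, same allele totals) that are no
    more probable than the observed one. Returns a p-value in (0, 1].
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = min(2 * n_AA + n_AB, 2 * n_BB + n_AB)
    if n_rare == 0:
        return 1.0

    # Unnormalised probabilities over feasible het counts via the standard
    # ratio recurrence, anchored at the mid-range het count for stability.
    het_max = n_rare if (n_rare % 2 == n_AB % 2) else n_rare - 1
    hets = list(range(n_AB % 2, het_max + 1, 2))
    mid_idx = len(hets) // 2
    probs = [0.0] * len(hets)
    probs[mid_idx] = 1.0
    # downward from mid: P(h-2)/P(h) = h(h-1) / ((nr-h+2)(nc-h+2))  with
    # nr, nc the rare/common homozygote-allele pools
    for i in range(mid_idx, 0, -1):
        h = hets[i]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
    for i in range(mid_idx, len(hets) - 1):
        h = hets[i]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[i + 1] = probs[i] * 4.0 * rare_hom * common_hom / ((h + 2) * (h + 1))
    total = sum(probs)
    p_obs = probs[hets.index(n_AB)] / total
    p = sum(x for x in probs if x / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# SNP QC
# ---------------------------------------------------------------------------


def snp_qc(matrix: SNPGenotypeMatrix, config: FilterConfig | None = None) -> list[str]:
    """Return SNP ids passing MAF > 1%, call rate > 95% and HWE p > 1e-4.

    All three comparisons are strict.
    """
    config = config or FilterConfig()
    g = matrix.genotypes
    if g.shape[1] != len(matrix.sample_ids):
        raise ValueError("matrix/sample mismatch")
    kept = []
    n_samples = g.shape[1]
    for i, (snp_id, _, _) in enumerate(matrix.snps):
        row = g[i]
        obs = row[~np.isnan(row)]
        if obs.size == 0:
            continue
        call_rate = obs.size / n_samples
        if not (call_rate > config.snp_callrate_min):
            continue
        af = obs.sum() / (2 * obs.size)
        maf = min(af, 1 - af)
        if not (maf > config.snp_maf_min):
            continue
        n_bb = int((obs == 0).sum())
        n_ab = int((obs == 1).sum())
        n_aa = int((obs == 2).sum())
        if not (hwe_exact_p(n_aa, n_ab, n_bb) > config.snp_hwe_p_min):
            continue
        kept.append(snp_id)
    return kept
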