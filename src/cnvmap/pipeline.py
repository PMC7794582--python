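"""End-to-end orchestration: calls -> QC -> CNVRs -> concordance -> map."""

from __future__ import annotations

from dataclasses import dataclass, field

from .concordance import ConcordanceStats, ValidatedCNVR, validate
from .io import CNPGenotypeTable
from .mapbuild import (
    MapLocus,
    attach_reference_matches,
    drop_false_positives,
    find_novel,
    union_merge,
)
from .qc import FilterConfig, filter_calls_verbose
from .regions import CNVRegion, build_cnvrs, merge_adjacent_all


@dataclass
class PipelineResult:
    cnvrs_a: list[CNVRegion]
    cnvrs_b: list[CNVRegion]
    validated: list[ValidatedCNVR]
    concordance: ConcordanceStats
    map_loci: list[MapLocus]
    novel: list[MapLocus]
    filter_log: dict = field(default_factory=dict)


def run_pipeline(
    calls_a,
    calls_b,
    cnp_table: CNPGenotypeTable | None,
    n_samples: int,
    config: FilterConfig | None = None,
    overlap_fraction: float = 0.5,
    gap_frac: float = 0.2,
    refsets=(),
    fp_freq_threshold: float = 90.0,
) -> PipelineResult:
    """The full map-construction chain on two callers' call sets.

    Per-sample adjacent calls are re-merged, then QC-filtered; each call
    set is collapsed into CNVRs; set-A loci are validated against set B by
    reciprocal overlap; validated loci are union-merged with allelic CNP
    loci; reference panels supply frequency matches, the high-frequency
    false-positive filter and novelty flags.
    """
    config = config or FilterConfig()
    filter_log = {}
    merged_a = merge_adjacent_all(calls_a, gap_frac)
    merged_b = merge_adjacent_all(calls_b, gap_frac)
    kept_a, dropped_a = filter_calls_verbose(merged_a, config)
    kept_b, dropped_b = filter_calls_verbose(merged_b, config)
    filter_log["calls_a"] = {"in": len(merged_a), "kept": len(kept_a), "dropped": _reasons(dropped_a)}
    filter_log["calls_b"] = {"in": len(merged_b), "kept": len(kept_b), "dropped": _reasons(dropped_b)}

    cnvrs_a = build_cnvrs(kept_a, n_samples=n_samples)
    cnvrs_b = build_cnvrs(kept_b, n_samples=n_samples)
    validated, stats = validate(cnvrs_a, cnvrs_b, f=overlap_fraction)

    map_loci = union_merge(validated, cnp_table, n_samples=n_samples)
    map_loci = attach_reference_matches(map_loci, refsets, f=overlap_fraction)
    map_loci = drop_false_positives(map_loci, refsets, freq_threshold=fp_freq_threshold)
    novel = find_novel(map_loci, refsets, f=overlap_fraction)
    return PipelineResult(
        cnvrs_a=cnvrs_a,
        cnvrs_b=cnvrs_b,
        validated=validated,
        concordance=stats,
        map_loci=map_loci,
        novel=novel,
        filter_log=filter_log,
    )


def _reasons(dropped) -> dict:
    out: dict[str, int] = {}
    for _, reason in dropped:
        out[reason] = out.get(reason, 0) + 1
    return out
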