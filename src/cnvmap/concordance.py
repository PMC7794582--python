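"""Cross-caller validation of CNVR sets by reciprocal overlap.

A locus from set A is validated when some locus of set B shares at least a
fraction ``f`` (default 0.5, inclusive) of BOTH lengths. Validated loci
keep their set-A boundaries. State concordance compares direction only
(loss vs gain); mixed loci are concordant with either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import reciprocal_overlap_fraction, shared_bases
from .regions import CNVRegion

# re-exported here because this module owns the criterion
__all__ = [
    "ValidatedCNVR",
    "ConcordanceStats",
    "reciprocal_overlap_fraction",
    "validate",
]


@dataclass
class ValidatedCNVR:
    base: CNVRegion
    partner_ids: list[str]
    state_concordant: bool


@dataclass
class ConcordanceStats:
    n_a: int
    n_validated: int
    pct_any_overlap: float
    pct_validated: float
    pct_state_concordant: float  # among validated loci


def _direction_concordant(type_a: str, type_b: str) -> bool:
    if "mixed" in (type_a, type_b):
        return True
    return type_a == type_b


def validate(set_a, set_b, f: float = 0.5):
    """Validate loci of ``set_a`` against ``set_b``.

    Returns ``(validated, stats)`` where ``validated`` holds one
    :class:`ValidatedCNVR` per validated set-A locus. The pair criterion is
    symmetric (a validates against b iff b against a) and the validated
    count is non-increasing in ``f``.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError(f"overlap fraction must be in (0, 1], got {f}")
    set_a = list(set_a)
    set_b = list(set_b)
    by_chrom: dict[int, list[CNVRegion]] = {}
    for r in set_b:
        by_chrom.setdefault(r.interval.chrom_order, []).append(r)
    validated: list[ValidatedCNVR] = []
    n_any = 0
    for a in set_a:
        partners = []
        any_overlap = False
        concordant = True
        for b in by_chrom.get(a.interval.chrom_order, ()):
            if shared_bases(a.interval, b.interval) > 0:
                any_overlap = True
                fa, fb = reciprocal_overlap_fraction(a.interval, b.interval)
                if fa >= f and fb >= f:
                    partners.append(b)
        n_any += any_overlap
        if partners:
            concordant = all(
                _direction_concordant(a.cnvr_type, b.cnvr_type) for b in partners
            )
            validated.append(
                ValidatedCNVR(
                    base=a,
                    partner_ids=[b.locus_id for b in partners],
                    state_concordant=concordant,
                )
            )
    n_a = len(set_a)
    n_v = len(validated)
    stats = ConcordanceStats(
        n_a=n_a,
        n_validated=n_v,
        pct_any_overlap=round(100.0 * n_any / n_a, 2) if n_a else 0.0,
        pct_validated=round(100.0 * n_v / n_a, 2) if n_a else 0.0,
        pct_state_concordant=round(
            100.0 * sum(v.state_concordant for v in validated) / n_v, 2
        )
        if n_v
        else 0.0,
    )
    return validated, stats
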