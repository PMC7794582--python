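"""Genomic intervals on autosomes.

Coordinates are half-open ``[start, end)`` throughout: the length of an
interval is ``end - start`` with no off-by-one adjustment, so printed
breakpoints of the form ``chr:start-end`` reproduce printed kb lengths
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

AUTOSOMES = tuple(str(i) for i in range(1, 23))
_AUTOSOME_SET = frozenset(AUTOSOMES)


class ChromosomeError(ValueError):
    """Raised for chromosome labels outside the accepted autosome set."""


def normalize_chrom(label: str | int) -> str:
    """Normalize a chromosome label to "1".."22".

    Accepts "chr1", "Chr1", "CHR1", "1" or the integer 1; idempotent and
    case-insensitive. Raises :class:`ChromosomeError` for anything that is
    not an autosome (sex chromosomes, mitochondria, contigs).
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s not in _AUTOSOME_SET:
        raise ChromosomeError(f"not an autosome: {label!r}")
    return s


def is_autosome(label: str | int) -> bool:
    try:
        normalize_chrom(label)
    except ChromosomeError:
        return False
    return True


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open autosomal interval.

    Ordering is (numeric chromosome, start, end), the tie-break used for
    deterministic locus ids.
    """

    chrom_order: int  # numeric chromosome, first for sorting
    start: int
    end: int

    def __init__(self, chrom: str | int, start: int, end: int):
        c = normalize_chrom(chrom)
        start = int(start)
        end = int(end)
        if start < 0:
            raise ValueError(f"negative start: {start}")
        if end <= start:
            raise ValueError(f"end must exceed start: [{start}, {end})")
        object.__setattr__(self, "chrom_order", int(c))
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    @property
    def chrom(self) -> str:
        return str(self.chrom_order)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        """Length in kb, rounded to 3 decimals (bp precision)."""
        return round(self.length / 1000.0, 3)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base."""
        return self.chrom_order == other.chrom_order and shared_bases(self, other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom_order == other.chrom_order
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # "11:111478291-111677695"
        return f"{self.chrom}:{self.start}-{self.end}"


def shared_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 on different chromosomes)."""
    if a.chrom_order != b.chrom_order:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def union_span(intervals) -> GenomicInterval:
    """Smallest interval covering all inputs; inputs must share a chromosome."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("union of no intervals")
    chroms = {iv.chrom_order for iv in intervals}
    if len(chroms) != 1:
        raise ValueError("union across chromosomes")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


def reciprocal_overlap_fraction(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float]:
    """Fractions of each interval covered by the shared span.

    Returns ``(shared/len(a), shared/len(b))``; ``(0.0, 0.0)`` when the
    intervals lie on different chromosomes (not an error).
    """
    sh = shared_bases(a, b)
    return sh / a.length, sh / b.length
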