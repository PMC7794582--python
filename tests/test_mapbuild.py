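import itertools

import numpy as np
import pytest

from cnvmap.intervals import GenomicInterval
from cnvmap.io import CNPGenotypeTable, CNVCall, ReferenceSVSet
from cnvmap.mapbuild import (
    MapLocus,
    attach_reference_matches,
    drop_false_positives,
    find_novel,
    frequency_correlation,
    match_reference,
    union_merge,
)
from cnvmap.regions import build_cnvrs


def one_locus(chrom, start, end, freq=50.0, states=(1,), lid="L1"):
    return MapLocus(
        id=lid,
        interval=GenomicInterval(chrom, start, end),
        map_type="DEL" if all(s < 2 for s in states) else "MIX",
        states_present=frozenset(states),
        frequency_pct=freq,
    )


def cnp_table(entries, sample_ids):
    """entries: list of (locus_id, chrom, start, end, genotype row)."""
    return CNPGenotypeTable(
        loci=[(e[0], GenomicInterval(e[1], e[2], e[3])) for e in entries],
        genotypes=np.array([e[4] for e in entries]),
        sample_ids=sample_ids,
    )


class TestUnionMerge:
    def vcnvr(self, chrom, start, end, samples, cn=1, lid=None):
        calls = [CNVCall(s, GenomicInterval(chrom, start, end), cn, 10) for s in samples]
        (r,) = build_cnvrs(calls)
        if lid:
            r.locus_id = lid
        return r

    def test_disjoint_units_stay_separate(self):
        v = self.vcnvr(1, 100_000, 200_000, ["s1"], lid="CNVR_1_1")
        cnps = cnp_table([("CNP1", 1, 300_000, 400_000, [2, 1, 2])], ["s1", "s2", "s3"])
        loci = union_merge([v], cnps, n_samples=3)
        assert [m.id for m in loci] == ["CNVR_1_1", "CNP1"]

    def test_overlapping_units_merge_with_concatenated_id(self):
        v = self.vcnvr(1, 100, 300, ["s1"], lid="CNVR_1_31")
        cnps = cnp_table([("CNP118", 1, 250, 400, [2, 1, 1])], ["s1", "s2", "s3"])
        (m,) = union_merge([v], cnps, n_samples=3)
        assert m.id == "CNVR_1_31_CNP118"
        assert (m.interval.start, m.interval.end) == (100, 400)
        # carriers: s1 from the vCNVR, s2+s3 from the CNP genotypes
        assert m.frequency_pct == 100.0

    def test_state_union_sets_mixed_type(self):
        v = self.vcnvr(1, 100, 300, ["s1"], cn=1)
        cnps = cnp_table([("CNP1", 1, 250, 400, [3, 2, 2])], ["s1", "s2", "s3"])
        (m,) = union_merge([v], cnps, n_samples=3)
        assert m.map_type == "MIX" and m.states_present == {1, 3}

    def test_non_allelic_cnp_loci_ignored(self):
        cnps = cnp_table([("CNP1", 1, 100, 400, [2, 2, 2])], ["s1", "s2", "s3"])
        assert union_merge([], cnps, n_samples=3) == []

    def test_output_non_overlapping_and_covers_union(self):
        rng = np.random.default_rng(3)
        vs = []
        for i in range(30):
            s = int(rng.integers(0, 100_000))
            vs.append(self.vcnvr(1, s, s + int(rng.integers(1_000, 30_000)), [f"s{i}"]))
        loci = union_merge(vs, None, n_samples=30)
        for a, b in itertools.combinations(loci, 2):
            assert not a.interval.overlaps(b.interval)
        base_union = set()
        for v in vs:
            base_union.update(range(v.interval.start, v.interval.end))
        got_union = set()
        for m in loci:
            got_union.update(range(m.interval.start, m.interval.end))
        assert got_union == base_union


class TestMatchReference:
    def test_exact_match_sums_alt_frequencies(self):
        locus = one_locus(1, 1000, 5000)
        rs = ReferenceSVSet("kgp", [(GenomicInterval(1, 1000, 5000), [0.1, 0.05])])
        assert match_reference(locus, rs) == pytest.approx(0.15)

    def test_sub_threshold_overlap_is_no_match(self):
        locus = one_locus(1, 0, 1000)
        # shares 400/1000 of locus, 400/1333 of record
        rs = ReferenceSVSet("kgp", [(GenomicInterval(1, 600, 1933), [0.2])])
        assert match_reference(locus, rs) is None

    def test_empty_refset(self):
        assert match_reference(one_locus(1, 0, 1000), ReferenceSVSet("kgp", [])) is None

    def test_best_record_by_overlap_product(self):
        locus = one_locus(1, 0, 1000)
        rs = ReferenceSVSet(
            "kgp",
            [
                (GenomicInterval(1, 0, 1600), [0.9]),  # fractions (1.0, 0.625)
                (GenomicInterval(1, 0, 1000), [0.3]),  # fractions (1.0, 1.0) - best
            ],
        )
        assert match_reference(locus, rs) == pytest.approx(0.3)


class TestDropFalsePositives:
    def test_high_freq_unmatched_removed(self):
        loci = [one_locus(1, 0, 1000, freq=95.0)]
        assert drop_false_positives(loci, [ReferenceSVSet("kgp", [])]) == []

    def test_high_freq_matched_kept(self):
        loci = [one_locus(1, 0, 1000, freq=95.0)]
        rs = ReferenceSVSet("kgp", [(GenomicInterval(1, 0, 1000), [0.5])])
        assert len(drop_false_positives(loci, [rs, ReferenceSVSet("gnomad", [])])) == 1

    def test_never_removes_at_or_below_threshold(self):
        rng = np.random.default_rng(5)
        loci = [
            one_locus(1, i * 10_000, i * 10_000 + 1000, freq=float(rng.uniform(0.9, 90)))
            for i in range(100)
        ]
        kept = drop_false_positives(loci, [ReferenceSVSet("kgp", [])])
        assert kept == loci


class TestFindNovel:
    def test_sixty_percent_share_is_known(self):
        loci = [one_locus(1, 0, 1000)]
        rs = ReferenceSVSet("dgv", [(GenomicInterval(1, 400, 10_000), [0.1])])
        assert find_novel(loci, [rs]) == []
        assert loci[0].novel is False

    def test_exactly_half_share_is_known(self):
        loci = [one_locus(1, 0, 1000)]
        rs = ReferenceSVSet("dgv", [(GenomicInterval(1, 500, 10_000), [])])
        assert find_novel(loci, [rs]) == []

    def test_no_overlap_anywhere_is_novel(self):
        loci = [one_locus(1, 0, 1000)]
        rs = ReferenceSVSet("dgv", [(GenomicInterval(2, 0, 1000), [0.1])])
        novel = find_novel(loci, [rs])
        assert len(novel) == 1 and novel[0].novel

    def test_one_sided_criterion_ignores_record_length(self):
        # a huge reference record covering the locus makes it known even
        # though the reciprocal criterion would fail
        loci = [one_locus(1, 0, 1000)]
        rs = ReferenceSVSet("dgv", [(GenomicInterval(1, 0, 1_000_000), [])])
        assert find_novel(loci, [rs]) == []

    def test_monotone_in_refsets(self):
        rng = np.random.default_rng(9)
        loci = [
            one_locus(1, i * 5_000, i * 5_000 + int(rng.integers(1_000, 4_000)))
            for i in range(50)
        ]
        refsets = []
        counts = [len(find_novel(loci, refsets))]
        assert counts[0] == len(loci)  # no panels -> everything novel
        for k in range(3):
            recs = [
                (GenomicInterval(1, int(s), int(s) + 3_000), [0.1])
                for s in rng.integers(0, 250_000, 30)
            ]
            refsets.append(ReferenceSVSet(f"panel{k}", recs))
            counts.append(len(find_novel(loci, refsets)))
        assert counts == sorted(counts, reverse=True)


class TestFrequencyCorrelation:
    def test_perfect_linear(self):
        pairs = [(x, 2 * x) for x in range(1, 11)]
        r, (lo, hi), p = frequency_correlation(pairs)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        pairs = [(x, -x) for x in range(1, 11)]
        r, _, _ = frequency_correlation(pairs)
        assert r == pytest.approx(-1.0)

    def test_textbook_formula(self):
        pairs = [(1.0, 2.0), (2.0, 1.0), (3.0, 4.0), (4.0, 3.0), (5.0, 7.0)]
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, (lo, hi), p = frequency_correlation(pairs)
        assert r == pytest.approx(expected)
        assert lo < r < hi

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            frequency_correlation([(1, 1), (1, 2), (1, 3)])

    def test_simulated_truth_frequencies_correlate(self, small_truth):
        # truth loci copied into a refset with their true carrier
        # frequencies: cohort frequencies correlate near-perfectly
        refset = ReferenceSVSet(
            "truth",
            [(t.interval, [t.carrier_count / 102]) for t in small_truth.loci],
        )
        loci = [
            one_locus(
                t.interval.chrom, t.interval.start, t.interval.end,
                freq=t.frequency_pct(102), lid=t.locus_id,
            )
            for t in small_truth.loci
        ]
        loci = attach_reference_matches(loci, [refset])
        pairs = [
            (m.frequency_pct / 100, m.ref_matches["truth"]) for m in loci if m.ref_matches
        ]
        assert len(pairs) >= 50
        r, _, _ = frequency_correlation(pairs)
        assert r >= 0.95
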