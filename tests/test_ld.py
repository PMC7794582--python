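import numpy as np
import pytest

from conftest import grid_search_r2
from cnvmap.intervals import GenomicInterval
from cnvmap.io import CNPGenotypeTable, SNPGenotypeMatrix
from cnvmap.ld import (
    BiallelicDeletion,
    em_r2,
    find_tag_snp,
    gwas_cross,
    ld_scan,
    select_biallelic_deletions,
    snp_distance,
    snps_in_window,
    spearman_trend,
    taggability_summary,
    trend_tests,
)


def deletion(lid="D1", chrom=1, start=100_000, end=110_000, dosage=None):
    dosage = np.asarray(dosage, dtype=float)
    return BiallelicDeletion(
        lid, GenomicInterval(chrom, start, end), dosage, int((dosage > 0).sum())
    )


class TestSelectBiallelicDeletions:
    def table(self, rows, ids=None):
        n = len(rows[0])
        return CNPGenotypeTable(
            loci=[
                (ids[i] if ids else f"CNP{i}", GenomicInterval(1, 10_000 * (i + 1), 10_000 * (i + 1) + 2_000))
                for i in range(len(rows))
            ],
            genotypes=np.array(rows),
            sample_ids=[f"S{j}" for j in range(n)],
        )

    def test_duplication_state_excludes_locus(self):
        t = self.table([[3, 1, 1, 1, 1, 2]])
        assert select_biallelic_deletions(t) == []

    def test_minimum_carrier_count(self):
        t = self.table([[1, 1, 1, 2, 2, 2], [1, 1, 1, 1, 2, 2]])
        got = select_biallelic_deletions(t)
        assert [d.locus_id for d in got] == ["CNP1"]

    def test_dosage_and_frequency(self):
        row = [1] * 4 + [2] * 98
        t = self.table([row])
        (d,) = select_biallelic_deletions(t)
        assert d.carrier_count == 4
        assert round(100 * d.carrier_count / 102, 2) == 3.92
        assert (d.dosage == (2 - np.array(row))).all()


class TestEmR2:
    def test_identical_vectors(self):
        d = np.array([0] * 20 + [1] * 40 + [2] * 40, dtype=float)
        assert em_r2(d, d) == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_error(self):
        with pytest.raises(ValueError):
            em_r2([1, 1, 1, 1], [0, 1, 2, 1])

    def test_perfect_repulsion_table(self):
        # counts ((20,0,0),(0,40,0),(0,0,40)) along the diagonal
        a = np.repeat([0, 1, 2], [20, 40, 40]).astype(float)
        b = a.copy()
        assert em_r2(a, b) == pytest.approx(grid_search_r2(a, b), abs=1e-3)

    def test_independent_large_sample(self):
        rng = np.random.default_rng(42)
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.4, 10_000).astype(float)
        assert em_r2(a, b) < 0.01

    def test_missing_pairwise_dropped(self):
        a = np.array([0, 1, 2, 1, np.nan, 0, 2, 1, 1, 0])
        b = np.array([0, 1, 2, 1, 2, np.nan, 2, 1, 1, 0])
        keep = ~(np.isnan(a) | np.isnan(b))
        assert em_r2(a, b) == pytest.approx(em_r2(a[keep], b[keep]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        while True:
            a = rng.integers(0, 3, n).astype(float)
            b = rng.integers(0, 3, n).astype(float)
            if a.std() > 0 and b.std() > 0:
                break
        assert em_r2(a, b) == pytest.approx(grid_search_r2(a, b), abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_allele_relabeling_invariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.integers(0, 3, 120).astype(float)
        b = rng.integers(0, 3, 120).astype(float)
        if a.std() == 0 or b.std() == 0:
            return
        base = em_r2(a, b)
        assert em_r2(b, a) == pytest.approx(base, abs=1e-9)
        assert em_r2(2 - a, b) == pytest.approx(base, abs=1e-6)
        assert em_r2(a, 2 - b) == pytest.approx(base, abs=1e-6)

    def test_parameter_recovery_from_known_haplotypes(self):
        # haplotypes simulated at known allele and haplotype frequencies:
        # the genotype-EM estimate approaches the analytic r2
        rng = np.random.default_rng(7)
        pA, pB, d_prime = 0.3, 0.4, 0.6
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
        D = d_prime * d_max
        hfreq = [pA * pB + D, pA * (1 - pB) - D, (1 - pA) * pB - D, (1 - pA) * (1 - pB) + D]
        n = 10_000
        haps = rng.choice(4, size=(n, 2), p=hfreq)
        a_allele = np.isin(haps, (0, 1)).astype(int)
        b_allele = np.isin(haps, (0, 2)).astype(int)
        a, b = a_allele.sum(axis=1).astype(float), b_allele.sum(axis=1).astype(float)
        analytic = D * D / (pA * (1 - pA) * pB * (1 - pB))
        assert em_r2(a, b) == pytest.approx(analytic, abs=0.05)


class TestWindows:
    def test_distance_zero_inside(self):
        d = deletion(dosage=[1, 1, 1, 1, 2, 2])
        assert snp_distance(d.interval, 105_000) == 0

    def test_window_boundary_inclusive(self):
        d = deletion(dosage=[1, 1, 1, 1, 2, 2])
        snps = [
            ("exact", "1", 100_000 - 200_000),
            ("beyond", "1", 100_000 - 200_001),
            ("inside", "1", 101_000),
            ("other_chrom", "2", 100_000),
        ]
        got = dict(snps_in_window(d, snps, 200_000))
        assert got == {"exact": 200_000, "inside": 0}


class TestFindTagSnp:
    def matrix(self, entries):
        return SNPGenotypeMatrix(
            snps=[(sid, chrom, pos) for sid, chrom, pos, _ in entries],
            genotypes=np.array([row for _, _, _, row in entries], dtype=float),
            sample_ids=[f"S{j}" for j in range(len(entries[0][3]))],
        )

    def test_single_perfect_candidate(self):
        dos = [1, 1, 1, 1, 0, 0, 0, 0]
        d = deletion(dosage=dos)
        m = self.matrix([("rs1", "1", 95_000, dos)])
        snp_id, r2 = find_tag_snp(d, m, 200_000)
        assert snp_id == "rs1" and r2 == pytest.approx(1.0, abs=1e-9)

    def test_tie_breaks_by_distance(self):
        dos = [1, 1, 1, 1, 0, 0, 0, 0]
        d = deletion(dosage=dos)  # interval [100000, 110000)
        m = self.matrix(
            [("far", "1", 160_000, dos), ("near", "1", 120_000, dos)]
        )
        snp_id, _ = find_tag_snp(d, m, 200_000)
        assert snp_id == "near"

    def test_no_polymorphic_candidate(self):
        d = deletion(dosage=[1, 1, 1, 1, 0, 0, 0, 0])
        m = self.matrix([("rs1", "1", 95_000, [0] * 8)])
        assert find_tag_snp(d, m, 200_000) is None

    def test_injected_tag_recovered(self, noisy_truth):
        from cnvmap.simulate import simulate_cnp_table, simulate_snp_panel

        cnp = simulate_cnp_table(noisy_truth)
        snps, injected = simulate_snp_panel(noisy_truth, cnp, target_r2=0.9)
        deletions = {d.locus_id: d for d in select_biallelic_deletions(cnp)}
        assert injected  # the default cohort produces taggable deletions
        for lid, (snp_id, achieved) in injected.items():
            got = find_tag_snp(deletions[lid], snps, 200_000)
            assert got is not None and got[0] == snp_id
            assert achieved == pytest.approx(0.9, abs=0.03)


class TestSummariesAndTrends:
    def results(self, spec):
        from cnvmap.ld import LDResult

        return [
            LDResult(lid, sid, r2, dist, 200_000, r2 >= 0.8)
            for lid, sid, r2, dist in spec
        ]

    def test_all_perfectly_tagged(self):
        res = self.results([("D1", "rs1", 1.0, 10), ("D2", "rs2", 1.0, 10)])
        s = taggability_summary(res)
        assert s["proportion_tagged"] == {0.5: 1.0, 0.8: 1.0}

    def test_none_tagged(self):
        res = self.results([("D1", "rs1", 0.1, 10)])
        s = taggability_summary(res)
        assert s["proportion_tagged"] == {0.5: 0.0, 0.8: 0.0}

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        res = self.results(
            [(f"D{i}", f"rs{i}", float(rng.uniform()), 10) for i in range(100)]
        )
        s = taggability_summary(res)
        assert s["proportion_tagged"][0.8] <= s["proportion_tagged"][0.5]

    def test_empty_results_zeroed(self):
        s = taggability_summary([])
        assert s["n_deletions"] == 0 and s["strong_snp_count_max"] == 0

    def test_spearman_exact_ranks(self):
        rho, _ = spearman_trend([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_trend([1, 2, 3], [9, 5, 1])
        assert rho == pytest.approx(-1.0)
        # fixed 6-pair table against the hand rank formula 1 - 6*sum(d^2)/(n(n^2-1))
        x = [3, 1, 4, 1.5, 5, 9]
        y = [2, 7, 1, 8, 2.5, 8.5]
        import scipy.stats as ss

        rx, ry = ss.rankdata(x), ss.rankdata(y)
        d2 = ((rx - ry) ** 2).sum()
        rho, _ = spearman_trend(x, y)
        assert rho == pytest.approx(1 - 6 * d2 / (6 * 35))

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            spearman_trend([1, 1, 1], [1, 2, 3])

    def test_trend_tests_structure(self):
        rng = np.random.default_rng(8)
        spec = []
        props = {}
        for i in range(20):
            lid = f"D{i}"
            props[lid] = {"length": float(rng.integers(1_000, 100_000)),
                          "snp_density": float(rng.uniform(0.1, 2.0))}
            for j in range(5):
                spec.append((lid, f"rs{i}_{j}", float(rng.uniform()), int(rng.integers(0, 100_000))))
        out = trend_tests(self.results(spec), props)
        assert set(out) == {"r2_vs_distance", "r2_vs_length", "tag_count_vs_length", "r2_vs_snp_density"}
        for rho, p in out.values():
            assert -1.0 <= rho <= 1.0 and 0.0 <= p <= 1.0


class TestGwasCross:
    def test_empty_table(self):
        res = TestSummariesAndTrends().results([("D1", "rs1", 1.0, 10)])
        assert gwas_cross(res, {}) == []

    def test_strict_threshold(self):
        res = TestSummariesAndTrends().results(
            [("D1", "rs1", 1.0, 10), ("D2", "rs2", 0.49, 10), ("D3", "rs3", 0.5, 10)]
        )
        table = {"rs1": "multiple sclerosis", "rs2": "obesity", "rs3": "HDL"}
        got = gwas_cross(res, table, r2_min=0.5)
        assert got == [("D1", "rs1", 1.0, "multiple sclerosis")]
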