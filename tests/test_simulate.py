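import numpy as np
import pytest

from cnvmap.ld import em_r2
from cnvmap.qc import FilterConfig, filter_calls
from cnvmap.simulate import (
    CallerNoise,
    SimulationConfig,
    simulate_caller,
    simulate_cnp_table,
    simulate_tagged_snp,
    simulate_truth,
    write_fixture_bundle,
)


class TestSimulateTruth:
    def test_empty_config(self):
        truth = simulate_truth(SimulationConfig(n_loci=0, seed=1))
        assert truth.loci == []

    def test_deterministic_for_seed(self):
        cfg = SimulationConfig(n_loci=40, seed=9)
        t1, t2 = simulate_truth(cfg), simulate_truth(cfg)
        assert [(x.interval, x.cn.tolist()) for x in t1.loci] == [
            (x.interval, x.cn.tolist()) for x in t2.loci
        ]

    def test_loci_non_overlapping_with_gap(self):
        cfg = SimulationConfig(n_loci=100, seed=3)
        truth = simulate_truth(cfg)
        by_chrom = {}
        for t in truth.loci:
            by_chrom.setdefault(t.interval.chrom, []).append(t.interval)
        for ivs in by_chrom.values():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end >= cfg.min_locus_gap

    def test_singletons_have_one_carrier(self):
        truth = simulate_truth(SimulationConfig(n_loci=100, seed=4))
        for t in truth.loci:
            assert t.carrier_count >= 1

    def test_type_proportions_converge(self):
        cfg = SimulationConfig(n_loci=1000, n_chroms=22, chrom_length=2_000_000_000, seed=12)
        truth = simulate_truth(cfg)
        classes = [t.locus_class for t in truth.loci]
        for cls, expect in zip(("del", "dup", "mixed"), cfg.type_probs):
            got = classes.count(cls) / len(classes)
            assert abs(got - expect) <= 0.03

    def test_infeasible_config_error(self):
        cfg = SimulationConfig(n_loci=50, n_chroms=1, chrom_length=4_000_000, seed=1)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_truth(cfg)


class TestSimulateCaller:
    def test_zero_noise_reproduces_truth_events(self, small_truth):
        calls = simulate_caller(small_truth, CallerNoise.zero(), "penncnv")
        truth_events = {
            (t.interval.chrom, t.interval.start, t.interval.end,
             small_truth.sample_ids[i], int(t.cn[i]))
            for t in small_truth.loci
            for i in np.flatnonzero(t.carrier_mask)
        }
        got = {
            (c.interval.chrom, c.interval.start, c.interval.end, c.sample_id, c.cn)
            for c in calls
        }
        assert got == truth_events

    def test_total_false_negative_rate_gives_empty_output(self, small_truth):
        noise = CallerNoise(fn_rate=1.0, fp_per_sample=0.0)
        assert simulate_caller(small_truth, noise, "penncnv") == []

    def test_boundary_jitter_magnitude(self):
        cfg = SimulationConfig(n_loci=120, seed=21,
                               singleton_mass=0.0, noise=CallerNoise(jitter_sd=5_000, fn_rate=0, fp_per_sample=0, split_prob=0))
        truth = simulate_truth(cfg)
        calls = simulate_caller(truth, None, "penncnv")
        tmap = {}
        for t in truth.loci:
            tmap[t.interval.chrom] = tmap.get(t.interval.chrom, []) + [t.interval]
        errors = []
        for c in calls:
            best = min(tmap[c.interval.chrom], key=lambda iv: abs(iv.start - c.interval.start))
            errors.append(abs(c.interval.start - best.start))
            errors.append(abs(c.interval.end - best.end))
        # mean absolute error of a half-normal with sd 5000 is sd*sqrt(2/pi)
        half_normal_mean = 5_000 * np.sqrt(2 / np.pi)
        se = 5_000 * np.sqrt(1 - 2 / np.pi) / np.sqrt(len(errors))
        assert abs(np.mean(errors) - half_normal_mean) <= 3 * se

    def test_split_large_calls_rejoin_under_adjacent_merge(self):
        from cnvmap.regions import merge_adjacent_all

        cfg = SimulationConfig(
            n_loci=30, seed=31, min_len=600_000, max_len=1_500_000,
            noise=CallerNoise(jitter_sd=0, fn_rate=0, fp_per_sample=0, split_prob=1.0),
        )
        truth = simulate_truth(cfg)
        calls = simulate_caller(truth, None, "penncnv")
        n_events = sum(t.carrier_count for t in truth.loci)
        assert len(calls) > n_events  # splitting happened
        merged = merge_adjacent_all(calls)
        assert len(merged) == n_events
        spans = {
            (c.interval.chrom, c.interval.start, c.interval.end) for c in merged
        }
        truth_spans = {
            (t.interval.chrom, t.interval.start, t.interval.end) for t in truth.loci
        }
        assert spans == truth_spans

    def test_probe_counts_pass_default_qc(self, small_truth):
        calls = simulate_caller(small_truth, CallerNoise.zero(), "penncnv")
        assert filter_calls(calls, FilterConfig()) == calls


class TestSimulateCnp:
    def test_genotypes_match_truth(self, small_truth):
        cnp = simulate_cnp_table(small_truth, fraction=0.5)
        assert len(cnp.loci) == 30
        truth_by_iv = {
            (t.interval.chrom, t.interval.start, t.interval.end): t
            for t in small_truth.loci
        }
        for (lid, iv), row in zip(cnp.loci, cnp.genotypes):
            t = truth_by_iv[(iv.chrom, iv.start, iv.end)]
            assert (row == t.cn).all()


class TestSimulateTaggedSnp:
    @pytest.fixture
    def dosage(self):
        rng = np.random.default_rng(5)
        d = np.repeat([0.0, 1.0, 2.0], [60, 32, 10])
        rng.shuffle(d)
        return d

    def test_target_one_is_copy(self, dosage):
        snp, achieved = simulate_tagged_snp(dosage, 1.0, seed=1)
        assert achieved == pytest.approx(1.0, abs=1e-9)
        assert em_r2(dosage, snp) == pytest.approx(1.0, abs=1e-9)

    def test_target_zero_independent(self, dosage):
        snp, achieved = simulate_tagged_snp(dosage, 0.0, seed=1)
        assert achieved < 0.05

    @pytest.mark.parametrize("target", [0.8, 0.9, 0.5])
    def test_intermediate_targets(self, dosage, target):
        snp, achieved = simulate_tagged_snp(dosage, target, seed=2)
        assert achieved == pytest.approx(target, abs=0.03)
        assert em_r2(dosage, snp) == pytest.approx(achieved, abs=1e-9)

    def test_monomorphic_deletion_error(self):
        with pytest.raises(ValueError):
            simulate_tagged_snp(np.zeros(50), 0.9, seed=1)

    def test_unreachable_target_reports_feasible_value(self):
        # a singleton-like deletion cannot support r2 = 0.9 +- 0.03 tuning
        d = np.array([1.0] + [0.0] * 101)
        with pytest.raises(ValueError, match="unreachable|feasible"):
            simulate_tagged_snp(d, 0.45, seed=3)


class TestFixtureBundle:
    def test_bundle_round_trips_through_readers(self, tmp_path, small_truth):
        from cnvmap.io import (
            parse_penncnv_rawcnv,
            read_call_tsv,
            read_cnp_tsv,
            read_snp_tsv,
        )

        paths = write_fixture_bundle(small_truth, tmp_path / "bundle")
        with open(paths["penncnv"]) as fh:
            calls_a = parse_penncnv_rawcnv(fh)
        calls_b = read_call_tsv(paths["birdseye"], "birdseye")
        cnp = read_cnp_tsv(paths["cnp"])
        snps = read_snp_tsv(paths["snp"])
        assert len(calls_a) > 0 and len(calls_b) > 0
        assert cnp.n_samples == 102 and snps.genotypes.shape[1] == 102

    def test_bundles_byte_identical_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(n_loci=25, seed=13)
        for d in ("one", "two"):
            write_fixture_bundle(simulate_truth(cfg), tmp_path / d)
        for name in ("truth.tsv", "penncnv.rawcnv", "birdseye_calls.tsv",
                     "cnp_genotypes.tsv", "snp_genotypes.tsv"):
            assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()
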