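"""Build a population CNV map from two callers' calls, end to end.

Simulates a 102-sample cohort, lets two noisy callers observe it, and runs
QC -> adjacent-merge -> CNVR construction -> reciprocal-overlap validation
-> union with genotyped CNP loci.
"""

from cnvmap import run_pipeline, summarize
from cnvmap.simulate import (
    SimulationConfig,
    simulate_caller,
    simulate_cnp_table,
    simulate_truth,
)

config = SimulationConfig(n_loci=150, seed=42)
truth = simulate_truth(config)
calls_a = simulate_caller(truth, None, "penncnv")
calls_b = simulate_caller(truth, None, "birdseye")
cnp = simulate_cnp_table(truth)

result = run_pipeline(calls_a, calls_b, cnp, n_samples=config.n_samples)
summary = summarize(
    [c for r in result.cnvrs_a for c in r.members], result.cnvrs_a, config.n_samples
)

print(f"simulated truth loci:        {len(truth.loci)}")
print(f"caller A calls after QC:     {result.filter_log['calls_a']['kept']}")
print(f"caller A CNVRs:              {len(result.cnvrs_a)}")
print(f"caller B CNVRs:              {len(result.cnvrs_b)}")
print(f"validated CNVRs (recip 50%): {result.concordance.n_validated} "
      f"({result.concordance.pct_validated}% of A)")
print(f"global map loci:             {len(result.map_loci)}")
print(f"carrier rate:                {summary.carrier_rate_pct}%")
print(f"genome coverage:             {summary.genome_coverage_bp / 1e6:.3f} Mb")
print(f"deletion:duplication ratio:  {summary.del_dup_ratio:.2f}")
# The validated count approaches the truth count because both callers see
# the same events; spurious single-caller calls fail reciprocal validation.
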