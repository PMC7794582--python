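"""Synthetic CNV cohorts with two noisy callers, CNP genotypes and SNPs in
controlled LD with deletions.

The generator emulates an array-genotyped cohort: a landscape of
non-overlapping CNV loci with population frequencies from singleton to
near-fixed, integer copy states 0-6, two callers observing the truth with
boundary jitter, false negatives/positives and large-call splitting, and
SNP loci whose alleles segregate with deletion alleles at controllable r2.
Every generator is a pure function of (config, seed): independent
pseudo-random streams are derived from the master seed by fixed offsets,
so adding a generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval
from .io import (
    CNPGenotypeTable,
    CNVCall,
    SNPGenotypeMatrix,
    write_bed,
    write_call_tsv,
    write_cnp_tsv,
    write_snp_tsv,
)

# fixed sub-stream offsets from the master seed
_TRUTH, _PENNCNV, _BIRDSEYE, _CNP, _SNP = 1, 2, 3, 4, 5


@dataclass
class CallerNoise:
    """Observation model of one caller."""

    jitter_sd: float = 200.0  # bp, gaussian boundary error
    fn_rate: float = 0.01  # per carrier event
    fp_per_sample: float = 2.0  # Poisson mean of spurious calls
    split_prob: float = 0.1  # for events > split_threshold
    split_threshold: int = 500_000
    confidence_shape: float = 20.0  # gamma confidence model (birdseye)
    confidence_scale: float = 1.0

    @classmethod
    def zero(cls) -> "CallerNoise":
        return cls(jitter_sd=0.0, fn_rate=0.0, fp_per_sample=0.0, split_prob=0.0)


@dataclass
class SimulationConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror an array-based population CNV survey: 102 diploid
    individuals; locus lengths log-uniform on [1 kb, 2 Mb]; ~28% singleton
    loci, the rest with carrier frequencies drawn from a scaled beta on
    (0.01, 0.99]; locus state model del-only/dup-only/mixed with
    probabilities (0.57, 0.22, 0.21). Probe density reflects the array's
    probe enrichment inside CNV regions so that legitimate >=1 kb events
    carry enough markers.
    """

    n_samples: int = 102
    n_loci: int = 200
    min_len: int = 1_000
    max_len: int = 2_000_000
    singleton_mass: float = 0.28
    freq_beta: tuple = (0.6, 2.4)  # carrier-frequency beta, scaled to (0.01, 0.99]
    type_probs: tuple = (0.57, 0.22, 0.21)  # del, dup, mixed
    hom_prob: float = 0.15  # P(cn=0 | del carrier) / P(cn=4 | dup carrier), mixed loci
    probe_rate_per_kb: float = 12.0
    noise: CallerNoise = field(default_factory=CallerNoise)
    n_chroms: int = 22
    chrom_length: int = 250_000_000
    min_locus_gap: int = 2_000_000
    seed: int = 0

    def __post_init__(self):
        for p in (self.singleton_mass, *self.type_probs):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.type_probs) - 1.0) > 1e-9:
            raise ValueError("type_probs must sum to 1")


@dataclass
class TruthLocus:
    locus_id: str
    interval: GenomicInterval
    locus_class: str  # intended model: del | dup | mixed
    cn: np.ndarray  # per-sample integer copy number

    @property
    def carrier_mask(self) -> np.ndarray:
        return self.cn != 2

    @property
    def carrier_count(self) -> int:
        return int(self.carrier_mask.sum())

    @property
    def realized_type(self) -> str:
        states = self.cn[self.carrier_mask]
        if states.size == 0:
            raise ValueError("locus with no carriers")
        if states.max() < 2:
            return "loss"
        if states.min() > 2:
            return "gain"
        return "mixed"

    @property
    def states_present(self) -> frozenset:
        return frozenset(int(s) for s in np.unique(self.cn[self.carrier_mask]))

    def frequency_pct(self, n_samples: int) -> float:
        return round(100.0 * self.carrier_count / n_samples, 2)


@dataclass
class TruthSet:
    config: SimulationConfig
    sample_ids: list[str]
    loci: list[TruthLocus]


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------


def _place_loci(config: SimulationConfig, rng: np.random.Generator):
    """Non-overlapping placements with a minimum inter-locus gap."""
    placed: dict[int, list[tuple[int, int]]] = {c: [] for c in range(1, config.n_chroms + 1)}
    out = []
    log_lo, log_hi = np.log(config.min_len), np.log(config.max_len)
    for i in range(config.n_loci):
        chrom = 1 + i % config.n_chroms
        length = int(round(np.exp(rng.uniform(log_lo, log_hi))))
        for attempt in range(200):
            start = int(rng.integers(1_000_000, config.chrom_length - length - 1_000_000))
            end = start + length
            ok = all(
                end + config.min_locus_gap <= s or e + config.min_locus_gap <= start
                for s, e in placed[chrom]
            )
            if ok:
                placed[chrom].append((start, end))
                out.append((chrom, start, end))
                break
        else:
            raise ValueError(
                f"cannot place locus {i}: configuration infeasible "
                f"(loci do not fit on the simulated chromosomes)"
            )
    return out


def _genotype_locus(
    locus_class: str, carrier_freq: float, singleton: bool,
    n_samples: int, hom_prob: float, rng: np.random.Generator,
) -> np.ndarray:
    cn = np.full(n_samples, 2, dtype=int)
    if singleton:
        idx = int(rng.integers(n_samples))
        if locus_class == "del":
            cn[idx] = 1
        elif locus_class == "dup":
            cn[idx] = 3
        else:
            cn[idx] = 1 if rng.random() < 0.5 else 3
        return cn
    for _ in range(200):
        if locus_class in ("del", "dup"):
            # one segregating allele at Hardy-Weinberg proportions
            q = 1.0 - np.sqrt(max(0.0, 1.0 - carrier_freq))
            k = rng.binomial(2, q, size=n_samples)
            cn = 2 - k if locus_class == "del" else 2 + k
        else:
            cn = np.full(n_samples, 2, dtype=int)
            carriers = rng.random(n_samples) < carrier_freq
            for idx in np.flatnonzero(carriers):
                if rng.random() < 0.5:
                    cn[idx] = 0 if rng.random() < hom_prob else 1
                else:
                    cn[idx] = 4 if rng.random() < hom_prob else 3
        if (cn != 2).any():
            return cn
    # extremely low carrier frequency: force one carrier
    cn = np.full(n_samples, 2, dtype=int)
    cn[int(rng.integers(n_samples))] = 1 if locus_class != "dup" else 3
    return cn


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Deterministic truth landscape for a given (config, seed)."""
    rng = np.random.default_rng(config.seed + _TRUTH)
    sample_ids = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    if config.n_loci == 0:
        return TruthSet(config, sample_ids, [])
    placements = _place_loci(config, rng)
    classes = rng.choice(["del", "dup", "mixed"], size=config.n_loci, p=config.type_probs)
    loci = []
    counters: dict[int, int] = {}
    a, b = config.freq_beta
    # assign ids in positional order per chromosome
    order = sorted(range(config.n_loci), key=lambda i: (placements[i][0], placements[i][1]))
    for i in order:
        chrom, start, end = placements[i]
        singleton = rng.random() < config.singleton_mass
        freq = 0.0 if singleton else 0.01 + 0.98 * rng.beta(a, b)
        cn = _genotype_locus(
            classes[i], freq, singleton, config.n_samples, config.hom_prob, rng
        )
        counters[chrom] = counters.get(chrom, 0) + 1
        loci.append(
            TruthLocus(
                locus_id=f"TRUTH_{chrom}_{counters[chrom]}",
                interval=GenomicInterval(chrom, start, end),
                locus_class=str(classes[i]),
                cn=cn,
            )
        )
    return TruthSet(config, sample_ids, loci)


# ---------------------------------------------------------------------------
# Caller observation
# ---------------------------------------------------------------------------


def _probes_for(length: int, rate_per_kb: float) -> int:
    return max(1, int(round(rate_per_kb * length / 1000.0)))


def _observe_event(
    interval: GenomicInterval, noise: CallerNoise, rng: np.random.Generator
) -> GenomicInterval:
    if noise.jitter_sd == 0:
        return interval
    for _ in range(10):
        s = int(round(interval.start + rng.normal(0, noise.jitter_sd)))
        e = int(round(interval.end + rng.normal(0, noise.jitter_sd)))
        if e - s >= 100 and s >= 0:
            return GenomicInterval(interval.chrom, s, e)
    return GenomicInterval(interval.chrom, interval.start, interval.start + 100)


def _split_event(
    interval: GenomicInterval, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Break a large event into ~100-150 kb fragments with small gaps."""
    pieces = []
    pos = interval.start
    while pos < interval.end:
        chunk = int(rng.integers(100_000, 150_001))
        end = min(pos + chunk, interval.end)
        if interval.end - end < 50_000:  # absorb a short tail
            end = interval.end
        pieces.append(GenomicInterval(interval.chrom, pos, end))
        pos = end + int(rng.integers(500, 3_000))
    return pieces


def simulate_caller(
    truth: TruthSet, noise: CallerNoise | None, source: str, seed_offset: int | None = None
) -> list[CNVCall]:
    """One caller's observation of the truth.

    With zero noise the returned calls equal the truth events exactly
    (probe counts are deterministic in the event length).
    """
    config = truth.config
    if noise is None:
        noise = config.noise
    if seed_offset is None:
        seed_offset = {"penncnv": _PENNCNV, "birdseye": _BIRDSEYE}.get(source, 7)
    rng = np.random.default_rng(config.seed + seed_offset)
    calls: list[CNVCall] = []

    def confidence(rng) -> float | None:
        if source == "penncnv":
            return None
        return float(rng.gamma(noise.confidence_shape, noise.confidence_scale))

    for locus in truth.loci:
        for s_idx in np.flatnonzero(locus.carrier_mask):
            if noise.fn_rate > 0 and rng.random() < noise.fn_rate:
                continue
            obs = _observe_event(locus.interval, noise, rng)
            if obs.length > noise.split_threshold and rng.random() < noise.split_prob:
                pieces = _split_event(obs, rng)
            else:
                pieces = [obs]
            for piece in pieces:
                calls.append(
                    CNVCall(
                        sample_id=truth.sample_ids[s_idx],
                        interval=piece,
                        cn=int(locus.cn[s_idx]),
                        num_probes=_probes_for(piece.length, config.probe_rate_per_kb),
                        confidence=confidence(rng),
                        source=source,
                    )
                )
    # spurious calls, uniform over the simulated genome
    if noise.fp_per_sample > 0:
        log_lo, log_hi = np.log(config.min_len), np.log(100_000)
        for sample in truth.sample_ids:
            for _ in range(rng.poisson(noise.fp_per_sample)):
                chrom = int(rng.integers(1, config.n_chroms + 1))
                length = int(round(np.exp(rng.uniform(log_lo, log_hi))))
                start = int(rng.integers(0, config.chrom_length - length))
                calls.append(
                    CNVCall(
                        sample_id=sample,
                        interval=GenomicInterval(chrom, start, start + length),
                        cn=int(rng.choice([1, 3])),
                        num_probes=_probes_for(length, config.probe_rate_per_kb),
                        confidence=confidence(rng),
                        source=source,
                    )
                )
    calls.sort(key=lambda c: (c.interval.chrom_order, c.interval.start, c.sample_id))
    return calls


def format_penncnv_rawcnv(calls) -> list[str]:
    """Render calls in the PennCNV rawcnv report layout."""
    lines = []
    for c in calls:
        iv = c.interval
        lines.append(
            f"chr{iv.chrom}:{iv.start}-{iv.end} numsnp={c.num_probes} "
            f"length={iv.length:,} state{min(c.cn, 5)},cn={c.cn} {c.sample_id} "
            f"startsnp=rs{iv.start} endsnp=rs{iv.end}"
        )
    return lines


# ---------------------------------------------------------------------------
# CNP genotypes
# ---------------------------------------------------------------------------


def simulate_cnp_table(truth: TruthSet, fraction: float = 0.5) -> CNPGenotypeTable:
    """Genotyped copy-number polymorphisms at a subset of the truth loci.

    The genotyping step observes true integer copy numbers without error at
    predefined locus boundaries (the CNP panel is assumed to pre-date the
    cohort), so the table equals the truth restricted to the sampled loci.
    """
    rng = np.random.default_rng(truth.config.seed + _CNP)
    n = len(truth.loci)
    chosen = sorted(rng.choice(n, size=int(round(fraction * n)), replace=False)) if n else []
    loci = []
    genotypes = []
    for rank, i in enumerate(chosen, start=1):
        t = truth.loci[i]
        loci.append((f"CNP{rank}", t.interval))
        genotypes.append(t.cn.copy())
    genotypes = np.asarray(genotypes, dtype=int) if loci else np.zeros((0, truth.config.n_samples), dtype=int)
    return CNPGenotypeTable(loci, genotypes, list(truth.sample_ids))


# ---------------------------------------------------------------------------
# Tagged SNPs
# ---------------------------------------------------------------------------


def _haplotypes_from_dosage(dosage: np.ndarray) -> np.ndarray:
    """(n, 2) haplotype alleles consistent with an unphased dosage vector."""
    haps = np.zeros((dosage.size, 2), dtype=int)
    haps[dosage >= 1, 0] = 1
    haps[dosage == 2, 1] = 1
    return haps


def simulate_tagged_snp(
    deletion_dosages, target_r2: float, seed: int, tol: float = 0.03, max_iter: int = 2000
):
    """Construct a SNP dosage vector in LD with a deletion at a target r2.

    Starts from a SNP whose alleles copy the deletion allele on the same
    haplotypes (r2 = 1) and greedily flips individual SNP haplotype alleles
    until the EM-estimated r2 is within ``tol`` of the target. Returns
    ``(snp_dosage, achieved_r2)``; raises ``ValueError`` with the feasible
    value when the target cannot be approached (granularity of the allele
    counts at this sample size).
    """
    from .ld import em_r2

    if not (0.0 <= target_r2 <= 1.0):
        raise ValueError("target_r2 must be in [0, 1]")
    d = np.asarray(deletion_dosages, dtype=float)
    if np.nanstd(d) == 0:
        raise ValueError("deletion dosage vector is monomorphic")
    rng = np.random.default_rng(seed)
    n = d.size

    if target_r2 <= 0.05:
        # independent draw; keep the least-correlated of a few attempts
        best = None
        for _ in range(25):
            q = rng.uniform(0.1, 0.5)
            snp = rng.binomial(2, q, size=n).astype(float)
            if np.std(snp) == 0:
                continue
            r2 = em_r2(d, snp)
            if best is None or r2 < best[1]:
                best = (snp, r2)
        if best is None:
            raise ValueError("could not draw a polymorphic independent SNP")
        return best

    haps = _haplotypes_from_dosage(d)
    snp = haps.copy()
    cur = em_r2(d, snp.sum(axis=1).astype(float))
    best_seen = cur
    for _ in range(max_iter):
        if abs(cur - target_r2) <= tol:
            break
        improved = False
        for _ in range(60):
            i = int(rng.integers(n))
            j = int(rng.integers(2))
            snp[i, j] ^= 1
            dos = snp.sum(axis=1).astype(float)
            if np.std(dos) == 0:
                snp[i, j] ^= 1
                continue
            new = em_r2(d, dos)
            if abs(new - target_r2) < abs(cur - target_r2) - 1e-12:
                cur = new
                improved = True
                break
            snp[i, j] ^= 1
        best_seen = min(best_seen, cur, key=lambda v: abs(v - target_r2))
        if not improved:
            break
    if abs(cur - target_r2) > tol:
        raise ValueError(
            f"target r2={target_r2} unreachable at this allele frequency; "
            f"closest feasible value {cur:.3f}"
        )
    return snp.sum(axis=1).astype(float), cur


def simulate_snp_panel(
    truth: TruthSet,
    cnp_table: CNPGenotypeTable,
    target_r2: float = 0.9,
    n_background_per_deletion: int = 10,
    min_carriers_for_tag: int = 8,
    flank: int = 100_000,
):
    """A SNP panel around the bi-allelic deletions of the CNP table.

    Each deletion with enough carriers receives one injected tag SNP at the
    target r2 plus independent background SNPs in the flanking window.
    Returns ``(matrix, injected)`` where ``injected`` maps locus_id ->
    (snp_id, achieved_r2).
    """
    from .ld import select_biallelic_deletions

    rng = np.random.default_rng(truth.config.seed + _SNP)
    deletions = select_biallelic_deletions(cnp_table)
    snps = []
    rows = []
    injected: dict[str, tuple[str, float]] = {}
    counter = 0
    for deletion in deletions:
        iv = deletion.interval
        if deletion.carrier_count >= min_carriers_for_tag:
            try:
                dosage, achieved = simulate_tagged_snp(
                    deletion.dosage, target_r2, seed=int(rng.integers(2**31 - 1))
                )
                counter += 1
                snp_id = f"rs_tag_{counter}"
                pos = max(0, iv.start - int(rng.integers(1_000, flank)))
                snps.append((snp_id, iv.chrom, pos))
                rows.append(dosage)
                injected[deletion.locus_id] = (snp_id, achieved)
            except ValueError:
                pass
        for _ in range(n_background_per_deletion):
            counter += 1
            q = rng.uniform(0.05, 0.5)
            dosage = rng.binomial(2, q, size=truth.config.n_samples).astype(float)
            offset = int(rng.integers(-flank, flank + iv.length))
            pos = max(0, iv.start + offset)
            snps.append((f"rs_bg_{counter}", iv.chrom, pos))
            rows.append(dosage)
    genotypes = (
        np.vstack(rows) if rows else np.zeros((0, truth.config.n_samples))
    )
    return SNPGenotypeMatrix(snps, genotypes, list(truth.sample_ids)), injected


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


def write_fixture_bundle(truth: TruthSet, out_dir, header_lines=()) -> dict:
    """Write the whole synthetic dataset as a directory of text fixtures:
    truth TSV, PennCNV rawcnv, birdseye call TSV, CNP TSV, SNP TSV and an
    (empty by default) exclusion BED. Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth": out / "truth.tsv",
        "penncnv": out / "penncnv.rawcnv",
        "birdseye": out / "birdseye_calls.tsv",
        "cnp": out / "cnp_genotypes.tsv",
        "snp": out / "snp_genotypes.tsv",
        "exclude": out / "exclusion.bed",
    }
    import pandas as pd

    truth_rows = []
    for t in truth.loci:
        truth_rows.append(
            {
                "locus_id": t.locus_id,
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "type": t.realized_type,
                "carrier_count": t.carrier_count,
                "frequency_pct": t.frequency_pct(truth.config.n_samples),
                "cn": ",".join(str(int(c)) for c in t.cn),
            }
        )
    with open(paths["truth"], "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(truth_rows).to_csv(fh, sep="\t", index=False)

    penncnv = simulate_caller(truth, None, "penncnv")
    with open(paths["penncnv"], "w") as fh:
        fh.write("\n".join(format_penncnv_rawcnv(penncnv)) + ("\n" if penncnv else ""))
    birdseye = simulate_caller(truth, None, "birdseye")
    write_call_tsv(birdseye, paths["birdseye"], header_lines)
    cnp = simulate_cnp_table(truth)
    write_cnp_tsv(cnp, paths["cnp"], header_lines)
    snp_matrix, _ = simulate_snp_panel(truth, cnp)
    write_snp_tsv(snp_matrix, paths["snp"], header_lines)
    write_bed([], paths["exclude"], header_lines)
    return paths
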