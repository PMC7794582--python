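"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by enumeration or direct
definition (overlap graphs, log-factorial multinomials, likelihood grids)
so they stay independent of the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from cnvmap.intervals import GenomicInterval
from cnvmap.io import CNVCall
from cnvmap.simulate import CallerNoise, SimulationConfig, simulate_truth


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_cnvrs(calls):
    """Union-closure by explicit pairwise overlap graph + connected
    components; returns a set of (chrom, start, end, frozenset(samples))."""
    calls = list(calls)
    n = len(calls)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i].interval, calls[j].interval
            if a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) > 0:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for j in adj[k]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(comp)
    out = set()
    for comp in comps:
        ivs = [calls[k].interval for k in comp]
        out.add(
            (
                ivs[0].chrom,
                min(iv.start for iv in ivs),
                max(iv.end for iv in ivs),
                frozenset(calls[k].sample_id for k in comp),
            )
        )
    return out


_HWE_CACHE: dict = {}


def hwe_enumeration_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE p by full enumeration with log-factorials."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    key = (n, na)
    if key not in _HWE_CACHE:
        logs = {}
        for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
            raa = (na - h) // 2
            rbb = n - h - raa
            if raa < 0 or rbb < 0:
                continue
            logs[h] = (
                math.lgamma(n + 1)
                - math.lgamma(raa + 1)
                - math.lgamma(h + 1)
                - math.lgamma(rbb + 1)
                + h * math.log(2)
            )
        mx = max(logs.values())
        tot = sum(math.exp(v - mx) for v in logs.values())
        _HWE_CACHE[key] = {h: math.exp(v - mx) / tot for h, v in logs.items()}
    probs = _HWE_CACHE[key]
    p_obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def grid_search_r2(dosage_a, dosage_b, step: float = 1e-4) -> float:
    """r2 from the haplotype frequency maximizing the unphased-genotype
    likelihood over a grid on the single free parameter p11."""
    a = np.asarray(dosage_a)
    b = np.asarray(dosage_b)
    t = np.zeros((3, 3))
    for x, y in zip(a, b):
        t[int(x), int(y)] += 1
    n = t.sum()
    pA = (t.sum(1) * np.arange(3)).sum() / (2 * n)
    pB = (t.sum(0) * np.arange(3)).sum() / (2 * n)
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
    p11 = np.arange(lo, hi + step, step)
    h11, h10 = p11, pA - p11
    h01, h00 = pB - p11, 1 - pA - pB + p11
    geno_prob = {
        (0, 0): h00**2, (0, 1): 2 * h00 * h01, (0, 2): h01**2,
        (1, 0): 2 * h00 * h10, (1, 1): 2 * (h11 * h00 + h10 * h01), (1, 2): 2 * h01 * h11,
        (2, 0): h10**2, (2, 1): 2 * h10 * h11, (2, 2): h11**2,
    }
    ll = np.zeros_like(p11)
    for (x, y), g in geno_prob.items():
        if t[x, y]:
            ll = ll + t[x, y] * np.log(np.maximum(g, 1e-300))
    best = p11[int(np.argmax(ll))]
    d = best - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return float(min(1.0, d * d / denom))


def random_calls(rng: np.random.Generator, n_calls: int, n_samples: int = 20):
    """Random overlapping call instances for the clustering oracle."""
    calls = []
    for _ in range(n_calls):
        chrom = int(rng.integers(1, 4))
        start = int(rng.integers(0, 50_000))
        length = int(rng.integers(1_000, 20_000))
        calls.append(
            CNVCall(
                sample_id=f"S{int(rng.integers(n_samples)):03d}",
                interval=GenomicInterval(chrom, start, start + length),
                cn=int(rng.choice([0, 1, 3, 4])),
                num_probes=10,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_truth():
    cfg = SimulationConfig(n_loci=60, seed=5, noise=CallerNoise.zero())
    return simulate_truth(cfg)


@pytest.fixture(scope="session")
def noisy_truth():
    cfg = SimulationConfig(n_loci=120, seed=11)
    return simulate_truth(cfg)
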