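"""Independent brute-force oracles used to validate the implementation.

Each oracle is written directly from the defining formula or by exhaustive
enumeration, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def pi_bruteforce_pairs(alt_count: int, n_alleles: int) -> float:
    """Per-site pi by enumerating all haplotype pairs and counting
    mismatches."""
    haps = [1] * alt_count + [0] * (n_alleles - alt_count)
    pairs = list(combinations(range(n_alleles), 2))
    if not pairs:
        return float("nan")
    diff = sum(1 for i, j in pairs if haps[i] != haps[j])
    return diff / len(pairs)


def window_pi_bruteforce(dosages: np.ndarray) -> float:
    """Window pi sum from a complete-data (sites x samples) dosage slice by
    explicit pairwise haplotype comparison per site."""
    total = 0.0
    for row in dosages:
        alt = int(row.sum())
        n = 2 * len(row)
        total += pi_bruteforce_pairs(alt, n)
    return total


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_d_oracle(dosages: np.ndarray) -> float:
    """Tajima's D for one population's window slice, recomputed from scratch.

    dosages: (sites, samples) with MISSING = -1.  Uses the same definitions
    the engine documents (median called-allele count over segregating sites)
    but derives every quantity independently.
    """
    pi_sum = 0.0
    s = 0
    ns = []
    for row in dosages:
        called = row[row != MISSING]
        n = 2 * len(called)
        if n < 2:
            continue
        j = int(called.sum())
        if 0 < j < n:
            s += 1
            ns.append(n)
            pi_sum += 2.0 * j * (n - j) / (n * (n - 1.0))
    if s == 0:
        return float("nan")
    n = int(np.median(ns))
    if n < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - s / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def hudson_window_fst_oracle(dosages_a: np.ndarray,
                             dosages_b: np.ndarray) -> float:
    """Ratio-of-averages Hudson window FST recomputed site by site."""
    num_sum = 0.0
    den_sum = 0.0
    for row_a, row_b in zip(dosages_a, dosages_b):
        ca = row_a[row_a != MISSING]
        cb = row_b[row_b != MISSING]
        n1, n2 = 2 * len(ca), 2 * len(cb)
        if n1 < 2 or n2 < 2:
            continue
        p1 = ca.sum() / n1
        p2 = cb.sum() / n2
        num_sum += ((p1 - p2) ** 2
                    - p1 * (1 - p1) / (n1 - 1)
                    - p2 * (1 - p2) / (n2 - 1))
        den_sum += p1 * (1 - p2) + p2 * (1 - p1)
    if den_sum == 0:
        return float("nan")
    return num_sum / den_sum


# ---------------------------------------------------------------------------
# PLINK-semantics ROH
# ---------------------------------------------------------------------------

def roh_bruteforce(positions, dosages, *, min_kb=300.0, window=50,
                   max_het=3, max_missing=3, threshold=0.05,
                   max_gap_kb=1000.0, density_kb=100.0,
                   min_snps=100) -> list[tuple[int, int, int]]:
    """Enumerate ROH segments (start_bp, end_bp, n_snps) directly.

    Every scan window is checked explicitly, every SNP's hit rate computed
    by iterating its overlapping windows, and every candidate run tested
    against all thresholds.
    """
    positions = list(positions)
    dosages = list(dosages)
    n = len(dosages)
    if n == 0:
        return []
    # 1. scan-window verdicts
    if n < window:
        spans = [(0, n - 1)]
    else:
        spans = [(i, i + window - 1) for i in range(n - window + 1)]
    verdicts = []
    for a, b in spans:
        chunk = dosages[a:b + 1]
        het = sum(1 for d in chunk if d == 1)
        mis = sum(1 for d in chunk if d == MISSING)
        verdicts.append(het <= max_het and mis <= max_missing)
    # 2. per-SNP hit rates
    eligible = []
    for k in range(n):
        overl = [v for (a, b), v in zip(spans, verdicts) if a <= k <= b]
        rate = sum(overl) / len(overl)
        eligible.append(rate >= threshold)
    # 3. runs of eligible SNPs, split at big gaps, thresholds
    segments = []
    runs = []
    start = None
    for k in range(n):
        if eligible[k] and start is None:
            start = k
        if not eligible[k] and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))
    for a, b in runs:
        pieces = []
        pa = a
        for k in range(a, b):
            if positions[k + 1] - positions[k] > max_gap_kb * 1000.0:
                pieces.append((pa, k))
                pa = k + 1
        pieces.append((pa, b))
        for pa, pb in pieces:
            length_kb = (positions[pb] - positions[pa] + 1) / 1000.0
            count = pb - pa + 1
            if length_kb < min_kb or count < min_snps:
                continue
            if length_kb / count > density_kb:
                continue
            segments.append((positions[pa], positions[pb], count))
    return segments


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by hypergeometric enumeration in rationals.

    Table [[a, b], [c, d]]; probability-mass ordering: sum P(k) over all
    tables with the same margins whose probability is <= the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum((prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs),
               Fraction(0))


def bh_stepup_oracle(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, m * p_values[i] / rank)
        q[i] = val
        prev = val
    return q
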