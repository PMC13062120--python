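"""Per-SNP allele-frequency contrasts: fixation classes, Fisher tests, FDR.

For each commercial-indigenous pair, every tested SNP gets allele counts per
population, a two-sided Fisher exact p-value on the 2x2 ref/alt count table,
a Benjamini-Hochberg q-value (adjusted within the pair across all tested
SNPs), genotype-class fractions, and a fixation class:

* ``fixed_in_a`` / ``near_fixed_a`` — one allele at frequency >= 1.0 / 0.95
  in population a while the *same* allele is rare (<= 0.08) in population b;
* symmetric ``_b`` classes;
* ``not_fixed`` otherwise.

The classification is polarity-symmetric (invariant under a global ref/alt
relabeling): both the ALT and the REF allele are examined.  When both
populations are reciprocally fixed the a-side class wins (documented
tie-break; population a is the commercial population in pipeline use).

The cross-comparison consistency rule retains SNPs whose (fixation class
assigned AND q < 0.05) holds in strictly more than 70% of the pairwise
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io_core import MISSING, GenotypeMatrix, PopulationMap


@dataclass(frozen=True)
class FixationConfig:
    fixed_af: float = 1.0
    near_fixed_af: float = 0.95
    rare_af: float = 0.08
    q_cutoff: float = 0.05
    min_consistency_share: float = 0.7  # strict >


def allele_counts(gm: GenotypeMatrix, pmap: PopulationMap,
                  population: str) -> tuple[np.ndarray, np.ndarray]:
    """(ref_count, alt_count) per site over non-missing alleles."""
    idx = gm.sample_indices(pmap.samples_of(population))
    d = gm.dosage[:, idx]
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=1).astype(np.int64)
    total = 2 * called.sum(axis=1).astype(np.int64)
    return total - alt, alt


def fisher_exact_two_sided(ref_a: int, alt_a: int,
                           ref_b: int, alt_b: int) -> float:
    """Two-sided Fisher exact p on [[ref_a, alt_a], [ref_b, alt_b]].

    Uses the probability-mass ordering (sum of hypergeometric probabilities
    of tables no more likely than the observed one); a zero margin gives
    p = 1 by convention.
    """
    table = np.array([[ref_a, alt_a], [ref_b, alt_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_fixation(af_a: float, af_b: float,
                      cfg: FixationConfig | None = None) -> str:
    """Fixation class for one SNP given ALT frequencies in both populations."""
    cfg = cfg or FixationConfig()
    if np.isnan(af_a) or np.isnan(af_b):
        return "not_fixed"
    # examine both allele polarities: (freq of allele in a, same allele in b)
    for fa, fb in ((af_a, af_b), (1.0 - af_a, 1.0 - af_b)):
        if fa >= cfg.near_fixed_af and fb <= cfg.rare_af:
            return "fixed_in_a" if fa >= cfg.fixed_af else "near_fixed_a"
    for fb, fa in ((af_b, af_a), (1.0 - af_b, 1.0 - af_a)):
        if fb >= cfg.near_fixed_af and fa <= cfg.rare_af:
            return "fixed_in_b" if fb >= cfg.fixed_af else "near_fixed_b"
    return "not_fixed"


def genotype_fractions(gm: GenotypeMatrix, pmap: PopulationMap,
                       population: str) -> pd.DataFrame:
    """Per-site fractions of 0/0, 0/1 and 1/1 among called genotypes."""
    idx = gm.sample_indices(pmap.samples_of(population))
    d = gm.dosage[:, idx]
    called = (d != MISSING).sum(axis=1).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        return pd.DataFrame({
            "frac_hom_ref": (d == 0).sum(axis=1) / called,
            "frac_het": (d == 1).sum(axis=1) / called,
            "frac_hom_alt": (d == 2).sum(axis=1) / called,
        })


def compare_pair(gm: GenotypeMatrix, pmap: PopulationMap,
                 pop_a: str, pop_b: str,
                 site_mask: np.ndarray | None = None,
                 cfg: FixationConfig | None = None) -> pd.DataFrame:
    """Full per-SNP fixation table for one population pair.

    ``pop_a`` is conventionally the commercial population.  ``site_mask``
    restricts testing (e.g. to SNPs inside candidate genes); q-values are
    adjusted across the tested SNPs of this pair only.
    """
    cfg = cfg or FixationConfig()
    mask = (np.ones(gm.n_sites, dtype=bool) if site_mask is None
            else np.asarray(site_mask, dtype=bool))
    sub = gm.subset_sites(mask)
    ref_a, alt_a = allele_counts(sub, pmap, pop_a)
    ref_b, alt_b = allele_counts(sub, pmap, pop_b)
    tot_a, tot_b = ref_a + alt_a, ref_b + alt_b
    with np.errstate(divide="ignore", invalid="ignore"):
        af_a = np.where(tot_a > 0, alt_a / tot_a, np.nan)
        af_b = np.where(tot_b > 0, alt_b / tot_b, np.nan)
    p = np.array([fisher_exact_two_sided(ref_a[i], alt_a[i], ref_b[i], alt_b[i])
                  for i in range(sub.n_sites)])
    q = bh_fdr(p) if sub.n_sites else p
    classes = [classify_fixation(af_a[i], af_b[i], cfg)
               for i in range(sub.n_sites)]
    out = sub.sites[["chrom", "pos", "ref", "alt"]].copy()
    out["af_a"] = af_a
    out["af_b"] = af_b
    fr_a = genotype_fractions(sub, pmap, pop_a).add_suffix("_a")
    fr_b = genotype_fractions(sub, pmap, pop_b).add_suffix("_b")
    out = pd.concat([out, fr_a, fr_b], axis=1)
    out["p_value"] = p
    out["q_value"] = q
    out["fixation_class"] = classes
    return out


def shared_fixation_support(results: dict[str, pd.DataFrame],
                            min_share: float = 0.5,
                            q_cutoff: float = 0.05) -> pd.DataFrame:
    """SNPs near-fixed (class assigned, q < cutoff) in >= ceil(share * K)
    of K pairwise comparisons.

    This is the gene-evidence aggregation rule and mirrors the >= 50%
    sharing logic used for convergent windows; the stricter
    :func:`cross_comparison_consistency` (> 70%) is a separate analysis.
    """
    import math
    if len(results) < 2:
        raise ValueError("need at least two pairwise comparisons")
    pops = list(results)
    need = math.ceil(min_share * len(pops))
    base = results[pops[0]][["chrom", "pos", "ref", "alt"]].copy()
    support = np.zeros(len(base), dtype=np.int64)
    for pop in pops:
        df = results[pop]
        if len(df) != len(base) or not (df["pos"].to_numpy()
                                        == base["pos"].to_numpy()).all():
            raise ValueError("comparison tables must share one site set")
        support += ((df["fixation_class"] != "not_fixed")
                    & (df["q_value"] < q_cutoff)).to_numpy()
    base["n_supporting"] = support
    base["supported"] = support >= need
    return base


def cross_comparison_consistency(
        results: dict[str, pd.DataFrame],
        cfg: FixationConfig | None = None) -> pd.DataFrame:
    """SNPs with an assigned fixation class and q < cutoff in > 70% of pairs.

    ``results`` maps indigenous population name -> compare_pair output (all
    on the same site set).  Returns one row per SNP with the supporting
    count, share and a ``consistent`` flag (strict > min_consistency_share).
    """
    cfg = cfg or FixationConfig()
    if len(results) < 2:
        raise ValueError("need at least two pairwise comparisons")
    pops = list(results)
    base = results[pops[0]][["chrom", "pos", "ref", "alt"]].copy()
    support = np.zeros(len(base), dtype=np.int64)
    for pop in pops:
        df = results[pop]
        if len(df) != len(base) or not (df["pos"].to_numpy()
                                        == base["pos"].to_numpy()).all():
            raise ValueError("comparison tables must share one site set")
        ok = ((df["fixation_class"] != "not_fixed")
              & (df["q_value"] < cfg.q_cutoff)).to_numpy()
        support += ok
    share = support / len(pops)
    base["n_supporting"] = support
    base["share"] = share
    base["consistent"] = share > cfg.min_consistency_share
    return base
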