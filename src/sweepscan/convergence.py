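"""Convergent-sweep filtering and gene-level evidence aggregation.

The multi-step filter mirrors the scan design: per pair, windows with at
least 5 SNPs are ranked and the extreme sets selected (top 5% of FST; top
and bottom 2.5% of log2 pi-ratio and of the Tajima's D difference, ties at
the cut included, undefined values excluded from the ranking denominator);
a window becomes a convergent call for a method when it is selected in at
least 50% of the pairwise comparisons (count thresholds use ceilings).

Gene evidence then aggregates four methods -- FST, pi-ratio, D-difference
(window overlap) and ROH (per-population segment coverage) -- plus near-
fixed SNP support, into the candidate rule: a gene is a candidate iff it is
supported by >= 3 of the 4 methods and/or contains >= 1 consistently
near-fixed SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GeneRecord

WindowKey = tuple[str, int, int]  # (chrom, start, end), 1-based inclusive


@dataclass(frozen=True)
class ConvergenceConfig:
    min_snps_per_window: int = 5
    top_fst_fraction: float = 0.05
    tail_fraction: float = 0.025
    min_share: float = 0.5            # >= ceil(share * K) comparisons
    tails: str = "union"              # "union" or "sweep" (direction-specific)
    roh_min_carriers: int = 1
    roh_min_pop_share: float = 0.5
    min_methods: int = 3


def filter_min_snps(scan: pd.DataFrame, min_snps: int = 5) -> pd.DataFrame:
    """Drop windows with fewer than ``min_snps`` pooled-pair SNPs."""
    return scan[scan["n_snps"] >= min_snps].reset_index(drop=True)


def _window_keys(df: pd.DataFrame) -> list[WindowKey]:
    return list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))


def select_top_fst(scan: pd.DataFrame,
                   top_fraction: float = 0.05) -> set[WindowKey]:
    """Windows in the top fraction of defined FST values, ties included."""
    defined = scan[scan["fst"].notna()]
    if defined.empty:
        return set()
    k = math.ceil(top_fraction * len(defined))
    cut = defined["fst"].nlargest(k).iloc[-1]
    return set(_window_keys(defined[defined["fst"] >= cut]))


def select_tails(scan: pd.DataFrame, statistic: str,
                 tail_fraction: float = 0.025
                 ) -> tuple[set[WindowKey], set[WindowKey]]:
    """(upper, lower) tail window sets of a statistic, ties included."""
    defined = scan[scan[statistic].notna()]
    if defined.empty:
        return set(), set()
    k = math.ceil(tail_fraction * len(defined))
    upper_cut = defined[statistic].nlargest(k).iloc[-1]
    lower_cut = defined[statistic].nsmallest(k).iloc[-1]
    upper = set(_window_keys(defined[defined[statistic] >= upper_cut]))
    lower = set(_window_keys(defined[defined[statistic] <= lower_cut]))
    return upper, lower


def shared_across_comparisons(window_sets: dict[str, set[WindowKey]],
                              min_share: float = 0.5) -> pd.DataFrame:
    """Windows present in at least ceil(min_share * K) of K comparisons.

    Returns a DataFrame with window coordinates, the supporting populations
    and the shared fraction.
    """
    if len(window_sets) < 2:
        raise ValueError("need at least two comparisons")
    k = len(window_sets)
    need = math.ceil(min_share * k)
    counter: dict[WindowKey, list[str]] = {}
    for pop, ws in window_sets.items():
        for w in ws:
            counter.setdefault(w, []).append(pop)
    rows = [{"chrom": w[0], "start": w[1], "end": w[2],
             "populations_supporting": ",".join(sorted(pops)),
             "n_supporting": len(pops), "shared_fraction": len(pops) / k}
            for w, pops in counter.items() if len(pops) >= need]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                     "populations_supporting",
                                     "n_supporting", "shared_fraction"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def call_convergent_windows(scans: dict[str, pd.DataFrame],
                            cfg: ConvergenceConfig | None = None
                            ) -> dict[str, pd.DataFrame]:
    """Per-method convergent window calls from all pairwise scans.

    Returns ``{"fst": ..., "pi_ratio": ..., "tajima_diff": ...}`` shared-call
    tables.  With ``cfg.tails == "union"`` both tails of the pi-ratio and
    D-difference distributions are eligible; with ``"sweep"`` only the
    commercial-sweep direction (upper tail of log2(pi_ind/pi_com), upper
    tail of D_ind - D_com) is used.
    """
    cfg = cfg or ConvergenceConfig()
    filtered = {pop: filter_min_snps(scan, cfg.min_snps_per_window)
                for pop, scan in scans.items()}
    fst_sets = {pop: select_top_fst(s, cfg.top_fst_fraction)
                for pop, s in filtered.items()}
    pi_sets, d_sets = {}, {}
    for pop, s in filtered.items():
        up, lo = select_tails(s, "log2_pi_ratio", cfg.tail_fraction)
        pi_sets[pop] = up if cfg.tails == "sweep" else up | lo
        up, lo = select_tails(s, "d_diff", cfg.tail_fraction)
        d_sets[pop] = up if cfg.tails == "sweep" else up | lo
    return {
        "fst": shared_across_comparisons(fst_sets, cfg.min_share),
        "pi_ratio": shared_across_comparisons(pi_sets, cfg.min_share),
        "tajima_diff": shared_across_comparisons(d_sets, cfg.min_share),
    }


# ---------------------------------------------------------------------------
# Interval / gene overlap
# ---------------------------------------------------------------------------

def intervals_overlap(start_a: int, end_a: int,
                      start_b: int, end_b: int) -> bool:
    """Closed-interval intersection: max(starts) <= min(ends)."""
    return max(start_a, start_b) <= min(end_a, end_b)


def overlap_genes(intervals: pd.DataFrame,
                  genes: list[GeneRecord]) -> dict[str, list[WindowKey]]:
    """Map gene_id -> supporting intervals (1-based inclusive both sides).

    ``intervals`` needs chrom/start/end columns.  Sort-based sweep per
    chromosome; equivalent to the all-pairs closed-interval test.
    """
    result: dict[str, list[WindowKey]] = {}
    if intervals.empty:
        return result
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        by_chrom[chrom] = arr[np.argsort(arr[:, 0])]
    for gene in genes:
        arr = by_chrom.get(gene.chrom)
        if arr is None:
            continue
        # candidate intervals: start <= gene.end, end >= gene.start
        hi = np.searchsorted(arr[:, 0], gene.end, side="right")
        hits = arr[:hi][arr[:hi, 1] >= gene.start]
        if len(hits):
            result[gene.gene_id] = [(gene.chrom, int(s), int(e))
                                    for s, e in hits]
    return result


def roh_gene_support(segments: pd.DataFrame, genes: list[GeneRecord],
                     sample_to_pop: dict[str, str],
                     populations: list[str],
                     min_carriers: int = 1,
                     min_pop_share: float = 0.5) -> set[str]:
    """Genes supported by the ROH method.

    Per population a gene is ROH-covered when >= ``min_carriers``
    individuals carry a segment overlapping its span; the method supports
    the gene when it is covered in >= ceil(min_pop_share * n_pops) of
    ``populations``.
    """
    need_pops = math.ceil(min_pop_share * len(populations))
    if segments.empty:
        return set()
    seg = segments.copy()
    seg["population"] = seg["sample"].map(sample_to_pop)
    seg = seg[seg["population"].isin(populations)]
    supported = set()
    for gene in genes:
        on_chrom = seg[seg["chrom"] == gene.chrom]
        hits = on_chrom[(on_chrom["start"] <= gene.end)
                        & (on_chrom["end"] >= gene.start)]
        pops_covering = 0
        for _, grp in hits.groupby("population"):
            if grp["sample"].nunique() >= min_carriers:
                pops_covering += 1
        if pops_covering >= need_pops:
            supported.add(gene.gene_id)
    return supported


# ---------------------------------------------------------------------------
# Gene evidence aggregation
# ---------------------------------------------------------------------------

METHODS = ("fst", "pi_ratio", "tajima_diff", "roh")


def aggregate_gene_evidence(
        method_gene_sets: dict[str, set[str]],
        genes: list[GeneRecord],
        near_fixed_counts: dict[str, int] | None = None,
        min_methods: int = 3) -> pd.DataFrame:
    """Gene-level evidence table and candidate calls.

    ``method_gene_sets`` maps each of the four method names to its supported
    gene_id set; ``near_fixed_counts`` maps gene_id -> number of
    consistently near-fixed SNPs (FDR-significant).  A gene is a candidate
    iff n_methods >= min_methods or near_fixed_snps >= 1.  Every gene
    touched by at least one method or fixation evidence gets a row.
    """
    unknown = set(method_gene_sets) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    near_fixed_counts = near_fixed_counts or {}
    by_id = {g.gene_id: g for g in genes}
    touched = set().union(*method_gene_sets.values()) if method_gene_sets else set()
    touched |= {g for g, c in near_fixed_counts.items() if c > 0}
    rows = []
    for gid in sorted(touched):
        methods = sorted(m for m in METHODS
                         if gid in method_gene_sets.get(m, set()))
        nf = int(near_fixed_counts.get(gid, 0))
        gene = by_id.get(gid)
        rows.append({
            "gene_id": gid,
            "gene_name": gene.gene_name if gene else None,
            "chrom": gene.chrom if gene else None,
            "start": gene.start if gene else None,
            "end": gene.end if gene else None,
            "methods": ",".join(methods),
            "n_methods": len(methods),
            "near_fixed_snps": nf,
            "candidate": len(methods) >= min_methods or nf >= 1,
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "gene_name", "chrom", "start", "end",
        "methods", "n_methods", "near_fixed_snps", "candidate"])
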