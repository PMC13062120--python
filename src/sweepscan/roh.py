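"""Runs of homozygosity with PLINK ``--homozyg`` scanning-window semantics.

The detector works per sample and per chromosome on position-sorted diploid
dosages:

1. every 50-SNP sliding scan window (step one SNP) is a *hit* iff it contains
   at most ``max_het_in_window`` heterozygous and ``max_missing_in_window``
   missing calls;
2. a SNP is ROH-eligible iff the fraction of scan windows overlapping it that
   are hits is >= ``hit_threshold`` (edge SNPs overlap fewer windows);
3. maximal runs of consecutive eligible SNPs are split where the inter-SNP
   gap exceeds ``max_gap_kb``, then kept iff span >= ``min_kb``, SNP count >=
   ``min_snps_in_run`` and average spacing (span_kb / n_snps) <=
   ``min_density_kb_per_snp``.

Chromosomes with fewer SNPs than the scan window are evaluated with a single
truncated window (a documented divergence risk from PLINK edge behaviour).
Also provided: the method-of-moments inbreeding coefficient from observed vs
expected homozygosity (PLINK ``--het``) and the ROH-based coefficient F_ROH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class RohParams:
    """PLINK --homozyg thresholds (defaults mirror PLINK v1.9)."""

    min_kb: float = 300.0
    scan_window_snps: int = 50
    max_het_in_window: int = 3
    max_missing_in_window: int = 3
    hit_threshold: float = 0.05
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 100.0
    min_snps_in_run: int = 100

    def __post_init__(self) -> None:
        if min(self.min_kb, self.scan_window_snps, self.max_gap_kb,
               self.min_density_kb_per_snp, self.min_snps_in_run) <= 0:
            raise ValueError("RohParams: size/count parameters must be positive")
        if not 0.0 < self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must be in (0, 1]")


# length classes: short < 1 Mb, medium 1 to < 3 Mb, long >= 3 Mb
def length_class(length_kb: float) -> str:
    if length_kb < 1000.0:
        return "short"
    if length_kb < 3000.0:
        return "medium"
    return "long"


def scan_window_verdicts(dosages: np.ndarray,
                         params: RohParams) -> np.ndarray:
    """Hit verdict per scan window for one sample's chromosome.

    ``dosages`` is a position-sorted int vector (0/1/2, MISSING = -1).
    Returns a boolean array of length ``max(1, n - window + 1)``; with fewer
    SNPs than the window a single truncated window is evaluated.
    """
    d = np.asarray(dosages)
    het = (d == 1).astype(np.int32)
    mis = (d == MISSING).astype(np.int32)
    w = params.scan_window_snps
    if len(d) == 0:
        return np.zeros(0, dtype=bool)
    if len(d) < w:
        return np.array([het.sum() <= params.max_het_in_window
                         and mis.sum() <= params.max_missing_in_window])
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    het_w = ch[w:] - ch[:-w]
    mis_w = cm[w:] - cm[:-w]
    return (het_w <= params.max_het_in_window) & (mis_w <= params.max_missing_in_window)


def snp_hit_rates(n_snps: int, verdicts: np.ndarray,
                  params: RohParams) -> np.ndarray:
    """Per-SNP fraction of overlapping scan windows that are hits."""
    w = params.scan_window_snps
    if n_snps == 0:
        return np.zeros(0)
    if n_snps < w:
        # single truncated window covers every SNP
        return np.full(n_snps, 1.0 if verdicts[0] else 0.0)
    n_win = len(verdicts)
    hits = np.concatenate([[0], np.cumsum(verdicts.astype(np.int64))])
    k = np.arange(n_snps)
    first = np.maximum(0, k - w + 1)
    last = np.minimum(n_win - 1, k)
    n_overlap = last - first + 1
    n_hit = hits[last + 1] - hits[first]
    return n_hit / n_overlap


def call_roh_segments_for_sample(positions: np.ndarray, dosages: np.ndarray,
                                 sample: str, chrom: str,
                                 params: RohParams) -> list[dict]:
    """ROH segments for one sample on one chromosome."""
    verdicts = scan_window_verdicts(dosages, params)
    rates = snp_hit_rates(len(dosages), verdicts, params)
    eligible = rates >= params.hit_threshold
    segments = []
    for run_start, run_end in _runs(eligible):
        # split runs at gaps exceeding max_gap_kb
        for a, b in _split_at_gaps(positions, run_start, run_end,
                                   params.max_gap_kb * 1000.0):
            start_bp = int(positions[a])
            end_bp = int(positions[b])
            n = b - a + 1
            length_kb = (end_bp - start_bp + 1) / 1000.0
            if length_kb < params.min_kb:
                continue
            if n < params.min_snps_in_run:
                continue
            if length_kb / n > params.min_density_kb_per_snp:
                continue
            segments.append({
                "sample": sample, "chrom": chrom,
                "start": start_bp, "end": end_bp,
                "n_snps": n, "length_kb": length_kb,
                "length_class": length_class(length_kb),
            })
    return segments


def _runs(mask: np.ndarray):
    """Yield (first, last) index pairs of maximal True runs."""
    if len(mask) == 0:
        return
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    yield from zip(starts, ends)


def _split_at_gaps(positions: np.ndarray, first: int, last: int,
                   max_gap_bp: float):
    """Split the index run [first, last] where adjacent SNP gaps exceed max."""
    a = first
    for k in range(first, last):
        if positions[k + 1] - positions[k] > max_gap_bp:
            yield a, k
            a = k + 1
    yield a, last


def call_roh(gm: GenotypeMatrix, samples: list[str] | None = None,
             params: RohParams | None = None) -> pd.DataFrame:
    """ROH segments for a cohort; mirrors PLINK .hom columns."""
    params = params or RohParams()
    samples = samples if samples is not None else list(gm.samples)
    idx = gm.sample_indices(samples)
    out: list[dict] = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        positions = grp["pos"].to_numpy()
        for name, j in zip(samples, idx):
            out.extend(call_roh_segments_for_sample(
                positions, gm.dosage[rows][:, j], name, chrom, params))
    return pd.DataFrame(
        out, columns=["sample", "chrom", "start", "end",
                      "n_snps", "length_kb", "length_class"])


# ---------------------------------------------------------------------------
# Inbreeding coefficients
# ---------------------------------------------------------------------------

def inbreeding_from_het(gm: GenotypeMatrix,
                        cohort: list[str] | None = None) -> pd.DataFrame:
    """Method-of-moments F per sample: (O(hom) - E(hom)) / (N - E(hom)).

    E(hom) at a site is 1 - 2 p (1 - p) n/(n - 1), with p the cohort ALT
    frequency and n the cohort called allele count; summed over the sites
    where the sample has a call (PLINK ``--het`` semantics).
    """
    cohort = cohort if cohort is not None else list(gm.samples)
    idx = gm.sample_indices(cohort)
    d = gm.dosage[:, idx]
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=1).astype(np.float64)
    n = 2.0 * called.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n
        e_hom_site = 1.0 - 2.0 * p * (1.0 - p) * n / (n - 1.0)
    usable = n >= 2
    rows = []
    for name, j in zip(cohort, idx):
        has_call = called[:, j] & usable
        n_sites = int(has_call.sum())
        obs_hom = int(((d[:, j] == 0) | (d[:, j] == 2))[has_call].sum())
        exp_hom = float(e_hom_site[has_call].sum())
        denom = n_sites - exp_hom
        f = (obs_hom - exp_hom) / denom if denom != 0 else float("nan")
        rows.append({"sample": name, "observed_hom": obs_hom,
                     "expected_hom": exp_hom, "n_nonmissing": n_sites,
                     "f_het": f})
    return pd.DataFrame(rows)


def f_roh(segments: pd.DataFrame, genome_length_bp: float,
          sample: str | None = None) -> float:
    """Fraction of the genome covered by ROH segments."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    seg = segments if sample is None else segments[segments["sample"] == sample]
    if len(seg) == 0:
        return 0.0
    total = float((seg["end"] - seg["start"] + 1).sum())
    return total / genome_length_bp


def snp_span_genome_length(gm: GenotypeMatrix) -> float:
    """Sum over chromosomes of the span between first and last SNP.

    Default F_ROH denominator when assembly lengths are not supplied.
    """
    total = 0.0
    for _, grp in gm.sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos):
            total += float(pos[-1] - pos[0] + 1)
    return total
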