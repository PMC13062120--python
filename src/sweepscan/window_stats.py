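"""Sliding-window selection statistics: nucleotide diversity, Tajima's D, FST.

The engine tiles each chromosome with fixed-size windows (default 100 kb,
10 kb step; only full windows are emitted, anchored at position 1) and, for a
commercial-indigenous population pair, computes per window:

* ``pi`` per population — the sum over sites of the unbiased per-site
  heterozygosity 2 j (n - j) / (n (n - 1)) where j is the ALT allele count
  and n the called allele count (window *sums*, the PopGenome convention;
  any shared per-bp normalization cancels in the ratio);
* Tajima's D per population — D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1)),
  with the sample size for the constants taken as the median called allele
  count over the window's segregating sites (missing data makes n vary);
* window FST — Hudson's estimator as a ratio of averages of the per-site
  numerator/denominator components (Weir & Cockerham selectable);
* the two derived contrasts used for convergence filtering:
  log2(pi_indigenous / pi_commercial) and D_indigenous - D_commercial.

Undefined values (no data, zero diversity ratio, non-positive variance)
propagate as NaN, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, PopulationMap

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_STEP = 10_000
MIN_N_FOR_TAJIMA_D = 4  # minimum haplotypes before D is attempted


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowGrid:
    """Full sliding windows per chromosome, 1-based inclusive."""

    window_size: int
    step: int
    windows: dict[str, np.ndarray] = field(default_factory=dict)
    # windows[chrom] is an (n, 2) int array of [start, end]

    def n_windows(self) -> int:
        return sum(len(w) for w in self.windows.values())


def make_windows(chrom_lengths: dict[str, int],
                 window_size: int = DEFAULT_WINDOW_SIZE,
                 step: int = DEFAULT_STEP) -> WindowGrid:
    """Tile chromosomes with full windows: start_k = 1 + (k-1)*step."""
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    grid = {}
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom}: length must be >= 1")
        n = (length - window_size) // step + 1 if length >= window_size else 0
        starts = 1 + step * np.arange(n, dtype=np.int64)
        grid[chrom] = np.column_stack([starts, starts + window_size - 1])
    return WindowGrid(window_size=window_size, step=step, windows=grid)


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------

def site_pi(alt_count, called_alleles):
    """Unbiased per-site diversity: fraction of differing haplotype pairs.

    2 j (n - j) / (n (n - 1)); NaN when n < 2.  Vectorized.
    """
    j = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(called_alleles, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def site_fst_hudson(p1, n1, p2, n2):
    """Hudson FST per-site components (numerator, denominator).

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    n1/n2 are called allele counts; sites with n <= 1 in either population
    must be excluded by the caller.  Vectorized.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    num = ((p1 - p2) ** 2
           - p1 * (1.0 - p1) / (n1 - 1.0)
           - p2 * (1.0 - p2) / (n2 - 1.0))
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


def _wc_components(dosage_1: np.ndarray, dosage_2: np.ndarray):
    """Weir & Cockerham a, b, c per site from diploid dosage slices.

    dosage_i: (sites, samples) int arrays with MISSING = -1.
    Follows the r = 2 population form of Weir & Cockerham (1984) including
    the observed-heterozygosity correction.
    """
    comps = []
    for d in (dosage_1, dosage_2):
        called = d != MISSING
        n_ind = called.sum(axis=1).astype(np.float64)           # diploids
        alt = np.where(called, d, 0).sum(axis=1).astype(np.float64)
        het = ((d == 1) & called).sum(axis=1).astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / (2.0 * n_ind)
            h = het / n_ind
        comps.append((n_ind, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (p_bar * (1 - p_bar)
                                       - (r - 1.0) / r * s2
                                       - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    usable = (n1 >= 1) & (n2 >= 1) & (n_bar > 1)
    return a, b, c, usable


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Closed-form constants of Tajima's D for n sampled haplotypes."""
    if n < 2:
        raise ValueError("Tajima constants require n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_summaries(pi_sum: float, s: int, n: int) -> float:
    """Tajima's D from a window's pi sum, segregating-site count and n.

    NaN when S = 0, n below the minimum, or the variance term is not
    positive.
    """
    if s <= 0 or n < MIN_N_FOR_TAJIMA_D:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_sum - s / k["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Pair scan
# ---------------------------------------------------------------------------

def _pop_site_arrays(gm: GenotypeMatrix, sample_idx: np.ndarray):
    """(alt_count, called_alleles) per site for one population."""
    d = gm.dosage[:, sample_idx]
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=1).astype(np.int64)
    n = 2 * called.sum(axis=1).astype(np.int64)
    return alt, n


def _window_slices(positions: np.ndarray, windows: np.ndarray):
    """Half-open [lo, hi) index ranges of sites falling in each window."""
    lo = np.searchsorted(positions, windows[:, 0], side="left")
    hi = np.searchsorted(positions, windows[:, 1], side="right")
    return lo, hi


def _cumsum_window(values: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    c = np.concatenate([[0.0], np.cumsum(values, dtype=np.float64)])
    return c[hi] - c[lo]


def compute_pair_scan(gm: GenotypeMatrix, pmap: PopulationMap,
                      indigenous_pop: str, commercial_pop: str,
                      grid: WindowGrid,
                      fst_estimator: str = "hudson",
                      clamp_negative_fst: bool = False) -> pd.DataFrame:
    """One WindowStat row per window for an indigenous-commercial pair.

    Returns a DataFrame with columns ``chrom, start, end, n_snps, pi_ind,
    pi_com, d_ind, d_com, fst, log2_pi_ratio, d_diff``.  ``n_snps`` counts
    sites segregating in the pooled pair.  Negative FST values are reported
    as computed unless ``clamp_negative_fst``.
    """
    if fst_estimator not in ("hudson", "weir_cockerham"):
        raise ValueError(f"unknown FST estimator: {fst_estimator}")
    idx_ind = gm.sample_indices(pmap.samples_of(indigenous_pop))
    idx_com = gm.sample_indices(pmap.samples_of(commercial_pop))

    alt_i, n_i = _pop_site_arrays(gm, idx_ind)
    alt_c, n_c = _pop_site_arrays(gm, idx_com)
    pi_i = np.nan_to_num(site_pi(alt_i, n_i), nan=0.0)
    pi_c = np.nan_to_num(site_pi(alt_c, n_c), nan=0.0)
    seg_i = (alt_i > 0) & (alt_i < n_i)
    seg_c = (alt_c > 0) & (alt_c < n_c)
    alt_pool, n_pool = alt_i + alt_c, n_i + n_c
    seg_pool = (alt_pool > 0) & (alt_pool < n_pool)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = np.where(n_i > 0, alt_i / n_i, np.nan)
        p_c = np.where(n_c > 0, alt_c / n_c, np.nan)

    if fst_estimator == "hudson":
        usable = (n_i >= 2) & (n_c >= 2)
        num = np.zeros(gm.n_sites)
        den = np.zeros(gm.n_sites)
        if usable.any():
            nu, de = site_fst_hudson(p_i[usable], n_i[usable],
                                     p_c[usable], n_c[usable])
            num[usable], den[usable] = nu, de
    else:
        a, b, c, usable = _wc_components(gm.dosage[:, idx_ind],
                                         gm.dosage[:, idx_com])
        num = np.where(usable, a, 0.0)
        den = np.where(usable, a + b + c, 0.0)
        num, den = np.nan_to_num(num), np.nan_to_num(den)

    rows = []
    for chrom, windows in grid.windows.items():
        chrom_mask = (gm.sites["chrom"] == chrom).to_numpy()
        pos = gm.sites["pos"].to_numpy()[chrom_mask]
        if len(windows) == 0:
            continue
        lo, hi = _window_slices(pos, windows)

        def w(values):
            return _cumsum_window(np.asarray(values, dtype=np.float64)[chrom_mask],
                                  lo, hi)

        n_snps = w(seg_pool).astype(np.int64)
        wpi_i = w(pi_i)
        wpi_c = w(pi_c)
        s_ind = w(seg_i).astype(np.int64)
        s_com = w(seg_c).astype(np.int64)
        wnum = w(num)
        wden = w(den)
        called_any = w((n_i + n_c) > 0).astype(np.int64)

        with np.errstate(divide="ignore", invalid="ignore"):
            fst = wnum / wden
        fst = np.where(wden > 0, fst, np.nan)
        if clamp_negative_fst:
            fst = np.where(np.isnan(fst), fst, np.clip(fst, 0.0, 1.0))

        # Tajima's D per population: n = median called alleles over the
        # window's segregating sites
        d_ind = np.full(len(windows), np.nan)
        d_com = np.full(len(windows), np.nan)
        n_i_chr = n_i[chrom_mask]
        n_c_chr = n_c[chrom_mask]
        seg_i_chr = seg_i[chrom_mask]
        seg_c_chr = seg_c[chrom_mask]
        pi_i_chr = pi_i[chrom_mask]
        pi_c_chr = pi_c[chrom_mask]
        for k in range(len(windows)):
            sl = slice(lo[k], hi[k])
            for (seg_chr, n_chr, pi_chr, out) in (
                    (seg_i_chr, n_i_chr, pi_i_chr, d_ind),
                    (seg_c_chr, n_c_chr, pi_c_chr, d_com)):
                segs = seg_chr[sl]
                s = int(segs.sum())
                if s == 0:
                    continue
                n_med = int(np.median(n_chr[sl][segs]))
                out[k] = tajimas_d_from_summaries(
                    float(pi_chr[sl][segs].sum()), s, n_med)

        # windows with no called genotypes at all: pi undefined, not zero
        wpi_i = np.where(called_any > 0, wpi_i, np.nan)
        wpi_c = np.where(called_any > 0, wpi_c, np.nan)

        with np.errstate(divide="ignore", invalid="ignore"):
            log2_ratio = np.log2(wpi_i / wpi_c)
        log2_ratio = np.where((wpi_i > 0) & (wpi_c > 0), log2_ratio, np.nan)

        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": windows[:, 0],
            "end": windows[:, 1],
            "n_snps": n_snps,
            "pi_ind": wpi_i,
            "pi_com": wpi_c,
            "s_ind": s_ind,
            "s_com": s_com,
            "d_ind": d_ind,
            "d_com": d_com,
            "fst": fst,
            "log2_pi_ratio": log2_ratio,
            "d_diff": d_ind - d_com,
        }))
    if not rows:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "n_snps", "pi_ind", "pi_com",
            "s_ind", "s_com", "d_ind", "d_com", "fst",
            "log2_pi_ratio", "d_diff"])
    return pd.concat(rows, ignore_index=True)


def compute_all_pair_scans(gm: GenotypeMatrix, pmap: PopulationMap,
                           grid: WindowGrid,
                           fst_estimator: str = "hudson",
                           ) -> dict[str, pd.DataFrame]:
    """Scan every indigenous population against the commercial one."""
    com = pmap.commercial_population
    return {pop: compute_pair_scan(gm, pmap, pop, com, grid,
                                   fst_estimator=fst_estimator)
            for pop in pmap.indigenous_populations}
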