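"""Multi-population genotype simulator with known injected sweeps.

The generator emulates the study design the pipeline targets: one commercial
population with extra drift versus several indigenous populations, related
through a Balding-Nichols island model.  Per site an ancestral frequency is
drawn from Uniform(0.05, 0.95) and each population's frequency from
Beta(p (1-F)/F, (1-p) (1-F)/F), with F = ``global_fst`` for indigenous
populations and ``global_fst + commercial_extra_fst`` for the commercial
one.  Selective sweeps are injected by setting the target population's
allele frequency inside each sweep interval to ``final_af`` (polarity
randomized per site), which simultaneously produces high window FST,
collapsed diversity, an excess of rare variants (negative Tajima's D) and
near-fixed alleles -- the full signature the pipeline is built to detect.

Genotypes are drawn site-wise under Hardy-Weinberg equilibrium with free
recombination between sites (no linkage), which keeps the generator fast
and dependency-free; the realism limits of that choice are documented in
the methods note.  All randomness flows from the single seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_core import GenotypeMatrix, PopulationMap, write_bed, write_vcf
import pandas as pd

# Default sweep width (bp).  Three sweeps of this width on the default 5 Mb
# chromosome keep the truth-window footprint within the detection budget of
# the paper-prescribed tail fractions (top 5% FST, 2.5% tails) while leaving
# enough swept SNPs for the fixation-consistency signal; see the methods
# note for the power analysis behind this value.
DEFAULT_SWEEP_WIDTH = 20_000

COMMERCIAL_POP = "commercial"


@dataclass(frozen=True)
class Sweep:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    target_pop: str = COMMERCIAL_POP
    final_af: float = 0.995

    def __post_init__(self) -> None:
        if not 0.5 < self.final_af <= 1.0:
            raise ValueError("final_af must be in (0.5, 1]")
        if self.start > self.end:
            raise ValueError("sweep start > end")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pops_indigenous: int = 4
    diploids_per_pop: int = 25
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000})
    snp_density: float = 1.0       # mean SNPs per kb
    global_fst: float = 0.05
    commercial_extra_fst: float = 0.15
    sweeps: list[Sweep] | None = None   # None -> three default sweeps
    n_genes: int = 50
    gene_min_bp: int = 5_000
    gene_max_bp: int = 50_000

    def __post_init__(self) -> None:
        if not 0.0 < self.global_fst < 1.0:
            raise ValueError("global_fst must be in (0, 1)")
        if self.sweeps is None:
            self.sweeps = default_sweeps(self.chrom_lengths)
        for sw in self.sweeps:
            length = self.chrom_lengths.get(sw.chrom)
            if length is None or sw.end > length or sw.start < 1:
                raise ValueError(f"sweep outside chromosome: {sw}")
        _check_no_overlap(self.sweeps)

    @property
    def populations(self) -> list[str]:
        return [COMMERCIAL_POP] + [f"indigenous_{i + 1}"
                                   for i in range(self.n_pops_indigenous)]


def default_sweeps(chrom_lengths: dict[str, int],
                   width: int = DEFAULT_SWEEP_WIDTH,
                   final_af: float = 0.995) -> list[Sweep]:
    """Three commercial-population sweeps at 1/4, 1/2 and 3/4 of the first
    chromosome, aligned to the 10 kb window step."""
    chrom, length = next(iter(chrom_lengths.items()))
    sweeps = []
    for frac in (0.25, 0.5, 0.75):
        start = int(frac * length) // 10_000 * 10_000 + 1
        sweeps.append(Sweep(chrom=chrom, start=start,
                            end=start + width - 1, final_af=final_af))
    return sweeps


def _check_no_overlap(sweeps: list[Sweep]) -> None:
    by_pop: dict[tuple[str, str], list[Sweep]] = {}
    for sw in sweeps:
        by_pop.setdefault((sw.target_pop, sw.chrom), []).append(sw)
    for key, group in by_pop.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping sweeps for {key[0]} on {key[1]}: {a} / {b}")


@dataclass
class TruthSet:
    """Ground truth of a simulation run, for recovery testing."""

    sweeps: list[Sweep]
    positions: dict[str, np.ndarray]            # chrom -> 1-based positions
    ancestral_freqs: dict[str, np.ndarray]      # chrom -> per-site p
    pop_freqs: dict[str, dict[str, np.ndarray]]  # chrom -> pop -> per-site f
    genes: "pd.DataFrame | None" = None          # toy gene table
    sweep_gene_ids: dict[int, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Frequency model
# ---------------------------------------------------------------------------

def draw_site_frequencies(cfg: SimulationConfig,
                          rng: np.random.Generator) -> TruthSet:
    """Draw SNP positions, ancestral and per-population frequencies."""
    positions: dict[str, np.ndarray] = {}
    ancestral: dict[str, np.ndarray] = {}
    pop_freqs: dict[str, dict[str, np.ndarray]] = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_sites = rng.poisson(cfg.snp_density * length / 1000.0)
        n_sites = min(n_sites, length)
        pos = np.sort(rng.choice(length, size=n_sites, replace=False) + 1)
        p = rng.uniform(0.05, 0.95, size=n_sites)
        freqs: dict[str, np.ndarray] = {}
        for pop in cfg.populations:
            f = cfg.global_fst
            if pop == COMMERCIAL_POP:
                f += cfg.commercial_extra_fst
            ratio = (1.0 - f) / f
            freqs[pop] = rng.beta(p * ratio, (1.0 - p) * ratio)
        positions[chrom] = pos
        ancestral[chrom] = p
        pop_freqs[chrom] = freqs
    return TruthSet(sweeps=list(cfg.sweeps), positions=positions,
                    ancestral_freqs=ancestral, pop_freqs=pop_freqs)


def inject_sweeps(truth: TruthSet, cfg: SimulationConfig,
                  rng: np.random.Generator) -> TruthSet:
    """Set target-population frequencies inside each sweep interval.

    Polarity is randomized per site: the swept allele is ALT (frequency
    ``final_af``) or REF (ALT frequency ``1 - final_af``) with equal
    probability.  Non-target populations are untouched.
    """
    for sw in truth.sweeps:
        pos = truth.positions[sw.chrom]
        mask = (pos >= sw.start) & (pos <= sw.end)
        n = int(mask.sum())
        polarity = rng.random(n) < 0.5
        swept = np.where(polarity, sw.final_af, 1.0 - sw.final_af)
        truth.pop_freqs[sw.chrom][sw.target_pop][mask] = swept
    return truth


# ---------------------------------------------------------------------------
# Genotypes, genes, emission
# ---------------------------------------------------------------------------

def sample_genotype_matrix(cfg: SimulationConfig, truth: TruthSet,
                           rng: np.random.Generator
                           ) -> tuple[GenotypeMatrix, PopulationMap]:
    """Draw HWE genotypes Binomial(2, pop frequency) site-wise."""
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for pop in cfg.populations:
        for k in range(cfg.diploids_per_pop):
            name = f"{pop}_{k + 1:03d}"
            samples.append(name)
            assignments[name] = pop
    roles = {pop: ("commercial" if pop == COMMERCIAL_POP else "indigenous")
             for pop in cfg.populations}
    pmap = PopulationMap(assignments=assignments, roles=roles)

    site_frames = []
    dosage_blocks = []
    for chrom in cfg.chrom_lengths:
        pos = truth.positions[chrom]
        n_sites = len(pos)
        block = np.empty((n_sites, len(samples)), dtype=np.int8)
        col = 0
        for pop in cfg.populations:
            f = truth.pop_freqs[chrom][pop]
            draws = rng.binomial(
                2, f[:, None], size=(n_sites, cfg.diploids_per_pop))
            block[:, col:col + cfg.diploids_per_pop] = draws
            col += cfg.diploids_per_pop
        dosage_blocks.append(block)
        site_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos.astype(np.int64),
            "ref": "A", "alt": "G", "site_id": None,
            "is_biallelic_snp": True}))
    sites = pd.concat(site_frames, ignore_index=True)
    dosage = (np.vstack(dosage_blocks) if dosage_blocks
              else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(sites=sites, samples=samples, dosage=dosage), pmap


def make_toy_genes(cfg: SimulationConfig, truth: TruthSet,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Toy gene table; at least one gene sits fully inside each sweep."""
    rows = []
    gid = 0
    for i, sw in enumerate(truth.sweeps):
        # the anchored truth gene spans the whole swept interval (bounded by
        # the configured gene size range) so gene-level recovery is
        # well-defined regardless of where inside the sweep the signal sits
        width = sw.end - sw.start + 1
        glen = int(np.clip(width, cfg.gene_min_bp, cfg.gene_max_bp))
        offset = 0 if glen >= width else int(rng.integers(0, width - glen + 1))
        gid += 1
        rows.append({"gene_id": f"gene{gid:03d}", "chrom": sw.chrom,
                     "start": sw.start + offset,
                     "end": sw.start + offset + glen - 1,
                     "strand": "+", "sweep_index": i})
        truth.sweep_gene_ids.setdefault(i, []).append(f"gene{gid:03d}")
    chroms = list(cfg.chrom_lengths)
    lengths = [cfg.chrom_lengths[c] for c in chroms]
    total = sum(lengths)
    while gid < cfg.n_genes:
        gid += 1
        c = chroms[int(rng.choice(len(chroms),
                                  p=np.asarray(lengths) / total))]
        glen = int(rng.integers(cfg.gene_min_bp, cfg.gene_max_bp + 1))
        start = int(rng.integers(1, cfg.chrom_lengths[c] - glen + 1))
        rows.append({"gene_id": f"gene{gid:03d}", "chrom": c,
                     "start": start, "end": start + glen - 1,
                     "strand": "+" if rng.random() < 0.5 else "-",
                     "sweep_index": -1})
    genes = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    truth.genes = genes
    return genes


def write_gtf(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; gene_name "{row.gene_id}";'
            fh.write("\t".join([
                row.chrom, "sweepscan_sim", "gene", str(int(row.start)),
                str(int(row.end)), ".", row.strand, ".", attrs]) + "\n")


def write_population_map(pmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, pop in pmap.assignments.items():
            fh.write(f"{sample}\t{pop}\t{pmap.roles[pop]}\n")


def simulate(cfg: SimulationConfig
             ) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame, TruthSet]:
    """Run the full generator in memory: frequencies, sweeps, genotypes,
    toy genes.  Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    truth = draw_site_frequencies(cfg, rng)
    truth = inject_sweeps(truth, cfg, rng)
    gm, pmap = sample_genotype_matrix(cfg, truth, rng)
    genes = make_toy_genes(cfg, truth, rng)
    return gm, pmap, genes, truth


def emit(cfg: SimulationConfig, out_dir: str | os.PathLike,
         vcf_name: str = "data.vcf") -> dict[str, str]:
    """Simulate and write data.vcf, genes.gtf, popmap.tsv, truth files."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    gm, pmap, genes, truth = simulate(cfg)
    paths = {
        "vcf": os.path.join(out_dir, vcf_name),
        "gtf": os.path.join(out_dir, "genes.gtf"),
        "popmap": os.path.join(out_dir, "popmap.tsv"),
        "truth_bed": os.path.join(out_dir, "truth_sweeps.bed"),
        "truth_json": os.path.join(out_dir, "truth_params.json"),
    }
    write_vcf(gm, paths["vcf"], contig_lengths=cfg.chrom_lengths)
    write_gtf(genes, paths["gtf"])
    write_population_map(pmap, paths["popmap"])
    write_bed([(s.chrom, s.start, s.end, f"sweep{i}")
               for i, s in enumerate(truth.sweeps)], paths["truth_bed"])
    with open(paths["truth_json"], "w") as fh:
        json.dump({
            "seed": cfg.seed,
            "populations": cfg.populations,
            "diploids_per_pop": cfg.diploids_per_pop,
            "chrom_lengths": cfg.chrom_lengths,
            "snp_density": cfg.snp_density,
            "global_fst": cfg.global_fst,
            "commercial_extra_fst": cfg.commercial_extra_fst,
            "sweeps": [asdict(s) for s in truth.sweeps],
            "sweep_gene_ids": truth.sweep_gene_ids,
            "n_sites": {c: int(len(p)) for c, p in truth.positions.items()},
        }, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# Truth helpers for recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(outdir: str | os.PathLike, truth: TruthSet,
                      grid) -> dict:
    """Score a pipeline run against the simulation truth.

    Reads the stage outputs under ``outdir`` and reports: the fraction of
    sweep-overlapping windows present in the union of the per-method
    convergent calls; how many sweeps have >= 1 anchored truth gene flagged
    candidate; the number of injected SNPs passing the > 70% consistency
    rule; and the false-positive rate among genes not overlapping any sweep.
    """
    outdir = str(outdir)
    truth_windows = sweep_overlapping_windows(grid, truth.sweeps)
    called: set[tuple] = set()
    for method in ("fst", "pi_ratio", "tajima_diff"):
        df = pd.read_csv(os.path.join(outdir, f"windows_{method}.tsv"),
                         sep="\t")
        called |= set(zip(df["chrom"], df["start"].astype(int),
                          df["end"].astype(int)))
    n_hit = len(called & truth_windows)

    evidence = pd.read_csv(os.path.join(outdir, "gene_evidence.tsv"), sep="\t")
    candidates = set(evidence.loc[evidence["candidate"], "gene_id"])
    sweeps_recovered = sum(
        1 for gids in truth.sweep_gene_ids.values()
        if any(g in candidates for g in gids))

    cons_path = os.path.join(outdir, "fixation_consistency.tsv")
    n_consistent_injected = 0
    if os.path.exists(cons_path):
        cons = pd.read_csv(cons_path, sep="\t")
        if len(cons):
            in_sweep = np.zeros(len(cons), dtype=bool)
            pos = cons["pos"].to_numpy()
            chrom = cons["chrom"].to_numpy()
            for sw in truth.sweeps:
                in_sweep |= ((chrom == sw.chrom) & (pos >= sw.start)
                             & (pos <= sw.end))
            n_consistent_injected = int(
                (cons["consistent"].to_numpy() & in_sweep).sum())

    genes = truth.genes
    def overlaps_sweep(row) -> bool:
        return any(row.chrom == sw.chrom
                   and max(row.start, sw.start) <= min(row.end, sw.end)
                   for sw in truth.sweeps)
    truth_gene_ids = {r.gene_id for r in genes.itertuples(index=False)
                      if overlaps_sweep(r)}
    null_genes = set(genes["gene_id"]) - truth_gene_ids
    fp = len(candidates - truth_gene_ids)
    return {
        "n_truth_windows": len(truth_windows),
        "n_truth_windows_called": n_hit,
        "window_recovery": n_hit / len(truth_windows) if truth_windows else float("nan"),
        "n_sweeps": len(truth.sweeps),
        "sweeps_with_candidate_gene": sweeps_recovered,
        "n_consistent_injected_snps": n_consistent_injected,
        "false_positive_gene_rate": fp / len(null_genes) if null_genes else 0.0,
        "n_candidate_genes": len(candidates),
    }


def sweep_overlapping_windows(grid, sweeps: list[Sweep]) -> set[tuple]:
    """Window keys (chrom, start, end) overlapping any sweep interval."""
    truth = set()
    for sw in sweeps:
        windows = grid.windows.get(sw.chrom)
        if windows is None:
            continue
        for start, end in windows:
            if max(start, sw.start) <= min(end, sw.end):
                truth.add((sw.chrom, int(start), int(end)))
    return truth
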