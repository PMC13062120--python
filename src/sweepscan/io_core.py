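"""Genotype data model, standard-format I/O, and per-genotype/per-site filters.

The central container is :class:`GenotypeMatrix`, a sites x samples grid of
diploid allele dosages (count of ALT copies, 0/1/2) with an explicit MISSING
state and optional per-call genotype quality (GQ) and depth (DP).  All
coordinates are 1-based inclusive throughout the package (the native VCF/GTF
convention); conversion to BED's 0-based half-open intervals is localized in
the BED writer.

Filtering follows VCFtools semantics: per-genotype masks (GQ/DP) are applied
first, then per-site filters (biallelic SNP, call rate, minor allele count)
see the already-masked calls.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1  # dosage code for an uncalled genotype; never conflated with 0


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class FilterConfig:
    """Site/genotype filter thresholds (VCFtools-style defaults)."""

    min_gq: int = 20
    min_dp: int = 8
    max_dp: int = 150
    max_missing_fraction: float = 0.1  # call rate >= 0.9
    min_minor_allele_count: int = 5
    biallelic_snps_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.min_dp > self.max_dp:
            raise ValueError("min_dp must be <= max_dp")


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    calls_masked: int = 0
    sites_non_biallelic_snp: int = 0
    sites_low_call_rate: int = 0
    sites_low_mac: int = 0

    @property
    def sites_removed(self) -> int:
        return (self.sites_non_biallelic_snp + self.sites_low_call_rate
                + self.sites_low_mac)


@dataclass
class GenotypeMatrix:
    """Diploid biallelic-SNP genotypes for a cohort.

    Attributes
    ----------
    sites:
        DataFrame with columns ``chrom, pos, ref, alt, site_id, is_biallelic_snp``,
        sorted by (chrom, pos), unique (chrom, pos).
    samples:
        Ordered sample identifiers.
    dosage:
        int8 array (n_sites, n_samples); count of ALT copies, ``MISSING`` (-1)
        for uncalled genotypes.  For retained non-biallelic records the dosage
        is meaningful only for allele indices 0/1; such records carry
        ``is_biallelic_snp == False`` and are dropped by the site filter.
    gq, dp:
        Optional per-call genotype quality / depth (same shape as dosage,
        -1 where absent), or None when the VCF carried no such FORMAT field.
    """

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n_sites, n_samples = self.dosage.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValueError("dosage grid does not match sites x samples")
        key = self.sites[["chrom", "pos"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate site {dup.chrom}:{dup.pos}")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("sites must be position-sorted within chromosome")

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def sample_indices(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.asarray([lookup[s] for s in names], dtype=np.intp)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[mask],
            gq=None if self.gq is None else self.gq[mask],
            dp=None if self.dp is None else self.dp[mask],
        )


@dataclass(frozen=True)
class PopulationMap:
    """Sample -> population assignment plus commercial/indigenous roles."""

    assignments: dict[str, str]
    roles: dict[str, str]  # population -> "commercial" | "indigenous"

    def __post_init__(self) -> None:
        bad = {p: r for p, r in self.roles.items()
               if r not in ("commercial", "indigenous")}
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        commercial = [p for p, r in self.roles.items() if r == "commercial"]
        if len(commercial) != 1:
            raise ValueError(
                f"exactly one commercial population required, got {commercial}")
        if not any(r == "indigenous" for r in self.roles.values()):
            raise ValueError("at least one indigenous population required")

    @property
    def commercial_population(self) -> str:
        return next(p for p, r in self.roles.items() if r == "commercial")

    @property
    def indigenous_populations(self) -> list[str]:
        return [p for p, r in self.roles.items() if r == "indigenous"]

    @property
    def populations(self) -> list[str]:
        return list(self.roles)

    def samples_of(self, population: str) -> list[str]:
        if population not in self.roles:
            raise KeyError(f"unknown population: {population}")
        return [s for s, p in self.assignments.items() if p == population]


@dataclass(frozen=True)
class GeneRecord:
    """One gene span, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, samples: list[str] | None = None,
             drop_non_snps: bool = False) -> GenotypeMatrix:
    """Read a VCF 4.x file (plain or bgzip) into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are retained by default (flagged via the
    ``is_biallelic_snp`` site column) so that :func:`apply_site_filters` can
    count them; pass ``drop_non_snps=True`` to discard them at load time.
    Phasing is ignored (``0|1`` is read as ``0/1``).  Haploid or >2-ploid
    genotype fields are rejected.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    if samples is not None:
        absent = sorted(set(samples) - set(reader.samples))
        if absent:
            raise KeyError(f"samples not present in VCF: {absent}")
        reader.set_samples(samples)
    sample_names = list(reader.samples)

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str | None] = []
    snp_flags: list[bool] = []
    dosage_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    has_gq = has_dp = False
    ploidy_checked = False

    for rec in reader:
        if not ploidy_checked and rec.genotypes:
            ploidy = len(rec.genotypes[0]) - 1  # last entry is the phased flag
            if ploidy != 2:
                raise FormatError(
                    f"diploid genotypes required, found ploidy {ploidy} "
                    f"at {rec.CHROM}:{rec.POS}")
            ploidy_checked = True
        alt_list = rec.ALT
        is_bsnp = (len(alt_list) == 1 and len(rec.REF) == 1
                   and len(alt_list[0]) == 1 and rec.is_snp)
        if drop_non_snps and not is_bsnp:
            continue
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(",".join(alt_list) if alt_list else ".")
        ids.append(rec.ID)
        snp_flags.append(is_bsnp)
        gt = rec.gt_types.astype(np.int8)  # 0,1,2 dosage; 3 = unknown
        gt[gt == 3] = MISSING
        dosage_rows.append(gt)
        for field, rows_out, flag in (("GQ", gq_rows, "gq"),
                                      ("DP", dp_rows, "dp")):
            try:
                vals = rec.format(field)
            except KeyError:
                vals = None
            if vals is None:
                rows_out.append(np.full(len(sample_names), -1, dtype=np.int32))
            else:
                col = vals[:, 0].astype(np.int64)
                col = np.where((col < 0) | (col > 2**31 - 2), -1, col)
                rows_out.append(col.astype(np.int32))
                if np.any(col >= 0):
                    if flag == "gq":
                        has_gq = True
                    else:
                        has_dp = True

    sites = pd.DataFrame({
        "chrom": chroms,
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": refs,
        "alt": alts,
        "site_id": ids,
        "is_biallelic_snp": np.asarray(snp_flags, dtype=bool),
    })
    n = len(sites)
    dosage = (np.vstack(dosage_rows) if n else
              np.empty((0, len(sample_names)), dtype=np.int8))
    gm = GenotypeMatrix(
        sites=sites,
        samples=sample_names,
        dosage=dosage,
        gq=np.vstack(gq_rows) if (n and has_gq) else None,
        dp=np.vstack(dp_rows) if (n and has_dp) else None,
    )
    # enforce position-sorted sites (keep chromosome file order)
    chrom_first = {c: i for i, c in enumerate(dict.fromkeys(gm.sites["chrom"]))}
    order = sorted(range(n), key=lambda i: (chrom_first[gm.sites["chrom"].iloc[i]],
                                            int(gm.sites["pos"].iloc[i])))
    if list(order) != list(range(n)):
        idx = np.asarray(order)
        gm = GenotypeMatrix(
            sites=gm.sites.iloc[idx].reset_index(drop=True),
            samples=gm.samples,
            dosage=gm.dosage[idx],
            gq=None if gm.gq is None else gm.gq[idx],
            dp=None if gm.dp is None else gm.dp[idx],
        )
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (plain text or .gz).

    Emits GT plus GQ/DP FORMAT fields when present on the matrix.  Genotypes
    are written unphased; dosage 0/1/2 maps to 0/0, 0/1, 1/1.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    has_gq, has_dp = gm.gq is not None, gm.dp is not None
    fmt = "GT" + (":GQ" if has_gq else "") + (":DP" if has_dp else "")

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(gm.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                     'Description="Genotype quality">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        sites = gm.sites
        for i in range(gm.n_sites):
            row = sites.iloc[i]
            calls = []
            for j in range(gm.n_samples):
                parts = [gt_str[int(gm.dosage[i, j])]]
                if has_gq:
                    v = int(gm.gq[i, j])
                    parts.append("." if v < 0 else str(v))
                if has_dp:
                    v = int(gm.dp[i, j])
                    parts.append("." if v < 0 else str(v))
                calls.append(":".join(parts))
            fh.write("\t".join([
                str(row.chrom), str(int(row.pos)),
                row.site_id if row.site_id else ".",
                row.ref, row.alt, ".", "PASS", ".", fmt, *calls]) + "\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_site_filters(
        gm: GenotypeMatrix,
        cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply per-genotype masking then per-site filters.

    Order (observable, e.g. a site whose low-GQ calls push missingness over
    threshold is dropped by the call-rate rule):

    1. calls with GQ < min_gq or DP outside [min_dp, max_dp] are set MISSING;
    2. non-biallelic-SNP sites dropped (when ``biallelic_snps_only``);
    3. sites with missing fraction > max_missing_fraction dropped;
    4. sites with minor allele count (over non-missing calls) < MAC dropped.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    if gm.n_sites == 0:
        return gm, report

    dosage = gm.dosage.copy()
    called = dosage != MISSING
    mask = np.zeros_like(called)
    if gm.gq is not None:
        mask |= called & (gm.gq >= 0) & (gm.gq < cfg.min_gq)
    if gm.dp is not None:
        mask |= called & (gm.dp >= 0) & ((gm.dp < cfg.min_dp) | (gm.dp > cfg.max_dp))
    report.calls_masked = int(mask.sum())
    dosage[mask] = MISSING

    gm = GenotypeMatrix(sites=gm.sites, samples=gm.samples, dosage=dosage,
                        gq=gm.gq, dp=gm.dp)

    keep = np.ones(gm.n_sites, dtype=bool)
    if cfg.biallelic_snps_only:
        bad = ~gm.sites["is_biallelic_snp"].to_numpy()
        report.sites_non_biallelic_snp = int(bad.sum())
        keep &= ~bad

    called = gm.dosage != MISSING
    missing_frac = 1.0 - called.sum(axis=1) / gm.n_samples
    bad = keep & (missing_frac > cfg.max_missing_fraction)
    report.sites_low_call_rate = int(bad.sum())
    keep &= ~bad

    alt = np.where(called, gm.dosage, 0).sum(axis=1)
    total = 2 * called.sum(axis=1)
    mac = np.minimum(alt, total - alt)
    bad = keep & (mac < cfg.min_minor_allele_count)
    report.sites_low_mac = int(bad.sum())
    keep &= ~bad

    return gm.subset_sites(keep), report


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_population_map(path: str | os.PathLike) -> PopulationMap:
    """Read a TSV population map: ``sample<TAB>population[<TAB>role]``.

    Roles default to ``indigenous``; marking any sample of a population
    ``commercial`` marks the population.  Conflicting roles for one
    population, duplicate samples, or zero commercial populations are errors.
    """
    assignments: dict[str, str] = {}
    roles: dict[str, str] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns")
            sample, pop = fields[0], fields[1]
            role = fields[2].strip().lower() if len(fields) == 3 else "indigenous"
            if sample in assignments:
                raise ValueError(f"duplicate sample in population map: {sample}")
            assignments[sample] = pop
            prev = roles.get(pop)
            if prev is not None and prev != role:
                raise ValueError(
                    f"population {pop} assigned conflicting roles "
                    f"{prev!r} and {role!r}")
            roles[pop] = role
    return PopulationMap(assignments=assignments, roles=roles)


def check_population_map(gm: GenotypeMatrix,
                         pmap: PopulationMap) -> dict[str, list[str]]:
    """Report sample-set mismatches between a matrix and a population map."""
    in_matrix = set(gm.samples)
    in_map = set(pmap.assignments)
    return {
        "in_map_not_in_matrix": sorted(in_map - in_matrix),
        "in_matrix_not_in_map": sorted(in_matrix - in_map),
    }


def check_chrom_names(gm: GenotypeMatrix,
                      genes: list[GeneRecord]) -> dict[str, list[str]]:
    """Report chromosome-name mismatches between genotypes and annotation."""
    vcf_chroms = set(gm.sites["chrom"])
    gtf_chroms = {g.chrom for g in genes}
    return {
        "vcf_only": sorted(vcf_chroms - gtf_chroms),
        "annotation_only": sorted(gtf_chroms - vcf_chroms),
    }


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gtf_genes(path: str | os.PathLike,
                   feature_type: str = "gene") -> list[GeneRecord]:
    """Extract gene records from a GTF or GFF3 file (gzip OK).

    Only features of ``feature_type`` are kept; transcripts/exons are ignored.
    Coordinates are returned 1-based inclusive (GTF native).
    """
    import pyranges as pr

    p = str(path)
    base = p[:-3] if p.endswith(".gz") else p
    is_gff3 = base.endswith((".gff", ".gff3"))
    df = (pr.read_gff3(p) if is_gff3 else pr.read_gtf(p)).df
    if df.empty or "Feature" not in df.columns:
        raise FormatError(f"no features parsed from {path}")
    df = df[df["Feature"] == feature_type]
    if df.empty:
        raise FormatError(
            f"no {feature_type!r} features in {path}; if genes are encoded "
            "under another feature type pass feature_type=...")
    id_col = "gene_id" if "gene_id" in df.columns else "ID"
    name_col = "gene_name" if "gene_name" in df.columns else ("Name" if "Name" in df.columns else None)
    records = []
    for row in df.itertuples(index=False):
        name = getattr(row, name_col) if name_col else None
        records.append(GeneRecord(
            gene_id=str(getattr(row, id_col)),
            chrom=str(row.Chromosome),
            start=int(row.Start) + 1,  # pyranges stores 0-based starts
            end=int(row.End),
            strand=str(getattr(row, "Strand", ".")),
            gene_name=None if name is None or pd.isna(name) else str(name),
        ))
    records.sort(key=lambda g: (g.chrom, g.start, g.end))
    return records


# ---------------------------------------------------------------------------
# BED / TSV writers
# ---------------------------------------------------------------------------

def write_bed(intervals, path: str | os.PathLike) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED.

    ``intervals`` is an iterable of (chrom, start, end[, name[, score]])
    tuples or objects with those attributes.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, (tuple, list)):
                chrom, start, end, *rest = iv
            else:
                chrom, start, end = iv.chrom, iv.start, iv.end
                rest = []
            fields = [str(chrom), str(int(start) - 1), str(int(end))]
            fields += [str(x) for x in rest]
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple]:
    """Read BED into 1-based inclusive (chrom, start, end, *extra) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2]), *f[3:]))
    return out


def write_results_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table as TSV with header (header-only when empty)."""
    rows.to_csv(path, sep="\t", index=False)
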