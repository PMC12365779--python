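"""Synthetic methyl-capture cohorts with known truth.

Because no granulosa-cell methylome cohort of this design is publicly
deposited, every downstream stage is exercised against simulated data with
planted signal.  The generator emulates a targeted (EPIC-capture-like)
bisulfite experiment:

* CpG positions are clustered inside capture targets scattered over the
  autosomes; a configurable fraction of targets coincides with a CpG
  island, and gene models are placed around targets so that promoter,
  1-5 kb upstream, exonic, intronic and intergenic sites all occur.
* Per-site per-sample read depth is negative-binomial.
* Methylated counts are beta-binomial with mean ``pi`` and intraclass
  correlation ``rho`` (``rho = 0`` reduces exactly to binomial sampling).
* Planted hyper-/hypomethylated regions shift ``pi`` additively by
  ``delta`` percentage points for the affected group, clamped to
  [0.01, 0.99].

The default group sizes (10 treated / 4 untreated / 10 control) mirror the
three study arms the pipeline was designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    CpGRecord,
    GeneModel,
    GeneSetCollection,
    GenomicInterval,
    chrom_sort_key,
    read_bed,
    read_bismark_coverage,
    read_gene_models,
    read_gmt,
    write_bed,
    write_gene_models_bed12,
    write_gmt,
    _open_text,
)

PI_MIN, PI_MAX = 0.01, 0.99

_CHROMS = [f"chr{i}" for i in range(1, 23)]


class ConfigError(ValueError):
    """Simulation configuration is infeasible or invalid."""


@dataclass
class PlantedRegion:
    """A region whose methylation is shifted for one group.

    Coordinates may be left unset; the layout step then assigns the region
    to a capture target and anchors it on ``n_cpgs`` consecutive simulated
    CpGs (0-based half-open interval covering them).
    """

    affected_group: str
    delta: float  # signed shift in percentage points
    n_cpgs: int = 5
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.n_cpgs < 3:
            raise ConfigError("planted region needs n_cpgs >= 3 to be callable")
        if not (0 < abs(self.delta) <= 100):
            raise ConfigError("planted delta must be a non-zero percentage shift")

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based CpG position falls inside the region."""
        return (
            self.chrom == chrom
            and self.start is not None
            and self.end is not None
            and self.start <= pos - 1 < self.end
        )


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort generator."""

    seed: int
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"treated": 10, "untreated": 4, "control": 10}
    )
    n_targets: int = 80
    cpgs_per_target: tuple[int, int] = (5, 12)
    target_span_bp: tuple[int, int] = (300, 1000)
    baseline_meth: float = 0.3
    dispersion: float = 0.05  # beta-binomial intraclass correlation rho
    coverage_mean: float = 30.0
    coverage_size: float = 30.0  # negative-binomial size (inverse dispersion)
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    island_fraction: float = 0.3
    n_gene_sets: int = 40
    gene_set_size: tuple[int, int] = (5, 30)
    truth_set_boost: float = 0.5  # chance a truth-region gene is spiked into a set

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not (0 < self.baseline_meth < 1):
            raise ConfigError("baseline_meth must lie in (0, 1)")
        if not (0 <= self.dispersion < 1):
            raise ConfigError("dispersion must lie in [0, 1)")
        if not (0 <= self.island_fraction <= 1):
            raise ConfigError("island_fraction must lie in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_size <= 0:
            raise ConfigError("coverage parameters must be positive")
        if min(self.n_per_group.values(), default=0) < 1:
            raise ConfigError("every group needs at least one sample")
        if self.n_targets < 1:
            raise ConfigError("n_targets must be positive")
        lo, hi = self.cpgs_per_target
        if lo < 1 or hi < lo:
            raise ConfigError("cpgs_per_target range invalid")
        slo, shi = self.target_span_bp
        if slo < 10 or shi < slo:
            raise ConfigError("target_span_bp range invalid")
        if self.planted_regions:
            need = max(r.n_cpgs for r in self.planted_regions)
            if hi < need:
                raise ConfigError(
                    f"cpgs_per_target max {hi} cannot host planted regions of"
                    f" {need} CpGs"
                )
            if self.n_targets < len(self.planted_regions):
                raise ConfigError("fewer targets than planted regions")
            unknown = {r.affected_group for r in self.planted_regions} - set(
                self.n_per_group
            )
            if unknown:
                raise ConfigError(f"planted regions reference unknown groups {unknown}")

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)


@dataclass
class SimulatedCohort:
    records: list[CpGRecord]
    truth: list[PlantedRegion]
    islands: list[GenomicInterval]
    genes: list[GeneModel]
    gene_sets: GeneSetCollection


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------


def beta_binomial(
    rng: np.random.Generator,
    n: np.ndarray,
    pi: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Draw beta-binomial counts with mean ``n*pi`` and correlation ``rho``.

    Parameterized as alpha = pi*(1-rho)/rho, beta = (1-pi)*(1-rho)/rho, so
    rho is the intraclass correlation and rho -> 0 recovers the binomial.
    """
    n = np.asarray(n)
    pi = np.broadcast_to(np.asarray(pi, dtype=float), n.shape)
    if rho <= 0:
        return rng.binomial(n, pi)
    alpha = pi * (1 - rho) / rho
    beta = (1 - pi) * (1 - rho) / rho
    p = rng.beta(alpha, beta)
    return rng.binomial(n, p)


def _negbin_coverage(
    rng: np.random.Generator, mean: float, size: float, shape: tuple[int, ...]
) -> np.ndarray:
    p = size / (size + mean)
    return rng.negative_binomial(size, p, shape)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

_PLACEMENTS = ("promoter", "upstream", "exonic", "intronic", "none")


def _layout(config: SimulationConfig, rng: np.random.Generator):
    span_lo, span_hi = config.target_span_bp
    k_lo, k_hi = config.cpgs_per_target
    cursors = {c: 10_000 for c in _CHROMS}

    sites: list[tuple[str, int]] = []  # (chrom, 1-based pos) in layout order
    islands: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    planted: list[PlantedRegion] = []
    truth_genes: list[str] = []

    # targets hosting a planted region come first so span/CpG feasibility holds
    region_specs = list(config.planted_regions)

    for t in range(config.n_targets):
        chrom = _CHROMS[t % len(_CHROMS)]
        region = region_specs[t] if t < len(region_specs) else None
        span = int(rng.integers(span_lo, span_hi + 1))
        k = int(rng.integers(k_lo, k_hi + 1))
        if region is not None:
            span = min(span, 760)  # keep the anchored run well inside 1 kb
            k = max(k, region.n_cpgs)
            span = max(span, k + 1)
        start0 = cursors[chrom]
        offsets = np.sort(rng.choice(span, size=min(k, span), replace=False))
        positions = [int(start0 + off + 1) for off in offsets]  # 1-based
        sites.extend((chrom, p) for p in positions)

        if rng.random() < config.island_fraction:
            pad_l = int(rng.integers(0, 200))
            pad_r = int(rng.integers(0, 200))
            islands.append(
                GenomicInterval(chrom, start0 - pad_l, start0 + span + pad_r, f"cpgi_{t}")
            )

        if region is not None:
            i0 = int(rng.integers(0, len(positions) - region.n_cpgs + 1))
            run = positions[i0 : i0 + region.n_cpgs]
            placed = PlantedRegion(
                affected_group=region.affected_group,
                delta=region.delta,
                n_cpgs=region.n_cpgs,
                chrom=chrom,
                start=run[0] - 1,
                end=run[-1],
            )
            planted.append(placed)

        placement = _PLACEMENTS[t % len(_PLACEMENTS)]
        if placement != "none":
            strand = "+" if t % 2 == 0 else "-"
            gene = _place_gene(t, chrom, start0, start0 + span, strand, placement, rng)
            genes.append(gene)
            if region is not None:
                truth_genes.append(gene.gene_name)

        cursors[chrom] = start0 + span + 50_000 + int(rng.integers(0, 50_000))

    gene_sets = _draw_gene_sets(config, rng, [g.gene_name for g in genes], truth_genes)
    return sites, islands, genes, gene_sets, planted


def _place_gene(
    idx: int,
    chrom: str,
    s: int,
    e: int,
    strand: str,
    placement: str,
    rng: np.random.Generator,
) -> GeneModel:
    """Place a two-exon gene so target CpGs land in the requested class."""
    if strand == "+":
        if placement == "promoter":
            tss = e + 300
            exons = [(tss, tss + 300), (tss + 800, tss + 1200)]
        elif placement == "upstream":
            tss = e + 3000
            exons = [(tss, tss + 300), (tss + 800, tss + 1200)]
        elif placement == "exonic":
            exons = [(s - 100, e + 100), (e + 300, e + 700)]
        else:  # intronic
            exons = [(s - 500, s - 300), (e + 300, e + 500)]
    else:
        if placement == "promoter":
            tss0 = s - 300  # TSS coordinate is the exon end on the minus strand
            exons = [(tss0 - 1200, tss0 - 800), (tss0 - 300, tss0)]
        elif placement == "upstream":
            tss0 = s - 3000
            exons = [(tss0 - 1200, tss0 - 800), (tss0 - 300, tss0)]
        elif placement == "exonic":
            exons = [(s - 700, s - 300), (s - 100, e + 100)]
        else:
            exons = [(s - 500, s - 300), (e + 300, e + 500)]
    biotype = "coding" if rng.random() < 2 / 3 else "noncoding"
    name = f"GENE{idx:04d}"
    return GeneModel.from_exons(
        name,
        name,
        biotype,
        chrom,
        strand,
        [GenomicInterval(chrom, a, b) for a, b in exons],
    )


def _draw_gene_sets(
    config: SimulationConfig,
    rng: np.random.Generator,
    symbols: list[str],
    truth_genes: list[str],
) -> GeneSetCollection:
    coll = GeneSetCollection()
    if not symbols:
        return coll
    lo, hi = config.gene_set_size
    hi = min(hi, len(symbols))
    lo = min(lo, hi)
    for i in range(config.n_gene_sets):
        k = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(symbols, size=k, replace=False))
        if truth_genes and rng.random() < config.truth_set_boost:
            members.append(truth_genes[int(rng.integers(0, len(truth_genes)))])
        coll.add(f"SIM_SET_{i:03d}", "simulated gene set", members)
    return coll


def simulate_genome_layout(config: SimulationConfig):
    """Return (cpg_positions, islands, genes, gene_sets) for the config.

    ``cpg_positions`` is a list of (chrom, 1-based position) tuples.
    """
    rng = np.random.default_rng(config.seed)
    sites, islands, genes, gene_sets, _ = _layout(config, rng)
    return sites, islands, genes, gene_sets


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate counts for all samples at all simulated CpG sites."""
    rng = np.random.default_rng(config.seed)
    sites, islands, genes, gene_sets, planted = _layout(config, rng)

    n_sites = len(sites)
    pi0 = float(np.clip(config.baseline_meth, PI_MIN, PI_MAX))
    records: list[CpGRecord] = []

    for group in config.groups:
        pi = np.full(n_sites, pi0)
        for region in planted:
            if region.affected_group != group:
                continue
            for i, (chrom, pos) in enumerate(sites):
                if region.contains(chrom, pos):
                    pi[i] = np.clip(pi0 + region.delta / 100.0, PI_MIN, PI_MAX)
        n_samples = config.n_per_group[group]
        cov = _negbin_coverage(
            rng, config.coverage_mean, config.coverage_size, (n_samples, n_sites)
        )
        meth = beta_binomial(rng, cov, pi[None, :], config.dispersion)
        for s in range(n_samples):
            sample_id = f"{group}_{s + 1:02d}"
            for i, (chrom, pos) in enumerate(sites):
                records.append(
                    CpGRecord(
                        chrom,
                        pos,
                        int(meth[s, i]),
                        int(cov[s, i] - meth[s, i]),
                        sample_id,
                        group,
                    )
                )
    return SimulatedCohort(records, planted, islands, genes, gene_sets)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["chrom", "start", "end", "affected_group", "delta", "n_cpgs"]


def write_truth(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """Write the cohort as files re-readable by the io layer.

    Emits one Bismark coverage file per sample (``<sample>.cov.gz``), the
    island BED, the gene models (BED12 + biotype column), the gene sets
    (GMT), the planted-truth TSV and a sample sheet.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    by_sample: dict[str, list[CpGRecord]] = {}
    groups: dict[str, str] = {}
    for rec in cohort.records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
        groups[rec.sample_id] = rec.group

    for sample_id in sorted(by_sample):
        recs = sorted(by_sample[sample_id], key=lambda r: (chrom_sort_key(r.chrom), r.pos))
        with _open_text(out / f"{sample_id}.cov.gz", "wt") as fh:
            for r in recs:
                total = r.count_meth + r.count_unmeth
                pct = 100.0 * r.count_meth / total if total else 0.0
                fh.write(
                    f"{r.chrom}\t{r.pos}\t{r.pos}\t{pct:.2f}\t"
                    f"{r.count_meth}\t{r.count_unmeth}\n"
                )

    with open(out / "sample_sheet.tsv", "w") as fh:
        fh.write("sample_id\tgroup\tcoverage_path\n")
        for sample_id in sorted(by_sample):
            fh.write(f"{sample_id}\t{groups[sample_id]}\t{sample_id}.cov.gz\n")

    write_bed(cohort.islands, out / "islands.bed")
    write_gene_models_bed12(cohort.genes, out / "genes.bed12")
    write_gmt(cohort.gene_sets, out / "gene_sets.gmt")

    with open(out / "truth.tsv", "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in cohort.truth:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.affected_group}\t"
                f"{r.delta:.2f}\t{r.n_cpgs}\n"
            )


def load_cohort(in_dir: str | Path) -> SimulatedCohort:
    """Read back a directory written by :func:`write_truth`."""
    d = Path(in_dir)
    records: list[CpGRecord] = []
    with open(d / "sample_sheet.tsv") as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ValueError(f"{d}/sample_sheet.tsv: unexpected header")
        for line in fh:
            if not line.strip():
                continue
            sample_id, group, rel = line.rstrip("\n").split("\t")
            records.extend(read_bismark_coverage(d / rel, sample_id, group))
    truth: list[PlantedRegion] = []
    truth_path = d / "truth.tsv"
    if truth_path.exists():
        with open(truth_path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, group, delta, n_cpgs = line.rstrip("\n").split("\t")
                truth.append(
                    PlantedRegion(
                        affected_group=group,
                        delta=float(delta),
                        n_cpgs=int(n_cpgs),
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                    )
                )
    islands = read_bed(d / "islands.bed") if (d / "islands.bed").exists() else []
    genes = (
        read_gene_models(d / "genes.bed12", "bed12")
        if (d / "genes.bed12").exists()
        else []
    )
    gene_sets = (
        read_gmt(d / "gene_sets.gmt")
        if (d / "gene_sets.gmt").exists()
        else GeneSetCollection()
    )
    return SimulatedCohort(records, truth, islands, genes, gene_sets)


def study_planted_regions(
    n_per_direction: int = 6,
    delta: float = 40.0,
    n_cpgs: int = 5,
    groups: tuple[str, str] = ("untreated", "treated"),
) -> list[PlantedRegion]:
    """Default planted truth: hyper and hypo regions for each contrast group."""
    regions: list[PlantedRegion] = []
    for group in groups:
        for i in range(n_per_direction):
            sign = 1.0 if i % 2 == 0 else -1.0
            regions.append(PlantedRegion(group, sign * delta, n_cpgs))
    return regions
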