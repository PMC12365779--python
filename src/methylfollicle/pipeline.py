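"""End-to-end orchestration: simulate/load -> test -> DMS -> DMR -> annotate
-> enrich -> cross-compare, with a machine-readable run manifest.

A run is fully determined by its config (including the seed): re-running
with identical inputs produces byte-identical outputs, which the manifest
makes checkable by recording a SHA-256 per output file.  The manifest also
keeps per-stage record counts, including the site-accounting identity
``sites_in = sites_filtered_out + sites_tested + sites_untestable``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import AnnotationIndex, feature_biotype_split, proportions_table
from .comparisons import intersect_dmrs_opposite
from .diff_methylation import (
    EmptyResultError,
    bh_adjust,
    call_dms,
    compare_groups,
    filter_coverage,
)
from .dmr_caller import call_dmrs, summarize_dmr
from .enrichment import hypergeometric_ora, map_dms_to_genes
from .io_formats import read_bed, write_results_tsv
from .synthetic_data import (
    PlantedRegion,
    SimulatedCohort,
    SimulationConfig,
    load_cohort,
    simulate_cohort,
    study_planted_regions,
    write_truth,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class Thresholds:
    min_cov: int = 10
    max_percentile: float = 99.9
    diff_threshold: float = 25.0
    q_threshold: float = 0.01
    min_cpgs: int = 3
    max_span: int = 1000
    min_mean_diff: float = 25.0

    def __post_init__(self) -> None:
        if min(self.min_cov, self.min_cpgs, self.max_span) <= 0:
            raise ValueError("thresholds must be positive")
        if self.diff_threshold <= 0 or self.q_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineConfig:
    """One reproducible run: comparisons, thresholds, inputs, seed, outputs.

    The default comparison list mirrors the two-contrast design the
    pipeline was built for: treatment effect (treated vs untreated) and
    disease effect (untreated vs control); the opposite-direction
    intersection is taken between the second (disease) and first
    (treatment) comparisons' DMR sets.
    """

    seed: int
    out_dir: str
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("treated", "untreated"), ("untreated", "control")]
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    shore_width: int = 2000
    promoter_width: int = 1000
    upstream_far: int = 5000
    map_window: int = 5000
    top_n: int = 30
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    enhancers_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        sim_raw = raw.pop("simulation", None)
        simulation = None
        if sim_raw is not None:
            sim_raw.setdefault("seed", raw.get("seed"))
            planted = [PlantedRegion(**r) for r in sim_raw.pop("planted_regions", [])]
            for key in ("cpgs_per_target", "target_span_bp", "gene_set_size"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            simulation = SimulationConfig(planted_regions=planted, **sim_raw)
        comparisons = [tuple(c) for c in raw.pop("comparisons", [])] or None
        cfg = cls(thresholds=thresholds, simulation=simulation, **raw)
        if comparisons:
            cfg.comparisons = comparisons
        return cfg

    def canonical(self) -> str:
        """Deterministic serialization used for the config hash.

        The output directory is excluded: it locates results but does not
        change the analysis, so runs into different directories from the
        same config hash (and compare) equal.
        """
        payload = asdict(self)
        payload.pop("out_dir", None)
        return json.dumps(payload, sort_keys=True, default=str)


def default_config(seed: int, out_dir: str) -> PipelineConfig:
    """Study-condition default: 10/4/10 cohort with planted truth regions."""
    sim = SimulationConfig(seed=seed, planted_regions=study_planted_regions())
    return PipelineConfig(seed=seed, out_dir=out_dir, simulation=sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_cohort(config: PipelineConfig) -> SimulatedCohort:
    if config.input_dir:
        return load_cohort(config.input_dir)
    sim = config.simulation or SimulationConfig(
        seed=config.seed, planted_regions=study_planted_regions()
    )
    return simulate_cohort(sim)


def run_pipeline(config: PipelineConfig, write_cohort: bool = False) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _resolve_cohort(config)
    groups = {r.group for r in cohort.records}
    for case, control in config.comparisons:
        if case not in groups or control not in groups:
            raise PipelineError(
                f"stage validate: comparison {case} vs {control} references a "
                f"group absent from the cohort (have {sorted(groups)})"
            )

    if write_cohort:
        write_truth(cohort, out / "cohort")

    enhancers = read_bed(config.enhancers_path) if config.enhancers_path else None
    index = AnnotationIndex(
        cohort.islands,
        cohort.genes,
        enhancers=enhancers,
        shore_width=config.shore_width,
        promoter_width=config.promoter_width,
        upstream_far=config.upstream_far,
    )

    th = config.thresholds
    manifest: dict = {
        "tool": "methylfollicle",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "comparisons": {},
        "outputs": {},
    }

    dmrs_by_comparison: dict[str, list] = {}
    for case, control in config.comparisons:
        name = f"{case}_vs_{control}"
        comp_dir = out / name
        comp_dir.mkdir(exist_ok=True)
        subset = [r for r in cohort.records if r.group in (case, control)]
        sites_in = len({(r.chrom, r.pos) for r in subset})
        try:
            filtered = filter_coverage(
                subset, min_cov=th.min_cov, max_percentile=th.max_percentile
            )
            results = compare_groups(filtered, case, control)
        except EmptyResultError as exc:
            raise PipelineError(f"stage diffmeth[{name}]: {exc}") from exc
        q = bh_adjust([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
        call_dms(results, diff_threshold=th.diff_threshold, q_threshold=th.q_threshold)

        sites_kept = len(results)
        sites_tested = sum(1 for r in results if not math.isnan(r.p_value))
        dms = [r for r in results if r.is_dms]
        n_hyper = sum(1 for r in dms if r.direction == "hyper")
        n_hypo = len(dms) - n_hyper

        dmrs = call_dmrs(
            dms,
            min_cpgs=th.min_cpgs,
            max_span=th.max_span,
            min_mean_diff=th.min_mean_diff,
        )
        for d in dmrs:
            summarize_dmr(d, results, index)
        dmrs_by_comparison[name] = dmrs

        write_results_tsv(results, comp_dir / "dms.tsv", "dms")
        write_results_tsv(dmrs, comp_dir / "dmr.tsv", "dmr")
        write_results_tsv(
            proportions_table(dms, "context", index).rows,
            comp_dir / "proportions_context.tsv",
            "proportions",
        )
        write_results_tsv(
            proportions_table(dms, "genic", index).rows,
            comp_dir / "proportions_genic.tsv",
            "proportions",
        )

        universe = {
            g.gene_name
            for r in results
            for g in index.genes_near_tss(r.chrom, r.pos, window=config.map_window)
        } & cohort.gene_sets.all_genes()
        enrichment_counts = {}
        for direction in ("hyper", "hypo"):
            query = map_dms_to_genes(
                [r for r in dms if r.direction == direction],
                index,
                window=config.map_window,
            )
            try:
                enr = hypergeometric_ora(query, cohort.gene_sets, universe)
            except ValueError as exc:
                logger.warning("enrich[%s/%s] skipped: %s", name, direction, exc)
                enr = []
            write_results_tsv(enr, comp_dir / f"enrichment_{direction}.tsv", "enrichment")
            enrichment_counts[direction] = {
                "tested_sets": len(enr),
                "passing_sets": sum(1 for e in enr if e.passes_filters),
            }

        biotype = feature_biotype_split(dms, index, window=config.map_window)
        counts = {
            "sites_in": sites_in,
            "sites_filtered_out": sites_in - sites_kept,
            "sites_tested": sites_tested,
            "sites_untestable": sites_kept - sites_tested,
            "n_dms": len(dms),
            "n_dms_hyper": n_hyper,
            "n_dms_hypo": n_hypo,
            "n_dmrs": len(dmrs),
            "biotype_coding_fraction": None
            if biotype.n_features == 0
            else round(biotype.coding_fraction, 4),
            "enrichment": enrichment_counts,
        }
        if counts["sites_in"] != (
            counts["sites_filtered_out"]
            + counts["sites_tested"]
            + counts["sites_untestable"]
        ):
            raise PipelineError(f"stage accounting[{name}]: site counts do not conserve")
        manifest["comparisons"][name] = counts

    if len(config.comparisons) >= 2:
        treat_name = "{}_vs_{}".format(*config.comparisons[0])
        disease_name = "{}_vs_{}".format(*config.comparisons[1])
        opposing = intersect_dmrs_opposite(
            dmrs_by_comparison[disease_name], dmrs_by_comparison[treat_name]
        )
        write_results_tsv(opposing, out / "opposing.tsv", "opposing")
        manifest["opposing"] = {
            "disease_comparison": disease_name,
            "treatment_comparison": treat_name,
            "n_opposing": len(opposing),
        }

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report_summary(run_dir: str | Path, top_n: int = 30) -> str:
    """Human-readable markdown report for a completed run; writes report.md."""
    from .io_formats import chrom_sort_key, read_results_tsv

    run = Path(run_dir)
    with open(run / "manifest.json") as fh:
        manifest = json.load(fh)

    lines = ["# Differential methylation run summary", ""]
    lines.append(f"seed: {manifest['seed']}  |  config: {manifest['config_sha256'][:12]}")
    lines.append("")

    for name, counts in manifest["comparisons"].items():
        lines.append(f"## Comparison: {name.replace('_', ' ')}")
        lines.append("")
        n_dms = counts["n_dms"]
        if n_dms == 0:
            lines.append("No differentially methylated sites were called.")
            lines.append("")
            continue
        hyper, hypo = counts["n_dms_hyper"], counts["n_dms_hypo"]
        lines.append(
            f"{n_dms} DMSs: {hyper} hypermethylated "
            f"({100 * hyper / n_dms:.1f}%), {hypo} hypomethylated "
            f"({100 * hypo / n_dms:.1f}%); {counts['n_dmrs']} DMRs."
        )
        lines.append("")
        for table, title in (
            ("proportions_context.tsv", "CpG context proportions"),
            ("proportions_genic.tsv", "Genic annotation proportions"),
        ):
            rows = read_results_tsv(run / name / table, "proportions")
            lines.append(f"### {title}")
            lines.append("")
            lines.append("| stratum | category | count | percent |")
            lines.append("|---|---|---:|---:|")
            for r in rows:
                lines.append(
                    f"| {r['stratum']} | {r['category']} | {r['count']} | "
                    f"{r['percent']:.1f} |"
                )
            lines.append("")
        dmr_rows = read_results_tsv(run / name / "dmr.tsv", "dmr")
        if dmr_rows:
            dmr_rows.sort(
                key=lambda r: (r["q_value"], chrom_sort_key(str(r["chrom"])), r["start"])
            )
            lines.append(f"### Top {min(top_n, len(dmr_rows))} DMRs (by q-value)")
            lines.append("")
            lines.append(
                "| location | size (bp) | state | sig CpGs | q | mean MD | max MD |"
                " feature |"
            )
            lines.append("|---|---:|---|---:|---|---:|---:|---|")
            for r in dmr_rows[:top_n]:
                lines.append(
                    f"| {r['location']} | {r['size_bp']} | {r['state']} | "
                    f"{r['sig_cpgs']} | {r['q_value']:.2e} | {r['mean_md']:.2f} | "
                    f"{r['max_md']:.2f} | {r['genomic_feature']} |"
                )
            lines.append("")

    if "opposing" in manifest:
        lines.append("## Regions changing direction between comparisons")
        lines.append("")
        lines.append(f"{manifest['opposing']['n_opposing']} opposite-direction regions.")
        rows = read_results_tsv(run / "opposing.tsv", "opposing")
        if rows:
            lines.append("")
            lines.append("| chrom | start | disease state | treatment state | feature |")
            lines.append("|---|---:|---|---|---|")
            for r in rows:
                lines.append(
                    f"| {r['chrom']} | {r['start']} | {r['state_disease']} | "
                    f"{r['state_treatment']} | {r['feature']} |"
                )
        lines.append("")

    report = "\n".join(lines)
    with open(run / "report.md", "w") as fh:
        fh.write(report)
    return report
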