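"""Gene-set over-representation of hypo-/hypermethylated DMS gene lists.

Hyper- and hypomethylated DMSs are mapped to gene symbols (features with a
TSS within +-5 kb of a DMS) and each list is tested separately against a
gene-set collection with the one-sided hypergeometric test, BH-corrected
across sets.  A set survives the reporting filters when it has at least
five genes in the universe and q <= 0.05.  The universe is restricted to
genes that appear in at least one gene set (unmappable genes carry no
information for the test) and, when the caller supplies it, to genes
annotatable to a tested CpG.

Driver-gene tabulation ranks overlap genes by how many surviving sets they
appear in — a simple view of which genes carry the enrichment signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .annotation import AnnotationIndex
from .diff_methylation import bh_adjust
from .io_formats import GeneSetCollection

MIN_SET_SIZE = 5
Q_CUTOFF = 0.05


@dataclass
class EnrichmentResult:
    set_id: str
    set_size_in_universe: int
    overlap: int
    p_value: float
    q_value: float = float("nan")
    passes_filters: bool = False
    overlap_genes: list[str] = field(default_factory=list)


def map_dms_to_genes(dms_list, index: AnnotationIndex, window: int = 5000) -> set[str]:
    """Deduplicated symbols of features with a TSS within ``window`` of any DMS."""
    genes: set[str] = set()
    for r in dms_list:
        for gene in index.genes_near_tss(r.chrom, r.pos, window=window):
            genes.add(gene.gene_name)
    return genes


def hypergeometric_ora(
    query_genes: set[str],
    gene_sets: GeneSetCollection,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of the query against every gene set.

    p = P(X >= overlap) with population |universe|, successes |set ∩
    universe| and draws |query ∩ universe|; BH across all tested sets.
    """
    universe = universe & gene_sets.all_genes()
    if not universe:
        raise ValueError("universe is empty after restriction to mappable genes")
    query = set(query_genes) & universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")

    M = len(universe)
    N = len(query)
    results: list[EnrichmentResult] = []
    for set_id in sorted(gene_sets.sets):
        members = set(gene_sets.members(set_id)) & universe
        K = len(members)
        if K == 0:
            continue
        overlap_genes = sorted(query & members)
        k = len(overlap_genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        results.append(EnrichmentResult(set_id, K, k, min(p, 1.0), overlap_genes=overlap_genes))

    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.passes_filters = r.set_size_in_universe >= MIN_SET_SIZE and r.q_value <= Q_CUTOFF
    return results


def driver_genes(results: list[EnrichmentResult]) -> list[tuple[str, int]]:
    """Overlap genes ranked by membership count across surviving sets.

    Ties break alphabetically.  Returns (gene, n_passing_sets) pairs.
    """
    counts: dict[str, int] = {}
    for r in results:
        if not r.passes_filters:
            continue
        for gene in r.overlap_genes:
            counts[gene] = counts.get(gene, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
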