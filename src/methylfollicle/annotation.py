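"""CpG-context and genic annotation of sites and regions.

Context classification partitions every CpG into island / shore / other
with precedence island > shore: shores are the +-2 kb flanks of islands
minus any island bases (the island-flank convention of the standard
annotation tools).  Genic annotation is multi-label over promoter
(< 1 kb upstream of the TSS), 1-5 kb (the further upstream band), exon,
intron and — when a user-supplied enhancer track is given — enhancer;
"intergenic" is the fallback when nothing overlaps.  Both upstream bands
are strand-oriented.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

GENIC_LABEL_ORDER = ["promoter", "1-5 kb", "exon", "intron", "enhancer", "intergenic"]


@dataclass
class ProportionRow:
    stratum: str  # hyper | hypo | all
    category: str
    count: int
    percent: float


@dataclass
class ProportionTable:
    rows: list[ProportionRow]

    def stratum(self, name: str) -> list[ProportionRow]:
        return [r for r in self.rows if r.stratum == name]

    def percent(self, stratum: str, category: str) -> float:
        for r in self.rows:
            if r.stratum == stratum and r.category == category:
                return r.percent
        raise KeyError((stratum, category))


@dataclass
class BiotypeSplit:
    coding_fraction: float
    noncoding_fraction: float
    n_features: int
    note: str = ""


def proportions_from_counts(counts: dict[str, int], stratum: str = "all") -> ProportionTable:
    """Turn category counts into a one-stratum proportion table (1-decimal %)."""
    total = sum(counts.values())
    rows = [
        ProportionRow(stratum, cat, n, round(100.0 * n / total, 1) if total else 0.0)
        for cat, n in counts.items()
    ]
    return ProportionTable(rows)


class AnnotationIndex:
    """Island/shore geography plus gene-feature intervals for fast lookup."""

    def __init__(
        self,
        islands: list[GenomicInterval],
        genes: list[GeneModel],
        enhancers: list[GenomicInterval] | None = None,
        shore_width: int = 2000,
        promoter_width: int = 1000,
        upstream_far: int = 5000,
    ) -> None:
        self.shore_width = shore_width
        self.promoter_width = promoter_width
        self.upstream_far = upstream_far
        self.genes = list(genes)
        if enhancers is None:
            logger.warning(
                "no enhancer track supplied; the 'enhancer' label is unavailable"
            )
        self._has_enhancers = enhancers is not None

        self._islands: dict[str, IntervalTree] = {}
        for iv in islands:
            self._islands.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

        # Shores: island flanks with island bases chopped out.
        self._shores: dict[str, IntervalTree] = {}
        for iv in islands:
            tree = self._shores.setdefault(iv.chrom, IntervalTree())
            left = max(0, iv.start - shore_width)
            if left < iv.start:
                tree.addi(left, iv.start)
            tree.addi(iv.end, iv.end + shore_width)
        for chrom, tree in self._shores.items():
            for island in self._islands.get(chrom, IntervalTree()):
                tree.chop(island.begin, island.end)

        self._enhancers: dict[str, IntervalTree] = {}
        for iv in enhancers or []:
            self._enhancers.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

        # Genic feature intervals, labelled with (label, gene).
        self._features: dict[str, IntervalTree] = {}
        self._tss_by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
        for gene in self.genes:
            tree = self._features.setdefault(gene.chrom, IntervalTree())
            for label, start, end in self._gene_bands(gene):
                if start < end:
                    tree.addi(start, end, (label, gene))
            self._tss_by_chrom.setdefault(gene.chrom, []).append((gene.tss, gene))
        for entries in self._tss_by_chrom.values():
            entries.sort(key=lambda t: t[0])

    def _gene_bands(self, gene: GeneModel):
        pw, uf = self.promoter_width, self.upstream_far
        if gene.strand == "+":
            yield "promoter", gene.tss - pw, gene.tss
            yield "1-5 kb", gene.tss - uf, gene.tss - pw
        else:
            yield "promoter", gene.tss, gene.tss + pw
            yield "1-5 kb", gene.tss + pw, gene.tss + uf
        for exon in gene.exons:
            yield "exon", exon.start, exon.end
        for intron in gene.introns:
            yield "intron", intron.start, intron.end

    # -- context -----------------------------------------------------------

    def classify_cpg_context(self, chrom: str, pos: int) -> str:
        """island | shore | other for a 1-based CpG position."""
        x = pos - 1
        if chrom in self._islands and self._islands[chrom].overlaps_point(x):
            return "island"
        if chrom in self._shores and self._shores[chrom].overlaps_point(x):
            return "shore"
        return "other"

    def shores(self) -> list[GenomicInterval]:
        out = []
        for chrom, tree in self._shores.items():
            out.extend(GenomicInterval(chrom, iv.begin, iv.end) for iv in sorted(tree))
        return out

    # -- genic labels ------------------------------------------------------

    def annotate_genic(self, site_or_region) -> list[str]:
        """All genic labels overlapping a site (chrom, 1-based pos) or region.

        Regions are anything with chrom/start/end attributes (1-based
        inclusive endpoints, as region records store them).  Returns labels
        in the fixed vocabulary order; ['intergenic'] when nothing overlaps.
        """
        chrom, lo, hi = self._coords(site_or_region)
        found: set[str] = set()
        if chrom in self._features:
            for hit in self._features[chrom].overlap(lo, hi):
                found.add(hit.data[0])
        if self._has_enhancers and chrom in self._enhancers:
            if self._enhancers[chrom].overlap(lo, hi):
                found.add("enhancer")
        labels = [lab for lab in GENIC_LABEL_ORDER if lab in found]
        return labels or ["intergenic"]

    @staticmethod
    def _coords(site_or_region) -> tuple[str, int, int]:
        if isinstance(site_or_region, tuple):
            chrom, pos = site_or_region
            return chrom, pos - 1, pos
        if isinstance(site_or_region, GenomicInterval):
            return site_or_region.chrom, site_or_region.start, site_or_region.end
        chrom = site_or_region.chrom
        return chrom, site_or_region.start - 1, site_or_region.end

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        """Genes whose feature bands overlap a 1-based position."""
        out: list[GeneModel] = []
        if chrom in self._features:
            for hit in sorted(
                self._features[chrom].overlap(pos - 1, pos),
                key=lambda h: h.data[1].gene_id,
            ):
                gene = hit.data[1]
                if gene not in out:
                    out.append(gene)
        return out

    def genes_near_tss(
        self, chrom: str, start: int, end: int | None = None, window: int = 5000
    ) -> list[GeneModel]:
        """Genes whose TSS lies within ``window`` bp of a position or region."""
        if end is None:
            end = start
        entries = self._tss_by_chrom.get(chrom, [])
        if not entries:
            return []
        keys = [t for t, _ in entries]
        lo = bisect.bisect_left(keys, start - 1 - window)
        hi = bisect.bisect_right(keys, end + window)
        return [g for _, g in entries[lo:hi]]


# ---------------------------------------------------------------------------
# Stratified reporting
# ---------------------------------------------------------------------------


def classify_cpg_context(pos, index: AnnotationIndex, chrom: str | None = None) -> str:
    """Functional wrapper; accepts (chrom, pos) tuple or chrom+pos."""
    if chrom is None:
        chrom, pos = pos
    return index.classify_cpg_context(chrom, pos)


def annotate_genic(site_or_region, index: AnnotationIndex) -> list[str]:
    return index.annotate_genic(site_or_region)


def primary_genic_label(labels: list[str]) -> str:
    """Single-label reduction by the fixed precedence, for partition tables."""
    for lab in GENIC_LABEL_ORDER:
        if lab in labels:
            return lab
    return "intergenic"


def feature_biotype_split(dms_list, index: AnnotationIndex, window: int = 5000) -> BiotypeSplit:
    """Coding/noncoding split of unique features with a TSS within ``window``.

    Fractions are over unique genomic features hit, not over DMSs.
    """
    features: dict[str, str] = {}
    for r in dms_list:
        for gene in index.genes_near_tss(r.chrom, r.pos, window=window):
            features[gene.gene_id] = gene.biotype
    n = len(features)
    if n == 0:
        return BiotypeSplit(float("nan"), float("nan"), 0, "no features in window")
    coding = sum(1 for b in features.values() if b == "coding")
    return BiotypeSplit(coding / n, (n - coding) / n, n)


def proportions_table(dms_list, classifier: str, index: AnnotationIndex) -> ProportionTable:
    """Counts and 1-decimal percentages per category, stratified by direction.

    ``classifier`` is ``context`` (island/shore/other) or ``genic`` (the
    primary genic label, so each site lands in exactly one category and the
    strata are true partitions).
    """
    if classifier not in {"context", "genic"}:
        raise ValueError("classifier must be 'context' or 'genic'")
    rows: list[ProportionRow] = []
    strata = {
        "hyper": [r for r in dms_list if r.direction == "hyper"],
        "hypo": [r for r in dms_list if r.direction == "hypo"],
        "all": list(dms_list),
    }
    if classifier == "context":
        categories = ["island", "shore", "other"]
        label = lambda r: index.classify_cpg_context(r.chrom, r.pos)
    else:
        categories = list(GENIC_LABEL_ORDER)
        label = lambda r: primary_genic_label(index.annotate_genic((r.chrom, r.pos)))
    for stratum, sites in strata.items():
        counts = {c: 0 for c in categories}
        for r in sites:
            counts[label(r)] += 1
        total = len(sites)
        for cat in categories:
            pct = round(100.0 * counts[cat] / total, 1) if total else 0.0
            rows.append(ProportionRow(stratum, cat, counts[cat], pct))
    return ProportionTable(rows)
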