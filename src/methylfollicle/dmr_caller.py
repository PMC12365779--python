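"""Aggregate concordant DMSs into differentially methylated regions.

A DMR is a run of at least three same-direction DMSs whose first and last
positions lie within 1,000 bp of each other and whose mean methylation
difference exceeds 25 percentage points in magnitude.  Chaining is greedy
left-to-right per chromosome and per direction: the current chain absorbs
the next same-direction DMS while the span constraint holds, then closes;
chains never share a DMS.  Non-significant CpGs (and opposite-direction
DMSs) inside the span do not break a chain — the rule counts significant
CpGs only.

Region size is reported as ``end - start`` of the first/last constituent
DMS positions (1-based), matching how such tables are conventionally
printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import AnnotationIndex
from .diff_methylation import CpGTestResult
from .io_formats import chrom_sort_key


class IntegrityError(ValueError):
    """A DMR references a constituent site that is missing upstream."""


@dataclass
class DMR:
    """A called region with its summary fields.

    ``start`` / ``end`` are the 1-based positions of the first and last
    constituent DMS; ``size_bp = end - start``.  Context counts and the
    genic annotation are populated by :func:`summarize_dmr`.
    """

    chrom: str
    start: int
    end: int
    state: str  # hyper | hypo
    sig_cpgs: int
    constituents: list[int]  # 1-based positions of constituent DMSs
    mean_md: float
    max_md: float  # signed, largest magnitude among constituents
    size_bp: int = 0
    q_value: float | None = None
    n_island: int | None = None
    n_shore: int | None = None
    n_other: int | None = None
    genomic_feature: str = ""
    genic_annotation: str = ""

    def __post_init__(self) -> None:
        if not self.size_bp:
            self.size_bp = self.end - self.start


def _summaries(diffs: list[float]) -> tuple[float, float]:
    mean_md = sum(diffs) / len(diffs)
    max_md = max(diffs, key=abs)
    return mean_md, max_md


def call_dmrs(
    dms_list: list[CpGTestResult],
    min_cpgs: int = 3,
    max_span: int = 1000,
    min_mean_diff: float = 25.0,
) -> list[DMR]:
    """Chain DMSs into DMRs; input must contain DMS-flagged sites only."""
    for r in dms_list:
        if not r.is_dms:
            raise ValueError(f"non-DMS site {r.chrom}:{r.pos} passed to call_dmrs")

    by_key: dict[tuple[str, str], list[CpGTestResult]] = {}
    for r in dms_list:
        by_key.setdefault((r.chrom, r.direction), []).append(r)

    dmrs: list[DMR] = []
    for (chrom, direction), sites in by_key.items():
        sites.sort(key=lambda r: r.pos)
        i = 0
        while i < len(sites):
            j = i
            while j + 1 < len(sites) and sites[j + 1].pos - sites[i].pos <= max_span:
                j += 1
            chain = sites[i : j + 1]
            if len(chain) >= min_cpgs:
                diffs = [r.meth_diff for r in chain]
                mean_md, max_md = _summaries(diffs)
                if abs(mean_md) > min_mean_diff:
                    dmrs.append(
                        DMR(
                            chrom=chrom,
                            start=chain[0].pos,
                            end=chain[-1].pos,
                            state=direction,
                            sig_cpgs=len(chain),
                            constituents=[r.pos for r in chain],
                            mean_md=mean_md,
                            max_md=max_md,
                        )
                    )
            i = j + 1

    dmrs.sort(key=lambda d: (chrom_sort_key(d.chrom), d.start))
    return dmrs


def summarize_dmr(
    dmr: DMR,
    test_results: list[CpGTestResult],
    context_index: AnnotationIndex | None = None,
) -> DMR:
    """Populate q-value, effect summaries, context counts and annotation.

    Every constituent position must be present in ``test_results``;
    a missing constituent raises :class:`IntegrityError`.
    """
    lookup = {(r.chrom, r.pos): r for r in test_results}
    members: list[CpGTestResult] = []
    for pos in dmr.constituents:
        r = lookup.get((dmr.chrom, pos))
        if r is None:
            raise IntegrityError(f"constituent {dmr.chrom}:{pos} missing from results")
        members.append(r)

    diffs = [r.meth_diff for r in members]
    dmr.mean_md, dmr.max_md = _summaries(diffs)
    dmr.q_value = min(r.q_value for r in members)

    if context_index is not None:
        counts = {"island": 0, "shore": 0, "other": 0}
        for r in members:
            counts[context_index.classify_cpg_context(r.chrom, r.pos)] += 1
        dmr.n_island = counts["island"]
        dmr.n_shore = counts["shore"]
        dmr.n_other = counts["other"]

        labels: list[str] = []
        features: list[str] = []
        for r in members:
            for label in context_index.annotate_genic((r.chrom, r.pos)):
                if label not in labels:
                    labels.append(label)
            for gene in context_index.genes_at(r.chrom, r.pos):
                if gene.gene_name not in features:
                    features.append(gene.gene_name)
        if not features:
            near = context_index.genes_near_tss(dmr.chrom, dmr.start, dmr.end)
            features = [g.gene_name for g in near]
        dmr.genic_annotation = " & ".join(labels)
        dmr.genomic_feature = "/".join(features)
    return dmr
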