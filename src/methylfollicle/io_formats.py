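"""Readers and writers for the external formats the pipeline touches.

Input side: Bismark coverage tables (one file per sample), BED3/BED6
intervals (CpG islands, enhancers), gene models (BED12, optionally with a
13th biotype column, or a minimal GTF dialect) and GMT gene-set
collections.  Output side: the pipeline's result tables, one fixed TSV
schema per stage.

Conventions
-----------
* Intervals are stored 0-based half-open, exactly as in BED.
* CpG sites keep the 1-based coordinate of the cytosine, as in Bismark
  coverage files; interval-overlap tests subtract one at the boundary.
* Chromosome names are taken verbatim: ``chr1`` and ``1`` never compare
  equal.  A naming mismatch between inputs surfaces as an explicit empty
  overlap downstream rather than being silently patched here.
* Every reader and writer is gzip-transparent (``.gz`` suffix).
* Result writers pin float formatting (two decimals for percentages and
  methylation differences, six-significant-digit scientific notation for
  p/q values) so that identical runs produce byte-identical files.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a format invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CpGRecord:
    """Methylated/unmethylated read counts for one CpG site in one sample.

    ``pos`` is the 1-based genomic coordinate of the cytosine, as printed
    in the Bismark coverage file it came from.
    """

    chrom: str
    pos: int
    count_meth: int
    count_unmeth: int
    sample_id: str
    group: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"CpG position must be >= 1, got {self.pos}")
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValidationError("read counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, as in BED."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class GeneModel:
    """A gene with sorted non-overlapping exons and a strand-aware TSS.

    The TSS is the leftmost exon start on the + strand and the rightmost
    exon end on the - strand (both in the 0-based half-open system, so on
    the minus strand the TSS base itself is ``tss - 1``).  Introns are the
    gaps between consecutive exons.
    """

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    tss: int
    exons: list[GenomicInterval]
    introns: list[GenomicInterval] = field(default_factory=list)

    @classmethod
    def from_exons(
        cls,
        gene_id: str,
        gene_name: str,
        biotype: str,
        chrom: str,
        strand: str,
        exons: Sequence[GenomicInterval],
    ) -> "GeneModel":
        if not exons:
            raise ValidationError(f"gene {gene_id} has no exons")
        if strand not in {"+", "-"}:
            raise ValidationError(f"gene {gene_id}: strand must be '+' or '-'")
        if biotype not in {"coding", "noncoding"}:
            raise ValidationError(f"gene {gene_id}: biotype must be coding/noncoding")
        exons = sorted(exons, key=lambda e: (e.start, e.end))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"gene {gene_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        tss = exons[0].start if strand == "+" else exons[-1].end
        introns = [
            GenomicInterval(chrom, a.end, b.start)
            for a, b in zip(exons, exons[1:])
            if b.start > a.end
        ]
        return cls(gene_id, gene_name, biotype, chrom, strand, tss, list(exons), introns)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


@dataclass(slots=True)
class GeneSetCollection:
    """Mapping set_id -> (description, member gene symbols), deduplicated."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def add(self, set_id: str, description: str, members: Iterable[str]) -> None:
        if set_id in self.sets:
            raise ValidationError(f"duplicate gene set id {set_id!r}")
        seen: dict[str, None] = {}
        for m in members:
            seen.setdefault(m)
        self.sets[set_id] = (description, list(seen))

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out.update(genes)
        return out


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime pinned to zero so identical runs are byte-identical
            return io.TextIOWrapper(
                gzip.GzipFile(path, "wb", mtime=0), encoding="utf-8"
            )
        return gzip.open(path, mode)
    return open(path, mode)


_CHROM_RE = re.compile(r"^(?:chr)?(\d+|X|Y|MT?)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> tuple[int, float, str]:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    m = _CHROM_RE.match(chrom)
    if m:
        token = m.group(1).upper()
        if token.isdigit():
            return (0, int(token), "")
        return (0, {"X": 23, "Y": 24, "M": 25, "MT": 25}[token], "")
    return (1, 0, chrom)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_bismark_coverage(
    path: str | Path, sample_id: str, group: str
) -> list[CpGRecord]:
    """Read a Bismark coverage file (chrom, start, end, %meth, meth, unmeth).

    The position is taken from the 1-based start column; the percent column
    is ignored and recomputed downstream from the counts.
    """
    records: list[CpGRecord] = []
    seen: set[tuple[str, int]] = set()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                pos = int(fields[1])
                count_meth = int(fields[4])
                count_unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            if pos < 1 or count_meth < 0 or count_unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative or zero-position value")
            key = (chrom, pos)
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate site {chrom}:{pos}")
            seen.add(key)
            records.append(
                CpGRecord(chrom, pos, count_meth, count_unmeth, sample_id, group)
            )
    return records


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, kept 0-based half-open exactly as in BED."""
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 else None
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in {"+", "-", "."}:
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand != ".":
                cols.append(iv.name if iv.name is not None else ".")
            if iv.strand != ".":
                cols.extend(["0", iv.strand])
            fh.write("\t".join(cols) + "\n")


_CODING_BIOTYPES = {"coding", "protein_coding"}
_NONCODING_BIOTYPES = {
    "noncoding",
    "lncRNA",
    "lincRNA",
    "miRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "antisense",
    "misc_RNA",
    "ncRNA",
    "pseudogene",
    "processed_pseudogene",
    "unprocessed_pseudogene",
}


def _map_biotype(raw: str, gene_id: str) -> str:
    if raw in _CODING_BIOTYPES:
        return "coding"
    if raw in _NONCODING_BIOTYPES:
        return "noncoding"
    logger.warning("unknown biotype %r for gene %s; treating as noncoding", raw, gene_id)
    return "noncoding"


def read_gene_models(path: str | Path, dialect: str) -> list[GeneModel]:
    """Read gene models from BED12 (optional 13th biotype column) or minimal GTF.

    The GTF dialect understands ``gene`` and ``exon`` features and the
    ``gene_id`` / ``gene_name`` / ``gene_biotype`` attributes only.
    """
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r} (use 'bed12' or 'gtf')")


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs >= 12 columns")
            chrom, start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
            n_blocks = int(fields[9])
            if n_blocks < 1:
                raise ValidationError(f"{path}:{lineno}: blockCount must be >= 1")
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block lists disagree with blockCount")
            exons = [
                GenomicInterval(chrom, start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            ]
            biotype = _map_biotype(fields[12] if len(fields) >= 13 else "coding", name)
            try:
                genes.append(
                    GeneModel.from_exons(name, name, biotype, chrom, strand, exons)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path: str | Path) -> list[GeneModel]:
    meta: dict[str, dict[str, str]] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: GTF needs 9 tab-separated columns")
            chrom, _, feature, start, end, _, strand, _, attrs_raw = fields[:9]
            if feature not in {"gene", "exon"}:
                continue
            attrs = dict(_GTF_ATTR_RE.findall(attrs_raw))
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if gene_id not in meta:
                order.append(gene_id)
                meta[gene_id] = {
                    "chrom": chrom,
                    "strand": strand,
                    "gene_name": attrs.get("gene_name", gene_id),
                    "biotype": attrs.get("gene_biotype", "coding"),
                }
                exons[gene_id] = []
            if attrs.get("gene_name"):
                meta[gene_id]["gene_name"] = attrs["gene_name"]
            if attrs.get("gene_biotype"):
                meta[gene_id]["biotype"] = attrs["gene_biotype"]
            iv = GenomicInterval(chrom, int(start) - 1, int(end))  # GTF is 1-based closed
            if feature == "exon":
                exons[gene_id].append(iv)
            elif not exons[gene_id]:
                # keep gene extent as a fallback single exon until exon lines appear
                meta[gene_id]["_extent"] = f"{iv.start},{iv.end}"
    genes: list[GeneModel] = []
    for gid in order:
        info = meta[gid]
        ex = exons[gid]
        if not ex and "_extent" in info:
            s, e = (int(x) for x in info["_extent"].split(","))
            ex = [GenomicInterval(info["chrom"], s, e)]
        genes.append(
            GeneModel.from_exons(
                gid,
                info["gene_name"],
                _map_biotype(info["biotype"], gid),
                info["chrom"],
                info["strand"],
                ex,
            )
        )
    return genes


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 plus a 13th biotype column (read back as-is)."""
    with _open_text(path, "wt") as fh:
        for g in genes:
            start, end = g.start, g.end
            sizes = ",".join(str(len(e)) for e in g.exons)
            offsets = ",".join(str(e.start - start) for e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(start),
                        str(end),
                        g.gene_name,
                        "0",
                        g.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                        g.biotype,
                    ]
                )
                + "\n"
            )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: set_id, description, then member symbols."""
    coll = GeneSetCollection()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT needs >= 3 tab-separated fields")
            try:
                coll.add(fields[0], fields[1], fields[2:])
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

# column -> (candidate source attributes, format kind)
# kinds: s=string, i=int, f2=fixed 2 decimals, f1=fixed 1 decimal,
#        e=scientific, b=bool, loc=chrom:start-end composite
_SCHEMAS: dict[str, list[tuple[str, tuple[str, ...], str]]] = {
    "dms": [
        ("chrom", ("chrom",), "s"),
        ("pos", ("pos",), "i"),
        ("meth_case", ("meth_case", "meth_frac_case"), "f2"),
        ("meth_ctrl", ("meth_ctrl", "meth_frac_control"), "f2"),
        ("diff", ("diff", "meth_diff"), "f2"),
        ("p", ("p", "p_value"), "e"),
        ("q", ("q", "q_value"), "e"),
        ("dms", ("dms", "is_dms"), "b"),
        ("direction", ("direction",), "s"),
    ],
    "dmr": [
        ("location", ("location",), "s"),
        ("size_bp", ("size_bp",), "i"),
        ("state", ("state",), "s"),
        ("sig_cpgs", ("sig_cpgs",), "i"),
        ("n_island", ("n_island",), "i"),
        ("n_shore", ("n_shore",), "i"),
        ("n_other", ("n_other",), "i"),
        ("q_value", ("q_value",), "e"),
        ("mean_md", ("mean_md",), "f2"),
        ("max_md", ("max_md",), "f2"),
        ("genomic_feature", ("genomic_feature",), "s"),
        ("genic_annotation", ("genic_annotation",), "s"),
    ],
    "proportions": [
        ("stratum", ("stratum",), "s"),
        ("category", ("category",), "s"),
        ("count", ("count",), "i"),
        ("percent", ("percent",), "f1"),
    ],
    "enrichment": [
        ("set_id", ("set_id",), "s"),
        ("set_size", ("set_size", "set_size_in_universe"), "i"),
        ("overlap", ("overlap",), "i"),
        ("p", ("p", "p_value"), "e"),
        ("q", ("q", "q_value"), "e"),
        ("passes", ("passes", "passes_filters"), "b"),
        ("genes", ("genes", "overlap_genes"), "s"),
    ],
    "opposing": [
        ("chrom", ("chrom",), "s"),
        ("start", ("start",), "i"),
        ("end", ("end",), "i"),
        ("state_disease", ("state_disease",), "s"),
        ("state_treatment", ("state_treatment",), "s"),
        ("feature", ("feature",), "s"),
    ],
    "qpcr": [
        ("sample_id", ("sample_id",), "s"),
        ("group", ("group",), "s"),
        ("gene", ("gene",), "s"),
        ("ct", ("ct",), "f2"),
    ],
}

_SORT_KEYS: dict[str, tuple[str, ...]] = {
    "dms": ("chrom", "pos"),
    "dmr": ("chrom", "start"),
    "opposing": ("chrom", "start"),
}


def _get_field(record, names: tuple[str, ...]):
    for name in names:
        if isinstance(record, dict):
            if name in record:
                return record[name]
        elif hasattr(record, name):
            return getattr(record, name)
    raise KeyError(f"record {record!r} has none of {names}")


def _as_row(record, schema: str) -> dict[str, object]:
    row: dict[str, object] = {}
    if schema == "dmr":
        chrom = _get_field(record, ("chrom",))
        start = _get_field(record, ("start",))
        end = _get_field(record, ("end",))
        row["location"] = f"{chrom}:{start}-{end}"
        row["chrom"], row["start"], row["end"] = chrom, start, end
    if schema == "opposing" and not isinstance(record, dict) and hasattr(record, "interval"):
        iv = record.interval
        row["chrom"], row["start"], row["end"] = iv.chrom, iv.start, iv.end
    for col, sources, _ in _SCHEMAS[schema]:
        if col in row:
            continue
        value = _get_field(record, sources)
        if col == "genes" and not isinstance(value, str):
            value = ",".join(value)
        row[col] = value
    return row


def _format(value, kind: str) -> str:
    if value is None:
        return "NA"
    if kind == "s":
        return str(value)
    if kind == "i":
        return str(int(value))
    if kind == "f2":
        return f"{float(value):.2f}"
    if kind == "f1":
        return f"{float(value):.1f}"
    if kind == "e":
        return f"{float(value):.6e}"
    if kind == "b":
        return "True" if value else "False"
    raise AssertionError(kind)


def write_results_tsv(records: Iterable, path: str | Path, schema: str) -> None:
    """Write a result table with a fixed column order and pinned formatting.

    ``schema`` is one of dms, dmr, proportions, enrichment, opposing, qpcr.
    Genomic schemas are sorted by (chromosome, position).
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown results schema {schema!r}")
    spec = _SCHEMAS[schema]
    rows = [_as_row(r, schema) for r in records]
    if schema in _SORT_KEYS:
        keys = _SORT_KEYS[schema]
        rows.sort(key=lambda r: (chrom_sort_key(str(r[keys[0]])), r[keys[1]]))
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(col for col, _, _ in spec) + "\n")
        for row in rows:
            fh.write("\t".join(_format(row[col], kind) for col, _, kind in spec) + "\n")


_LOCATION_RE = re.compile(r"^(.+):(\d+)-(\d+)$")


def read_results_tsv(path: str | Path, schema: str) -> list[dict[str, object]]:
    """Read back a table written by :func:`write_results_tsv` as typed dicts."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown results schema {schema!r}")
    spec = _SCHEMAS[schema]
    out: list[dict[str, object]] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [col for col, _, _ in spec]
        if header != expected:
            raise ParseError(f"{path}: header {header} != expected {expected}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            if len(values) != len(spec):
                raise ParseError(f"{path}:{lineno}: wrong column count")
            row: dict[str, object] = {}
            for (col, _, kind), text in zip(spec, values):
                if text == "NA":
                    row[col] = None
                elif kind == "i":
                    row[col] = int(text)
                elif kind in {"f2", "f1", "e"}:
                    row[col] = float(text)
                elif kind == "b":
                    row[col] = text == "True"
                else:
                    row[col] = text
            if schema == "dmr":
                m = _LOCATION_RE.match(str(row["location"]))
                if not m:
                    raise ParseError(f"{path}:{lineno}: bad location {row['location']!r}")
                row["chrom"] = m.group(1)
                row["start"] = int(m.group(2))
                row["end"] = int(m.group(3))
            out.append(row)
    return out
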