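"""Cross-comparison logic and qPCR fold-change validation.

Two comparisons drive the design: the treatment effect (treated vs
untreated) and the disease effect (untreated vs control).  Regions called
in both but with opposite states — e.g. hypomethylated by the disease and
hypermethylated under treatment — are candidate insult-and-correction
loci.  Matching anchors on the identical (chromosome, start) coordinate.

Expression validation uses the ddCt method: per sample,
dCt = Ct(target) - Ct(reference); per group the mean dCt; then
ddCt = dCt(case) - dCt(control) and fold change = 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import GenomicInterval, chrom_sort_key


@dataclass(frozen=True)
class OpposingDMR:
    interval: GenomicInterval
    state_disease: str
    state_treatment: str
    feature: str

    def __post_init__(self) -> None:
        if self.state_disease == self.state_treatment:
            raise ValueError("opposing DMR must change direction between comparisons")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    group: str
    gene: str
    ct: float  # technical-duplicate mean cycle threshold

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")


def intersect_dmrs_opposite(dmrs_disease: Sequence, dmrs_treatment: Sequence) -> list[OpposingDMR]:
    """Regions present in both DMR sets with opposite states.

    Matching is by identical (chrom, start) anchor; the stored interval and
    feature come from the disease-effect record.  Output is sorted by
    chromosome then start.
    """
    by_anchor = {(d.chrom, d.start): d for d in dmrs_treatment}
    out: list[OpposingDMR] = []
    for d in dmrs_disease:
        t = by_anchor.get((d.chrom, d.start))
        if t is None or t.state == d.state:
            continue
        feature = getattr(d, "genomic_feature", "") or getattr(d, "feature", "")
        out.append(
            OpposingDMR(
                GenomicInterval(d.chrom, d.start, max(d.end, d.start + 1)),
                state_disease=d.state,
                state_treatment=t.state,
                feature=feature,
            )
        )
    out.sort(key=lambda o: (chrom_sort_key(o.chrom), o.start))
    return out


def _group_delta_ct(
    measurements: Iterable[QpcrMeasurement], target: str, reference: str, group: str
) -> tuple[float, list[float]]:
    """Mean per-sample dCt for one group; errors name samples missing the reference."""
    target_ct: dict[str, float] = {}
    ref_ct: dict[str, float] = {}
    for m in measurements:
        if m.group != group:
            continue
        if m.gene == target:
            target_ct[m.sample_id] = m.ct
        elif m.gene == reference:
            ref_ct[m.sample_id] = m.ct
    if not target_ct:
        raise ValueError(f"no {target!r} measurements in group {group!r}")
    missing = sorted(set(target_ct) - set(ref_ct))
    if missing:
        raise ValueError(
            f"samples missing reference gene {reference!r} in group {group!r}: "
            + ", ".join(missing)
        )
    per_sample = [target_ct[s] - ref_ct[s] for s in sorted(target_ct)]
    return sum(per_sample) / len(per_sample), per_sample


def ddct_fold_change(
    measurements: Sequence[QpcrMeasurement],
    target: str,
    reference: str,
    case_group: str,
    control_group: str,
) -> float:
    """Relative fold change 2^(-ddCt) of target vs reference, case vs control."""
    dct_case, _ = _group_delta_ct(measurements, target, reference, case_group)
    dct_ctrl, _ = _group_delta_ct(measurements, target, reference, control_group)
    return 2.0 ** (-(dct_case - dct_ctrl))


def ddct_per_sample(
    measurements: Sequence[QpcrMeasurement],
    target: str,
    reference: str,
    group: str,
) -> list[float]:
    """Per-sample dCt values for one group (for distribution reporting)."""
    _, per_sample = _group_delta_ct(measurements, target, reference, group)
    return per_sample


def direction_consistency(region_state: str, fold_change: float, tau: float = 0.2) -> str:
    """Concordance of a region's methylation state with an expression fold change.

    Hypomethylation is expected to permit expression (fold >= 1 + tau) and
    hypermethylation to repress it (fold <= 1 - tau); changes within tau of
    1 count as no_change, anything else is discordant.
    """
    if region_state not in {"hyper", "hypo"}:
        raise ValueError(f"region state must be hyper/hypo, got {region_state!r}")
    if region_state == "hypo" and fold_change >= 1.0 + tau:
        return "concordant"
    if region_state == "hyper" and fold_change <= 1.0 - tau:
        return "concordant"
    if abs(fold_change - 1.0) <= tau:
        return "no_change"
    return "discordant"
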