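"""Per-CpG differential methylation testing and DMS calling.

The group comparison follows the methylKit-style logistic regression of
methylated/unmethylated counts on group membership.  With a group-only
covariate the binomial MLE of each group's methylation level is simply its
pooled methylated fraction, so the likelihood-ratio statistic (chi-square,
1 df) has a closed form and needs no iterative fitting.  When each group
contributes exactly one sample the comparison degenerates to a 2x2 table
and a two-sided Fisher's exact test is used instead.

A site is a DMS when the pooled percent-methylation difference exceeds 25
percentage points in magnitude and the BH-adjusted p (q-value) is below
0.01, both strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .io_formats import CpGRecord


class EmptyResultError(ValueError):
    """Filtering or testing left no usable sites."""


@dataclass
class CpGTestResult:
    """One CpG site's case-vs-control comparison."""

    chrom: str
    pos: int
    n_samples_case: int
    n_samples_control: int
    meth_frac_case: float  # pooled percent methylation, case group
    meth_frac_control: float
    meth_diff: float  # case - control, percentage points
    p_value: float
    q_value: float = math.nan
    is_dms: bool = False
    direction: str = "none"  # hyper | hypo | none


# ---------------------------------------------------------------------------
# Coverage filtering
# ---------------------------------------------------------------------------


def filter_coverage(
    records: list[CpGRecord],
    min_cov: int = 10,
    max_percentile: float = 99.9,
) -> list[CpGRecord]:
    """methylKit-style per-sample coverage filter plus complete-case intersection.

    Per sample, sites with total coverage below ``min_cov`` are removed, as
    are sites above that sample's ``max_percentile`` coverage quantile
    (PCR-duplicate guard).  Only sites that survive in *every* sample are
    retained, so downstream tests always see complete data.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not (50 < max_percentile <= 100):
        raise ValueError("max_percentile must lie in (50, 100]")
    if not records:
        raise EmptyResultError("no records to filter")

    by_sample: dict[str, list[CpGRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    n_samples = len(by_sample)

    kept: list[CpGRecord] = []
    site_counts: dict[tuple[str, int], int] = {}
    for sample_recs in by_sample.values():
        covs = np.array([r.coverage for r in sample_recs])
        ceiling = np.percentile(covs, max_percentile)
        for rec, cov in zip(sample_recs, covs):
            if min_cov <= cov <= ceiling:
                kept.append(rec)
                site_counts[(rec.chrom, rec.pos)] = (
                    site_counts.get((rec.chrom, rec.pos), 0) + 1
                )

    complete = {site for site, n in site_counts.items() if n == n_samples}
    out = [r for r in kept if (r.chrom, r.pos) in complete]
    if not out:
        raise EmptyResultError(
            f"coverage filter (min_cov={min_cov}, max_percentile={max_percentile}) "
            "removed every site"
        )
    return out


# ---------------------------------------------------------------------------
# Per-site tests
# ---------------------------------------------------------------------------


def _binomial_loglik(m, u, p):
    return xlogy(m, p) + xlogy(u, 1.0 - p)


def test_cpg(
    case_counts: list[tuple[int, int]],
    control_counts: list[tuple[int, int]],
) -> tuple[float, float]:
    """Test one site; counts are (meth, unmeth) pairs, one per sample.

    Returns (statistic, p).  Multi-sample groups use the logistic LRT;
    a 1-vs-1 design uses two-sided Fisher's exact on the 2x2 table.  A
    group with zero total coverage yields (nan, nan) — the site is
    untestable and excluded from multiple-testing correction.
    """
    mc = sum(m for m, _ in case_counts)
    uc = sum(u for _, u in case_counts)
    mk = sum(m for m, _ in control_counts)
    uk = sum(u for _, u in control_counts)
    if mc + uc == 0 or mk + uk == 0:
        return math.nan, math.nan
    if len(case_counts) == 1 and len(control_counts) == 1:
        result = stats.fisher_exact([[mc, uc], [mk, uk]], alternative="two-sided")
        return float(result[0]), float(result[1])
    return _lrt_from_pooled(mc, uc, mk, uk)


def _lrt_from_pooled(mc, uc, mk, uk) -> tuple[float, float]:
    pc = mc / (mc + uc)
    pk = mk / (mk + uk)
    pa = (mc + mk) / (mc + uc + mk + uk)
    stat = 2.0 * (
        _binomial_loglik(mc, uc, pc)
        + _binomial_loglik(mk, uk, pk)
        - _binomial_loglik(mc, uc, pa)
        - _binomial_loglik(mk, uk, pa)
    )
    stat = max(float(stat), 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, NaN-aware.

    q_(i) = min_{j >= i} p_(j) * n / j over the sorted non-NaN p's, capped
    at 1; NaN inputs stay NaN and do not count toward n.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    mask = ~np.isnan(p)
    ps = p[mask]
    if ps.size and (ps.min() < 0 or ps.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    n = ps.size
    if n == 0:
        return q
    order = np.argsort(ps, kind="stable")
    scaled = ps[order] * n / np.arange(1, n + 1)
    stepped = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(stepped, 1.0)
    q[mask] = out
    return q


def call_dms(
    results: list[CpGTestResult],
    diff_threshold: float = 25.0,
    q_threshold: float = 0.01,
) -> list[CpGTestResult]:
    """Flag DMSs: |meth_diff| > diff_threshold and q < q_threshold (strict)."""
    for r in results:
        if (
            not math.isnan(r.q_value)
            and abs(r.meth_diff) > diff_threshold
            and r.q_value < q_threshold
        ):
            r.is_dms = True
            r.direction = "hyper" if r.meth_diff > 0 else "hypo"
        else:
            r.is_dms = False
            r.direction = "none"
    return results


# ---------------------------------------------------------------------------
# Comparison driver
# ---------------------------------------------------------------------------


def compare_groups(
    records: list[CpGRecord],
    case_group: str,
    control_group: str,
) -> list[CpGTestResult]:
    """Test every site present in (already filtered) records of two groups.

    ``meth_diff`` is pooled case percent minus pooled control percent, the
    "methylation difference" in percentage points.  q-values are left
    unset; apply :func:`bh_adjust` / :func:`call_dms` afterwards.
    """
    subset = [r for r in records if r.group in (case_group, control_group)]
    if not subset:
        raise EmptyResultError(
            f"no records for groups {case_group!r} / {control_group!r}"
        )
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in subset],
            "pos": [r.pos for r in subset],
            "group": [r.group for r in subset],
            "sample_id": [r.sample_id for r in subset],
            "meth": [r.count_meth for r in subset],
            "unmeth": [r.count_unmeth for r in subset],
        }
    )
    n_case = df.loc[df["group"] == case_group, "sample_id"].nunique()
    n_ctrl = df.loc[df["group"] == control_group, "sample_id"].nunique()
    if n_case == 0 or n_ctrl == 0:
        raise EmptyResultError("one comparison group has no samples")

    pooled = (
        df.groupby(["chrom", "pos", "group"], sort=False)[["meth", "unmeth"]]
        .sum()
        .unstack("group")
    )
    mc = pooled[("meth", case_group)].to_numpy(dtype=float)
    uc = pooled[("unmeth", case_group)].to_numpy(dtype=float)
    mk = pooled[("meth", control_group)].to_numpy(dtype=float)
    uk = pooled[("unmeth", control_group)].to_numpy(dtype=float)
    chroms = pooled.index.get_level_values("chrom")
    positions = pooled.index.get_level_values("pos")

    tot_c = mc + uc
    tot_k = mk + uk
    testable = (tot_c > 0) & (tot_k > 0) & ~np.isnan(tot_c) & ~np.isnan(tot_k)

    frac_c = np.where(tot_c > 0, mc / np.where(tot_c > 0, tot_c, 1), np.nan)
    frac_k = np.where(tot_k > 0, mk / np.where(tot_k > 0, tot_k, 1), np.nan)

    if n_case == 1 and n_ctrl == 1:
        p = np.full(mc.shape, np.nan)
        for i in np.flatnonzero(testable):
            _, p[i] = stats.fisher_exact(
                [[int(mc[i]), int(uc[i])], [int(mk[i]), int(uk[i])]],
                alternative="two-sided",
            )
    else:
        pc = np.where(testable, frac_c, 0.5)
        pk = np.where(testable, frac_k, 0.5)
        pa = np.where(testable, (mc + mk) / np.where(testable, tot_c + tot_k, 1), 0.5)
        stat = 2.0 * (
            _binomial_loglik(mc, uc, pc)
            + _binomial_loglik(mk, uk, pk)
            - _binomial_loglik(mc, uc, pa)
            - _binomial_loglik(mk, uk, pa)
        )
        stat = np.clip(stat, 0.0, None)
        p = np.where(testable, stats.chi2.sf(stat, df=1), np.nan)

    results = [
        CpGTestResult(
            chrom=str(chroms[i]),
            pos=int(positions[i]),
            n_samples_case=n_case,
            n_samples_control=n_ctrl,
            meth_frac_case=100.0 * frac_c[i],
            meth_frac_control=100.0 * frac_k[i],
            meth_diff=100.0 * (frac_c[i] - frac_k[i]),
            p_value=float(p[i]),
        )
        for i in range(len(mc))
    ]
    return results


def analyze_comparison(
    records: list[CpGRecord],
    case_group: str,
    control_group: str,
    min_cov: int = 10,
    max_percentile: float = 99.9,
    diff_threshold: float = 25.0,
    q_threshold: float = 0.01,
) -> list[CpGTestResult]:
    """Filter, test, BH-adjust and call DMSs for one comparison."""
    subset = [r for r in records if r.group in (case_group, control_group)]
    filtered = filter_coverage(subset, min_cov=min_cov, max_percentile=max_percentile)
    results = compare_groups(filtered, case_group, control_group)
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return call_dms(results, diff_threshold=diff_threshold, q_threshold=q_threshold)
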