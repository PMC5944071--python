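"""Statistical identification of mutations between t0 and outgrowth samples.

Three tests are combined at each candidate site.  A chi-square goodness-of-
fit test compares the outgrowth's read counts per allele and strand against
expectations formed from the t0 proportions.  Per allele and per strand, an
upper-tail binomial p-value compares the outgrowth count against the t0
allelic fraction on that strand (pseudo-counted where the t0 count is zero).
The per-allele composite score

    score = sqrt( (-log10 p_top)^2 + (-log10 p_bottom)^2 + (-log10 p_chi)^2 )

is the distance from certainty that no mutation occurred.  A site is called
when p_chi < 0.1 and some allele has composite score above the Sidak
FWER-derived threshold with both strand binomial p-values < 0.1 — requiring
both strands suppresses calls driven by mismapped single-strand reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .counts import SiteCounts
from .genotype import GenotypeCall, sidak_alpha
from .tracks import Interval

__all__ = [
    "FilterStatus",
    "Thresholds",
    "SiteStatistics",
    "sidak_alpha",
    "site_statistics_batch",
    "compare_site",
    "decide_mutation",
    "decide_mutation_batch",
    "single_strand_or_single_allele",
    "apply_filters",
]

_P_MIN = 1e-300  # keeps -log10 finite


class FilterStatus(str, Enum):
    PASS = "pass"
    EXCLUDED_REGION = "excluded_region"
    ABNORMAL_DEPTH = "abnormal_depth"
    LOW_DEPTH = "low_depth"
    T0_SUBCLONAL_BIAS = "t0_subclonal_bias"
    SINGLE_STRAND_SINGLE_ALLELE = "single_strand_single_allele"
    BELOW_THRESHOLD = "below_threshold"


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for mutation calling."""

    fwer: float = 0.01
    n_tests: int = 1
    marginal_p_max: float = 0.1
    min_depth: int = 20

    @property
    def per_test_alpha(self) -> float:
        return sidak_alpha(self.fwer, self.n_tests)

    @property
    def composite_threshold(self) -> float:
        """The FWER-derived bound compared against the composite score."""
        return -math.log10(self.per_test_alpha)


@dataclass
class SiteStatistics:
    """Per-site test results; lists are parallel to the site's alleles."""

    alleles: list[str]
    p_chi: float
    p_top: list[float]
    p_bottom: list[float]

    @property
    def composite(self) -> list[float]:
        lc = -math.log10(max(self.p_chi, _P_MIN))
        return [
            math.sqrt(
                math.log10(max(pt, _P_MIN)) ** 2
                + math.log10(max(pb, _P_MIN)) ** 2
                + lc**2
            )
            for pt, pb in zip(self.p_top, self.p_bottom)
        ]


def site_statistics_batch(
    t0_top: np.ndarray,
    t0_bottom: np.ndarray,
    og_top: np.ndarray,
    og_bottom: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised statistics for ``n`` sites sharing an allele count ``k``.

    All inputs have shape (n, k).  Returns ``(p_chi, p_top, p_bottom,
    composite)`` with ``p_chi`` of shape (n,) and the rest (n, k).

    The chi-square expectation takes the t0 cell proportions (every cell
    pseudo-counted by 1) times the outgrowth total; df = 2k - 1.  The
    binomial tests use per-strand outgrowth totals as trials and the t0
    per-strand allele fraction (floored at 1/(strand total + 1) when the t0
    count is zero) as success probability.
    """
    t0_top = np.asarray(t0_top, dtype=np.float64)
    t0_bottom = np.asarray(t0_bottom, dtype=np.float64)
    og_top = np.asarray(og_top, dtype=np.float64)
    og_bottom = np.asarray(og_bottom, dtype=np.float64)
    n, k = t0_top.shape

    # chi-square over alleles x strands
    t0_cells = np.concatenate([t0_top, t0_bottom], axis=1) + 1.0
    og_cells = np.concatenate([og_top, og_bottom], axis=1)
    props = t0_cells / t0_cells.sum(axis=1, keepdims=True)
    expected = props * og_cells.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.sum((og_cells - expected) ** 2 / expected, axis=1)
    p_chi = stats.chi2.sf(stat, df=2 * k - 1)
    p_chi = np.clip(p_chi, _P_MIN, 1.0)

    def strand_binom(t0_counts: np.ndarray, og_counts: np.ndarray) -> np.ndarray:
        t0_tot = t0_counts.sum(axis=1, keepdims=True)
        og_tot = og_counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = t0_counts / t0_tot
        frac = np.where(np.isfinite(frac), frac, 0.0)
        # pseudo-count where the t0 read count is zero
        frac = np.where(t0_counts == 0, 1.0 / (t0_tot + 1.0), frac)
        p = stats.binom.sf(og_counts - 1.0, np.broadcast_to(og_tot, og_counts.shape), frac)
        return np.clip(p, _P_MIN, 1.0)

    p_top = strand_binom(t0_top, og_top)
    p_bottom = strand_binom(t0_bottom, og_bottom)

    composite = np.sqrt(
        np.log10(p_top) ** 2
        + np.log10(p_bottom) ** 2
        + (np.log10(p_chi) ** 2)[:, None]
    )
    return p_chi, p_top, p_bottom, composite


def _strand_arrays(site: SiteCounts, sample: str) -> tuple[np.ndarray, np.ndarray]:
    per_allele = site.counts[sample]
    return (
        np.array([sc.top for sc in per_allele], dtype=np.float64),
        np.array([sc.bottom for sc in per_allele], dtype=np.float64),
    )


def compare_site(site: SiteCounts, t0_sample: str, outgrowth_sample: str) -> SiteStatistics:
    """Compute all site statistics for one (t0, outgrowth) pair."""
    t0t, t0b = _strand_arrays(site, t0_sample)
    ogt, ogb = _strand_arrays(site, outgrowth_sample)
    p_chi, p_top, p_bottom, _ = site_statistics_batch(
        t0t[None, :], t0b[None, :], ogt[None, :], ogb[None, :]
    )
    return SiteStatistics(
        alleles=list(site.alleles),
        p_chi=float(p_chi[0]),
        p_top=[float(v) for v in p_top[0]],
        p_bottom=[float(v) for v in p_bottom[0]],
    )


def decide_mutation(
    statistics: SiteStatistics, thresholds: Thresholds
) -> tuple[bool, list[bool]]:
    """Apply the composite decision rule.

    Returns ``(site_is_putative_mutation, per_allele_flags)``: p_chi must be
    below 0.1 and at least one allele must combine composite score above the
    FWER-derived threshold with both strand p-values below 0.1.
    """
    if statistics.p_chi >= thresholds.marginal_p_max:
        return False, [False] * len(statistics.alleles)
    comp = statistics.composite
    flags = [
        c > thresholds.composite_threshold
        and pt < thresholds.marginal_p_max
        and pb < thresholds.marginal_p_max
        for c, pt, pb in zip(comp, statistics.p_top, statistics.p_bottom)
    ]
    return any(flags), flags


def decide_mutation_batch(
    p_chi: np.ndarray,
    p_top: np.ndarray,
    p_bottom: np.ndarray,
    composite: np.ndarray,
    thresholds: Thresholds,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised decision rule; returns (site mask (n,), allele mask (n, k))."""
    allele_ok = (
        (composite > thresholds.composite_threshold)
        & (p_top < thresholds.marginal_p_max)
        & (p_bottom < thresholds.marginal_p_max)
    )
    site_ok = (p_chi < thresholds.marginal_p_max) & allele_ok.any(axis=1)
    return site_ok, allele_ok & site_ok[:, None]


def single_strand_or_single_allele(site: SiteCounts, t0_sample: str, outgrowth_sample: str) -> bool:
    """True when the comparison is not meaningful at this site.

    Either sample having all of its reads on a single strand, or fewer than
    two alleles carrying reads across both samples combined, marks the
    mismapping-prone coverage pattern excluded from comparison.
    """
    observed = 0
    for i in range(len(site.alleles)):
        tot = sum(site.counts[s][i].total for s in (t0_sample, outgrowth_sample))
        if tot > 0:
            observed += 1
    if observed < 2:
        return True
    for s in (t0_sample, outgrowth_sample):
        per_allele = site.counts[s]
        top = sum(sc.top for sc in per_allele)
        bottom = sum(sc.bottom for sc in per_allele)
        if top == 0 or bottom == 0:
            return True
    return False


def _in_regions(regions: Sequence[Interval], chrom: str, pos: int) -> bool:
    return any(iv.contains(chrom, pos) for iv in regions)


def apply_filters(
    site: SiteCounts,
    t0_sample: str,
    outgrowth_sample: str,
    decision: bool,
    thresholds: Thresholds,
    abnormal_regions: Sequence[Interval] = (),
    exclusions: Sequence[Interval] = (),
    t0_call: Optional[GenotypeCall] = None,
) -> FilterStatus:
    """Assign the first matching filter reason for a candidate site.

    Order: user exclusion BED; abnormal-depth region (either sample's);
    depth below threshold in either sample; t0 subclonal strand-bias flag;
    single-strand/single-allele coverage; statistical thresholds.
    """
    if _in_regions(exclusions, site.chrom, site.pos):
        return FilterStatus.EXCLUDED_REGION
    if _in_regions(abnormal_regions, site.chrom, site.pos):
        return FilterStatus.ABNORMAL_DEPTH
    if (
        site.depth(t0_sample) < thresholds.min_depth
        or site.depth(outgrowth_sample) < thresholds.min_depth
    ):
        return FilterStatus.LOW_DEPTH
    if t0_call is not None and t0_call.subclonal_rejected_reason == "strand_bias":
        return FilterStatus.T0_SUBCLONAL_BIAS
    if single_strand_or_single_allele(site, t0_sample, outgrowth_sample):
        return FilterStatus.SINGLE_STRAND_SINGLE_ALLELE
    if not decision:
        return FilterStatus.BELOW_THRESHOLD
    return FilterStatus.PASS
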