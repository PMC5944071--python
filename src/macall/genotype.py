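"""Clonal and subclonal genotype calling by score minimisation.

Observed allelic frequencies at a site are assumed to arise from a clonal
genotype (an allele multiset of cardinality equal to the local copy number)
plus, optionally, a subclonal genotype differing in exactly one allele and
present at a fraction of 1/2, 1/4 or 1/8 — a mutation in the first, second
or third post-bottleneck division.  Every candidate model's expected allele
frequencies are corrected for repeat-context PCR indel error, floored with a
two-read pseudo-count, and scored against the observed frequencies with

    score = sum_i | ln(o_i / e_i) |

The minimum-score model wins; ties go to the model with the most reference
alleles (t0) or most alleles shared with the t0 call (outgrowth).  Subclonal
components must additionally survive a genome-wide-corrected binomial test
and a strand-bias test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Callable, Optional, Sequence

from scipy import stats

from .counts import SiteCounts
from .coverage import StrandBiasDistribution, strand_bias_p_value
from .repeats import RepeatTract

__all__ = [
    "SUBCLONAL_FRACTIONS",
    "GenotypeModel",
    "GenotypeCall",
    "enumerate_models",
    "expected_frequencies",
    "correct_for_indel_error",
    "floor_frequencies",
    "score_genotype",
    "call_genotype",
    "validate_subclonal",
    "sidak_alpha",
]

SUBCLONAL_FRACTIONS = (0.500, 0.250, 0.125)
_TIE_TOL = 1e-9

Genotype = tuple[str, ...]  # sorted allele multiset


@dataclass(frozen=True)
class GenotypeModel:
    """One candidate model: clonal genotype, optional subclonal variant."""

    clonal: Genotype
    subclonal: Optional[Genotype] = None
    fraction: Optional[float] = None

    @property
    def subclonal_allele(self) -> Optional[str]:
        """The allele by which the subclonal genotype differs from the clonal."""
        if self.subclonal is None:
            return None
        counts = dict.fromkeys(set(self.subclonal), 0)
        for a in self.subclonal:
            counts[a] += 1
        for a in self.clonal:
            if a in counts and counts[a] > 0:
                counts[a] -= 1
        for a, c in counts.items():
            if c > 0:
                return a
        return None


@dataclass
class GenotypeCall:
    clonal: Genotype
    subclonal: Optional[tuple[str, float]] = None
    score: float = 0.0
    subclonal_rejected_reason: Optional[str] = None  # "binomial" | "strand_bias"

    @property
    def has_subclonal(self) -> bool:
        return self.subclonal is not None


def sidak_alpha(fwer: float, n_tests: int) -> float:
    """Per-test alpha controlling family-wise error at ``fwer`` over ``n_tests``.

    alpha = 1 - (1 - fwer)^(1/n), evaluated via expm1/log1p so the identity
    (1 - alpha)^n = 1 - fwer holds to full double precision at genome-scale n.
    """
    if not 0.0 < fwer < 1.0:
        raise ValueError("fwer must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return -math.expm1(math.log1p(-fwer) / n_tests)


def enumerate_models(
    observed_alleles: Sequence[str], copy_number: int
) -> list[GenotypeModel]:
    """All clonal-only and clonal+subclonal models for a site.

    Clonal genotypes are every multiset of size ``copy_number`` over the
    observed alleles; subclonal genotypes substitute exactly one allele of
    the clonal genotype with a different observed allele, at each allowed
    fraction.  Duplicates (identical clonal/subclonal/fraction) are removed.
    """
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    alleles = sorted(set(observed_alleles))
    if not alleles:
        raise ValueError("at least one observed allele required")
    models: list[GenotypeModel] = []
    seen: set[tuple] = set()
    for clonal in combinations_with_replacement(alleles, copy_number):
        key = (clonal, None, None)
        if key not in seen:
            seen.add(key)
            models.append(GenotypeModel(clonal=clonal))
        for i in range(copy_number):
            for alt in alleles:
                if alt == clonal[i]:
                    continue
                sub = tuple(sorted(clonal[:i] + (alt,) + clonal[i + 1 :]))
                for frac in SUBCLONAL_FRACTIONS:
                    key = (clonal, sub, frac)
                    if key not in seen:
                        seen.add(key)
                        models.append(
                            GenotypeModel(clonal=clonal, subclonal=sub, fraction=frac)
                        )
    return models


def expected_frequencies(model: GenotypeModel) -> dict[str, float]:
    """Expected allele frequencies of a clonal(+subclonal) model.

    freq(a) = (1 - f) * count(a, clonal)/|clonal| + f * count(a, subclonal)/|subclonal|
    """
    freqs: dict[str, float] = {}
    f = model.fraction if model.subclonal is not None else 0.0
    n_clonal = len(model.clonal)
    for a in model.clonal:
        freqs[a] = freqs.get(a, 0.0) + (1.0 - f) / n_clonal
    if model.subclonal is not None:
        n_sub = len(model.subclonal)
        for a in model.subclonal:
            freqs[a] = freqs.get(a, 0.0) + f / n_sub
    return freqs


def correct_for_indel_error(
    expected: dict[str, float],
    tract: Optional[RepeatTract],
    rates: Callable[[str, int], float],
    ref_allele: str,
) -> dict[str, float]:
    """Redistribute expected mass to single-unit slippage products.

    For each allele carrying expected mass, a fraction equal to the
    single-unit deletion (insertion) error rate at that allele's implied
    tract length is moved to the allele one repeat unit shorter (longer).
    ``rates(event, tract_length)`` supplies the per-read error rates.  Total
    mass is conserved; with no repeat context this is the identity.
    """
    if tract is None:
        return dict(expected)
    unit = tract.unit
    ul = len(unit)
    out: dict[str, float] = {a: 0.0 for a in expected}
    for allele, mass in expected.items():
        if mass == 0.0 or not allele.startswith(unit):
            out[allele] = out.get(allele, 0.0) + mass
            continue
        implied_length = tract.tract_length + (len(allele) - len(ref_allele))
        r_ins = rates("insertion", implied_length)
        r_del = rates("deletion", implied_length)
        plus = unit + allele
        minus = allele[ul:] if len(allele) > ul else None
        if minus is None:
            r_del = 0.0
        moved = mass * (r_ins + r_del)
        out[allele] = out.get(allele, 0.0) + mass - moved
        if r_ins > 0.0:
            out[plus] = out.get(plus, 0.0) + mass * r_ins
        if r_del > 0.0 and minus is not None:
            out[minus] = out.get(minus, 0.0) + mass * r_del
    return out


def floor_frequencies(expected: dict[str, float], total_depth: int) -> dict[str, float]:
    """Replace zero frequencies with 2/total_depth (one pseudo-count per strand)."""
    if total_depth <= 0:
        raise ValueError("total_depth must be > 0")
    floor = 2.0 / total_depth
    return {a: (f if f > 0.0 else floor) for a, f in expected.items()}


def score_genotype(
    observed: dict[str, float],
    expected: dict[str, float],
    floor: float = 0.0,
) -> float:
    """Sum of |ln(o/e)| over the alleles observed with non-zero frequency.

    The score compares the model's expected rates against the observed rates
    of the site's observed alleles; alleles the model predicts but that carry
    no reads in this sample (e.g. error-correction mass on an unseen slippage
    product) contribute nothing.  An observed allele the model assigns zero
    (or no) expected mass falls back to ``floor`` — the 2/depth pseudo-count
    frequency — penalising models that ignore real alleles.
    """
    score = 0.0
    for a, o in observed.items():
        if o <= 0.0:
            continue
        e = expected.get(a, 0.0)
        if e <= 0.0:
            e = floor
        if e <= 0.0:
            return math.inf
        score += abs(math.log(o / e))
    return score


def _expected_for_model(
    model: GenotypeModel,
    tract: Optional[RepeatTract],
    rates: Optional[Callable[[str, int], float]],
    ref_allele: str,
    depth: int,
) -> dict[str, float]:
    e = expected_frequencies(model)
    if tract is not None and rates is not None:
        e = correct_for_indel_error(e, tract, rates, ref_allele)
    return floor_frequencies(e, depth)


def call_genotype(
    site: SiteCounts,
    sample: str,
    copy_number: int,
    role: str = "t0",
    t0_call: Optional[GenotypeCall] = None,
    tract: Optional[RepeatTract] = None,
    rates: Optional[Callable[[str, int], float]] = None,
) -> Optional[GenotypeCall]:
    """Call the minimum-score genotype model for one sample at one site.

    Returns None (site skipped) at zero depth.  Ties are broken by reference
    allele count for the t0 sample and by allele overlap with the t0 call
    for outgrowths, then lexicographically for determinism.
    """
    if role == "outgrowth" and t0_call is None:
        raise ValueError("outgrowth calls require the t0 call for tie-breaking")
    per_allele = site.counts[sample]
    totals = [sc.total for sc in per_allele]
    depth = sum(totals)
    if depth == 0:
        return None
    observed = {a: t / depth for a, t in zip(site.alleles, totals)}
    floor = 2.0 / depth
    ref = site.ref

    best: Optional[GenotypeModel] = None
    best_score = math.inf
    for model in enumerate_models(site.alleles, copy_number):
        e = _expected_for_model(model, tract, rates, ref, depth)
        s = score_genotype(observed, e, floor=floor)
        if s < best_score - _TIE_TOL:
            best, best_score = model, s
        elif abs(s - best_score) <= _TIE_TOL and best is not None:
            if _prefer(model, best, ref, role, t0_call):
                best = model
    assert best is not None
    sub = None
    if best.subclonal is not None:
        sub = (best.subclonal_allele, best.fraction)
    return GenotypeCall(clonal=best.clonal, subclonal=sub, score=best_score)


def _ref_count(genotype: Genotype, ref: str) -> int:
    return sum(1 for a in genotype if a == ref)


def _shared_count(genotype: Genotype, other: Genotype) -> int:
    pool = list(other)
    shared = 0
    for a in genotype:
        if a in pool:
            pool.remove(a)
            shared += 1
    return shared


def _prefer(
    candidate: GenotypeModel,
    incumbent: GenotypeModel,
    ref: str,
    role: str,
    t0_call: Optional[GenotypeCall],
) -> bool:
    """Tie-break between equal-score models."""
    if role == "t0":
        c, i = _ref_count(candidate.clonal, ref), _ref_count(incumbent.clonal, ref)
    else:
        assert t0_call is not None
        c = _shared_count(candidate.clonal, t0_call.clonal)
        i = _shared_count(incumbent.clonal, t0_call.clonal)
    if c != i:
        return c > i
    # deterministic final tie-break: clonal-only preferred, then lexicographic
    c_key = (candidate.subclonal is not None, candidate.clonal, candidate.subclonal or (), candidate.fraction or 0.0)
    i_key = (incumbent.subclonal is not None, incumbent.clonal, incumbent.subclonal or (), incumbent.fraction or 0.0)
    return c_key < i_key


def validate_subclonal(
    call: GenotypeCall,
    site: SiteCounts,
    sample: str,
    bias_distribution: StrandBiasDistribution,
    n_tests: int,
    fwer: float = 0.01,
    tract: Optional[RepeatTract] = None,
    rates: Optional[Callable[[str, int], float]] = None,
) -> GenotypeCall:
    """Test a subclonal component; revert to the clonal genotype if it fails.

    The subclonal allele's pooled read count is compared by upper-tail
    binomial test against its expected frequency under the clonal-only model
    (the 2/depth floor when that model assigns it no mass); retention
    requires p below the Sidak per-test threshold.  The allele's strand
    ratio is then tested two-tailed against the genome-wide distribution;
    p below the threshold reverts the call and flags strand bias.
    """
    if not call.has_subclonal:
        return call
    allele, _ = call.subclonal
    alpha = sidak_alpha(fwer, n_tests)
    per_allele = site.counts[sample]
    depth = sum(sc.total for sc in per_allele)
    idx = site.alleles.index(allele)
    k = per_allele[idx].total
    clonal_model = GenotypeModel(clonal=call.clonal)
    e_clonal = _expected_for_model(clonal_model, tract, rates, site.ref, depth)
    p_expected = e_clonal.get(allele, 2.0 / depth)
    p_binom = float(stats.binom.sf(k - 1, depth, min(p_expected, 1.0)))
    if p_binom > alpha:
        return GenotypeCall(
            clonal=call.clonal, subclonal=None, score=call.score,
            subclonal_rejected_reason="binomial",
        )
    sc = per_allele[idx]
    if sc.total > 0:
        p_bias = strand_bias_p_value(sc.top, sc.bottom, bias_distribution)
        if p_bias < alpha:
            return GenotypeCall(
                clonal=call.clonal, subclonal=None, score=call.score,
                subclonal_rejected_reason="strand_bias",
            )
    return call
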