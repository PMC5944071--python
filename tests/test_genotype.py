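"""Genotype calling: model enumeration, scoring, tie-breaks and subclonal tests."""

from __future__ import annotations

import math
from itertools import combinations_with_replacement

import numpy as np
import pytest
from scipy import stats

from macall.counts import SiteCounts, StrandCounts
from macall.coverage import StrandBiasDistribution
from macall.genotype import (
    SUBCLONAL_FRACTIONS,
    GenotypeCall,
    GenotypeModel,
    call_genotype,
    correct_for_indel_error,
    enumerate_models,
    expected_frequencies,
    floor_frequencies,
    score_genotype,
    sidak_alpha,
    validate_subclonal,
)
from macall.repeats import RepeatTract


# --------------------------------------------------------- independent oracle


def oracle_models(alleles, copy_number):
    """Brute-force enumeration of (clonal, subclonal, fraction) models."""
    alleles = sorted(set(alleles))
    out = set()
    for clonal in combinations_with_replacement(alleles, copy_number):
        out.add((clonal, None, None))
        for i in range(copy_number):
            for alt in alleles:
                if alt != clonal[i]:
                    sub = tuple(sorted(clonal[:i] + (alt,) + clonal[i + 1 :]))
                    for f in SUBCLONAL_FRACTIONS:
                        out.add((clonal, sub, f))
    return out


def oracle_expected(clonal, subclonal, fraction):
    freqs = {}
    f = fraction if subclonal else 0.0
    for a in clonal:
        freqs[a] = freqs.get(a, 0.0) + (1 - f) / len(clonal)
    if subclonal:
        for a in subclonal:
            freqs[a] = freqs.get(a, 0.0) + f / len(subclonal)
    return freqs


def oracle_best_model(observed_counts: dict[str, int], copy_number: int):
    """Exhaustive minimum-score search (no repeat context, no tie-breaks)."""
    depth = sum(observed_counts.values())
    floor = 2.0 / depth
    observed = {a: c / depth for a, c in observed_counts.items()}
    best, best_score = None, math.inf
    ordered = sorted(
        oracle_models(observed_counts, copy_number),
        key=lambda t: (t[0], t[1] or (), t[2] or 0.0),
    )
    for clonal, sub, f in ordered:
        e = oracle_expected(clonal, sub, f)
        e = {a: (v if v > 0 else floor) for a, v in e.items()}
        score = 0.0
        for a, o in observed.items():
            if o <= 0:
                continue
            score += abs(math.log(o / e.get(a, floor)))
        if score < best_score - 1e-12:
            best, best_score = (clonal, sub, f), score
    return best, best_score


# -------------------------------------------------------------- enumeration


class TestEnumerateModels:
    def test_two_alleles_diploid(self):
        models = enumerate_models(["A", "C"], 2)
        clonal_only = [m for m in models if m.subclonal is None]
        assert {m.clonal for m in clonal_only} == {("A", "A"), ("A", "C"), ("C", "C")}
        assert len(models) == len(oracle_models(["A", "C"], 2))

    def test_single_allele_no_subclonal(self):
        models = enumerate_models(["A"], 2)
        assert len(models) == 1
        assert models[0].clonal == ("A", "A") and models[0].subclonal is None

    def test_haploid_two_alleles(self):
        models = enumerate_models(["A", "C"], 1)
        clonal = {m.clonal for m in models if m.subclonal is None}
        assert clonal == {("A",), ("C",)}
        sub = {(m.clonal, m.subclonal, m.fraction) for m in models if m.subclonal}
        assert (("A",), ("C",), 0.5) in sub
        assert len(models) == len(oracle_models(["A", "C"], 1))

    @pytest.mark.parametrize("k,ploidy", [(2, 2), (3, 2), (2, 3), (4, 2), (3, 3)])
    def test_matches_oracle_enumeration(self, k, ploidy):
        alleles = ["A", "C", "G", "T"][:k]
        got = {
            (m.clonal, m.subclonal, m.fraction) for m in enumerate_models(alleles, ploidy)
        }
        assert got == oracle_models(alleles, ploidy)


# --------------------------------------------------------- expected frequencies


class TestExpectedFrequencies:
    def test_clonal_only(self):
        assert expected_frequencies(GenotypeModel(clonal=("A", "A"))) == {"A": 1.0}

    def test_subclonal_quarter(self):
        model = GenotypeModel(clonal=("A", "A"), subclonal=("A", "C"), fraction=0.25)
        freqs = expected_frequencies(model)
        assert freqs == pytest.approx({"A": 0.875, "C": 0.125})

    def test_subclonal_half_with_het_clonal(self):
        model = GenotypeModel(clonal=("A", "C"), subclonal=("C", "C"), fraction=0.5)
        freqs = expected_frequencies(model)
        assert freqs == pytest.approx({"A": 0.25, "C": 0.75})

    def test_sums_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ploidy = int(rng.integers(1, 4))
            alleles = ["A", "C", "G", "T"][: rng.integers(2, 5)]
            models = enumerate_models(alleles, ploidy)
            m = models[rng.integers(len(models))]
            assert sum(expected_frequencies(m).values()) == pytest.approx(1.0)


# ------------------------------------------------------------ error correction


TRACT_AA = RepeatTract("chr1", 100, 101, "A")


class TestIndelErrorCorrection:
    def test_worked_example(self):
        # homozygous AA|AA with +1-unit rate 0.03 and -1-unit rate 0.05
        rates = lambda event, x: {"insertion": 0.03, "deletion": 0.05}[event]
        corrected = correct_for_indel_error({"AA": 1.0}, TRACT_AA, rates, "AA")
        assert corrected == pytest.approx({"A": 0.05, "AA": 0.92, "AAA": 0.03})

    def test_zero_rates_identity(self):
        rates = lambda event, x: 0.0
        assert correct_for_indel_error({"AA": 1.0}, TRACT_AA, rates, "AA") == {"AA": 1.0}

    def test_no_repeat_context_identity(self):
        assert correct_for_indel_error({"A": 1.0}, None, None, "A") == {"A": 1.0}

    def test_mass_conserved_for_random_rates(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            ri, rd = rng.uniform(0, 0.2, size=2)
            f = float(rng.uniform(0.2, 0.8))
            expected = {"AAA": f, "AA": 1.0 - f}
            rates = lambda event, x, _ri=ri, _rd=rd: _ri if event == "insertion" else _rd
            tract = RepeatTract("chr1", 100, 102, "A")
            corrected = correct_for_indel_error(expected, tract, rates, "AAA")
            assert sum(corrected.values()) == pytest.approx(1.0)
            assert all(v >= 0 for v in corrected.values())


class TestFloor:
    def test_zero_replaced(self):
        assert floor_frequencies({"A": 1.0, "C": 0.0}, 100) == {"A": 1.0, "C": 0.02}

    def test_no_zeros_identity(self):
        freqs = {"A": 0.7, "C": 0.3}
        assert floor_frequencies(freqs, 100) == freqs

    def test_floor_value(self):
        assert floor_frequencies({"A": 0.0}, 40)["A"] == pytest.approx(0.05)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            floor_frequencies({"A": 1.0}, 0)


class TestScore:
    def test_perfect_match_zero(self):
        assert score_genotype({"A": 0.5, "C": 0.5}, {"A": 0.5, "C": 0.5}) == 0.0

    def test_known_value(self):
        score = score_genotype({"A": 0.5, "C": 0.5}, {"A": 0.25, "C": 0.75})
        assert score == pytest.approx(abs(math.log(2)) + abs(math.log(2 / 3)))

    def test_missing_expected_allele_floored(self):
        score = score_genotype({"A": 0.9, "C": 0.1}, {"A": 1.0}, floor=0.02)
        assert score == pytest.approx(abs(math.log(0.9)) + abs(math.log(0.1 / 0.02)))


# -------------------------------------------------------------- call_genotype


def _site(counts_by_allele: dict[str, tuple[int, int]], sample="s") -> SiteCounts:
    alleles = list(counts_by_allele)
    return SiteCounts(
        "chr1", 500, alleles,
        {sample: [StrandCounts(*counts_by_allele[a]) for a in alleles]},
    )


class TestCallGenotype:
    def test_homozygous_clean(self):
        call = call_genotype(_site({"A": (30, 30)}), "s", 2)
        assert call.clonal == ("A", "A") and call.score < 1e-9
        assert not call.has_subclonal

    def test_heterozygous_clean(self):
        call = call_genotype(_site({"A": (15, 15), "C": (15, 15)}), "s", 2)
        assert call.clonal == ("A", "C")

    def test_zero_depth_skipped(self):
        assert call_genotype(_site({"A": (0, 0)}), "s", 2) is None

    def test_outgrowth_requires_t0_call(self):
        with pytest.raises(ValueError):
            call_genotype(_site({"A": (30, 30)}), "s", 2, role="outgrowth")

    def test_t0_tie_prefers_reference(self):
        # no reads at all for either allele cannot happen; construct a true
        # tie by symmetry: equal counts for two alleles make A|A and C|C
        # mirror images, so the reference-allele rule must decide
        site = _site({"A": (15, 15), "C": (15, 15)})
        call = call_genotype(site, "s", 1)
        assert call.clonal == ("A",)  # reference allele wins the tie

    def test_outgrowth_tie_prefers_shared_with_t0(self):
        site = SiteCounts(
            "chr1", 500, ["C", "A"],
            {"s": [StrandCounts(15, 15), StrandCounts(15, 15)]},
        )
        t0_call = GenotypeCall(clonal=("A",))
        call = call_genotype(site, "s", 1, role="outgrowth", t0_call=t0_call)
        assert call.clonal == ("A",)  # shares the t0 allele despite C being ref

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        """Minimum-score model equals brute-force search on random sites."""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            k = int(rng.integers(1, 4))
            alleles = ["A", "C", "G", "T"][:k]
            ploidy = int(rng.integers(1, 4))
            depth = int(rng.integers(30, 120))
            probs = rng.dirichlet(np.ones(k))
            counts = rng.multinomial(depth, probs)
            if counts.sum() == 0:
                continue
            by_allele = {
                a: (int(c) - int(c) // 2, int(c) // 2)
                for a, c in zip(alleles, counts)
            }
            site = _site(by_allele)
            call = call_genotype(site, "s", ploidy)
            _, o_score = oracle_best_model(
                {a: int(c) for a, c in zip(alleles, counts)}, ploidy
            )
            # the call achieves the exhaustive minimum score
            assert call.score == pytest.approx(o_score, abs=1e-9)
            assert len(call.clonal) == ploidy
            assert set(call.clonal) <= set(alleles)


# ---------------------------------------------------------- subclonal checks


BIAS = StrandBiasDistribution(mean=0.0, std=0.3)


class TestValidateSubclonal:
    def _subclonal_call(self):
        return GenotypeCall(
            clonal=("A", "A"), subclonal=("C", 0.125), score=0.1
        )

    def test_zero_supporting_reads_reverted(self):
        site = SiteCounts(
            "chr1", 500, ["A", "C"],
            {"s": [StrandCounts(50, 50), StrandCounts(0, 0)]},
        )
        out = validate_subclonal(self._subclonal_call(), site, "s", BIAS, n_tests=10**7)
        assert not out.has_subclonal
        assert out.subclonal_rejected_reason == "binomial"

    @pytest.mark.parametrize("k", [2, 6, 12, 20])
    def test_binomial_threshold_matches_exact_computation(self, k):
        depth = 100
        site = SiteCounts(
            "chr1", 500, ["A", "C"],
            {"s": [StrandCounts((depth - k) // 2, (depth - k + 1) // 2),
                   StrandCounts(k - k // 2, k // 2)]},
        )
        n_tests = 10**7
        out = validate_subclonal(
            self._subclonal_call(), site, "s", BIAS, n_tests=n_tests
        )
        p = float(stats.binom.sf(k - 1, depth, 2.0 / depth))
        alpha = sidak_alpha(0.01, n_tests)
        assert out.has_subclonal == (p <= alpha)

    def test_strand_bias_reversion(self):
        site = SiteCounts(
            "chr1", 500, ["A", "C"],
            {"s": [StrandCounts(45, 40), StrandCounts(15, 0)]},
        )
        out = validate_subclonal(
            self._subclonal_call(), site, "s", BIAS, n_tests=100
        )
        # 15:0 under N(0, 0.3): |z| = ln(16)/0.3 ~ 9.2 -> p ~ 3e-20 < alpha
        assert not out.has_subclonal
        assert out.subclonal_rejected_reason == "strand_bias"

    def test_strong_balanced_subclone_retained(self):
        # 20/100 balanced reads vs expected floor 0.02: binomial tail ~1e-15,
        # far below the Sidak alpha, and no strand imbalance
        site = SiteCounts(
            "chr1", 500, ["A", "C"],
            {"s": [StrandCounts(40, 40), StrandCounts(10, 10)]},
        )
        out = validate_subclonal(
            self._subclonal_call(), site, "s", BIAS, n_tests=10**6
        )
        assert out.has_subclonal


def test_genotype_accuracy_on_clean_clonal_sites():
    """Planted clonal genotypes at depth >= 40 are recovered >= 99%."""
    rng = np.random.default_rng(77)
    correct = 0
    n = 400
    for _ in range(n):
        truth = [("A", "A"), ("A", "C"), ("C", "C")][rng.integers(3)]
        depth = int(rng.integers(40, 80))
        f_c = sum(a == "C" for a in truth) / 2
        c_count = rng.binomial(depth, min(f_c + 0.001, 1.0))
        a_count = depth - c_count
        site = _site({"A": (a_count - a_count // 2, a_count // 2),
                      "C": (c_count - c_count // 2, c_count // 2)})
        call = call_genotype(site, "s", 2)
        if call.clonal == truth:
            correct += 1
    assert correct / n >= 0.99
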