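"""Mutation rates, the legacy false-negative correction, and the homopolymer
indel-accumulation Monte Carlo.

The per-bp per-generation mutation rate for mutation type i in genomic bin b
of strain j is

    mu_bp,i,j = N_i,b,j / (N_bp,b * gen_tot,j)

with N_bp,b replaced by the global ploidy for whole-genome rates.  The
false-negative model B(L; D, p) estimates how often partially-traversing
reads push a repeat indel under a hard allelic-fraction cutoff in
depth-cutoff-based callers; observed rates are corrected by 1/(1 - B).  The
Monte Carlo asks whether sequential single-base slippage events alone can
account for observed multi-base deletions in long A/T homopolymers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "RateQuery",
    "FNModel",
    "SimSpec",
    "SimResult",
    "mutation_rate",
    "false_negative_rate",
    "simulate_indel_accumulation",
]


@dataclass(frozen=True)
class RateQuery:
    """Inputs for one rate computation."""

    n_mutations: float  # ploidy-accounted mutation count in the bin
    n_bp: float  # base pairs in the bin (global ploidy for whole-genome rates)
    generations: float  # summed generations across kindred isolates

    def __post_init__(self) -> None:
        if self.n_mutations < 0 or self.n_bp <= 0:
            raise ValueError("counts must be >= 0 and bin size > 0")
        if self.generations <= 0:
            raise ValueError("generations must be > 0")


def mutation_rate(query: RateQuery) -> float:
    """Mutation rate per base pair per generation."""
    return query.n_mutations / (query.n_bp * query.generations)


@dataclass(frozen=True)
class FNModel:
    """False-negative model for repeat indels under an allelic-fraction cutoff.

    L: repeat tract length (bp); D: average depth; R: read length;
    C: allelic fraction cutoff; delta_L: indel length change (bp).
    """

    L: int
    D: float
    R: int
    C: float
    delta_L: int = 1

    @property
    def p_traverse(self) -> float:
        """Fraction of overlapping reads that cross the whole tract."""
        return (self.R - 2 * (self.L + self.delta_L)) / (self.R - (self.L + self.delta_L))

    def __post_init__(self) -> None:
        if not 0.0 < self.p_traverse < 1.0:
            raise ValueError(
                f"p = {self.p_traverse:.4g} outside (0, 1); requires R > 2(L + delta_L)"
            )
        if self.C <= 0 or self.D <= 0:
            raise ValueError("D and C must be > 0")


def false_negative_rate(model: FNModel) -> tuple[float, float]:
    """(B, 1/(1-B)): the false-negative probability and the rate correction.

    B = sum_{x=0}^{L} C(n, x) p^x (1-p)^(n-x) with n = round(D*C) trials and
    traversal probability p — the chance that no more than L of the reads
    needed to clear the cutoff actually traverse the tract.
    """
    n = int(round(model.D * model.C))
    p = model.p_traverse
    b = float(stats.binom.cdf(model.L, n, p))
    if b >= 1.0:
        raise ValueError("B = 1; correction undefined")
    return b, 1.0 / (1.0 - b)


@dataclass(frozen=True)
class SimSpec:
    """Specification of the homopolymer indel-accumulation Monte Carlo.

    ``insertion_rates`` / ``deletion_rates`` map homopolymer length (7-18)
    to the per-generation single-base event probability.
    ``length_census`` maps starting length to the number of genomic tracts.
    """

    insertion_rates: Mapping[int, float]
    deletion_rates: Mapping[int, float]
    length_census: Mapping[int, int]
    generations: int
    iterations: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for table in (self.insertion_rates, self.deletion_rates):
            for rate in table.values():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError("rates must lie in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class SimResult:
    """Per-starting-length multi-base deletion counts across iterations."""

    start_lengths: list[int]
    counts: dict[int, np.ndarray] = field(default_factory=dict)  # (iterations,)

    def mean(self, length: int) -> float:
        return float(np.mean(self.counts[length]))

    def envelope(self, length: int, level: float = 0.95) -> tuple[float, float]:
        """Central confidence envelope of the simulated counts."""
        lo = (1.0 - level) / 2.0
        return (
            float(np.quantile(self.counts[length], lo)),
            float(np.quantile(self.counts[length], 1.0 - lo)),
        )

    def exceeds_envelope(self, length: int, observed: float, level: float = 0.95) -> bool:
        """Whether an observed multi-base deletion count exceeds the envelope."""
        return observed > self.envelope(length, level)[1]


def _rate_lookup(table: Mapping[int, float], lengths: np.ndarray) -> np.ndarray:
    """Rate for each length; lengths off the table use the nearest key."""
    if not table:
        return np.zeros(lengths.shape)
    keys = np.array(sorted(table))
    vals = np.array([table[k] for k in keys])
    hi = np.clip(np.searchsorted(keys, lengths), 0, len(keys) - 1)
    lo = np.clip(hi - 1, 0, len(keys) - 1)
    use_hi = np.abs(keys[hi] - lengths) <= np.abs(keys[lo] - lengths)
    return np.where(use_hi, vals[hi], vals[lo])


def simulate_indel_accumulation(spec: SimSpec) -> SimResult:
    """Monte Carlo of single-base slippage accumulation in homopolymers.

    Each tract's length performs a per-generation random walk: -1 with the
    deletion rate for its current length, +1 with the insertion rate,
    unchanged otherwise.  Rates are re-indexed by the current length each
    generation (clamped to the table's range).  A tract counts as a
    multi-base deletion when its final length is at least 2 bp below its
    start.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    result = SimResult(start_lengths=sorted(spec.length_census))
    for start_length in result.start_lengths:
        n_tracts = spec.length_census[start_length]
        lengths = np.full((spec.iterations, n_tracts), start_length, dtype=np.int64)
        for _ in range(spec.generations):
            flat = lengths.ravel()
            del_r = _rate_lookup(spec.deletion_rates, flat)
            ins_r = _rate_lookup(spec.insertion_rates, flat)
            u = rng.random(flat.shape)
            step = np.where(u < del_r, -1, np.where(u < del_r + ins_r, 1, 0))
            lengths = np.maximum(flat + step, 0).reshape(lengths.shape)
        multi_del = (start_length - lengths) >= 2
        result.counts[start_length] = multi_del.sum(axis=1)
    return result
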