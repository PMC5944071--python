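"""Synthetic ancestor/outgrowth datasets with known ground truth.

The generator emulates the data model the statistical engine consumes:
clonal and subclonal genotypes at a given ploidy, per-strand binomial read
sampling, log-normal strand-bias noise, Gaussian depth variation with
optional chromosome-end bias and planted abnormal regions, and
repeat-context PCR indel errors following the logistic rate model.  It does
not simulate reads; the contract is the counts table plus depth tracks and
per-repeat traversing-coverage observations.

Counts at a site are drawn per strand from the error-perturbed true allele
frequencies; candidate sites are those where any sample shows non-reference
evidence, mirroring how a sensitive variant caller selects sites.  A
deterministic "expectation mode" replaces sampling by rounded expected
values for exact unit tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .counts import SiteCounts, StrandCounts
from .coverage import DepthCorrectionModel, distance_from_chromosome_end
from .genotype import GenotypeModel, expected_frequencies, correct_for_indel_error
from .indel_error import RepeatObservation
from .repeats import RepeatTract, find_repeats
from .tracks import DepthTrack, Interval

__all__ = [
    "PlantedMutation",
    "TruthParams",
    "TruthManifest",
    "SyntheticPair",
    "generate_reference",
    "generate_pair",
    "plan_mutations",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

T0 = "t0"
OUTGROWTH = "outgrowth"

# Logistic indel-error parameters per repeat unit length: the homopolymer
# curve rises from a ~1e-3 floor to ~0.15 per traversing read around 10 bp,
# consistent with PCR slippage behaviour; longer units slip less.
DEFAULT_INDEL_PARAMS: dict[tuple[str, int], tuple[float, float, float, float]] = {
    ("deletion", 1): (0.001, 0.15, 0.9, 10.0),
    ("insertion", 1): (0.001, 0.10, 0.9, 11.0),
    ("deletion", 2): (0.0005, 0.08, 0.7, 12.0),
    ("insertion", 2): (0.0005, 0.05, 0.7, 13.0),
    ("deletion", 3): (0.0003, 0.05, 0.6, 15.0),
    ("insertion", 3): (0.0003, 0.03, 0.6, 16.0),
    ("deletion", 4): (0.0002, 0.04, 0.6, 18.0),
    ("insertion", 4): (0.0002, 0.02, 0.6, 19.0),
}


def logistic_rate(params: tuple[float, float, float, float], x: float | np.ndarray):
    M, L, k, x0 = params
    return M + L / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0)))


@dataclass(frozen=True)
class PlantedMutation:
    """Ground truth for one planted mutation in the outgrowth sample."""

    chrom: str
    pos: int  # 1-based; for indels, the tract start
    ref_allele: str
    alt_allele: str
    fraction: Optional[float] = None  # None = clonal; else 0.5 / 0.25 / 0.125
    kind: str = "substitution"  # substitution | insertion | deletion

    @property
    def is_clonal(self) -> bool:
        return self.fraction is None


@dataclass
class TruthParams:
    """Study conditions for a synthetic ancestor/outgrowth pair."""

    ploidy: int = 2
    depth_mean: float = 50.0
    depth_sd: float = 6.0
    strand_bias_sd: float = 0.2
    seq_error_rate: float = 1e-3
    read_length: int = 150
    indel_error_params: dict[tuple[str, int], tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_PARAMS)
    )
    mutations: list[PlantedMutation] = field(default_factory=list)
    het_positions: list[int] = field(default_factory=list)  # true het in both samples
    end_bias: Optional[DepthCorrectionModel] = None
    abnormal_regions: list[tuple[Interval, float]] = field(default_factory=list)
    generations: float = 100.0
    expectation_mode: bool = False


@dataclass
class TruthManifest:
    """Everything needed to recompute expected pipeline output."""

    seed: int
    params: TruthParams
    chrom_lengths: dict[str, int]

    def to_json(self) -> str:
        payload = asdict(self)
        payload["params"]["indel_error_params"] = {
            f"{e}:{u}": v for (e, u), v in self.params.indel_error_params.items()
        }
        payload["params"]["abnormal_regions"] = [
            [iv.chrom, iv.start, iv.end, mult]
            for iv, mult in self.params.abnormal_regions
        ]
        payload["params"]["end_bias"] = (
            asdict(self.params.end_bias) if self.params.end_bias else None
        )
        return json.dumps(payload, indent=1, default=int)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        payload = json.loads(text)
        p = payload["params"]
        p["indel_error_params"] = {
            (k.split(":")[0], int(k.split(":")[1])): tuple(v)
            for k, v in p["indel_error_params"].items()
        }
        p["abnormal_regions"] = [
            (Interval(c, s, e), m) for c, s, e, m in p["abnormal_regions"]
        ]
        p["end_bias"] = DepthCorrectionModel(**p["end_bias"]) if p["end_bias"] else None
        p["mutations"] = [PlantedMutation(**m) for m in p["mutations"]]
        return cls(
            seed=payload["seed"],
            params=TruthParams(**p),
            chrom_lengths=payload["chrom_lengths"],
        )


@dataclass
class SyntheticPair:
    """In-memory bundle of one generated ancestor/outgrowth dataset."""

    reference: dict[str, str]
    repeats: list[RepeatTract]
    depth: dict[str, DepthTrack]  # sample -> track
    sites: list[SiteCounts]
    observations: dict[str, list[RepeatObservation]]  # sample -> per-repeat
    manifest: TruthManifest

    @property
    def sample_names(self) -> list[str]:
        return [T0, OUTGROWTH]


def generate_reference(
    seed: int,
    length: int,
    repeat_spec: Sequence[tuple[str, int, int]] = (),
    chrom: str = "chr1",
    max_attempts: int = 50,
) -> tuple[dict[str, str], list[RepeatTract]]:
    """Random reference with planted repeat tracts.

    ``repeat_spec`` lists (unit, tract_length, count) triples.  Planted
    tracts are non-overlapping, flanked by breaking bases, and verified to
    appear exactly in :func:`find_repeats` output (placement retries until
    they do).  Returns the sequence and the planted tract list.
    """
    rng = np.random.default_rng(seed)
    total_planted = sum(tl * c for _, tl, c in repeat_spec)
    if total_planted * 3 > length:
        raise ValueError("repeat spec does not fit in the requested length")
    for _ in range(max_attempts):
        seq_arr = _BASES[rng.integers(0, 4, size=length)]
        if not repeat_spec:
            return {chrom: seq_arr.tobytes().decode("ascii")}, []
        planted: list[RepeatTract] = []
        occupied = np.zeros(length, dtype=bool)
        ok = True
        for unit, tract_length, count in repeat_spec:
            for _ in range(count):
                placed = False
                for _ in range(200):
                    start0 = int(rng.integers(2, length - tract_length - 2))
                    lo, hi = start0 - len(unit) - 1, start0 + tract_length + len(unit) + 1
                    if occupied[max(lo, 0) : hi].any():
                        continue
                    tract_seq = (unit * (tract_length // len(unit) + 1))[:tract_length]
                    seq_arr[start0 : start0 + tract_length] = np.frombuffer(
                        tract_seq.encode(), dtype=np.uint8
                    )
                    # breaking flanks: any base that does not extend the pattern
                    choices = [b for b in "ACGT" if b != tract_seq[-1]]
                    seq_arr[start0 - 1] = ord(
                        [b for b in "ACGT" if b != tract_seq[0]][int(rng.integers(3))]
                    )
                    seq_arr[start0 + tract_length] = ord(choices[int(rng.integers(3))])
                    occupied[max(lo, 0) : hi] = True
                    planted.append(
                        RepeatTract(chrom, start0 + 1, start0 + tract_length, unit)
                    )
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        seq = seq_arr.tobytes().decode("ascii")
        found = {
            (t.chrom, t.start, t.end, t.unit) for t in find_repeats(seq, chrom)
        }
        if all((t.chrom, t.start, t.end, t.unit) in found for t in planted):
            planted.sort()
            return {chrom: seq}, planted
    raise ValueError("could not place repeat spec; sequence too crowded")


def plan_mutations(
    reference: dict[str, str],
    repeats: Sequence[RepeatTract],
    n_substitutions: int,
    n_indels: int,
    seed: int,
    subclonal_fractions: Sequence[Optional[float]] = (None,),
    max_indel_tract: int = 10,
    min_indel_tract: int = 5,
) -> list[PlantedMutation]:
    """Choose mutation positions: substitutions clear of repeats, single-unit
    indels in repeat tracts of length ``min_indel_tract``..``max_indel_tract``.

    ``subclonal_fractions`` cycles over the planted mutations (None = clonal).
    """
    rng = np.random.default_rng(seed)
    (chrom, seq), = reference.items()
    length = len(seq)
    occupied = np.zeros(length, dtype=bool)
    # keep substitutions clear of slippage-prone tracts (short unit-3/4
    # partial repeats are effectively unique sequence)
    for t in repeats:
        if len(t.unit) <= 2 or t.tract_length >= 6:
            occupied[max(t.start - 5, 0) : t.end + 5] = True
    free = np.flatnonzero(~occupied[100 : length - 100]) + 100
    subs_pos = rng.choice(free, size=n_substitutions, replace=False)
    mutations: list[PlantedMutation] = []
    fi = 0
    for pos0 in sorted(int(v) for v in subs_pos):
        ref_base = seq[pos0]
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        frac = subclonal_fractions[fi % len(subclonal_fractions)]
        fi += 1
        mutations.append(
            PlantedMutation(chrom, pos0 + 1, ref_base, str(alt), frac, "substitution")
        )
    eligible = [
        t for t in repeats
        if min_indel_tract <= t.tract_length <= max_indel_tract
        and t.tract_length - len(t.unit) >= len(t.unit)
    ]
    if n_indels > len(eligible):
        raise ValueError(f"only {len(eligible)} eligible repeat tracts for indels")
    chosen = rng.choice(len(eligible), size=n_indels, replace=False)
    for i in sorted(int(v) for v in chosen):
        t = eligible[i]
        ref_allele = reference[t.chrom][t.start - 1 : t.end]
        if rng.random() < 0.5 and len(ref_allele) > len(t.unit):
            alt = ref_allele[len(t.unit) :]
            kind = "deletion"
        else:
            alt = t.unit + ref_allele
            kind = "insertion"
        frac = subclonal_fractions[fi % len(subclonal_fractions)]
        fi += 1
        mutations.append(PlantedMutation(t.chrom, t.start, ref_allele, alt, frac, kind))
    mutations.sort(key=lambda m: m.pos)
    return mutations


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_depth(
    rng: np.random.Generator, length: int, params: TruthParams
) -> np.ndarray:
    if params.expectation_mode:
        base = np.full(length, params.depth_mean)
    else:
        base = rng.normal(params.depth_mean, params.depth_sd, size=length)
    if params.end_bias is not None:
        base = base * np.asarray(
            params.end_bias.factor(distance_from_chromosome_end(length))
        )
    for iv, mult in params.abnormal_regions:
        base[iv.start : iv.end] *= mult
    return np.maximum(np.rint(base), 0).astype(np.int64)


def _split_strands(
    rng: np.random.Generator, counts: np.ndarray, p_top: np.ndarray, expectation: bool
) -> tuple[np.ndarray, np.ndarray]:
    if expectation:
        top = np.rint(counts * p_top).astype(np.int64)
    else:
        top = rng.binomial(counts, p_top)
    return top, counts - top


def _site_true_frequencies(
    mutation: Optional[PlantedMutation],
    ref_allele: str,
    alt_allele: str,
    ploidy: int,
    sample: str,
    is_het: bool,
) -> dict[str, float]:
    """Expected allele frequencies from the true genotype (before errors)."""
    if sample == OUTGROWTH and mutation is not None:
        if mutation.is_clonal:
            clonal = tuple(sorted([alt_allele] + [ref_allele] * (ploidy - 1)))
            model = GenotypeModel(clonal=clonal)
        else:
            clonal = tuple([ref_allele] * ploidy)
            sub = tuple(sorted([alt_allele] + [ref_allele] * (ploidy - 1)))
            model = GenotypeModel(clonal=clonal, subclonal=sub, fraction=mutation.fraction)
    elif is_het:
        clonal = tuple(sorted([alt_allele] + [ref_allele] * (ploidy - 1)))
        model = GenotypeModel(clonal=clonal)
    else:
        model = GenotypeModel(clonal=tuple([ref_allele] * ploidy))
    return expected_frequencies(model)


def generate_pair(
    reference: dict[str, str],
    params: TruthParams,
    seed: int,
    repeats: Optional[Sequence[RepeatTract]] = None,
) -> SyntheticPair:
    """Generate matched t0/outgrowth depth tracks, counts and observations.

    All randomness flows from ``seed``; identical inputs give identical
    output.  See the module docstring for the generative model.
    """
    rng = np.random.default_rng(seed)
    (chrom, seq), = reference.items()
    length = len(seq)
    if repeats is None:
        repeats = find_repeats(seq, chrom)
    repeats = sorted(repeats)
    exp_mode = params.expectation_mode

    depth = {s: _draw_depth(rng, length, params) for s in (T0, OUTGROWTH)}

    mut_by_pos = {m.pos: m for m in params.mutations}
    het_set = set(params.het_positions)
    seq_bytes = np.frombuffer(seq.encode(), dtype=np.uint8)

    # --- substitution-error candidate sites -------------------------------
    err = {}
    for s in (T0, OUTGROWTH):
        if exp_mode or params.seq_error_rate == 0:
            err[s] = np.zeros(length, dtype=np.int64)
        else:
            err[s] = rng.binomial(depth[s], params.seq_error_rate)
    special = set(mut_by_pos) | het_set
    err_pos0 = np.flatnonzero((err[T0] + err[OUTGROWTH]) > 0)
    err_pos0 = np.array(
        [p for p in err_pos0 if (p + 1) not in special], dtype=np.int64
    )

    sites: list[SiteCounts] = []

    def draw_p_top(size: int) -> np.ndarray:
        if exp_mode:
            return np.full(size, 0.5)
        return _sigmoid(rng.normal(0.0, params.strand_bias_sd, size=size))

    # error-only sites: biallelic, same error base in both samples
    if err_pos0.size:
        n_err_sites = err_pos0.size
        alt_offsets = rng.integers(1, 4, size=n_err_sites).tolist()
        strand_counts: dict[str, tuple] = {}
        for s in (T0, OUTGROWTH):
            alt_n = err[s][err_pos0]
            ref_n = np.maximum(depth[s][err_pos0] - alt_n, 0)
            p_top = draw_p_top(n_err_sites)
            rt, rb = _split_strands(rng, ref_n, p_top, exp_mode)
            at, ab = _split_strands(rng, alt_n, p_top, exp_mode)
            strand_counts[s] = (rt.tolist(), rb.tolist(), at.tolist(), ab.tolist())
        ref_bases = seq_bytes[err_pos0]
        ref_idx = np.searchsorted(_BASES, ref_bases).tolist()
        pos_list = (err_pos0 + 1).tolist()
        sc0 = strand_counts[T0]
        sc1 = strand_counts[OUTGROWTH]
        for j in range(n_err_sites):
            ri = ref_idx[j]
            counts = {
                T0: [
                    StrandCounts(sc0[0][j], sc0[1][j]),
                    StrandCounts(sc0[2][j], sc0[3][j]),
                ],
                OUTGROWTH: [
                    StrandCounts(sc1[0][j], sc1[1][j]),
                    StrandCounts(sc1[2][j], sc1[3][j]),
                ],
            }
            sites.append(
                SiteCounts(
                    chrom=chrom,
                    pos=pos_list[j],
                    alleles=["ACGT"[ri], "ACGT"[(ri + alt_offsets[j]) % 4]],
                    counts=counts,
                )
            )

    # --- planted substitution / het sites ---------------------------------
    for pos in sorted(special):
        m = mut_by_pos.get(pos)
        if m is not None and m.kind != "substitution":
            continue  # indel mutations are handled with their tract below
        p0 = pos - 1
        ref_base = chr(seq_bytes[p0])
        alt_base = m.alt_allele if m is not None else "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        counts = {}
        for s in (T0, OUTGROWTH):
            d = int(depth[s][p0])
            freqs = _site_true_frequencies(
                m, ref_base, alt_base, params.ploidy, s, pos in het_set
            )
            f_alt = freqs.get(alt_base, 0.0)
            # residual sequencing error adds alt evidence in both samples
            f_alt = f_alt + (0.0 if exp_mode else params.seq_error_rate / 3.0)
            if exp_mode:
                alt_n = int(np.rint(d * f_alt))
            else:
                alt_n = int(rng.binomial(d, min(f_alt, 1.0)))
            ref_n = d - alt_n
            p_top = draw_p_top(1)
            rt, rb = _split_strands(rng, np.array([ref_n]), p_top, exp_mode)
            at, ab = _split_strands(rng, np.array([alt_n]), p_top, exp_mode)
            counts[s] = [
                StrandCounts(int(rt[0]), int(rb[0])),
                StrandCounts(int(at[0]), int(ab[0])),
            ]
        sites.append(
            SiteCounts(chrom=chrom, pos=pos, alleles=[ref_base, alt_base], counts=counts)
        )

    # --- repeat tracts: traversing coverage, PCR indel errors, indel muts --
    n_rep = len(repeats)
    tract_len = np.array([t.tract_length for t in repeats], dtype=np.int64)
    unit_len = np.array([len(t.unit) for t in repeats], dtype=np.int64)
    mid0 = np.array([(t.start + t.end) // 2 - 1 for t in repeats], dtype=np.int64)
    with np.errstate(invalid="ignore"):
        p_trav = (params.read_length - 2.0 * (tract_len + 1)) / (
            params.read_length - (tract_len + 1)
        )
    p_trav = np.clip(p_trav, 0.05, 1.0)
    rate_del = np.zeros(n_rep)
    rate_ins = np.zeros(n_rep)
    for ul in (1, 2, 3, 4):
        mask = unit_len == ul
        if not mask.any():
            continue
        dp = params.indel_error_params.get(("deletion", ul))
        ip = params.indel_error_params.get(("insertion", ul))
        if dp:
            rate_del[mask] = logistic_rate(dp, tract_len[mask])
        if ip:
            rate_ins[mask] = logistic_rate(ip, tract_len[mask])

    mut_by_tract_start = {
        m.pos: m for m in params.mutations if m.kind in ("insertion", "deletion")
    }
    mutated_idx = {
        i for i, t in enumerate(repeats) if t.start in mut_by_tract_start
    }

    observations: dict[str, list[RepeatObservation]] = {T0: [], OUTGROWTH: []}
    # per-sample allele-count dicts for repeat sites that need counts rows
    tract_counts: dict[int, dict[str, dict[str, int]]] = {}

    for s in (T0, OUTGROWTH):
        d_mid = depth[s][mid0] if n_rep else np.zeros(0, dtype=np.int64)
        if exp_mode:
            t_cov = np.rint(d_mid * p_trav).astype(np.int64)
            del_n = np.rint(t_cov * rate_del).astype(np.int64)
            ins_n = np.rint(t_cov * rate_ins).astype(np.int64)
        else:
            t_cov = rng.binomial(d_mid, p_trav)
            del_n = np.minimum(rng.binomial(t_cov, rate_del), t_cov)
            ins_n = np.minimum(rng.binomial(t_cov, rate_ins), t_cov - del_n)
        cov_l = t_cov.tolist()
        del_l = del_n.tolist()
        ins_l = ins_n.tolist()
        ul_l = unit_len.tolist()
        obs = observations[s]
        append = obs.append
        for i, t in enumerate(repeats):
            cov, dn, im, ul = cov_l[i], del_l[i], ins_l[i], ul_l[i]
            is_mut = i in mutated_idx
            if is_mut and s == OUTGROWTH:
                # genotype-aware multinomial draw for mutated tracts
                mut = mut_by_tract_start[t.start]
                ref_allele = seq[t.start - 1 : t.end]
                freqs = _site_true_frequencies(
                    mut, ref_allele, mut.alt_allele, params.ploidy, s, False
                )
                rates = lambda event, x, _ul=ul: float(
                    logistic_rate(params.indel_error_params.get((event, _ul), (0, 0, 1, 0)), x)
                )
                freqs = correct_for_indel_error(freqs, t, rates, ref_allele)
                alleles = sorted(freqs, key=lambda a: (a != ref_allele, a))
                probs = np.clip(np.array([freqs[a] for a in alleles]), 0.0, None)
                probs = probs / probs.sum()
                if exp_mode:
                    counts_vec = np.rint(cov * probs).astype(np.int64)
                else:
                    counts_vec = rng.multinomial(cov, probs)
                per_allele = {a: int(c) for a, c in zip(alleles, counts_vec)}
                indel_counts: dict[tuple[str, int], int] = {}
                for a, c in per_allele.items():
                    delta = (len(a) - len(ref_allele)) // ul
                    if c == 0 or delta == 0:
                        continue
                    event = "insertion" if delta > 0 else "deletion"
                    key = (event, abs(delta))
                    indel_counts[key] = indel_counts.get(key, 0) + c
                append(RepeatObservation(t, cov, indel_counts))
                tract_counts.setdefault(i, {})[s] = per_allele
                continue
            if dn == 0 and im == 0 and not is_mut:
                append(RepeatObservation(t, cov, {}))
                continue
            ref_allele = seq[t.start - 1 : t.end]
            if dn and len(ref_allele) <= ul:
                dn = 0  # deleting the whole allele is not representable
            per_allele = {ref_allele: cov - dn - im}
            indel_counts = {}
            if dn:
                per_allele[ref_allele[ul:]] = dn
                indel_counts[("deletion", 1)] = dn
            if im:
                per_allele[t.unit + ref_allele] = im
                indel_counts[("insertion", 1)] = im
            append(RepeatObservation(t, cov, indel_counts))
            if is_mut or dn or im:
                tract_counts.setdefault(i, {})[s] = per_allele

    # assemble counts rows for repeat sites with a single vectorised strand split
    tract_items = sorted(tract_counts.items())
    flat_counts: list[int] = []
    flat_p: list[float] = []
    layout: list[tuple[RepeatTract, list[str]]] = []
    p_site = draw_p_top(2 * len(tract_items)).tolist()
    for row_i, (i, per_sample) in enumerate(tract_items):
        t = repeats[i]
        ref_allele = seq[t.start - 1 : t.end]
        allele_set = {ref_allele}
        for per in per_sample.values():
            allele_set.update(a for a, c in per.items() if c > 0)
        if t.start in mut_by_tract_start:
            allele_set.add(mut_by_tract_start[t.start].alt_allele)
        alleles = [ref_allele] + sorted(a for a in allele_set if a != ref_allele)
        layout.append((t, alleles))
        for si, s in enumerate((T0, OUTGROWTH)):
            per = per_sample.get(
                s, {ref_allele: int(observations[s][i].traversing_coverage)}
            )
            p = p_site[2 * row_i + si]
            for a in alleles:
                flat_counts.append(max(per.get(a, 0), 0))
                flat_p.append(p)
    if flat_counts:
        tops, bottoms = _split_strands(
            rng, np.array(flat_counts), np.array(flat_p), exp_mode
        )
        tops = tops.tolist()
        bottoms = bottoms.tolist()
        cursor = 0
        for t, alleles in layout:
            counts = {}
            for s in (T0, OUTGROWTH):
                row = []
                for _ in alleles:
                    row.append(StrandCounts(tops[cursor], bottoms[cursor]))
                    cursor += 1
                counts[s] = row
            sites.append(
                SiteCounts(chrom=chrom, pos=t.start, alleles=alleles, counts=counts)
            )

    sites.sort(key=lambda s: s.pos)
    tracks = {
        s: DepthTrack(depths={chrom: depth[s].astype(np.float64)}) for s in (T0, OUTGROWTH)
    }
    manifest = TruthManifest(
        seed=seed, params=params, chrom_lengths={chrom: length}
    )
    return SyntheticPair(
        reference=reference,
        repeats=list(repeats),
        depth=tracks,
        sites=sites,
        observations=observations,
        manifest=manifest,
    )
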