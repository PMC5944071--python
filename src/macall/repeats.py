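"""Simple-repeat tract discovery in the reference genome.

Slipped-strand errors during PCR and sequencing concentrate in simple
repeats, so the error model is stratified by repeat unit length (1-4 nt) and
total tract length in bp.  A tract qualifies when its total length is at
least 4 bp (partial trailing units count), its unit is not itself periodic
(``ATAT`` reduces to ``AT``), and it is not wholly contained in another tract
of the same unit or a circular permutation of that unit.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "RepeatTract",
    "find_repeats",
    "find_repeats_genome",
    "sample_repeats",
    "read_repeat_file",
    "write_repeat_file",
    "RepeatIndex",
    "minimal_period",
]

MAX_UNIT = 4
MIN_TRACT_BP = 4


@dataclass(frozen=True, order=True)
class RepeatTract:
    """A simple repeat: ``unit`` repeated across [start, end] (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    unit: str

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1


def minimal_period(s: str) -> int:
    """Smallest p such that s[i] == s[i-p] for all i >= p."""
    for p in range(1, len(s)):
        if all(s[i] == s[i - p] for i in range(p, len(s))):
            return p
    return len(s)


def find_repeats(sequence: str, chrom: str = "chr1") -> list[RepeatTract]:
    """Enumerate maximal simple-repeat tracts with unit length 1-4.

    ``N`` bases break tracts; any other non-ACGT symbol is an error.  For each
    unit length u the scan finds maximal runs of positions matching the base u
    earlier; a run of r matches is a tract of length r + u.  Maximal runs at a
    fixed u are disjoint, and units of different lengths cannot be circular
    permutations of each other, so the containment rule is satisfied by
    construction; periodic units are dropped explicitly.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbol(s) in sequence: {sorted(bad)}")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    is_n = arr == ord("N")
    tracts: list[RepeatTract] = []
    for u in range(1, MAX_UNIT + 1):
        if n <= u:
            break
        eq = arr[u:] == arr[:-u]
        # a match at offset j asserts the repeat pattern over seq[j:j+u+1];
        # any N in that window (endpoints or interior) breaks the tract
        prefix = np.concatenate(([0], np.cumsum(is_n)))
        eq &= (prefix[u + 1 :] - prefix[: -(u + 1)]) == 0
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)  # exclusive
        min_run = max(MIN_TRACT_BP - u, 1)
        for rs, re in zip(run_starts.tolist(), run_ends.tolist()):
            run = re - rs
            if run < min_run:
                continue
            start0 = rs  # 0-based start of the tract
            length = run + u
            unit = seq[start0 : start0 + u]
            if minimal_period(unit) != u:
                continue
            tracts.append(RepeatTract(chrom, start0 + 1, start0 + length, unit))
    tracts.sort(key=lambda t: (t.start, len(t.unit), t.end))
    return tracts


def find_repeats_genome(sequences: dict[str, str]) -> list[RepeatTract]:
    """Run :func:`find_repeats` per chromosome; output sorted by chrom name."""
    out: list[RepeatTract] = []
    for chrom in sorted(sequences):
        out.extend(find_repeats(sequences[chrom], chrom))
    return out


def sample_repeats(
    repeats: Sequence[RepeatTract], n: int, seed: int
) -> list[RepeatTract]:
    """Uniform sample without replacement of min(n, len(repeats)) tracts.

    Deterministic for a fixed seed; output preserves genomic order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= len(repeats):
        return list(repeats)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(repeats), size=n, replace=False)
    return [repeats[i] for i in sorted(idx)]


def write_repeat_file(repeats: Iterable[RepeatTract], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tunit\ttract_length\n")
        for t in repeats:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.unit}\t{t.tract_length}\n")


def read_repeat_file(path: str | Path) -> list[RepeatTract]:
    out: list[RepeatTract] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, unit = line.split("\t")[:4]
            out.append(RepeatTract(chrom, int(start), int(end), unit))
    return out


class RepeatIndex:
    """Position -> enclosing tract lookup (smallest unit wins on overlap)."""

    def __init__(self, repeats: Iterable[RepeatTract]) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[RepeatTract]]] = {}
        grouped: dict[str, list[RepeatTract]] = {}
        for t in repeats:
            grouped.setdefault(t.chrom, []).append(t)
        self._max_len: dict[str, int] = {}
        for chrom, ts in grouped.items():
            ts.sort(key=lambda t: (t.start, len(t.unit)))
            self._by_chrom[chrom] = ([t.start for t in ts], ts)
            self._max_len[chrom] = max(t.tract_length for t in ts)

    def at(self, chrom: str, pos: int) -> Optional[RepeatTract]:
        """Tract containing the 1-based position, or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ts = entry
        i = bisect_right(starts, pos)
        best: Optional[RepeatTract] = None
        max_len = self._max_len[chrom]
        # walk left over tracts starting at or before pos
        for j in range(i - 1, -1, -1):
            t = ts[j]
            if pos - t.start >= max_len:
                break
            if t.end >= pos:
                if best is None or len(t.unit) < len(best.unit):
                    best = t
        return best
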