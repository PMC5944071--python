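"""Per-position depth tracks, bedGraph/BED I/O and copy-number maps.

Depth tracks store one value per reference position (1-based internally,
numpy array index 0 == position 1).  On disk they are bedGraph: 0-based
half-open intervals, run-length compressed on write.  BED conventions apply
to filtered-region files and the optional copy-number map (4th column = copy
number).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "DepthTrack",
    "Interval",
    "CopyNumberMap",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_copy_number_bed",
]


@dataclass
class DepthTrack:
    """chrom -> array of per-position depth (index 0 is position 1)."""

    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.depths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.depths

    @property
    def chroms(self) -> list[str]:
        return list(self.depths)

    def at(self, chrom: str, pos: int) -> float:
        """Depth at a 1-based position."""
        return float(self.depths[chrom][pos - 1])

    def total_length(self) -> int:
        return sum(len(a) for a in self.depths.values())


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return chrom == self.chrom and self.start < pos <= self.end


class CopyNumberMap:
    """Per-position copy-number overrides; sample ploidy applies elsewhere.

    Intervals must be non-overlapping within a chromosome.
    """

    def __init__(self, entries: Iterable[tuple[Interval, int]] = ()) -> None:
        self._by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for iv, cn in entries:
            if cn < 1:
                raise ValueError("copy number must be >= 1")
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, cn))
        for chrom, ivs in self._by_chrom.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping copy-number intervals on {chrom}")

    def copy_number(self, chrom: str, pos: int, default: int) -> int:
        """Copy number at a 1-based position; ``default`` is the sample ploidy."""
        for start, end, cn in self._by_chrom.get(chrom, ()):
            if start < pos <= end:
                return cn
        return default

    def per_position(self, chrom: str, length: int, default: int) -> np.ndarray:
        """Expand to an integer array of per-position copy numbers."""
        out = np.full(length, default, dtype=np.int64)
        for start, end, cn in self._by_chrom.get(chrom, ()):
            out[start : min(end, length)] = cn
        return out


def read_bedgraph(path: str | Path) -> DepthTrack:
    """Read a bedGraph into a per-position track.

    Chromosome lengths are inferred from the last covered interval; positions
    past the last interval are absent.  Overlapping intervals and negative
    values are errors.
    """
    segments: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start_s, end_s, value_s = line.split("\t")[:4]
            start, end, value = int(start_s), int(end_s), float(value_s)
            if value < 0:
                raise ValueError(f"line {lineno}: negative depth {value}")
            segments.setdefault(chrom, []).append((start, end, value))
    track = DepthTrack()
    for chrom, segs in segments.items():
        segs.sort()
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
        length = segs[-1][1]
        arr = np.zeros(length, dtype=np.float64)
        for start, end, value in segs:
            arr[start:end] = value
        track.depths[chrom] = arr
    return track


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    """Write a track as run-length-compressed bedGraph (trailing zeros kept)."""
    with open(path, "w") as fh:
        for chrom, arr in track.depths.items():
            if len(arr) == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                v_str = str(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{chrom}\t{s}\t{e}\t{v_str}\n")


def read_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            out.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_copy_number_bed(path: str | Path) -> CopyNumberMap:
    """BED with copy number in the 4th column."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            entries.append((Interval(fields[0], int(fields[1]), int(fields[2])), int(fields[3])))
    return CopyNumberMap(entries)
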