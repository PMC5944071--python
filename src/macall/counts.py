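"""Strand-specific allele counts at candidate sites.

The counts table is the adapter contract that replaces a local-reassembly
variant caller's per-sample strand counts.  It is tab-delimited with a header
row::

    #chrom  pos     alleles <sample1>       <sample2> ...

``pos`` is 1-based; ``alleles`` is a comma-separated list of allele sequences
with the reference allele first (insertion/deletion alleles are full,
left-anchored sequence strings).  Each sample column holds one ``top:bottom``
integer pair per allele, comma-separated in allele order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = ["StrandCounts", "SiteCounts", "read_counts_table", "write_counts_table"]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class StrandCounts:
    """Read counts on the top and bottom strand for one allele."""

    top: int
    bottom: int

    def __post_init__(self) -> None:
        if self.top < 0 or self.bottom < 0:
            raise ValueError("strand counts must be non-negative")

    @property
    def total(self) -> int:
        return self.top + self.bottom


@dataclass(slots=True)
class SiteCounts:
    """Per-sample, per-allele strand counts at one genomic position.

    ``alleles`` is ordered with the reference allele at index 0.  ``counts``
    maps sample name -> list of :class:`StrandCounts` parallel to ``alleles``.
    """

    chrom: str
    pos: int  # 1-based
    alleles: list[str]
    counts: dict[str, list[StrandCounts]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("at least one allele required")
        for a in self.alleles:
            # str.strip with allowed chars is a C-speed membership check
            if not a or a.strip("ACGT"):
                raise ValueError(f"invalid allele string {a!r}")
        for sample, per_allele in self.counts.items():
            if len(per_allele) != len(self.alleles):
                raise ValueError(
                    f"sample {sample!r}: {len(per_allele)} count pairs for "
                    f"{len(self.alleles)} alleles"
                )

    @property
    def ref(self) -> str:
        return self.alleles[0]

    def depth(self, sample: str) -> int:
        """Total read count for ``sample`` across alleles and strands."""
        return sum(sc.total for sc in self.counts[sample])

    def allele_total(self, sample: str, allele: str) -> int:
        return self.counts[sample][self.alleles.index(allele)].total


def _parse_pair(token: str) -> StrandCounts:
    try:
        top_s, bottom_s = token.split(":")
        return StrandCounts(int(top_s), int(bottom_s))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed top:bottom pair {token!r}") from exc


def read_counts_table(path: str | Path, samples: Sequence[str]) -> Iterator[SiteCounts]:
    """Stream :class:`SiteCounts` records from a counts table.

    ``samples`` is the list of sample names that must be present; a missing
    column raises ``ValueError``.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return
        columns = header.lstrip("#").rstrip("\n").split("\t")
        if columns[:3] != ["chrom", "pos", "alleles"]:
            raise ValueError("counts table must start with chrom, pos, alleles columns")
        sample_cols = columns[3:]
        missing = [s for s in samples if s not in sample_cols]
        if missing:
            raise ValueError(f"counts table missing sample column(s): {', '.join(missing)}")
        indices = {s: sample_cols.index(s) for s in samples}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 + len(sample_cols):
                raise ValueError(f"line {lineno}: expected {3 + len(sample_cols)} fields")
            chrom, pos_s, alleles_s = fields[:3]
            alleles = alleles_s.split(",")
            counts: dict[str, list[StrandCounts]] = {}
            for s in samples:
                pairs = fields[3 + indices[s]].split(",")
                if len(pairs) != len(alleles):
                    raise ValueError(
                        f"line {lineno}, sample {s!r}: {len(pairs)} pairs for "
                        f"{len(alleles)} alleles"
                    )
                counts[s] = [_parse_pair(p) for p in pairs]
            yield SiteCounts(chrom=chrom, pos=int(pos_s), alleles=alleles, counts=counts)


def write_counts_table(
    sites: Iterable[SiteCounts], samples: Sequence[str], path: str | Path
) -> None:
    """Write sites to a counts table with one column per sample."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\talleles\t" + "\t".join(samples) + "\n")
        for site in sites:
            cols = [site.chrom, str(site.pos), ",".join(site.alleles)]
            for s in samples:
                per_allele = site.counts[s]
                cols.append(",".join(f"{sc.top}:{sc.bottom}" for sc in per_allele))
            fh.write("\t".join(cols) + "\n")
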