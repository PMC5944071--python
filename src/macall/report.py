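"""Mutation records and the tab-delimited / VCF output writers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pysam

from .mutations import FilterStatus, SiteStatistics
from .paths import MutationEvent, format_hgvs

__all__ = ["MutationRecord", "write_mutations_tsv", "write_vcf"]


@dataclass
class MutationRecord:
    """One inferred mutation at one position in one outgrowth sample."""

    chrom: str
    pos: int  # 1-based
    sample: str
    alleles: list[str]  # site alleles, reference first
    events: list[MutationEvent] = field(default_factory=list)
    ambiguous_events: list[MutationEvent] = field(default_factory=list)
    t0_genotype: tuple[str, ...] = ()
    outgrowth_genotype: tuple[str, ...] = ()
    pac: str = "no"  # no | yes | ambiguous
    statistics: Optional[SiteStatistics] = None
    filter_status: FilterStatus = FilterStatus.PASS
    subclonal: Optional[tuple[str, float]] = None

    @property
    def ref(self) -> str:
        return self.alleles[0]

    @property
    def hgvs(self) -> str:
        parts = [
            format_hgvs(e, self.chrom, self.pos, self.ref)
            for e in list(self.events) + list(self.ambiguous_events)
        ]
        return ";".join(parts)

    @property
    def max_composite(self) -> float:
        if self.statistics is None:
            return float("nan")
        return max(self.statistics.composite, default=float("nan"))


_TSV_COLUMNS = [
    "chrom", "pos", "sample", "ref", "alleles", "t0_genotype",
    "outgrowth_genotype", "hgvs", "pac", "subclonal", "p_chi", "p_top",
    "p_bottom", "composite", "filter_status",
]


def write_mutations_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Tab-delimited report carrying the HGVS string and all statistics."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            if r.statistics is not None:
                p_chi = f"{r.statistics.p_chi:.3g}"
                p_top = ",".join(f"{v:.3g}" for v in r.statistics.p_top)
                p_bottom = ",".join(f"{v:.3g}" for v in r.statistics.p_bottom)
                composite = ",".join(f"{v:.4g}" for v in r.statistics.composite)
            else:
                p_chi = p_top = p_bottom = composite = ""
            sub = f"{r.subclonal[0]}:{r.subclonal[1]}" if r.subclonal else ""
            fh.write(
                "\t".join(
                    [
                        r.chrom, str(r.pos), r.sample, r.ref, ",".join(r.alleles),
                        "|".join(r.t0_genotype), "|".join(r.outgrowth_genotype),
                        r.hgvs, r.pac, sub, p_chi, p_top, p_bottom, composite,
                        r.filter_status.value,
                    ]
                )
                + "\n"
            )


def _vcf_header(chrom_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    for status in FilterStatus:
        if status is not FilterStatus.PASS:
            header.filters.add(status.value, None, None, f"Filtered: {status.value}")
    header.info.add("SAMPLE", 1, "String", "Outgrowth sample carrying the mutation")
    header.info.add("HGVS", 1, "String", "HGVS-style event description")
    header.info.add("PAC", 1, "String", "Potential allelic conversion flag (no/yes/ambiguous)")
    header.info.add("AMBIG", 0, "Flag", "Mutation identity is ambiguous")
    header.info.add("SCORE", 1, "Float", "Maximum per-allele composite score")
    header.info.add("PCHI", 1, "Float", "Chi-square goodness-of-fit p-value")
    return header


def write_vcf(
    records: Sequence[MutationRecord],
    reference: Mapping[str, str],
    path: str | Path,
) -> None:
    """VCF 4.2 output, one record per mutation position per sample.

    ``reference`` maps chromosome name to sequence and is used both for the
    contig header lines and to verify the reference allele at each position;
    a mismatch raises ``ValueError``.
    """
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    header = _vcf_header(chrom_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            seq = reference[r.chrom]
            expected = seq[r.pos - 1 : r.pos - 1 + len(r.ref)].upper()
            if expected != r.ref:
                raise ValueError(
                    f"reference mismatch at {r.chrom}:{r.pos}: "
                    f"record ref {r.ref!r} vs genome {expected!r}"
                )
            alleles = tuple(r.alleles) if len(r.alleles) > 1 else (r.ref, ".")
            rec = vcf.new_record(contig=r.chrom, start=r.pos - 1, alleles=alleles)
            if r.filter_status is FilterStatus.PASS:
                rec.filter.add("PASS")
            else:
                rec.filter.add(r.filter_status.value)
            rec.info["SAMPLE"] = r.sample
            if r.hgvs:
                rec.info["HGVS"] = r.hgvs.replace(";", "&").replace(" ", "_")
            rec.info["PAC"] = r.pac
            if r.ambiguous_events:
                rec.info["AMBIG"] = True
            if r.statistics is not None:
                rec.info["SCORE"] = r.max_composite
                rec.info["PCHI"] = r.statistics.p_chi
            vcf.write(rec)
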