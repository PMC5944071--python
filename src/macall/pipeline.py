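"""Full-analysis orchestration: models, calling, inference, filtering, reports.

The stages mirror the analysis a mutation-accumulation experiment needs:

1. per sample — fit the depth Gaussian, detect abnormal-depth regions, fit
   the strand-bias Gaussian, and fit the repeat indel-error curves;
2. per outgrowth — compute site statistics against the t0 control, apply
   the composite decision rule and filters, call genotypes at putative
   sites, infer parsimonious mutation events, and emit records.

Genotype calling is deliberately deferred to sites whose statistics fire:
the statistical rule defines putative sites, genotype comparison defines
the reported mutation.  Sites that fail the statistical rule are labelled
below_threshold without evaluating the t0 subclonal-bias condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .counts import SiteCounts
from .coverage import (
    DepthDistribution,
    StrandBiasDistribution,
    detect_abnormal_regions,
    fit_depth_distribution,
    fit_strand_bias_distribution,
)
from .genotype import GenotypeCall, call_genotype, validate_subclonal
from .indel_error import IndelErrorModel, RepeatObservation, fit_sample_error_model
from .mutations import (
    FilterStatus,
    Thresholds,
    apply_filters,
    decide_mutation_batch,
    site_statistics_batch,
    SiteStatistics,
)
from .paths import enumerate_shortest_paths, extract_consensus_events, flag_pac
from .report import MutationRecord
from .repeats import RepeatIndex, RepeatTract
from .tracks import CopyNumberMap, DepthTrack, Interval

logger = logging.getLogger(__name__)

__all__ = [
    "SampleModels",
    "PipelineConfig",
    "call_mutations_for_pair",
    "fit_sample_models",
    "run_pipeline",
    "recall_mutations",
]


@dataclass
class SampleModels:
    """Fitted per-sample models."""

    depth: Optional[DepthDistribution] = None
    strand_bias: Optional[StrandBiasDistribution] = None
    indel_error: Optional[IndelErrorModel] = None
    abnormal_regions: list[Interval] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Thresholds and options of the analysis."""

    fwer: float = 0.01
    depth_p_threshold: float = 1e-4
    merge_distance: int = 1000
    window: int = 25
    min_depth: int = 20
    exclusions: list[Interval] = field(default_factory=list)
    copy_numbers: Optional[CopyNumberMap] = None


def fit_sample_models(
    depth_track: DepthTrack,
    sites: Sequence[SiteCounts],
    sample: str,
    ploidy: int,
    observations: Optional[Sequence[RepeatObservation]] = None,
    config: Optional[PipelineConfig] = None,
) -> SampleModels:
    """Fit depth, strand-bias and indel-error models for one sample."""
    config = config or PipelineConfig()
    models = SampleModels()
    models.depth = fit_depth_distribution(depth_track, config.copy_numbers, ploidy)
    models.abnormal_regions = detect_abnormal_regions(
        depth_track,
        models.depth,
        config.copy_numbers,
        ploidy,
        window=config.window,
        p_threshold=config.depth_p_threshold,
        merge_distance=config.merge_distance,
    )
    tops = np.array(
        [sum(sc.top for sc in s.counts[sample]) for s in sites], dtype=np.float64
    )
    bottoms = np.array(
        [sum(sc.bottom for sc in s.counts[sample]) for s in sites], dtype=np.float64
    )
    try:
        models.strand_bias = fit_strand_bias_distribution(tops, bottoms)
    except ValueError:
        logger.warning("sample %s: strand-bias fit failed; using unit Gaussian", sample)
        models.strand_bias = StrandBiasDistribution(mean=0.0, std=0.5)
    if observations:
        models.indel_error = fit_sample_error_model(observations)
    return models


def _queryable_positions(
    chrom_lengths: dict[str, int],
    exclusions: Sequence[Interval],
    abnormal: Sequence[Interval],
) -> int:
    total = sum(chrom_lengths.values())
    removed = 0
    for iv in list(exclusions) + list(abnormal):
        if iv.chrom in chrom_lengths:
            removed += min(iv.end, chrom_lengths[iv.chrom]) - iv.start
    return max(total - removed, 1)


def _group_by_allele_count(sites: Sequence[SiteCounts]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(sites):
        groups.setdefault(len(s.alleles), []).append(i)
    return groups


def call_mutations_for_pair(
    sites: Sequence[SiteCounts],
    t0_sample: str,
    outgrowth_sample: str,
    chrom_lengths: dict[str, int],
    t0_models: SampleModels,
    outgrowth_models: SampleModels,
    t0_ploidy: int = 2,
    outgrowth_ploidy: int = 2,
    repeats: Optional[Sequence[RepeatTract]] = None,
    config: Optional[PipelineConfig] = None,
) -> tuple[list[MutationRecord], Thresholds]:
    """Identify mutations between one outgrowth and the t0 control.

    Returns all emitted records (statistically notable sites, i.e. any
    allele's composite score above the FWER-derived threshold, each with
    its filter status) plus the thresholds used.  Records with
    ``filter_status == PASS`` are the mutation calls.
    """
    config = config or PipelineConfig()
    abnormal = list(t0_models.abnormal_regions) + list(outgrowth_models.abnormal_regions)
    n_tests = _queryable_positions(chrom_lengths, config.exclusions, abnormal)
    thresholds = Thresholds(
        fwer=config.fwer, n_tests=n_tests, min_depth=config.min_depth
    )
    repeat_index = RepeatIndex(repeats) if repeats else None

    records: list[MutationRecord] = []
    groups = _group_by_allele_count(sites)
    for k, idxs in sorted(groups.items()):
        n = len(idxs)
        t0_top = np.empty((n, k)); t0_bot = np.empty((n, k))
        og_top = np.empty((n, k)); og_bot = np.empty((n, k))
        for row, i in enumerate(idxs):
            s = sites[i]
            for j, sc in enumerate(s.counts[t0_sample]):
                t0_top[row, j] = sc.top
                t0_bot[row, j] = sc.bottom
            for j, sc in enumerate(s.counts[outgrowth_sample]):
                og_top[row, j] = sc.top
                og_bot[row, j] = sc.bottom
        p_chi, p_top, p_bot, composite = site_statistics_batch(
            t0_top, t0_bot, og_top, og_bot
        )
        site_ok, _ = decide_mutation_batch(p_chi, p_top, p_bot, composite, thresholds)
        notable = composite.max(axis=1) > thresholds.composite_threshold
        for row in np.flatnonzero(notable):
            i = idxs[row]
            site = sites[i]
            stats = SiteStatistics(
                alleles=list(site.alleles),
                p_chi=float(p_chi[row]),
                p_top=[float(v) for v in p_top[row]],
                p_bottom=[float(v) for v in p_bot[row]],
            )
            record = _build_record(
                site,
                stats,
                bool(site_ok[row]),
                t0_sample,
                outgrowth_sample,
                t0_models,
                outgrowth_models,
                t0_ploidy,
                outgrowth_ploidy,
                repeat_index,
                abnormal,
                config,
                thresholds,
            )
            if record is not None:
                records.append(record)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, thresholds


def _rates_fn(models: SampleModels, tract: Optional[RepeatTract]):
    if models.indel_error is None or tract is None:
        return None
    ul = len(tract.unit)
    return lambda event, x: models.indel_error.rate(event, ul, x)


def _build_record(
    site: SiteCounts,
    stats: SiteStatistics,
    decision: bool,
    t0_sample: str,
    outgrowth_sample: str,
    t0_models: SampleModels,
    outgrowth_models: SampleModels,
    t0_ploidy: int,
    outgrowth_ploidy: int,
    repeat_index: Optional[RepeatIndex],
    abnormal: Sequence[Interval],
    config: PipelineConfig,
    thresholds: Thresholds,
) -> Optional[MutationRecord]:
    tract = repeat_index.at(site.chrom, site.pos) if repeat_index else None

    t0_call: Optional[GenotypeCall] = None
    og_call: Optional[GenotypeCall] = None
    status = apply_filters(
        site, t0_sample, outgrowth_sample, decision, thresholds,
        abnormal_regions=abnormal, exclusions=config.exclusions,
    )
    record = MutationRecord(
        chrom=site.chrom,
        pos=site.pos,
        sample=outgrowth_sample,
        alleles=list(site.alleles),
        statistics=stats,
        filter_status=status,
    )
    if status is not FilterStatus.PASS:
        return record

    # putative mutation: genotype both samples, then infer events
    t0_cn = (
        config.copy_numbers.copy_number(site.chrom, site.pos, t0_ploidy)
        if config.copy_numbers
        else t0_ploidy
    )
    og_cn = (
        config.copy_numbers.copy_number(site.chrom, site.pos, outgrowth_ploidy)
        if config.copy_numbers
        else outgrowth_ploidy
    )
    t0_call = call_genotype(
        site, t0_sample, t0_cn, role="t0", tract=tract,
        rates=_rates_fn(t0_models, tract),
    )
    if t0_call is None:
        record.filter_status = FilterStatus.LOW_DEPTH
        return record
    if t0_call.has_subclonal:
        t0_call = validate_subclonal(
            t0_call, site, t0_sample, t0_models.strand_bias, thresholds.n_tests,
            fwer=thresholds.fwer, tract=tract, rates=_rates_fn(t0_models, tract),
        )
        if t0_call.subclonal_rejected_reason == "strand_bias":
            record.filter_status = FilterStatus.T0_SUBCLONAL_BIAS
            return record
    og_call = call_genotype(
        site, outgrowth_sample, og_cn, role="outgrowth", t0_call=t0_call,
        tract=tract, rates=_rates_fn(outgrowth_models, tract),
    )
    if og_call is None:
        record.filter_status = FilterStatus.LOW_DEPTH
        return record
    if og_call.has_subclonal:
        og_call = validate_subclonal(
            og_call, site, outgrowth_sample, outgrowth_models.strand_bias,
            thresholds.n_tests, fwer=thresholds.fwer, tract=tract,
            rates=_rates_fn(outgrowth_models, tract),
        )

    record.t0_genotype = t0_call.clonal
    record.outgrowth_genotype = og_call.clonal
    record.subclonal = og_call.subclonal

    source = t0_call.clonal
    target = og_call.clonal
    if target == source and og_call.has_subclonal:
        target = _with_subclonal(og_call)
    if target == source:
        # statistics fired but the genotypes agree: nothing to report
        return None
    paths = enumerate_shortest_paths(source, target, site.alleles)
    certain, ambiguous = extract_consensus_events(paths)
    record.events = certain
    record.ambiguous_events = ambiguous
    record.pac = flag_pac(certain + ambiguous, source, target)
    return record


def _with_subclonal(call: GenotypeCall) -> tuple[str, ...]:
    allele, _ = call.subclonal
    # the subclonal genotype replaces one clonal allele with the new one
    clonal = list(call.clonal)
    for i, a in enumerate(clonal):
        if a != allele:
            clonal[i] = allele
            break
    return tuple(sorted(clonal))


# ---------------------------------------------------------------------------
# file-based orchestration
# ---------------------------------------------------------------------------


def _load_reference(path: str) -> dict[str, str]:
    import pyfaidx

    fasta = pyfaidx.Fasta(path)
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def _write_models_report(models: SampleModels, sample: str, out_dir) -> None:
    from pathlib import Path

    path = Path(out_dir) / f"{sample}.models.txt"
    with open(path, "w") as fh:
        fh.write(f"sample\t{sample}\n")
        if models.depth:
            fh.write(f"depth_mean\t{models.depth.mean:.6g}\n")
            fh.write(f"depth_std\t{models.depth.std:.6g}\n")
        if models.strand_bias:
            fh.write(f"strand_bias_mean\t{models.strand_bias.mean:.6g}\n")
            fh.write(f"strand_bias_std\t{models.strand_bias.std:.6g}\n")
        if models.indel_error:
            for (event, ul), fit in sorted(models.indel_error.fits.items()):
                fh.write(
                    f"indel_error\t{event}\tunit_{ul}\tM={fit.M:.6g}\t"
                    f"L={fit.L:.6g}\tk={fit.k:.6g}\tx0={fit.x0:.6g}\n"
                )


def run_pipeline(
    sample_sheet: str,
    reference_fasta: str,
    output_dir: str,
    config: Optional[PipelineConfig] = None,
    repeat_file: Optional[str] = None,
    depth_overrides: Optional[dict[str, str]] = None,
    ploidy_overrides: Optional[dict[str, int]] = None,
) -> dict[str, list[MutationRecord]]:
    """Run the full analysis from files; returns records per outgrowth.

    Per sample: fit depth/strand-bias/indel-error models, write abnormal
    regions (BED) and model parameters (plain text).  Per outgrowth: call
    mutations against the t0 control and write TSV + VCF reports.
    """
    from pathlib import Path

    from .indel_error import read_repeat_observations
    from .report import write_mutations_tsv, write_vcf
    from .repeats import find_repeats_genome, read_repeat_file
    from .samples import read_sample_sheet
    from .tracks import read_bedgraph, write_bed

    config = config or PipelineConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = read_sample_sheet(sample_sheet)
    t0 = next(c for c in configs if c.is_t0)
    outgrowths = [c for c in configs if not c.is_t0]
    reference = _load_reference(reference_fasta)
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    repeats = (
        read_repeat_file(repeat_file)
        if repeat_file
        else find_repeats_genome(reference)
    )

    # read each counts table once for every sample that points at it
    by_path: dict[str, list[str]] = {}
    for c in configs:
        if c.counts_path is None:
            raise ValueError(f"sample {c.name} has no counts path")
        by_path.setdefault(c.counts_path, []).append(c.name)
    from .counts import read_counts_table

    sites_by_path = {
        path: list(read_counts_table(path, names)) for path, names in by_path.items()
    }

    depth_overrides = depth_overrides or {}
    if ploidy_overrides:
        from dataclasses import replace

        configs = [
            replace(c, ploidy=ploidy_overrides.get(c.name, c.ploidy)) for c in configs
        ]
        t0 = next(c for c in configs if c.is_t0)
        outgrowths = [c for c in configs if not c.is_t0]

    models: dict[str, SampleModels] = {}
    for c in configs:
        track = read_bedgraph(depth_overrides.get(c.name, c.depth_path))
        obs = (
            read_repeat_observations(c.observations_path)
            if c.observations_path
            else None
        )
        m = fit_sample_models(
            track, sites_by_path[c.counts_path], c.name, c.ploidy, obs, config
        )
        models[c.name] = m
        write_bed(m.abnormal_regions, out / f"{c.name}.abnormal_regions.bed")
        _write_models_report(m, c.name, out)
        logger.info(
            "sample %s: depth %.1f±%.1f, %d abnormal regions",
            c.name, m.depth.mean, m.depth.std, len(m.abnormal_regions),
        )

    results: dict[str, list[MutationRecord]] = {}
    for og in outgrowths:
        if og.counts_path != t0.counts_path:
            raise ValueError(
                "t0 and outgrowth counts must come from the same table "
                f"({og.name} vs {t0.name})"
            )
        records, thresholds = call_mutations_for_pair(
            sites_by_path[og.counts_path],
            t0.name,
            og.name,
            chrom_lengths,
            models[t0.name],
            models[og.name],
            t0_ploidy=t0.ploidy,
            outgrowth_ploidy=og.ploidy,
            repeats=repeats,
            config=config,
        )
        results[og.name] = records
        write_mutations_tsv(records, out / f"{og.name}.mutations.tsv")
        write_vcf(records, reference, str(out / f"{og.name}.mutations.vcf"))
        n_pass = sum(r.filter_status is FilterStatus.PASS for r in records)
        logger.info(
            "outgrowth %s: %d records, %d pass (threshold %.3f)",
            og.name, len(records), n_pass, thresholds.composite_threshold,
        )
    return results


def recall_mutations(
    sample_sheet: str,
    reference_fasta: str,
    output_dir: str,
    config: Optional[PipelineConfig] = None,
    repeat_file: Optional[str] = None,
    depth_overrides: Optional[dict[str, str]] = None,
    ploidy_overrides: Optional[dict[str, int]] = None,
) -> dict[str, list[MutationRecord]]:
    """Re-run mutation calling under revised depth tracks or ploidies.

    Intended after depth correction or a copy-number revision: models are
    re-fit from the overridden inputs and calling repeats.  Requires prior
    run artifacts in ``output_dir``.
    """
    from pathlib import Path

    from .samples import read_sample_sheet

    out = Path(output_dir)
    configs = read_sample_sheet(sample_sheet)
    missing = [
        c.name for c in configs if not (out / f"{c.name}.models.txt").exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"no prior run artifacts for sample(s) {', '.join(missing)} in {out}"
        )
    return run_pipeline(
        sample_sheet,
        reference_fasta,
        output_dir,
        config=config,
        repeat_file=repeat_file,
        depth_overrides=depth_overrides,
        ploidy_overrides=ploidy_overrides,
    )
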