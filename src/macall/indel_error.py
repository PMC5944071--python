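"""Per-sample indel error rates in simple repeats.

PCR during library preparation introduces slippage indels whose rate grows
with repeat tract length.  For each sample, reads that fully traverse a known
repeat tract are counted, indel-containing traversals are summed per
(event type, unit length, tract length) stratum, and the rate-vs-length curve
is fitted with a four-parameter logistic

    error(x) = M + L / (1 + exp(-k (x - x0)))

where x is the tract length in bp.  The fitted curve supplies expected
insertion/deletion error rates during genotype calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

from .repeats import RepeatTract

__all__ = [
    "RepeatObservation",
    "IndelErrorFit",
    "IndelErrorModel",
    "aggregate_error_rates",
    "fit_error_function",
    "expected_error_rate",
    "fit_sample_error_model",
    "read_repeat_observations",
    "write_repeat_observations",
]

MIN_LOCI_PER_STRATUM = 10
RATE_CLAMP = 0.5  # cap on extrapolated rates so corrected masses stay sane


@dataclass(frozen=True)
class RepeatObservation:
    """Traversing coverage and indel-read counts at one repeat tract.

    ``indel_read_counts`` maps (event, size_in_units) -> read count, where
    event is "insertion" or "deletion" and size is a positive integer number
    of repeat units.
    """

    repeat: RepeatTract
    traversing_coverage: int
    indel_read_counts: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.traversing_coverage < 0:
            raise ValueError("traversing_coverage must be >= 0")
        if not self.indel_read_counts:
            return
        for (event, size), count in self.indel_read_counts.items():
            if event not in ("insertion", "deletion"):
                raise ValueError(f"unknown event {event!r}")
            if size < 1 or count < 0:
                raise ValueError("indel size must be >= 1 and count >= 0")
            if count > self.traversing_coverage:
                raise ValueError("indel count exceeds traversing coverage")


@dataclass(frozen=True)
class IndelErrorFit:
    """Logistic fit of one (event, unit length) error-rate curve."""

    event: str
    unit_length: int
    M: float
    L: float
    k: float
    x0: float
    fitted_lengths: tuple[int, ...] = ()

    def rate(self, tract_length: float) -> float:
        return expected_error_rate(self, tract_length)


def _logistic(x, M, L, k, x0):
    return M + L / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0)))


def aggregate_error_rates(observations: Iterable[RepeatObservation]) -> pd.DataFrame:
    """Pool observations into per-stratum error rates.

    Returns a DataFrame indexed by (event, unit_length, tract_length) with
    columns ``rate`` (indel reads / traversing coverage), ``n_loci``
    (distinct contributing tracts), ``indel_reads`` and ``coverage``.
    Strata with zero total coverage are omitted.
    """
    cov: dict[tuple[str, int, int], int] = {}
    reads: dict[tuple[str, int, int], int] = {}
    loci: dict[tuple[str, int, int], int] = {}
    for obs in observations:
        ul = len(obs.repeat.unit)
        tl = obs.repeat.tract_length
        for event in ("insertion", "deletion"):
            key = (event, ul, tl)
            cov[key] = cov.get(key, 0) + obs.traversing_coverage
            loci[key] = loci.get(key, 0) + 1
            n = sum(c for (e, _), c in obs.indel_read_counts.items() if e == event)
            reads[key] = reads.get(key, 0) + n
    records = []
    for key in sorted(cov):
        if cov[key] == 0:
            continue
        event, ul, tl = key
        records.append(
            {
                "event": event,
                "unit_length": ul,
                "tract_length": tl,
                "rate": reads[key] / cov[key],
                "n_loci": loci[key],
                "indel_reads": reads[key],
                "coverage": cov[key],
            }
        )
    df = pd.DataFrame.from_records(
        records,
        columns=["event", "unit_length", "tract_length", "rate", "n_loci", "indel_reads", "coverage"],
    )
    return df.set_index(["event", "unit_length", "tract_length"])


def fit_error_function(
    rate_table: pd.DataFrame, event: str, unit_length: int
) -> IndelErrorFit:
    """Least-squares logistic fit of rate vs tract length for one stratum set.

    Tract lengths observed at fewer than 10 distinct loci are excluded from
    the fit.  Raises ``ValueError("insufficient strata")`` when fewer than 4
    usable lengths remain; callers fall back to empirical rates.
    """
    try:
        sub = rate_table.loc[(event, unit_length)]
    except KeyError:
        raise ValueError("insufficient strata: none observed")
    sub = sub[sub["n_loci"] >= MIN_LOCI_PER_STRATUM]
    if len(sub) < 4:
        raise ValueError(f"insufficient strata: {len(sub)} usable tract lengths")
    x = sub.index.to_numpy(dtype=float)
    y = sub["rate"].to_numpy(dtype=float)

    m0 = float(y.min())
    l0 = max(float(y.max() - y.min()), 1e-6)
    p0 = (m0, l0, 1.0, float(np.median(x)))
    bounds = (
        [0.0, 0.0, 1e-6, x.min() - 5.0],
        [max(y.max(), 1e-6), 1.0, 10.0, x.max() + 5.0],
    )
    import warnings

    with warnings.catch_warnings():
        # flat strata leave some parameters unconstrained; the point estimate
        # is still the least-squares solution
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(
            _logistic, x, y, p0=p0, bounds=bounds, maxfev=50000
        )
    return IndelErrorFit(
        event=event,
        unit_length=unit_length,
        M=float(popt[0]),
        L=float(popt[1]),
        k=float(popt[2]),
        x0=float(popt[3]),
        fitted_lengths=tuple(int(v) for v in x),
    )


def expected_error_rate(fit: IndelErrorFit, tract_length: float) -> float:
    """Evaluate the logistic at ``tract_length``, clamped to [0, 0.5]."""
    rate = float(_logistic(tract_length, fit.M, fit.L, fit.k, fit.x0))
    return float(np.clip(rate, 0.0, RATE_CLAMP))


class IndelErrorModel:
    """Per-sample error-rate lookup with empirical fallback.

    Holds the logistic fits per (event, unit length) where fitting succeeded;
    where it did not, the stratum's empirical rate is used, else 0.
    """

    def __init__(self, rate_table: pd.DataFrame, fits: dict[tuple[str, int], IndelErrorFit]):
        self.rate_table = rate_table
        self.fits = fits

    def rate(self, event: str, unit_length: int, tract_length: int) -> float:
        fit = self.fits.get((event, unit_length))
        if fit is not None:
            return expected_error_rate(fit, tract_length)
        try:
            return float(
                np.clip(self.rate_table.loc[(event, unit_length, tract_length), "rate"], 0.0, RATE_CLAMP)
            )
        except KeyError:
            return 0.0


def fit_sample_error_model(observations: Iterable[RepeatObservation]) -> IndelErrorModel:
    """Aggregate and fit all (event, unit length) curves for one sample."""
    table = aggregate_error_rates(observations)
    fits: dict[tuple[str, int], IndelErrorFit] = {}
    for event in ("insertion", "deletion"):
        for ul in (1, 2, 3, 4):
            try:
                fits[(event, ul)] = fit_error_function(table, event, ul)
            except (ValueError, RuntimeError):
                continue
    return IndelErrorModel(table, fits)


def write_repeat_observations(
    observations: Iterable[RepeatObservation], path: str | Path
) -> None:
    """Tab-delimited per-repeat observation file (the adapter contract)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tunit\ttraversing_coverage\tindels\n")
        for obs in observations:
            r = obs.repeat
            indels = ";".join(
                f"{event}:{size}:{count}"
                for (event, size), count in sorted(obs.indel_read_counts.items())
            )
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.unit}\t{obs.traversing_coverage}\t{indels}\n"
            )


def read_repeat_observations(path: str | Path) -> list[RepeatObservation]:
    out: list[RepeatObservation] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, unit, cov, indels = line.rstrip("\n").split("\t")
            counts: dict[tuple[str, int], int] = {}
            if indels:
                for token in indels.split(";"):
                    event, size, count = token.split(":")
                    counts[(event, int(size))] = int(count)
            out.append(
                RepeatObservation(
                    repeat=RepeatTract(chrom, int(start), int(end), unit),
                    traversing_coverage=int(cov),
                    indel_read_counts=counts,
                )
            )
    return out
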