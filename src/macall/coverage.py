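"""Per-sample depth and strand-bias models.

Regions that map poorly or carry copy-number changes show more variation in
read coverage than chance allows, and skewed allelic fractions with them.
Depth of coverage (scaled to per-copy values by ploidy or a local copy-number
map) is modelled as Gaussian; windowed means far out in its tails mark
regions to filter.  Strand bias — the natural-log ratio of top- to
bottom-strand counts — is likewise modelled as Gaussian genome-wide and used
to reject subclonal calls driven by mismapped single-strand reads.  A
separate parametric model corrects the systematic depth elevation observed
near chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .tracks import CopyNumberMap, DepthTrack, Interval

__all__ = [
    "DepthDistribution",
    "StrandBiasDistribution",
    "DepthCorrectionModel",
    "fit_depth_distribution",
    "detect_abnormal_regions",
    "fit_strand_bias_distribution",
    "strand_bias_p_value",
    "fit_depth_correction",
    "correct_depths",
]


@dataclass(frozen=True)
class DepthDistribution:
    """Gaussian fit to per-copy read depth."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("std must be > 0")


@dataclass(frozen=True)
class StrandBiasDistribution:
    """Gaussian fit to ln(top/bottom) strand count ratios."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("std must be > 0")


@dataclass(frozen=True)
class DepthCorrectionModel:
    """Chromosome-end depth bias: expected depth relative to the genome mean.

    ``factor(x) = scalar * (1 - lognorm_cdf(x; mu, sigma)) + intercept +
    slope * x`` where x is distance in bp from the nearest chromosome end.
    """

    intercept: float
    scalar: float
    mu: float
    sigma: float
    slope: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    def factor(self, x: np.ndarray | float) -> np.ndarray | float:
        return _correction_factor(x, self.intercept, self.scalar, self.mu, self.sigma, self.slope)


def _correction_factor(x, intercept, scalar, mu, sigma, slope):
    x = np.asarray(x, dtype=np.float64)
    with np.errstate(divide="ignore"):
        lncdf = 0.5 + 0.5 * special.erf((np.log(np.maximum(x, 1e-12)) - mu) / (np.sqrt(2.0) * sigma))
    return scalar * (1.0 - lncdf) + intercept + slope * x


def _fit_gaussian_histogram(values: np.ndarray, bins) -> tuple[float, float]:
    """Least-squares Gaussian curve fit to a frequency histogram.

    More robust than moment estimation when the empirical distribution has a
    heavy tail (e.g. repetitive regions inflating depth).
    """
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    m0, s0 = float(np.mean(values)), float(np.std(values))
    if s0 == 0:
        raise ValueError("degenerate distribution: all values equal")
    a0 = float(counts.max())

    def gauss(x, a, m, s):
        return a * np.exp(-0.5 * ((x - m) / s) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts, p0=(a0, m0, s0),
            bounds=([0.0, centers.min() - 10 * s0, 1e-9], [np.inf, centers.max() + 10 * s0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"Gaussian histogram fit failed: {exc}") from exc
    _, mean, std = popt
    return float(mean), float(abs(std))


def _per_copy_depths(
    track: DepthTrack, copy_numbers: Optional[CopyNumberMap], ploidy: int
) -> np.ndarray:
    parts = []
    for chrom, arr in track.depths.items():
        if copy_numbers is not None:
            cn = copy_numbers.per_position(chrom, len(arr), ploidy)
        else:
            cn = ploidy
        parts.append(arr / cn)
    if not parts:
        raise ValueError("empty depth track")
    return np.concatenate(parts)


def fit_depth_distribution(
    track: DepthTrack,
    copy_numbers: Optional[CopyNumberMap] = None,
    ploidy: int = 2,
) -> DepthDistribution:
    """Fit the Gaussian depth distribution on per-copy depths.

    Depths are divided by the local copy number (from ``copy_numbers`` where
    provided, the sample ploidy elsewhere), binned at integer resolution, and
    a Gaussian curve is fitted to the histogram by least squares.
    """
    values = _per_copy_depths(track, copy_numbers, ploidy)
    if np.all(values == values[0]):
        raise ValueError("degenerate distribution: constant depth")
    hi = float(np.quantile(values, 0.999))
    n_bins = max(int(np.ceil(hi)) + 1, 10)
    mean, std = _fit_gaussian_histogram(values, bins=np.linspace(-0.5, hi + 0.5, n_bins + 1))
    return DepthDistribution(mean=mean, std=std)


def _windowed_mean(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows are truncated to the sequence."""
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(window)
    sums = np.convolve(arr, kernel, mode="same")
    counts = np.convolve(np.ones_like(arr), kernel, mode="same")
    return sums / counts


def detect_abnormal_regions(
    track: DepthTrack,
    distribution: DepthDistribution,
    copy_numbers: Optional[CopyNumberMap] = None,
    ploidy: int = 2,
    window: int = 25,
    p_threshold: float = 1e-4,
    merge_distance: int = 1000,
) -> list[Interval]:
    """Locate regions of abnormally high or low coverage.

    Per-copy depths are averaged in a ``window``-bp moving window, compared
    two-tailed against the fitted Gaussian, and significant positions on the
    same side of the mean within ``merge_distance`` of each other bound a
    region.  Output intervals are 0-based half-open BED spans covering
    [first, last] significant positions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    regions: list[Interval] = []
    for chrom, arr in track.depths.items():
        if copy_numbers is not None:
            per_copy = arr / copy_numbers.per_position(chrom, len(arr), ploidy)
        else:
            per_copy = arr / ploidy
        avg = _windowed_mean(per_copy, window)
        z = (avg - distribution.mean) / distribution.std
        p = 2.0 * stats.norm.sf(np.abs(z))
        sig = np.flatnonzero(p < p_threshold)
        if sig.size == 0:
            continue
        high = avg[sig] > distribution.mean
        # split where the gap exceeds merge_distance or the side flips
        breaks = np.flatnonzero(
            (np.diff(sig) > merge_distance) | (high[1:] != high[:-1])
        )
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [sig.size - 1]))
        for s, e in zip(starts, ends):
            first_pos = int(sig[s]) + 1  # 1-based
            last_pos = int(sig[e]) + 1
            regions.append(Interval(chrom, first_pos - 1, last_pos))
    return regions


def fit_strand_bias_distribution(
    top: Sequence[int] | np.ndarray, bottom: Sequence[int] | np.ndarray
) -> StrandBiasDistribution:
    """Fit the genome-wide Gaussian of ln(top/bottom) strand-count ratios.

    A pseudo-count of 1 is added to each strand before the ratio; positions
    with zero total count are skipped.
    """
    top = np.asarray(top, dtype=np.float64)
    bottom = np.asarray(bottom, dtype=np.float64)
    mask = (top + bottom) > 0
    ratios = np.log((top[mask] + 1.0) / (bottom[mask] + 1.0))
    if ratios.size < 2 or np.all(ratios == ratios[0]):
        raise ValueError("insufficient positions to fit strand-bias distribution")
    mean, std = _fit_gaussian_histogram(ratios, bins=100)
    return StrandBiasDistribution(mean=mean, std=std)


def strand_bias_p_value(
    top: int, bottom: int, distribution: StrandBiasDistribution
) -> float:
    """Two-tailed Gaussian p-value of the (pseudo-counted) ln strand ratio."""
    if top + bottom <= 0:
        raise ValueError("top + bottom must be > 0")
    ratio = np.log((top + 1.0) / (bottom + 1.0))
    z = (ratio - distribution.mean) / distribution.std
    lower = stats.norm.cdf(z)
    return float(2.0 * min(lower, 1.0 - lower))


def distance_from_chromosome_end(length: int) -> np.ndarray:
    """Per-position distance (bp) to the nearest chromosome end; ends are 1."""
    pos = np.arange(1, length + 1)
    return np.minimum(pos, length - pos + 1)


def fit_depth_correction(
    track: DepthTrack,
    chrom_lengths: Optional[dict[str, int]] = None,
    bin_size: int = 500,
) -> DepthCorrectionModel:
    """Fit the chromosome-end depth-bias model.

    The ratio of per-position depth to the genome-wide mean is binned by
    distance from the nearest chromosome end in ``bin_size``-bp bins; per-bin
    medians (excluding ratios above 4 or below 0.25) are fitted by non-linear
    least squares to ``factor(x)``.
    """
    chrom_lengths = chrom_lengths or {c: len(a) for c, a in track.depths.items()}
    all_depths = np.concatenate(list(track.depths.values()))
    gmean = float(np.mean(all_depths))
    if gmean <= 0:
        raise ValueError("non-positive genome-wide mean depth")
    ratios_parts, dist_parts = [], []
    for chrom, arr in track.depths.items():
        dist_parts.append(distance_from_chromosome_end(chrom_lengths[chrom])[: len(arr)])
        ratios_parts.append(arr / gmean)
    ratios = np.concatenate(ratios_parts)
    dists = np.concatenate(dist_parts)
    keep = (ratios <= 4.0) & (ratios >= 0.25)
    ratios, dists = ratios[keep], dists[keep]
    bin_idx = (dists - 1) // bin_size
    order = np.argsort(bin_idx, kind="stable")
    bin_idx, ratios = bin_idx[order], ratios[order]
    uniq, starts = np.unique(bin_idx, return_index=True)
    medians = np.array(
        [np.median(ratios[s:e]) for s, e in zip(starts, np.append(starts[1:], ratios.size))]
    )
    centers = (uniq + 0.5) * bin_size
    if centers.size < 10:
        raise ValueError(f"only {centers.size} usable bins; >= 10 required")

    p0 = (
        float(np.median(medians[centers > np.median(centers)])),  # intercept
        float(medians[0] - np.median(medians)),                   # scalar
        float(np.log(max(centers[min(3, centers.size - 1)], 2.0))),  # mu
        1.0,                                                       # sigma
        0.0,                                                       # slope
    )
    try:
        popt, _ = optimize.curve_fit(
            _correction_factor, centers, medians, p0=p0,
            bounds=(
                [-np.inf, -np.inf, np.log(1.0), 1e-6, -np.inf],
                [np.inf, np.inf, np.log(centers.max() * 10), 10.0, np.inf],
            ),
            maxfev=50000,
        )
    except RuntimeError as exc:
        raise ValueError(
            f"depth-correction fit did not converge ({exc}); "
            f"{centers.size} bins, median ratio {np.median(medians):.3f}"
        ) from exc
    model = DepthCorrectionModel(
        intercept=float(popt[0]), scalar=float(popt[1]), mu=float(popt[2]),
        sigma=float(abs(popt[3])), slope=float(popt[4]),
    )
    if np.any(np.asarray(model.factor(centers)) <= 0):
        raise ValueError("fitted correction factor non-positive over the data domain")
    return model


def correct_depths(track: DepthTrack, model: DepthCorrectionModel) -> DepthTrack:
    """Scale each position's depth by 1/factor(distance to nearest end)."""
    out = DepthTrack()
    for chrom, arr in track.depths.items():
        factor = np.asarray(model.factor(distance_from_chromosome_end(len(arr))))
        if np.any(factor <= 0):
            raise ValueError(f"non-positive correction factor on {chrom}")
        out.depths[chrom] = arr / factor
    return out
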