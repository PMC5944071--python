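"""Global ploidy estimation support via allelic-fraction histograms.

At a heterozygous site the fraction of reads supporting each allele clusters
around multiples of 1/ploidy, so the interior peaks of a genome-wide
allelic-fraction histogram indicate ploidy: the largest interior peak sits at
1/ploidy (and, above diploid, its mirror at 1 - 1/ploidy).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .counts import SiteCounts

__all__ = ["allelic_fraction_histogram"]

logger = logging.getLogger(__name__)


def allelic_fraction_histogram(
    sites: Iterable[SiteCounts], sample: str, n_bins: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-allele allelic fractions for one sample.

    The allelic fraction of an allele is its pooled-strand read count divided
    by the total read count at the position.  Zero-depth sites are skipped
    (and logged).  Returns ``(counts, bin_edges)`` over [0, 1] with ``n_bins``
    equal-width bins; counts sum to the number of retained (site, allele)
    observations.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    fractions: list[float] = []
    n_skipped = 0
    for site in sites:
        per_allele = site.counts.get(sample)
        if per_allele is None:
            continue
        totals = [sc.total for sc in per_allele]
        depth = sum(totals)
        if depth == 0:
            n_skipped += 1
            continue
        fractions.extend(t / depth for t in totals)
    if n_skipped:
        logger.info("allelic_fraction_histogram: skipped %d zero-depth sites", n_skipped)
    counts, edges = np.histogram(fractions, bins=n_bins, range=(0.0, 1.0))
    return counts, edges
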