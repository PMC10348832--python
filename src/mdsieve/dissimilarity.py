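"""Dissimilarity between property distributions.

Subsampling quality is judged by comparing the reference property's
distribution in the subsample against the full trajectory, both histogrammed
on the same bin edges.  The primary measure is the Bhattacharyya distance

    D_B(p, q) = -ln( sum_i sqrt(p_i * q_i) )

which is 0 iff the discrete distributions are identical and +inf when their
supports are disjoint.  Infinity is an ordinary, comparable value here (it
ranks worse than any finite distance in a size sweep) rather than an
exception.  Kullback-Leibler divergence and 1 - Pearson correlation of bin
probabilities are provided behind the same interface as extension measures.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from .errors import BinEdgeMismatchError
from .properties import DiscreteDistribution, PropertySeries, discretize
from .trajectory import FrameSample

__all__ = [
    "DissimilarityResult",
    "bhattacharyya_distance",
    "kl_divergence",
    "pearson_dissimilarity",
    "MEASURES",
    "compare_sample",
    "write_report_csv",
]


@dataclass
class DissimilarityResult:
    """A dissimilarity value with the bookkeeping needed to interpret it."""

    measure_name: str
    value: float
    n_bins: int
    sample_size: int
    full_size: int

    def __post_init__(self) -> None:
        if not (self.value >= 0 or math.isinf(self.value)):
            raise ValueError(f"dissimilarity must be >= 0, got {self.value}")


def _check_comparable(p: DiscreteDistribution, q: DiscreteDistribution) -> None:
    if p.n_bins != q.n_bins or not np.array_equal(p.bin_edges, q.bin_edges):
        raise BinEdgeMismatchError(
            "distributions were binned on different edges and cannot be "
            "compared; rebuild both with shared edges"
        )


def bhattacharyya_distance(
    p: DiscreteDistribution, q: DiscreteDistribution
) -> float:
    """Bhattacharyya distance -ln(sum_i sqrt(p_i q_i)) between two
    histograms on identical bin edges.

    Returns 0.0 exactly for identical distributions, and ``math.inf``
    (signalled, not raised) when the supports are disjoint.

    Raises
    ------
    BinEdgeMismatchError
        If the bin edges differ (enforced, never assumed).
    """
    _check_comparable(p, q)
    if np.array_equal(p.probabilities, q.probabilities):
        return 0.0
    bc = float(np.sum(np.sqrt(p.probabilities * q.probabilities)))
    if bc <= 0.0:
        return math.inf
    return -math.log(min(bc, 1.0))


def kl_divergence(p: DiscreteDistribution, q: DiscreteDistribution) -> float:
    """Kullback-Leibler divergence D(p || q); +inf when q lacks mass on a
    bin where p has some.  Extension measure (asymmetric)."""
    _check_comparable(p, q)
    pi, qi = p.probabilities, q.probabilities
    mask = pi > 0
    if np.any(qi[mask] == 0):
        return math.inf
    return float(np.sum(pi[mask] * np.log(pi[mask] / qi[mask])))


def pearson_dissimilarity(
    p: DiscreteDistribution, q: DiscreteDistribution
) -> float:
    """1 - Pearson correlation of bin probabilities. Extension measure;
    degenerate (constant) probability vectors give the maximal value 1."""
    _check_comparable(p, q)
    pi, qi = p.probabilities, q.probabilities
    if np.ptp(pi) == 0 or np.ptp(qi) == 0:
        return 1.0
    r = float(np.corrcoef(pi, qi)[0, 1])
    return min(max(1.0 - r, 0.0), 2.0)


MEASURES = {
    "bhattacharyya": bhattacharyya_distance,
    "kl": kl_divergence,
    "pearson": pearson_dissimilarity,
}


def compare_sample(
    series: PropertySeries,
    sample: FrameSample,
    n_bins: int = 100,
    measure: str = "bhattacharyya",
    range_override: tuple[float, float] | None = None,
    pseudocount: float = 0.0,
) -> DissimilarityResult:
    """Dissimilarity between a subsample's property distribution and the
    full series', on shared full-series bin edges.

    ``pseudocount`` optionally adds a constant to every bin of both
    histograms before normalization (off by default: pseudocounts change
    the textbook quantity).

    Raises
    ------
    DegenerateRangeError
        Propagated from binning a constant series without a range override.
    """
    if measure not in MEASURES:
        raise ValueError(
            f"unknown measure {measure!r}; choose from {sorted(MEASURES)}"
        )
    full = discretize(series, n_bins=n_bins, range_override=range_override)
    sub = discretize(
        series, n_bins=n_bins, range_override=(full.bin_edges[0], full.bin_edges[-1]),
        restrict_to=sample,
    )
    if pseudocount > 0.0:
        full = _with_pseudocount(full, pseudocount)
        sub = _with_pseudocount(sub, pseudocount)
    value = MEASURES[measure](full, sub)
    return DissimilarityResult(
        measure, value, n_bins, sample_size=len(sample), full_size=series.n_frames
    )


def _with_pseudocount(
    dist: DiscreteDistribution, eps: float
) -> DiscreteDistribution:
    # rebuild via probabilities, not counts, so eps need not be integral
    probs = dist.probabilities + eps
    probs /= probs.sum()
    out = DiscreteDistribution(dist.bin_edges, dist.counts)
    out.probabilities = probs
    return out


def write_report_csv(
    results: list[DissimilarityResult], path: str | os.PathLike
) -> None:
    """Write results as CSV: measure, n_bins, sample_size, full_size, distance.

    Infinite distances are serialized as ``inf``.
    """
    with open(os.fspath(path), "w") as fh:
        fh.write("measure,n_bins,sample_size,full_size,distance\n")
        for r in results:
            fh.write(
                f"{r.measure_name},{r.n_bins},{r.sample_size},"
                f"{r.full_size},{r.value:.10g}\n"
            )
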