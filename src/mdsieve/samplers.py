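"""Statistical samplers over trajectory frames.

Five strategies select frames a posteriori, independent of how the
trajectory was generated:

- :func:`sample_random` — a fixed number of frames uniformly without
  replacement;
- :func:`sample_uniform` — an equal number of frames per equal-width
  interval (stratum) of a reference property, flattening its distribution;
- :func:`sample_stratified` — an equal number of frames per labelled subset
  (e.g. per replica);
- :func:`sample_weighted` — frames drawn with chance proportional to
  user-provided weights (e.g. from :func:`weights_from_frequency`, which
  favours frequently observed conformational states);
- :func:`sample_bootstrap` — repeated uniform samples with replacement, for
  variability estimates.

Every sampler is a pure function of its inputs plus an integer seed.
Random, uniform and stratified draw without replacement; weighted defaults
to without replacement (sequential draws with renormalization) with an
opt-in ``replacement`` flag; bootstrapping is always with replacement.
Strata that cannot fill their quota contribute everything they have and the
shortfall is recorded on the sample — never silently redistributed, so an
"equal representation" guarantee is not distorted.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateRangeError, InputError, SampleSizeError
from .properties import PropertySeries, bin_index_of, discretize
from .trajectory import FrameSample

__all__ = [
    "FrameWeights",
    "StrataAssignment",
    "sample_random",
    "sample_uniform",
    "sample_stratified",
    "sample_weighted",
    "weights_from_frequency",
    "sample_bootstrap",
]


class FrameWeights:
    """One nonnegative weight per frame; normalizes to a probability vector."""

    def __init__(self, weights: np.ndarray):
        w = np.asarray(weights, dtype=np.float64)
        if w.ndim != 1 or len(w) == 0:
            raise InputError("weights must be a non-empty 1-D array")
        if not np.isfinite(w).all():
            raise InputError("weights contain non-finite values")
        if np.any(w < 0):
            raise InputError("weights must be nonnegative")
        if not np.any(w > 0):
            raise InputError("at least one weight must be positive")
        self.weights = w

    def __len__(self) -> int:
        return len(self.weights)

    def normalized(self) -> np.ndarray:
        return self.weights / self.weights.sum()

    @classmethod
    def from_file(cls, path: str, n_frames: int, one_based: bool = False
                  ) -> "FrameWeights":
        from .properties import import_property_series

        series = import_property_series(
            path, n_frames, one_based=one_based, property_name="weight"
        )
        return cls(series.values)


class StrataAssignment:
    """One label per frame; ``label_set`` keeps first-appearance order."""

    def __init__(self, labels):
        labels = np.asarray(labels)
        if labels.ndim != 1 or len(labels) == 0:
            raise InputError("labels must be a non-empty 1-D sequence")
        self.labels = labels
        _, first = np.unique(labels, return_index=True)
        self.label_set = [labels[i] for i in sorted(first)]

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_file(cls, path: str, n_frames: int, one_based: bool = False
                  ) -> "StrataAssignment":
        """Read a two-column (frame_index, label) text file."""
        import os

        from .errors import AlignmentError

        if not os.path.exists(path):
            raise InputError(f"labels file not found: {path}")
        seen: dict[int, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.strip()
                if not text or text.startswith("#"):
                    continue
                parts = text.replace(",", " ").split()
                if len(parts) != 2:
                    raise InputError(
                        f"{path}:{lineno}: expected two columns, got {len(parts)}"
                    )
                idx = int(parts[0]) - (1 if one_based else 0)
                if not 0 <= idx < n_frames:
                    raise AlignmentError(f"{path}:{lineno}: frame {parts[0]} out of range")
                if idx in seen:
                    raise AlignmentError(f"{path}:{lineno}: duplicate frame {idx}")
                seen[idx] = parts[1]
        missing = sorted(set(range(n_frames)) - seen.keys())
        if missing:
            raise AlignmentError(f"{path}: no label for frames {missing[:10]}")
        return cls(np.array([seen[i] for i in range(n_frames)]))


def _quotas(size: int, n_strata: int, occupied: np.ndarray) -> np.ndarray:
    """Per-stratum quotas: floor(size / n_strata) each, the remainder
    assigned one extra frame to the lowest-indexed occupied strata in order
    (deterministic, seed-independent)."""
    base = size // n_strata
    remainder = size - base * n_strata
    quotas = np.full(n_strata, base, dtype=np.intp)
    for s in np.flatnonzero(occupied):
        if remainder == 0:
            break
        quotas[s] += 1
        remainder -= 1
    return quotas


def sample_random(n_frames: int, size: int, seed: int) -> FrameSample:
    """Draw ``size`` distinct frames uniformly without replacement.

    Raises
    ------
    SampleSizeError
        If ``size`` is not in ``[1, n_frames]`` (no silent truncation).
    """
    if not 1 <= size <= n_frames:
        raise SampleSizeError(
            f"requested {size} frames from a {n_frames}-frame trajectory"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_frames, size=size, replace=False)
    return FrameSample(np.sort(idx), "random", size, seed)


def _draw_per_stratum(
    members_per_stratum: list[np.ndarray],
    quotas: np.ndarray,
    seed: int,
    strategy: str,
    size: int,
) -> FrameSample:
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    shortfall = 0
    for members, quota in zip(members_per_stratum, quotas):
        if quota == 0 or len(members) == 0:
            shortfall += int(quota) if len(members) == 0 else 0
            continue
        take = min(int(quota), len(members))
        shortfall += int(quota) - take
        picked = rng.choice(len(members), size=take, replace=False)
        chosen.append(members[picked])
    idx = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=np.intp)
    return FrameSample(idx, strategy, size, seed, shortfall=shortfall)


def sample_uniform(
    series: PropertySeries, size: int, n_strata: int, seed: int
) -> FrameSample:
    """Draw an (as far as possible) equal number of frames per equal-width
    interval of a reference property, so the sample represents the
    property's whole range evenly — e.g. all degrees of opening of a
    binding pocket for ensemble docking.

    The property range [min, max] is split into ``n_strata`` equal-width
    intervals; ``floor(size / n_strata)`` frames are drawn uniformly without
    replacement in each, the remainder going one-per-stratum to the
    lowest-indexed occupied intervals.  Intervals holding fewer frames than
    their quota contribute all of them; the shortfall is reported on the
    returned sample, not redistributed.

    Raises
    ------
    DegenerateRangeError
        If the series is constant (a single stratum would hold everything).
    SampleSizeError
        If ``size < n_strata`` or ``n_strata < 2``.
    """
    if n_strata < 2 or size < n_strata:
        raise SampleSizeError(
            f"need size >= n_strata >= 2, got size={size}, n_strata={n_strata}"
        )
    lo, hi = float(series.values.min()), float(series.values.max())
    if lo == hi:
        raise DegenerateRangeError(
            f"property {series.property_name!r} is constant; "
            "uniform-over-range sampling is undefined"
        )
    edges = np.linspace(lo, hi, n_strata + 1)
    which = bin_index_of(series.values, edges)
    members = [np.flatnonzero(which == s) for s in range(n_strata)]
    occupied = np.array([len(m) > 0 for m in members])
    quotas = _quotas(size, n_strata, occupied)
    return _draw_per_stratum(members, quotas, seed, "uniform", size)


def sample_stratified(
    strata: StrataAssignment, size: int, seed: int
) -> FrameSample:
    """Draw an equal number of frames per labelled subset of the trajectory
    (e.g. one label per concatenated replica).  Quota and shortfall rules
    are identical to :func:`sample_uniform`.
    """
    labels = strata.label_set
    if size < len(labels):
        raise SampleSizeError(
            f"need size >= number of labels ({len(labels)}), got {size}"
        )
    members = [np.flatnonzero(strata.labels == lab) for lab in labels]
    occupied = np.array([len(m) > 0 for m in members])
    quotas = _quotas(size, len(labels), occupied)
    return _draw_per_stratum(members, quotas, seed, "stratified", size)


def sample_weighted(
    weights: FrameWeights, size: int, seed: int, replacement: bool = False
) -> FrameSample:
    """Draw frames with chance proportional to per-frame weights.

    Without replacement (the default) the draw is sequential with
    renormalization after each pick; zero-weight frames are never selected.

    Raises
    ------
    SampleSizeError
        If, without replacement, ``size`` exceeds the number of
        strictly-positive weights.
    """
    p = weights.normalized()
    n_positive = int(np.count_nonzero(p))
    if size < 1:
        raise SampleSizeError(f"size must be >= 1, got {size}")
    if not replacement and size > n_positive:
        raise SampleSizeError(
            f"requested {size} frames without replacement but only "
            f"{n_positive} frames have positive weight"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(p), size=size, replace=replacement, p=p)
    return FrameSample(np.sort(idx), "weighted", size, seed, replacement=replacement)


def weights_from_frequency(series: PropertySeries, n_bins: int = 100,
                           range_override: tuple[float, float] | None = None
                           ) -> FrameWeights:
    """Weights that favour frequently observed conformations.

    Each frame's weight is the probability mass of the property bin it
    falls in (shared full-series edges, as in :func:`discretize`), then the
    vector is normalized over frames — each frame's selection chance is
    proportional to the frequency of its conformational state.  Frames
    outside an explicit range override get weight zero.
    """
    dist = discretize(series, n_bins=n_bins, range_override=range_override)
    which = bin_index_of(series.values, dist.bin_edges)
    w = np.where(which >= 0, dist.probabilities[which], 0.0)
    return FrameWeights(w / w.sum())


def sample_bootstrap(
    n_frames: int, size: int, n_iterations: int, seed: int
) -> list[FrameSample]:
    """Repeated uniform random samples WITH replacement.

    Returns ``n_iterations`` independent replicates of exactly ``size``
    draws each.  Replicate ``r`` derives its generator stream from
    ``(seed, r)``, so any single replicate is reproducible on its own.
    """
    if size < 1 or n_iterations < 1:
        raise SampleSizeError("size and n_iterations must be >= 1")
    if n_frames < 1:
        raise SampleSizeError("n_frames must be >= 1")
    replicates = []
    for r in range(n_iterations):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, n_frames, size=size)
        replicates.append(
            FrameSample(np.sort(idx), "bootstrap", size, seed, replacement=True)
        )
    return replicates
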