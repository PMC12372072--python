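"""Region-wise constrained-DTW similarity between barbell velocity traces.

A lift's velocity waveform is segmented at two landmarks — the first
velocity peak and the subsequent velocity minimum — into pre-sticking,
sticking and post-sticking regions.  Each region pair (experimental vs
simulated) is resampled to a common length, amplitude-scaled by the
experimental trace's global maximum, and compared with dynamic time
warping restricted to a Sakoe-Chiba band of half-width ``w`` percent of
the segment length.  The distance ``D`` maps to a similarity index

    SI = 1 - D / (D + L),       L = length of the longest series,

and significance comes from a permutation test that shuffles the sample
order of both series and recomputes SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class NoStickingRegionError(ValueError):
    """Trace has no peak-then-minimum pattern to anchor the segmentation."""


@dataclass(frozen=True)
class VelocityTrace:
    """A sampled velocity waveform (m/s) on a time or percent axis."""

    values: np.ndarray
    axis: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        if self.values.size < 10:
            raise ValueError("trace needs at least 10 samples")
        if self.values.shape != self.axis.shape:
            raise ValueError("values and axis must have equal length")
        if not (np.all(np.isfinite(self.values)) and np.all(np.isfinite(self.axis))):
            raise ValueError("trace must be finite")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class RegionScore:
    SI: float
    D: float
    p: float | None


@dataclass(frozen=True)
class SimilarityResult:
    """Per-region and global cDTW similarity between two traces."""

    regions: dict[str, RegionScore]
    anchors_a: tuple[int, int, int, int]
    anchors_b: tuple[int, int, int, int]
    w_percent: float
    n_resample: int


def resample_normalize(trace: VelocityTrace, n: int = 101, scale: float | None = None) -> VelocityTrace:
    """Resample to ``n`` uniform points over the trace's span.

    Linear interpolation; with ``scale`` given, the amplitude is divided by
    it (the comparison pipeline passes the experimental trace's global
    maximum so distances are dimensionless).
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to resample")
    axis = np.linspace(trace.axis[0], trace.axis[-1], n)
    vals = np.interp(axis, trace.axis, trace.values)
    if scale is not None:
        if scale == 0:
            raise ValueError("scale must be non-zero")
        vals = vals / scale
    return VelocityTrace(values=vals, axis=axis, label=trace.label)


def _smooth(x: np.ndarray, frac: float = 0.05) -> np.ndarray:
    win = max(1, int(round(frac * x.size)))
    if win % 2 == 0:
        win += 1
    if win == 1:
        return x
    kernel = np.ones(win) / win
    pad = win // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(padded, kernel, mode="valid")


def segment_regions(trace: VelocityTrace, smooth_frac: float = 0.05) -> tuple[int, int, int, int]:
    """Anchor indices (start, first_peak, minimum, end) of a lift trace.

    Peaks are detected on a lightly smoothed copy (centered moving average,
    window ``smooth_frac`` of the sample count); the anchors are the first
    interior local maximum and the subsequent local minimum.  Raises
    :class:`NoStickingRegionError` for a monotone trace.
    """
    v = _smooth(trace.values, smooth_frac)
    sign = np.sign(np.diff(v))
    sign[sign == 0] = 1
    maxima = np.nonzero((sign[:-1] > 0) & (sign[1:] < 0))[0] + 1
    minima = np.nonzero((sign[:-1] < 0) & (sign[1:] > 0))[0] + 1
    for i in maxima:
        later = minima[minima > i]
        if later.size:
            return 0, int(i), int(later[0]), len(trace) - 1
    raise NoStickingRegionError("no first-peak-then-minimum pattern found")


def _band_width(n: int, m: int, w_percent: float) -> int:
    w = math.ceil(w_percent / 100.0 * max(n, m))
    return max(w, 1, abs(n - m))


def cdtw_distance(a: np.ndarray, b: np.ndarray, w_percent: float = 20.0) -> float:
    """Constrained DTW distance with a Sakoe-Chiba band.

    Symmetric step pattern (match / insert / delete), local cost
    ``|a_i - b_j|``, band half-width ``ceil(w% * n)`` (at least 1 and at
    least ``|len(a) - len(b)|`` so the corners stay connected).  The
    dynamic program is evaluated along anti-diagonals with vectorised
    minima.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size == 0 or b.size == 0:
        raise ValueError("inputs must be non-empty 1-D arrays")
    if not 0 < w_percent <= 100:
        raise ValueError("w_percent must lie in (0, 100]")
    n, m = a.size, b.size
    w = _band_width(n, m, w_percent)
    INF = np.inf
    D = np.full((n, m), INF)
    cost = np.abs(a[:, None] - b[None, :])
    for k in range(n + m - 1):
        i = np.arange(max(0, k - m + 1), min(n - 1, k) + 1)
        j = k - i
        inband = np.abs(i - j) <= w
        i, j = i[inband], j[inband]
        if i.size == 0:
            continue
        if k == 0:
            D[0, 0] = cost[0, 0]
            continue
        up = np.where(i > 0, D[np.maximum(i - 1, 0), j], INF)
        left = np.where(j > 0, D[i, np.maximum(j - 1, 0)], INF)
        diag = np.where((i > 0) & (j > 0), D[np.maximum(i - 1, 0), np.maximum(j - 1, 0)], INF)
        D[i, j] = cost[i, j] + np.minimum(np.minimum(up, left), diag)
    d = float(D[n - 1, m - 1])
    if not np.isfinite(d):
        raise RuntimeError("band too narrow to connect the corners")
    return d


def similarity_index(a: np.ndarray, b: np.ndarray, w_percent: float = 20.0) -> float:
    """SI = 1 - D/(D + L) in [0, 1]; 1 iff the traces are identical."""
    D = cdtw_distance(a, b, w_percent)
    L = max(np.asarray(a).size, np.asarray(b).size)
    return 1.0 - D / (D + L)


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    w_percent: float = 20.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    shuffle: str = "both",
) -> float:
    """Permutation p-value for the observed SI.

    Each permutation shuffles the sample order of both series (or only the
    second with ``shuffle="one"``) and recomputes SI; the p-value is the
    plain proportion of permutations with SI >= the observed value (the
    smallest reportable p is 1/n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if shuffle not in ("both", "one"):
        raise ValueError("shuffle must be 'both' or 'one'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    si_obs = similarity_index(a, b, w_percent)
    count = 0
    for _ in range(n_perm):
        ap = rng.permutation(a) if shuffle == "both" else a
        bp = rng.permutation(b)
        if similarity_index(ap, bp, w_percent) >= si_obs - 1e-12:
            count += 1
    # plain proportion, floored at the test's resolution of 1/n_perm
    return max(count, 1) / n_perm


REGION_NAMES = ("pre_sticking", "sticking", "post_sticking")


def compare_traces(
    experimental: VelocityTrace,
    simulated: VelocityTrace,
    w_percent: float = 20.0,
    n_resample: int = 101,
    n_perm: int = 1000,
    seed: int = 0,
    shuffle: str = "both",
) -> SimilarityResult:
    """Full region-wise cDTW pipeline between two velocity traces.

    Each trace is segmented by its *own* anchors; corresponding regions are
    resampled to ``n_resample`` points, amplitude-scaled by the
    experimental trace's global maximum, and scored with SI and a
    permutation p-value.  A ``"global"`` entry compares the whole traces.
    """
    anchors_a = segment_regions(experimental)
    anchors_b = segment_regions(simulated)
    scale = float(np.max(np.abs(experimental.values)))
    if scale == 0:
        raise ValueError("experimental trace is identically zero")
    rng = np.random.default_rng(seed)
    regions: dict[str, RegionScore] = {}

    def score(seg_a: VelocityTrace, seg_b: VelocityTrace) -> RegionScore:
        ra = resample_normalize(seg_a, n_resample, scale=scale)
        rb = resample_normalize(seg_b, n_resample, scale=scale)
        D = cdtw_distance(ra.values, rb.values, w_percent)
        SI = 1.0 - D / (D + n_resample)
        p = permutation_test(ra.values, rb.values, w_percent, n_perm, rng, shuffle) if n_perm else None
        return RegionScore(SI=SI, D=D, p=p)

    for name, (ia, ib) in zip(
        REGION_NAMES,
        [(anchors_a[:2], anchors_b[:2]), (anchors_a[1:3], anchors_b[1:3]), (anchors_a[2:], anchors_b[2:])],
    ):
        seg_a = _slice(experimental, *ia)
        seg_b = _slice(simulated, *ib)
        regions[name] = score(seg_a, seg_b)
    regions["global"] = score(experimental, simulated)
    return SimilarityResult(
        regions=regions, anchors_a=anchors_a, anchors_b=anchors_b,
        w_percent=w_percent, n_resample=n_resample,
    )


def _slice(trace: VelocityTrace, i: int, j: int) -> VelocityTrace:
    if j - i + 1 < 2:
        raise ValueError("region too short")
    vals = trace.values[i : j + 1]
    axis = trace.axis[i : j + 1]
    if vals.size < 10:  # VelocityTrace requires >= 10 samples; upsample short regions
        fine = np.linspace(axis[0], axis[-1], 10)
        vals = np.interp(fine, axis, vals)
        axis = fine
    return VelocityTrace(values=vals, axis=axis, label=trace.label)
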