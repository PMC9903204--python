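"""Ladder calibration, MNase peak sizing and repeat-length estimation.

Partial micrococcal-nuclease digestion of chromatin yields DNA fragments
at integer multiples of the nucleosomal repeat length (NRL: core plus
linker DNA per nucleosome). On a gel, fragment size is read off a
standard curve built from the flanking ladder lanes — piecewise linear
in (rf, log10 size), the usual semi-log electrophoresis approximation —
and the NRL is estimated as mean ± s.d. of size_n / n over digestion
products n = 2..7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from chromassay.gel_profiles import (
    GelImage,
    LaneProfile,
    extract_lane,
    subtract_background,
)

__all__ = [
    "StandardCurve",
    "FragmentPeaks",
    "NRLEstimate",
    "fit_ladder",
    "detect_peaks",
    "size_peaks",
    "estimate_nrl",
    "calibrate_from_image",
    "analyze_mnase_gel",
]


@dataclass(frozen=True)
class StandardCurve:
    """Piecewise log-linear size calibration from flanking ladders.

    ``bands`` holds (size bp, rf) pairs where each rf is the mean
    migration of that band on the two flanks. Interpolation is linear in
    (rf, log10 size); queries outside the ladder range are linearly
    extrapolated from the end segments and flagged.
    """

    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bands = tuple(sorted(((float(s), float(r)) for s, r in self.bands), key=lambda b: b[1]))
        if len(bands) < 2:
            raise ValueError("need at least 2 ladder bands")
        sizes = [s for s, _ in bands]
        rfs = [r for _, r in bands]
        if any(np.diff(rfs) <= 0) or any(np.diff(sizes) >= 0):
            raise ValueError("rf must increase strictly as size decreases")
        object.__setattr__(self, "bands", bands)

    @property
    def rf_range(self) -> tuple[float, float]:
        return self.bands[0][1], self.bands[-1][1]

    def size_at(self, rf) -> np.ndarray:
        """Interpolated fragment size (bp) at the given rf values."""
        rf = np.atleast_1d(np.asarray(rf, dtype=float))
        rfs = np.array([r for _, r in self.bands])
        logs = np.log10([s for s, _ in self.bands])
        # linear extrapolation beyond the ladder from the end segments
        out = np.interp(rf, rfs, logs)
        below, above = rf < rfs[0], rf > rfs[-1]
        if below.any():
            slope = (logs[1] - logs[0]) / (rfs[1] - rfs[0])
            out[below] = logs[0] + slope * (rf[below] - rfs[0])
        if above.any():
            slope = (logs[-1] - logs[-2]) / (rfs[-1] - rfs[-2])
            out[above] = logs[-1] + slope * (rf[above] - rfs[-1])
        return 10.0**out

    def is_extrapolated(self, rf) -> np.ndarray:
        rf = np.atleast_1d(np.asarray(rf, dtype=float))
        lo, hi = self.rf_range
        return (rf < lo) | (rf > hi)


@dataclass(frozen=True)
class FragmentPeaks:
    """Sized digestion peaks with assigned fragment orders.

    Order 1 is the mononucleosome (largest rf, smallest size); orders
    ascend with size.
    """

    peak_rfs: tuple[float, ...]
    sizes: tuple[float, ...]
    orders: tuple[int, ...]
    extrapolated: tuple[bool, ...]

    def size_of(self, order: int) -> float:
        try:
            return self.sizes[self.orders.index(order)]
        except ValueError:
            raise KeyError(f"fragment order {order} not detected") from None


@dataclass(frozen=True)
class NRLEstimate:
    """Nucleosomal repeat length as mean ± s.d. of size_n/n, n = 2..7."""

    mean: float
    sd: float
    per_fragment: tuple[tuple[int, float], ...]


def fit_ladder(left_flank, right_flank) -> StandardCurve:
    """Standard curve from the mean migration of the two flanking
    ladder lanes.

    Both flanks must carry the same band sizes; per size the rf is
    averaged, so a symmetric gel tilt (flanks offset by ±δ) cancels.
    """
    left = {float(s): float(r) for s, r in left_flank}
    right = {float(s): float(r) for s, r in right_flank}
    if set(left) != set(right):
        raise ValueError("flanking ladders carry different size lists")
    if len(left) < 2:
        raise ValueError("need at least 2 ladder bands")
    bands = tuple((s, 0.5 * (left[s] + right[s])) for s in sorted(left, reverse=True))
    return StandardCurve(bands=bands)


def detect_peaks(
    profile: LaneProfile,
    min_prominence: float | None = None,
    smooth_window: int = 5,
) -> list[float]:
    """Band positions: local maxima of the moving-average-smoothed lane
    profile with prominence >= ``min_prominence`` (default 5% of the
    profile range), ordered by increasing rf."""
    if not profile.background_corrected:
        raise ValueError("profile must be background-corrected first")
    y = profile.intensity
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        y = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="same")[
            pad : pad + y.size
        ]
    if min_prominence is None:
        min_prominence = 0.05 * float(y.max() - y.min())
    if y.max() == y.min():
        return []
    idx, _ = find_peaks(y, prominence=min_prominence)
    return [float(profile.rf[i]) for i in sorted(idx)]


def size_peaks(peaks, curve: StandardCurve) -> FragmentPeaks:
    """Interpolate peak sizes from the standard curve and assign
    fragment orders 1..k starting at the largest rf (smallest
    fragment). Peaks outside the ladder range are flagged
    extrapolated."""
    rfs = sorted(float(p) for p in peaks)
    if not rfs:
        raise ValueError("no peaks to size")
    sizes = curve.size_at(rfs)
    flagged = curve.is_extrapolated(rfs)
    if np.any(np.diff(sizes) >= 0):
        raise ValueError("interpolated sizes not monotone in rf; orders ambiguous")
    order_by_rf = list(range(len(rfs), 0, -1))  # largest rf -> order 1
    return FragmentPeaks(
        peak_rfs=tuple(rfs),
        sizes=tuple(float(s) for s in sizes),
        orders=tuple(order_by_rf),
        extrapolated=tuple(bool(f) for f in flagged),
    )


def estimate_nrl(frag: FragmentPeaks, method: str = "ratio") -> NRLEstimate:
    """Repeat length from digestion fragments 2-7.

    ``method='ratio'`` (default) averages size_n/n over n = 2..7 and
    reports mean ± sample s.d.; ``'regression'`` fits size_n = NRL*n
    through the origin by least squares; ``'diff'`` averages successive
    size differences. All require fragments 2-7 to be present.
    """
    needed = range(2, 8)
    missing = [n for n in needed if n not in frag.orders]
    if missing:
        raise ValueError(f"missing MNase fragments of order: {missing}")
    pairs = tuple((n, frag.size_of(n)) for n in needed)
    per_fragment = tuple((n, s / n) for n, s in pairs)
    if method == "ratio":
        vals = np.array([v for _, v in per_fragment])
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    elif method == "regression":
        ns = np.array([n for n, _ in pairs], dtype=float)
        ss = np.array([s for _, s in pairs])
        mean = float((ns @ ss) / (ns @ ns))
        resid_sd = float(np.std(ss - mean * ns, ddof=1))
        sd = resid_sd / float(np.sqrt(ns @ ns))
    elif method == "diff":
        ss = np.array([s for _, s in pairs])
        diffs = np.diff(ss)
        mean, sd = float(diffs.mean()), float(diffs.std(ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    if mean <= 0:
        raise ValueError("estimated repeat length must be positive")
    return NRLEstimate(mean=mean, sd=sd, per_fragment=per_fragment)


def _flank_bands(image: GelImage, lane_index: int, ladder_sizes,
                 min_prominence, smooth_window):
    profile = subtract_background(extract_lane(image, lane_index))
    rfs = detect_peaks(profile, min_prominence=min_prominence,
                       smooth_window=smooth_window)
    sizes = sorted(ladder_sizes, reverse=True)  # largest size = smallest rf
    if len(rfs) != len(sizes):
        raise ValueError(
            f"flank lane {lane_index}: found {len(rfs)} peaks for "
            f"{len(sizes)} ladder sizes"
        )
    return list(zip(sizes, rfs))


def calibrate_from_image(
    image: GelImage,
    ladder_sizes,
    min_prominence: float | None = None,
    smooth_window: int = 5,
) -> StandardCurve:
    """Standard curve from a gel whose first and last lanes carry the
    same ladder: detect each flank's band peaks, pair them with the
    given sizes (largest size at the smallest rf) and average the two
    flanks."""
    left = _flank_bands(image, 0, ladder_sizes, min_prominence, smooth_window)
    right = _flank_bands(image, image.n_lanes - 1, ladder_sizes,
                         min_prominence, smooth_window)
    return fit_ladder(left, right)


def analyze_mnase_gel(
    image: GelImage,
    ladder_sizes,
    lane_index: int = 1,
    min_prominence: float | None = None,
    smooth_window: int = 5,
    method: str = "ratio",
) -> NRLEstimate:
    """End-to-end repeat-length estimation for one MNase digest lane:
    ladder calibration from the flanks, peak detection and sizing in the
    sample lane, then the fragments-2-7 estimator."""
    curve = calibrate_from_image(image, ladder_sizes, min_prominence, smooth_window)
    profile = subtract_background(extract_lane(image, lane_index))
    peaks = detect_peaks(profile, min_prominence=min_prominence,
                         smooth_window=smooth_window)
    frag = size_peaks(peaks, curve)
    return estimate_nrl(frag, method=method)
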