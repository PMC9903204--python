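"""Gel lane densitometry and digestion-kinetics fitting.

A gel lane is reduced to a 1-D profile of staining intensity versus
relative migration (Rf: 0 at the well, 1 at the bottom of the crop).
After background subtraction, the loading-independent summary of a lane
is the Rf of median band intensity: the 50th percentile of the
cumulative signal accumulated from the gel bottom. Plotting this median
Rf against restriction-digestion time and fitting a saturating
log-normal curve quantifies how fast a nucleosomal array is cut, i.e.
how accessible its linker DNA is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import norm

__all__ = [
    "GelImage",
    "LaneProfile",
    "CumulativeProfile",
    "DigestionTimecourse",
    "extract_lane",
    "subtract_background",
    "cumulative_from_bottom",
    "median_rf",
    "fit_digestion",
    "lognormal_rf",
]


@dataclass(frozen=True)
class GelImage:
    """A grayscale gel image with known lane boundaries.

    Parameters
    ----------
    intensity
        2-D non-negative array, wells at the top (row 0) unless
        ``wells_at_top`` is False.
    lane_bounds
        Column intervals ``(start, stop)`` (half-open) for each lane,
        disjoint and within the image width.
    wells_at_top
        Orientation flag; images loaded upside down are flipped on
        construction of profiles.
    """

    intensity: np.ndarray
    lane_bounds: tuple[tuple[int, int], ...]
    wells_at_top: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise ValueError("gel image must be 2-D")
        if np.any(arr < 0):
            raise ValueError("gel image intensities must be non-negative")
        object.__setattr__(self, "intensity", arr)
        bounds = tuple((int(a), int(b)) for a, b in self.lane_bounds)
        prev_stop = 0
        for a, b in sorted(bounds):
            if a < prev_stop or b <= a or b > arr.shape[1]:
                raise ValueError(
                    "lane bounds must be disjoint, non-empty and inside the image"
                )
            prev_stop = b
        object.__setattr__(self, "lane_bounds", bounds)

    @property
    def n_lanes(self) -> int:
        return len(self.lane_bounds)


@dataclass(frozen=True)
class LaneProfile:
    """Row-summed intensity of one lane versus relative migration."""

    rf: np.ndarray
    intensity: np.ndarray
    background_corrected: bool = False

    def __post_init__(self) -> None:
        rf = np.asarray(self.rf, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if rf.shape != inten.shape or rf.ndim != 1:
            raise ValueError("rf and intensity must be 1-D vectors of equal length")
        if rf.size < 2 or np.any(np.diff(rf) <= 0):
            raise ValueError("rf must be strictly increasing with >= 2 samples")
        if self.background_corrected and np.any(inten < 0):
            raise ValueError("corrected profile must be non-negative")
        object.__setattr__(self, "rf", rf)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class CumulativeProfile:
    """Fraction of total lane signal at migration >= rf."""

    rf: np.ndarray
    cum: np.ndarray

    def __post_init__(self) -> None:
        rf = np.asarray(self.rf, dtype=float)
        cum = np.asarray(self.cum, dtype=float)
        if rf.shape != cum.shape or rf.ndim != 1:
            raise ValueError("rf and cum must be 1-D vectors of equal length")
        if np.any(np.diff(cum) > 1e-12):
            raise ValueError("cumulative signal must be non-increasing in rf")
        object.__setattr__(self, "rf", rf)
        object.__setattr__(self, "cum", cum)


@dataclass(frozen=True)
class DigestionTimecourse:
    """Median-Rf values versus digestion time, optionally with a fitted
    saturating log-normal curve ``rf(t) = baseline + amplitude * Phi((ln t - mu)/sigma)``."""

    times: np.ndarray
    median_rfs: np.ndarray
    fit: tuple[float, float, float, float] | None = None
    fit_rss: float | None = None
    shape: str = "cdf"
    converged: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.median_rfs, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and median_rfs must be 1-D and equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "median_rfs", y)

    def predict(self, t) -> np.ndarray:
        if self.fit is None:
            raise ValueError("no fitted parameters available")
        return lognormal_rf(np.asarray(t, dtype=float), *self.fit, shape=self.shape)

    def plot(self, ax=None):
        """Plot the observed series and, if available, the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.median_rfs, "o", label="observed")
        if self.fit is not None:
            tt = np.linspace(self.times.min(), self.times.max(), 200)
            ax.plot(tt, self.predict(tt), "-", label="log-normal fit")
        ax.set_xlabel("digestion time (min)")
        ax.set_ylabel("median Rf")
        ax.legend()
        return ax


def lognormal_rf(t, baseline, amplitude, mu, sigma, shape="cdf"):
    """Saturating (``shape='cdf'``) or transient (``shape='pdf'``)
    log-normal-in-time migration model; t = 0 maps to the baseline."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(baseline))
    pos = t > 0
    z = (np.log(t[pos]) - mu) / sigma
    if shape == "cdf":
        out[pos] = baseline + amplitude * norm.cdf(z)
    elif shape == "pdf":
        # peak-normalised so `amplitude` is the maximum excursion
        out[pos] = baseline + amplitude * np.exp(-0.5 * z**2)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return out


def extract_lane(
    image: GelImage, lane_index: int, crop: tuple[int, int] | None = None
) -> LaneProfile:
    """Sum one lane's pixels row-wise into an intensity-vs-Rf profile.

    ``crop`` gives the (top, bottom) rows of the region from just below
    the well to the smallest band; defaults to the full image height.
    Rf is normalised to the crop so the first row is 0 and the last 1.
    """
    if not 0 <= lane_index < image.n_lanes:
        raise IndexError(
            f"lane_index {lane_index} out of range for {image.n_lanes} lanes"
        )
    arr = image.intensity if image.wells_at_top else image.intensity[::-1]
    top, bottom = (0, arr.shape[0]) if crop is None else (int(crop[0]), int(crop[1]))
    if not 0 <= top < bottom <= arr.shape[0]:
        raise ValueError("crop rows outside image")
    a, b = image.lane_bounds[lane_index]
    block = arr[top:bottom, a:b]
    if block.size == 0:
        raise ValueError("empty lane interval")
    intensity = block.sum(axis=1)
    rf = np.linspace(0.0, 1.0, intensity.size)
    return LaneProfile(rf=rf, intensity=intensity, background_corrected=False)


def subtract_background(
    profile: LaneProfile, background_rf: float = 0.97
) -> LaneProfile:
    """Subtract the mean intensity of the deep-gel region (Rf >= 0.97 by
    default), clipping negatives to zero."""
    if profile.background_corrected:
        raise ValueError("profile is already background-corrected")
    region = profile.rf >= background_rf
    if not region.any():
        raise ValueError(f"no samples at rf >= {background_rf}")
    bg = profile.intensity[region].mean()
    corrected = np.clip(profile.intensity - bg, 0.0, None)
    return replace(profile, intensity=corrected, background_corrected=True)


def cumulative_from_bottom(profile: LaneProfile) -> CumulativeProfile:
    """Cumulative signal accumulated from the gel bottom, normalised to
    the lane total (removes lane-loading differences)."""
    if not profile.background_corrected:
        raise ValueError("profile must be background-corrected first")
    total = profile.intensity.sum()
    if total <= 0:
        raise ValueError("zero total signal in lane")
    # suffix sum: fraction of signal at migration >= rf_k
    cum = np.cumsum(profile.intensity[::-1])[::-1] / total
    return CumulativeProfile(rf=profile.rf, cum=cum)


def median_rf(cumprofile: CumulativeProfile) -> float:
    """Rf of median band intensity: the smallest Rf at which the
    bottom-up cumulative signal has fallen to 0.5, linearly interpolated
    between the bracketing samples."""
    rf, cum = cumprofile.rf, cumprofile.cum
    below = np.nonzero(cum <= 0.5)[0]
    if below.size == 0:
        return float(rf[-1])
    k = below[0]
    if k == 0 or cum[k] == 0.5:
        return float(rf[k])
    c0, c1 = cum[k - 1], cum[k]
    frac = (c0 - 0.5) / (c0 - c1)
    return float(rf[k - 1] + frac * (rf[k] - rf[k - 1]))


def _fit_once(times, rfs, p0, bounds, shape):
    popt, _ = curve_fit(
        lambda t, b, a, m, s: lognormal_rf(t, b, a, m, s, shape=shape),
        times,
        rfs,
        p0=p0,
        bounds=bounds,
        maxfev=20000,
    )
    rss = float(np.sum((lognormal_rf(times, *popt, shape=shape) - rfs) ** 2))
    return tuple(float(p) for p in popt), rss


def fit_digestion(
    times, median_rfs, shape: str = "cdf", n_restarts: int = 8
) -> DigestionTimecourse:
    """Least-squares fit of the log-normal digestion model.

    The default ``shape='cdf'`` is monotone saturating,
    ``rf(t) = baseline + amplitude * Phi((ln t - mu)/sigma)``, which is
    the natural form for a median migration that only increases as
    fragments get smaller; a peak-normalised density shape is available
    for non-monotone series. Restarts perturb the initial guess; if no
    start converges the result carries ``fit=None`` and
    ``converged=False``.
    """
    tc = DigestionTimecourse(times=times, median_rfs=median_rfs, shape=shape)
    t, y = tc.times, tc.median_rfs
    if t.size < 4:
        raise ValueError("need at least 4 time points to fit 4 parameters")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("median Rf values must lie in [0, 1]")

    baseline0 = float(y[0])
    amp0 = float(y[-1] - y[0])
    pos_t = t[t > 0]
    mu0 = float(np.log(np.median(pos_t))) if pos_t.size else 0.0
    p0 = (baseline0, amp0 if abs(amp0) > 1e-6 else 1e-3, mu0, 0.5)
    # cdf shape is kept monotone non-decreasing by constraining amplitude >= 0
    lo = (0.0, 0.0 if shape == "cdf" else -1.0, -20.0, 1e-6)
    hi = (1.0, 1.0, 20.0, 20.0)
    p0 = tuple(np.clip(p0, lo, hi))

    rng = np.random.default_rng(0)
    best = None
    for k in range(n_restarts):
        trial = (
            p0
            if k == 0
            else tuple(
                np.clip(np.asarray(p0) + rng.normal(0, [0.05, 0.1, 1.0, 0.3]), lo, hi)
            )
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, rss = _fit_once(t, y, trial, (lo, hi), shape)
        except RuntimeError:
            continue
        if best is None or rss < best[1]:
            best = (popt, rss)
        if rss < 1e-16:
            break
    if best is None:
        return replace(tc, fit=None, fit_rss=None, converged=False)
    return replace(tc, fit=best[0], fit_rss=best[1], converged=True)
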