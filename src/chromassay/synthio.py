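"""Seeded synthetic inputs with ground truth for every assay.

Generators emulate the statistical structure the downstream analyses
assume: multi-lane gel images under the semi-log migration model
``rf = a - b*log10(size bp)`` with mass-weighted intercalating-dye
staining, MNase ladders at integer multiples of a nucleosomal repeat
length, digestion time courses whose median Rf follows a saturating
log-normal-in-time curve, melt curves as sums of sigmoidal transitions,
two-channel (DNA + ATAC-see) nuclei fields with controllable overlap,
and protein sequences with planted SPKK-family motifs.

All generators are deterministic given a :class:`SynthConfig` seed.
Noise is additive Gaussian clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import expit
from scipy.stats import norm

from chromassay.gel_profiles import DigestionTimecourse, GelImage
from chromassay.melt import MeltCurve

__all__ = [
    "SynthConfig",
    "GelSpec",
    "DEFAULT_LADDER",
    "default_migration_params",
    "make_gel",
    "make_mnase_ladder",
    "make_timecourse",
    "make_melt",
    "make_nuclei_field",
    "make_sequences",
]

#: 100 bp-style ladder used when none is given (bp).
DEFAULT_LADDER = (100, 200, 300, 400, 500, 700, 1000, 1500, 2000)

CORE_MOTIFS = ("SPKK", "SPKR", "SPRK", "SPRR")

# background alphabet excludes proline so the only S-P dinucleotides in a
# generated peptide are the planted ones (no accidental motifs, and no
# junction-made motifs when planting)
_BACKGROUND_AA = "ACDEFGHIKLMNQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    """Common generator knobs.

    seed
        RNG seed; identical seed and parameters give bit-identical output.
    noise_sd
        Additive Gaussian noise s.d. in intensity units (images,
        profiles) or in the output's own units (time courses).
    pixel_size
        Physical pixel size for images, µm/px.
    sampling
        Samples per lane (gels, time courses) or per °C (melt curves).
    """

    seed: int = 0
    noise_sd: float = 0.0
    pixel_size: float = 0.1
    sampling: float = 600

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling <= 0:
            raise ValueError("sampling must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_migration_params(
    sizes, rf_min: float = 0.08, rf_max: float = 0.92
) -> tuple[float, float]:
    """(a, b) of rf = a - b*log10(size) placing the given size range on
    [rf_min, rf_max]."""
    smin, smax = min(sizes), max(sizes)
    if smin <= 0:
        raise ValueError("sizes must be positive")
    if smin == smax:
        raise ValueError("need at least two distinct sizes")
    b = (rf_max - rf_min) / (math.log10(smax) - math.log10(smin))
    a = rf_max + b * math.log10(smin)
    return a, b


@dataclass(frozen=True)
class GelSpec:
    """Layout of a synthetic gel.

    lane_specs
        One band set per sample lane; each band is ``(size_bp,
        mass_fraction)`` and the fractions of a lane sum to 1.
    ladder_sizes
        Sizes of the flanking ladder lanes (first and last lane of the
        image), equal DNA mass per band.
    migration_params
        ``(a, b)`` of the semi-log migration model; defaults span the
        ladder across rf 0.05-0.95.
    band_width
        Gaussian s.d. of a band in rf units.
    """

    lane_specs: tuple[tuple[tuple[float, float], ...], ...]
    ladder_sizes: tuple[float, ...] = DEFAULT_LADDER
    migration_params: tuple[float, float] | None = None
    band_width: float = 0.008
    lane_width_px: int = 24
    gap_px: int = 6

    def __post_init__(self) -> None:
        lanes = tuple(tuple((float(s), float(f)) for s, f in lane) for lane in self.lane_specs)
        object.__setattr__(self, "lane_specs", lanes)
        object.__setattr__(self, "ladder_sizes", tuple(float(s) for s in self.ladder_sizes))
        for lane in lanes:
            if lane and abs(sum(f for _, f in lane) - 1.0) > 1e-9:
                raise ValueError("mass fractions per lane must sum to 1")
            if any(s <= 0 for s, _ in lane):
                raise ValueError("band sizes must be positive")
        if self.migration_params is None:
            object.__setattr__(
                self,
                "migration_params",
                default_migration_params(self.ladder_sizes, 0.05, 0.95),
            )

    def rf_of(self, size_bp: float) -> float:
        a, b = self.migration_params
        return a - b * math.log10(size_bp)


def _render_lane(rf_axis: np.ndarray, bands, band_width: float) -> np.ndarray:
    """Sum of Gaussians in rf; each band's integrated intensity is
    proportional to mass_fraction * size (mass-weighted staining)."""
    profile = np.zeros_like(rf_axis)
    step = rf_axis[1] - rf_axis[0]
    for rf0, weight in bands:
        dens = norm.pdf(rf_axis, loc=rf0, scale=band_width)
        profile += weight * dens * step
    return profile


def make_gel(spec: GelSpec, cfg: SynthConfig) -> GelImage:
    """Render a gel image: flanking ladder lanes plus one lane per band
    set in ``spec.lane_specs``.

    Each band is a Gaussian ridge in rf centred at ``a - b*log10(size)``
    whose integrated lane intensity is proportional to mass fraction
    times fragment size. Bands whose centre falls outside (0, 1) are
    rejected.
    """
    n_rows = int(cfg.sampling)
    rf_axis = np.linspace(0.0, 1.0, n_rows)
    # ladder masses balanced inversely to size (as commercial ladders
    # are) so every ladder band stains with equal brightness
    inv = np.array([1.0 / s for s in spec.ladder_sizes])
    ladder_masses = inv / inv.sum()

    def band_list(entries):
        out = []
        for size, frac in entries:
            rf0 = spec.rf_of(size)
            if not 0.0 < rf0 < 1.0:
                raise ValueError(
                    f"band of {size:g} bp migrates to rf {rf0:.3f}, outside (0, 1)"
                )
            out.append((rf0, frac * size))
        return out

    ladder = band_list(list(zip(spec.ladder_sizes, ladder_masses)))
    lanes = [ladder] + [band_list(lane) for lane in spec.lane_specs] + [ladder]

    w, g = spec.lane_width_px, spec.gap_px
    width = len(lanes) * w + (len(lanes) + 1) * g
    img = np.zeros((n_rows, width))
    bounds = []
    col = g
    for bands in lanes:
        img[:, col : col + w] = _render_lane(rf_axis, bands, spec.band_width)[:, None]
        bounds.append((col, col + w))
        col += w + g

    if cfg.noise_sd > 0:
        img = img + cfg.rng().normal(0.0, cfg.noise_sd, size=img.shape)
    return GelImage(intensity=np.clip(img, 0.0, None), lane_bounds=tuple(bounds))


def make_mnase_ladder(
    nrl: float,
    n_max: int = 8,
    decay: float = 0.7,
    cfg: SynthConfig = SynthConfig(),
    ladder_sizes=DEFAULT_LADDER,
    migration_params: tuple[float, float] | None = None,
    band_width: float = 0.008,
) -> GelImage:
    """Gel of a partial MNase digest: bands at ``n * nrl`` for
    n = 1..n_max with mass fractions proportional to ``decay**n``,
    between flanking ladder lanes.

    ``n_max >= 7`` is required because repeat-length estimation uses
    fragments 2-7 downstream.
    """
    if nrl <= 0:
        raise ValueError("nrl must be positive")
    if n_max < 7:
        raise ValueError("n_max must be >= 7 (fragments 2-7 needed downstream)")
    weights = np.array([decay**n for n in range(1, n_max + 1)])
    weights /= weights.sum()
    lane = tuple((n * nrl, w) for n, w in zip(range(1, n_max + 1), weights))
    all_sizes = list(ladder_sizes) + [n * nrl for n in range(1, n_max + 1)]
    if migration_params is None:
        migration_params = default_migration_params(all_sizes, 0.05, 0.95)
    spec = GelSpec(
        lane_specs=(lane,),
        ladder_sizes=tuple(ladder_sizes),
        migration_params=migration_params,
        band_width=band_width,
    )
    return make_gel(spec, cfg)


def make_timecourse(
    params: tuple[float, float, float, float],
    times,
    cfg: SynthConfig = SynthConfig(),
) -> DigestionTimecourse:
    """Median-Rf digestion series from the saturating log-normal model
    ``rf(t) = baseline + amplitude * Phi((ln t - mu)/sigma)`` (baseline
    at t = 0) plus Gaussian noise."""
    baseline, amplitude, mu, sigma = (float(p) for p in params)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (0.0 <= baseline <= 1.0 and 0.0 <= baseline + amplitude <= 1.0):
        raise ValueError("baseline and baseline+amplitude must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    y = np.full(t.shape, baseline)
    pos = t > 0
    y[pos] = baseline + amplitude * norm.cdf((np.log(t[pos]) - mu) / sigma)
    if cfg.noise_sd > 0:
        y = np.clip(y + cfg.rng().normal(0.0, cfg.noise_sd, size=y.shape), 0.0, 1.0)
    return DigestionTimecourse(times=t, median_rfs=y)


def make_melt(
    transitions,
    t_range: tuple[float, float],
    cfg: SynthConfig = SynthConfig(sampling=10),
    baseline: float = 100.0,
) -> MeltCurve:
    """Melt curve as a sum of logistic steps plus baseline and noise.

    ``transitions`` is a list of ``(Tm °C, width °C, amplitude)``;
    fluorescence is ``baseline + sum(amp * logistic((T - Tm)/width))``.
    ``cfg.sampling`` is samples per °C (10 gives a 0.1 °C step).
    """
    transitions = [(float(tm), float(w), float(a)) for tm, w, a in transitions]
    if not transitions:
        raise ValueError("at least one transition is required")
    lo, hi = float(t_range[0]), float(t_range[1])
    for tm, w, _ in transitions:
        if w <= 0:
            raise ValueError("transition widths must be positive")
        if not lo <= tm <= hi:
            raise ValueError(f"Tm {tm} outside temperature range {t_range}")
    n = int(round((hi - lo) * cfg.sampling)) + 1
    temp = np.linspace(lo, hi, n)
    fluor = np.full(n, baseline)
    for tm, w, a in transitions:
        fluor = fluor + a * expit((temp - tm) / w)
    if cfg.noise_sd > 0:
        fluor = fluor + cfg.rng().normal(0.0, cfg.noise_sd, size=n)
    return MeltCurve(temperature=temp, fluorescence=fluor)


def _draw_ellipse(canvas: np.ndarray, cy, cx, ry, rx, theta, value) -> int:
    """Rasterise a filled rotated ellipse additively; returns pixel count."""
    h, w = canvas.shape
    r = int(math.ceil(max(ry, rx))) + 2
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    canvas[y0:y1, x0:x1][inside] = value
    return int(inside.sum())


def make_nuclei_field(
    n: int,
    area_dist: tuple[float, float] = (600.0, 60.0),
    overlap_pairs: int = 0,
    atac_positive_fraction: float = 1.0,
    cfg: SynthConfig = SynthConfig(),
    shape: tuple[int, int] = (512, 512),
    foreground: float = 180.0,
    background: float = 20.0,
    max_tries: int = 2000,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Two-channel field of elliptical nuclei on a dark background.

    Returns ``({'dna': image, 'atac': image}, truth)`` where the truth
    table lists one row per nucleus: centre, drawn pixel area, and
    whether it carries ATAC-see signal. ``overlap_pairs`` pairs are
    placed with overlapping footprints (so naive connected-component
    counting undercounts by that many); all other nuclei are disjoint.
    A field too small to place ``n`` nuclei raises after bounded
    retries.
    """
    if n < 0 or overlap_pairs < 0 or 2 * overlap_pairs > n:
        raise ValueError("need n >= 0 and 2*overlap_pairs <= n")
    mean_a, sd_a = area_dist
    if mean_a <= 0:
        raise ValueError("mean area must be positive")
    rng = cfg.rng()
    h, w = shape
    dna = np.full(shape, float(background))
    atac = np.full(shape, float(background))

    n_atac = int(round(atac_positive_fraction * n))
    atac_flags = np.zeros(n, dtype=bool)
    atac_flags[:n_atac] = True
    rng.shuffle(atac_flags)

    placed = []  # (cy, cx, reach)
    rows = []

    def sample_geom():
        area = max(rng.normal(mean_a, sd_a), 9.0)
        aspect = rng.uniform(0.7, 1.0)
        ry = math.sqrt(area * aspect / math.pi)
        rx = math.sqrt(area / (aspect * math.pi))
        return area, ry, rx, rng.uniform(0, math.pi)

    def place_one(anchor=None, overlap=False):
        area, ry, rx, theta = sample_geom()
        reach = max(ry, rx)
        for _ in range(max_tries):
            if anchor is None:
                cy = rng.uniform(reach + 2, h - reach - 2)
                cx = rng.uniform(reach + 2, w - reach - 2)
            else:
                acy, acx, areach = anchor
                d = rng.uniform(0.6, 0.9) * (reach + areach)
                ang = rng.uniform(0, 2 * math.pi)
                cy, cx = acy + d * math.sin(ang), acx + d * math.cos(ang)
                if not (reach + 2 <= cy <= h - reach - 2 and reach + 2 <= cx <= w - reach - 2):
                    continue
            ok = True
            for py, px, pr in placed:
                sep = math.hypot(cy - py, cx - px)
                if anchor is not None and (py, px, pr) == anchor:
                    continue  # intended overlap partner
                if sep < reach + pr + 3:
                    ok = False
                    break
            if ok:
                return cy, cx, ry, rx, theta, reach
        raise RuntimeError(
            f"could not place nucleus after {max_tries} tries; field too crowded"
        )

    order = []
    for p in range(overlap_pairs):
        first = place_one()
        placed.append((first[0], first[1], first[5]))
        order.append(first)
        partner = place_one(anchor=placed[-1])
        placed.append((partner[0], partner[1], partner[5]))
        order.append(partner)
    for _ in range(n - 2 * overlap_pairs):
        obj = place_one()
        placed.append((obj[0], obj[1], obj[5]))
        order.append(obj)

    for i, (cy, cx, ry, rx, theta, _) in enumerate(order):
        area_px = _draw_ellipse(dna, cy, cx, ry, rx, theta, foreground)
        if atac_flags[i]:
            _draw_ellipse(atac, cy, cx, ry, rx, theta, foreground)
        rows.append(
            {
                "nucleus": i,
                "cy": cy,
                "cx": cx,
                "area_px": area_px,
                "area_um2": area_px * cfg.pixel_size**2,
                "atac_positive": bool(atac_flags[i]),
            }
        )

    if cfg.noise_sd > 0:
        dna = dna + rng.normal(0.0, cfg.noise_sd, size=shape)
        atac = atac + rng.normal(0.0, cfg.noise_sd, size=shape)
    images = {"dna": np.clip(dna, 0.0, None), "atac": np.clip(atac, 0.0, None)}
    truth = pd.DataFrame(
        rows,
        columns=["nucleus", "cy", "cx", "area_px", "area_um2", "atac_positive"],
    )
    return images, truth


def make_sequences(
    motifs_per_seq,
    length: int = 120,
    cfg: SynthConfig = SynthConfig(),
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random peptides with planted, non-overlapping SPKK-family motifs.

    One record per entry of ``motifs_per_seq``, each carrying exactly
    that many motif instances drawn from SPKK/SPKR/SPRK/SPRR. The
    background alphabet omits proline, so the background (and every
    motif junction) is guaranteed motif-free. Returns Biopython records
    and a truth table of (seq_id, start [1-based], motif).
    """
    counts = [int(c) for c in motifs_per_seq]
    if any(c < 0 for c in counts):
        raise ValueError("motif counts must be >= 0")
    rng = cfg.rng()
    records, rows = [], []
    for i, count in enumerate(counts):
        if 4 * count > length:
            raise ValueError(
                f"sequence of length {length} too short for {count} motifs"
            )
        seq = list(rng.choice(list(_BACKGROUND_AA), size=length))
        # choose non-overlapping 4-residue slots left to right
        free = length - 4 * count
        gaps = rng.multinomial(free, np.ones(count + 1) / (count + 1)) if count else []
        pos = 0
        seq_id = f"synthetic_{i}"
        for k in range(count):
            pos += gaps[k]
            motif = CORE_MOTIFS[rng.integers(len(CORE_MOTIFS))]
            seq[pos : pos + 4] = motif
            rows.append({"seq_id": seq_id, "start": pos + 1, "motif": motif})
            pos += 4
        records.append(
            SeqRecord(Seq("".join(seq)), id=seq_id, description=f"{count} planted motifs")
        )
    truth = pd.DataFrame(rows, columns=["seq_id", "start", "motif"])
    return records, truth
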