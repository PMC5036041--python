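"""Multi-parameter morphometric description of segmented colonies.

Each colony is described by a 120-parameter panel organized in three
families:

* ``volume``  -- size and intensity measures (areas, perimeters, axis
  lengths, interior/rim/outer-band intensity statistics);
* ``shape``   -- dimensionless form descriptors (circularity, solidity,
  eccentricity, Hu moments, radial-distribution shape, erosion
  profiles);
* ``frequency`` -- boundary-waviness descriptors from the colony
  outline's radius series: Fourier harmonic magnitudes and band
  energies, curvature statistics, fibrous-point counts, multiscale
  roughness.

The outline is sampled as 256 equal-angle radii about the centroid
(outer envelope per angular bin).  Equal-angle sampling makes every
boundary descriptor exactly invariant under a half-turn raster
rotation, which underwrites the plate-rotation reproducibility check.
The low-order Fourier band is the outline-smoothness descriptor and
the high-order band plus curvature-peak counts form the fibrous-points
descriptor.

Two selection filters reduce the panel to the analysis set: a greedy
correlation filter (drop any parameter whose |Pearson r| with an
already-kept parameter exceeds 0.98, the earliest kept parameter being
the representative) followed by a coefficient-of-variation filter
(drop parameters with 100*SD/|mean| > 30).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.measure import find_contours, perimeter_crofton, regionprops

from .segment import ColonyObject

__all__ = [
    "MorphProfile",
    "FilterReport",
    "compute_profile",
    "profiles_to_frame",
    "frame_to_profiles",
    "filter_correlated",
    "filter_high_cv",
    "apply_filters",
    "PANEL_NAMES",
    "PANEL_FAMILIES",
    "N_BOUNDARY_SAMPLES",
]

N_BOUNDARY_SAMPLES = 256
_RIM_WIDTHS = (5, 10, 20)
_CORE_WIDTHS = (10, 20)
_OUTER_WIDTHS = (5, 10)
_ROUGHNESS_WINDOWS = (8, 16, 32)
_CURVATURE_THRESHOLDS = (3.0, 5.0, 8.0)
_RADIUS_PROMINENCES = (0.02, 0.05, 0.10)
_FOURIER_SINGLE_K = (2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 16, 24, 32)
_EPS = 1e-12


@dataclass
class MorphProfile:
    """One colony's named morphometric vector with family tags."""

    colony_id: str
    values: dict[str, float]
    family_of: dict[str, str]
    border: bool = False
    line_id: str = ""
    true_class: str = ""

    def vector(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else list(self.values)
        missing = [n for n in names if n not in self.values]
        if missing:
            raise KeyError(f"profile {self.colony_id} missing parameters: {missing}")
        return np.array([self.values[n] for n in names], dtype=float)


@dataclass
class FilterReport:
    """Outcome of a parameter-selection pass."""

    kept: list[str]
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_high_cv: list[tuple[str, float]] = field(default_factory=list)

    @property
    def dropped(self) -> list[str]:
        return [d for d, _, _ in self.dropped_correlated] + [
            d for d, _ in self.dropped_high_cv
        ]


# ---------------------------------------------------------------------------
# Boundary analysis
# ---------------------------------------------------------------------------

def _radius_series(mask: np.ndarray, centroid: tuple[float, float]) -> np.ndarray:
    """256 equal-angle outer-envelope radii of the mask outline."""
    contours = find_contours(np.pad(mask, 1, mode="constant").astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask has no boundary")
    contour = max(contours, key=len) - 1.0  # undo the pad offset
    dy = contour[:, 0] - centroid[0]
    dx = contour[:, 1] - centroid[1]
    theta = np.arctan2(dy, dx)  # [-pi, pi)
    rho = np.hypot(dy, dx)
    n = N_BOUNDARY_SAMPLES
    bins = np.floor((theta + np.pi) / (2 * np.pi) * n).astype(int)
    bins = np.clip(bins, 0, n - 1)
    radii = np.full(n, -np.inf)
    np.maximum.at(radii, bins, rho)
    radii[np.isneginf(radii)] = np.nan
    if np.isnan(radii).any():
        # Circular linear interpolation across empty angular bins.
        idx = np.arange(n)
        good = ~np.isnan(radii)
        if good.sum() < 3:
            raise ValueError("degenerate boundary")
        radii = np.interp(
            idx, idx[good], radii[good], period=n
        )
    return radii


def _circular_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    padded = np.concatenate([x[-window:], x, x[:window]])
    sm = np.convolve(padded, kernel, mode="same")
    return sm[window:-window]


def _wrapped_peaks(x: np.ndarray, height: float | None, prominence: float | None) -> int:
    """Count peaks of a circular series (duplicate-free across the seam)."""
    n = len(x)
    tiled = np.concatenate([x, x, x])
    peaks, _ = find_peaks(tiled, height=height, prominence=prominence)
    inner = peaks[(peaks >= n) & (peaks < 2 * n)]
    return int(len(inner))


def _skew(x: np.ndarray) -> float:
    sd = x.std()
    if sd < _EPS:
        return 0.0
    return float(np.mean(((x - x.mean()) / sd) ** 3))


def _kurt(x: np.ndarray) -> float:
    sd = x.std()
    if sd < _EPS:
        return 0.0
    return float(np.mean(((x - x.mean()) / sd) ** 4) - 3.0)


def _boundary_descriptors(radii: np.ndarray) -> dict[str, float]:
    n = len(radii)
    r_mean = float(radii.mean())
    d: dict[str, float] = {}
    # Fourier magnitudes normalized by the mean radius.
    spec = np.fft.rfft(radii) / n
    mags = 2.0 * np.abs(spec) / max(r_mean, _EPS)
    kmax = len(mags) - 1
    for k in _FOURIER_SINGLE_K:
        d[f"fourier_mag_k{k}"] = float(mags[k]) if k <= kmax else 0.0
    power = mags**2

    def band(k0: int, k1: int) -> float:
        k1 = min(k1, kmax)
        if k0 > k1:
            return 0.0
        return float(np.sqrt(power[k0 : k1 + 1].sum()))

    d["fourier_low_band"] = band(2, 4)      # outline-smoothness complement
    d["fourier_mid_band"] = band(5, 8)
    d["fourier_high_band"] = band(9, 32)    # fibrous-points band
    d["fourier_vhigh_band"] = band(33, 128)
    d["fourier_total"] = band(2, 128)
    d["fourier_high_low_ratio"] = d["fourier_high_band"] / (
        d["fourier_low_band"] + _EPS
    )
    ks = np.arange(2, min(128, kmax) + 1)
    pw = power[2 : min(128, kmax) + 1]
    total = pw.sum()
    if total < _EPS:
        d["spectral_centroid"] = 0.0
        d["spectral_bandwidth"] = 0.0
        d["spectral_entropy"] = 0.0
    else:
        p = pw / total
        centroid = float((ks * p).sum())
        d["spectral_centroid"] = centroid
        d["spectral_bandwidth"] = float(np.sqrt(((ks - centroid) ** 2 * p).sum()))
        nz = p[p > _EPS]
        d["spectral_entropy"] = float(-(nz * np.log(nz)).sum())

    # Curvature of the polar curve, normalized by the mean radius.  The
    # series is lightly smoothed first (circular moving average, 5
    # samples) so pixel-level discretization jitter does not dominate
    # the second derivative; circular smoothing preserves the exact
    # half-turn-rotation invariance.
    dtheta = 2 * np.pi / n
    rs = _circular_moving_average(radii, 5)
    dr = (np.roll(rs, -1) - np.roll(rs, 1)) / (2 * dtheta)
    d2r = (np.roll(rs, -1) - 2 * rs + np.roll(rs, 1)) / dtheta**2
    denom = (rs**2 + dr**2) ** 1.5
    kappa = (rs**2 + 2 * dr**2 - rs * d2r) / np.maximum(denom, _EPS)
    kn = kappa * r_mean  # 1.0 everywhere for a circle
    d["curvature_mean"] = float(kn.mean())
    d["curvature_sd"] = float(kn.std())
    d["curvature_max"] = float(kn.max())
    d["curvature_min"] = float(kn.min())
    d["curvature_skew"] = _skew(kn)
    d["curvature_abs_mean"] = float(np.abs(kn).mean())
    for thr in _CURVATURE_THRESHOLDS:
        d[f"fibrous_points_t{thr:g}"] = float(
            _wrapped_peaks(kn, height=thr, prominence=None)
        )
    excess = np.clip(kn - 1.0, 0.0, None)
    d["fibrous_score"] = float(excess.mean())
    rel = (radii - r_mean) / max(r_mean, _EPS)
    for prom in _RADIUS_PROMINENCES:
        d[f"radius_peaks_p{prom:g}"] = float(
            _wrapped_peaks(rel, height=None, prominence=prom)
        )
    for w in _ROUGHNESS_WINDOWS:
        resid = radii - _circular_moving_average(radii, w)
        d[f"roughness_s{w}"] = float(resid.std() / max(r_mean, _EPS))
    d["roughness_ratio_8_32"] = d["roughness_s8"] / (d["roughness_s32"] + _EPS)
    step = np.diff(radii, append=radii[:1]) / max(r_mean, _EPS)
    d["dr_abs_mean"] = float(np.abs(step).mean())
    d["dr_sd"] = float(step.std())
    signs = np.sign(step)
    signs = signs[signs != 0]
    d["dr_zero_crossings"] = float(
        np.count_nonzero(signs != np.roll(signs, 1))
    ) if len(signs) else 0.0
    step2 = np.diff(step, append=step[:1])
    d["d2r_abs_mean"] = float(np.abs(step2).mean())
    d["bending_energy"] = float((kn**2).mean())
    # Radial-distribution shape descriptors (consumed by the shape family).
    d["_radius_mean"] = r_mean
    d["_radius_max"] = float(radii.max())
    d["_radius_min"] = float(radii.min())
    d["_radius_cv"] = float(radii.std() / max(r_mean, _EPS))
    d["_radius_skew"] = _skew(radii)
    d["_radius_kurt"] = _kurt(radii)
    q75, q25 = np.percentile(radii, [75, 25])
    d["_radius_iqr_norm"] = float((q75 - q25) / max(r_mean, _EPS))
    d["_circular_variance"] = float(np.mean((radii - r_mean) ** 2) / max(r_mean, _EPS) ** 2)
    return d


_FREQUENCY_NAMES = (
    tuple(f"fourier_mag_k{k}" for k in _FOURIER_SINGLE_K[:8])
    + (
        "fourier_low_band",
        "fourier_mid_band",
        "fourier_high_band",
        "fourier_vhigh_band",
        "fourier_total",
        "fourier_high_low_ratio",
        "spectral_centroid",
        "spectral_bandwidth",
        "spectral_entropy",
        "curvature_mean",
        "curvature_sd",
        "curvature_max",
        "curvature_min",
        "curvature_skew",
        "curvature_abs_mean",
    )
    + tuple(f"fibrous_points_t{t:g}" for t in _CURVATURE_THRESHOLDS)
    + ("fibrous_score",)
    + tuple(f"radius_peaks_p{p:g}" for p in _RADIUS_PROMINENCES)
    + tuple(f"roughness_s{w}" for w in _ROUGHNESS_WINDOWS)
    + (
        "roughness_ratio_8_32",
        "dr_abs_mean",
        "dr_sd",
        "dr_zero_crossings",
        "d2r_abs_mean",
        "bending_energy",
    )
    + tuple(f"fourier_mag_k{k}" for k in _FOURIER_SINGLE_K[8:])
)

_VOLUME_NAMES = (
    "area_px",
    "area_um2",
    "filled_area_px",
    "convex_area_px",
    "equiv_diameter_px",
    "equiv_diameter_um",
    "perimeter_px",
    "perimeter_um",
    "convex_perimeter_px",
    "major_axis_px",
    "minor_axis_px",
    "bbox_area_px",
    "feret_max_px",
    "radius_mean_px",
    "radius_max_px",
    "radius_min_px",
    "intensity_mean",
    "intensity_total",
    "intensity_sd",
    "intensity_min",
    "intensity_max",
    "intensity_median",
    "intensity_p10",
    "intensity_p25",
    "intensity_p75",
    "intensity_p90",
    "intensity_iqr",
    "rim_mean_w5",
    "rim_mean_w10",
    "rim_mean_w20",
    "rim_sd_w5",
    "rim_sd_w10",
    "rim_sd_w20",
    "core_mean_w10",
    "core_mean_w20",
    "core_sd_w10",
    "core_sd_w20",
    "outer_band_mean_w5",
    "outer_band_mean_w10",
    "rim_core_contrast_w10",
)

_SHAPE_NAMES = (
    "circularity",
    "solidity",
    "solidity_filled",
    "convex_deficiency",
    "eccentricity",
    "extent",
    "aspect_ratio",
    "elongation",
    "convexity",
    "compactness",
    "roundness_perimeter",
    "filled_ratio",
    "euler_number",
    "hu_moment_1",
    "hu_moment_2",
    "hu_moment_3",
    "hu_moment_4",
    "hu_moment_5",
    "hu_moment_6",
    "hu_moment_7",
    "radius_cv",
    "radius_skew",
    "radius_kurtosis",
    "radius_min_max_ratio",
    "radius_iqr_norm",
    "erosion_area_ratio_w5",
    "erosion_area_ratio_w10",
    "erosion_area_ratio_w20",
    "dilation_area_ratio_w5",
    "dilation_area_ratio_w10",
    "bbox_aspect",
    "extent_filled",
    "ellipse_area_ratio",
    "contour_complexity",
    "moment_dispersion",
    "circular_variance",
)

PANEL_NAMES: tuple[str, ...] = _VOLUME_NAMES + _SHAPE_NAMES + _FREQUENCY_NAMES
PANEL_FAMILIES: dict[str, str] = (
    {n: "volume" for n in _VOLUME_NAMES}
    | {n: "shape" for n in _SHAPE_NAMES}
    | {n: "frequency" for n in _FREQUENCY_NAMES}
)
assert len(PANEL_NAMES) == 120, len(PANEL_NAMES)
assert len(set(PANEL_NAMES)) == 120


def compute_profile(
    colony: ColonyObject,
    image: np.ndarray,
    um_per_px: float = 2.0,
    colony_id: str | None = None,
) -> MorphProfile:
    """Compute the full 120-parameter panel for one colony.

    Intensity statistics use the raw (unflattened) image.  Colonies
    touching the image border are computed normally but flagged via
    ``MorphProfile.border`` (border colonies are excluded from database
    construction by default).
    """
    mask_full = colony.mask
    if mask_full.shape != image.shape:
        raise ValueError("colony mask and image shapes differ")
    border = colony.touches_border()

    rows = np.any(mask_full, axis=1).nonzero()[0]
    cols = np.any(mask_full, axis=0).nonzero()[0]
    margin = max(_OUTER_WIDTHS) + 2
    r0 = max(rows[0] - margin, 0)
    r1 = min(rows[-1] + margin + 1, mask_full.shape[0])
    c0 = max(cols[0] - margin, 0)
    c1 = min(cols[-1] + margin + 1, mask_full.shape[1])
    mask = mask_full[r0:r1, c0:c1]
    img = image[r0:r1, c0:c1].astype(float)

    props = regionprops(mask.astype(np.uint8), intensity_image=img)[0]
    area = float(props.area)
    # Crofton (4-direction) perimeter: far less biased than pixel-edge
    # counting on smooth discretized outlines, and symmetric under a
    # half-turn rotation.
    perim = float(perimeter_crofton(mask, directions=4))
    convex_img = props.image_convex
    convex_area = float(props.area_convex)
    convex_perim = float(perimeter_crofton(convex_img, directions=4))
    filled_area = float(props.area_filled)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    bbox_rows = props.bbox[2] - props.bbox[0]
    bbox_cols = props.bbox[3] - props.bbox[1]
    centroid = props.centroid
    eq_diam_px = float(props.equivalent_diameter_area)

    din = ndimage.distance_transform_edt(mask)
    dout = ndimage.distance_transform_edt(~mask)
    inten = img[mask]

    radii = _radius_series(mask, centroid)
    bd = _boundary_descriptors(radii)

    v: dict[str, float] = {}
    v["area_px"] = area
    v["area_um2"] = area * um_per_px**2
    v["filled_area_px"] = filled_area
    v["convex_area_px"] = convex_area
    v["equiv_diameter_px"] = eq_diam_px
    v["equiv_diameter_um"] = eq_diam_px * um_per_px
    v["perimeter_px"] = perim
    v["perimeter_um"] = perim * um_per_px
    v["convex_perimeter_px"] = convex_perim
    v["major_axis_px"] = major
    v["minor_axis_px"] = minor
    v["bbox_area_px"] = float(bbox_rows * bbox_cols)
    v["feret_max_px"] = float(props.feret_diameter_max)
    v["radius_mean_px"] = bd["_radius_mean"]
    v["radius_max_px"] = bd["_radius_max"]
    v["radius_min_px"] = bd["_radius_min"]
    v["intensity_mean"] = float(inten.mean())
    v["intensity_total"] = float(inten.sum())
    v["intensity_sd"] = float(inten.std())
    v["intensity_min"] = float(inten.min())
    v["intensity_max"] = float(inten.max())
    p10, p25, p50, p75, p90 = np.percentile(inten, [10, 25, 50, 75, 90])
    v["intensity_median"] = float(p50)
    v["intensity_p10"] = float(p10)
    v["intensity_p25"] = float(p25)
    v["intensity_p75"] = float(p75)
    v["intensity_p90"] = float(p90)
    v["intensity_iqr"] = float(p75 - p25)

    def _stats(sel: np.ndarray) -> tuple[float, float]:
        vals = img[sel]
        if vals.size == 0:
            return 0.0, 0.0
        return float(vals.mean()), float(vals.std())

    for w in _RIM_WIDTHS:
        m, s = _stats(mask & (din <= w))
        v[f"rim_mean_w{w}"] = m
        v[f"rim_sd_w{w}"] = s
    for w in _CORE_WIDTHS:
        m, s = _stats(mask & (din > w))
        v[f"core_mean_w{w}"] = m
        v[f"core_sd_w{w}"] = s
    for w in _OUTER_WIDTHS:
        m, _ = _stats((~mask) & (dout <= w))
        v[f"outer_band_mean_w{w}"] = m
    v["rim_core_contrast_w10"] = v["rim_mean_w10"] - v["core_mean_w10"]

    v["circularity"] = 4 * np.pi * area / max(perim**2, _EPS)
    v["solidity"] = area / max(convex_area, _EPS)
    v["solidity_filled"] = filled_area / max(convex_area, _EPS)
    v["convex_deficiency"] = (convex_area - area) / max(area, _EPS)
    v["eccentricity"] = float(props.eccentricity)
    v["extent"] = float(props.extent)
    v["aspect_ratio"] = major / max(minor, _EPS)
    v["elongation"] = 1.0 - minor / max(major, _EPS)
    v["convexity"] = convex_perim / max(perim, _EPS)
    v["compactness"] = perim**2 / max(area, _EPS)
    v["roundness_perimeter"] = perim / max(np.pi * eq_diam_px, _EPS)
    v["filled_ratio"] = area / max(filled_area, _EPS)
    v["euler_number"] = float(props.euler_number)
    hu = props.moments_hu
    for i in range(7):
        h = hu[i]
        v[f"hu_moment_{i + 1}"] = float(
            -np.sign(h) * np.log10(abs(h)) if abs(h) > 1e-30 else 0.0
        )
    v["radius_cv"] = bd["_radius_cv"]
    v["radius_skew"] = bd["_radius_skew"]
    v["radius_kurtosis"] = bd["_radius_kurt"]
    v["radius_min_max_ratio"] = bd["_radius_min"] / max(bd["_radius_max"], _EPS)
    v["radius_iqr_norm"] = bd["_radius_iqr_norm"]
    for w in (5, 10, 20):
        v[f"erosion_area_ratio_w{w}"] = float((din > w).sum()) / max(area, _EPS)
    for w in _OUTER_WIDTHS:
        v[f"dilation_area_ratio_w{w}"] = (
            area + float(((~mask) & (dout <= w)).sum())
        ) / max(area, _EPS)
    v["bbox_aspect"] = max(bbox_rows, bbox_cols) / max(min(bbox_rows, bbox_cols), 1)
    v["extent_filled"] = filled_area / max(float(bbox_rows * bbox_cols), _EPS)
    v["ellipse_area_ratio"] = area / max(np.pi * major * minor / 4.0, _EPS)
    v["contour_complexity"] = perim / max(2 * np.pi * bd["_radius_mean"], _EPS)
    mu = props.moments_central
    v["moment_dispersion"] = 2 * np.pi * (mu[2, 0] + mu[0, 2]) / max(area**2, _EPS)
    v["circular_variance"] = bd["_circular_variance"]

    for name in _FREQUENCY_NAMES:
        v[name] = bd[name]

    values = {name: float(v[name]) for name in PANEL_NAMES}
    cid = colony_id if colony_id is not None else (
        f"{colony.source_image_id}:{colony.label}"
    )
    return MorphProfile(
        colony_id=cid,
        values=values,
        family_of=dict(PANEL_FAMILIES),
        border=border,
    )


# ---------------------------------------------------------------------------
# Profile tables
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: list[MorphProfile]) -> pd.DataFrame:
    """Colonies x parameters table (canonical parameter order)."""
    if not profiles:
        return pd.DataFrame(columns=list(PANEL_NAMES))
    names = list(profiles[0].values)
    data = {p.colony_id: [p.values[n] for n in names] for p in profiles}
    return pd.DataFrame.from_dict(data, orient="index", columns=names)


def frame_to_profiles(frame: pd.DataFrame) -> list[MorphProfile]:
    fam = {n: PANEL_FAMILIES.get(n, "volume") for n in frame.columns}
    return [
        MorphProfile(
            colony_id=str(idx),
            values={n: float(row[n]) for n in frame.columns},
            family_of=dict(fam),
        )
        for idx, row in frame.iterrows()
    ]


# ---------------------------------------------------------------------------
# Parameter-selection filters
# ---------------------------------------------------------------------------

def _matrix(profiles: list[MorphProfile]) -> tuple[np.ndarray, list[str]]:
    names = list(profiles[0].values)
    x = np.array([[p.values[n] for n in names] for p in profiles], dtype=float)
    return x, names


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; defined as 0 when either column has zero variance."""
    sa, sb = a.std(), b.std()
    if sa < _EPS or sb < _EPS:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def filter_correlated(
    profiles: list[MorphProfile], r_max: float = 0.98
) -> FilterReport:
    """Greedy elimination of highly correlated parameters.

    Walking the panel in canonical order, a parameter is dropped when
    its |Pearson r| across colonies with any already-kept parameter
    exceeds ``r_max``; the earliest such kept parameter is recorded as
    the representative.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to estimate correlations")
    x, names = _matrix(profiles)
    kept: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(names)):
        hit = None
        for i in kept:
            r = _safe_corr(x[:, i], x[:, j])
            if abs(r) > r_max:
                hit = (names[j], names[i], r)
                break
        if hit is None:
            kept.append(j)
        else:
            dropped.append(hit)
    return FilterReport(kept=[names[i] for i in kept], dropped_correlated=dropped)


def filter_high_cv(profiles: list[MorphProfile], cv_max: float = 30.0) -> FilterReport:
    """Drop parameters whose coefficient of variation exceeds ``cv_max``.

    CV = 100 * sample SD / |mean| on raw values; zero-mean parameters
    (infinite CV) are dropped.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to estimate a CV")
    x, names = _matrix(profiles)
    kept, dropped = [], []
    for j, name in enumerate(names):
        col = x[:, j]
        mean = col.mean()
        sd = col.std(ddof=1)
        if abs(mean) < _EPS:
            dropped.append((name, np.inf))
            continue
        cv = 100.0 * sd / abs(mean)
        if cv > cv_max:
            dropped.append((name, float(cv)))
        else:
            kept.append(name)
    return FilterReport(kept=kept, dropped_high_cv=dropped)


def apply_filters(
    profiles: list[MorphProfile],
    r_max: float = 0.98,
    cv_max: float = 30.0,
) -> FilterReport:
    """Correlation filter then CV filter (the documented composition).

    The composed pass is idempotent: re-applying it to the surviving
    panel changes nothing.
    """
    corr_report = filter_correlated(profiles, r_max=r_max)
    reduced = [
        MorphProfile(
            colony_id=p.colony_id,
            values={n: p.values[n] for n in corr_report.kept},
            family_of={n: p.family_of[n] for n in corr_report.kept},
            border=p.border,
            line_id=p.line_id,
            true_class=p.true_class,
        )
        for p in profiles
    ]
    cv_report = filter_high_cv(reduced, cv_max=cv_max)
    return FilterReport(
        kept=cv_report.kept,
        dropped_correlated=corr_report.dropped_correlated,
        dropped_high_cv=cv_report.dropped_high_cv,
    )
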