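"""Field-of-view geometry and illumination homogeneity.

Pixel pitch (microns per pixel) is estimated from an image of a calibration
grid of known pitch: the grid period in pixels is measured per axis from
the autocorrelation of the row/column mean profiles with sub-pixel
(parabolic) peak interpolation, and um/px = pitch_um / period_px. The FOV
size follows as um/px times the image extent. The same grid image exposes
geometric distortion: each grid line is traced with sub-pixel precision and
its maximum bow (perpendicular deviation from a straight-line fit) is
reported as a percentage of the FOV, signed pincushion (bowing toward the
field center) or barrel (away).

Homogeneity profiling normalizes a flat-field image of a uniform
fluorescent sample to its maximum and reports brightness profiles through
the center (horizontal, vertical, both diagonals), the displacement of the
brightest region from the geometric center, and edge-falloff ratios —
drifts in these against a stored reference flag alignment changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .fixtures import FlatFieldImage, GridImage


@dataclass
class PixelCalibration:
    um_per_px_x: float
    um_per_px_y: float
    fov_x_um: float
    fov_y_um: float
    grid_pitch_um: float
    n_periods_x: float
    n_periods_y: float
    method: str = "autocorrelation"


@dataclass
class HomogeneityReport:
    normalized_image: np.ndarray
    profiles: dict            # name -> 1D normalized intensity profile
    peak_offset: tuple        # (dy, dx) pixels, top-decile centroid vs center
    edge_ratios: dict         # name -> (start, end) normalized edge values
    zoom_tag: str
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Grid period estimation
# ---------------------------------------------------------------------------

def _parabolic_peak(y: np.ndarray, i: int) -> float:
    """Sub-sample peak location by fitting a parabola through 3 points."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def _profile_period(profile: np.ndarray, *, min_lag: int = 3,
                    significance: float = 0.2) -> float:
    """Fundamental period (px) of a 1D periodic profile.

    A coarse period comes from the first significant peak of the (unbiased,
    overlap-normalized) autocorrelation with parabolic interpolation; it is
    then refined by locating every dark-line minimum of the profile at
    sub-pixel precision and regressing position on line index — the slope is
    the period, with error shrinking with the number of visible lines.
    """
    raw = np.asarray(profile, float)
    p = raw - raw.mean()
    n = len(p)
    ac = np.correlate(p, p, mode="full")[n - 1:]
    if ac[0] <= 0:
        raise ValueError("flat profile: no periodic signal")
    # unbiased normalization: the raw estimate tapers linearly with lag,
    # which would pull interpolated peak positions toward zero
    ac = ac / (n - np.arange(n))
    ac = ac / ac[0]
    cand = None
    for i in range(min_lag, n // 2):
        if i + 1 < n and ac[i] >= ac[i - 1] and ac[i] > ac[i + 1] \
                and ac[i] >= significance:
            cand = i
            break
    if cand is None:
        raise ValueError("no significant autocorrelation peak: "
                         "grid period not detectable")
    p0 = _parabolic_peak(ac, cand)
    # refinement: sub-pixel positions of the line minima, slope vs index
    half = max(int(p0 / 3), 2)
    start = float(np.argmin(raw[:max(int(p0), half + 1)]))
    idx, positions = [], []
    k = 0
    while True:
        # predict from the last found minimum to avoid cumulative drift
        if positions:
            c = int(round(positions[-1] + (k - idx[-1]) * p0))
        else:
            c = int(round(start + k * p0))
        if c >= n:
            break
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        j = lo + int(np.argmin(raw[lo:hi]))
        if lo < j < hi - 1 and 0 < j < n - 1:
            idx.append(k)
            positions.append(_parabolic_peak(-raw, j))
        k += 1
    if len(positions) >= 3:
        slope = np.polyfit(idx, positions, 1)[0]
        if abs(slope / p0 - 1) < 0.2:  # sanity: refinement near coarse value
            return float(slope)
    return float(p0)


def estimate_grid_angle(img: np.ndarray) -> float:
    """Dominant grid orientation (deg, in [-45, 45]) from gradient directions.

    Gradient angles are mapped through a 4-fold circular mean so that the
    two perpendicular line families reinforce the same estimate.
    """
    gy, gx = np.gradient(np.asarray(img, float))
    mag = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)
    z = np.sum(mag * np.exp(4j * theta))
    return float(np.degrees(np.angle(z) / 4.0))


def estimate_pixel_pitch(
    img: GridImage, pitch_um: float | None = None, *,
    max_rotation_deg: float = 5.0,
) -> PixelCalibration:
    """Per-axis um/px and FOV size from a calibration-grid image.

    Requires the grid aligned to the scan axes within ``max_rotation_deg``
    (rotate the physical target rather than resampling the image) and at
    least ~3 periods visible per axis.
    """
    pitch_um = pitch_um if pitch_um is not None else img.pitch_um
    data = np.asarray(img.data, float)
    angle = estimate_grid_angle(data)
    if abs(angle) > max_rotation_deg:
        raise ValueError(
            f"grid rotated {angle:.1f} deg from the scan axes: rotate the "
            f"target to within +/-{max_rotation_deg} deg and reacquire"
        )
    period_x = _profile_period(data.mean(axis=0))
    period_y = _profile_period(data.mean(axis=1))
    ny, nx = data.shape
    if nx / period_x < 3 or ny / period_y < 3:
        raise ValueError("fewer than 3 grid periods visible: zoom out")
    ux, uy = pitch_um / period_x, pitch_um / period_y
    return PixelCalibration(
        um_per_px_x=ux, um_per_px_y=uy,
        fov_x_um=ux * nx, fov_y_um=uy * ny,
        grid_pitch_um=pitch_um,
        n_periods_x=nx / period_x, n_periods_y=ny / period_y,
    )


# ---------------------------------------------------------------------------
# Distortion
# ---------------------------------------------------------------------------

def _trace_lines(data: np.ndarray, axis: int, period: float,
                 min_span_frac: float) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Trace dark grid lines perpendicular to ``axis``.

    For vertical lines (axis=1): find approximate line centers from column
    minima of the mean profile, then per row locate the intensity minimum
    within +/- period/3 with parabolic sub-pixel refinement. Rows lying on
    a perpendicular (horizontal) grid line are skipped — at a crossing the
    whole search window is dark and the minimum is undefined. Returns a
    list of (approx_position, along_coords, across_positions).
    """
    if axis == 0:
        data = data.T
    ny, nx = data.shape
    prof = data.mean(axis=0)
    thr = prof.mean()
    centers = []
    i = 1
    while i < nx - 1:
        if prof[i] < thr and prof[i] <= prof[i - 1] and prof[i] < prof[i + 1]:
            centers.append(i)
            i += max(int(period * 0.6), 1)
        else:
            i += 1
    row_means = data.mean(axis=1)
    good_rows = np.nonzero(row_means > row_means.mean())[0]
    w = max(int(period / 3), 2)
    lines = []
    for c in centers:
        if c - w < 0 or c + w >= nx:
            continue
        along, across = [], []
        for y in good_rows:
            seg = data[y, c - w:c + w + 1]
            j = int(np.argmin(seg))
            if j == 0 or j == len(seg) - 1:
                continue  # minimum at the window edge: not this line
            along.append(float(y))
            across.append(c - w + _parabolic_peak(-seg, j))
        along, across = np.asarray(along), np.asarray(across)
        if len(along) >= 10 and np.ptp(along) >= min_span_frac * (ny - 1):
            lines.append((float(c), along, across))
    return lines


def assess_distortion(
    img: GridImage, cal: PixelCalibration, *, min_span_frac: float = 0.8
) -> dict:
    """Maximum grid-line bow as % of the FOV extent, signed by type.

    Each detected line is fit with a straight line; the bow is the largest
    perpendicular residual. Lines bowing toward the field center at their
    midpoint indicate pincushion distortion, away indicates barrel. Affine
    transformations (translation/rotation/scale) introduce no bow, so the
    metric isolates genuinely radial distortion.
    """
    data = np.asarray(img.data, float)
    ny, nx = data.shape
    period_x = cal.grid_pitch_um / cal.um_per_px_x
    period_y = cal.grid_pitch_um / cal.um_per_px_y
    results = []
    for axis, period, extent, center_across in (
        (1, period_x, nx, (nx - 1) / 2.0),   # vertical lines, x positions
        (0, period_y, ny, (ny - 1) / 2.0),   # horizontal lines, y positions
    ):
        lines = _trace_lines(data, axis, period, min_span_frac)
        for x0, along, across in lines:
            coeffs = np.polyfit(along, across, 1)
            resid = across - np.polyval(coeffs, along)
            bow_px = float(np.max(np.abs(resid)))
            # signed: residual at the middle of the line, toward-center positive
            mid = np.abs(along - along.mean()) < 0.17 * np.ptp(along)
            mid_dev = float(resid[mid].mean()) if mid.any() else 0.0
            toward_center = -np.sign(x0 - center_across) * np.sign(mid_dev)
            results.append({
                "axis": "vertical" if axis == 1 else "horizontal",
                "position_px": x0,
                "offcenter_px": abs(x0 - center_across),
                "bow_px": bow_px,
                "bow_pct": 100.0 * bow_px / extent,
                "toward_center": float(toward_center) if mid_dev != 0 else 0.0,
            })
    if not results:
        raise ValueError("no grid lines spanning the required fraction of the FOV")
    max_bow = max(r["bow_pct"] for r in results)
    # weight the sign vote by off-center distance: central lines carry no sign
    vote = sum(r["toward_center"] * r["offcenter_px"] for r in results)
    if max_bow < 0.1:
        kind = "none"
    elif vote > 0:
        kind = "pincushion"
    elif vote < 0:
        kind = "barrel"
    else:
        kind = "indeterminate"
    return {"max_bow_pct": max_bow, "distortion_type": kind, "lines": results}


# ---------------------------------------------------------------------------
# Homogeneity
# ---------------------------------------------------------------------------

def _diagonal_profile(img: np.ndarray, sign: int) -> np.ndarray:
    """Bilinear sample along a center diagonal at ~unit-pixel arc spacing."""
    ny, nx = img.shape
    n = int(np.hypot(ny - 1, nx - 1)) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = t * (ny - 1)
    cols = t * (nx - 1) if sign > 0 else (1 - t) * (nx - 1)
    return map_coordinates(img, np.vstack([rows, cols]), order=1)


def homogeneity_profile(
    img: FlatFieldImage | np.ndarray, n_average: int | None = None, *,
    zoom_tag: str | None = None, offset_flag_px: float = 5.0,
) -> HomogeneityReport:
    """Normalized flat-field profiles and peak-displacement diagnostics.

    A frame stack is averaged (use several frames: shot noise on a single
    frame obscures the smooth vignetting profile), normalized to its
    maximum, and sampled along the horizontal, vertical and two diagonal
    center profiles. If the global maximum is an isolated hot pixel
    (> 2% above the 99.9th percentile) the normalization falls back to the
    99.9th percentile with a warning. The peak offset is the centroid of
    the top-decile brightness region relative to the geometric center; a
    displacement beyond ``offset_flag_px`` is noted as possible
    misalignment.
    """
    if isinstance(img, FlatFieldImage):
        data = np.asarray(img.data, float)
        zoom_tag = zoom_tag or img.zoom_tag
    else:
        data = np.asarray(img, float)
        zoom_tag = zoom_tag or "unspecified"
    if data.ndim == 3:
        if n_average is not None:
            data = data[:n_average]
        data = data.mean(axis=0)
    notes = []
    peak = float(data.max())
    p999 = float(np.percentile(data, 99.9))
    if peak > 1.02 * p999 and p999 > 0:
        warnings.warn("normalization maximum looks like an isolated hot pixel; "
                      "using the 99.9th percentile")
        notes.append("hot-pixel normalization fallback")
        peak = p999
    norm = np.clip(data / peak, 0.0, 1.0)
    ny, nx = norm.shape
    profiles = {
        "horizontal": norm[ny // 2, :].copy(),
        "vertical": norm[:, nx // 2].copy(),
        "diag_main": _diagonal_profile(norm, +1),
        "diag_anti": _diagonal_profile(norm, -1),
    }
    edge_ratios = {k: (float(v[0]), float(v[-1])) for k, v in profiles.items()}
    top = norm >= np.percentile(norm, 90.0)
    yy, xx = np.nonzero(top)
    dy = float(yy.mean() - (ny - 1) / 2.0)
    dx = float(xx.mean() - (nx - 1) / 2.0)
    if np.hypot(dy, dx) > offset_flag_px:
        direction = []
        if abs(dy) > offset_flag_px / 2:
            direction.append("down" if dy > 0 else "up")
        if abs(dx) > offset_flag_px / 2:
            direction.append("right" if dx > 0 else "left")
        notes.append("possible misalignment: peak offset "
                     f"{'/'.join(direction) or 'radial'} by "
                     f"({dy:+.1f}, {dx:+.1f}) px")
    return HomogeneityReport(normalized_image=norm, profiles=profiles,
                             peak_offset=(dy, dx), edge_ratios=edge_ratios,
                             zoom_tag=zoom_tag, notes=notes)


def compare_homogeneity(
    current: HomogeneityReport, reference: HomogeneityReport,
    tolerance: float = 0.1,
) -> dict:
    """Per-profile maximum absolute difference vs a stored reference.

    Refuses to compare reports taken at different zooms or geometries —
    the vignetting profile depends on both.
    """
    if current.zoom_tag != reference.zoom_tag:
        raise ValueError(
            f"zoom mismatch: {current.zoom_tag!r} vs {reference.zoom_tag!r}"
        )
    if current.normalized_image.shape != reference.normalized_image.shape:
        raise ValueError("image geometry mismatch")
    diffs = {}
    for k in current.profiles:
        diffs[k] = float(np.max(np.abs(current.profiles[k]
                                       - reference.profiles[k])))
    worst = max(diffs.values())
    return {"max_abs_diff": worst, "per_profile": diffs,
            "tolerance": tolerance, "pass": worst <= tolerance}


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along the first (z) axis.

    Utility for field-curvature checks: project a z-stack of the thin
    fluorescent slide before homogeneity profiling.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (Z, H, W) stack")
    return stack.max(axis=0)
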