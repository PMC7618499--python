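"""Synthetic input generators.

Every analysis in this package estimates parameters of a statistical model
of the microscope (detector sensitivity, point-spread widths, grid geometry,
field flatness, PMT gain curves). These generators draw samples from exactly
those models with known ground-truth parameters, so each estimator can be
validated by parameter recovery without access to an instrument.

The generators deliberately do *not* simulate optics from first principles
(no diffraction integrals, no scattering, no indicator kinetics); they
reproduce the statistical structure each estimator assumes and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import FrameSequence, round_half_up
from .pmt import GainSweep


# ---------------------------------------------------------------------------
# Poisson-limited imaging movies
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Expected photon emission per pixel per frame, with optional dynamics.

    Parameters
    ----------
    brightness_map
        (H, W) array of expected photons per pixel per frame; must be >= 0.
    activity_traces
        Optional list of ``(mask, trace)`` pairs. ``mask`` is a boolean
        (H, W) region, ``trace`` a length-T multiplicative time course
        (> 0). Emulates slow fluorescence signals (e.g. calcium activity)
        riding on the shot-noise-limited baseline: a low-rank multiplicative
        model, intentionally agnostic of indicator kinetics.
    margin_gain_profile
        Optional per-column gain multiplier applied to the digitized signal,
        emulating acquisition-side compensation for slower scan speeds near
        the frame edges (which lowers the effective per-photon gain there).
    """

    height: int
    width: int
    brightness_map: np.ndarray | None = None
    activity_traces: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    margin_gain_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.brightness_map is None:
            self.brightness_map = np.ones((self.height, self.width))
        self.brightness_map = np.asarray(self.brightness_map, dtype=float)
        if self.brightness_map.shape != (self.height, self.width):
            raise ValueError("brightness_map shape must match (height, width)")
        if np.any(self.brightness_map < 0):
            raise ValueError("brightness_map must be non-negative")
        for mask, trace in self.activity_traces:
            if np.any(np.asarray(trace) <= 0):
                raise ValueError("activity multipliers must be positive")
        if self.margin_gain_profile is not None:
            self.margin_gain_profile = np.asarray(self.margin_gain_profile, float)
            if self.margin_gain_profile.shape != (self.width,):
                raise ValueError("margin_gain_profile must have one entry per column")


@dataclass
class DetectorSpec:
    """Linear photodetector model: ``value = round(q * photons + I0 + noise)``.

    ``q`` is the photon sensitivity in grayscale levels per detected photon,
    ``I0`` the zero-intensity grayscale level, ``read_noise_sd`` the standard
    deviation of additive Gaussian read noise in grayscale units.
    """

    q: float
    I0: float = 0.0
    read_noise_sd: float = 0.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError(f"photon sensitivity q must be positive, got {self.q}")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    @property
    def max_level(self) -> int:
        return 2**self.bit_depth - 1


def gen_poisson_movie(
    scene: SceneSpec,
    detector: DetectorSpec,
    n_frames: int,
    seed: int,
    *,
    dx: float | None = None,
    dy: float | None = None,
    dt: float | None = None,
    clip: bool = True,
) -> FrameSequence:
    """Draw a movie whose noise follows the linear-detector Poisson model.

    Each pixel value is ``round(q * Poisson(lambda) + I0 + N(0, sd))``,
    optionally clipped to the detector bit depth. ``clip=False`` keeps the
    unclipped values (still rounded), which is the regime in which the
    photon-transfer analysis is exactly unbiased; saturation distorts the
    variance-vs-intensity relation, so both regimes are generated on demand.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 (paired-frame analyses need pairs)")
    rng = np.random.default_rng(seed)
    lam = np.broadcast_to(scene.brightness_map, (n_frames, scene.height, scene.width))
    lam = np.array(lam, dtype=float)
    for mask, trace in scene.activity_traces:
        trace = np.asarray(trace, dtype=float)
        if trace.shape[0] != n_frames:
            raise ValueError("activity trace length must equal n_frames")
        lam[:, mask] *= trace[:, None]
    photons = rng.poisson(lam).astype(float)
    signal = detector.q * photons + detector.I0
    if scene.margin_gain_profile is not None:
        signal = (signal - detector.I0) * scene.margin_gain_profile[None, None, :] + detector.I0
    if detector.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, detector.read_noise_sd, signal.shape)
    values = round_half_up(signal)
    if clip:
        values = np.clip(values, 0, detector.max_level)
    meta = {"generator": "gen_poisson_movie", "seed": seed,
            "q": detector.q, "I0": detector.I0, "clip": clip}
    return FrameSequence(values, dx=dx, dy=dy, dt=dt, meta=meta)


# ---------------------------------------------------------------------------
# Bead stacks
# ---------------------------------------------------------------------------

@dataclass
class BeadStack:
    """A Z x H x W image stack of a (sub-diffraction) fluorescent bead."""

    data: np.ndarray
    z_step: float
    um_per_px_x: float
    um_per_px_y: float
    location_tag: str = "center"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("BeadStack data must be (Z, H, W)")


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gen_bead_stack(
    fwhm_xyz: tuple[float, float, float],
    pixel_pitch: float,
    z_step: float,
    amplitude: float,
    background: float,
    noise_sd: float,
    seed: int,
    *,
    tilt_deg: float = 0.0,
    z_range: float | None = None,
    shape_xy: tuple[int, int] = (33, 33),
    location_tag: str = "center",
) -> BeadStack:
    """Render a 3D Gaussian bead image with known FWHMs.

    The axial extent defaults to 5x the axial FWHM; an extent below twice
    the axial FWHM is refused because the axial Gaussian fit would be
    unconstrained (the profile never falls to half maximum inside the
    stack).

    ``tilt_deg`` shears the bead axis in the x-z plane, emulating a tilted
    PSF from misaligned optics.
    """
    fwhm_x, fwhm_y, fwhm_z = fwhm_xyz
    if z_range is None:
        z_range = 5.0 * fwhm_z
    if z_range < 2.0 * fwhm_z:
        raise ValueError(
            f"z-range {z_range} um < 2x axial FWHM {fwhm_z} um: fit unconstrained"
        )
    rng = np.random.default_rng(seed)
    n_planes = int(np.floor(z_range / z_step)) + 1
    ny, nx = shape_xy
    z = (np.arange(n_planes) - (n_planes - 1) / 2.0) * z_step
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_pitch
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_pitch
    sx, sy, sz = (f * _FWHM_TO_SIGMA for f in (fwhm_x, fwhm_y, fwhm_z))
    shear = np.tan(np.deg2rad(tilt_deg))
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :] - shear * zz
    profile = np.exp(-(xx**2 / (2 * sx**2) + yy**2 / (2 * sy**2) + zz**2 / (2 * sz**2)))
    data = amplitude * profile + background
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    meta = {"generator": "gen_bead_stack", "seed": seed,
            "fwhm_xyz": (fwhm_x, fwhm_y, fwhm_z), "tilt_deg": tilt_deg,
            "amplitude": amplitude, "background": background}
    return BeadStack(data, z_step=z_step, um_per_px_x=pixel_pitch,
                     um_per_px_y=pixel_pitch, location_tag=location_tag, meta=meta)


# ---------------------------------------------------------------------------
# Calibration grids
# ---------------------------------------------------------------------------

@dataclass
class GridImage:
    """Image of a periodic calibration grid (dark lines on bright field)."""

    data: np.ndarray
    pitch_um: float
    meta: dict = field(default_factory=dict)


def _inverse_radial_warp(rp: np.ndarray, k: float) -> np.ndarray:
    # invert r' = r (1 + k r^2) by fixed-point iteration; k r^2 << 1 in use
    r = rp.copy()
    for _ in range(25):
        r = rp / (1.0 + k * r**2)
    return r


def gen_grid_image(
    pitch_um: float,
    um_per_px: float,
    seed: int,
    *,
    distortion_coeff: float = 0.0,
    rotation_deg: float = 0.0,
    shape: tuple[int, int] = (512, 512),
    um_per_px_y: float | None = None,
    line_width_frac: float = 0.15,
    background: float = 1000.0,
    depth: float = 0.8,
    noise_sd: float = 0.0,
) -> GridImage:
    """Render a square calibration grid, optionally warped and rotated.

    The radial polynomial warp ``r' = r (1 + k r^2)`` (``k`` =
    ``distortion_coeff``, with r normalized to the half-diagonal) produces
    pincushion distortion for k > 0 and barrel distortion for k < 0.
    ``um_per_px_y`` allows anisotropic (non-square) pixels.
    """
    if um_per_px_y is None:
        um_per_px_y = um_per_px
    period_x = pitch_um / um_per_px
    period_y = pitch_um / um_per_px_y
    if min(period_x, period_y) < 4.0:
        raise ValueError(
            f"grid period {min(period_x, period_y):.2f} px < 4 px: unresolvable"
        )
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    u = xx - cx
    v = yy - cy
    if distortion_coeff != 0.0:
        rnorm = np.hypot(nx, ny) / 2.0
        rp = np.hypot(u, v) / rnorm
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rp > 0, _inverse_radial_warp(rp, distortion_coeff) / rp, 1.0)
        u = u * scale
        v = v * scale
    if rotation_deg != 0.0:
        th = np.deg2rad(rotation_deg)
        u, v = u * np.cos(th) + v * np.sin(th), -u * np.sin(th) + v * np.cos(th)
    # distance (px) to the nearest grid line along each axis
    dx_line = np.abs(((u + period_x / 2) % period_x) - period_x / 2)
    dy_line = np.abs(((v + period_y / 2) % period_y) - period_y / 2)
    wx, wy = line_width_frac * period_x, line_width_frac * period_y
    line = np.maximum(np.exp(-dx_line**2 / (2 * wx**2)),
                      np.exp(-dy_line**2 / (2 * wy**2)))
    data = background * (1.0 - depth * line)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    meta = {"generator": "gen_grid_image", "seed": seed, "um_per_px": um_per_px,
            "um_per_px_y": um_per_px_y, "distortion_coeff": distortion_coeff,
            "rotation_deg": rotation_deg}
    return GridImage(data, pitch_um=pitch_um, meta=meta)


# ---------------------------------------------------------------------------
# Flat-field (homogeneity) images
# ---------------------------------------------------------------------------

@dataclass
class FlatFieldImage:
    """Image of a uniform fluorescent slide: vignetting profile + noise."""

    data: np.ndarray
    zoom_tag: str = "zoom1"
    meta: dict = field(default_factory=dict)


def gen_vignette_field(
    profile: Callable[[np.ndarray], np.ndarray],
    seed: int,
    *,
    offset_xy: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    zoom_tag: str = "zoom1",
) -> FlatFieldImage:
    """Render a vignetted flat field.

    ``profile(r)`` gives brightness as a function of distance (in pixels)
    from the field center, which is displaced by ``offset_xy`` = (dx, dy)
    from the geometric image center (positive dy moves the bright peak
    down the image). ``profile(0)`` must be the maximum.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    cx = (nx - 1) / 2.0 + offset_xy[0]
    cy = (ny - 1) / 2.0 + offset_xy[1]
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    r = np.hypot(xx - cx, yy - cy)
    data = profile(r)
    if np.any(data > profile(np.zeros(1))[0] + 1e-9):
        raise ValueError("profile must attain its maximum at r = 0")
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    meta = {"generator": "gen_vignette_field", "seed": seed, "offset_xy": offset_xy}
    return FlatFieldImage(np.asarray(data, float), zoom_tag=zoom_tag, meta=meta)


# ---------------------------------------------------------------------------
# PMT gain sweeps
# ---------------------------------------------------------------------------

def gen_pmt_sweep(
    gains: Sequence[float],
    dark_rate_fn: Callable[[float], float],
    light_rate_fn: Callable[[float], float],
    seed: int,
    *,
    amplification_fn: Callable[[float], float] | None = None,
    offset: float = 40.0,
    read_noise_sd: float = 0.0,
    n_frames: int = 5,
    shape: tuple[int, int] = (64, 64),
    tia_gain: float = 100e-6,
    adc_volts: float = 1.0,
    adc_levels: int = 2048,
) -> GainSweep:
    """Draw paired dark/light frame series across PMT gain settings.

    Per gain ``g``, dark pixels are ``offset + A(g) * Poisson(dark_rate(g))``
    and light pixels additionally include ``light_rate(g)`` events;
    ``A(g)`` (``amplification_fn``, default identity) is the effective
    grayscale amplification. At zero gain the amplification is forced to
    zero so dark frames carry only the digitizer offset — this is the frame
    the black-point estimate is defined on, so a sweep without a zero-gain
    entry is refused.
    """
    gains = list(gains)
    if sorted(gains) != gains:
        raise ValueError("gains must be sorted ascending")
    if 0 not in gains and 0.0 not in gains:
        raise ValueError("sweep must include a zero-gain entry (black point undefined)")
    if amplification_fn is None:
        amplification_fn = lambda g: float(g)
    rng = np.random.default_rng(seed)
    dark_series: dict[float, FrameSequence] = {}
    light_series: dict[float, FrameSequence] = {}
    for g in gains:
        amp = 0.0 if g == 0 else float(amplification_fn(g))
        for role, rate_fn, store in (
            ("dark", dark_rate_fn, dark_series),
            ("light", lambda gg: dark_rate_fn(gg) + light_rate_fn(gg), light_series),
        ):
            lam = max(float(rate_fn(g)), 0.0)
            vals = offset + amp * rng.poisson(lam, (n_frames, *shape))
            if read_noise_sd > 0:
                vals = vals + rng.normal(0.0, read_noise_sd, vals.shape)
            store[g] = FrameSequence(round_half_up(vals),
                                     meta={"gain": g, "role": role})
    return GainSweep(gains=gains, dark_series=dark_series,
                     light_series=light_series, tia_gain=tia_gain,
                     adc_volts=adc_volts, adc_levels=adc_levels,
                     meta={"generator": "gen_pmt_sweep", "seed": seed,
                           "offset": offset})
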