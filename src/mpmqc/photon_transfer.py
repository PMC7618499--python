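"""Photon sensitivity estimation from paired-frame noise statistics.

A linear detector digitizes an expected photon count lambda per pixel per
frame as I = q * lambda + I0, where q is the photon sensitivity (grayscale
levels per detected photon) and I0 the zero-intensity level. Because photon
arrivals are Poisson, the temporal variance of the grayscale value is
V = q^2 * lambda = q * (I - I0): variance is linear in mean intensity with
slope q — the photon transfer curve (PTC).

Estimating the variance from *adjacent-frame differences* rather than the
full time series isolates the uncorrelated quantum noise from slow signals
(activity, drift, motion): for frames X and X' (X delayed by one frame),
M = round(X/2 + X'/2) estimates the local mean and D = (X' - X)^2 / 2 is an
unbiased single-sample variance estimate whenever the underlying rate is
unchanged between the two frames.

A count-weighted robust (Huber) line fit of V on I gives q as the slope and
I0 as the x-intercept; robustness suppresses the bright, activity-inflated
levels. The fit then converts movies into absolute photon-flux units and
ROI traces into photons per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import HuberRegressor

from .core import FrameSequence, round_half_up


@dataclass
class PhotonTransferCurve:
    """Variance vs intensity, with per-level sample counts.

    ``I``: strictly increasing unique intensity levels of the rounded pair
    means; ``C``: occupancy (number of pixel/frame-pair samples) per level;
    ``V``: mean squared half-difference per level.
    """

    I: np.ndarray
    C: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, float)
        self.C = np.asarray(self.C)
        self.V = np.asarray(self.V, float)
        if not (len(self.I) == len(self.C) == len(self.V)):
            raise ValueError("I, C, V must have equal length")
        if len(self.I) and np.any(np.diff(self.I) <= 0):
            raise ValueError("I must be strictly increasing")
        if np.any(self.C < 1) or np.any(self.V < 0):
            raise ValueError("C >= 1 and V >= 0 required")

    @property
    def n_samples(self) -> int:
        return int(self.C.sum())


@dataclass
class SensitivityFit:
    """Photon sensitivity fit: V ~ q * (I - I0)."""

    q: float
    I0: float
    n_levels_used: int
    robust_loss_scale: float
    valid: bool = True
    message: str = ""


@dataclass
class PhotonFluxMovie:
    """Movie rescaled to photon units.

    ``units_tag`` is ``per_pixel_frame`` (photons per pixel per frame) or
    ``per_um2_s`` (photons per square micron per second).
    """

    data: np.ndarray
    units_tag: str
    dt: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units_tag not in ("per_pixel_frame", "per_um2_s"):
            raise ValueError(f"unknown units_tag {self.units_tag!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("flux movie contains non-finite values")


@dataclass
class ROITrace:
    """Photon-rate trace for a region of interest, in photons per second."""

    trace: np.ndarray
    pixel_indices: np.ndarray  # (n, 2) row/col indices
    gamma: float = 1.0
    weights: np.ndarray | None = None


# ---------------------------------------------------------------------------
# PTC construction
# ---------------------------------------------------------------------------

def paired_moments(
    x: FrameSequence, exclude_margin: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Rounded pair means M and squared half-differences D.

    For consecutive frames X (t) and X' (t+1): M = round(X/2 + X'/2),
    D = (X' - X)^2 / 2, computed over the T-1 adjacent pairs after removing
    ``exclude_margin`` pixels from every image border (frame edges can carry
    laser-blanking and mirror-turnaround artifacts). Rounding is half-up, so
    M stays on the integer grayscale grid.
    """
    data = np.asarray(x.data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames for paired moments")
    m = int(exclude_margin)
    if m < 0:
        raise ValueError("exclude_margin must be >= 0")
    if 2 * m >= data.shape[1] or 2 * m >= data.shape[2]:
        raise ValueError("margin removes the entire image")
    if m > 0:
        data = data[:, m:-m, m:-m]
    a, b = data[:-1], data[1:]
    M = round_half_up(0.5 * a + 0.5 * b)
    D = 0.5 * (b - a) ** 2
    return M, D


def build_ptc(M: np.ndarray, D: np.ndarray) -> PhotonTransferCurve:
    """Aggregate (M, D) samples into the photon transfer curve.

    I is the sorted unique values of M; C_j counts samples at level I_j;
    V_j averages D over those samples. Occupancy is conserved:
    sum(C) equals the number of (pixel, frame-pair) samples.
    """
    M = np.asarray(M, float).ravel()
    D = np.asarray(D, float).ravel()
    if M.size == 0:
        raise ValueError("empty input")
    if M.shape != D.shape:
        raise ValueError("M and D must have the same shape")
    levels, inverse, counts = np.unique(M, return_inverse=True, return_counts=True)
    sums = np.bincount(inverse, weights=D, minlength=len(levels))
    return PhotonTransferCurve(I=levels, C=counts, V=sums / counts)


# ---------------------------------------------------------------------------
# Sensitivity fit
# ---------------------------------------------------------------------------

def fit_sensitivity(
    ptc: PhotonTransferCurve,
    *,
    count_floor: int = 100,
    saturation_level: float | None = None,
    epsilon: float = 1.35,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SensitivityFit:
    """Count-weighted Huber regression of V on I; q = slope, I0 = -b/q.

    Levels with fewer than ``count_floor`` samples are excluded (they stay
    in the PTC): sparse levels have noisy variance estimates that
    destabilize the robust loss. Levels within 1% of ``saturation_level``
    (e.g. the bit-depth maximum) are excluded as well, since clipping
    suppresses the variance there. A non-positive slope marks the fit
    invalid rather than raising — the PTC itself may be perfectly well
    formed (e.g. a static scene with pure read noise).
    """
    keep = ptc.C >= count_floor
    if saturation_level is not None:
        keep &= ptc.I < 0.99 * saturation_level
    I, C, V = ptc.I[keep], ptc.C[keep], ptc.V[keep]
    if len(I) < 2:
        raise ValueError(
            f"PTC degenerate: {len(I)} usable levels (need >= 2) "
            f"after occupancy floor {count_floor}"
        )
    # standardize: the joint (coef, scale) Huber optimization is badly
    # conditioned when V spans many orders of magnitude
    mI, sI = I.mean(), I.std()
    sV = V.std()
    if sI == 0 or sV == 0:
        raise ValueError("PTC degenerate: constant intensity or variance")
    w = C.astype(float)
    huber = HuberRegressor(epsilon=epsilon, max_iter=max_iter, tol=tol,
                           alpha=0.0, fit_intercept=True)
    huber.fit(((I - mI) / sI)[:, None], V / sV, sample_weight=w / w.mean())
    q = float(huber.coef_[0] * sV / sI)
    intercept = float(huber.intercept_ * sV - q * mI)
    scale = float(huber.scale_ * sV)
    if q <= 0:
        return SensitivityFit(q=q, I0=np.nan, n_levels_used=len(I),
                              robust_loss_scale=scale,
                              valid=False, message="non-positive PTC slope")
    return SensitivityFit(q=q, I0=float(-intercept / q), n_levels_used=len(I),
                          robust_loss_scale=scale)


# ---------------------------------------------------------------------------
# Diagnostics and unit conversion
# ---------------------------------------------------------------------------

def cov_image(x: FrameSequence, fit: SensitivityFit,
              exclude_margin: int = 0) -> np.ndarray:
    """Per-pixel ratio of observed to Poisson-predicted variance.

    Observed variance is the time average of the paired half-squared
    differences; the prediction is q * (mean - I0). The ratio is 1.0
    wherever quantum noise dominates, > 1 where extra variability (activity,
    motion, laser noise) is present, and < 1 where the acquisition system
    applies reduced gain (e.g. scan-speed compensation bands at the frame
    edges) or where clipping suppresses variance. Pixels whose mean does not
    exceed I0 are masked as NaN.
    """
    if not fit.valid:
        raise ValueError("cannot form CoV image from an invalid fit")
    M, D = paired_moments(x, exclude_margin=exclude_margin)
    data = np.asarray(x.data, float)
    m = int(exclude_margin)
    if m > 0:
        data = data[:, m:-m, m:-m]
    mean = data.mean(axis=0)
    observed = D.mean(axis=0)
    predicted = fit.q * (mean - fit.I0)
    ratio = np.full(mean.shape, np.nan)
    ok = predicted > 0
    ratio[ok] = observed[ok] / predicted[ok]
    return ratio


def to_photon_flux(
    x: FrameSequence, fit: SensitivityFit, units: str = "per_pixel_frame"
) -> PhotonFluxMovie:
    """Rescale a raw movie into photon units: (X - I0) / q.

    One detected photon raises the grayscale value by q, so dividing the
    offset-subtracted value by the sensitivity maps it to photon counts.
    ``per_um2_s`` additionally divides by dx * dy * dt (requires the pixel
    pitch and frame period metadata). Negative values (noise below I0) are
    retained: clipping them would bias ROI sums upward.
    """
    if not fit.valid:
        raise ValueError("cannot rescale with an invalid sensitivity fit")
    flux = (np.asarray(x.data, float) - fit.I0) / fit.q
    if units == "per_um2_s":
        x.require_physical_units()
        flux = flux / (x.dx * x.dy * x.dt)
    elif units != "per_pixel_frame":
        raise ValueError(f"unknown units {units!r}")
    return PhotonFluxMovie(flux, units_tag=units, dt=x.dt,
                           meta={"q": fit.q, "I0": fit.I0})


def roi_photon_rate(
    flux: PhotonFluxMovie, roi: np.ndarray, dt: float | None = None
) -> ROITrace:
    """Uniform-weight ROI photon rate: sum of flux over the ROI / dt.

    ``roi`` is a boolean mask or an (n, 2) array of row/col indices. The
    flux movie must be in per-pixel-per-frame units; the result is photons
    per second.
    """
    if flux.units_tag != "per_pixel_frame":
        raise ValueError("ROI rates are defined on per_pixel_frame flux movies")
    dt = dt if dt is not None else flux.dt
    if dt is None or dt <= 0:
        raise ValueError("frame period dt required for photons-per-second rates")
    rows, cols = _roi_indices(roi, flux.data.shape[1:])
    trace = flux.data[:, rows, cols].sum(axis=1) / dt
    return ROITrace(trace=trace, pixel_indices=np.column_stack([rows, cols]))


def weighted_roi_rate(
    flux: PhotonFluxMovie,
    roi: np.ndarray,
    weights: np.ndarray,
    dt: float | None = None,
    *,
    normalization: str = "simple",
) -> ROITrace:
    """Weighted-mask ROI rate y = (gamma / dt) * sum_i h_i * flux_i.

    gamma rescales the weighted sum back to total photon counts. The
    ``optimal`` normalization gamma = sum(h X-bar) / sum(h^2 X-bar) (X-bar
    the time-averaged flux) is unbiased for any intensity pattern; the
    ``simple`` form gamma = sum(h) / sum(h^2) matches it exactly on a
    uniform image and *under*-estimates on nonuniform images. Uniform unit
    weights give gamma = 1 and reduce to :func:`roi_photon_rate`.
    """
    if normalization not in ("optimal", "simple"):
        raise ValueError(f"unknown normalization {normalization!r}")
    dt = dt if dt is not None else flux.dt
    if dt is None or dt <= 0:
        raise ValueError("frame period dt required for photons-per-second rates")
    rows, cols = _roi_indices(roi, flux.data.shape[1:])
    h = np.asarray(weights, float).ravel()
    if h.shape[0] != rows.shape[0]:
        raise ValueError("one weight per ROI pixel required")
    if np.any(h < 0) or not np.any(h > 0):
        raise ValueError("weights must be >= 0 and not all zero")
    pix = flux.data[:, rows, cols]  # (T, n)
    if normalization == "optimal":
        xbar = pix.mean(axis=0)
        denom = np.sum(h**2 * xbar)
        if denom <= 0:
            import warnings
            warnings.warn("time-averaged flux is zero under the mask; "
                          "falling back to simple normalization")
            gamma = np.sum(h) / np.sum(h**2)
        else:
            gamma = float(np.sum(h * xbar) / denom)
    else:
        gamma = float(np.sum(h) / np.sum(h**2))
    trace = gamma * (pix * h[None, :]).sum(axis=1) / dt
    return ROITrace(trace=trace, pixel_indices=np.column_stack([rows, cols]),
                    gamma=gamma, weights=h)


def _roi_indices(roi: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError("ROI mask shape must match image shape")
        rows, cols = np.nonzero(roi)
    else:
        roi = np.atleast_2d(roi)
        if roi.shape[1] != 2:
            raise ValueError("ROI must be a boolean mask or (n, 2) indices")
        rows, cols = roi[:, 0].astype(int), roi[:, 1].astype(int)
    if rows.size == 0:
        raise ValueError("empty ROI")
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() >= shape[0] or cols.max() >= shape[1]):
        raise ValueError("ROI extends outside the image")
    return rows, cols
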