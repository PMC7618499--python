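"""Ultrafast-pulse calculators, dispersion-sweep optimization and laser-power
calibration.

Multiphoton excitation efficiency with a pulsed laser exceeds a CW laser of
equal average power by the enhancement factor

    g(n) = gp / (tau * f_rep)^(n-1),

where tau is the pulse FWHM, f_rep the repetition rate, n the photon order
of the absorption and gp a pulse-shape factor (1 for rectangular, 0.59 for
a hyperbolic-secant envelope, the typical mode-locked pulse shape). Short
pulses require spectral bandwidth: for a sech envelope the time-bandwidth
product is bounded by tau * dnu >= 0.3148, which converts to a wavelength
bandwidth dlambda = lambda0^2 * dnu / c.

Group delay dispersion (GDD) stretches pulses; the compensation optimum is
found by sweeping the compensator setting and maximizing mean fluorescence
intensity. Power delivery is calibrated as a lookup table from software
modulation value to measured milliwatts, with a shape-preserving monotone
interpolant and drift checks against historical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

C_M_PER_S = 299_792_458.0
SECH_TBP = 0.3148
SECH_SHAPE_FACTOR = 0.59


@dataclass
class PulseSpec:
    """Laser pulse: FWHM duration tau (s), repetition rate (Hz), center
    wavelength (m), pulse-shape factor gp, absorption photon order n."""

    tau: float
    f_rep: float
    lambda0: float = 920e-9
    gp: float = SECH_SHAPE_FACTOR
    n_photon: int = 2

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.f_rep <= 0 or self.lambda0 <= 0:
            raise ValueError("tau, f_rep, lambda0 must be positive")
        if self.tau * self.f_rep >= 1:
            raise ValueError("duty cycle tau * f_rep must be < 1 (pulsed regime)")


def enhancement_factor(p: PulseSpec) -> float:
    """Excitation enhancement of pulsed over CW operation at equal power."""
    return p.gp / (p.tau * p.f_rep) ** (p.n_photon - 1)


def transform_limited_bandwidth(tau: float, lambda0: float) -> float:
    """Minimum FWHM spectral bandwidth (nm) for a sech pulse of FWHM ``tau``.

    dnu = 0.3148 / tau; dlambda = lambda0^2 * dnu / c (first-order
    frequency-to-wavelength conversion). ``tau`` in seconds, ``lambda0`` in
    meters; returns nanometers.
    """
    if tau <= 0 or lambda0 <= 0:
        raise ValueError("tau and lambda0 must be positive")
    dnu = SECH_TBP / tau
    return lambda0**2 * dnu / C_M_PER_S * 1e9


# ---------------------------------------------------------------------------
# GDD sweep
# ---------------------------------------------------------------------------

@dataclass
class GDDSweep:
    """Mean (and optionally max) image intensity at each compensator setting."""

    gdd_values: np.ndarray      # fs^2
    mean_intensities: np.ndarray
    max_intensities: np.ndarray | None = None
    stage: str = "coarse"       # coarse ~2000 fs^2 steps, fine ~250 fs^2

    def __post_init__(self) -> None:
        self.gdd_values = np.asarray(self.gdd_values, float)
        self.mean_intensities = np.asarray(self.mean_intensities, float)
        d = np.diff(self.gdd_values)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("gdd_values must be strictly monotone")


def stability_check(
    times_s: np.ndarray, mean_series: np.ndarray, *,
    window_s: float = 120.0, threshold: float = 0.10,
) -> dict:
    """Photobleaching / source-stability check before a sweep.

    Requires the series to span at least ``window_s`` seconds; compares the
    mean intensity over the first and last tenths of the record. A relative
    change beyond ``threshold`` fails, indicating bleaching or source
    instability — sweep results would confound dispersion with drift.
    """
    t = np.asarray(times_s, float)
    y = np.asarray(mean_series, float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and series must be matching 1D arrays")
    span = t[-1] - t[0]
    if span < window_s:
        raise ValueError(f"series spans {span:.0f} s < required {window_s:.0f} s")
    k = max(len(y) // 10, 1)
    start, end = float(y[:k].mean()), float(y[-k:].mean())
    if start == 0:
        raise ValueError("zero starting intensity")
    change = (end - start) / start
    return {"relative_change": change, "threshold": threshold,
            "pass": abs(change) <= threshold,
            "advice": "" if abs(change) <= threshold else
            "intensity drifted: check photobleaching or source stability"}


def gdd_optimum(sweep: GDDSweep) -> dict:
    """Compensator setting maximizing mean intensity.

    Returns the grid argmax (authoritative: only tested settings are
    selectable) plus, when three points bracket the peak, a parabolic
    refinement of the apex. A maximum at the sweep boundary is flagged: the
    compensation range is insufficient and the true optimum lies outside.
    """
    g, y = sweep.gdd_values, sweep.mean_intensities
    if len(g) < 4:
        raise ValueError("need at least 4 sweep points")
    i = int(np.argmax(y))
    out = {"optimum_fs2": float(g[i]), "refined_fs2": None,
           "boundary_flag": False}
    if i == 0 or i == len(g) - 1:
        out["boundary_flag"] = True
        out["note"] = ("intensity still rising at the sweep limit: "
                       "insufficient compensation range")
        return out
    # parabola through the bracketing triple, in GDD coordinates
    x3, y3 = g[i - 1:i + 2], y[i - 1:i + 2]
    a, b, _ = np.polyfit(x3, y3, 2)
    if a < 0:
        out["refined_fs2"] = float(-b / (2 * a))
    return out


# ---------------------------------------------------------------------------
# Power calibration
# ---------------------------------------------------------------------------

@dataclass
class PowerCalibrationTable:
    """Modulation -> measured power lookup with acquisition metadata.

    ``beam_mode`` records whether the power reading was taken with a
    stationary or scanning beam — the two disagree (blanking, duty cycle),
    so comparisons across tables require matching modes.
    """

    modulation: np.ndarray
    power_mw: np.ndarray
    wavelength_nm: float
    objective_id: str
    beam_mode: str            # stationary | scanning
    fill_fraction: float | None = None
    sensor_id: str = ""
    date: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modulation = np.asarray(self.modulation, float)
        self.power_mw = np.asarray(self.power_mw, float)
        if self.beam_mode not in ("stationary", "scanning"):
            raise ValueError("beam_mode must be 'stationary' or 'scanning'")
        if np.any(self.power_mw < 0):
            raise ValueError("power_mw must be >= 0")
        order = np.argsort(self.modulation)
        self.modulation = self.modulation[order]
        self.power_mw = self.power_mw[order]
        if len(np.unique(self.modulation)) != len(self.modulation):
            raise ValueError("modulation values must be unique")

    @property
    def max_power_mw(self) -> float:
        return float(self.power_mw.max())


class PowerInterpolant:
    """Monotone (PCHIP) modulation->mW map with inverse lookup.

    An electro-optic modulator's transmission is sin^2-shaped in its drive,
    so the maximum power can occur well before 100% modulation; the inverse
    lookup is restricted to the monotone ascending branch below the
    detected maximum.
    """

    def __init__(self, table: PowerCalibrationTable, *,
                 noise_tolerance: float = 0.02):
        self.table = table
        m, p = table.modulation, table.power_mw
        if len(m) < 3:
            raise ValueError("need at least 3 calibration rows")
        self._forward = PchipInterpolator(m, p, extrapolate=False)
        imax = int(np.argmax(p))
        drops = np.diff(p[:imax + 1])
        if np.any(drops < -noise_tolerance * p.max()):
            warnings.warn("power is non-monotone below its maximum beyond "
                          "noise tolerance: check the modulator bias")
        self._imax = imax
        self._m_asc = m[:imax + 1]
        self._p_asc = p[:imax + 1]

    def __call__(self, modulation: float) -> float:
        m = self.table.modulation
        if modulation < m[0] or modulation > m[-1]:
            raise ValueError(
                f"modulation {modulation} outside calibrated range "
                f"[{m[0]}, {m[-1]}]"
            )
        return float(self._forward(modulation))

    def inverse(self, power_mw: float) -> float:
        """Modulation value achieving ``power_mw`` on the ascending branch."""
        pmax = float(self._p_asc[-1])
        pmin = float(self._p_asc[0])
        if power_mw > pmax:
            raise ValueError(
                f"requested {power_mw} mW exceeds achievable maximum {pmax} mW"
            )
        if power_mw < pmin:
            raise ValueError(f"requested {power_mw} mW below calibrated minimum")
        f = lambda m: float(self._forward(m)) - power_mw
        lo, hi = float(self._m_asc[0]), float(self._m_asc[-1])
        if f(lo) == 0:
            return lo
        if f(hi) == 0:
            return hi
        return float(brentq(f, lo, hi))


def build_power_calibration(
    rows, metadata: dict
) -> tuple[PowerCalibrationTable, PowerInterpolant]:
    """Assemble a calibration table from (modulation, power_mw) rows.

    ``metadata`` must carry wavelength_nm, objective_id and beam_mode; the
    beam mode is mandatory so later comparisons can refuse mixed-method
    tables.
    """
    rows = np.asarray(rows, float)
    if rows.ndim != 2 or rows.shape[1] != 2 or rows.shape[0] < 3:
        raise ValueError("need >= 3 (modulation, power_mw) rows")
    required = {"wavelength_nm", "objective_id", "beam_mode"}
    missing = required - set(metadata)
    if missing:
        raise ValueError(f"metadata missing {sorted(missing)}")
    table = PowerCalibrationTable(
        modulation=rows[:, 0], power_mw=rows[:, 1],
        wavelength_nm=float(metadata["wavelength_nm"]),
        objective_id=str(metadata["objective_id"]),
        beam_mode=str(metadata["beam_mode"]),
        fill_fraction=metadata.get("fill_fraction"),
        sensor_id=str(metadata.get("sensor_id", "")),
        date=str(metadata.get("date", "")),
    )
    return table, PowerInterpolant(table)


def power_drift_check(
    current: PowerCalibrationTable, reference: PowerCalibrationTable, *,
    tolerance: float = 0.05,
) -> dict:
    """Relative power drift vs a historical table; fails beyond ``tolerance``.

    Compares the maximum power and the power at every modulation value
    present in both tables. Refuses when wavelength, objective or beam mode
    differ — those legitimately change the delivered power.
    """
    for attr in ("wavelength_nm", "objective_id", "beam_mode"):
        if getattr(current, attr) != getattr(reference, attr):
            raise ValueError(f"cannot compare tables: {attr} differs")
    if reference.max_power_mw <= 0:
        raise ValueError("reference table has zero maximum power")
    drifts = {"max_power": (current.max_power_mw - reference.max_power_mw)
              / reference.max_power_mw}
    ref_map = dict(zip(reference.modulation, reference.power_mw))
    for m, p in zip(current.modulation, current.power_mw):
        if m in ref_map and ref_map[m] > 0:
            drifts[f"modulation_{m:g}"] = (p - ref_map[m]) / ref_map[m]
    worst = max(abs(v) for v in drifts.values())
    return {"drifts": drifts, "max_abs_drift": worst,
            "tolerance": tolerance, "pass": worst <= tolerance}
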