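"""Photomultiplier-tube benchmarking.

Compares paired dark/light image series acquired across a range of PMT gain
settings. The analysis yields, per gain: black-point-subtracted means and
standard deviations, SNR, a ROC-AUC separability score between light and
dark pixel distributions, and an anode-current estimate from the digitizer
and transimpedance-amplifier (TIA) configuration. A gain recommendation
combines the AUC plateau with high-voltage and anode-current safety limits.

For radioluminescent (tritium) reference sources, light output decays
exponentially with the tritium time constant of 17.75 years; historical
light-response means are rescaled by that decay factor before comparison so
only excess decline is attributed to the PMT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import FrameSequence

TRITIUM_TIME_CONSTANT_YEARS = 17.75


@dataclass
class GainSweep:
    """Paired dark/light frame series per gain, plus digitizer configuration.

    ``tia_gain`` is the transimpedance gain in A/V, ``adc_volts`` the ADC
    full-scale voltage and ``adc_levels`` the grayscale full scale, so that
    anode current = mean_grayscale * (adc_volts / adc_levels) * tia_gain.
    """

    gains: list
    dark_series: dict
    light_series: dict
    tia_gain: float = 100e-6
    adc_volts: float = 1.0
    adc_levels: int = 2048
    temperature: float | None = None
    hv_map: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if 0 not in self.gains and 0.0 not in self.gains:
            raise ValueError("GainSweep must include a zero-gain dark entry")
        missing = [g for g in self.gains
                   if g not in self.dark_series or g not in self.light_series]
        if missing:
            raise ValueError(f"dark/light series missing for gains {missing}")


def _analysis_frame(series: FrameSequence, whole_series: bool) -> np.ndarray:
    """Middle frame by default: start/stop frames can carry shutter artifacts."""
    data = np.asarray(series.data, dtype=float)
    if whole_series:
        return data.reshape(-1)
    return data[data.shape[0] // 2].reshape(-1)


def black_point(sweep: GainSweep, *, whole_series: bool = False) -> float:
    """Digitizer offset: mean pixel value of the zero-gain dark response."""
    zero = 0 if 0 in sweep.dark_series else 0.0
    if zero not in sweep.dark_series:
        raise ValueError("no zero-gain dark series: black point undefined")
    return float(np.mean(_analysis_frame(sweep.dark_series[zero], whole_series)))


def snr_per_gain(
    sweep: GainSweep, black: float, *, whole_series: bool = False
) -> pd.Series:
    """SNR_g = (mu_light - mu_dark) / sigma_dark at each gain.

    Gains where the dark response has zero variance yield NaN (undefined),
    never infinity.
    """
    out = {}
    for g in sweep.gains:
        dark = _analysis_frame(sweep.dark_series[g], whole_series) - black
        light = _analysis_frame(sweep.light_series[g], whole_series) - black
        sd = float(np.std(dark, ddof=1))
        out[g] = (float(np.mean(light)) - float(np.mean(dark))) / sd if sd > 0 else np.nan
    return pd.Series(out, name="snr")


def roc_auc(light: np.ndarray, dark: np.ndarray) -> float:
    """Probability a random light pixel exceeds a random dark pixel.

    Computed via the Mann-Whitney rank statistic with midrank tie handling,
    so ties contribute 1/2. Being a rank statistic, the result is invariant
    under any strictly monotone transform of the pixel values.
    """
    light = np.asarray(light, float).ravel()
    dark = np.asarray(dark, float).ravel()
    if light.size == 0 or dark.size == 0:
        raise ValueError("both pixel classes must be non-empty")
    ranks = rankdata(np.concatenate([light, dark]))
    r_light = ranks[: light.size].sum()
    u = r_light - light.size * (light.size + 1) / 2.0
    return float(u / (light.size * dark.size))


def roc_auc_per_gain(
    sweep: GainSweep, black: float, *, whole_series: bool = False
) -> pd.Series:
    """ROC-AUC separating light from dark pixel values at each gain."""
    out = {}
    for g in sweep.gains:
        dark = _analysis_frame(sweep.dark_series[g], whole_series) - black
        light = _analysis_frame(sweep.light_series[g], whole_series) - black
        out[g] = roc_auc(light, dark)
    return pd.Series(out, name="roc_auc")


def anode_current(
    mean_pixel: float, *, adc_volts: float, adc_levels: float, tia_gain: float
) -> float:
    """Estimated anode current (A) from a raw mean grayscale value.

    I = mu_pixel * (ADC_V / ADC_levels) * TIA_gain. Linear in mu_pixel.
    """
    if adc_levels <= 0 or tia_gain <= 0 or adc_volts <= 0:
        raise ValueError("ADC/TIA configuration values must be positive")
    return float(mean_pixel) * (adc_volts / adc_levels) * tia_gain


def tritium_decay_factor(interval_years: float) -> float:
    """Expected light-output decay factor k = exp(-d / 17.75) after d years."""
    if interval_years < 0:
        raise ValueError("interval must be non-negative")
    return math.exp(-interval_years / TRITIUM_TIME_CONSTANT_YEARS)


@dataclass
class PMTReport:
    """Per-gain benchmark table plus the black point and a recommendation."""

    table: pd.DataFrame  # index: gain; columns below
    black_point: float
    recommended_gain: float | None = None
    recommendation_reason: str = ""

    COLUMNS = ("mean_dark", "sd_dark", "mean_light", "sd_light",
               "snr", "roc_auc", "anode_current_A")


def analyze_sweep(sweep: GainSweep, *, whole_series: bool = False) -> PMTReport:
    """Full per-gain benchmark: black point, moments, SNR, AUC, anode current.

    Dark/light means and SDs are black-point subtracted; the anode-current
    estimate uses the *raw* light mean since the offset current flows too.
    """
    black = black_point(sweep, whole_series=whole_series)
    rows = []
    for g in sweep.gains:
        dark = _analysis_frame(sweep.dark_series[g], whole_series) - black
        light = _analysis_frame(sweep.light_series[g], whole_series) - black
        sd_dark = float(np.std(dark, ddof=1))
        rows.append({
            "gain": g,
            "mean_dark": float(np.mean(dark)),
            "sd_dark": sd_dark,
            "mean_light": float(np.mean(light)),
            "sd_light": float(np.std(light, ddof=1)),
            "snr": (float(np.mean(light)) - float(np.mean(dark))) / sd_dark
                   if sd_dark > 0 else np.nan,
            "roc_auc": roc_auc(light, dark),
            "anode_current_A": anode_current(
                float(np.mean(light)) + black,
                adc_volts=sweep.adc_volts, adc_levels=sweep.adc_levels,
                tia_gain=sweep.tia_gain),
        })
    table = pd.DataFrame(rows).set_index("gain")
    return PMTReport(table=table, black_point=black)


def recommend_gain(
    report: PMTReport,
    hv_map: dict,
    hv_max: float,
    anode_limit: float,
    *,
    plateau_frac: float = 0.995,
    exclude_zero_gain: bool = True,
) -> tuple[float | None, str]:
    """Smallest gain on the AUC plateau that respects HV and current limits.

    The plateau is operationalized as AUC >= ``plateau_frac`` of the sweep
    maximum. Admissible gains require HV <= 0.8 * ``hv_max`` (headroom below
    the tube's absolute maximum) and anode current <= ``anode_limit``. When
    the plateau lies entirely outside the admissible range the admissible
    gain with the highest AUC is returned instead. Returns ``(gain,
    reason)``; ``gain`` is None with an explanatory reason only when no
    setting is admissible at all.
    """
    tab = report.table
    if exclude_zero_gain:
        tab = tab[tab.index > 0]
    missing = [g for g in tab.index if g not in hv_map]
    if missing:
        raise ValueError(f"hv_map missing gains {missing}")
    if len(tab) == 0:
        return None, "empty sweep"
    reasons = []
    admissible = []
    for g in tab.index:
        if hv_map[g] > 0.8 * hv_max:
            reasons.append("HV headroom")
        elif tab.loc[g, "anode_current_A"] > anode_limit:
            reasons.append("anode current")
        else:
            admissible.append(g)
    if not admissible:
        return None, max(set(reasons), key=reasons.count)
    auc_max = tab["roc_auc"].max()
    plateau = [g for g in admissible
               if tab.loc[g, "roc_auc"] >= plateau_frac * auc_max]
    if plateau:
        return float(min(plateau)), "ok"
    best = max(admissible, key=lambda g: tab.loc[g, "roc_auc"])
    return float(best), "plateau unreachable within HV/current limits"
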