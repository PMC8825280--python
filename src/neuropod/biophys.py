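"""Fiber-optic attenuation and closed-form physiology computations.

The cut-back method measures optical output power at successively shortened
fiber lengths; attenuation in dB relative to the shortest length is
-10 log10(P(L)/P(Lmin)) and the loss coefficient alpha (dB/cm) is the
least-squares slope of attenuation against (L - Lmin).

Also housed here: bend transmission percentage, power density at the fiber
tip, gallbladder volume and emptying, gastric emptying, membrane capacitance
from the voltage-step current transient, and glutamate concentration from a
plate-reader standard curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CutbackSeries",
    "LossFit",
    "fit_loss",
    "bend_transmission",
    "power_density",
    "gallbladder_volume",
    "emptying_pct",
    "gastric_emptying_pct",
    "membrane_capacitance",
    "normalized_current",
    "glutamate_concentration",
]


@dataclass(frozen=True)
class CutbackSeries:
    """(length, output power) pairs from a cut-back measurement."""

    lengths_cm: np.ndarray
    power_mw: np.ndarray
    geometry: str = "straight"

    def __post_init__(self):
        L = np.asarray(self.lengths_cm, dtype=float)
        P = np.asarray(self.power_mw, dtype=float)
        object.__setattr__(self, "lengths_cm", L)
        object.__setattr__(self, "power_mw", P)
        if L.size != P.size:
            raise ValueError("lengths and powers must have equal length")
        if L.size < 2:
            raise ValueError("need at least two cut-back points")
        if not np.all(np.diff(L) > 0):
            raise ValueError("lengths must be strictly increasing")
        if np.any(P <= 0):
            raise ValueError("output powers must be positive")


@dataclass(frozen=True)
class LossFit:
    """Fitted attenuation: alpha in dB/cm plus intercept and residuals."""

    alpha_db_per_cm: float
    intercept_db: float
    residuals_db: np.ndarray
    n_points: int
    geometry: str = "straight"


def fit_loss(series: CutbackSeries, robust: bool = False) -> LossFit:
    """Fit the attenuation coefficient from a cut-back series.

    Attenuation is computed in dB relative to the shortest length and
    regressed on (L - Lmin) by ordinary least squares (the conventional
    cut-back analysis); ``robust=True`` uses the Theil-Sen slope instead.
    """
    x = series.lengths_cm - series.lengths_cm[0]
    attn = -10.0 * np.log10(series.power_mw / series.power_mw[0])
    if robust:
        slope, intercept, _, _ = stats.theilslopes(attn, x)
    else:
        slope, intercept = np.polyfit(x, attn, 1)
    resid = attn - (slope * x + intercept)
    return LossFit(
        alpha_db_per_cm=float(slope),
        intercept_db=float(intercept),
        residuals_db=resid,
        n_points=x.size,
        geometry=series.geometry,
    )


def bend_transmission(straight_mw: float, bent_mw: float) -> float:
    """Light output of a bent fiber as a percentage of the straight fiber."""
    if straight_mw <= 0:
        raise ValueError("straight-fiber power must be positive")
    return 100.0 * bent_mw / straight_mw


def power_density(power_mw: float, core_diameter_um: float = 230.0) -> float:
    """Optical intensity at the fiber tip in mW/mm^2 over the core area."""
    if core_diameter_um <= 0:
        raise ValueError("core diameter must be positive")
    radius_mm = core_diameter_um / 2000.0
    return power_mw / (math.pi * radius_mm**2)


def gallbladder_volume(length_mm: float, width_mm: float, depth_mm: float) -> float:
    """Ellipsoid-approximation gallbladder volume in microliters: l*w*d*pi/6."""
    return length_mm * width_mm * depth_mm * math.pi / 6.0


def emptying_pct(pre: float, post: float) -> float:
    """Percent change from pre- to post-infusion volume: 100*(pre-post)/pre."""
    if pre <= 0:
        raise ValueError("pre-infusion volume must be positive")
    return 100.0 * (pre - post) / pre


def gastric_emptying_pct(pre_g: float, post_g: float) -> float:
    """Gastric emptying as percent volume remaining: 100 * post / pre."""
    if pre_g <= 0:
        raise ValueError("pre-weight must be positive")
    return 100.0 * post_g / pre_g


def membrane_capacitance(tau_ms: float, i0_pa: float, de_mv: float) -> float:
    """C_m = tau * I0 / dE; with ms, pA and mV the result is in pF."""
    if de_mv == 0:
        raise ValueError("voltage step dE must be nonzero")
    return tau_ms * i0_pa / de_mv


def normalized_current(i_max_pa: float, c_m_pf: float) -> float:
    """Maximum current normalized to cell capacitance (pA/pF)."""
    if c_m_pf <= 0:
        raise ValueError("capacitance must be positive")
    return i_max_pa / c_m_pf


def glutamate_concentration(
    sample_reads,
    control_reads,
    standards,
) -> dict:
    """Interpolate glutamate concentrations from a plate-reader standard curve.

    ``sample_reads`` is per-well absorbance reads (wells x reads, typically 9
    reads per well, e.g. an experimental triplicate); ``control_reads`` are
    the no-enzyme control reads; ``standards`` is a sequence of
    (concentration, absorbance) pairs spanning the corrected absorbances.

    Per well: corrected = mean(sample reads) - mean(control reads); the
    concentration comes from the least-squares line fitted through the
    standards.  Wells whose corrected absorbance falls outside the standard
    range are flagged as extrapolated.
    """
    sample = np.atleast_2d(np.asarray(sample_reads, dtype=float))
    control_mean = float(np.mean(np.asarray(control_reads, dtype=float)))
    std = np.asarray(standards, dtype=float)
    if std.ndim != 2 or std.shape[0] < 2:
        raise ValueError("need at least two (concentration, absorbance) standards")
    conc_std, abs_std = std[:, 0], std[:, 1]
    if np.ptp(abs_std) == 0:
        raise ValueError("degenerate standards: identical absorbances")
    slope, intercept = np.polyfit(conc_std, abs_std, 1)
    if slope == 0:
        raise ValueError("degenerate standard curve: zero slope")
    corrected = sample.mean(axis=1) - control_mean
    conc = (corrected - intercept) / slope
    extrapolated = (corrected < abs_std.min()) | (corrected > abs_std.max())
    return {
        "corrected_absorbance": corrected,
        "concentration": conc,
        "mean_concentration": float(conc.mean()),
        "extrapolated": extrapolated,
        "curve": {"slope": float(slope), "intercept": float(intercept)},
    }
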