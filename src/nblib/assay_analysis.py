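"""Quantitative assay analysis: CD melt fitting, thermal reversibility,
four-parameter-logistic binding fits, positivity ratios, and scratch-assay
healing rates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingFit",
    "BindingSeries",
    "MeltCurve",
    "MeltFit",
    "NoTransitionError",
    "WoundSeries",
    "absorbance_ratio",
    "fit_binding_curve",
    "fit_two_state_melt",
    "fraction_folded",
    "molar_ellipticity",
    "reversibility",
    "wound_healing_rate",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)


class NoTransitionError(ValueError):
    """Raised when a melt curve shows no resolvable unfolding transition."""


def molar_ellipticity(
    raw_mdeg: float | np.ndarray,
    pathlength_cm: float,
    concentration_M: float,
    n_residues: int,
) -> float | np.ndarray:
    """Mean-residue molar ellipticity, deg cm^2 dmol^-1.

    [theta] = raw / (10 * pathlength * molar concentration * residue count).
    """
    if pathlength_cm <= 0 or concentration_M <= 0 or n_residues <= 0:
        raise ValueError("pathlength, concentration and residue count must be > 0")
    denom = 10.0 * pathlength_cm * concentration_M * n_residues
    if isinstance(raw_mdeg, (list, tuple, np.ndarray)):
        return np.asarray(raw_mdeg, dtype=float) / denom
    return raw_mdeg / denom


@dataclass
class MeltCurve:
    """Temperature scan of CD signal (ellipticity)."""

    temperatures: np.ndarray
    signal: np.ndarray
    metadata: dict | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.shape != self.signal.shape:
            raise ValueError("temperature and signal arrays must align")
        if len(self.temperatures) < 8:
            raise ValueError("need at least 8 points spanning the transition")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    tm: float
    slope: float
    folded_baseline: tuple[float, float]  # intercept, slope
    unfolded_baseline: tuple[float, float]
    fraction_folded: np.ndarray
    clipped: np.ndarray
    residual_sd: float
    vant_hoff_dH: float  # informational; J/mol

    def as_dict(self) -> dict:
        return {
            "tm_C": self.tm,
            "transition_slope": self.slope,
            "folded_baseline": list(self.folded_baseline),
            "unfolded_baseline": list(self.unfolded_baseline),
            "residual_sd": self.residual_sd,
            "vant_hoff_dH_J_per_mol": self.vant_hoff_dH,
        }


def _two_state(T, tm, s, af, bf, au, bu):
    f = 1.0 / (1.0 + np.exp((T - tm) / s))
    return (af + bf * T) * f + (au + bu * T) * (1.0 - f)


def fit_two_state_melt(
    curve: MeltCurve, min_amplitude_over_noise: float = 5.0
) -> MeltFit:
    """Nonlinear least-squares fit of a two-state sigmoid with linear baselines.

    Tm is initialized at the temperature of steepest numerical gradient, so
    the fit is deterministic for given data.
    """
    T, y = curve.temperatures, curve.signal
    n_edge = max(3, len(T) // 8)
    lo_fit = np.polyfit(T[:n_edge], y[:n_edge], 1)
    hi_fit = np.polyfit(T[-n_edge:], y[-n_edge:], 1)
    noise = max(
        float(np.std(y[:n_edge] - np.polyval(lo_fit, T[:n_edge]))),
        float(np.std(y[-n_edge:] - np.polyval(hi_fit, T[-n_edge:]))),
    )
    amplitude = abs(float(np.mean(y[:n_edge]) - np.mean(y[-n_edge:])))
    if amplitude <= 1e-12 or amplitude < min_amplitude_over_noise * noise:
        raise NoTransitionError(
            f"no transition detected: amplitude {amplitude:.3g} vs noise "
            f"{noise:.3g}"
        )

    grad = np.gradient(y, T)
    tm0 = float(T[np.argmax(np.abs(grad))])
    p0 = [tm0, 2.0, lo_fit[1], lo_fit[0], hi_fit[1], hi_fit[0]]
    try:
        popt, _ = curve_fit(_two_state, T, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise NoTransitionError(f"two-state fit failed to converge: {exc}") from exc
    tm, s, af, bf, au, bu = (float(v) for v in popt)
    if s < 0:  # absorb sign: 1/(1+exp) with negative slope flips baselines
        s, (af, bf), (au, bu) = -s, (au, bu), (af, bf)
    if not (T[0] <= tm <= T[-1]):
        raise NoTransitionError(f"fitted midpoint {tm:.1f} outside data range")
    fractions, clipped = fraction_folded(curve, (af, bf), (au, bu))
    resid = y - _two_state(T, tm, s, af, bf, au, bu)
    tm_K = tm + 273.15
    dH = GAS_CONSTANT * tm_K**2 / abs(s)  # van't Hoff estimate, informational
    return MeltFit(
        tm=tm,
        slope=s,
        folded_baseline=(af, bf),
        unfolded_baseline=(au, bu),
        fraction_folded=fractions,
        clipped=clipped,
        residual_sd=float(np.std(resid)),
        vant_hoff_dH=dH,
    )


def fraction_folded(
    curve: MeltCurve,
    folded_baseline: tuple[float, float],
    unfolded_baseline: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """f(T) = (theta - theta_U) / (theta_F - theta_U), clipped to [0, 1].

    Returns (fractions, clipped mask).  Baselines are (intercept, slope).
    """
    T, y = curve.temperatures, curve.signal
    theta_f = folded_baseline[0] + folded_baseline[1] * T
    theta_u = unfolded_baseline[0] + unfolded_baseline[1] * T
    denom = theta_f - theta_u
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("degenerate baselines: folded == unfolded")
    raw = (y - theta_u) / denom
    clipped_mask = (raw < 0) | (raw > 1)
    return np.clip(raw, 0.0, 1.0), clipped_mask


def reversibility(
    pre_signal: float | Sequence[float],
    post_signal: float | Sequence[float],
    baseline: float = 0.0,
) -> float:
    """Percent folded-signal amplitude recovered after cooling.

    Amplitudes are baseline-corrected means of the 25 degC point sets.
    """
    pre_amp = float(np.mean(np.asarray(pre_signal, dtype=float))) - baseline
    post_amp = float(np.mean(np.asarray(post_signal, dtype=float))) - baseline
    if pre_amp == 0:
        raise ValueError("pre-melt amplitude is zero")
    return 100.0 * post_amp / pre_amp


@dataclass
class BindingSeries:
    """Concentration / response series from an indirect ELISA titration."""

    concentrations: np.ndarray  # molar
    response: np.ndarray  # A450
    control_response: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentrations.shape != self.response.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")


@dataclass
class BindingFit:
    """4PL fit; EC50 is reported as the apparent KD of the titration."""

    ec50: float  # molar
    hill: float
    bottom: float
    top: float
    ci95: tuple[float, float]  # bootstrap CI on EC50, molar
    reliable: bool
    note: str = ""

    @property
    def ec50_nM(self) -> float:
        return self.ec50 * 1e9

    def as_dict(self) -> dict:
        return {
            "ec50_M": self.ec50,
            "ec50_nM": self.ec50_nM,
            "hill": self.hill,
            "bottom": self.bottom,
            "top": self.top,
            "ci95_M": list(self.ci95),
            "reliable": self.reliable,
            "note": self.note,
        }


def _four_pl(logc, log_ec50, hill, bottom, top):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_ec50 - logc)))


def _fit_4pl_once(logc: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    bottom0, top0 = float(np.min(y)), float(np.max(y))
    half = (bottom0 + top0) / 2.0
    idx = int(np.argmin(np.abs(y - half)))
    p0 = [float(logc[idx]), 1.0, bottom0, top0]
    popt, _ = curve_fit(_four_pl, logc, y, p0=p0, maxfev=20000)
    return tuple(float(v) for v in popt)  # type: ignore[return-value]


def fit_binding_curve(
    series: BindingSeries,
    n_bootstrap: int = 200,
    seed: int = 0,
    min_relative_range: float = 0.05,
) -> BindingFit:
    """Four-parameter logistic fit with a seeded residual-bootstrap 95% CI.

    Non-saturating or flat series are returned flagged unreliable rather than
    raising.
    """
    if len(series.concentrations) < 6:
        raise ValueError("need at least 6 concentrations")
    order = np.argsort(series.concentrations)
    conc = series.concentrations[order]
    y = series.response[order]
    logc = np.log(conc)
    y_range = float(np.max(y) - np.min(y))
    scale = max(abs(float(np.max(y))), 1e-12)
    if y_range < min_relative_range * scale:
        return BindingFit(
            ec50=float("nan"), hill=float("nan"),
            bottom=float(np.min(y)), top=float(np.max(y)),
            ci95=(float("nan"), float("nan")), reliable=False,
            note="response range below noise floor",
        )
    try:
        log_ec50, hill, bottom, top = _fit_4pl_once(logc, y)
    except RuntimeError:
        return BindingFit(
            float("nan"), float("nan"), float(np.min(y)), float(np.max(y)),
            (float("nan"), float("nan")), False, "fit failed to converge",
        )
    fitted = _four_pl(logc, log_ec50, hill, bottom, top)
    resid = y - fitted
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        y_b = fitted + rng.choice(resid, size=len(resid), replace=True)
        try:
            b_log_ec50, *_ = _fit_4pl_once(logc, y_b)
        except RuntimeError:
            continue
        boots.append(b_log_ec50)
    if boots:
        lo, hi = np.percentile(np.exp(boots), [2.5, 97.5])
    else:
        lo = hi = float("nan")
    ec50 = float(np.exp(log_ec50))
    reliable = bool(conc[0] <= ec50 <= conc[-1]) and bottom < top
    note = "" if reliable else "EC50 outside concentration range or inverted fit"
    return BindingFit(ec50, hill, bottom, top, (float(lo), float(hi)), reliable, note)


def absorbance_ratio(
    experimental: float, control: float, positivity_threshold: float = 2.0
) -> tuple[float, bool]:
    """Experimental/control signal ratio; positive iff strictly above threshold."""
    if control <= 0:
        raise ValueError("control signal must be positive")
    ratio = experimental / control
    return ratio, ratio > positivity_threshold


@dataclass
class WoundSeries:
    """Wound areas by timepoint (hours); must include the 0 h reference."""

    areas: dict[float, float]

    def __post_init__(self) -> None:
        if 0 not in self.areas and 0.0 not in self.areas:
            raise ValueError("missing 0 h wound area")
        if self.areas[0] <= 0:
            raise ValueError("0 h wound area must be positive")


def wound_healing_rate(series: WoundSeries) -> dict[float, tuple[float, bool]]:
    """Healing rate per timepoint: (area0 - area_t) / area0 * 100.

    Returns time -> (percent, wound_grew flag); negative rates are permitted
    and flagged.
    """
    area0 = series.areas[0]
    out: dict[float, tuple[float, bool]] = {}
    for t, area in sorted(series.areas.items()):
        rate = (area0 - area) / area0 * 100.0
        out[t] = (rate, rate < 0)
    return out
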