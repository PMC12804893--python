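"""Mechanistic H2 dry-deposition-velocity model.

The uptake of atmospheric H2 by soil is expressed as a deposition velocity
v_d (mm/s) from a series-resistance combination of a diffusive-barrier
conductance g_i (snow, canopy) and a soil conductance g_s:

    1 / v_d = 1 / g_i + 1 / g_s,            1 / g_i = 1 / g_snow + 1 / g_cano

g_s is the analytic uptake conductance of a semi-infinite reactive soil
layer,

    g_s = sqrt( k_m * f(s) * g(Ts) * h(SOC) * D_s ),

where k_m (s^-1) is the maximum microbial oxidation rate, D_s (m^2/s) the
soil gas diffusivity of H2, and f, g, h the dimensionless sensitivities to
moisture saturation, soil temperature and soil organic carbon. The moisture
sensitivity

    f(s) = (1/N) * (s - s_ws)^beta1 * (s_opt - s)^beta2

vanishes outside (s_ws, s_opt); the thresholds are obtained from two water
potentials (the water-stress threshold psi_ws and the optimum psi_opt)
through the soil's retention curve, so that a single pair of potentials
applies across soil textures. N normalizes max f = 1 at the analytic argmax
s* = (beta1 * s_opt + beta2 * s_ws) / (beta1 + beta2).

An unbounded conductance (no barrier) is represented by ``math.inf``,
contributing zero resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import CalibrationError, ConfigurationError, InputError
from .soil_water import RetentionCurve, psi_to_saturation

#: Standard atmosphere, Pa.
P_REF = 101325.0
#: Reference temperature for the free-air diffusivity, K (0 degC).
T_REF_K = 273.15

#: No-barrier sentinel: an unbounded conductance has zero resistance.
UNBOUNDED = math.inf


@dataclass(frozen=True)
class TempParams:
    """Gaussian temperature-response parameters.

    g(Ts) = exp(-(Ts - t_opt)^2 / (2 width^2)) for Ts > cutoff, else 0;
    normalized to 1 at the optimum. Units degC.
    """

    t_opt: float = 27.0
    width: float = 12.0
    cutoff: float = -5.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ConfigurationError("temperature response width must be > 0")
        if self.cutoff >= self.t_opt:
            raise ConfigurationError("freezing cutoff must lie below t_opt")


@dataclass(frozen=True)
class UptakeParams:
    """All tunable parameters of the deposition-velocity model.

    Attributes
    ----------
    psi_ws : float
        Water-stress threshold, MPa (default -100; the legacy literature
        value -3 is a supported configuration).
    psi_opt : float
        Optimum water potential, MPa (wet zero of f through the retention
        curve).
    beta1, beta2 : float
        Shape exponents of the moisture response (> 0).
    k_m : float
        Maximum H2 oxidation rate, s^-1 (> 0); normally set by calibration.
    soc_a, soc_b : float
        Intercept and slope of the linear SOC fit to maximum oxidation
        rates, min^-1 g^-1 and min^-1 g^-1 per %SOC.
    soc_ref : float
        Reference SOC (%) at which the relative (normalized) modulation
        h equals 1.
    soc_mode : str
        'relative' (default; h = (a + b soc)/(a + b soc_ref), used inside
        g_s so calibrated magnitudes are comparable), 'absolute'
        (h = a + b soc, the raw fit), or 'off' (h = 1).
    snow_porosity : float
        Porosity of the snow pack for the snow conductance.
    temp_params : TempParams
        Parameters of the Gaussian temperature response.
    d_free_air : float
        Free-air diffusivity of H2 at 0 degC and 1 atm, m^2/s.
    canopy_conductance : float
        Canopy conductance, m/s; ``math.inf`` means no canopy barrier.
    """

    psi_ws: float = -100.0
    psi_opt: float = -0.03
    beta1: float = 1.0
    beta2: float = 1.0
    k_m: float = 1e-4
    soc_a: float = 0.00387
    soc_b: float = 0.0024
    soc_ref: float = 2.0
    soc_mode: str = "relative"
    snow_porosity: float = 0.645
    temp_params: TempParams = field(default_factory=TempParams)
    d_free_air: float = 6.1e-5
    canopy_conductance: float = UNBOUNDED

    def __post_init__(self) -> None:
        if not self.psi_ws < self.psi_opt <= 0:
            raise ConfigurationError("require psi_ws < psi_opt <= 0")
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ConfigurationError("beta exponents must be positive")
        if not self.k_m > 0:
            raise ConfigurationError("k_m must be positive")
        if not 0 < self.snow_porosity < 1:
            raise ConfigurationError("snow porosity must be in (0, 1)")
        if self.soc_mode not in ("relative", "absolute", "off"):
            raise ConfigurationError(
                "soc_mode must be 'relative', 'absolute' or 'off'"
            )
        if not self.d_free_air > 0:
            raise ConfigurationError("d_free_air must be positive")
        if not self.canopy_conductance > 0:
            raise ConfigurationError(
                "canopy conductance must be positive (inf = no barrier)"
            )

    def with_km(self, k_m: float) -> "UptakeParams":
        return replace(self, k_m=k_m)


# ---------------------------------------------------------------------------
# Sensitivity functions


def moisture_thresholds(
    params: UptakeParams, curve: RetentionCurve
) -> tuple[float, float]:
    """Map (psi_ws, psi_opt) to saturations (s_ws, s_opt) via the curve.

    Potentials wetter than the air-entry potential map to s = 1.
    """
    s_ws = _sat_or_one(params.psi_ws, curve)
    s_opt = _sat_or_one(params.psi_opt, curve)
    if s_ws >= s_opt:
        raise ConfigurationError(
            f"s_ws = {s_ws:.4f} >= s_opt = {s_opt:.4f}: the moisture window "
            "is empty for this retention curve"
        )
    return s_ws, s_opt


def _sat_or_one(psi: float, curve: RetentionCurve) -> float:
    if psi > curve.psi_e:
        return 1.0
    return float(psi_to_saturation(psi, curve))


def f_moisture_raw(s, s_ws: float, s_opt: float, beta1: float, beta2: float):
    """Normalized moisture response on saturation thresholds.

    Zero outside (s_ws, s_opt); normalized so the maximum, at the analytic
    argmax s* = (beta1 s_opt + beta2 s_ws)/(beta1 + beta2), equals 1.
    """
    if s_ws >= s_opt:
        raise ConfigurationError("s_ws must be below s_opt")
    s = np.asarray(s, dtype=float)
    s_star = (beta1 * s_opt + beta2 * s_ws) / (beta1 + beta2)
    norm = (s_star - s_ws) ** beta1 * (s_opt - s_star) ** beta2
    inside = (s > s_ws) & (s < s_opt)
    out = np.zeros_like(s)
    si = s[inside]
    out[inside] = (si - s_ws) ** beta1 * (s_opt - si) ** beta2 / norm
    return float(out) if out.ndim == 0 else out


def f_moisture(s, params: UptakeParams, curve: RetentionCurve):
    """Moisture sensitivity f(s) in [0, 1] for a soil's retention curve."""
    s_ws, s_opt = moisture_thresholds(params, curve)
    return f_moisture_raw(s, s_ws, s_opt, params.beta1, params.beta2)


def g_temperature(t_soil, temp_params: TempParams = TempParams()):
    """Temperature sensitivity in [0, 1]: Gaussian optimum, frozen cutoff."""
    t = np.asarray(t_soil, dtype=float)
    out = np.exp(-((t - temp_params.t_opt) ** 2) / (2.0 * temp_params.width**2))
    out = np.where(t <= temp_params.cutoff, 0.0, out)
    return float(out) if out.ndim == 0 else out


def h_soc(soc, params: UptakeParams, mode: str | None = None):
    """SOC modulation of the maximum oxidation rate.

    'absolute': the linear fit a + b*soc in min^-1 g^-1 (the empirical
    relation between a soil's maximum oxidation rate and its SOC).
    'relative': that fit normalized to 1 at soc_ref, the dimensionless form
    used inside g_s. 'off': identically 1.
    """
    soc = np.asarray(soc, dtype=float)
    if np.any(soc < 0):
        raise InputError("SOC cannot be negative")
    mode = params.soc_mode if mode is None else mode
    if mode == "off":
        out = np.ones_like(soc)
    elif mode == "absolute":
        out = params.soc_a + params.soc_b * soc
    elif mode == "relative":
        out = (params.soc_a + params.soc_b * soc) / (
            params.soc_a + params.soc_b * params.soc_ref
        )
    else:
        raise ConfigurationError(f"unknown SOC mode {mode!r}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Diffusivity and conductances


def d_air(t_soil, pressure=P_REF, params: UptakeParams = None):
    """Free-air H2 diffusivity (m^2/s) at soil temperature (degC) and pressure.

    Scales the reference value by (T/T_ref)^1.75 * (P_ref/P).
    """
    d0 = params.d_free_air if params is not None else 6.1e-5
    t_k = np.asarray(t_soil, dtype=float) + T_REF_K
    out = d0 * (t_k / T_REF_K) ** 1.75 * (P_REF / np.asarray(pressure, dtype=float))
    return float(out) if out.ndim == 0 else out


def soil_diffusivity(s, porosity, t_soil=0.0, pressure=P_REF,
                     params: UptakeParams | None = None):
    """Soil gas diffusivity of H2, m^2/s (Millington-Quirk).

    D_s = D_air(T, P) * porosity^(4/3) * (1 - s)^(10/3); equivalently
    theta_a^(10/3) / porosity^2 with air-filled porosity
    theta_a = porosity * (1 - s). Zero at full saturation.
    """
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise InputError("saturation must be in [0, 1]")
    da = d_air(t_soil, pressure, params)
    out = da * np.asarray(porosity, dtype=float) ** (4.0 / 3.0) * (1.0 - s) ** (
        10.0 / 3.0
    )
    return float(out) if out.ndim == 0 else out


def conductance_soil(
    params: UptakeParams,
    s,
    t_soil,
    soc,
    porosity,
    curve: RetentionCurve,
    pressure=P_REF,
):
    """Soil uptake conductance g_s = sqrt(k_m f g h D_s), m/s.

    Zero whenever any biotic factor is zero (too dry, frozen) or the soil
    is fully water-saturated. h uses the parameter set's soc_mode.
    """
    f = f_moisture(s, params, curve)
    g = g_temperature(t_soil, params.temp_params)
    h = h_soc(soc, params)
    ds = soil_diffusivity(s, porosity, t_soil, pressure, params)
    prod = params.k_m * f * g * h * ds
    if np.any(np.asarray(prod) < 0):
        raise ConfigurationError("negative factor inside g_s")
    out = np.sqrt(prod)
    return float(out) if np.ndim(out) == 0 else out


def conductance_snow(
    snow_depth, params: UptakeParams, t_soil=0.0, pressure=P_REF
):
    """Snow-pack conductance, m/s; unbounded (inf) when no snow.

    g_snow = D_air(T, P) * snow_porosity^(4/3) / depth.
    """
    depth = np.asarray(snow_depth, dtype=float)
    if np.any(depth < 0):
        raise InputError("snow depth cannot be negative")
    da = d_air(t_soil, pressure, params)
    with np.errstate(divide="ignore"):
        out = np.where(
            depth > 0,
            da * params.snow_porosity ** (4.0 / 3.0) / np.where(depth > 0, depth, 1.0),
            UNBOUNDED,
        )
    return float(out) if out.ndim == 0 else out


def deposition_velocity(g_s, g_snow=UNBOUNDED, g_cano=UNBOUNDED):
    """Series-resistance deposition velocity, mm/s.

    1/v_d = 1/g_snow + 1/g_cano + 1/g_s, with unbounded (inf) conductances
    contributing zero resistance; v_d = 0 wherever g_s = 0. Inputs in m/s,
    output in mm/s.
    """
    g_s = np.asarray(g_s, dtype=float)
    g_snow = np.asarray(g_snow, dtype=float)
    g_cano = np.asarray(g_cano, dtype=float)
    if np.any(g_s < 0) or np.any(g_snow < 0) or np.any(g_cano < 0):
        raise InputError("conductances must be non-negative")
    resistance = _inv(g_snow) + _inv(g_cano) + _inv(g_s)
    # infinite resistance (g_s = 0) -> vd = 0; zero resistance -> unbounded
    vd = np.where(
        resistance > 0,
        1.0 / np.where(resistance > 0, resistance, 1.0),
        np.inf,
    )
    vd = vd * 1000.0  # m/s -> mm/s
    return float(vd) if vd.ndim == 0 else vd


def _inv(g):
    """Resistance of a conductance; inf (unbounded) -> 0, 0 -> inf."""
    g = np.asarray(g, dtype=float)
    with np.errstate(divide="ignore"):
        r = np.where(np.isinf(g), 0.0, np.where(g > 0, 1.0 / np.where(g > 0, g, 1.0),
                                                np.inf))
    return r


# ---------------------------------------------------------------------------
# Calibration

K_M_BOUNDS = (1e-8, 1e2)  # s^-1


def calibrate_km(
    forcing,
    params: UptakeParams,
    target_vd: float = 0.09,
    rtol: float = 1e-6,
) -> float:
    """Find k_m such that the area-weighted time-mean v_d equals target_vd.

    The global mean v_d is strictly increasing in k_m (g_s scales as
    sqrt(k_m) and the harmonic combination preserves monotonicity), so a
    bisection on log k_m converges unconditionally. Tolerance is relative
    on the achieved mean.

    Raises
    ------
    CalibrationError
        If the target is not bracketed by k_m in [1e-8, 1e2] s^-1.
    """
    from .gridsim import _grid_components  # local import: avoids cycle

    if not target_vd > 0:
        raise CalibrationError("target deposition velocity must be positive")
    biotic_ds, r_barrier, weights = _grid_components(forcing, params)

    def mean_vd_at(log_km: float) -> float:
        km = 10.0**log_km
        with np.errstate(divide="ignore"):
            g_s = np.sqrt(km * biotic_ds)
            res = r_barrier + np.where(g_s > 0, 1.0 / np.where(g_s > 0, g_s, 1.0),
                                       np.inf)
            vd = np.where(g_s > 0, 1000.0 / res, 0.0)
        return float(weights @ vd.mean(axis=1))

    lo, hi = math.log10(K_M_BOUNDS[0]), math.log10(K_M_BOUNDS[1])
    f_lo = mean_vd_at(lo) - target_vd
    f_hi = mean_vd_at(hi) - target_vd
    if f_lo > 0 or f_hi < 0:
        raise CalibrationError(
            f"target {target_vd} mm/s not bracketed by k_m in "
            f"[{K_M_BOUNDS[0]:g}, {K_M_BOUNDS[1]:g}] s^-1 "
            f"(achievable range [{f_lo + target_vd:.3g}, {f_hi + target_vd:.3g}])"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = mean_vd_at(mid)
        if abs(val - target_vd) <= rtol * target_vd:
            return 10.0**mid
        if val < target_vd:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection failed to converge")
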