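"""Soil moisture accounting: LOI/SOC, moisture conversions, retention curves,
and water-stress threshold estimation.

Water potential (psi, MPa, <= 0) is the intrinsic measure of soil water
availability; saturation s is the fraction of pore volume filled with water.
The two are linked by the soil water characteristic (retention) curve, here
a two-parameter Campbell / Brooks-Corey power law

    psi(s) = psi_e * s**(-b),

with air-entry potential psi_e < 0 and shape exponent b > 0. The water-stress
threshold psi_ws for microbial H2 oxidation is estimated as the interval
between the wettest water potential with no detected oxidation and the driest
one at which oxidation was observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError, InputError, NoBracketError

#: Mineral particle density used for porosity/bulk-density consistency, g/cm3.
PARTICLE_DENSITY = 2.65


def loi_from_weights(dry_weight: float, combusted_weight: float) -> float:
    """Loss on ignition, percent of initial dry weight.

    LOI (%) = (dry - combusted) / dry * 100.
    """
    if not dry_weight > 0:
        raise InputError("dry weight must be positive")
    if not 0 < combusted_weight <= dry_weight:
        raise InputError("combusted weight must lie in (0, dry weight]")
    return (dry_weight - combusted_weight) / dry_weight * 100.0


def soc_from_loi(loi: float) -> float:
    """Soil organic carbon (%) from loss on ignition: SOC = 0.58 * LOI."""
    if not 0.0 <= loi <= 100.0:
        raise InputError("LOI must be in [0, 100] percent")
    return 0.58 * loi


@dataclass(frozen=True)
class RetentionCurve:
    """Campbell power-law water retention: psi(s) = psi_e * s**(-b).

    psi_e is the air-entry potential (MPa, < 0; psi at full saturation) and
    b > 0 the texture-dependent shape exponent. psi is strictly decreasing
    (more negative) as the soil dries.
    """

    psi_e: float
    b: float

    def __post_init__(self) -> None:
        if not self.psi_e < 0:
            raise InputError("air-entry potential psi_e must be negative")
        if not self.b > 0:
            raise InputError("shape exponent b must be positive")

    def psi(self, s):
        """Water potential (MPa) at saturation s in (0, 1]."""
        return saturation_to_psi(s, self)

    def saturation(self, psi):
        """Saturation in (0, 1] at water potential psi <= psi_e."""
        return psi_to_saturation(psi, self)


def saturation_to_psi(s, curve: RetentionCurve):
    """psi = psi_e * s**(-b); s must be in (0, 1] (s = 0 is singular)."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise InputError("saturation must be positive (psi diverges at s = 0)")
    if np.any(s > 1):
        raise InputError("saturation cannot exceed 1")
    out = curve.psi_e * s ** (-curve.b)
    return float(out) if out.ndim == 0 else out


def psi_to_saturation(psi, curve: RetentionCurve):
    """Invert the retention curve: s = (psi / psi_e)**(-1/b).

    Requires psi <= psi_e (at or dry of air entry); wetter potentials are
    outside the power law's domain.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > curve.psi_e):
        raise InputError(
            f"psi must be <= air-entry potential ({curve.psi_e} MPa)"
        )
    out = (psi / curve.psi_e) ** (-1.0 / curve.b)
    return float(out) if out.ndim == 0 else out


def fit_retention(pairs: Sequence[tuple[float, float]]) -> RetentionCurve:
    """Fit (psi_e, b) by least squares on ln(-psi) = ln(-psi_e) - b ln(s).

    ``pairs`` are (saturation, psi) with 0 < s <= 1 and psi < 0; at least
    3 pairs with at least 2 distinct saturations are required.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InputError("need at least 3 (saturation, psi) pairs")
    s, psi = arr[:, 0], arr[:, 1]
    if np.any(s <= 0) or np.any(s > 1):
        raise InputError("saturations must be in (0, 1]")
    if np.any(psi >= 0):
        raise InputError("water potentials must be negative")
    ln_s = np.log(s)
    if np.ptp(ln_s) == 0:
        raise FitError("degenerate pairs: all saturations identical")
    A = np.vstack([np.ones_like(ln_s), -ln_s]).T
    coef, *_ = np.linalg.lstsq(A, np.log(-psi), rcond=None)
    psi_e = -float(np.exp(coef[0]))
    b = float(coef[1])
    if not b > 0:
        raise FitError(f"fitted exponent b = {b:.3g} is not positive")
    return RetentionCurve(psi_e=psi_e, b=b)


@dataclass(frozen=True)
class SoilProperties:
    """Static physical properties of one soil."""

    soil_id: str
    porosity: float
    bulk_density: float
    soc_percent: float = 0.0
    texture: str = ""
    retention: RetentionCurve | None = None

    def __post_init__(self) -> None:
        if not 0 < self.porosity < 1:
            raise InputError("porosity must be in (0, 1)")
        if not self.bulk_density > 0:
            raise InputError("bulk density must be positive")
        if self.soc_percent < 0:
            raise InputError("SOC cannot be negative")
        implied = PARTICLE_DENSITY * (1.0 - self.porosity)
        if self.bulk_density > implied * 1.05:
            warnings.warn(
                f"{self.soil_id}: bulk density {self.bulk_density} g/cm3 "
                f"exceeds {implied:.3f} implied by porosity "
                f"{self.porosity} at particle density {PARTICLE_DENSITY}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MoistureState:
    """Coupled moisture representations of one sample.

    gravimetric_w: g water per g dry soil; volumetric_theta = w * bulk
    density (water density 1 g/cm3); saturation_s = theta / porosity,
    in [0, 1]; psi: matric potential, MPa <= 0 (None when no retention
    curve is attached or s = 0, where the power law is singular).
    """

    gravimetric_w: float
    volumetric_theta: float
    saturation_s: float
    psi: float | None = None


def moisture_state(gravimetric_w: float, props: SoilProperties) -> MoistureState:
    """Derive volumetric content, saturation and (optionally) psi from w.

    theta = w * bulk_density; s = theta / porosity, clipped to [0, 1] with a
    warning if clipping occurred (water added beyond pore volume).
    """
    if gravimetric_w < 0:
        raise InputError("gravimetric water content cannot be negative")
    theta = gravimetric_w * props.bulk_density
    s = theta / props.porosity
    if s > 1.0:
        warnings.warn(
            f"saturation {s:.3f} exceeds 1; clipped (theta > porosity)",
            stacklevel=2,
        )
        s = 1.0
    psi = None
    if props.retention is not None and s > 0:
        psi = float(saturation_to_psi(s, props.retention))
    return MoistureState(
        gravimetric_w=gravimetric_w,
        volumetric_theta=theta,
        saturation_s=s,
        psi=psi,
    )


@dataclass(frozen=True)
class PsiRateObservation:
    """One incubation's water potential, oxidation rate and detection flag."""

    psi: float  # MPa, <= 0
    rate: float  # min^-1 g^-1, >= 0
    detected: bool

    def __post_init__(self) -> None:
        if self.psi > 0:
            raise InputError("water potential must be <= 0 MPa")
        if self.rate < 0:
            raise InputError("rate cannot be negative")
        if self.detected and not self.rate > 0:
            raise InputError("a detected observation must have rate > 0")


@dataclass(frozen=True)
class ThresholdInterval:
    """Bracketing interval [psi_lo, psi_hi] for the water-stress threshold.

    psi_lo is the dry bound (wettest potential with no detected oxidation),
    psi_hi the wet bound (driest potential with detected oxidation).
    """

    psi_lo: float
    psi_hi: float

    def __post_init__(self) -> None:
        if not self.psi_lo <= self.psi_hi <= 0:
            raise InputError("need psi_lo <= psi_hi <= 0")

    @property
    def width(self) -> float:
        return self.psi_hi - self.psi_lo

    def __contains__(self, psi: float) -> bool:
        return self.psi_lo <= psi <= self.psi_hi


def estimate_psi_ws(obs: Sequence[PsiRateObservation]) -> ThresholdInterval:
    """Bracket the water-stress threshold from detection/non-detection data.

    The interval runs from the highest (wettest) psi among non-detections to
    the lowest (driest) psi among detections. If replicate scatter makes the
    ranges overlap (some non-detection wetter than a detection), the
    degenerate interval at the detected bound is returned with a warning.

    Raises
    ------
    NoBracketError
        If all observations are detections, or all non-detections.
    """
    det = [o.psi for o in obs if o.detected]
    undet = [o.psi for o in obs if not o.detected]
    if not det or not undet:
        raise NoBracketError(
            "need at least one detected and one undetected observation"
        )
    psi_hi = min(det)
    psi_lo = max(undet)
    if psi_lo > psi_hi:
        warnings.warn(
            f"detection ranges overlap (non-detection at {psi_lo} MPa is "
            f"wetter than detection at {psi_hi} MPa); returning degenerate "
            "interval at the detected bound",
            stacklevel=2,
        )
        psi_lo = psi_hi
    return ThresholdInterval(psi_lo=psi_lo, psi_hi=psi_hi)


def read_psi_rate_csv(path) -> pd.DataFrame:
    """Read an observation table: sample_id, psi_mpa, rate, detected [, soil_id]."""
    df = pd.read_csv(path)
    required = {"psi_mpa", "rate", "detected"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"observation CSV missing columns: {sorted(missing)}")
    return df


def thresholds_by_group(df: pd.DataFrame, by: str = "soil_id") -> pd.DataFrame:
    """Apply estimate_psi_ws per group of an observation table."""
    rows = []
    for key, grp in df.groupby(by, sort=True):
        obs = [
            PsiRateObservation(
                psi=float(r.psi_mpa), rate=float(r.rate), detected=bool(r.detected)
            )
            for r in grp.itertuples()
        ]
        iv = estimate_psi_ws(obs)
        rows.append({by: key, "psi_lo_mpa": iv.psi_lo, "psi_hi_mpa": iv.psi_hi})
    return pd.DataFrame(rows)
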