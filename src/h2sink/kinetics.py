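"""First-order H2 oxidation kinetics from incubation headspace drawdown.

Headspace H2 in a closed bottle containing active soil decays approximately
as C(t) = C0 * exp(-k t); the rate constant k (min^-1), normalized per gram
of dry soil, is the standard proxy for the microbial H2 oxidation rate.
Measurements below the analytical detection limit are censored (dropped),
and detection is decided against killed / no-soil controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import CensoredSeriesError, InputError

#: Analytical limit of detection of the gas chromatograph, ppb.
DEFAULT_LOD_PPB = 57.0


@dataclass(frozen=True)
class IncubationSeries:
    """One bottle's headspace H2 time series plus soil/bottle metadata.

    Parameters
    ----------
    sample_id : str
        Identifier of the incubation bottle.
    times : array-like
        Sampling times in minutes, strictly increasing, at least 3 points.
    h2_ppb : array-like
        Headspace H2 mixing ratios (ppb), non-negative, same length as times.
    dry_mass : float
        Dry soil mass in the bottle, grams (> 0).
    headspace_volume : float
        Bottle headspace, mL (> 0).
    lod_ppb : float
        Concentration detection limit; points strictly below are censored.
    is_control : bool
        True for killed (autoclaved), no-soil, or air-dried control bottles.
    """

    sample_id: str
    times: np.ndarray
    h2_ppb: np.ndarray
    dry_mass: float
    headspace_volume: float = 120.0
    lod_ppb: float = DEFAULT_LOD_PPB
    is_control: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.h2_ppb, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "h2_ppb", c)
        if t.ndim != 1 or c.ndim != 1 or len(t) != len(c):
            raise InputError("times and h2_ppb must be 1-D and equally long")
        if len(t) < 3:
            raise InputError("an incubation series needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if np.any(c < 0):
            raise InputError("mixing ratios must be non-negative")
        if not self.dry_mass > 0:
            raise InputError("dry_mass must be positive")
        if not self.headspace_volume > 0:
            raise InputError("headspace_volume must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """Fitted first-order rate constant and its per-gram normalization."""

    sample_id: str
    k: float  # min^-1, >= 0
    k_se: float  # standard error of k, min^-1
    k_per_g: float  # min^-1 g(dry soil)^-1
    c0_ppb: float  # fitted initial mixing ratio
    n_used: int  # points retained after LOD censoring
    r_squared: float  # in [0, 1], on the retained points
    detected: bool  # k > 0 and k - 2 k_se > 0


def _decay(t: np.ndarray, c0: float, k: float) -> np.ndarray:
    return c0 * np.exp(-k * t)


def fit_first_order(series: IncubationSeries) -> RateEstimate:
    """Fit C(t) = C0 exp(-k t) to an above-LOD censored headspace series.

    Points strictly below the concentration detection limit are dropped; a
    series whose first point is censored, or with fewer than 3 retained
    points, is rejected. The fit is seeded by ordinary least squares on
    ln C vs t and refined by nonlinear least squares on the original scale
    (k constrained to be non-negative). ``detected`` uses a one-sided
    two-standard-error criterion.

    Raises
    ------
    CensoredSeriesError
        If fewer than 3 points remain above the LOD, or the initial point
        is below it.
    """
    keep = series.h2_ppb >= series.lod_ppb
    if not keep[0]:
        raise CensoredSeriesError(
            f"{series.sample_id}: initial point below LOD ({series.lod_ppb} ppb)"
        )
    t = series.times[keep]
    c = series.h2_ppb[keep]
    n_used = int(keep.sum())
    if n_used < 3:
        raise CensoredSeriesError(
            f"{series.sample_id}: only {n_used} points above LOD, need >= 3"
        )

    # log-linear seed: ln C = ln C0 - k t  (C >= LOD > 0 so logs are safe)
    A = np.vstack([np.ones_like(t), t]).T
    coef, *_ = np.linalg.lstsq(A, np.log(c), rcond=None)
    intercept, slope = coef

    if slope >= 0:
        # no drawdown: the constrained optimum is k = 0, C0 = mean(C)
        c0_hat = float(np.mean(c))
        resid = c - c0_hat
        dof = max(n_used - 2, 1)
        # slope SE of the log-linear fit, propagated as the scale of k
        log_resid = np.log(c) - A @ coef
        s2 = float(log_resid @ log_resid) / dof
        sxx = float(np.sum((t - t.mean()) ** 2))
        k_se = float(np.sqrt(s2 / sxx)) if sxx > 0 else np.inf
        r2 = _r_squared(c, np.full_like(c, c0_hat))
        return RateEstimate(
            sample_id=series.sample_id,
            k=0.0,
            k_se=k_se,
            k_per_g=0.0,
            c0_ppb=c0_hat,
            n_used=n_used,
            r_squared=r2,
            detected=False,
        )

    p0 = (float(np.exp(intercept)), float(-slope))
    popt, pcov = curve_fit(
        _decay, t, c, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
    )
    c0_hat, k_hat = float(popt[0]), float(popt[1])
    k_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    r2 = _r_squared(c, _decay(t, c0_hat, k_hat))
    detected = k_hat > 0 and (k_hat - 2.0 * k_se) > 0
    return RateEstimate(
        sample_id=series.sample_id,
        k=k_hat,
        k_se=k_se,
        k_per_g=k_hat / series.dry_mass,
        c0_ppb=c0_hat,
        n_used=n_used,
        r_squared=r2,
        detected=detected,
    )


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def normalize_rate(estimate: RateEstimate, dry_mass: float) -> float:
    """Rate constant per gram dry soil, min^-1 g^-1."""
    if not dry_mass > 0:
        raise InputError("dry_mass must be positive")
    return estimate.k / dry_mass


def compare_to_controls(
    sample: RateEstimate, controls: Sequence[RateEstimate]
) -> bool:
    """True iff the sample's uptake exceeds the strongest control.

    The sample must itself be detected, and its k must exceed the largest
    control k by more than twice the pooled standard error. A tie is
    non-detection.
    """
    if len(controls) == 0:
        raise InputError("at least one control estimate is required")
    if not sample.detected:
        return False
    worst = max(controls, key=lambda e: e.k)
    pooled_se = float(np.hypot(sample.k_se, worst.k_se))
    return sample.k > worst.k + 2.0 * pooled_se


# ---------------------------------------------------------------------------
# CSV interface: one long table of observations + one metadata table


def read_incubation_csv(
    series_path: str | Path, meta_path: str | Path
) -> list[IncubationSeries]:
    """Load incubation series from a long-format CSV plus a metadata CSV.

    ``series_path`` columns: sample_id, time_min, h2_ppb.
    ``meta_path`` columns: sample_id, dry_mass_g, headspace_ml and optionally
    lod_ppb, is_control.
    """
    obs = pd.read_csv(series_path)
    meta = pd.read_csv(meta_path).set_index("sample_id")
    out: list[IncubationSeries] = []
    for sid, grp in obs.groupby("sample_id", sort=True):
        if sid not in meta.index:
            raise InputError(f"sample {sid!r} missing from metadata table")
        row = meta.loc[sid]
        grp = grp.sort_values("time_min")
        out.append(
            IncubationSeries(
                sample_id=str(sid),
                times=grp["time_min"].to_numpy(float),
                h2_ppb=grp["h2_ppb"].to_numpy(float),
                dry_mass=float(row["dry_mass_g"]),
                headspace_volume=float(row.get("headspace_ml", 120.0)),
                lod_ppb=float(row.get("lod_ppb", DEFAULT_LOD_PPB)),
                is_control=bool(row.get("is_control", False)),
            )
        )
    return out


def fit_rates_table(series: Iterable[IncubationSeries]) -> pd.DataFrame:
    """Fit every series and tabulate the estimates (one row per sample)."""
    rows = []
    for s in series:
        est = fit_first_order(s)
        rows.append(
            {
                "sample_id": est.sample_id,
                "k": est.k,
                "k_se": est.k_se,
                "k_per_g": est.k_per_g,
                "c0_ppb": est.c0_ppb,
                "n_used": est.n_used,
                "r_squared": est.r_squared,
                "detected": est.detected,
                "is_control": s.is_control,
            }
        )
    return pd.DataFrame(rows)
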