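"""Synthetic inputs for the whole pipeline: gridded forcing with climate-zone
structure, noisy incubation drawdown series, water-potential/rate observation
tables, and retention-curve samples.

All generators are pure functions of (spec, seed). One master seed is
expanded into independent substreams (forcing moisture, temperature, SOC,
zone layout, ...) so that adding a generator never perturbs existing
outputs. Soil-moisture saturation follows an AR(1) process on the logit
scale, back-transformed to respect [0, 1] without hard clipping; soil
temperature is a seasonal cosine plus white noise; snow appears only in
continental/polar cold seasons; SOC is static and lognormal per zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError, InputError
from .gridsim import ZONES, ForcingGrid
from .kinetics import DEFAULT_LOD_PPB, IncubationSeries
from .soil_water import PsiRateObservation, RetentionCurve

# Per-zone climatology defaults: mean saturation, logit-scale sd, AR(1)
# coefficient; mean soil temperature (degC), seasonal amplitude, noise sd;
# SOC lognormal median (%) and log-sd; nominal latitude band (deg) for
# cos-latitude area weights; Campbell retention parameters and porosity by
# dominant texture.
ZONE_DEFAULTS: Mapping[str, dict] = {
    "tropical": dict(
        s_mean=0.60, s_sd=0.35, s_rho=0.985, s_cell_sd=0.4,
        t_mean=26.0, t_amp=2.0, t_sd=1.5,
        soc_med=1.8, soc_sigma=0.5, lat=(0.0, 20.0),
        psi_e=-0.0030, b=6.0, porosity=0.50, snow_max=0.0,
    ),
    "desert": dict(
        s_mean=0.08, s_sd=0.45, s_rho=0.98, s_cell_sd=0.9,
        t_mean=26.0, t_amp=9.0, t_sd=2.5,
        soc_med=0.3, soc_sigma=0.6, lat=(15.0, 35.0),
        psi_e=-0.0012, b=3.5, porosity=0.40, snow_max=0.0,
    ),
    "semi-arid": dict(
        s_mean=0.17, s_sd=0.45, s_rho=0.98, s_cell_sd=0.8,
        t_mean=20.0, t_amp=10.0, t_sd=2.0,
        soc_med=0.8, soc_sigma=0.5, lat=(20.0, 40.0),
        psi_e=-0.0018, b=4.0, porosity=0.43, snow_max=0.0,
    ),
    "temperate": dict(
        s_mean=0.45, s_sd=0.35, s_rho=0.985, s_cell_sd=0.4,
        t_mean=12.0, t_amp=9.0, t_sd=2.0,
        soc_med=2.5, soc_sigma=0.4, lat=(35.0, 55.0),
        psi_e=-0.0035, b=5.0, porosity=0.48, snow_max=0.05,
    ),
    "continental": dict(
        s_mean=0.50, s_sd=0.30, s_rho=0.985, s_cell_sd=0.4,
        t_mean=4.0, t_amp=16.0, t_sd=2.5,
        soc_med=3.5, soc_sigma=0.4, lat=(45.0, 60.0),
        psi_e=-0.0035, b=5.0, porosity=0.48, snow_max=0.4,
    ),
    "polar": dict(
        s_mean=0.55, s_sd=0.25, s_rho=0.99, s_cell_sd=0.4,
        t_mean=-6.0, t_amp=14.0, t_sd=2.0,
        soc_med=5.0, soc_sigma=0.5, lat=(60.0, 80.0),
        psi_e=-0.0030, b=4.5, porosity=0.50, snow_max=0.8,
    ),
}

#: Rough land-area mix north of 60 degrees S.
DEFAULT_ZONE_MIX: Mapping[str, float] = {
    "tropical": 0.20,
    "desert": 0.14,
    "semi-arid": 0.14,
    "temperate": 0.20,
    "continental": 0.22,
    "polar": 0.10,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible synthetic forcing grid.

    ``zone_mix`` gives the fraction of cells per climate zone (sums to 1);
    ``zone_params`` can override any ZONE_DEFAULTS entry per zone;
    ``drying_trend`` is the saturation offset subtracted from desert and
    semi-arid mean saturation in the 'late' epoch, mimicking a multidecadal
    drying of the arid zones.
    """

    seed: int = 0
    n_cells: int = 100
    n_times: int = 8760
    dt_hours: float = 1.0
    zone_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_MIX)
    )
    zone_params: Mapping[str, dict] = field(default_factory=dict)
    drying_trend: float = 0.05
    drying_zones: tuple[str, ...] = ("desert", "semi-arid")

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_times <= 0:
            raise InputError("n_cells and n_times must be positive")
        mix = dict(self.zone_mix)
        unknown = set(mix) - set(ZONES)
        if unknown:
            raise InputError(f"unknown zones in zone_mix: {sorted(unknown)}")
        if any(v < 0 for v in mix.values()):
            raise InputError("zone_mix fractions must be non-negative")
        total = sum(mix.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise InputError(f"zone_mix must sum to 1 (got {total})")

    def params_for(self, zone: str) -> dict:
        p = dict(ZONE_DEFAULTS[zone])
        p.update(self.zone_params.get(zone, {}))
        return p


def _zone_counts(spec: SyntheticSpec) -> dict[str, int]:
    """Largest-remainder apportionment of n_cells across zones."""
    mix = {z: spec.zone_mix.get(z, 0.0) for z in ZONES}
    raw = {z: mix[z] * spec.n_cells for z in ZONES}
    counts = {z: int(np.floor(raw[z])) for z in ZONES}
    remainder = spec.n_cells - sum(counts.values())
    order = sorted(ZONES, key=lambda z: raw[z] - counts[z], reverse=True)
    for z in order[:remainder]:
        counts[z] += 1
    return counts


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _ar1(
    rng: np.random.Generator, n_cells: int, n_times: int, mu, sd, rho
) -> np.ndarray:
    """Stationary AR(1) panels with per-row mean/sd/lag-1 coefficient."""
    mu = np.broadcast_to(np.asarray(mu, float), (n_cells,))[:, None]
    sd = np.broadcast_to(np.asarray(sd, float), (n_cells,))[:, None]
    rho = np.broadcast_to(np.asarray(rho, float), (n_cells,))[:, None]
    eps_sd = sd * np.sqrt(1.0 - rho**2)
    x = np.empty((n_cells, n_times))
    x[:, 0:1] = mu + sd * rng.standard_normal((n_cells, 1))
    shocks = rng.standard_normal((n_cells, n_times))
    for t in range(1, n_times):
        x[:, t : t + 1] = (
            mu
            + rho * (x[:, t - 1 : t] - mu)
            + eps_sd * shocks[:, t : t + 1]
        )
    return x


def gen_forcing(spec: SyntheticSpec, epoch: str = "early") -> ForcingGrid:
    """Generate a zone-structured forcing grid, bit-reproducible per seed.

    ``epoch`` is 'early' (baseline) or 'late' (the drying_trend offset is
    applied to the arid zones' mean saturation); both epochs share every
    random substream, so they differ only through the prescribed moisture
    shift.
    """
    if epoch not in ("early", "late"):
        raise InputError("epoch must be 'early' or 'late'")
    n, nt = spec.n_cells, spec.n_times
    ss = np.random.SeedSequence(spec.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("layout", "moisture", "temperature", "soc"), ss.spawn(4)
        )
    }

    counts = _zone_counts(spec)
    zones = np.concatenate([[z] * counts[z] for z in ZONES if counts[z] > 0])
    zones = zones[streams["layout"].permutation(n)]

    # nominal latitude per cell -> cos-latitude area weight
    lat_lo = np.array([spec.params_for(z)["lat"][0] for z in zones])
    lat_hi = np.array([spec.params_for(z)["lat"][1] for z in zones])
    lat = lat_lo + (lat_hi - lat_lo) * streams["layout"].random(n)
    weights = np.cos(np.deg2rad(lat))
    weights /= weights.sum()

    def zvec(key: str) -> np.ndarray:
        return np.array([spec.params_for(z)[key] for z in zones], dtype=float)

    s_mean = zvec("s_mean")
    if epoch == "late" and spec.drying_trend != 0.0:
        drying = np.isin(zones, spec.drying_zones)
        s_mean = np.where(
            drying, np.clip(s_mean - spec.drying_trend, 0.01, 0.99), s_mean
        )

    # per-cell climatological offset within a zone (dry vs wet sites),
    # drawn before the AR(1) shocks so epochs share identical draws
    cell_offset = zvec("s_cell_sd") * streams["moisture"].standard_normal(n)
    x = _ar1(
        streams["moisture"],
        n,
        nt,
        _logit(s_mean) + cell_offset,
        zvec("s_sd"),
        zvec("s_rho"),
    )
    saturation = _sigmoid(x)

    hours = np.arange(nt) * spec.dt_hours
    phase = 2.0 * np.pi * hours / 8760.0  # one year = 8760 h
    t_soil = (
        zvec("t_mean")[:, None]
        - zvec("t_amp")[:, None] * np.cos(phase)[None, :]
        + zvec("t_sd")[:, None] * streams["temperature"].standard_normal((n, nt))
    )

    # snow: cold-season cover in zones with snow_max > 0, depth growing
    # linearly with frost intensity and saturating at snow_max
    snow_max = zvec("snow_max")[:, None]
    snow_depth = np.where(
        (snow_max > 0) & (t_soil < 0.0),
        snow_max * np.minimum(1.0, -t_soil / 10.0),
        0.0,
    )

    soc = np.exp(
        np.log(zvec("soc_med"))
        + zvec("soc_sigma") * streams["soc"].standard_normal(n)
    )

    return ForcingGrid(
        cell_ids=np.arange(n),
        area_weights=weights,
        zone_labels=zones,
        times=hours,
        saturation=saturation,
        t_soil=t_soil,
        snow_depth=snow_depth,
        soc=soc,
        psi_e=zvec("psi_e"),
        b=zvec("b"),
        porosity=zvec("porosity"),
    )


def gen_incubation(
    k_true: float,
    c0: float = 550.0,
    noise_sd: float = 5.0,
    times: Sequence[float] | None = None,
    lod: float = DEFAULT_LOD_PPB,
    seed: int = 0,
    sample_id: str = "synthetic",
    dry_mass: float = 2.0,
    is_control: bool = False,
) -> IncubationSeries:
    """Noisy exponential headspace drawdown: C(t) = c0 e^(-k t) + noise.

    Gaussian measurement noise, floored at 0 ppb; k_true in min^-1 and
    times in minutes (default: 12 points over 2 hours).
    """
    if k_true < 0:
        raise InputError("k_true cannot be negative")
    if times is None:
        times = np.linspace(0.0, 120.0, 12)
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    c = c0 * np.exp(-k_true * t)
    if noise_sd > 0:
        c = c + noise_sd * rng.standard_normal(t.shape)
    c = np.maximum(c, 0.0)
    return IncubationSeries(
        sample_id=sample_id,
        times=t,
        h2_ppb=c,
        dry_mass=dry_mass,
        lod_ppb=lod,
        is_control=is_control,
    )


def gen_psi_rate_obs(
    psi_ws_true: float,
    psi_grid: Sequence[float],
    rate_max: float = 0.01,
    noise_sd: float = 0.0,
    detection_floor: float = 1e-6,
    seed: int = 0,
) -> list[PsiRateObservation]:
    """Observation table around a known water-stress threshold.

    The modeled rate ramps linearly from 0 at psi_ws_true to rate_max at
    psi = 0; optional Gaussian noise is added and negatives are floored at
    0. An observation is 'detected' when its rate clears detection_floor.
    The grid must bracket the threshold so that at least one detection and
    one non-detection result.
    """
    psi = np.asarray(psi_grid, dtype=float)
    if np.any(psi > 0) or psi_ws_true >= 0:
        raise InputError("water potentials must be negative")
    if psi.min() >= psi_ws_true or psi.max() <= psi_ws_true:
        raise GenerationError(
            "psi_grid must span the true threshold on both sides"
        )
    rng = np.random.default_rng(seed)
    activity = np.clip((psi - psi_ws_true) / (0.0 - psi_ws_true), 0.0, None)
    rate = rate_max * activity
    if noise_sd > 0:
        rate = rate + noise_sd * rng.standard_normal(psi.shape)
    rate = np.maximum(rate, 0.0)
    detected = rate > detection_floor
    if not detected.any() or detected.all():
        raise GenerationError(
            "generated table does not bracket the threshold after noise"
        )
    return [
        PsiRateObservation(psi=float(p), rate=float(r), detected=bool(d))
        for p, r, d in zip(psi, rate, detected)
    ]


def gen_retention_pairs(
    curve: RetentionCurve,
    n: int = 20,
    noise: float = 0.0,
    seed: int = 0,
    s_min: float = 0.02,
) -> list[tuple[float, float]]:
    """(saturation, psi) samples from a curve, log-spaced in s.

    ``noise`` is a multiplicative lognormal factor on -psi (e.g. 0.05 for
    5% scatter).
    """
    if n < 3:
        raise InputError("need at least 3 pairs")
    rng = np.random.default_rng(seed)
    s = np.geomspace(s_min, 1.0, n)
    psi = curve.psi_e * s ** (-curve.b)
    if noise > 0:
        psi = psi * np.exp(noise * rng.standard_normal(n))
    return [(float(si), float(pi)) for si, pi in zip(s, psi)]
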