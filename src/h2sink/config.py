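"""YAML run configuration with strict key validation.

Keys carry their units in the name (psi_ws_mpa, target_vd_mm_s). Unknown
keys are rejected rather than silently ignored, so typos cannot produce a
run with hidden defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthetic import SyntheticSpec
from .uptake import UNBOUNDED, TempParams, UptakeParams

_PARAM_KEYS = {
    "psi_ws_mpa": "psi_ws",
    "psi_opt_mpa": "psi_opt",
    "beta1": "beta1",
    "beta2": "beta2",
    "k_m_per_s": "k_m",
    "soc_intercept_min1_g1": "soc_a",
    "soc_slope_min1_g1_per_pct": "soc_b",
    "soc_ref_pct": "soc_ref",
    "soc_mode": "soc_mode",
    "snow_porosity": "snow_porosity",
    "d_free_air_m2_s": "d_free_air",
    "canopy_conductance_m_s": "canopy_conductance",
}
_TEMP_KEYS = {"t_opt_c": "t_opt", "width_c": "width", "cutoff_c": "cutoff"}
_SPEC_KEYS = (
    "seed",
    "n_cells",
    "n_times",
    "dt_hours",
    "zone_mix",
    "zone_params",
    "drying_trend",
    "drying_zones",
)
_TOP_KEYS = {"params", "temperature", "synthetic", "target_vd_mm_s", "log_level"}


def _check_keys(block: dict, allowed, where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown keys in {where}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


def params_from_dict(block: dict, temp_block: dict | None = None) -> UptakeParams:
    """Build UptakeParams from unit-suffixed YAML keys."""
    _check_keys(block, _PARAM_KEYS, "params")
    kwargs = {_PARAM_KEYS[k]: v for k, v in block.items()}
    if kwargs.get("canopy_conductance") in ("none", None):
        kwargs["canopy_conductance"] = UNBOUNDED
    if temp_block is not None:
        _check_keys(temp_block, _TEMP_KEYS, "temperature")
        kwargs["temp_params"] = TempParams(
            **{_TEMP_KEYS[k]: v for k, v in temp_block.items()}
        )
    return UptakeParams(**kwargs)


def spec_from_dict(block: dict) -> SyntheticSpec:
    _check_keys(block, _SPEC_KEYS, "synthetic")
    if "drying_zones" in block:
        block = {**block, "drying_zones": tuple(block["drying_zones"])}
    return SyntheticSpec(**block)


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    params: UptakeParams = field(default_factory=UptakeParams)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    target_vd_mm_s: float = 0.09
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, "top level")
        params = params_from_dict(
            raw.get("params", {}), raw.get("temperature")
        )
        spec = spec_from_dict(raw.get("synthetic", {}))
        return cls(
            params=params,
            synthetic=spec,
            target_vd_mm_s=float(raw.get("target_vd_mm_s", 0.09)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def resolved(self) -> dict:
        """The full parameter set as a plain dict (for logging/reports)."""
        params = dataclasses.asdict(self.params)
        if params["canopy_conductance"] == UNBOUNDED:
            params["canopy_conductance"] = "none"
        spec = dataclasses.asdict(self.synthetic)
        spec["zone_mix"] = dict(spec["zone_mix"])
        spec["drying_zones"] = list(spec["drying_zones"])
        return {
            "params": params,
            "synthetic": spec,
            "target_vd_mm_s": self.target_vd_mm_s,
            "log_level": self.log_level,
        }
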