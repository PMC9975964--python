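"""Run configuration: schema, defaults, validation, loading.

A run is described by one flat YAML (or plain dict) document: the grid, the
seasonal calendar, the point source, generator settings, one block per
scenario (emission scale, monthly means, population year, energy and climate
summaries), the ERFs, and the attainment targets.  Every random stage draws
from the single required top-level ``seed``.
"""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Any

import yaml

from . import ahmedabad
from .grids import MONTHS

__all__ = ["default_config", "load_config", "validate_config", "config_hash", "ConfigError"]

SEASON_NAMES = ("winter", "pre-monsoon", "monsoon", "post-monsoon")


class ConfigError(ValueError):
    """Configuration failed validation; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def default_config() -> dict[str, Any]:
    """The bundled demo configuration: a 32×32 grid, the three study
    scenarios with published monthly means, and the default ERFs/targets."""
    scenarios = []
    emission_scale = {"baseline_2018": 1.0, "bau_2030": 1.06, "ma_2030": 0.0}
    pop_year = {"baseline_2018": "2018", "bau_2030": "2030", "ma_2030": "2030"}
    for label in ahmedabad.SCENARIOS:
        energy = ahmedabad.ENERGY[label]
        climate = ahmedabad.CLIMATE[label]
        scenarios.append(
            {
                "label": label,
                "emission_scale": emission_scale[label],
                "population_year": pop_year[label],
                "monthly_means": dict(ahmedabad.MONTHLY_PM25[label]),
                "monthly_sd": dict(ahmedabad.MONTHLY_PM25_SD[label]),
                "energy": {
                    "tpp_supply": energy.tpp_supply,
                    "surat_supply": energy.surat_supply,
                    "renewable_supply": energy.renewable_supply,
                    "cooling_demand": energy.cooling_demand,
                    "added_cool_roof_area_km2": energy.added_cool_roof_area_km2,
                },
                "climate": {
                    "average_temperature_c": climate.average_temperature_c,
                    "wind_speed_10m": climate.wind_speed_10m,
                    "relative_humidity_2m": climate.relative_humidity_2m,
                },
            }
        )
    return {
        "seed": 42,
        "scenarios": scenarios,
        "grid": {"n_rows": 32, "n_cols": 32, "cell_area_km2": 4.2},
        "calendar": {"winter": 3, "pre-monsoon": 3, "monsoon": 4, "post-monsoon": 2},
        "background": {"correlation_length": 3.0},
        # plume sized so the source adds roughly 10% of the city mean at
        # baseline scale; a generator knob, not a measured quantity
        "source": {"row": 18, "col": 14, "monthly_contribution": 70.0, "decay_length": 4.0},
        "population": {"concentration_gradient_weight": 1.0},
        "populations": {
            "2018": {
                "total_0_99": ahmedabad.POPULATION["2018"].total_0_99,
                "total_25_99": ahmedabad.POPULATION["2018"].total_25_99,
                "total_30_99": ahmedabad.POPULATION["2018"].total_30_99,
            },
            "2030": {
                "total_0_99": ahmedabad.POPULATION["2030"].total_0_99,
                "total_25_99": ahmedabad.POPULATION["2030"].total_25_99,
                "total_30_99": ahmedabad.POPULATION["2030"].total_30_99,
            },
        },
        "baseline_mortality": {"rate_per_100k": 684.21, "age_band": "30_99"},
        "monitors": {
            "n_monitors": 10,
            "noise_sd": 5.0,
            "days_per_month": 30,
            "bias_by_season": {
                "winter": 0.30,
                "pre-monsoon": 0.25,
                "monsoon": 0.20,
                "post-monsoon": 0.005,
            },
        },
        "reference_scenario": "baseline_2018",
        "bau_scenario": "bau_2030",
        "erfs": "default",
        "targets": "default",
    }


def load_config(path) -> dict[str, Any]:
    """Load a YAML config file and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, other: dict) -> None:
    for key, value in other.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def validate_config(cfg: dict[str, Any]) -> list[str]:
    """Return every violation found (empty list means the config is valid)."""
    errors: list[str] = []

    seed = cfg.get("seed")
    if not isinstance(seed, int):
        errors.append("seed: a top-level integer seed is required")

    grid = cfg.get("grid", {})
    if grid.get("n_rows", 0) < 1 or grid.get("n_cols", 0) < 1:
        errors.append("grid: n_rows and n_cols must be >= 1")
    if grid.get("cell_area_km2", 4.2) <= 0:
        errors.append("grid: cell_area_km2 must be positive")

    cal = cfg.get("calendar", {})
    if set(cal) != set(SEASON_NAMES):
        errors.append(f"calendar: seasons must be exactly {SEASON_NAMES}")
    elif sum(cal.values()) != 12:
        errors.append(
            f"calendar: months represented must sum to 12, got {sum(cal.values())}"
        )

    scenarios = cfg.get("scenarios", [])
    labels = [s.get("label") for s in scenarios]
    if len(labels) != len(set(labels)):
        errors.append("scenarios: labels must be unique")
    for sc in scenarios:
        label = sc.get("label", "<unlabelled>")
        if sc.get("emission_scale", 0.0) < 0:
            errors.append(f"scenario {label}: emission_scale must be >= 0")
        means = sc.get("monthly_means", {})
        missing = [m for m in MONTHS if m not in means]
        if missing:
            errors.append(f"scenario {label}: monthly_means missing {missing}")
        elif any(means[m] < 0 for m in MONTHS):
            errors.append(f"scenario {label}: monthly_means must be >= 0")
        if sc.get("population_year") not in cfg.get("populations", {}):
            errors.append(f"scenario {label}: unknown population_year")
    ref = cfg.get("reference_scenario")
    if scenarios and ref not in labels:
        errors.append(f"reference_scenario {ref!r} is not a configured scenario")
    for sc in scenarios:
        if sc.get("label") == ref and sc.get("emission_scale") != 1.0:
            errors.append("reference (baseline) scenario must have emission_scale 1.0")

    for year, totals in cfg.get("populations", {}).items():
        t0 = totals.get("total_0_99", 0)
        t25 = totals.get("total_25_99", 0)
        t30 = totals.get("total_30_99", 0)
        if min(t0, t25, t30) <= 0:
            errors.append(f"populations[{year}]: totals must be positive")
        elif not t30 <= t25 <= t0:
            errors.append(f"populations[{year}]: age bands must nest (30-99 <= 25-99 <= 0-99)")

    if cfg.get("baseline_mortality", {}).get("rate_per_100k", 0) <= 0:
        errors.append("baseline_mortality: rate_per_100k must be positive")

    src = cfg.get("source", {})
    n_rows, n_cols = grid.get("n_rows", 0), grid.get("n_cols", 0)
    if not (0 <= src.get("row", -1) < n_rows and 0 <= src.get("col", -1) < n_cols):
        errors.append("source: location must lie inside the grid")
    if src.get("decay_length", 0) <= 0:
        errors.append("source: decay_length must be positive")

    mon = cfg.get("monitors", {})
    for season, bias in mon.get("bias_by_season", {}).items():
        if bias >= 1.0:
            errors.append(f"monitors: bias for {season} must be < 1")

    erfs = cfg.get("erfs")
    if erfs != "default":
        for block in erfs or []:
            name = block.get("name", "<unnamed>")
            family = block.get("family")
            if family == "loglinear":
                if block.get("rr_per_10", 0) <= 0:
                    errors.append(f"erf {name}: rr_per_10 must be positive")
            elif family == "gemm":
                if block.get("alpha", 1.6) <= 0 or block.get("nu", 36.8) <= 0:
                    errors.append(f"erf {name}: alpha and nu must be positive")
            else:
                errors.append(f"erf {name}: family must be 'loglinear' or 'gemm'")
    return errors


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable hash of the full configuration (provenance)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def dump_config(cfg: dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(copy.deepcopy(cfg), fh, sort_keys=False)
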