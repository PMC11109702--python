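"""Configuration objects for the synthetic register and the pipeline.

Rates are annual hazards on piecewise-constant age bands, written as
``[lo, hi, rate]`` triples with half-open intervals ``[lo, hi)`` in years.
Sex-specific hazards map ``"female"``/``"male"`` to band lists.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import yaml


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


Bands = list  # list of [lo_age, hi_age, annual_rate]


def rate_at(bands: Bands, age: float) -> float:
    """Annual hazard for an age under half-open [lo, hi) bands; 0 if uncovered."""
    for lo, hi, r in bands:
        if lo <= age < hi:
            return float(r)
    return 0.0


def _check_bands(name: str, bands: Bands, cap: float | None = None) -> None:
    for row in bands:
        if len(row) != 3:
            raise ConfigError(f"{name}: bands must be [lo, hi, rate] triples")
        lo, hi, r = row
        if not (0 <= lo < hi):
            raise ConfigError(f"{name}: band [{lo}, {hi}) is not a valid age interval")
        if not (r >= 0 and r == r and r != float("inf")):
            raise ConfigError(f"{name}: rate must be finite and non-negative")
        if cap is not None and r > cap:
            raise ConfigError(f"{name}: rate {r} exceeds {cap}")


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name}: probability must lie in [0, 1]")


DEFAULT_FERTILITY = [[15, 20, 0.10], [20, 30, 0.22], [30, 40, 0.15], [40, 50, 0.05]]
DEFAULT_MORTALITY = [[0, 1, 0.05], [1, 5, 0.010], [5, 15, 0.002],
                     [15, 50, 0.004], [50, 65, 0.012], [65, 110, 0.08]]
DEFAULT_MARRIAGE = {
    "female": [[15, 20, 0.08], [20, 25, 0.18], [25, 35, 0.10]],
    "male": [[18, 25, 0.06], [25, 35, 0.12]],
}
DEFAULT_FOSTERING = {
    "female": [[1, 16, 0.020]],
    "male": [[1, 16, 0.015]],
}
# Rough bounding box of a ~150 km^2 lakeshore strip in northern Malawi.
DEFAULT_AREA = (33.85, -10.05, 34.00, -9.85)


@dataclass
class SimConfig:
    """Parameters of the synthetic HDSS register generator.

    The defaults emulate the demographic regime the analysis assumes: a
    young, high-fertility rural population observed 2004-2017 with patrilocal
    marriage migration, divorce return-moves, child fostering toward kin
    (maternal-weighted), occasional whole-household relocations and a share
    of moves crossing the surveillance boundary.
    """

    seed: int = 0
    n_founder_households: int = 80
    area_bounds: tuple = DEFAULT_AREA  # (lon_min, lat_min, lon_max, lat_max)
    period_start: date = date(2004, 1, 1)
    period_end: date = date(2017, 12, 31)
    fertility_rate: Bands = field(default_factory=lambda: [list(b) for b in DEFAULT_FERTILITY])
    mortality_rate: Bands = field(default_factory=lambda: [list(b) for b in DEFAULT_MORTALITY])
    marriage_hazard: dict = field(default_factory=lambda: {k: [list(b) for b in v]
                                                           for k, v in DEFAULT_MARRIAGE.items()})
    divorce_hazard: float = 0.03
    patrilocality_prob: float = 0.8
    fostering_hazard: dict = field(default_factory=lambda: {k: [list(b) for b in v]
                                                            for k, v in DEFAULT_FOSTERING.items()})
    relocation_hazard: float = 0.04
    external_move_prob: float = 0.15
    survey_month: int = 7
    # secondary knobs (documented in docs/methods.md)
    return_hazard: float = 0.20          # re-entry hazard for out-migrants, per year
    polygyny_prob: float = 0.15          # chance a once-married man is eligible again
    maternal_foster_weight: float = 0.7  # weight toward maternal-kin fostering homes
    local_relocation_prob: float = 0.6   # household relocations that stay within 4 km

    def validate(self) -> "SimConfig":
        if not isinstance(self.seed, int):
            raise ConfigError("seed: must be an integer")
        if self.n_founder_households < 1:
            raise ConfigError("n_founder_households: must be >= 1")
        lon0, lat0, lon1, lat1 = self.area_bounds
        if not (lon0 < lon1 and lat0 < lat1):
            raise ConfigError("area_bounds: rectangle is degenerate")
        if abs(lon0) > 180 or abs(lon1) > 180 or abs(lat0) > 90 or abs(lat1) > 90:
            raise ConfigError("area_bounds: outside WGS84 range")
        if not self.period_start < self.period_end:
            raise ConfigError("period: start must precede end")
        _check_bands("fertility_rate", self.fertility_rate)
        _check_bands("mortality_rate", self.mortality_rate)
        for sex in ("female", "male"):
            _check_bands(f"marriage_hazard[{sex}]", self.marriage_hazard.get(sex, []))
            _check_bands(f"fostering_hazard[{sex}]", self.fostering_hazard.get(sex, []))
        for name in ("divorce_hazard", "relocation_hazard", "return_hazard"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ConfigError(f"{name}: must be finite and non-negative")
        for name in ("patrilocality_prob", "external_move_prob", "polygyny_prob",
                     "maternal_foster_weight", "local_relocation_prob"):
            _check_prob(name, getattr(self, name))
        if not 1 <= self.survey_month <= 12:
            raise ConfigError("survey_month: must be 1..12")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config field(s): {sorted(bad)}")
        kw = dict(raw)
        for key in ("period_start", "period_end"):
            if key in kw and isinstance(kw[key], str):
                kw[key] = date.fromisoformat(kw[key])
        if "area_bounds" in kw:
            kw["area_bounds"] = tuple(kw["area_bounds"])
        return cls(**kw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_start"] = self.period_start.isoformat()
        d["period_end"] = self.period_end.isoformat()
        d["area_bounds"] = list(self.area_bounds)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: study constants plus I/O paths.

    The defaults are the analysis constants: 4 km short/long cutoff, 250 m
    kin-proximity/density radius, 5 m minimum displacement, and the
    12-month-forward / 6-month-backward survey validity window.
    """

    outdir: str = "run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    cutoff_km: float = 4.0
    radius_m: float = 250.0
    min_move_m: float = 5.0
    survey_back_days: int = 183   # how far before a snapshot a survey stays valid
    survey_fwd_days: int = 366
    max_age: int = 34             # upper age for the exploratory risk curves
    stages: tuple = ("simulate", "panel", "moves", "family", "describe", "model")

    def validate(self) -> "PipelineConfig":
        if self.cutoff_km <= 0:
            raise ConfigError("cutoff_km: must be positive")
        if self.radius_m <= 0:
            raise ConfigError("radius_m: must be positive")
        if self.min_move_m < 0:
            raise ConfigError("min_move_m: must be non-negative")
        self.sim.validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(raw.pop("sim", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(sim=sim, **raw)
        # keep one seed for the whole run unless the sim block overrides it
        if "seed" not in (raw or {}):
            pass
        cfg.sim.seed = cfg.sim.seed or cfg.seed
        return cfg.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
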