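"""Configuration for the synthetic world generator."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


def _default_effect_sizes() -> dict:
    # transformed-scale coefficients (linear, quadratic) of the response
    # model used by regression-style worlds; only CP and NSR act by default
    return {
        "log1p_CP": (0.9, -0.09),
        "sqrt_NSR": (0.15, 0.0),
    }


def _default_establishment() -> dict:
    # logit-scale coefficients on standardised covariates at the
    # introduction site
    return {"intercept": 0.4, "temp_median": 0.8, "precip_median": 0.5}


@dataclass
class WorldConfig:
    """Ground-truth parameters of a synthetic introduction world.

    The defaults describe a desk-scale world: a 20 x 20 equal-area grid,
    24 country blocks in 6 realms, 60 species in 8 families, and 400
    introduction events over 1500-2000 with the historical/modern era split
    at 1903.  Covariate fields are Gaussian random fields with an
    exponential correlation length of ``grf_range_cells`` cells, which at
    the default of 8 produces the strong positive spatial autocorrelation
    seen in real gridded richness data.
    """

    n_rows: int = 20
    n_cols: int = 20
    cell_km: float = 96.486
    n_countries: int = 24
    n_species: int = 60
    n_families: int = 8
    year_range: tuple = (1500, 2000)
    grf_range_cells: float = 8.0
    era_split_year: int = 1903
    colonial_fraction: float = 0.3
    gdp_lognormal_params: tuple = (8.43, 1.0)  # ln Int$: median ~ Int$4,600
    effect_sizes: dict = field(default_factory=_default_effect_sizes)
    establishment_logit_params: dict = field(
        default_factory=_default_establishment)
    seed: int = 0
    # event-process parameters
    n_events: int = 400
    colonial_odds: float = 8.0   # pre-split odds multiplier for colonies
    gdp_log_slope: float = 1.0   # post-split log-odds slope on ln GDP(2000)
    family_alpha: float = 0.5    # Dirichlet concentration; <1 clumps families
    intensity_breaks: tuple = (1850, 1955)
    intensity_levels: tuple = (1.0, 6.0, 40.0)
    # range-building parameters
    max_intro_cells: int = 4
    spread_kernel_cells: float = 1.0
    n_ports: int = 5
    n_realms: int = 6
    sar_lambda: float = 0.6      # spatial error parameter of response noise
    noise_sd: float = 0.3        # sd of the response noise on the log scale

    def validate(self) -> "WorldConfig":
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("grid must be at least 4 x 4")
        if min(self.n_countries, self.n_species, self.n_families,
               self.n_realms, self.n_ports) < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.colonial_fraction <= 1.0):
            raise ValueError("colonial_fraction must lie in [0, 1]")
        if self.n_events > self.n_species * self.n_countries:
            raise ValueError(
                "n_events exceeds n_species x n_countries; infeasible")
        if self.year_range[0] >= self.year_range[1]:
            raise ValueError("year_range must be increasing")
        if self.grf_range_cells < 0:
            raise ValueError("grf_range_cells must be non-negative")
        if self.n_realms > self.n_countries:
            raise ValueError("cannot have more realms than countries")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("year_range", "gdp_lognormal_params", "intensity_breaks",
                    "intensity_levels"):
            if key in d:
                d[key] = tuple(d[key])
        if "effect_sizes" in d:
            d["effect_sizes"] = {k: tuple(v)
                                 for k, v in d["effect_sizes"].items()}
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path) -> "WorldConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(path.read_text())
        elif path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        return cls.from_dict(data)
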