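"""Experiment configuration: JSON schema, validation, defaults, fixtures.

A config gathers everything the planner needs — stocks, grid corners, seed
settings, robot limits, RNG seed — in one validated JSON document.  Schema
errors name the offending JSON path; unknown keys warn instead of failing so
configs stay forward-compatible.  ``generate_fixture`` produces three
deterministic config+model pairs whose simulated diagrams exhibit the named
topology (a classic banded landscape, a dual-metastable landscape, and a
nucleation-limited one) for demos and end-to-end tests.
"""

from __future__ import annotations

import json
import logging
import warnings
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .chem_core import Component, Mixture, Unit, normalize_molar
from .design import (
    CornerSpec,
    GridDesign,
    RobotSpec,
    SeedMode,
    StockSet,
)
from .simulate import PhaseModel

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Config failed schema or cross-field validation; message lists JSON paths."""


# ---------------------------------------------------------------------------
# Mixture (de)serialization shared across config, recipes and the CLI
# ---------------------------------------------------------------------------

def mixture_from_dict(raw: dict) -> Mixture:
    comps = {}
    for name, spec in (raw.get("components") or {}).items():
        comps[name] = Component(name, float(spec["conc"]), Unit(spec.get("unit", "mM")))
    return normalize_molar(Mixture(comps, raw.get("pH")))


def mixture_to_dict(m: Mixture) -> dict:
    out: dict = {"components": {
        name: {"conc": c.concentration, "unit": c.unit.value}
        for name, c in m.components.items()
    }}
    if m.pH is not None:
        out["pH"] = m.pH
    return out


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

class ComponentCfg(BaseModel):
    model_config = ConfigDict(extra="allow")
    conc: float = Field(ge=0)
    unit: Literal["mg_per_ml", "M", "mM", "percent_w_v", "fraction"] = "mM"


class MixtureCfg(BaseModel):
    model_config = ConfigDict(extra="allow")
    components: dict[str, ComponentCfg] = Field(default_factory=dict)
    pH: float | None = None

    def build(self) -> Mixture:
        return mixture_from_dict(self.model_dump())


class StocksCfg(BaseModel):
    model_config = ConfigDict(extra="allow")
    protein: ComponentCfg
    protein_name: str = "protein"
    cocktail: MixtureCfg
    primary_precipitant: str
    seed_dilution: float = Field(default=1.0, gt=0, le=1)
    seed_carrier: MixtureCfg = Field(default_factory=MixtureCfg)
    diluent: MixtureCfg = Field(default_factory=MixtureCfg)


class CornersCfg(BaseModel):
    model_config = ConfigDict(extra="allow")
    c00: tuple[float, float]
    c0n: tuple[float, float]
    cn0: tuple[float, float]
    cnn: tuple[float, float]


class GridCfg(BaseModel):
    model_config = ConfigDict(extra="allow")
    rows: int = Field(ge=2)
    cols: int = Field(ge=2)
    drop_volume_ul: float = Field(gt=0)
    corners: CornersCfg
    seed_mode: Literal["none", "premixed_in_cocktail", "separate_channel"] = "none"
    seed_fraction: float = Field(default=0.1, ge=0, lt=1)
    transpose: bool = False
    plate_capacity: int = 96


class RobotCfg(BaseModel):
    model_config = ConfigDict(extra="allow")
    precision_ul: float = Field(default=0.01, ge=0)
    min_dispense_ul: float = Field(default=0.1, ge=0)


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="allow")
    stocks: StocksCfg
    grid: GridCfg
    robot: RobotCfg = Field(default_factory=RobotCfg)
    seed: int = 0

    @model_validator(mode="after")
    def _corners_feasible(self):
        """Corner targets must be reachable from the stocks."""
        p_stock = self.stocks.protein.conc
        cocktail = self.stocks.cocktail.build()
        c_stock = cocktail.concentration_of(self.stocks.primary_precipitant)
        if c_stock <= 0:
            raise ValueError(
                f"stocks.cocktail.components must contain primary precipitant "
                f"{self.stocks.primary_precipitant!r} at positive concentration"
            )
        problems = []
        for corner in ("c00", "c0n", "cn0", "cnn"):
            protein, precip = getattr(self.grid.corners, corner)
            if protein > p_stock:
                problems.append(f"grid.corners.{corner}: protein {protein:g} "
                                f"exceeds stock {p_stock:g} mg/ml")
            if precip > c_stock:
                problems.append(f"grid.corners.{corner}: precipitant {precip:g} "
                                f"exceeds cocktail stock {c_stock:g}")
        if problems:
            raise ValueError("; ".join(problems))
        return self

    # -- builders -----------------------------------------------------------

    def stock_set(self) -> StockSet:
        s = self.stocks
        protein_stock = Mixture({s.protein_name: Component(
            s.protein_name, s.protein.conc, Unit(s.protein.unit))})
        return StockSet(
            protein_stock=protein_stock,
            protein_name=s.protein_name,
            cocktail_stock=s.cocktail.build(),
            primary_precipitant=s.primary_precipitant,
            seed_stock_dilution=s.seed_dilution,
            seed_carrier=s.seed_carrier.build(),
            diluent=s.diluent.build(),
        )

    def grid_design(self, seeded: bool | None = None) -> GridDesign:
        g = self.grid
        seed_mode = SeedMode(g.seed_mode)
        if seeded is False:
            seed_mode = SeedMode.NONE
        elif seeded is True and seed_mode == SeedMode.NONE:
            seed_mode = SeedMode.SEPARATE
        return GridDesign(
            rows=g.rows, cols=g.cols, drop_volume=g.drop_volume_ul,
            corners=CornerSpec(tuple(g.corners.c00), tuple(g.corners.c0n),
                               tuple(g.corners.cn0), tuple(g.corners.cnn)),
            seed_mode=seed_mode, seed_fraction=g.seed_fraction,
            transpose=g.transpose, plate_capacity=g.plate_capacity,
        )

    def robot_spec(self) -> RobotSpec:
        return RobotSpec(precision_ul=self.robot.precision_ul,
                         min_dispense_ul=self.robot.min_dispense_ul)


_KNOWN_TOP = {"stocks", "grid", "robot", "seed"}


def load_config(path) -> ExperimentConfig:
    """Load and validate a config; defaults are applied and logged."""
    with open(path) as fh:
        raw = json.load(fh)
    return parse_config(raw)


def parse_config(raw: dict) -> ExperimentConfig:
    unknown = sorted(set(raw) - _KNOWN_TOP)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {unknown}")
        log.warning("ignoring unknown config keys: %s", unknown)
    try:
        cfg = ExperimentConfig.model_validate(raw)
    except ValidationError as err:
        msgs = []
        for e in err.errors():
            path = ".".join(str(p) for p in e["loc"]) or "<root>"
            msgs.append(f"{path}: {e['msg']}")
        raise ConfigError("invalid config: " + "; ".join(msgs)) from err
    log.info("config loaded: grid %dx%d, drop %.2f ul, seed_mode %s, "
             "robot precision %.3g ul, min dispense %.3g ul, rng seed %d",
             cfg.grid.rows, cfg.grid.cols, cfg.grid.drop_volume_ul,
             cfg.grid.seed_mode, cfg.robot.precision_ul,
             cfg.robot.min_dispense_ul, cfg.seed)
    return cfg


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.model_dump(), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("classic", "dual_metastable", "nucleation_limited")


def generate_fixture(name: str) -> tuple[ExperimentConfig, PhaseModel]:
    """Deterministic (config, model) pair with a named diagram topology.

    * ``classic`` — salting-out only; one contiguous band per zone, ordered
      undersaturated → metastable → nucleation → precipitation along any path
      of increasing supersaturation.
    * ``dual_metastable`` — salting-in plus salting-out; solubility peaks at
      an intermediate precipitant concentration so the metastable wells split
      into two or more disjoint lobes.
    * ``nucleation_limited`` — the metastable ceiling sits just below the
      grid's maximum supersaturation, so exactly one well nucleates
      spontaneously while seeding crystallises the majority of the plate.
    """
    if name == "classic":
        raw = {
            "stocks": {
                "protein": {"conc": 64, "unit": "mg_per_ml"},
                "protein_name": "model_protein",
                "cocktail": {"components": {"ammonium_sulfate": {"conc": 4000, "unit": "mM"}},
                             "pH": 7.0},
                "primary_precipitant": "ammonium_sulfate",
            },
            "grid": {
                "rows": 8, "cols": 12, "drop_volume_ul": 2.0,
                "corners": {"c00": [24, 400], "c0n": [24, 1800],
                            "cn0": [4, 1200], "cnn": [4, 3200]},
                "seed_mode": "separate_channel", "seed_fraction": 0.1,
            },
            "seed": 0,
        }
        model = PhaseModel(S0=20.0, K=6e-7, beta=0.0,
                           sigma_nuc=2.0, sigma_shower=4.0, sigma_prec=8.0)
    elif name == "dual_metastable":
        raw = {
            "stocks": {
                "protein": {"conc": 64, "unit": "mg_per_ml"},
                "protein_name": "model_protein",
                "cocktail": {"components": {"sodium_formate": {"conc": 8000, "unit": "mM"}}},
                "primary_precipitant": "sodium_formate",
            },
            "grid": {
                "rows": 8, "cols": 12, "drop_volume_ul": 2.0,
                "corners": {"c00": [30, 400], "c0n": [30, 2900],
                            "cn0": [6, 400], "cnn": [6, 2900]},
                "seed_mode": "separate_channel", "seed_fraction": 0.1,
            },
            "seed": 0,
        }
        model = PhaseModel(S0=4.0, beta=3.071e-3, K=1.0236e-6,
                           sigma_nuc=2.0, sigma_shower=3.0, sigma_prec=4.0)
    elif name == "nucleation_limited":
        raw = {
            "stocks": {
                "protein": {"conc": 36, "unit": "mg_per_ml"},
                "protein_name": "xylanase",
                "cocktail": {"components": {"sodium_formate": {"conc": 8000, "unit": "mM"}}},
                "primary_precipitant": "sodium_formate",
            },
            "grid": {
                "rows": 8, "cols": 12, "drop_volume_ul": 2.0,
                "corners": {"c00": [16, 2600], "c0n": [16, 4400],
                            "cn0": [6, 3800], "cnn": [6, 5600]},
                "seed_mode": "premixed_in_cocktail", "seed_fraction": 0.0,
            },
            "seed": 0,
        }
        model = PhaseModel(S0=25.0, K=6.5e-8, beta=0.0,
                           sigma_nuc=2.23, sigma_shower=4.0, sigma_prec=5.0)
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return parse_config(raw), model
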