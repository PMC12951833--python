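"""Diagonal-sampling plate design.

A phase-diagram plate is defined by four corner conditions — (protein mg/ml,
primary-precipitant concentration) pairs — which the planner interpolates
bilinearly over a well grid.  Because the corners need not form a rectangle,
the well-to-well gradients can be set roughly parallel to the expected
solubility boundary (diagonal sampling), concentrating wells where zone
transitions happen instead of wasting them deep inside one zone.

Each well is realised from at most four channels: protein stock, cocktail
(the complete precipitant+buffer reagent, co-diluted as a unit), optional
seed stock, and diluent (water) absorbing the remainder.  Volumes are exact
at planning time; robot-precision rounding is applied plate-wide with the
residual pushed into the diluent channel so every drop still sums exactly to
the drop volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    WATER,
    InfeasibleTargetError,
    Mixture,
    Unit,
    VolumetricPart,
    dilute,
    mix,
    volume_for_target,
)


class DesignError(ValueError):
    """A plate design that cannot be realised at all."""


class SeedMode(str, Enum):
    NONE = "none"
    PREMIXED = "premixed_in_cocktail"
    SEPARATE = "separate_channel"


@dataclass
class StockSet:
    """The physical stocks a plate is dispensed from.

    ``protein_name`` designates which component of ``protein_stock`` is the
    protein (mg/ml); ``primary_precipitant`` designates the cocktail component
    whose final concentration the grid axes refer to.  The whole cocktail is
    co-diluted, so all its components scale together with the precipitant.
    """

    protein_stock: Mixture
    protein_name: str
    cocktail_stock: Mixture
    primary_precipitant: str
    seed_stock_dilution: float = 1.0
    seed_carrier: Mixture = field(default_factory=Mixture)
    diluent: Mixture = field(default_factory=Mixture)

    def __post_init__(self):
        if self.protein_conc <= 0:
            raise DesignError(f"protein stock {self.protein_name!r} must have positive concentration")
        if self.precipitant_conc <= 0:
            raise DesignError(
                f"cocktail must contain primary precipitant {self.primary_precipitant!r} "
                "at positive concentration"
            )
        if not (0 < self.seed_stock_dilution <= 1):
            raise DesignError("seed_stock_dilution must be in (0, 1]")

    @property
    def protein_conc(self) -> float:
        return self.protein_stock.concentration_of(self.protein_name)

    @property
    def precipitant_conc(self) -> float:
        return self.cocktail_stock.concentration_of(self.primary_precipitant)

    @property
    def precipitant_unit(self) -> Unit:
        return self.cocktail_stock.unit_of(self.primary_precipitant)


Corner = tuple[float, float]  # (protein mg/ml, precipitant concentration)


@dataclass
class CornerSpec:
    """Four corner conditions in layout order (row0,col0), (row0,colN), (rowN,col0), (rowN,colN)."""

    c00: Corner
    c0n: Corner
    cn0: Corner
    cnn: Corner

    def as_array(self) -> np.ndarray:
        return np.array([self.c00, self.c0n, self.cn0, self.cnn], dtype=float)

    def transposed(self) -> "CornerSpec":
        return CornerSpec(self.c00, self.cn0, self.c0n, self.cnn)


@dataclass
class RobotSpec:
    """Dispensing hardware limits: volume resolution and smallest reliable shot."""

    precision_ul: float = 0.01
    min_dispense_ul: float = 0.1


@dataclass
class GridDesign:
    rows: int
    cols: int
    drop_volume: float
    corners: CornerSpec
    seed_mode: SeedMode = SeedMode.NONE
    seed_fraction: float = 0.1
    transpose: bool = False
    plate_capacity: int = 96

    def __post_init__(self):
        self.seed_mode = SeedMode(self.seed_mode)
        if self.rows < 2 or self.cols < 2:
            raise DesignError("grid needs at least 2 rows and 2 columns")
        if self.drop_volume <= 0:
            raise DesignError("drop volume must be positive")
        if not (0 <= self.seed_fraction < 1):
            raise DesignError("seed_fraction must be in [0, 1)")
        if self.rows * self.cols > self.plate_capacity:
            raise DesignError(
                f"{self.rows}x{self.cols} = {self.rows * self.cols} wells exceeds "
                f"plate capacity {self.plate_capacity}"
            )


@dataclass
class WellPlan:
    """One well: its target condition and the channel volumes realising it."""

    well_label: str
    row: int
    col: int
    protein_mg_ml: float
    precipitant_conc: float
    target: Mixture
    v_protein: float
    v_cocktail: float
    v_seed: float
    v_diluent: float
    feasible: bool
    seed_dilution: float | None = None

    @property
    def total_volume(self) -> float:
        return self.v_protein + self.v_cocktail + self.v_seed + self.v_diluent


@dataclass
class PlateTotals:
    v_protein: float = 0.0
    v_cocktail: float = 0.0
    v_seed: float = 0.0
    v_diluent: float = 0.0
    protein_mass_mg: float = 0.0


@dataclass
class PlateDesign:
    stock_set: StockSet
    grid_design: GridDesign
    wells: list[WellPlan]
    totals: PlateTotals
    robot: RobotSpec = field(default_factory=RobotSpec)
    replicates: list[str] = field(default_factory=list)


def well_label(row: int, col: int) -> str:
    """'A1'-style label; rows beyond Z continue AA, AB, ..."""
    letters = ""
    r = row
    while True:
        letters = chr(ord("A") + r % 26) + letters
        r = r // 26 - 1
        if r < 0:
            break
    return f"{letters}{col + 1}"


def interpolate_corners(corners: CornerSpec, rows: int, cols: int) -> np.ndarray:
    """Bilinear interpolation of the four corners over a rows×cols grid.

    Returns an array of shape (rows, cols, 2) holding (protein, precipitant)
    per well.  Grid corners reproduce the input corners exactly and every row
    and column is affine in the well index.
    """
    if rows < 2 or cols < 2:
        raise DesignError("interpolation needs rows, cols >= 2")
    u = np.linspace(0.0, 1.0, rows)[:, None, None]
    v = np.linspace(0.0, 1.0, cols)[None, :, None]
    c00, c0n, cn0, cnn = (np.asarray(c, dtype=float) for c in
                          (corners.c00, corners.c0n, corners.cn0, corners.cnn))
    return ((1 - u) * (1 - v) * c00 + (1 - u) * v * c0n
            + u * (1 - v) * cn0 + u * v * cnn)


def _seed_volume(grid: GridDesign) -> float:
    if grid.seed_mode == SeedMode.SEPARATE:
        return grid.drop_volume * grid.seed_fraction
    return 0.0


def plan_well(target: Corner, stocks: StockSet, grid: GridDesign,
              row: int = 0, col: int = 0, *, feas_tol: float = 1e-3,
              min_dispense: float = 0.1, seed_dilution: float | None = None) -> WellPlan:
    """Channel volumes for one target (protein, precipitant) condition.

    Exact (unrounded) arithmetic: v_protein = V_d·P/P_stock, v_cocktail =
    V_d·c/C_stock (the whole cocktail co-dilutes), v_seed a fixed fraction of
    the drop when seeding runs on its own channel, diluent the remainder.  A
    negative remainder within ``feas_tol`` µl is clamped to zero (floating
    slack); a larger deficit marks the well infeasible but still returns it,
    so plate reports show the unreachable corner of phase space honestly.
    """
    protein_final, precipitant_final = target
    vd = grid.drop_volume
    v_protein = volume_for_target(protein_final, stocks.protein_conc, vd,
                                  component=stocks.protein_name)
    v_cocktail = volume_for_target(precipitant_final, stocks.precipitant_conc, vd,
                                   component=stocks.primary_precipitant)
    v_seed = _seed_volume(grid)

    remainder = vd - (v_protein + v_cocktail + v_seed)
    feasible = remainder >= -feas_tol
    v_diluent = max(remainder, 0.0) if feasible else 0.0

    for v in (v_protein, v_cocktail, v_seed, v_diluent):
        if 0 < v < min_dispense - 1e-12:
            feasible = False

    eff_dilution = seed_dilution
    if eff_dilution is None and grid.seed_mode != SeedMode.NONE:
        eff_dilution = stocks.seed_stock_dilution

    target_mix = _well_target_mixture(v_protein, v_cocktail, v_seed, v_diluent,
                                      stocks, eff_dilution)
    return WellPlan(
        well_label=well_label(row, col), row=row, col=col,
        protein_mg_ml=protein_final, precipitant_conc=precipitant_final,
        target=target_mix,
        v_protein=v_protein, v_cocktail=v_cocktail, v_seed=v_seed,
        v_diluent=v_diluent, feasible=feasible, seed_dilution=eff_dilution,
    )


def _well_target_mixture(v_protein: float, v_cocktail: float, v_seed: float,
                         v_diluent: float, stocks: StockSet,
                         seed_dilution: float | None) -> Mixture:
    parts = []
    if v_protein > 0:
        parts.append(VolumetricPart(stocks.protein_stock, v_protein))
    if v_cocktail > 0:
        parts.append(VolumetricPart(stocks.cocktail_stock, v_cocktail))
    if v_seed > 0:
        carrier = stocks.seed_carrier
        if seed_dilution is not None and not carrier.is_water():
            carrier = dilute(carrier, seed_dilution)
        parts.append(VolumetricPart(carrier, v_seed))
    if v_diluent > 0:
        parts.append(VolumetricPart(stocks.diluent, v_diluent))
    if not parts:
        return Mixture()
    return mix(parts)


def plan_plate(grid: GridDesign, stocks: StockSet,
               robot: RobotSpec | None = None) -> PlateDesign:
    """Full plate: interpolate corners, plan every well, round, total up.

    Channel volumes are rounded to the robot's resolution with the residual
    assigned to the diluent channel so each drop sums exactly to the drop
    volume; the rounding therefore perturbs water, never an active component's
    target concentration beyond resolution.  Raises :class:`DesignError` if no
    well at all is feasible.
    """
    robot = robot or RobotSpec()
    corners = grid.corners.transposed() if grid.transpose else grid.corners
    targets = interpolate_corners(corners, grid.rows, grid.cols)
    wells: list[WellPlan] = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            w = plan_well(tuple(targets[r, c]), stocks, grid, row=r, col=c,
                          min_dispense=robot.min_dispense_ul)
            _round_well(w, grid.drop_volume, robot)
            wells.append(w)

    if not any(w.feasible for w in wells):
        pmax = stocks.protein_conc
        cmax = stocks.precipitant_conc
        raise DesignError(
            "no feasible well: every target violates "
            f"P/{pmax:g} + c/{cmax:g} + seed_fraction <= 1"
        )

    totals = PlateTotals(
        v_protein=sum(w.v_protein for w in wells),
        v_cocktail=sum(w.v_cocktail for w in wells),
        v_seed=sum(w.v_seed for w in wells),
        v_diluent=sum(w.v_diluent for w in wells),
    )
    totals.protein_mass_mg = totals.v_protein * stocks.protein_conc / 1000.0
    return PlateDesign(stock_set=stocks, grid_design=grid, wells=wells,
                       totals=totals, robot=robot)


def _round_well(w: WellPlan, drop_volume: float, robot: RobotSpec) -> None:
    """Round active channels to robot precision; diluent absorbs the residual."""
    q = robot.precision_ul
    if q <= 0:
        return

    def quantize(v: float) -> float:
        # half-up to the robot resolution, then normalize the decimal so the
        # value round-trips through CSV text exactly
        return round(math.floor(v / q + 0.5) * q, 10)

    w.v_protein = quantize(w.v_protein)
    w.v_cocktail = quantize(w.v_cocktail)
    w.v_seed = quantize(w.v_seed)
    residual = round(drop_volume - (w.v_protein + w.v_cocktail + w.v_seed), 10)
    if residual < 0:
        # rounding overshot the drop: trim the largest active channel
        deficit = -residual
        if w.v_cocktail >= w.v_protein:
            w.v_cocktail -= deficit
        else:
            w.v_protein -= deficit
        residual = 0.0
    w.v_diluent = residual


#: Fixed dispense order: bulk first, protein (the reactive channel) last.
CHANNEL_ORDER = ("diluent", "cocktail", "seed", "protein")


def export_worklist(plate: PlateDesign) -> pd.DataFrame:
    """One row per (well, channel) dispense, zero volumes omitted.

    Channel order per well is diluent, cocktail, seed, protein.
    """
    stocks = plate.stock_set
    names = {
        "protein": stocks.protein_name,
        "cocktail": "cocktail",
        "seed": "seed_stock",
        "diluent": "water" if stocks.diluent.is_water() else "diluent",
    }
    rows = []
    for w in plate.wells:
        vols = {"protein": w.v_protein, "cocktail": w.v_cocktail,
                "seed": w.v_seed, "diluent": w.v_diluent}
        for channel in CHANNEL_ORDER:
            v = vols[channel]
            if v > 0:
                rows.append({"well": w.well_label, "channel": channel,
                             "source_name": names[channel],
                             "volume_ul": round(v, 6)})
    return pd.DataFrame(rows, columns=["well", "channel", "source_name", "volume_ul"])


PLATE_CSV_COLUMNS = ["well", "row", "col", "protein_mg_ml", "precipitant_conc",
                     "precipitant_unit", "v_protein_ul", "v_cocktail_ul",
                     "v_seed_ul", "v_diluent_ul", "feasible"]


def plate_to_frame(plate: PlateDesign) -> pd.DataFrame:
    unit = plate.stock_set.precipitant_unit
    rows = [{
        "well": w.well_label, "row": w.row, "col": w.col,
        "protein_mg_ml": w.protein_mg_ml,
        "precipitant_conc": w.precipitant_conc,
        "precipitant_unit": unit.value if unit else "",
        "v_protein_ul": w.v_protein, "v_cocktail_ul": w.v_cocktail,
        "v_seed_ul": w.v_seed, "v_diluent_ul": w.v_diluent,
        "feasible": w.feasible,
    } for w in plate.wells]
    return pd.DataFrame(rows, columns=PLATE_CSV_COLUMNS)


def write_plate_csv(plate: PlateDesign, path) -> None:
    plate_to_frame(plate).to_csv(path, index=False)


def read_plate_csv(path) -> list[WellPlan]:
    """Read a plate map back as bare WellPlans (targets and volumes only)."""
    df = pd.read_csv(path)
    wells = []
    for rec in df.to_dict("records"):
        unit = Unit(rec["precipitant_unit"]) if rec.get("precipitant_unit") else Unit.MM
        target = Mixture.of(
            protein=(rec["protein_mg_ml"], Unit.MG_PER_ML),
            precipitant=(rec["precipitant_conc"], unit),
        )
        wells.append(WellPlan(
            well_label=str(rec["well"]), row=int(rec["row"]), col=int(rec["col"]),
            protein_mg_ml=float(rec["protein_mg_ml"]),
            precipitant_conc=float(rec["precipitant_conc"]),
            target=target,
            v_protein=float(rec["v_protein_ul"]), v_cocktail=float(rec["v_cocktail_ul"]),
            v_seed=float(rec["v_seed_ul"]), v_diluent=float(rec["v_diluent_ul"]),
            feasible=bool(rec["feasible"]),
        ))
    return wells
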