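"""Seed-stock serial dilution and cross-matrix titration plates.

Seed-stock concentration is the main lever controlling crystal number versus
crystal size: neat stock gives dense microcrystal showers, deep dilutions
give a few large single crystals.  A cross-matrix titration crosses a serial
dilution of the seed stock (rows) against a set of crystallization conditions
(columns) on one plate, so the right dilution can be read off per condition.

Seed "concentration" here is a unitless fraction of neat — absolute particle
densities are never quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem_core import Mixture
from .design import (
    DesignError,
    GridDesign,
    CornerSpec,
    PlateDesign,
    PlateTotals,
    RobotSpec,
    SeedMode,
    StockSet,
    WellPlan,
    plan_well,
    well_label,
)

Condition = tuple[float, float]  # (protein mg/ml, precipitant conc)


@dataclass
class TitrationDesign:
    """Rows = descending dilution factors (first is neat), cols = conditions."""

    dilution_factors: list[float]
    conditions: list[Condition]

    def __post_init__(self):
        f = self.dilution_factors
        if not f:
            raise ValueError("need at least one dilution factor")
        if f[0] != 1:
            raise ValueError("first dilution factor must be 1 (neat)")
        if any(not (0 < x <= 1) for x in f):
            raise ValueError("factors must be in (0, 1]")
        if any(b >= a for a, b in zip(f, f[1:])):
            raise ValueError("factors must be strictly decreasing")


def serial_dilution(levels: int, step: float) -> list[float]:
    """[step^0, step^-1, ..., step^-(levels-1)] — e.g. 8 decade levels run
    from neat down to 1e-7."""
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if step <= 1:
        raise ValueError(f"step must be > 1, got {step}")
    return [step ** -i for i in range(levels)]


def dilution_pipetting_plan(factors: list[float], well_volume: float,
                            carryover: float | None = None) -> list[dict]:
    """Optional physical plan for a serial dilution.

    Each level after the first is made by transferring ``carryover`` µl of the
    previous level into (well_volume - carryover) µl of carrier, so the
    transfer ratio must match the step between adjacent factors.  Default
    carryover is well_volume * (f[i+1]/f[i]).
    """
    plan = [{"level": 0, "factor": 1.0, "action": f"dispense {well_volume:g} ul neat seed stock"}]
    for i in range(1, len(factors)):
        ratio = factors[i] / factors[i - 1]
        transfer = carryover if carryover is not None else well_volume * ratio
        carrier = well_volume / ratio - transfer if carryover is not None else well_volume - transfer
        plan.append({
            "level": i, "factor": factors[i],
            "action": (f"transfer {transfer:g} ul of level {i - 1} into "
                       f"{max(carrier, 0):g} ul carrier"),
        })
    return plan


def cross_matrix(dilutions: list[float], conditions: list[Condition],
                 stocks: StockSet, drop_volume: float,
                 seed_fraction: float = 0.1,
                 robot: RobotSpec | None = None,
                 plate_capacity: int = 96) -> PlateDesign:
    """Titration plate: every (dilution, condition) pair becomes one well.

    The seed channel volume is the same in every well (seed_fraction of the
    drop); only the seed-stock dilution varies by row, so the in-drop seed
    concentration is proportional to the row's factor.  Condition arithmetic
    is delegated to the regular well planner.  Duplicate conditions are
    allowed and flagged as replicates.
    """
    TitrationDesign(list(dilutions), list(conditions))  # validate
    robot = robot or RobotSpec()
    n = len(dilutions) * len(conditions)
    if n > plate_capacity:
        raise DesignError(f"{len(dilutions)}x{len(conditions)} = {n} wells "
                          f"exceeds plate capacity {plate_capacity}")

    # synthetic grid covering the condition span; only used for bookkeeping
    rows = max(len(dilutions), 2)
    cols = max(len(conditions), 2)
    span = CornerSpec(conditions[0], conditions[-1], conditions[0], conditions[-1])
    grid = GridDesign(rows=rows, cols=cols, drop_volume=drop_volume, corners=span,
                      seed_mode=SeedMode.SEPARATE, seed_fraction=seed_fraction,
                      plate_capacity=max(plate_capacity, rows * cols))

    wells: list[WellPlan] = []
    for r, factor in enumerate(dilutions):
        for c, cond in enumerate(conditions):
            w = plan_well(cond, stocks, grid, row=r, col=c,
                          min_dispense=robot.min_dispense_ul,
                          seed_dilution=factor)
            wells.append(w)

    seen: dict[Condition, int] = {}
    replicates = []
    for c, cond in enumerate(conditions):
        if cond in seen:
            replicates.append(f"column {c + 1} replicates column {seen[cond] + 1} "
                              f"(condition {cond})")
        else:
            seen[cond] = c

    totals = PlateTotals(
        v_protein=sum(w.v_protein for w in wells),
        v_cocktail=sum(w.v_cocktail for w in wells),
        v_seed=sum(w.v_seed for w in wells),
        v_diluent=sum(w.v_diluent for w in wells),
    )
    totals.protein_mass_mg = totals.v_protein * stocks.protein_conc / 1000.0
    return PlateDesign(stock_set=stocks, grid_design=grid, wells=wells,
                       totals=totals, robot=robot, replicates=replicates)
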