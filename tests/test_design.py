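"""Plate planner: corner interpolation, well volumes, rounding, worklists."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phaseplan.chem_core import InfeasibleTargetError, Mixture, VolumetricPart, mix
from phaseplan.design import (
    CornerSpec,
    DesignError,
    GridDesign,
    RobotSpec,
    SeedMode,
    StockSet,
    export_worklist,
    interpolate_corners,
    plan_plate,
    plan_well,
    read_plate_csv,
    well_label,
    write_plate_csv,
)

from conftest import make_grid, make_stocks


class TestInterpolateCorners:
    def test_two_by_two_reproduces_corners(self):
        corners = CornerSpec((20, 500), (18, 2000), (6, 1000), (4, 3000))
        grid = interpolate_corners(corners, 2, 2)
        assert grid[0, 0] == pytest.approx((20, 500))
        assert grid[0, 1] == pytest.approx((18, 2000))
        assert grid[1, 0] == pytest.approx((6, 1000))
        assert grid[1, 1] == pytest.approx((4, 3000))

    def test_center_is_mean_of_corners(self):
        corners = CornerSpec((20, 500), (18, 2000), (6, 1000), (4, 3000))
        grid = interpolate_corners(corners, 3, 3)
        assert grid[1, 1] == pytest.approx((12, 1625))  # mean of the four corners

    def test_equal_edge_protein_gives_identical_column_ladders(self):
        # equal protein on the top edge and on the bottom edge -> every column
        # carries the same protein ladder (brute-force bilinear check)
        corners = CornerSpec((20, 100), (20, 900), (5, 300), (5, 1500))
        grid = interpolate_corners(corners, 6, 7)
        for c in range(7):
            assert grid[:, c, 0] == pytest.approx(grid[:, 0, 0])

    def test_rejects_degenerate_grid(self):
        with pytest.raises(DesignError):
            interpolate_corners(CornerSpec((1, 1), (1, 1), (1, 1), (1, 1)), 1, 2)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(2, 8))
    def test_rows_and_columns_are_affine(self, rows, cols):
        corners = CornerSpec((22, 400), (17, 1800), (6, 1200), (3, 3200))
        grid = interpolate_corners(corners, rows, cols)
        for axis, n in ((0, rows), (1, cols)):
            if n < 3:
                continue
            line = np.moveaxis(grid, axis, 0)
            ends = line[0] + (line[-1] - line[0]) * np.linspace(0, 1, n).reshape(-1, 1, 1)
            assert np.max(np.abs(line - ends)) < 1e-9


class TestPlanWell:
    def test_xylanase_seed_well_closure(self, xylanase_stocks):
        """15.95 mg/ml xylanase in 4.4556 M formate uses the whole 2 ul drop:
        0.8861 ul protein + 1.1139 ul cocktail, zero diluent."""
        grid = make_grid(c00=(16, 4000), c0n=(16, 5000), cn0=(10, 4000), cnn=(10, 5000))
        w = plan_well((15.95, 4455.6), xylanase_stocks, grid)
        assert w.v_protein == pytest.approx(0.8861, abs=5e-5)
        assert w.v_cocktail == pytest.approx(1.1139, abs=5e-5)
        assert w.v_diluent == pytest.approx(0.0, abs=1e-4)
        assert w.feasible

    def test_pure_diluent_well(self, xylanase_stocks):
        w = plan_well((0, 0), xylanase_stocks, make_grid())
        assert (w.v_protein, w.v_cocktail, w.v_seed) == (0, 0, 0)
        assert w.v_diluent == pytest.approx(2.0)

    def test_protein_above_stock_raises(self, xylanase_stocks):
        with pytest.raises(InfeasibleTargetError):
            plan_well((40, 1000), xylanase_stocks, make_grid())

    def test_overfull_well_flagged_not_raised(self, xylanase_stocks):
        w = plan_well((30, 7000), xylanase_stocks, make_grid())
        assert not w.feasible

    def test_target_mixture_reproduced_by_mixing(self, xylanase_stocks):
        w = plan_well((12, 3000), xylanase_stocks, make_grid())
        remix = mix([VolumetricPart(xylanase_stocks.protein_stock, w.v_protein),
                     VolumetricPart(xylanase_stocks.cocktail_stock, w.v_cocktail),
                     VolumetricPart(xylanase_stocks.diluent, w.v_diluent)])
        assert remix.concentration_of("xylanase") == pytest.approx(12)
        assert remix.concentration_of("sodium_formate") == pytest.approx(3000)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.floats(0, 36), st.floats(0, 8000), st.floats(0, 0.4))
    def test_feasibility_frontier_predicate(self, protein, precip, seed_fraction):
        """feasible iff P/P_stock + c/C_stock + seed_fraction <= 1 (+ slack)."""
        stocks = make_stocks(36, 8000)
        grid = make_grid(seed_mode=SeedMode.SEPARATE, seed_fraction=seed_fraction)
        w = plan_well((protein, precip), stocks, grid, min_dispense=0.0)
        load = protein / 36 + precip / 8000 + seed_fraction
        if load <= 1 - 1e-6:
            assert w.feasible
        elif load > 1 + 1e-3:
            assert not w.feasible

    def test_feasibility_frontier_sweep(self):
        """Brute-force 50x50 target sweep against the closed-form predicate."""
        stocks = make_stocks(36, 8000)
        grid = make_grid(seed_mode=SeedMode.SEPARATE, seed_fraction=0.1)
        for protein in np.linspace(0, 36, 50):
            for precip in np.linspace(0, 8000, 50):
                w = plan_well((protein, precip), stocks, grid, min_dispense=0.0)
                load = protein / 36 + precip / 8000 + 0.1
                # feas_tol of 1e-3 ul on a 2 ul drop is 5e-4 in load units
                assert w.feasible == (load <= 1 + 5e-4 + 1e-12)


class TestPlanPlate:
    def test_protein_budget_low_end(self):
        """A plate consuming 15 ul of a 10 mg/ml stock holds 0.15 mg protein."""
        stocks = make_stocks(10, 4000, protein_name="concanavalin_a")
        # 30 wells at 2 ul, protein target 2.5 mg/ml -> 0.5 ul/well -> 15 ul
        grid = GridDesign(rows=5, cols=6, drop_volume=2.0,
                          corners=CornerSpec((2.5, 500), (2.5, 2000), (2.5, 500), (2.5, 2000)))
        plate = plan_plate(grid, stocks)
        assert plate.totals.v_protein == pytest.approx(15.0, abs=0.01)
        assert plate.totals.protein_mass_mg == pytest.approx(0.15, abs=1e-3)

    def test_protein_budget_high_end(self):
        """60 ul of a 64 mg/ml stock is 3.84 mg, i.e. 3.8 mg at 2 s.f."""
        stocks = make_stocks(64, 4000)
        # 96 wells at 2 ul, protein 20 mg/ml -> 0.625 ul/well -> 60 ul
        grid = GridDesign(rows=8, cols=12, drop_volume=2.0,
                          corners=CornerSpec((20, 500), (20, 2000), (20, 500), (20, 2000)))
        plate = plan_plate(grid, stocks, RobotSpec(precision_ul=0.005))
        assert plate.totals.v_protein == pytest.approx(60.0, abs=0.05)
        assert plate.totals.protein_mass_mg == pytest.approx(3.84, abs=5e-3)
        assert float(f"{plate.totals.protein_mass_mg:.2g}") == 3.8

    def test_pure_diluent_plate(self):
        stocks = make_stocks()
        grid = GridDesign(rows=2, cols=2, drop_volume=2.0,
                          corners=CornerSpec((0, 0), (0, 0), (0, 0), (0, 0)))
        plate = plan_plate(grid, stocks)
        assert plate.totals.v_protein == 0
        assert plate.totals.v_diluent == pytest.approx(8.0)

    def test_all_infeasible_raises(self):
        stocks = make_stocks(10, 1000)
        grid = GridDesign(rows=2, cols=2, drop_volume=2.0,
                          corners=CornerSpec((9, 900), (9, 900), (9, 900), (9, 900)))
        with pytest.raises(DesignError, match="no feasible well"):
            plan_plate(grid, stocks)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(2, 8), st.integers(2, 8), st.floats(1, 4),
           st.sampled_from(list(SeedMode)))
    def test_volume_conservation_after_rounding(self, rows, cols, drop, seed_mode):
        stocks = make_stocks(40, 5000)
        grid = make_grid(rows=rows, cols=cols, drop=drop,
                         c00=(18, 400), c0n=(15, 2000), cn0=(5, 900), cnn=(3, 3000),
                         seed_mode=seed_mode)
        plate = plan_plate(grid, stocks)
        for w in plate.wells:
            assert w.total_volume == pytest.approx(drop, abs=1e-9)
            assert min(w.v_protein, w.v_cocktail, w.v_seed, w.v_diluent) >= 0

    def test_corner_wells_reproduce_corner_spec(self):
        stocks = make_stocks(40, 5000)
        grid = make_grid(rows=6, cols=8, c00=(18, 400), c0n=(15, 2000),
                         cn0=(5, 900), cnn=(3, 3000))
        plate = plan_plate(grid, stocks)
        by_rc = {(w.row, w.col): w for w in plate.wells}
        for (r, c), corner in [((0, 0), (18, 400)), ((0, 7), (15, 2000)),
                               ((5, 0), (5, 900)), ((5, 7), (3, 3000))]:
            w = by_rc[(r, c)]
            assert (w.protein_mg_ml, w.precipitant_conc) == pytest.approx(corner)
            # realized volumes reproduce the corner within robot precision
            assert w.v_protein * 40 / grid.drop_volume == pytest.approx(corner[0], abs=0.01 * 40 / 2)

    def test_doubling_drop_volume_doubles_totals(self):
        stocks = make_stocks(40, 5000)
        t1 = plan_plate(make_grid(drop=2.0), stocks, RobotSpec(precision_ul=0)).totals
        t2 = plan_plate(make_grid(drop=4.0), stocks, RobotSpec(precision_ul=0)).totals
        for attr in ("v_protein", "v_cocktail", "v_seed", "v_diluent", "protein_mass_mg"):
            assert getattr(t2, attr) == pytest.approx(2 * getattr(t1, attr), rel=1e-9)


class TestWorklist:
    def test_rows_sorted_and_match_wellplans(self):
        stocks = make_stocks(40, 5000)
        plate = plan_plate(make_grid(rows=2, cols=2, c00=(10, 500), c0n=(10, 2000),
                                     cn0=(5, 500), cnn=(5, 2000)), stocks)
        wl = export_worklist(plate)
        assert list(wl.columns) == ["well", "channel", "source_name", "volume_ul"]
        a1 = wl[wl.well == "A1"]
        w = plate.wells[0]
        assert list(a1.channel) == [ch for ch, v in
                                    [("diluent", w.v_diluent), ("cocktail", w.v_cocktail),
                                     ("seed", w.v_seed), ("protein", w.v_protein)] if v > 0]
        assert a1[a1.channel == "protein"].volume_ul.iloc[0] == pytest.approx(w.v_protein)

    def test_no_seed_rows_without_seeding(self):
        stocks = make_stocks(40, 5000)
        plate = plan_plate(make_grid(seed_mode=SeedMode.NONE), stocks)
        assert not (export_worklist(plate).channel == "seed").any()

    def test_plate_csv_round_trip_bit_exact(self, tmp_path):
        stocks = make_stocks(40, 5000)
        plate = plan_plate(make_grid(seed_mode=SeedMode.SEPARATE), stocks)
        path = tmp_path / "plate.csv"
        write_plate_csv(plate, path)
        wells = read_plate_csv(path)
        assert len(wells) == len(plate.wells)
        for a, b in zip(plate.wells, wells):
            assert (a.v_protein, a.v_cocktail, a.v_seed, a.v_diluent) == \
                   (b.v_protein, b.v_cocktail, b.v_seed, b.v_diluent)
            assert a.well_label == b.well_label and a.feasible == b.feasible


def test_well_labels():
    assert well_label(0, 0) == "A1"
    assert well_label(7, 11) == "H12"
    assert well_label(26, 0) == "AA1"
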