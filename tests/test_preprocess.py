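"""Tests for grid construction, axis alignment, liver reconstruction, and IO."""

import numpy as np
import pandas as pd
import pytest

from wspfit.likelihood import PSEUDO_LEVEL, CountGrid
from wspfit.model import FixedEffectDesign
from wspfit.preprocess import (
    CellTable,
    align_axis,
    bin_coordinates,
    build_count_grid,
    read_cell_table,
    reconstruct_liver_pseudocells,
)


def make_cortex_cells(n_per_stratum=2, n_bins=100, seed=0):
    """Dense synthetic cortex-like design: 6 genes, 2 cell types, 4 mice
    (2 per age), hemisphere x age fixed factors, every bin occupied."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(6)]
    rows = []
    i = 0
    for mouse, age in [("m1", 0), ("m2", 0), ("m3", 1), ("m4", 1)]:
        for hemi in (0, 1):
            for ct in ("glut", "gaba"):
                for b in range(n_bins):
                    for _ in range(n_per_stratum):
                        row = dict(
                            cell=f"c{i}", bin=b, cell_type=ct, hemisphere=hemi,
                            age=age, mouse=mouse,
                        )
                        for g in genes:
                            row[g] = int(rng.poisson(2.0))
                        rows.append(row)
                        i += 1
    return CellTable(
        data=pd.DataFrame(rows), genes=genes, coord_cols=None, bin_col="bin",
        cell_type_col="cell_type", factor_cols=["hemisphere", "age"],
        random_col="mouse",
    )


def make_liver_cells(seed=0):
    """Liver-like design: 6 genes, 1 cell type, 10 mice at 4 ZTs (2,2,3,3),
    8 zone bins, every bin occupied."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(6)]
    mice = {f"m{i + 1}": zt for i, zt in enumerate(
        ["ZT0", "ZT0", "ZT6", "ZT6", "ZT12", "ZT12", "ZT12", "ZT18", "ZT18", "ZT18"]
    )}
    rows = []
    i = 0
    for mouse, zt in mice.items():
        for b in range(8):
            for _ in range(3):
                row = dict(cell=f"c{i}", bin=b, ZT=zt, mouse=mouse)
                for g in genes:
                    row[g] = int(rng.poisson(4.0))
                rows.append(row)
                i += 1
    return CellTable(
        data=pd.DataFrame(rows), genes=genes, coord_cols=None, bin_col="bin",
        factor_cols=[], random_col="mouse",
    )


class TestBuildCountGrid:
    def test_cortex_design_combinatorics(self):
        cells = make_cortex_cells()
        design = FixedEffectDesign(factors=("hemisphere", "age"))
        grid = build_count_grid(cells, design, axis=100)
        assert grid.n_potential_rows == 24000
        # each mouse observed at one age: half the real-mouse rows are empty
        assert grid.n_empty_rows == 9600

    def test_liver_design_combinatorics(self):
        cells = make_liver_cells()
        design = FixedEffectDesign(
            time_factor="ZT", time_levels=("ZT0", "ZT6", "ZT12", "ZT18")
        )
        grid = build_count_grid(cells, design, axis=8)
        assert grid.n_potential_rows == 2112
        assert grid.n_filled_rows == 672

    def test_total_counts_conserved_per_gene(self):
        cells = make_cortex_cells(n_per_stratum=1)
        design = FixedEffectDesign(factors=("hemisphere", "age"))
        grid = build_count_grid(cells, design, axis=100)
        real = grid.data[grid.data["random_level"] != PSEUDO_LEVEL]
        for g in cells.genes:
            assert (
                real[real["gene"] == g]["count"].sum()
                == cells.data[g].sum()
            )

    def test_row_count_is_exact_product(self):
        cells = make_liver_cells()
        design = FixedEffectDesign(
            time_factor="ZT", time_levels=("ZT0", "ZT6", "ZT12", "ZT18")
        )
        grid = build_count_grid(cells, design, axis=8)
        assert len(grid.data) == 6 * 1 * 4 * 11 * 8

    def test_pseudo_level_is_mean_log_linked_count(self):
        cells = make_cortex_cells(n_per_stratum=1, n_bins=5)
        design = FixedEffectDesign(factors=("hemisphere", "age"))
        grid = build_count_grid(cells, design, axis=5)
        df = grid.data
        g, ct, combo, b = "g0", "glut", df["interaction"].iloc[0], 2
        sel = df[(df["gene"] == g) & (df["cell_type"] == ct)
                 & (df["interaction"] == combo) & (df["bin"] == b) & (~df["empty"])]
        real = sel[sel["random_level"] != PSEUDO_LEVEL]["count"]
        pseudo = sel[sel["random_level"] == PSEUDO_LEVEL]["count"].iloc[0]
        assert pseudo == round(np.expm1(np.log1p(real).mean()))

    def test_unknown_factor_level_errors(self):
        cells = make_liver_cells()
        cells.data.loc[0, "ZT"] = "ZT99"
        design = FixedEffectDesign(
            time_factor="ZT", time_levels=("ZT0", "ZT6", "ZT12", "ZT18")
        )
        with pytest.raises(ValueError):
            build_count_grid(cells, design, axis=8)


class TestIO:
    def test_cell_table_round_trip(self, tmp_path):
        cells = make_liver_cells(seed=3)
        path = tmp_path / "cells.csv"
        cells.to_csv(path)
        back = read_cell_table(
            path, genes=cells.genes, coord_cols=None, bin_col="bin",
            factor_cols=[], random_col="mouse",
        )
        pd.testing.assert_frame_equal(
            back.data, cells.data, check_dtype=False
        )

    def test_grid_round_trip(self, tmp_path):
        cells = make_liver_cells()
        design = FixedEffectDesign(
            time_factor="ZT", time_levels=("ZT0", "ZT6", "ZT12", "ZT18")
        )
        grid = build_count_grid(cells, design, axis=8)
        path = tmp_path / "grid.csv"
        grid.to_csv(path)
        back = CountGrid.from_csv(path, combos=grid.combos)
        assert back.n_potential_rows == grid.n_potential_rows
        assert back.n_empty_rows == grid.n_empty_rows
        a = grid.data.sort_values(["gene", "cell_type", "interaction", "random_level", "bin"])
        b = back.data.sort_values(["gene", "cell_type", "interaction", "random_level", "bin"])
        assert np.array_equal(a["count"].to_numpy(), b["count"].to_numpy())

    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        back = read_cell_table(path, genes=["g"], coord_cols=None, bin_col="bin")
        assert len(back) == 0

    def test_schema_mismatch_names_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"cell": ["a"], "x": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_cell_table(path, genes=["g"], coord_cols=("x", "y"))


def make_layered_cells(slope=0.0, curvature=0.0, a=0.0, seed=0, n=400):
    """Synthetic curved cortical layers y = -c (x - a)^2 + b + offset."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for layer, offset in [("L6", 0.0), ("L5", 1.0), ("L4", 2.0), ("L23", 3.0)]:
        x = rng.uniform(-5, 5, n)
        y = slope * x - curvature * (x - a) ** 2 + offset + rng.normal(0, 0.01, n)
        for xi, yi in zip(x, y):
            rows.append(dict(cell=f"c{i}", x=xi, y=yi, layer=layer, g=1))
            i += 1
    return CellTable(data=pd.DataFrame(rows), genes=["g"], coord_cols=("x", "y"))


class TestAlignAxis:
    def test_level_layers_identity_rotation(self):
        cells = make_layered_cells(slope=0.0, curvature=0.0)
        out = align_axis(cells, reference_layer="L4", anchor_layer="L5",
                         layer_col="layer", n_bins=50)
        assert out.bin_col == "bin"
        assert out.data["bin"].between(0, 49).all()
        # deeper layers land in lower bins than superficial ones
        m6 = out.data[out.data["layer"] == "L6"]["bin"].mean()
        m23 = out.data[out.data["layer"] == "L23"]["bin"].mean()
        assert m6 < m23

    def test_curved_layers_flattened(self):
        cells = make_layered_cells(slope=0.3, curvature=0.05, a=1.0, seed=1)
        out = align_axis(cells, reference_layer="L4", anchor_layer="L5",
                         layer_col="layer", n_bins=50)
        ref = out.data[out.data["layer"] == "L4"]
        m = np.polyfit(ref["x_aligned"], ref["y_aligned"], 1)[0]
        c = np.polyfit(ref["x_aligned"], ref["y_aligned"], 2)[0]
        assert abs(m) < 1e-3
        assert abs(c) < 1e-4

    def test_equivariant_under_global_motion(self):
        base = make_layered_cells(slope=0.0, curvature=0.0, seed=2)
        out1 = align_axis(base, reference_layer="L4", layer_col="layer",
                          n_bins=40, seed=9)
        theta = 0.4
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = base.data.copy()
        xy = moved[["x", "y"]].to_numpy() @ R.T + np.array([13.0, -7.0])
        moved["x"], moved["y"] = xy[:, 0], xy[:, 1]
        cells2 = CellTable(data=moved, genes=["g"], coord_cols=("x", "y"))
        out2 = align_axis(cells2, reference_layer="L4", layer_col="layer",
                          n_bins=40, seed=9)
        same = (out1.data["bin"] == out2.data["bin"]).mean()
        assert same > 0.95  # identical up to binning jitter

    def test_too_few_reference_cells(self):
        cells = make_layered_cells(n=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            align_axis(cells, reference_layer="L4", layer_col="layer")


class TestLiverReconstruction:
    def _zoned(self, n=100, y=0.004, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"cell": [f"c{i}" for i in range(n)]})
        df["GLUL"] = y
        for z in range(8):
            df[f"P{z + 1}"] = rng.uniform(0, 1, n)
        return df

    def test_zero_expression_gives_zero_counts(self):
        zoned = self._zoned(y=0.0)
        out = reconstruct_liver_pseudocells(
            zoned, genes=["GLUL"], prob_cols=[f"P{z}" for z in range(1, 9)]
        )
        assert out.data["GLUL"].sum() == 0
        assert len(out) == 100 * 8

    def test_zero_probability_zone_is_empty(self):
        zoned = self._zoned(y=0.5)
        zoned[[f"P{z}" for z in range(1, 9)]] = 0.0
        zoned["P3"] = 1.0
        out = reconstruct_liver_pseudocells(
            zoned, genes=["GLUL"], prob_cols=[f"P{z}" for z in range(1, 9)], seed=1
        )
        assert out.data[out.data["bin"] != 2]["GLUL"].sum() == 0
        assert out.data[out.data["bin"] == 2]["GLUL"].sum() > 0

    def test_poisson_mean_scaling(self):
        """y = 0.004 at scale 1000 draws counts with mean about 4."""
        zoned = self._zoned(n=10**4, y=0.004, seed=2)
        zoned[[f"P{z}" for z in range(1, 9)]] = 1.0
        out = reconstruct_liver_pseudocells(
            zoned, genes=["GLUL"], prob_cols=[f"P{z}" for z in range(1, 9)], seed=2
        )
        assert out.data["GLUL"].mean() == pytest.approx(4.0, rel=0.05)

    def test_probability_validation(self):
        zoned = self._zoned()
        zoned["P1"] = 1.5
        with pytest.raises(ValueError, match="probabilities"):
            reconstruct_liver_pseudocells(
                zoned, genes=["GLUL"], prob_cols=[f"P{z}" for z in range(1, 9)]
            )

    def test_deterministic(self):
        zoned = self._zoned(seed=5)
        a = reconstruct_liver_pseudocells(
            zoned, genes=["GLUL"], prob_cols=[f"P{z}" for z in range(1, 9)], seed=7
        )
        b = reconstruct_liver_pseudocells(
            zoned, genes=["GLUL"], prob_cols=[f"P{z}" for z in range(1, 9)], seed=7
        )
        assert a.data.equals(b.data)


def test_bin_coordinates_contract():
    v = np.array([0.0, 0.5, 0.999, 1.0])
    b = bin_coordinates(v, 10, lo=0.0, hi=1.0)
    assert b.min() >= 0 and b.max() <= 9
    assert list(b) == [0, 5, 9, 9]
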