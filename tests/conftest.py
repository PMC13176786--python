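"""Shared fixtures: model-generated count grids with known ground truth.

The generator here is the oracle side of parameter-recovery and calibration
tests: it draws counts directly from the generative story (design-weighted
effects -> warp -> sigmoid -> gamma-convolved Poisson) through the *scalar*
model path, independent of the vectorized fitting code it is used to check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wspfit.likelihood import PSEUDO_LEVEL, CountGrid, sample_counts
from wspfit.model import (
    EffectArray,
    FixedEffectDesign,
    SpatialAxis,
    assemble_spatial_params,
    kernel_rate,
)


def make_model_grid(
    true_r,
    true_s,
    true_p,
    beta_r,
    zeta=0.05,
    n_bins=100,
    n_levels=4,
    rho_sd=0.1,
    seed=0,
    factor="treat",
):
    """Simulate a 1-gene count grid straight from the generative model.

    Returns ``(grid, design, true_effects, true_rho)``; the pseudo reference
    level is generated at rho = 0 (its defining property).
    """
    rng = np.random.default_rng(seed)
    design = FixedEffectDesign(factors=(factor,))
    axis = SpatialAxis(n_bins)
    d = len(true_p)
    e = EffectArray.zeros(d, design.n_interactions)
    e.rates[:, 0] = true_r
    e.rates[:, 1] = beta_r
    if d:
        e.slopes[:, 0] = true_s
        e.points[:, 0] = true_p
    combos = design.combinations()
    labels = design.combination_labels()
    levels = [PSEUDO_LEVEL] + [f"m{i + 1}" for i in range(n_levels)]
    true_rho = {
        k: np.array([rng.normal(0.0, rho_sd), 0.0, 0.0])
        for k in levels
        if k != PSEUDO_LEVEL
    }
    rows = []
    for lbl, xi in zip(labels, combos):
        for k in levels:
            rho = np.zeros(3) if k == PSEUDO_LEVEL else true_rho[k]
            block = assemble_spatial_params(e, rho, xi, design, axis)
            lam = kernel_rate(np.arange(n_bins), block)
            y = sample_counts(lam, zeta, rng=rng)
            for x in range(n_bins):
                rows.append(
                    dict(
                        gene="g", cell_type="all", interaction=lbl,
                        random_level=k, bin=x, count=int(y[x]), empty=False,
                    )
                )
    grid = CountGrid(
        data=pd.DataFrame(rows), genes=["g"], cell_types=["all"],
        combo_labels=labels, combos=np.array(combos), random_levels=levels,
        n_bins=n_bins,
    )
    return grid, design, e, true_rho


@pytest.fixture(scope="session")
def step_grid():
    """A sharp one-step profile (log-linked rates 3 -> 1) with a 0.3 treatment effect."""
    return make_model_grid(
        true_r=[3.0, 1.0], true_s=[5.0], true_p=[50.0], beta_r=[0.3], seed=7
    )


@pytest.fixture(scope="session")
def tiny_null_cells():
    """Cell-level table with a flat profile and a truly null treatment factor."""
    return make_null_cells(seed=0)


def make_null_cells(seed=0, n_cells=900, n_bins=15, mean=3.0):
    """Cells on a short axis, two replicates x two conditions, no true effect.

    Each (replicate, condition) observation holds a fixed quarter of the
    cells, as in a real design where condition and replicate are properties
    of the observation unit rather than of individual cells.
    """
    from wspfit.preprocess import CellTable

    rng = np.random.default_rng(seed)
    per = n_cells // 4
    frames = []
    i = 0
    for rep in ("r1", "r2"):
        for cond in (0, 1):
            frames.append(
                pd.DataFrame(
                    {
                        "cell": [f"c{j}" for j in range(i, i + per)],
                        "bin": rng.integers(0, n_bins, per),
                        "condition": cond,
                        "replicate": rep,
                        "g": rng.poisson(mean, per),
                    }
                )
            )
            i += per
    return CellTable(
        data=pd.concat(frames, ignore_index=True), genes=["g"], coord_cols=None,
        bin_col="bin", factor_cols=["condition"], random_col="replicate",
    )
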