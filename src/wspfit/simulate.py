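"""Attractor simulations: semi-synthetic benchmark data with known truth.

An attractor simulation starts from *seed* data — cells on a 2-D patch with
over-dispersed integer counts for a few genes — and produces replicated
reference/treatment observations with precisely controlled properties:

1. all cell coordinates are shuffled without regard to identity, erasing any
   real spatial structure;
2. at least one gene is chosen to be spatially variable (SVG); each SVG
   gene's transcript-bearing cells are pulled toward a random attractor point
   by a per-cell uniform fraction of a per-gene pull strength;
3. a subset of the SVGs receives a non-null treatment effect on rate of at
   least 5% (up- or down-regulation);
4. each replicate gets a small random affine coordinate perturbation and a
   per-replicate multiplicative rate effect, realized on integer counts by
   binomial thinning (decreases) or Poisson top-up (increases).

The spatial variability, fixed effects and random effects are generated
entirely independently of the WSP model equations, so recovering them is a
fair test.  A synthetic seed generator stands in for external seed files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import sample_counts
from .preprocess import CellTable

__all__ = [
    "SeedData",
    "AttractorConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "generate_synthetic_seed",
    "attractor_simulate",
    "radial_transform",
]


@dataclass
class SeedData:
    """Cells on a rectangular patch with per-gene integer counts."""

    cells: pd.DataFrame  # columns: cell, x, y, <genes>
    genes: list[str]
    patch: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.cells):
            c = self.cells[self.genes].to_numpy()
            if (c < 0).any():
                raise ValueError("seed counts must be non-negative")
            xy = self.cells[["x", "y"]].to_numpy()
            if (xy < 0).any() or (xy[:, 0] > self.patch[0]).any() or (
                xy[:, 1] > self.patch[1]
            ).any():
                raise ValueError("seed coordinates outside the declared patch")


def generate_synthetic_seed(
    n_cells: int = 4000,
    n_genes: int = 4,
    patch_size: float = 2.0,
    dispersion: float = 1.0,
    seed: int | None = 0,
    gene_means: tuple[float, ...] | None = None,
) -> SeedData:
    """Synthetic seed: uniform cells with gamma-convolved-Poisson counts.

    Defaults emulate a 2x2 patch of a MERFISH section with four genes whose
    per-cell mean counts span sparse to abundant; counts are over-dispersed
    with dispersion factor ``dispersion``.
    """
    rng = np.random.default_rng(seed)
    if gene_means is None:
        gene_means = (2.0, 10.0, 0.5, 3.0) if n_genes == 4 else tuple(
            np.geomspace(0.5, 10.0, n_genes)
        )
    genes = [f"gene{i + 1}" for i in range(n_genes)]
    xy = rng.uniform(0, patch_size, size=(n_cells, 2))
    data = {"cell": [f"c{i}" for i in range(n_cells)], "x": xy[:, 0], "y": xy[:, 1]}
    for g, mu in zip(genes, gene_means):
        data[g] = sample_counts(np.full(n_cells, mu), dispersion, rng=rng)
    return SeedData(
        cells=pd.DataFrame(data), genes=genes, patch=(patch_size, patch_size)
    )


@dataclass
class AttractorConfig:
    """Study conditions of the attractor simulator (all exposed)."""

    n_replicates: int = 4
    p_svg: float = 0.5
    p_effect: float = 0.5
    effect_range: tuple[float, float] = (0.05, 0.5)
    pull_range: tuple[float, float] = (0.3, 0.9)
    rotation_max_deg: float = 5.0
    translation_max_frac: float = 0.02
    scale_jitter: float = 0.02
    random_effect_sd: float = 0.1


@dataclass
class SimulationTruth:
    """Stipulated ground truth of one simulation, for benchmark scoring."""

    genes: list[str]
    is_svg: list[bool]
    attractor: list[tuple[float, float] | None]
    effect_factor: list[float]   # multiplicative rate factor; 1.0 for nulls
    beta: list[float]            # log_e(effect_factor)
    pull: list[float]
    rho: list[float]             # per-replicate log rate scaling eta_k
    master_seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        d["attractor"] = [None if a is None else tuple(a) for a in d["attractor"]]
        return cls(**d)


@dataclass
class SimulatedDataset:
    """Replicate x condition cell tables plus the truth that generated them."""

    tables: dict[tuple[int, int], pd.DataFrame]  # (replicate, condition) -> cells
    truth: SimulationTruth
    genes: list[str]
    patch: tuple[float, float]

    def combined_cells(self) -> CellTable:
        """Stack all observations with replicate and condition annotations."""
        parts = []
        for (k, cond), df in sorted(self.tables.items()):
            d = df.copy()
            d["replicate"] = f"rep{k + 1}"
            d["condition"] = cond
            parts.append(d)
        data = pd.concat(parts, ignore_index=True)
        return CellTable(
            data=data, genes=list(self.genes), coord_cols=("x", "y"),
            factor_cols=["condition"], random_col="replicate",
        )


def _scale_counts(y: np.ndarray, factor: float, rng: np.random.Generator) -> np.ndarray:
    """Realize a multiplicative rate change on integer counts."""
    y = y.astype(int)
    if factor <= 1.0:
        return rng.binomial(y, factor)
    return y + rng.poisson(y * (factor - 1.0))


def attractor_simulate(
    seed_data: SeedData,
    config: AttractorConfig | None = None,
    master_seed: int = 0,
) -> SimulatedDataset:
    """Run one attractor simulation; a pure function of (seed, config, master_seed)."""
    cfg = config or AttractorConfig()
    if cfg.p_svg <= 0:
        raise ValueError("at least one SVG is required; p_svg must be positive")
    rng = np.random.default_rng(master_seed)
    genes = seed_data.genes
    G = len(genes)
    base = seed_data.cells.copy().reset_index(drop=True)
    counts = base[genes].to_numpy(dtype=int)
    coords = base[["x", "y"]].to_numpy(dtype=float).copy()
    # 1. shuffle coordinates without regard to cell identity
    coords = coords[rng.permutation(len(coords))]
    # 2. spatially variable genes pulled toward random attractors (>= 1 SVG)
    while True:
        is_svg = rng.random(G) < cfg.p_svg
        if is_svg.any():
            break
    attractor: list[tuple[float, float] | None] = [None] * G
    pull = np.zeros(G)
    for gi in range(G):
        if not is_svg[gi]:
            continue
        attr = rng.uniform(0, 1, size=2) * np.asarray(seed_data.patch)
        attractor[gi] = (float(attr[0]), float(attr[1]))
        pull[gi] = rng.uniform(*cfg.pull_range)
        bearing = counts[:, gi] > 0
        u = rng.random(int(bearing.sum()))
        shrink = (1.0 - pull[gi] * u)[:, None]
        coords[bearing] = attr + (coords[bearing] - attr) * shrink
    # 3. non-null treatment effects (rate up/down by at least 5%) on some SVGs
    effect_factor = np.ones(G)
    for gi in range(G):
        if is_svg[gi] and rng.random() < cfg.p_effect:
            mag = rng.uniform(*cfg.effect_range)
            effect_factor[gi] = 1.0 + mag if rng.random() < 0.5 else 1.0 - mag
    beta = np.log(effect_factor)
    # 4. replicates: affine coordinate noise + per-replicate rate scaling
    eta = rng.normal(0.0, cfg.random_effect_sd, size=cfg.n_replicates)
    center = np.asarray(seed_data.patch) / 2.0
    tables: dict[tuple[int, int], pd.DataFrame] = {}
    for k in range(cfg.n_replicates):
        for cond in (0, 1):
            ang = np.deg2rad(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg))
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            scale = 1.0 + rng.uniform(-cfg.scale_jitter, cfg.scale_jitter)
            trans = rng.uniform(
                -cfg.translation_max_frac, cfg.translation_max_frac, size=2
            ) * np.asarray(seed_data.patch)
            xy = (coords - center) @ R.T * scale + center + trans
            df = pd.DataFrame(
                {"cell": base["cell"], "x": xy[:, 0], "y": xy[:, 1]}
            )
            for gi, g in enumerate(genes):
                f = float(np.exp(eta[k]))
                if cond == 1:
                    f *= float(effect_factor[gi])
                df[g] = _scale_counts(counts[:, gi], f, rng)
            tables[(k, cond)] = df
    truth = SimulationTruth(
        genes=list(genes), is_svg=[bool(v) for v in is_svg], attractor=attractor,
        effect_factor=[float(v) for v in effect_factor], beta=[float(v) for v in beta],
        pull=[float(v) for v in pull], rho=[float(v) for v in eta],
        master_seed=int(master_seed),
    )
    return SimulatedDataset(
        tables=tables, truth=truth, genes=list(genes), patch=seed_data.patch
    )


def radial_transform(
    cells: CellTable, patch: tuple[float, float] | None = None, compensate: bool = True
) -> CellTable:
    """Wrap the controlled axis onto the radial axis out from the origin.

    Maps ``<x, y> -> <x cos(2 pi y / max(y)), x sin(2 pi y / max(y))>`` so the
    count distribution along the original ``x`` axis is reproduced along the
    radial axis (the radial distance of every transformed point equals its
    original ``x``).  With ``compensate=True`` counts are additionally
    weighted by radial distance and renormalized (largest-remainder rounding,
    preserving per-gene totals) to offset radial area dilution.
    """
    if cells.coord_cols is None:
        raise ValueError("radial_transform needs 2-D coordinates")
    df = cells.data.copy()
    xc, yc = cells.coord_cols
    x = df[xc].to_numpy(dtype=float)
    y = df[yc].to_numpy(dtype=float)
    ymax = y.max() if patch is None else float(patch[1])
    if ymax <= 0:
        raise ValueError("orthogonal coordinate has zero extent")
    theta = 2.0 * np.pi * y / ymax
    df[xc] = x * np.cos(theta)
    df[yc] = x * np.sin(theta)
    if compensate:
        r = np.abs(x)
        for g in cells.genes:
            cnt = df[g].to_numpy(dtype=float)
            total = cnt.sum()
            w = cnt * r
            if w.sum() <= 0:
                continue
            w = w * (total / w.sum())
            base_int = np.floor(w).astype(int)
            short = int(round(total - base_int.sum()))
            if short > 0:
                order = np.argsort(-(w - base_int))
                base_int[order[:short]] += 1
            df[g] = base_int
    return replace(cells, data=df)
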