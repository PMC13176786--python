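"""Cell-table handling, design-grid construction, axis alignment, and the
liver pseudo-cell reconstruction.

The modeling pipeline starts from a *cell table*: one row per cell with
spatial coordinates (or an already-binned 1-D position), per-gene integer
counts, an optional cell type, binary fixed-factor levels (or an ordered time
level) and a random-effect level (e.g. animal id).  :func:`build_count_grid`
aggregates it into the full-factorial design grid the model is fit to,
including the synthesized pseudo reference random level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .likelihood import CountGrid, PSEUDO_LEVEL
from .model import FixedEffectDesign, SpatialAxis

logger = logging.getLogger(__name__)

__all__ = [
    "CellTable",
    "build_count_grid",
    "GridBuilder",
    "bin_coordinates",
    "align_axis",
    "reconstruct_liver_pseudocells",
    "read_cell_table",
]


@dataclass
class CellTable:
    """Cell-level records: coordinates/bin, per-gene counts, annotations."""

    data: pd.DataFrame
    genes: list[str]
    cell_col: str = "cell"
    coord_cols: tuple[str, str] | None = ("x", "y")
    bin_col: str | None = None
    cell_type_col: str | None = None
    factor_cols: list[str] = field(default_factory=list)
    random_col: str | None = None

    def __post_init__(self) -> None:
        needed = [self.cell_col, *self.genes, *self.factor_cols]
        if self.coord_cols:
            needed += list(self.coord_cols)
        if self.bin_col:
            needed.append(self.bin_col)
        if self.cell_type_col:
            needed.append(self.cell_type_col)
        if self.random_col:
            needed.append(self.random_col)
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise ValueError(f"cell table is missing columns: {missing}")
        if len(self.data):
            counts = self.data[self.genes].to_numpy()
            if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
                raise ValueError("gene counts must be non-negative integers")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_cell_table(
    path,
    genes: Sequence[str],
    cell_col: str = "cell",
    coord_cols: tuple[str, str] | None = ("x", "y"),
    bin_col: str | None = None,
    cell_type_col: str | None = None,
    factor_cols: Sequence[str] = (),
    random_col: str | None = None,
) -> CellTable:
    """Read a delimited cell table, validating the declared schema.

    An empty file yields an empty (but well-formed) table.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        cols = [cell_col, *(coord_cols or ()), *genes, *factor_cols]
        cols += [c for c in (bin_col, cell_type_col, random_col) if c]
        df = pd.DataFrame(columns=cols)
    return CellTable(
        data=df, genes=list(genes), cell_col=cell_col, coord_cols=coord_cols,
        bin_col=bin_col, cell_type_col=cell_type_col,
        factor_cols=list(factor_cols), random_col=random_col,
    )


def bin_coordinates(
    values: np.ndarray, n_bins: int, lo: float | None = None, hi: float | None = None
) -> np.ndarray:
    """Linear binning of a coordinate into integer bins ``0 .. n_bins - 1``."""
    values = np.asarray(values, dtype=float)
    lo = float(values.min()) if lo is None else lo
    hi = float(values.max()) if hi is None else hi
    if hi <= lo:
        return np.zeros(len(values), dtype=int)
    b = np.floor((values - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(b, 0, n_bins - 1)


# ---------------------------------------------------------------------------
# design-grid construction
# ---------------------------------------------------------------------------


@dataclass
class FastCountGrid:
    """Tensor-backed view of a design grid (no DataFrame).

    Duck-type equivalent of :class:`~wspfit.likelihood.CountGrid` for the
    fitting path; used by bootstrap refits where rebuilding a DataFrame per
    resample would dominate the run time.  ``y``/``empty`` are shaped
    (gene, cell type, combination, random level, bin) with the pseudo level
    first.
    """

    y: np.ndarray
    empty: np.ndarray
    genes: list[str]
    cell_types: list[str]
    combo_labels: list[str]
    combos: np.ndarray
    random_levels: list[str]
    n_bins: int

    @property
    def axis(self) -> SpatialAxis:
        return SpatialAxis(n_bins=self.n_bins)

    @property
    def n_filled_rows(self) -> int:
        return int((~self.empty).sum())

    def real_levels(self) -> list[str]:
        return [k for k in self.random_levels if k != PSEUDO_LEVEL]

    def gene_tensors(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        gi = self.genes.index(gene)
        return self.y[gi], ~self.empty[gi]


class GridBuilder:
    """Pre-indexed aggregator from a cell table to the design grid.

    Splitting preparation from aggregation lets bootstrap resampling rebuild
    the grid thousands of times without re-validating or re-encoding cells:
    :meth:`build` accepts an optional cell-index selection (with repeats).
    """

    def __init__(self, cells: CellTable, design: FixedEffectDesign, n_bins: int | None = None):
        df = cells.data
        self.design = design
        self.genes = list(cells.genes)
        if cells.bin_col is None:
            raise ValueError("cells must carry a bin column; use bin_coordinates first")
        bins = df[cells.bin_col].to_numpy(dtype=int)
        self.n_bins = int(bins.max()) + 1 if n_bins is None else int(n_bins)
        if bins.min() < 0 or bins.max() >= self.n_bins:
            raise ValueError("bin indices outside [0, n_bins)")
        self.bins = bins
        # cell types
        if cells.cell_type_col:
            self.cell_types = sorted(df[cells.cell_type_col].astype(str).unique())
            self.c_idx = (
                pd.Categorical(df[cells.cell_type_col].astype(str), categories=self.cell_types)
                .codes.astype(int)
            )
        else:
            self.cell_types = ["all"]
            self.c_idx = np.zeros(len(df), dtype=int)
        # interaction combinations
        combos = design.combinations()
        self.combos = np.array(combos, dtype=int).reshape(len(combos), -1)
        self.combo_labels = design.combination_labels()
        lookup = {tuple(xi): i for i, xi in enumerate(self.combos)}
        xi_rows = np.array(
            [
                design.encode({f: row[f] for f in cells.factor_cols}
                              | ({design.time_factor: row[design.time_factor]}
                                 if design.time_factor else {}))
                for row in df[list(cells.factor_cols)
                              + ([design.time_factor] if design.time_factor else [])]
                .to_dict("records")
            ]
        ) if (cells.factor_cols or design.time_factor) else np.zeros((len(df), 0), dtype=int)
        try:
            self.j_idx = np.array([lookup[tuple(xi)] for xi in xi_rows], dtype=int)
        except KeyError as err:  # pragma: no cover - encode() already validates
            raise ValueError(f"unknown factor combination {err}") from err
        # random levels
        if cells.random_col:
            self.real_levels = sorted(df[cells.random_col].astype(str).unique())
            self.k_idx = (
                pd.Categorical(df[cells.random_col].astype(str), categories=self.real_levels)
                .codes.astype(int)
            )
        else:
            self.real_levels = ["sample"]
            self.k_idx = np.zeros(len(df), dtype=int)
        self.random_levels = [PSEUDO_LEVEL] + self.real_levels
        self.counts = df[self.genes].to_numpy(dtype=float)
        # composite stratum id (random level x interaction combination)
        self.strata = self.k_idx * len(self.combo_labels) + self.j_idx
        self._shape = (
            len(self.cell_types), len(self.combo_labels),
            len(self.real_levels), self.n_bins,
        )

    def _tensors(self, selection: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        if selection is None:
            c, j, k, b, cnt = self.c_idx, self.j_idx, self.k_idx, self.bins, self.counts
        else:
            c, j, k, b = (
                self.c_idx[selection], self.j_idx[selection],
                self.k_idx[selection], self.bins[selection],
            )
            cnt = self.counts[selection]
        C, Jx, Kr, nb = self._shape
        flat = ((c * Jx + j) * Kr + k) * nb + b
        presence = np.bincount(flat, minlength=C * Jx * Kr * nb).reshape(self._shape)
        y_real = np.stack(
            [
                np.bincount(flat, weights=cnt[:, gi], minlength=C * Jx * Kr * nb)
                .reshape(self._shape)
                for gi in range(len(self.genes))
            ]
        )  # (G, C, Jx, Kr, nb)
        nonempty = presence > 0
        # pseudo reference level: mean of log-linked counts across real levels
        with np.errstate(invalid="ignore", divide="ignore"):
            n_ne = nonempty.sum(axis=2)  # (C, Jx, nb)
            m = np.where(
                n_ne > 0,
                (np.log1p(y_real) * nonempty).sum(axis=3) / np.maximum(n_ne, 1),
                0.0,
            )  # (G, C, Jx, nb)
        y_pseudo = np.rint(np.expm1(m))
        pseudo_empty = n_ne == 0
        # assemble full tensors with the pseudo level first
        G = len(self.genes)
        K = Kr + 1
        y = np.concatenate([y_pseudo[:, :, :, None, :], y_real], axis=3)  # (G,C,Jx,K,nb)
        empty = np.zeros((G, C, Jx, K, nb), dtype=bool)
        empty[:, :, :, 0, :] = pseudo_empty[None, :, :, :]
        empty[:, :, :, 1:, :] = (~nonempty)[None, :, :, :, :]
        y = np.where(empty, 0.0, y)
        return y, empty

    def build_tensors(self, selection: np.ndarray | None = None) -> FastCountGrid:
        """Tensor-only aggregation (the fast path used by bootstrap refits)."""
        y, empty = self._tensors(selection)
        return FastCountGrid(
            y=y, empty=empty, genes=list(self.genes), cell_types=list(self.cell_types),
            combo_labels=list(self.combo_labels), combos=self.combos,
            random_levels=list(self.random_levels), n_bins=self.n_bins,
        )

    def build(self, selection: np.ndarray | None = None) -> CountGrid:
        """Aggregate (optionally a resampled selection of) cells into a grid."""
        y, empty = self._tensors(selection)
        C, Jx, Kr, nb = self._shape
        G, K = len(self.genes), Kr + 1
        df = pd.DataFrame(
            {
                "gene": np.repeat(self.genes, C * Jx * K * nb),
                "cell_type": np.tile(np.repeat(self.cell_types, Jx * K * nb), G),
                "interaction": np.tile(np.repeat(self.combo_labels, K * nb), G * C),
                "random_level": np.tile(np.repeat(self.random_levels, nb), G * C * Jx),
                "bin": np.tile(np.arange(nb), G * C * Jx * K),
                "count": y.ravel().astype(int),
                "empty": empty.ravel(),
            }
        )
        return CountGrid(
            data=df, genes=list(self.genes), cell_types=list(self.cell_types),
            combo_labels=list(self.combo_labels), combos=self.combos,
            random_levels=list(self.random_levels), n_bins=self.n_bins,
        )

    def resample_strata(self, rng: np.random.Generator) -> np.ndarray:
        """Draw cells with replacement within each (random level x combo) stratum."""
        sel = np.empty(len(self.strata), dtype=int)
        pos = 0
        for s in np.unique(self.strata):
            idx = np.flatnonzero(self.strata == s)
            take = rng.integers(0, len(idx), size=len(idx))
            sel[pos : pos + len(idx)] = idx[take]
            pos += len(idx)
        return sel[:pos]


def build_count_grid(
    cells: CellTable, design: FixedEffectDesign, axis: SpatialAxis | int | None = None
) -> CountGrid:
    """Aggregate a cell table into the full-factorial design grid.

    One row per (gene, cell type, interaction combination, random level, bin)
    including the synthesized pseudo reference level; combinations with no
    contributing cells are flagged empty.  Total counts per gene are
    conserved on real levels.
    """
    if isinstance(axis, SpatialAxis):
        n_bins = axis.n_bins
    else:
        n_bins = axis
    return GridBuilder(cells, design, n_bins=n_bins).build()


# ---------------------------------------------------------------------------
# laminar axis alignment
# ---------------------------------------------------------------------------


def _stretch_columns(
    a: np.ndarray, b: np.ndarray, n_bins: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-column occupancy stretch of coordinate ``b`` within bins of ``a``.

    Within each integer bin of ``a``, values of ``b`` above the midpoint are
    linearly pulled so the occupied maximum lands at ``n_bins - eps`` and
    values below so the occupied minimum lands at ``eps``; points near the
    midpoint move proportionally less (distance-weighted rescaling).
    """
    out = b.copy()
    mid = n_bins / 2.0
    cols = np.floor(a).astype(int)
    for col in np.unique(cols):
        sel = cols == col
        bv = out[sel]
        hi = bv[bv >= mid]
        if len(hi):
            bmax = hi.max()
            eps = rng.uniform(0, 0.5)
            if bmax > mid:
                bv[bv >= mid] = mid + (hi - mid) * (n_bins - eps - mid) / (bmax - mid)
        lo = bv[bv < mid]
        if len(lo):
            bmin = lo.min()
            eps = rng.uniform(0, 0.5)
            if bmin < mid:
                bv[bv < mid] = mid - (mid - lo) * (mid - eps) / (mid - bmin)
        out[sel] = bv
    return out


def align_axis(
    cells: CellTable,
    reference_layer: str,
    anchor_layer: str | None = None,
    layer_col: str = "layer",
    n_bins: int = 100,
    superficial_layer: str | None = None,
    seed: int = 0,
) -> CellTable:
    """Transform 2-D coordinates into binned laminar/columnar coordinates.

    Four steps: (1) translate by the mean point of the anchor stratum;
    (2) level by rotating through ``-arctan(m)`` of a linear fit to the
    reference stratum (reflecting so the superficial stratum is on top);
    (3) flatten curvature by subtracting a least-squares quadratic fit to the
    reference stratum; (4) bin both axes to ``0 .. n_bins - 1`` and stretch
    occupancy to the bin bounds with a distance-weighted rescaling and a
    small uniform jitter at the extremes.  The aligned (laminar) axis is
    stored in a ``bin`` column; the orthogonal axis in ``bin_orth``.
    """
    if cells.coord_cols is None:
        raise ValueError("align_axis needs 2-D coordinates")
    df = cells.data.copy()
    xc, yc = cells.coord_cols
    if layer_col not in df.columns:
        raise ValueError(f"cell table has no layer column {layer_col!r}")
    ref = df[df[layer_col] == reference_layer]
    if len(ref) < 3:
        raise ValueError(f"reference stratum {reference_layer!r} has fewer than 3 cells")
    anchor = df[df[layer_col] == anchor_layer] if anchor_layer else ref
    if len(anchor) == 0:
        raise ValueError(f"anchor stratum {anchor_layer!r} is empty")
    x = df[xc].to_numpy(dtype=float)
    y = df[yc].to_numpy(dtype=float)
    # step 1: translate to the anchor-stratum mean
    x = x - anchor[xc].mean()
    y = y - anchor[yc].mean()
    refm = df[layer_col] == reference_layer
    # step 2: level by the reference-stratum slope
    m, _ = np.polyfit(x[refm], y[refm], 1)
    theta = -np.arctan(m)
    ct, st = np.cos(theta), np.sin(theta)
    x, y = x * ct - y * st, x * st + y * ct
    if superficial_layer is not None:
        sup = df[layer_col] == superficial_layer
        if y[sup].mean() < y[refm].mean():
            y = -y
    # step 3: flatten curvature (subtract the fitted quadratic, keep its level)
    coef = np.polyfit(x[refm], y[refm], 2)
    y = y - np.polyval(coef, x) + np.polyval(coef, 0.0)
    # step 4: bin and stretch occupancy to fill [0, n_bins)
    rng = np.random.default_rng(seed)
    out = df.copy()
    out["x_aligned"] = x
    out["y_aligned"] = y
    xs = (x - x.min()) / max(x.max() - x.min(), 1e-12) * n_bins
    ys = (y - y.min()) / max(y.max() - y.min(), 1e-12) * n_bins
    ys = _stretch_columns(xs, ys, n_bins, rng)
    xs = _stretch_columns(ys, xs, n_bins, rng)
    out["bin"] = np.clip(np.floor(ys).astype(int), 0, n_bins - 1)
    out["bin_orth"] = np.clip(np.floor(xs).astype(int), 0, n_bins - 1)
    return replace(cells, data=out, bin_col="bin")


# ---------------------------------------------------------------------------
# liver pseudo-cell reconstruction
# ---------------------------------------------------------------------------


def reconstruct_liver_pseudocells(
    zoned: pd.DataFrame,
    genes: Sequence[str],
    prob_cols: Sequence[str],
    cell_col: str = "cell",
    scale: float = 1000.0,
    seed: int | None = 0,
) -> CellTable:
    """Turn zone-probability expression data into integer pseudo-cell counts.

    For each cell with normalized per-gene expression ``y`` and zone
    membership probabilities ``P_x`` (zones ordered central to portal), draws
    ``y_x ~ Pois(scale * y)`` per zone and gene and a shared zone membership
    ``b_x ~ Binom(1, P_x)``, emitting one pseudo-cell per zone with counts
    ``y_x * b_x`` at bin ``x``.  Deterministic given ``seed``.
    """
    probs = zoned[list(prob_cols)].to_numpy(dtype=float)
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("zone probabilities must lie in [0, 1]")
    expr = zoned[list(genes)].to_numpy(dtype=float)
    if (expr < 0).any():
        raise ValueError("normalized expression must be non-negative")
    rng = np.random.default_rng(seed)
    n, Z = probs.shape
    memb = rng.binomial(1, probs)                       # (n, Z)
    rows = []
    extra = zoned.drop(columns=list(genes) + list(prob_cols))
    for z in range(Z):
        draws = rng.poisson(np.clip(scale * expr, 0, None))  # (n, G)
        counts = draws * memb[:, z : z + 1]
        block = extra.copy()
        block[cell_col] = zoned[cell_col].astype(str) + f":z{z}"
        block["bin"] = z
        for gi, g in enumerate(genes):
            block[g] = counts[:, gi]
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    return CellTable(
        data=out, genes=list(genes), cell_col=cell_col, coord_cols=None, bin_col="bin"
    )
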