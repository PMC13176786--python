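"""Core WSP predictor: logistic building blocks, warping, and fixed-effect designs.

A warped sigmoidal Poisson-process (WSP) model describes the log-linked kernel
rate of a gene's expression along a bounded 1-D spatial axis as a sum of
logistic transitions,

    log_e(lambda + 1) = Psi_d(x, r, s, p)
                      = r_1 + sum_i (r_{i+1} - r_i) / (1 + exp(-s_i (x - p_i))),

with ``d`` transition points ``p`` (the model *degree*), ``d + 1`` block rates
``r`` and transition slope scalars ``s``.  Fixed (treatment) effects enter the
spatial parameters linearly through a factorial design of binary factors;
random (replicate) effects enter through a smooth, bound-respecting warp.

Everything in this module is a pure function of its inputs; fitting lives in
:mod:`wspfit.fitting`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "EPS_Z",
    "SpatialAxis",
    "BlockParams",
    "FixedEffectDesign",
    "EffectArray",
    "logistic",
    "wsp_sigmoid",
    "warp_ratio",
    "warp",
    "interaction_weights",
    "expand_time_series",
    "assemble_spatial_params",
    "predict_log_rate",
    "kernel_rate",
    "log2_fold_change",
]

#: Floor applied to rates and slope scalars so the predictor stays defined
#: while an optimizer explores unconstrained effect values.
EPS_Z = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialAxis:
    """A discretized bounded spatial axis.

    Bins are integers ``0 .. n_bins - 1``; bin ``i`` covers the half-open
    interval ``[i, i + 1)`` in axis units and is evaluated at its left edge.
    The axis upper bound ``b_p`` (the bound for transition points) defaults to
    ``n_bins``.
    """

    n_bins: int
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("a spatial axis needs at least 2 bins")
        if self.upper_bound is None:
            object.__setattr__(self, "upper_bound", float(self.n_bins))
        if self.upper_bound <= 0:
            raise ValueError("axis upper bound must be positive")

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.n_bins)


@dataclass
class BlockParams:
    """Spatial parameters of a single WSP sigmoid.

    ``rates`` has length ``degree + 1`` (log-link scale, all >= 0),
    ``slopes`` and ``points`` have length ``degree``; transition points are
    strictly increasing within ``[0, upper_bound]``.
    """

    rates: np.ndarray
    slopes: np.ndarray
    points: np.ndarray
    upper_bound: float = np.inf

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.slopes = np.atleast_1d(np.asarray(self.slopes, dtype=float))
        self.points = np.atleast_1d(np.asarray(self.points, dtype=float))
        d = self.degree
        if self.rates.shape != (d + 1,) or self.slopes.shape != (d,):
            raise ValueError("rates must have length degree+1 and slopes length degree")
        if np.any(self.rates < 0) or np.any(self.slopes < 0):
            raise ValueError("rates and slope scalars must be non-negative")
        if d and (np.any(np.diff(self.points) <= 0)):
            raise ValueError("transition points must be strictly increasing")
        if d and (self.points[0] < 0 or self.points[-1] > self.upper_bound):
            raise ValueError("transition points must lie in [0, upper_bound]")

    @property
    def degree(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# sigmoid building blocks
# ---------------------------------------------------------------------------


def logistic(x, r, s):
    """Logistic sigmoid ``r / (1 + exp(s * x))``.

    Asymptotes at ``r`` toward -inf and at zero toward +inf; the midpoint
    value at ``x = 0`` is ``r / 2``.  Evaluated via ``expit`` so it never
    overflows for large ``|s * x|``.
    """
    return np.asarray(r) * expit(-np.asarray(s) * np.asarray(x))


def wsp_sigmoid(x, block: BlockParams):
    """Degree-``d`` WSP sigmoid ``Psi_d(x, r, s, p)``.

    For ``d = 0`` this is the constant ``r_1``.  Vectorizes over ``x``.
    """
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, block.rates[0], dtype=float)
    for i in range(block.degree):
        rise = block.rates[i + 1] - block.rates[i]
        out = out + rise * expit(block.slopes[i] * (x - block.points[i]))
    return out if out.ndim else float(out)


def predict_log_rate(x, block: BlockParams):
    """Log-linked kernel rate ``Psi_d(x)``; the kernel rate is ``e^Psi - 1``."""
    return wsp_sigmoid(x, block)


def kernel_rate(x, block: BlockParams):
    """Kernel rate ``lambda = e^Psi - 1`` (always >= 0 for valid blocks)."""
    lam = np.expm1(wsp_sigmoid(x, block))
    return np.maximum(lam, 0.0)


# ---------------------------------------------------------------------------
# warping (random effects on bounded parameters)
# ---------------------------------------------------------------------------


def warp_ratio(X, rho, b):
    """Warping ratio ``phi(X, rho, b) = 1 - exp(rho^2)^(-X/b)`` in ``[0, 1)``."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("warp_ratio requires X >= 0")
    if np.any(np.asarray(b) <= 0):
        raise ValueError("warp_ratio requires b > 0")
    return -np.expm1(-(np.asarray(rho) ** 2) * X / b)


def warp(z, rho, b):
    """Warp ``z`` in ``[0, b]`` by random effect ``rho``, staying in ``[0, b]``.

    Positive ``rho`` skews ``z`` asymptotically toward the upper bound,
    negative ``rho`` toward zero, and ``rho = 0`` is the identity.  For
    ``b = inf`` the warp reduces to linear scaling: ``z * (1 + rho^2)`` for
    ``rho >= 0`` and ``z * exp(-rho^2)`` for ``rho < 0``.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(z < 0) or np.any(z > b):
        raise ValueError("warp requires 0 <= z <= b")
    pos = rho >= 0
    if np.isinf(b):
        out = np.where(pos, z * (1.0 + rho**2), z * np.exp(-(rho**2)))
    else:
        up = z + warp_ratio(z, rho, b) * (b - z)
        down = z - warp_ratio(np.maximum(b - z, 0.0), rho, b) * z
        out = np.where(pos, up, down)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------


@dataclass
class FixedEffectDesign:
    """Binary fixed factors, optional ordered time series, and their interactions.

    ``factors`` are ordinary binary factors (reference level coded 0).  A time
    series is handled as an ordered set of cumulative binary indicators: a
    sample observed at level ``T_m`` activates the indicators of all levels
    ``T_l`` with ``l <= m`` (the first level is the reference and has no
    indicator).  Interactions are all products of the binary factors; time
    indicators additionally interact pairwise with each non-time factor but
    never with each other.

    Canonical interaction order: baseline (empty product) first, then main
    effects in declared factor order, then higher-order products in
    lexicographic order of member indices.
    """

    factors: tuple[str, ...] = ()
    time_factor: str | None = None
    time_levels: tuple[str, ...] = ()
    interactions: list[tuple[int, ...]] = field(init=False)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.time_levels = tuple(self.time_levels)
        if self.time_factor is not None and len(self.time_levels) < 2:
            raise ValueError("a time factor needs at least 2 ordered levels")
        self.interactions = self._build_interactions()

    # -- structure ---------------------------------------------------------

    @property
    def time_indicators(self) -> tuple[str, ...]:
        if self.time_factor is None:
            return ()
        return tuple(f"{self.time_factor}:{lvl}" for lvl in self.time_levels[1:])

    @property
    def binary_names(self) -> tuple[str, ...]:
        """All binary variables: declared factors then cumulative time indicators."""
        return self.factors + self.time_indicators

    @property
    def n_binary(self) -> int:
        return len(self.binary_names)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def _build_interactions(self) -> list[tuple[int, ...]]:
        n_f = len(self.factors)
        n_t = len(self.time_indicators)
        subsets: list[tuple[int, ...]] = []
        # every product of non-time factors
        for size in range(n_f + 1):
            subsets.extend(itertools.combinations(range(n_f), size))
        # each time indicator alone and crossed with each single non-time factor
        for t in range(n_f, n_f + n_t):
            subsets.append((t,))
            for f in range(n_f):
                subsets.append((f, t))
        # canonical order: baseline, singletons in declared order, then products
        subsets = sorted(set(subsets), key=lambda s: (len(s) > 1, len(s), s))
        return subsets

    @property
    def interaction_labels(self) -> list[str]:
        names = self.binary_names
        return [
            "baseline" if not s else "*".join(names[i] for i in s)
            for s in self.interactions
        ]

    # -- encodings ---------------------------------------------------------

    def weights(self, xi: Sequence[int]) -> np.ndarray:
        """Interaction weight vector ``w_j(xi)``; ``w_1`` is always 1."""
        xi = np.asarray(xi)
        if xi.shape != (self.n_binary,) or not np.isin(xi, (0, 1)).all():
            raise ValueError(f"xi must be a binary vector of length {self.n_binary}")
        return np.array(
            [1 if not s else int(np.prod(xi[list(s)])) for s in self.interactions],
            dtype=int,
        )

    def weight_matrix(self) -> np.ndarray:
        """Stacked weight vectors for every observable combination (rows)."""
        return np.array([self.weights(xi) for xi in self.combinations()], dtype=float)

    def combinations(self) -> list[np.ndarray]:
        """All observable ``xi`` patterns (time indicators are cumulative)."""
        n_f = len(self.factors)
        base = list(itertools.product((0, 1), repeat=n_f))
        if self.time_factor is None:
            return [np.array(b, dtype=int) for b in base]
        out = []
        for b in base:
            for m in range(len(self.time_levels)):
                t = expand_time_series(self.time_levels, self.time_levels[m])
                out.append(np.concatenate([np.array(b, dtype=int), t]))
        return out

    def combination_labels(self) -> list[str]:
        labels = []
        for xi in self.combinations():
            parts = [f"{name}={xi[i]}" for i, name in enumerate(self.factors)]
            if self.time_factor is not None:
                t = xi[len(self.factors):]
                lvl = self.time_levels[int(t.sum())]
                parts.append(f"{self.time_factor}={lvl}")
            labels.append("|".join(parts) if parts else "all")
        return labels

    def encode(self, values: Mapping[str, object]) -> np.ndarray:
        """Encode one sample's factor levels into a binary ``xi`` vector."""
        xi = []
        for name in self.factors:
            v = values[name]
            if v not in (0, 1, "0", "1", False, True):
                raise ValueError(f"factor {name!r} must be binary, got {v!r}")
            xi.append(int(v))
        if self.time_factor is not None:
            xi.extend(expand_time_series(self.time_levels, values[self.time_factor]))
        return np.array(xi, dtype=int)


def interaction_weights(xi: Sequence[int], design: FixedEffectDesign) -> np.ndarray:
    """Weight function of Eq-11 style factorial interactions (see design docs)."""
    return design.weights(xi)


def expand_time_series(levels: Sequence[str], observed_level: str) -> np.ndarray:
    """Cumulative indicator coding of an ordered time series.

    Returns one indicator per non-reference level; a sample at level ``T_m``
    activates the indicators of all levels up to and including ``T_m``.
    """
    levels = list(levels)
    if observed_level not in levels:
        raise ValueError(f"unknown time level {observed_level!r}; known: {levels}")
    m = levels.index(observed_level)
    return np.array([1 if l <= m else 0 for l in range(1, len(levels))], dtype=int)


# ---------------------------------------------------------------------------
# effect arrays and assembly
# ---------------------------------------------------------------------------


@dataclass
class EffectArray:
    """Fixed effects for one (gene, cell type): per spatial parameter, per
    block/transition, per interaction.

    Column 0 of each array is the baseline (reference level) and must obey the
    spatial-parameter bounds; the other columns are zero-centered effects.
    """

    rates: np.ndarray   # (degree + 1, n_interactions)
    slopes: np.ndarray  # (degree, n_interactions)
    points: np.ndarray  # (degree, n_interactions)

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        self.slopes = np.asarray(self.slopes, dtype=float).reshape(
            -1, self.rates.shape[1]
        )
        self.points = np.asarray(self.points, dtype=float).reshape(
            -1, self.rates.shape[1]
        )
        if self.rates.shape[0] != self.degree + 1:
            raise ValueError("rates must have degree+1 rows")

    @property
    def degree(self) -> int:
        return self.points.shape[0]

    @property
    def n_interactions(self) -> int:
        return self.rates.shape[1]

    @classmethod
    def zeros(cls, degree: int, n_interactions: int) -> "EffectArray":
        return cls(
            rates=np.zeros((degree + 1, n_interactions)),
            slopes=np.zeros((degree, n_interactions)),
            points=np.zeros((degree, n_interactions)),
        )


def assemble_spatial_params(
    effects: EffectArray,
    rho: Sequence[float],
    xi: Sequence[int],
    design: FixedEffectDesign,
    axis: SpatialAxis,
) -> BlockParams:
    """Combine fixed effects, then warp by the random effects, for one row group.

    Implements the two-stage predictor assembly: the design-weighted sum of
    effect values gives each spatial parameter, which is then warped by the
    random effect of the row's random level (``rho = (rho_r, rho_s, rho_p)``;
    the pseudo reference level uses zeros).  Rates and slopes warp against an
    infinite bound, transition points against the axis upper bound.  Values
    are floored at ``EPS_Z`` and transition triples re-sorted so the returned
    :class:`BlockParams` is always valid.
    """
    w = design.weights(xi).astype(float)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (3,):
        raise ValueError("rho must be the (rho_r, rho_s, rho_p) triple")
    b_p = axis.upper_bound
    z_r = effects.rates @ w
    z_s = effects.slopes @ w
    z_p = effects.points @ w
    if not (np.isfinite(z_r).all() and np.isfinite(z_s).all() and np.isfinite(z_p).all()):
        raise FloatingPointError("non-finite spatial parameter from effect sum")
    z_r = np.maximum(z_r, EPS_Z)
    z_s = np.maximum(z_s, EPS_Z)
    z_p = np.clip(z_p, 0.0, b_p)
    r_w = np.asarray(warp(z_r, rho[0], np.inf))
    s_w = np.maximum(np.asarray(warp(z_s, rho[1], np.inf)), EPS_Z)
    p_w = np.clip(np.asarray(warp(z_p, rho[2], b_p)), 0.0, b_p)
    d = effects.degree
    if d:
        rises = np.diff(r_w)
        order = np.argsort(p_w, kind="stable")
        p_w, s_w, rises = p_w[order], s_w[order], rises[order]
        # force strict increase after ties introduced by clipping/warping
        for i in range(1, d):
            if p_w[i] <= p_w[i - 1]:
                p_w[i] = p_w[i - 1] + 1e-9
        p_w = np.minimum(p_w, b_p)
        for i in range(d - 2, -1, -1):
            if p_w[i] >= p_w[i + 1]:
                p_w[i] = p_w[i + 1] - 1e-9
        r_w = np.concatenate([[r_w[0]], r_w[0] + np.cumsum(rises)])
        r_w = np.maximum(r_w, EPS_Z)
    return BlockParams(rates=r_w, slopes=s_w, points=p_w, upper_bound=b_p)


def log2_fold_change(
    effects: EffectArray, active_interactions: Sequence[int], block: int
) -> float:
    """Log-2 fold change of ``lambda + 1`` for a block under active treatments.

    Sums the active non-baseline rate effects for the block and divides by
    ``log_e(2)``; the baseline (interaction 0) is excluded.
    """
    total = sum(
        effects.rates[block, j] for j in active_interactions if j != 0
    )
    return float(total / np.log(2.0))
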