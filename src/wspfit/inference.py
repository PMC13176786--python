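"""Resampling-based inference: bootstrap CIs/p-values and optional MCMC.

Confidence intervals and p-values are estimated empirically from the
distribution of refitted parameters over bootstrap resamples of cells (drawn
with replacement within random-level x interaction-combination strata, which
preserves the design).  Two-sided p-values for zero-centered parameters use
the smoothed sign-crossing formula ``p = 2 * min(#{<=0}+1, #{>=0}+1)/(B+1)``;
multiplicity over the family of all non-baseline fixed effects is handled by
Holm's step-down procedure (Bonferroni optional).  A Metropolis-Hastings
random walk on the unconstrained internal coordinates is available as an
alternative but ships disabled by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .fitting import FitOptions, FitResult, GeneModel, WspParams, fit
from .model import FixedEffectDesign
from .preprocess import CellTable, GridBuilder

logger = logging.getLogger(__name__)

__all__ = ["ResampleEnsemble", "bootstrap", "mcmc", "summarize_tests"]


@dataclass
class ResampleEnsemble:
    """Resampled parameter vectors around a full-data fit.

    ``matrix`` holds one flattened (natural-scale) parameter vector per
    resample, in the order of :meth:`WspParams.flatten`; only converged
    resamples enter CI and p-value computation.
    """

    full: FitResult
    matrix: np.ndarray          # (B, n_parameters)
    gene_converged: np.ndarray  # (B, n_genes) bool; genes refit independently
    seed: int | None = None
    kind: str = "bootstrap"

    @property
    def B(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def genes(self) -> list[str]:
        return self.full.params.genes

    @property
    def converged(self) -> np.ndarray:
        return self.gene_converged.all(axis=1) if self.B else np.empty(0, dtype=bool)

    @property
    def n_converged(self) -> int:
        return int(self.converged.sum())


def _refit_resample(
    builder, design, options, full: FitResult, child_seed
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(child_seed)
    for _ in range(10):
        sel = builder.resample_strata(rng)
        grid_b = builder.build_tensors(sel)
        # a stratum that had cells always resamples to at least one cell; the
        # redraw guard only fires on pathological inputs
        if grid_b.n_filled_rows > 0:
            break
        logger.warning("resample produced an all-empty grid; redrawing")
    res = fit(
        grid_b, design, options,
        init=full.params, dispersion=full.dispersion, degrees=full.params.degrees,
    )
    conv = np.array([res.gene_status[g] for g in full.params.genes], dtype=bool)
    return res.params.flatten(), conv


def bootstrap(
    cells: CellTable,
    design: FixedEffectDesign,
    options: FitOptions | None = None,
    B: int = 1000,
    seed: int = 0,
    workers: int = 1,
    n_bins: int | None = None,
    resample_max_iter: int = 200,
    full: FitResult | None = None,
) -> ResampleEnsemble:
    """Bootstrap across cells: stratified resampling, grid rebuild, warm refit.

    Resamples are embarrassingly parallel and seeded individually from the
    master seed, so results are identical for any worker count.  Refits are
    warm-started from the full-data optimum with a reduced iteration cap and
    hold degrees and dispersion factors fixed.
    """
    options = options or FitOptions()
    builder = GridBuilder(cells, design, n_bins=n_bins)
    if full is None:
        full = fit(builder.build(), design, options)
    ropt = FitOptions(
        **{
            **options.__dict__,
            "max_iter": resample_max_iter,
            # percentile resolution is limited by B, not optimizer precision;
            # a single optimizer run without kink restarts is enough per resample
            "ftol": max(options.ftol, 1e-7),
            "restarts": 1,
        }
    )
    children = np.random.SeedSequence(seed).spawn(B)
    if B == 0:
        return ResampleEnsemble(
            full=full, matrix=np.empty((0, full.params.n_parameters)),
            gene_converged=np.empty((0, len(full.params.genes)), dtype=bool), seed=seed,
        )
    out = Parallel(n_jobs=workers)(
        delayed(_refit_resample)(builder, design, ropt, full, cs) for cs in children
    )
    matrix = np.vstack([vec for vec, _ in out])
    conv = np.vstack([ok for _, ok in out])
    return ResampleEnsemble(full=full, matrix=matrix, gene_converged=conv, seed=seed)


def mcmc(
    grid,
    design: FixedEffectDesign,
    options: FitOptions | None = None,
    n_steps: int = 0,
    seed: int = 0,
    proposal_scale: float = 0.02,
    thin: int = 10,
    adapt: bool = True,
    full: FitResult | None = None,
) -> ResampleEnsemble:
    """Metropolis-Hastings random walk on the internal coordinates.

    Symmetric Gaussian proposals, acceptance by likelihood ratio, adaptive
    proposal scaling toward 0.23 acceptance during the first fifth of the
    chain, thinned samples returned.  Disabled by default (``n_steps = 0``
    returns only the starting fit).
    """
    options = options or FitOptions()
    if full is None:
        full = fit(grid, design, options)
    params = full.params
    zl = {(r.gene, r.cell_type): r.zeta for r in full.dispersion.table.itertuples(index=False)}
    models = {
        g: GeneModel(
            grid, g, design, params.degrees[g],
            {c: zl.get((g, c), 0.0) for c in grid.cell_types},
            objective=options.objective,
        )
        for g in grid.genes
    }
    rng = np.random.default_rng(seed)
    state = {g: models[g].pack(params.effects[g], params.rho[g]) for g in grid.genes}
    nll = {g: models[g].value_and_grad(state[g])[0] for g in grid.genes}
    scale = float(proposal_scale)
    samples: list[np.ndarray] = []
    accepted, proposed = 0, 0
    burn = max(n_steps // 5, 1)
    for step in range(n_steps):
        for g in grid.genes:
            prop = state[g] + scale * rng.standard_normal(len(state[g]))
            nll_p = models[g].value_and_grad(prop)[0]
            proposed += 1
            if np.log(rng.random()) < nll[g] - nll_p:
                state[g], nll[g] = prop, nll_p
                accepted += 1
        if adapt and scale > 0 and step < burn and (step + 1) % 25 == 0:
            rate = accepted / max(proposed, 1)
            scale *= float(np.exp(0.5 * (rate - 0.23)))
        if step >= burn and (step - burn) % thin == 0:
            vec = _state_to_flat(params, models, state, grid)
            samples.append(vec)
    rate = accepted / max(proposed, 1)
    if scale == 0:
        warnings.warn("proposal scale is 0; the chain is degenerate", stacklevel=2)
    elif n_steps and not (0.05 <= rate <= 0.6):
        warnings.warn(f"MCMC acceptance rate {rate:.2f} outside [0.05, 0.6]", stacklevel=2)
    matrix = (
        np.vstack(samples) if samples else np.empty((0, params.n_parameters))
    )
    return ResampleEnsemble(
        full=full, matrix=matrix,
        gene_converged=np.ones((len(samples), len(grid.genes)), dtype=bool),
        seed=seed, kind="mcmc",
    )


def _state_to_flat(params: WspParams, models, state, grid) -> np.ndarray:
    eff = {}
    rho = {}
    for g in grid.genes:
        e, r = models[g].unpack(state[g])
        eff[g], rho[g] = e, r
    from dataclasses import replace

    return replace(params, effects=eff, rho=rho).flatten()


def summarize_tests(ens: ResampleEnsemble, method: str = "holm") -> pd.DataFrame:
    """Percentile CIs for all parameters; adjusted p-values for fixed effects.

    Two-sided p-values are computed only for zero-centered parameters (fixed
    effects off the baseline level); random effects get CIs but no p-values.
    The multiplicity family pools every non-baseline fixed effect of the
    model run; Holm step-down is the default, Bonferroni optional.
    Significance tiers: ns, * (<0.05), ** (<0.01), *** (<0.001).
    """
    if method not in ("holm", "bonferroni"):
        raise ValueError("method must be 'holm' or 'bonferroni'")
    table = ens.full.params.to_table()
    table["estimate"] = ens.full.params.flatten()
    gene_idx = {g: i for i, g in enumerate(ens.genes)}
    col_gene = table["gene"].map(gene_idx).to_numpy()
    n_bad = int(ens.B - ens.gene_converged.sum() / max(len(ens.genes), 1)) if ens.B else 0
    if ens.B and ens.gene_converged.mean() < 0.9:
        warnings.warn(
            f"about {n_bad} of {ens.B} resample fits did not converge (> 10%)",
            stacklevel=2,
        )
        table.attrs["convergence_warning"] = True
    is_effect = (table["cell_type"] != "*") & (table["level"] != "baseline")
    lo = np.full(len(table), np.nan)
    hi = np.full(len(table), np.nan)
    pvals = np.full(len(table), np.nan)
    if ens.B:
        for i in range(len(table)):
            ok = ens.gene_converged[:, col_gene[i]]
            theta = ens.matrix[ok, i]
            if len(theta) == 0:
                continue
            lo[i], hi[i] = np.percentile(theta, [2.5, 97.5])
            if is_effect.iloc[i]:
                if theta.max() == theta.min():
                    # a parameter that never varies under resampling carries no
                    # sign-crossing information; leave its p-value undefined
                    pass
                else:
                    n_le = int((theta <= 0).sum())
                    n_ge = int((theta >= 0).sum())
                    pvals[i] = min(2.0 * min(n_le + 1, n_ge + 1) / (len(theta) + 1), 1.0)
        table["lower_CI"] = lo
        table["upper_CI"] = hi
    table["p_raw"] = pvals
    adj = np.full(len(table), np.nan)
    mask = ~np.isnan(pvals)
    if mask.any():
        adj[mask] = multipletests(pvals[mask], method=method)[1]
    table["p_adjusted"] = adj
    table["tier"] = [
        "" if np.isnan(p) else
        "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"
        for p in adj
    ]
    table["value"] = table["estimate"]
    return table
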