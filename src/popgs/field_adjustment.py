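"""Spatial adjustment of replicated field observations.

Micro-environmental heterogeneity across a field trial is absorbed by a
random tensor-product cubic B-spline surface over the row/column axes,
fitted jointly with a genetic effect (pedigree relationship matrix) by
EM-REML on Henderson's equations.  Knot numbers are selected by a grid
search on AIC; rougher surfaces (more knots) chase finer-grained
heterogeneity, smoother ones (fewer knots) resist overfitting.  The fitted
surface is subtracted from each observation and the residual genotype
replicates are averaged into adjusted clonal means — the phenotypes used by
every downstream prediction model.  Re-averaging over a subset of blocks
(e.g. 3 of 6) produces the degraded-phenotype variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .core import InvalidParameterError, RelationshipMatrix
from .genomic import regularize
from .mixed_model import _emreml_mme

__all__ = ["bspline_surface_design", "fit_spatial", "adjust_and_average",
           "SpatialFit"]


def _axis_basis(x: np.ndarray, n_knots: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if n_knots < 2:
        raise InvalidParameterError("need at least 2 knots per axis")
    if n_knots > np.unique(x).size:
        raise InvalidParameterError(
            f"{n_knots} knots for {np.unique(x).size} distinct coordinates")
    inner = np.linspace(lo, hi, n_knots)
    t = np.concatenate([[lo] * 3, inner, [hi] * 3])
    return BSpline.design_matrix(x, t, k=3).toarray()


def bspline_surface_design(rows, cols, n_knots_row: int,
                           n_knots_col: int) -> np.ndarray:
    """Tensor product of clamped cubic B-spline bases over plot coordinates.

    With ``k`` equally spaced anchoring knots per axis the basis has
    ``k + 2`` functions per axis, hence ``(k_r + 2)(k_c + 2)`` surface
    coefficients.  Each design row sums to 1 (partition of unity).
    """
    Br = _axis_basis(rows, n_knots_row)
    Bc = _axis_basis(cols, n_knots_col)
    # row-wise Khatri-Rao product
    return (Br[:, :, None] * Bc[:, None, :]).reshape(len(Br), -1)


@dataclass
class SpatialFit:
    """Best-AIC spatial fit for one trait."""

    trait: str
    knots: tuple[int, int]
    variance_components: dict[str, float]
    loglik: float
    aic: float
    surface: pd.Series            # indexed like the observation rows used
    mu: float
    genotype_blup: pd.Series
    knot_search: pd.DataFrame
    observations_index: pd.Index
    converged: bool = True
    log: list = dc_field(default_factory=list)


def fit_spatial(observations: pd.DataFrame, genotype_K: RelationshipMatrix,
                knot_grid=None, trait: str | None = None,
                max_iter: int = 500, aic_tolerance: float = 2.0) -> SpatialFit:
    """Fit genotype + spatial-surface mixed model, selecting knots by AIC.

    ``observations`` is long-format with columns trial, block, row, col,
    genotype, trait, value.  The model per trait is
    ``y = mu + genotype + surface + residual`` with the genotype effect
    correlated by ``genotype_K`` and i.i.d. spline coefficients nested
    within trial.  The knot pair minimising AIC over ``knot_grid`` (default
    ``{4, 6, 8, 10}`` per axis, square pairs) wins; among pairs within
    ``aic_tolerance`` of the minimum (indistinguishable fits by the usual
    delta-AIC < 2 convention) the smoothest surface — fewest coefficients —
    is preferred.
    """
    req = {"trial", "block", "row", "col", "genotype", "trait", "value"}
    missing = req - set(observations.columns)
    if missing:
        raise InvalidParameterError(f"observations lack columns {missing}")
    traits = observations["trait"].unique()
    if trait is None:
        if len(traits) > 1:
            raise InvalidParameterError(
                f"several traits present {list(traits)}; pass trait=")
        trait = traits[0]
    obs = observations.loc[observations["trait"] == trait]
    if obs["block"].nunique() < 2:
        raise InvalidParameterError("need at least 2 blocks")
    if knot_grid is None:
        knot_grid = [(k, k) for k in (4, 6, 8, 10)]

    y = obs["value"].to_numpy(dtype=float)
    genos = list(pd.unique(obs["genotype"].astype(str)))
    Kg = regularize(genotype_K.submatrix(genos), 1e-6)
    gidx = {g: k for k, g in enumerate(genos)}
    Zg = np.zeros((len(obs), len(genos)))
    Zg[np.arange(len(obs)), [gidx[g] for g in obs["genotype"].astype(str)]] = 1.0
    Kinv = np.linalg.inv(Kg.values)
    logdetK = float(np.linalg.slogdet(Kg.values)[1])
    X = np.ones((len(obs), 1))

    trials = list(pd.unique(obs["trial"]))
    rows = obs["row"].to_numpy(dtype=float)
    cols = obs["col"].to_numpy(dtype=float)

    results, errors = [], []
    warm = None
    for kr, kc in knot_grid:
        try:
            blocks = []
            total_cols = 0
            Zs_parts = []
            for tr in trials:
                sel = (obs["trial"] == tr).to_numpy()
                B = bspline_surface_design(rows[sel], cols[sel], kr, kc)
                Zs_parts.append((sel, B))
                total_cols += B.shape[1]
            Zs = np.zeros((len(obs), total_cols))
            c0 = 0
            for sel, B in Zs_parts:
                Zs[sel, c0:c0 + B.shape[1]] = B
                c0 += B.shape[1]
            theta, ll, trace, conv, n_iter, sol, offs = _emreml_mme(
                y, X, [Zg, Zs], [Kg.values, None], [Kinv, np.eye(total_cols)],
                [logdetK, 0.0], max_iter=max_iter, theta0=warm)
            if not conv:
                raise InvalidParameterError(
                    f"knot pair ({kr},{kc}) did not converge")
            warm = theta.copy()
            aic = -2.0 * ll + 2.0 * 3  # three variance parameters
            results.append({"kr": kr, "kc": kc, "sigma_g": theta[0],
                            "sigma_s": theta[1], "sigma_e": theta[2],
                            "loglik": ll, "aic": aic, "n_iter": n_iter,
                            "sol": sol, "offs": offs, "Zs": Zs})
        except (InvalidParameterError, np.linalg.LinAlgError) as exc:
            errors.append(f"({kr},{kc}): {exc}")
    if not results:
        raise InvalidParameterError(
            "no knot pair could be fitted: " + "; ".join(errors))

    table = pd.DataFrame([{k: r[k] for k in
                           ("kr", "kc", "sigma_g", "sigma_s", "sigma_e",
                            "loglik", "aic", "n_iter")} for r in results])
    aics = np.array([r["aic"] for r in results])
    close = np.flatnonzero(aics <= aics.min() + aic_tolerance)
    n_coef = [(results[k]["kr"] + 2) * (results[k]["kc"] + 2) for k in close]
    best = results[int(close[int(np.argmin(n_coef))])]
    sol, offs, Zs = best["sol"], best["offs"], best["Zs"]
    mu = float(sol[0])
    g_hat = sol[offs[0]:offs[1]]
    s_hat = sol[offs[1]:offs[2]]
    surface = Zs @ s_hat
    # identifiability: centre the surface within each trial, absorb the mean
    trial_means = {}
    for tr in trials:
        sel = (obs["trial"] == tr).to_numpy()
        m = float(surface[sel].mean())
        surface[sel] -= m
        trial_means[tr] = m
    mu += float(np.mean(list(trial_means.values())))

    return SpatialFit(
        trait=str(trait), knots=(best["kr"], best["kc"]),
        variance_components={"genetic": float(best["sigma_g"]),
                             "spatial": float(best["sigma_s"]),
                             "residual": float(best["sigma_e"])},
        loglik=float(best["loglik"]), aic=float(best["aic"]),
        surface=pd.Series(surface, index=obs.index),
        mu=mu, genotype_blup=pd.Series(g_hat, index=genos),
        knot_search=table, observations_index=obs.index, log=errors)


def adjust_and_average(observations: pd.DataFrame, fit: SpatialFit,
                       blocks=None) -> pd.DataFrame:
    """Adjusted clonal means: average of (value - surface) over blocks.

    ``blocks`` restricts the averaging to a subset (e.g. ``[1, 3, 5]``);
    genotypes absent from the retained blocks are dropped with a warning.
    Returns a frame with genotype, trait, mean, n_reps_used, blocks_used.
    """
    obs = observations.loc[fit.observations_index]
    adjusted = obs["value"].to_numpy(dtype=float) - fit.surface.to_numpy()
    work = obs.assign(adjusted=adjusted)
    if blocks is not None:
        blocks = list(blocks)
        if not blocks:
            raise InvalidParameterError("empty block subset")
        missing = set(blocks) - set(obs["block"].unique())
        if missing:
            raise InvalidParameterError(f"blocks {missing} not observed")
        kept = work.loc[work["block"].isin(blocks)]
    else:
        blocks = sorted(obs["block"].unique())
        kept = work
    dropped = set(work["genotype"]) - set(kept["genotype"])
    if dropped:
        warnings.warn(f"{len(dropped)} genotypes absent from retained blocks "
                      "were dropped", stacklevel=2)
    out = (kept.groupby("genotype", sort=False)["adjusted"]
           .agg(["mean", "count"]).reset_index())
    out.columns = ["genotype", "mean", "n_reps_used"]
    out.insert(1, "trait", fit.trait)
    out["blocks_used"] = ",".join(str(b) for b in blocks)
    return out
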