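"""REML variance components and BLUP prediction.

Models are individual-level mixed models on (spatially adjusted) clonal
means: ``y = X b + Z u + e`` with ``u ~ N(0, K sigma_a^2)`` for a
relationship matrix ``K`` (pedigree A or genomic G), optionally plus a
dominance term ``W d`` with its own relationship matrix, and iid residuals.
Variance components are estimated by EM-REML with Aitken acceleration; EM
steps never decrease the restricted likelihood, and accelerated steps are
accepted only when they improve it, so the log-likelihood trace is
monotone by construction.  BLUPs of all individuals in the relationship
matrix (phenotyped or not) are recovered from the converged fit through
``u_hat = sigma^2 K[:, phenotyped] P y``.

Three computational paths share the same driver:

* single relationship matrix: the model is folded to the phenotyped subset
  and rotated by the eigenbasis of ``K_ff``, making every EM step O(n);
* several relationship matrices (additive + dominance): EM via the dense
  n x n phenotypic covariance;
* replicated observations (used by the spatial adjustment): EM on
  Henderson's mixed-model equations.

The multi-trait model estimates unstructured genetic and residual
covariance matrices; with complete data it uses the same eigen-rotation
(rows become independent t-variate normals), with per-trait missing values
it runs EM on the observed entries so each individual contributes the
traits it has.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .core import (ConvergenceError, InvalidParameterError,
                   RelationshipMatrix)

__all__ = [
    "VarianceComponents", "FittedModel", "fit_reml", "fit_multitrait",
    "heritability", "predict_gebv",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VarianceComponents:
    """Estimated (co)variance parameters of one model.

    ``components`` maps term names (e.g. ``"additive"``, ``"dominance"``,
    ``"residual"``) to variances.  Multi-trait fits additionally carry the
    unstructured genetic and residual covariance matrices.
    """

    components: dict[str, float]
    traits: list[str] | None = None
    genetic_cov: np.ndarray | None = None
    residual_cov: np.ndarray | None = None

    def genetic_correlations(self) -> np.ndarray:
        if self.genetic_cov is None:
            raise InvalidParameterError("single-trait fit has no genetic correlations")
        sd = np.sqrt(np.diag(self.genetic_cov))
        return self.genetic_cov / np.outer(sd, sd)


@dataclass
class FittedModel:
    """A converged (or final-iterate) REML fit with its BLUP solutions."""

    terms: list[str]
    vc: VarianceComponents
    loglik: float
    aic: float
    beta: np.ndarray
    blups: dict[str, pd.Series]
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    phenotyped_ids: list[str]
    diagnostics: dict = field(default_factory=dict)

    @property
    def gebv(self) -> pd.Series:
        """BLUP of additive genetic merit for every individual in K."""
        return self.blups[self.terms[0]]

    def heritability(self) -> float:
        return heritability(self.vc)


def heritability(vc: VarianceComponents | dict) -> float:
    """Narrow-sense heritability ``sigma_a^2 / (sigma_a^2 + sigma_d^2 + sigma_e^2)``
    on the scale of the response (here: adjusted clonal means)."""
    comps = vc.components if isinstance(vc, VarianceComponents) else dict(vc)
    total = float(sum(comps.values()))
    if total <= 0:
        raise InvalidParameterError("total variance is zero")
    additive = comps.get("additive")
    if additive is None:
        additive = comps[next(k for k in comps if k != "residual")]
    return float(additive) / total


def predict_gebv(model: FittedModel, ids) -> pd.Series:
    """BLUP solutions restricted to ``ids`` (phenotyped or not)."""
    gebv = model.gebv
    missing = [i for i in ids if str(i) not in gebv.index]
    if missing:
        raise InvalidParameterError(f"ids not in fitted matrix: {missing[:5]}")
    return gebv.loc[[str(i) for i in ids]]


# ---------------------------------------------------------------------------
# Monotone EM driver with Aitken acceleration
# ---------------------------------------------------------------------------

def _run_em(theta0, evaluate, lower, max_iter, tol_loglik, tol_var,
            accelerate=True):
    """Drive EM to convergence, monotonically in the restricted likelihood.

    ``evaluate(theta) -> (loglik, theta_em[, theta_ai])`` returns the
    restricted log-likelihood at ``theta``, the EM update from it, and
    optionally an average-information (Newton-type) candidate.  Each
    iteration evaluates the EM update, the AI candidate (when supplied) and
    periodically an Aitken extrapolation, and keeps whichever attains the
    highest log-likelihood.  Since the EM update alone never decreases the
    likelihood, the accepted sequence is monotone.
    """

    def _eval(th):
        out = evaluate(th)
        return out if len(out) == 3 else (*out, None)

    theta = np.asarray(theta0, dtype=float)
    ll, theta_em, theta_ai = _eval(theta)
    trace = [ll]
    for it in range(1, max_iter + 1):
        em1 = np.maximum(theta_em, lower)
        ll_em, em2, ai_next = _eval(em1)
        best = (ll_em, em1, em2, ai_next)
        if accelerate and theta_ai is not None and np.isfinite(theta_ai).all():
            cand = np.maximum(theta_ai, lower)
            ll_c, em_c, ai_c = _eval(cand)
            if ll_c > best[0]:
                best = (ll_c, cand, em_c, ai_c)
        if accelerate:
            # boundary candidate: a vanishing component decays only
            # harmonically under EM, so try snapping it to its floor
            snap = np.isfinite(lower) & (em1 < 1e-3 * em1.max()) \
                & (em1 > lower)
            if snap.any():
                bc = em1.copy()
                bc[snap] = lower[snap]
                ll_b, em_b, ai_b = _eval(bc)
                if ll_b > best[0]:
                    best = (ll_b, bc, em_b, ai_b)
        if accelerate:
            # squared (Aitken delta-squared / SQUAREM) extrapolation through
            # two successive EM updates
            r = em1 - theta
            v = (em2 - em1) - r
            nv = float(np.linalg.norm(v))
            if nv > 0:
                alpha = min(-float(np.linalg.norm(r)) / nv, -1.0)
                sq = np.maximum(theta - 2 * alpha * r + alpha * alpha * v,
                                lower)
                ll_s, em_s, ai_s = _eval(sq)
                if ll_s > best[0]:
                    best = (ll_s, sq, em_s, ai_s)
        ll_new, cand, theta_em, theta_ai = best
        rel_ll = abs(ll_new - ll) / (1.0 + abs(ll))
        rel_var = np.max(np.abs(cand - theta) / (np.abs(theta) + 1e-30))
        theta, ll = cand, ll_new
        trace.append(ll)
        if rel_ll < tol_loglik and rel_var < tol_var:
            return theta, ll, np.array(trace), True, it
    return theta, ll, np.array(trace), False, max_iter


# ---------------------------------------------------------------------------
# Single-kernel path (eigen rotation)
# ---------------------------------------------------------------------------

def _eigh_psd(K):
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    return lam, U


def _single_kernel_evaluator(lam, ystar, Xstar, rank):
    n, p = Xstar.shape

    def evaluate(theta):
        sa, se = theta
        v = sa * lam + se
        w = 1.0 / v
        XtW = Xstar.T * w
        XtWX = XtW @ Xstar
        cf = cho_factor(XtWX)
        beta = cho_solve(cf, XtW @ ystar)
        r = ystar - Xstar @ beta
        Py = w * r
        Cx = cho_solve(cf, np.eye(p))
        # diag of V^-1 X (X'V^-1 X)^-1 X' V^-1
        h = np.einsum("ij,jk,ik->i", Xstar, Cx, Xstar) * w * w
        trP = w.sum() - h.sum()
        trPA = (w * lam).sum() - (h * lam).sum()
        yPAPy = float((lam * Py * Py).sum())
        yPPy = float((Py * Py).sum())
        sign, logdet_xtwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * (np.log(v).sum() + logdet_xtwx
                     + float(r @ Py) + (n - p) * _LOG2PI)
        sa_new = sa + sa * sa * (yPAPy - trPA) / max(rank, 1)
        se_new = se + se * se * (yPPy - trP) / n

        def Pdot(vv):
            wv = w * vv
            return wv - w * (Xstar @ cho_solve(cf, Xstar.T @ wv))

        va, ve = lam * Py, Py
        Pva, Pve = Pdot(va), Pdot(ve)
        ai = 0.5 * np.array([[va @ Pva, va @ Pve], [ve @ Pva, ve @ Pve]])
        score = -0.5 * np.array([trPA - yPAPy, trP - yPPy])
        theta_ai = _ai_candidate(theta, ai, score)
        return ll, np.array([sa_new, se_new]), theta_ai

    return evaluate


def _ai_candidate(theta, ai, score):
    try:
        step = np.linalg.solve(ai, score)
    except np.linalg.LinAlgError:
        return None
    cand = theta + step
    return cand if np.isfinite(cand).all() else None


# ---------------------------------------------------------------------------
# Multi-kernel path (dense phenotypic covariance)
# ---------------------------------------------------------------------------

def _multi_kernel_evaluator(Ks, ranks, y, X):
    n, p = X.shape

    def evaluate(theta):
        V = theta[-1] * np.eye(n)
        for s, K in zip(theta[:-1], Ks):
            V += s * K
        cf = cho_factor(V)
        Vinv = cho_solve(cf, np.eye(n))
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        cfx = cho_factor(XtVinvX)
        P = Vinv - VinvX @ cho_solve(cfx, VinvX.T)
        Py = P @ y
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        sign, logdet_x = np.linalg.slogdet(XtVinvX)
        ll = -0.5 * (logdet_v + logdet_x + float(y @ Py) + (n - p) * _LOG2PI)
        new = np.empty_like(theta)
        vs, quads, trs = [], [], []
        for k, (s, K, q) in enumerate(zip(theta[:-1], Ks, ranks)):
            v = K @ Py
            quad, tr = float(Py @ v), float((P * K).sum())
            vs.append(v)
            quads.append(quad)
            trs.append(tr)
            new[k] = s + s * s * (quad - tr) / q
        se = theta[-1]
        vs.append(Py)
        quads.append(float(Py @ Py))
        trs.append(float(np.trace(P)))
        new[-1] = se + se * se * (quads[-1] - trs[-1]) / n
        Vmat = np.column_stack(vs)
        ai = 0.5 * (Vmat.T @ P @ Vmat)
        score = -0.5 * (np.array(trs) - np.array(quads))
        return ll, new, _ai_candidate(theta, ai, score)

    return evaluate


def fit_reml(y: pd.Series, terms: list[tuple[str, RelationshipMatrix]],
             max_iter: int = 500, tol_loglik: float = 1e-8,
             tol_var: float = 1e-6, accelerate: bool = True,
             raise_on_nonconvergence: bool = True) -> FittedModel:
    """Single-trait EM-REML fit with an intercept and 1+ genetic terms.

    Parameters
    ----------
    y:
        Phenotypes (adjusted clonal means) indexed by genotype id.  Every id
        must be present in every supplied relationship matrix.
    terms:
        ``(name, RelationshipMatrix)`` pairs, e.g. ``[("additive", G)]`` or
        ``[("additive", A), ("dominance", D)]``.  With more than one term the
        matrices should be positive definite (see ``genomic.regularize``).

    Returns BLUPs for **all** individuals of each relationship matrix;
    unphenotyped individuals are predicted through their covariance with
    phenotyped ones.  Raises :class:`ConvergenceError` (carrying the last
    iterate in ``.model``) if REML does not converge.
    """
    y = y.dropna()
    if len(y) < 2:
        raise InvalidParameterError("need at least 2 phenotyped individuals")
    if not terms:
        raise InvalidParameterError("at least one random term is required")
    f_ids = [str(i) for i in y.index]
    if len(set(f_ids)) != len(f_ids):
        raise InvalidParameterError("duplicate ids in phenotype vector")
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    X = np.ones((n, 1))
    vary = float(np.var(yv)) or 1.0
    floor = 1e-8 * vary

    names = [t[0] for t in terms]
    Kffs = [t[1].values[np.ix_(t[1].indices(f_ids), t[1].indices(f_ids))]
            for t in terms]

    if len(terms) == 1:
        lam, U = _eigh_psd(Kffs[0])
        rank = int((lam > 1e-10 * max(lam[-1], 1.0)).sum())
        ystar = U.T @ yv
        Xstar = U.T @ X
        evaluate = _single_kernel_evaluator(lam, ystar, Xstar, rank)
        theta0 = np.array([0.5 * vary, 0.5 * vary])
    else:
        ranks = []
        for K in Kffs:
            lk = np.linalg.eigvalsh((K + K.T) / 2.0)
            ranks.append(int((lk > 1e-10 * max(lk[-1], 1.0)).sum()))
            if lk[0] < -1e-6 * max(lk[-1], 1.0):
                raise InvalidParameterError(
                    "relationship matrix is not PSD; regularize first")
        evaluate = _multi_kernel_evaluator(Kffs, ranks, yv, X)
        theta0 = np.full(len(terms) + 1, vary / (len(terms) + 1))

    lower = np.full_like(theta0, floor)
    theta, ll, trace, converged, n_iter = _run_em(
        theta0, evaluate, lower, max_iter, tol_loglik, tol_var, accelerate)

    comps = {nm: float(s) for nm, s in zip(names, theta[:-1])}
    comps["residual"] = float(theta[-1])
    vc = VarianceComponents(components=comps)
    k_par = len(theta)
    aic = -2.0 * ll + 2.0 * k_par

    # BLUPs via u_hat = sigma^2 K[:, f] P y
    if len(terms) == 1:
        sa, se = theta
        w = 1.0 / (sa * lam + se)
        XtW = Xstar.T * w
        beta = np.linalg.solve(XtW @ Xstar, XtW @ ystar)
        Py = U @ (w * (ystar - Xstar @ beta))
    else:
        V = theta[-1] * np.eye(n)
        for s, K in zip(theta[:-1], Kffs):
            V += s * K
        cf = cho_factor(V)
        Vinv_y = cho_solve(cf, yv)
        Vinv_X = cho_solve(cf, X)
        beta = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
        Py = cho_solve(cf, yv - X @ beta)

    blups = {}
    for (nm, K), s in zip(terms, theta[:-1]):
        cols = K.indices(f_ids)
        blups[nm] = pd.Series(s * (K.values[:, cols] @ Py), index=K.ids,
                              name=nm)

    at_bound = [nm for nm, s in zip(names + ["residual"], theta)
                if s <= floor * (1.0 + 1e-6)]
    model = FittedModel(
        terms=names, vc=vc, loglik=float(ll), aic=float(aic),
        beta=np.atleast_1d(beta), blups=blups, converged=converged,
        n_iter=n_iter, loglik_trace=trace, phenotyped_ids=f_ids,
        diagnostics={"at_lower_bound": at_bound},
    )
    if not converged and raise_on_nonconvergence:
        raise ConvergenceError(
            f"EM-REML did not converge in {max_iter} iterations", model=model)
    return model


# ---------------------------------------------------------------------------
# Multi-trait REML
# ---------------------------------------------------------------------------

def _bend_psd(S, rel_floor=1e-8):
    """Bend a symmetric matrix to the nearest PSD matrix (eigenvalue floor)."""
    S = (S + S.T) / 2.0
    lam, U = np.linalg.eigh(S)
    floor = rel_floor * max(lam[-1], 1e-12)
    if lam[0] >= floor:
        return S, False
    lam = np.clip(lam, floor, None)
    return (U * lam) @ U.T, True


def _pack(G0, R0, t):
    iu = np.triu_indices(t)
    return np.concatenate([G0[iu], R0[iu]])


def _unpack(theta, t):
    iu = np.triu_indices(t)
    m = len(iu[0])
    G0 = np.zeros((t, t))
    R0 = np.zeros((t, t))
    G0[iu] = theta[:m]
    R0[iu] = theta[m:]
    G0 = G0 + np.triu(G0, 1).T
    R0 = R0 + np.triu(R0, 1).T
    return G0, R0


def _multitrait_complete_evaluator(lam, Zstar, xstar, t, rank, bent_flag):
    n = len(lam)
    pos = lam > 1e-10 * max(lam[-1], 1.0)

    def evaluate(theta):
        G0, R0 = _unpack(theta, t)
        G0, b1 = _bend_psd(G0)
        R0, b2 = _bend_psd(R0, rel_floor=1e-10)
        if b1 or b2:
            bent_flag["bent"] = True
        Vi = lam[:, None, None] * G0 + R0  # (n, t, t)
        Wi = np.linalg.inv(Vi)
        x2 = xstar * xstar
        A = np.einsum("i,ijk->jk", x2, Wi)
        b = np.einsum("i,ijk,ik->j", xstar, Wi, Zstar)
        beta = np.linalg.solve(A, b)
        Vb = np.linalg.inv(A)
        R = Zstar - xstar[:, None] * beta
        WR = np.einsum("ijk,ik->ij", Wi, R)
        ghat = lam[:, None] * (WR @ G0.T)
        ehat = WR @ R0.T
        G0W = np.einsum("jk,ikl->ijl", G0, Wi)      # G0 Wi, (n,t,t)
        R0W = np.einsum("jk,ikl->ijl", R0, Wi)
        # conditional covariances with the REML correction through Var(beta)
        GWx = G0W * xstar[:, None, None]
        RWx = R0W * xstar[:, None, None]
        Cg = (lam[:, None, None] * G0
              - lam[:, None, None] ** 2 * np.einsum("ijk,kl->ijl", G0W, G0)
              + lam[:, None, None] ** 2
              * np.einsum("ijk,kl,iml->ijm", GWx, Vb, GWx))
        Ce = (R0[None] - np.einsum("ijk,kl->ijl", R0W, R0)
              + np.einsum("ijk,kl,iml->ijm", RWx, Vb, RWx))
        lam_safe = np.where(pos, lam, 1.0)
        contrib = (np.einsum("ij,ik->ijk", ghat, ghat) + Cg) / lam_safe[:, None, None]
        G0_new = contrib[pos].sum(axis=0) / max(rank, 1)
        R0_new = (np.einsum("ij,ik->ijk", ehat, ehat) + Ce).sum(axis=0) / n
        sign, logdet_A = np.linalg.slogdet(A)
        logdet_Vi = np.linalg.slogdet(Vi)[1].sum()
        quad = float(np.einsum("ij,ijk,ik->", R, Wi, R))
        ll = -0.5 * (logdet_Vi + logdet_A + quad + (n * t - t) * _LOG2PI)
        return ll, _pack((G0_new + G0_new.T) / 2, (R0_new + R0_new.T) / 2, t)

    return evaluate


def _multitrait_missing_evaluator(Kff, lam, U, Zobs, obs_i, obs_j, t,
                                  bent_flag):
    n = Kff.shape[0]
    pos = lam > 1e-10 * max(lam[-1], 1.0)
    rank = int(pos.sum())
    Kplus = (U[:, pos] / lam[pos]) @ U[:, pos].T
    n_obs = len(Zobs)
    X = np.zeros((n_obs, t))
    X[np.arange(n_obs), obs_j] = 1.0
    same = (obs_i[:, None] == obs_i[None, :])
    K_oo = Kff[np.ix_(obs_i, obs_i)]

    def evaluate(theta):
        G0, R0 = _unpack(theta, t)
        G0, b1 = _bend_psd(G0)
        R0, b2 = _bend_psd(R0, rel_floor=1e-10)
        if b1 or b2:
            bent_flag["bent"] = True
        Sg_oo = G0[np.ix_(obs_j, obs_j)] * K_oo
        R_oo = R0[np.ix_(obs_j, obs_j)] * same
        V = Sg_oo + R_oo
        cf = cho_factor(V)
        Vinv = cho_solve(cf, np.eye(n_obs))
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        beta = np.linalg.solve(XtVinvX, VinvX.T @ Zobs)
        P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
        Pz = P @ Zobs
        # genetic: u over all (individual, trait) cells
        Bg = (Kff[:, obs_i][:, None, :]
              * G0[:, obs_j][None, :, :])     # (n, t, n_obs): Sigma_g[:, obs]
        uhat = Bg @ Pz                        # (n, t)
        BgP = Bg.reshape(n * t, n_obs) @ P
        Cu = (np.kron(Kff, G0)
              - BgP @ Bg.reshape(n * t, n_obs).T).reshape(n, t, n, t)
        G0_new = (uhat.T @ Kplus @ uhat
                  + np.einsum("ik,ijkl->jl", Kplus, Cu)) / max(rank, 1)
        # residual: e over all cells, missing entries imputed by the E-step
        Br = np.zeros((n, t, n_obs))
        Br[obs_i, :, np.arange(n_obs)] = R0[:, obs_j].T
        ehat = Br @ Pz
        BrP = Br.reshape(n * t, n_obs) @ P
        Ce = (np.kron(np.eye(n), R0)
              - BrP @ Br.reshape(n * t, n_obs).T).reshape(n, t, n, t)
        Ce_diag = Ce[np.arange(n), :, np.arange(n), :]   # (n, t, t)
        R0_new = (np.einsum("ij,ik->jk", ehat, ehat) + Ce_diag.sum(axis=0)) / n
        sign, logdet_x = np.linalg.slogdet(XtVinvX)
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        resid = Zobs - X @ beta
        ll = -0.5 * (logdet_v + logdet_x + float(resid @ Vinv @ resid)
                     + (n_obs - t) * _LOG2PI)
        return ll, _pack((G0_new + G0_new.T) / 2, (R0_new + R0_new.T) / 2, t)

    return evaluate


def fit_multitrait(Y: pd.DataFrame, K: RelationshipMatrix,
                   max_iter: int = 500, tol_loglik: float = 1e-8,
                   tol_var: float = 1e-6, accelerate: bool = True,
                   raise_on_nonconvergence: bool = True) -> FittedModel:
    """Multi-trait additive G-BLUP with unstructured covariances.

    ``Y`` is an individuals x traits frame indexed by genotype id; NaN marks
    a missing trait value (the individual still contributes its observed
    traits).  Estimates genetic and residual covariance matrices by EM-REML,
    bending non-PD updates to the nearest PSD matrix (logged in
    ``diagnostics['bent']``), and returns per-trait GEBVs for all
    individuals in ``K``.
    """
    if Y.shape[1] < 2:
        raise InvalidParameterError("multi-trait model needs >= 2 traits")
    Y = Y.loc[Y.notna().any(axis=1)]
    traits = [str(c) for c in Y.columns]
    t = len(traits)
    f_ids = [str(i) for i in Y.index]
    idx = K.indices(f_ids)
    Kff = K.values[np.ix_(idx, idx)]
    Z = Y.to_numpy(dtype=float)
    n = len(f_ids)

    S0 = Y.cov(min_periods=2).to_numpy()  # pairwise-complete start value
    if np.isnan(S0).any():
        S0 = np.diag(np.nanvar(Z, axis=0))
    S0, _ = _bend_psd(S0 + np.eye(t) * 1e-8 * np.nanvar(Z))
    theta0 = _pack(0.5 * S0, 0.5 * S0, t)
    scale = float(np.nanvar(Z)) or 1.0
    lower = np.full_like(theta0, -np.inf)
    iu = np.triu_indices(t)
    diag_mask = np.concatenate([iu[0] == iu[1]] * 2)
    lower[diag_mask] = 1e-8 * scale

    bent_flag = {"bent": False}
    complete = not np.isnan(Z).any()
    lam, U = _eigh_psd(Kff)
    rank = int((lam > 1e-10 * max(lam[-1], 1.0)).sum())
    if complete:
        Zstar = U.T @ Z
        xstar = U.T @ np.ones(n)
        evaluate = _multitrait_complete_evaluator(lam, Zstar, xstar, t, rank,
                                                  bent_flag)
    else:
        mask = ~np.isnan(Z)
        obs_i, obs_j = np.nonzero(mask)
        Zobs = Z[obs_i, obs_j]
        evaluate = _multitrait_missing_evaluator(Kff, lam, U, Zobs, obs_i,
                                                 obs_j, t, bent_flag)

    theta, ll, trace, converged, n_iter = _run_em(
        theta0, evaluate, lower, max_iter, tol_loglik, tol_var, accelerate)
    G0, R0 = _unpack(theta, t)
    G0, _ = _bend_psd(G0)
    R0, _ = _bend_psd(R0, rel_floor=1e-10)

    # GEBVs: u_all = K[:, f] Kff^+ u_f, with u_f from the converged E-step
    if complete:
        Vi = lam[:, None, None] * G0 + R0
        Wi = np.linalg.inv(Vi)
        x2 = (U.T @ np.ones(n)) ** 2
        xs = U.T @ np.ones(n)
        A = np.einsum("i,ijk->jk", x2, Wi)
        b = np.einsum("i,ijk,ik->j", xs, Wi, U.T @ Z)
        beta = np.linalg.solve(A, b)
        Rr = (U.T @ Z) - xs[:, None] * beta
        S = np.einsum("ijk,ik->ij", Wi, Rr) @ G0.T   # G0 Wi r_i rows
        u_all = K.values[:, idx] @ (U @ S)
    else:
        mask = ~np.isnan(Z)
        obs_i, obs_j = np.nonzero(mask)
        Zobs = Z[obs_i, obs_j]
        n_obs = len(Zobs)
        X = np.zeros((n_obs, t))
        X[np.arange(n_obs), obs_j] = 1.0
        Sg_oo = G0[np.ix_(obs_j, obs_j)] * Kff[np.ix_(obs_i, obs_i)]
        R_oo = R0[np.ix_(obs_j, obs_j)] * (obs_i[:, None] == obs_i[None, :])
        V = Sg_oo + R_oo
        cf = cho_factor(V)
        VinvX = cho_solve(cf, X)
        beta = np.linalg.solve(X.T @ VinvX, VinvX.T @ Zobs)
        Pz = cho_solve(cf, Zobs - X @ beta)
        Bg = Kff[:, obs_i][:, None, :] * G0[:, obs_j][None, :, :]
        u_f = Bg @ Pz
        pos = lam > 1e-10 * max(lam[-1], 1.0)
        Kplus = (U[:, pos] / lam[pos]) @ U[:, pos].T
        u_all = K.values[:, idx] @ (Kplus @ u_f)

    blups = {trait: pd.Series(u_all[:, j], index=K.ids, name=trait)
             for j, trait in enumerate(traits)}
    comps = {f"genetic_{trait}": float(G0[j, j]) for j, trait in enumerate(traits)}
    comps.update({f"residual_{trait}": float(R0[j, j])
                  for j, trait in enumerate(traits)})
    vc = VarianceComponents(components=comps, traits=traits,
                            genetic_cov=G0, residual_cov=R0)
    k_par = t * (t + 1)
    aic = -2.0 * ll + 2.0 * k_par
    sd = np.sqrt(np.diag(G0))
    corr = G0 / np.outer(sd, sd)
    near_bound = bool((np.abs(corr[np.triu_indices(t, 1)]) > 0.999).any())
    if near_bound:
        warnings.warn("genetic correlation at its boundary (|r| ~ 1)",
                      stacklevel=2)
    model = FittedModel(
        terms=list(traits), vc=vc, loglik=float(ll), aic=float(aic),
        beta=np.atleast_1d(beta), blups=blups, converged=converged,
        n_iter=n_iter, loglik_trace=trace, phenotyped_ids=f_ids,
        diagnostics={"bent": bent_flag["bent"],
                     "correlation_at_boundary": near_bound},
    )
    if not converged and raise_on_nonconvergence:
        raise ConvergenceError(
            f"multi-trait EM-REML did not converge in {max_iter} iterations",
            model=model)
    return model


# ---------------------------------------------------------------------------
# MME-based EM-REML for replicated observations (used by field_adjustment)
# ---------------------------------------------------------------------------

def _emreml_mme(y, X, Z_blocks, K_blocks, Kinv_blocks, logdet_K_blocks,
                max_iter=500, tol_loglik=1e-8, tol_var=1e-6,
                accelerate=True, theta0=None):
    """EM-REML through Henderson's mixed-model equations.

    ``Z_blocks`` are incidence matrices (one per random term); ``K_blocks``
    and ``Kinv_blocks`` the forward/inverse covariance structures (identity
    for iid terms, ``None`` in ``K_blocks`` is read as identity);
    ``logdet_K_blocks`` the log-determinants of the forward structures.
    Returns (theta, loglik, trace, converged, n_iter, solution, offsets)
    where ``solution`` stacks fixed-effect and random-effect estimates at
    the REML variance components.
    """
    n, p = X.shape
    W = np.hstack([X] + Z_blocks)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    sizes = [Z.shape[1] for Z in Z_blocks]
    offs = np.cumsum([p] + sizes)
    vary = float(np.var(y)) or 1.0
    floor = 1e-8 * vary
    r = len(Z_blocks)

    def build(theta):
        M = WtW / theta[-1]
        for k in range(r):
            a, b = offs[k], offs[k + 1]
            M[a:b, a:b] += Kinv_blocks[k] / theta[k]
        return M

    def evaluate(theta):
        M = build(theta)
        cf = cho_factor(M)
        sol = cho_solve(cf, Wty / theta[-1])
        Minv = cho_solve(cf, np.eye(M.shape[0]))
        se = theta[-1]
        new = np.empty_like(theta)
        resid = y - W @ sol
        Py = resid / se

        def Pdot(v):
            return (v - W @ cho_solve(cf, W.T @ v / se)) / se

        quads, trs, vs, tr_list = [], [], [], []
        for k in range(r):
            a, b = offs[k], offs[k + 1]
            u = sol[a:b]
            quad_u = float(u @ Kinv_blocks[k] @ u)
            tr_u = float((Kinv_blocks[k] * Minv[a:b, a:b]).sum())
            tr_list.append(tr_u)
            new[k] = (quad_u + tr_u) / sizes[k]
            # score pieces: y'P Gk P y and tr(P Gk)
            quads.append(quad_u / theta[k] ** 2)
            trs.append((sizes[k] - tr_u / theta[k]) / theta[k])
            ZtPy = Z_blocks[k].T @ Py
            KZtPy = ZtPy if K_blocks[k] is None else K_blocks[k] @ ZtPy
            vs.append(Z_blocks[k] @ KZtPy)
        resid_ss = yty - float(sol @ Wty)
        new[-1] = resid_ss / (n - p)
        quads.append(float(Py @ Py))
        trs.append((n - p - sum(sizes[k] - tr_list[k] / theta[k]
                                for k in range(r))) / se)
        vs.append(Py)
        Vmat = np.column_stack(vs)
        ai = 0.5 * (Vmat.T @ np.column_stack([Pdot(v) for v in vs]))
        score = -0.5 * (np.array(trs) - np.array(quads))
        theta_ai = _ai_candidate(theta, ai, score)
        logdet_M = 2.0 * np.log(np.diag(cf[0])).sum()
        logdet_G = sum(sizes[k] * np.log(theta[k]) + logdet_K_blocks[k]
                       for k in range(r))
        yPy = resid_ss / se
        ll = -0.5 * (logdet_M + n * np.log(se) + logdet_G + yPy
                     + (n - p) * _LOG2PI)
        return ll, new, theta_ai

    if theta0 is None:
        theta0 = np.full(r + 1, vary / (r + 1))
    lower = np.full(r + 1, floor)
    theta, ll, trace, converged, n_iter = _run_em(
        np.asarray(theta0, float), evaluate, lower, max_iter, tol_loglik,
        tol_var, accelerate)
    M = build(theta)
    sol = cho_solve(cho_factor(M), Wty / theta[-1])
    return theta, ll, trace, converged, n_iter, sol, offs
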