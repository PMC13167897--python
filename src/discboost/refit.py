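"""Penalized Newton re-estimation of a selected model structure.

Boosting shrinks coefficients towards zero; after selection the chosen terms
are refit by maximising the penalized log-likelihood

    l_lambda(omega) = l(omega) - (lambda/2) theta' S theta,

where the quadratic penalty acts only on the spline blocks of time-varying
effects (P-spline: squared second differences of the coefficients;
smoothing-spline: integrated squared second derivatives of the fitted
curves).  The smoothing parameter is chosen by the Takeuchi information
criterion TIC = -2 l + 2 tr(I_lambda^{-1} I_0).  The refit also provides the
re-estimation degrees of freedom

    df = tr(2 I_lambda^{-1} I_0 - I_0 I_lambda^{-1} I_0 I_lambda^{-1})

used by the re-estimation BIC stopping rule, evaluated along the boosting
path every few iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .basis import (SplineBasis, pspline_penalty_block,
                    smoothing_spline_penalty_block)
from .boosting import BoostingTrace, INT, TI, TV
from .data import DiscreteSurvivalData, ModelState
from .model import log_likelihood_from_eta

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple([0.0] + [10 ** e for e in np.arange(-3, 3.5, 0.5)])


@dataclass(frozen=True)
class ModelStructure:
    """Term-level structure of a selected model (0-based covariate indices)."""

    main: tuple          # covariates with a phi term
    tv: tuple            # covariates with a theta block
    pairs: tuple         # interaction pairs (j, j'), j < j'

    @classmethod
    def from_terms(cls, terms) -> "ModelStructure":
        main = sorted({idx for cat, idx in terms if cat == TI})
        tv = sorted({idx for cat, idx in terms if cat == TV})
        pairs = sorted({idx for cat, idx in terms if cat == INT})
        return cls(tuple(main), tuple(tv), tuple(pairs))

    @classmethod
    def from_state(cls, state: ModelState) -> "ModelStructure":
        return cls(tuple(np.where(state.phi != 0)[0]),
                   tuple(np.where(np.any(state.theta != 0, axis=1))[0]),
                   tuple(state.selected_pairs()))

    def n_params(self, S: int, K1: int) -> int:
        return S + len(self.main) + len(self.tv) * K1 + len(self.pairs)

    def slices(self, S: int, K1: int):
        p1, p2, p3 = len(self.main), len(self.tv), len(self.pairs)
        o = S
        return {"gamma": slice(0, S), "phi": slice(o, o + p1),
                "theta": slice(o + p1, o + p1 + p2 * K1),
                "alpha": slice(o + p1 + p2 * K1, o + p1 + p2 * K1 + p3)}

    def to_state(self, omega: np.ndarray, S: int, P: int, K1: int) -> ModelState:
        sl = self.slices(S, K1)
        state = ModelState.zeros(S, P, K1)
        state.gamma[:] = omega[sl["gamma"]]
        state.phi[list(self.main)] = omega[sl["phi"]]
        th = omega[sl["theta"]].reshape(len(self.tv), K1)
        for r, j in enumerate(self.tv):
            state.theta[j] = th[r]
        al = omega[sl["alpha"]]
        for r, p in enumerate(self.pairs):
            state.alpha[p] = float(al[r])
        return state


@dataclass
class PenaltySpec:
    """Quadratic wiggliness penalty on the selected spline blocks."""

    kind: str = "pspline"          # none | pspline | smoothing_spline
    lam: float = 0.0
    Smat: np.ndarray | None = None  # (p2*K1, p2*K1) block over theta coords

    def __post_init__(self):
        if self.kind not in ("none", "pspline", "smoothing_spline"):
            raise ValueError("penalty kind must be none, pspline or smoothing_spline")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class FitResult:
    structure: ModelStructure
    omega: np.ndarray
    loglik: float
    penalized_loglik: float
    I0: np.ndarray
    Ilambda: np.ndarray
    converged: bool
    iterations: int
    lam: float
    penalty_kind: str
    df_reest: float | None = None
    bic_reest: float | None = None
    tic: float | None = None

    def to_state(self, data: DiscreteSurvivalData, basis: SplineBasis) -> ModelState:
        return self.structure.to_state(self.omega, data.grid.S, data.P, basis.K1)


def penalty_matrix(basis: SplineBasis, kind: str, n_tv: int) -> np.ndarray:
    """Block-diagonal penalty over n_tv spline blocks of K-1 coefficients."""
    K1 = basis.K1
    if n_tv == 0 or kind == "none":
        return np.zeros((n_tv * K1, n_tv * K1))
    if kind == "pspline":
        block = pspline_penalty_block(K1)
    elif kind == "smoothing_spline":
        block = smoothing_spline_penalty_block(basis)
    else:
        raise ValueError(f"unknown penalty kind {kind!r}")
    S = np.zeros((n_tv * K1, n_tv * K1))
    for r in range(n_tv):
        S[r * K1:(r + 1) * K1, r * K1:(r + 1) * K1] = block
    return S


def _full_penalty(structure: ModelStructure, basis: SplineBasis, pen: PenaltySpec,
                  S: int) -> np.ndarray:
    """Embed the theta-block penalty into the full omega coordinates."""
    p = structure.n_params(S, basis.K1)
    out = np.zeros((p, p))
    n_tv = len(structure.tv)
    if n_tv and pen.kind != "none":
        Sth = pen.Smat if pen.Smat is not None else penalty_matrix(basis, pen.kind, n_tv)
        sl = structure.slices(S, basis.K1)["theta"]
        out[sl, sl] = Sth
    return out


class _StructureDesign:
    """Block-wise (per time index) design assembly for a selected structure.

    Nothing of size N x p is ever materialised; each risk-set block's design
    is built transiently and aggregated into the score and information.
    """

    def __init__(self, data: DiscreteSurvivalData, basis: SplineBasis,
                 structure: ModelStructure):
        self.data = data
        self.basis = basis
        self.structure = structure
        self.S = data.grid.S
        self.K1 = basis.K1
        self.p = structure.n_params(self.S, self.K1)
        self.sl = structure.slices(self.S, self.K1)
        self.main_idx = list(structure.main)
        self.tv_idx = list(structure.tv)
        self.pair_cols = np.stack(
            [data.Z[:, j] * data.Z[:, jp] for j, jp in structure.pairs], axis=1
        ) if structure.pairs else np.empty((data.n, 0))

    def eta(self, omega: np.ndarray) -> np.ndarray:
        data, sl = self.data, self.sl
        subj, s0 = data.obs_subject, data.obs_s - 1
        eta = omega[sl["gamma"]][s0].copy()
        if self.main_idx:
            eta += (data.Z[:, self.main_idx] @ omega[sl["phi"]])[subj]
        if self.tv_idx:
            th = omega[sl["theta"]].reshape(len(self.tv_idx), self.K1)
            tv = data.Z[:, self.tv_idx] @ th               # n x K1
            eta += np.einsum("ok,ok->o", tv[subj], self.basis.Bmat[s0])
        if self.pair_cols.shape[1]:
            eta += (self.pair_cols @ omega[sl["alpha"]])[subj]
        return eta

    def _block_cov_design(self, s: int, rows_subj: np.ndarray) -> np.ndarray:
        """Covariate part of the design rows for risk-set block s (0-based)."""
        Z = self.data.Z
        parts = []
        if self.main_idx:
            parts.append(Z[np.ix_(rows_subj, self.main_idx)])
        if self.tv_idx:
            Ztv = Z[np.ix_(rows_subj, self.tv_idx)]
            Bs = self.basis.Bmat[s]
            parts.append((Ztv[:, :, None] * Bs[None, None, :]).reshape(len(rows_subj), -1))
        if self.pair_cols.shape[1]:
            parts.append(self.pair_cols[rows_subj])
        if not parts:
            return np.empty((len(rows_subj), 0))
        return np.concatenate(parts, axis=1)

    def score_and_information(self, omega: np.ndarray):
        """Exact analytic score and observed information of the log-likelihood."""
        data = self.data
        eta = self.eta(omega)
        mu = expit(eta)
        U = data.y - mu
        w = mu * (1.0 - mu)
        p, S = self.p, self.S
        q = p - S
        g = np.zeros(p)
        I0 = np.zeros((p, p))
        starts, counts = data.block_starts, data.risk_counts
        gcov = np.zeros(q)
        Icc = np.zeros((q, q))
        for s in range(S):
            if counts[s] == 0:
                continue
            sl_o = slice(starts[s], starts[s] + counts[s])
            rows = data.obs_subject[sl_o]
            C = self._block_cov_design(s, rows)
            Us, ws = U[sl_o], w[sl_o]
            g[s] = Us.sum()
            I0[s, s] = ws.sum()
            if q:
                gcov += C.T @ Us
                wc = ws[:, None] * C
                Icc += C.T @ wc
                I0[s, S:] = ws @ C
                I0[S:, s] = I0[s, S:]
        if q:
            g[S:] = gcov
            I0[S:, S:] = Icc
        ll = log_likelihood_from_eta(eta, data.y)
        return ll, g, I0


def penalized_loglik(omega, data: DiscreteSurvivalData, basis: SplineBasis,
                     structure: ModelStructure, pen: PenaltySpec) -> float:
    des = _StructureDesign(data, basis, structure)
    ll = log_likelihood_from_eta(des.eta(omega), data.y)
    Sfull = _full_penalty(structure, basis, pen, data.grid.S)
    return ll - 0.5 * pen.lam * float(omega @ Sfull @ omega)


def score_and_information(omega, data: DiscreteSurvivalData, basis: SplineBasis,
                          structure: ModelStructure, pen: PenaltySpec):
    """(penalized score, I0, Ilambda) at omega."""
    des = _StructureDesign(data, basis, structure)
    _, g, I0 = des.score_and_information(omega)
    Sfull = _full_penalty(structure, basis, pen, data.grid.S)
    g_pen = g - pen.lam * (Sfull @ omega)
    return g_pen, I0, I0 + pen.lam * Sfull


def newton_fit(data: DiscreteSurvivalData, basis: SplineBasis,
               structure: ModelStructure, pen: PenaltySpec,
               init: np.ndarray | None = None,
               max_iter: int = 100, tol: float = 1e-8,
               armijo_c: float = 1e-4, max_halvings: int = 30) -> FitResult:
    """Maximise the penalized log-likelihood by damped Newton ascent.

    The step multiplier alpha <= 1 is chosen by Armijo backtracking, so the
    penalized objective never decreases across accepted steps.  Non-converged
    fits return the best iterate with ``converged=False``.
    """
    des = _StructureDesign(data, basis, structure)
    p = des.p
    Sfull = _full_penalty(structure, basis, pen, data.grid.S)
    lam = pen.lam
    omega = np.zeros(p) if init is None else np.array(init, float)
    if omega.shape != (p,):
        raise ValueError("init has wrong length for this structure")

    def objective(om, ll=None):
        if ll is None:
            ll = log_likelihood_from_eta(des.eta(om), data.y)
        return ll - 0.5 * lam * float(om @ Sfull @ om)

    ll, g, I0 = des.score_and_information(omega)
    f = objective(omega, ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_pen = g - lam * (Sfull @ omega)
        if np.max(np.abs(g_pen)) < tol:
            converged = True
            break
        Ilam = I0 + lam * Sfull
        try:
            step = np.linalg.solve(Ilam, g_pen)
        except np.linalg.LinAlgError:
            jitter = 1e-8 * max(np.trace(Ilam) / p, 1.0)
            warnings.warn("singular information matrix; adding ridge jitter")
            step = np.linalg.solve(Ilam + jitter * np.eye(p), g_pen)
        gd = float(g_pen @ step)
        if gd <= 0:    # not an ascent direction (can happen far from optimum)
            step = g_pen
            gd = float(g_pen @ g_pen)
        alpha = 1.0
        for _ in range(max_halvings):
            cand = omega + alpha * step
            fc = objective(cand)
            if np.isfinite(fc) and fc >= f + armijo_c * alpha * gd:
                break
            alpha *= 0.5
        else:
            break      # line search failed; keep best iterate
        omega = cand
        ll, g, I0 = des.score_and_information(omega)
        f = objective(omega, ll)
    Ilam = I0 + lam * Sfull
    return FitResult(structure=structure, omega=omega, loglik=ll,
                     penalized_loglik=f, I0=I0, Ilambda=Ilam,
                     converged=converged, iterations=it, lam=lam,
                     penalty_kind=pen.kind)


def _solve_psd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric PSD A, ridging singular directions.

    Unidentified parameters (e.g. baseline entries of times with no events or
    an empty risk set) make the observed information singular; a small ridge
    on the scale of the diagonal leaves identified directions untouched.
    """
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        p = A.shape[0]
        ridge = 1e-10 * max(float(np.trace(A)) / p, 1.0)
        warnings.warn("singular information matrix; ridging unidentified directions")
        return np.linalg.solve(A + ridge * np.eye(p), B)


def takeuchi_ic(fit: FitResult) -> float:
    """TIC = -2 l + 2 tr(I_lambda^{-1} I_0)."""
    M = _solve_psd(fit.Ilambda, fit.I0)
    return -2.0 * fit.loglik + 2.0 * float(np.trace(M))


def reestimation_df(I0: np.ndarray, Ilambda: np.ndarray) -> float:
    """tr(2 I_lambda^{-1} I_0 - I_0 I_lambda^{-1} I_0 I_lambda^{-1}).

    Equals the parameter count exactly at lambda = 0.
    """
    M = _solve_psd(Ilambda, I0)
    return float(2.0 * np.trace(M) - np.sum(M * M.T))


def tic_select_lambda(data: DiscreteSurvivalData, basis: SplineBasis,
                      structure: ModelStructure,
                      lambda_grid=DEFAULT_LAMBDA_GRID, kind: str = "pspline",
                      init: np.ndarray | None = None):
    """Fit at every lambda on the grid; return (lambda*, fit*) minimising TIC."""
    if len(lambda_grid) == 0:
        raise ValueError("empty lambda grid")
    if not structure.tv:
        # no spline blocks: penalty is inert, a single unpenalized fit suffices
        fit = newton_fit(data, basis, structure, PenaltySpec("none", 0.0), init=init)
        fit.tic = takeuchi_ic(fit)
        return 0.0, fit
    best = None
    warm = init
    for lam in lambda_grid:
        pen = PenaltySpec(kind if lam > 0 else kind, float(lam))
        fit = newton_fit(data, basis, structure, pen, init=warm)
        fit.tic = takeuchi_ic(fit)
        warm = fit.omega
        if best is None or fit.tic < best[1].tic:
            best = (float(lam), fit)
    if best is None:
        raise RuntimeError("all penalized fits failed")
    return best


def reestimation_bic_path(data: DiscreteSurvivalData, basis: SplineBasis,
                          trace: BoostingTrace, every: int = 5,
                          kind: str = "pspline",
                          lambda_grid=DEFAULT_LAMBDA_GRID,
                          patience: int | None = None):
    """Re-estimation BIC stopping rule along the boosting path.

    Every ``every``-th iteration (plus the final one) the structure selected
    so far is refit by penalized Newton with lambda chosen by TIC, and
    BIC(m) = -2 l + log(n) df_reest is recorded.  The structure only changes
    when a term enters for the first time, so refits are cached per distinct
    structure.  With ``patience`` set, the scan stops once the BIC has not
    improved for that many consecutive evaluation points.  Returns
    (m_stop, fit at m_stop, list of (m, bic) records).
    """
    ms = list(range(every, trace.m_run + 1, every))
    if trace.m_run not in ms:
        ms.append(trace.m_run)
    cache: dict = {}
    warm_fit = None
    path = []
    logn = np.log(trace.n)
    best_bic, since_best = np.inf, 0
    for m in ms:
        structure = ModelStructure.from_terms(trace.structure_at(m))
        key = (structure.main, structure.tv, structure.pairs)
        if key not in cache:
            init = _warm_start(warm_fit, structure, data.grid.S, basis.K1)
            lam, fit = tic_select_lambda(data, basis, structure,
                                         lambda_grid=lambda_grid, kind=kind,
                                         init=init)
            fit.df_reest = reestimation_df(fit.I0, fit.Ilambda)
            fit.bic_reest = -2.0 * fit.loglik + logn * fit.df_reest
            cache[key] = fit
            warm_fit = fit
        bic = cache[key].bic_reest
        path.append((m, bic))
        if bic < best_bic:
            best_bic, since_best = bic, 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                break
    m_stop, _ = min(path, key=lambda t: (t[1], t[0]))
    structure = ModelStructure.from_terms(trace.structure_at(m_stop))
    fit = cache[(structure.main, structure.tv, structure.pairs)]
    return m_stop, fit, path


def _warm_start(prev: FitResult | None, structure: ModelStructure,
                S: int, K1: int) -> np.ndarray | None:
    """Map a previous (nested) fit's parameters into a larger structure."""
    if prev is None:
        return None
    omega = np.zeros(structure.n_params(S, K1))
    sl_new, sl_old = structure.slices(S, K1), prev.structure.slices(S, K1)
    omega[sl_new["gamma"]] = prev.omega[sl_old["gamma"]]
    old_phi = dict(zip(prev.structure.main, prev.omega[sl_old["phi"]]))
    omega[sl_new["phi"]] = [old_phi.get(j, 0.0) for j in structure.main]
    old_th = prev.omega[sl_old["theta"]].reshape(len(prev.structure.tv), K1)
    old_th = {j: old_th[r] for r, j in enumerate(prev.structure.tv)}
    th = np.zeros((len(structure.tv), K1))
    for r, j in enumerate(structure.tv):
        if j in old_th:
            th[r] = old_th[j]
    omega[sl_new["theta"]] = th.ravel()
    old_al = dict(zip(prev.structure.pairs, prev.omega[sl_old["alpha"]]))
    omega[sl_new["alpha"]] = [old_al.get(p, 0.0) for p in structure.pairs]
    return omega


def hazard_ratio_curve(fit: FitResult, basis: SplineBasis, z1, z0,
                       level: float = 0.95):
    """Time-varying odds/hazard-ratio curve exp{f(t_s;z1) - f(t_s;z0)} with
    delta-method confidence bands from the inverse penalized information."""
    from scipy.stats import norm

    z1 = np.asarray(z1, float)
    z0 = np.asarray(z0, float)
    S = fit.I0.shape[0] - (len(fit.structure.main)
                           + len(fit.structure.tv) * basis.K1
                           + len(fit.structure.pairs))
    sl = fit.structure.slices(S, basis.K1)
    times = basis.times
    zq = norm.ppf(0.5 + level / 2.0)
    cov = _solve_psd(fit.Ilambda, np.eye(fit.Ilambda.shape[0]))
    est = np.empty(S)
    lo = np.empty(S)
    hi = np.empty(S)
    dz = z1 - z0
    for s in range(S):
        c = np.zeros(fit.omega.size)
        c[sl["phi"]] = dz[list(fit.structure.main)]
        if fit.structure.tv:
            Bs = basis.Bmat[s]
            c[sl["theta"]] = np.outer(dz[list(fit.structure.tv)], Bs).ravel()
        for r, (j, jp) in enumerate(fit.structure.pairs):
            c[sl["alpha"].start + r] = z1[j] * z1[jp] - z0[j] * z0[jp]
        log_est = float(c @ fit.omega)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        est[s] = np.exp(log_est)
        lo[s] = np.exp(log_est - zq * se)
        hi[s] = np.exp(min(log_est + zq * se, 700.0))   # inf-safe upper band
    return {"time": times.copy(), "estimate": est, "lo": lo, "hi": hi}
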