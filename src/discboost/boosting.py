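"""Component-wise gradient boosting for the discrete logistic hazard model.

Each iteration recomputes the pseudo-observation gradient U_is = y_is -
expit(eta_is), updates the baseline log-odds gamma by its closed-form least
squares fit to U (step size nu_gamma = 1), then fits U by least squares to
every eligible term -- time-independent effects, spline blocks of
time-varying effects, and interaction pairs currently allowed by the
hierarchy -- and advances only the best-fitting term by a step nu (default
0.5).  Interaction eligibility is managed through the dynamic candidate sets
G1 (covariates with any selected main term) and G2 (pairs allowed by the
strong/weak/no-hierarchy rule).

The boosting BIC stopping rule tracks an approximate hat matrix over the N
pseudo-observations,

    B_1 = nu W^[0] H^{g_1},   B_m = B_{m-1} + nu W^[m-1] H^{g_m} (I - B_{m-1}),

with H^g the least-squares projection onto the design columns of term g and W
the diagonal of logistic working weights; the gamma update's projection is
composed before the selected term's each iteration.  df(m) = trace(B_m) and
BIC(m) = -2 loglik + log(n) df(m), minimised over the path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .basis import SplineBasis
from .data import DiscreteSurvivalData, ModelState
from .model import log_likelihood_from_eta

logger = logging.getLogger(__name__)

TI, TV, INT = "TI", "TV", "INT"
_CATEGORY_ORDER = {TI: 0, TV: 1, INT: 2}


@dataclass
class BoostingConfig:
    nu: float = 0.5
    nu_gamma: float = 1.0
    m_max: int = 500
    hierarchy: str = "strong"          # strong | weak | none
    tv_hierarchy: bool = False         # theta_j eligible only once phi_j != 0
    stopping: str = "boosting_bic"     # boosting_bic | reestimation_bic | fixed
    seed: int = 0
    hat_cap: int = 20000               # refuse dense N x N hat matrix above this
    bic_patience: int | None = None    # stop once BIC unimproved this long
    hat_method: str = "dense"          # dense | probe (randomised trace)
    n_probes: int = 256                # probe vectors for hat_method="probe"
    hat_include_gamma: bool = True     # compose the gamma projection into B_m

    def __post_init__(self):
        if not (0 < self.nu <= 1):
            raise ValueError("nu must be in (0, 1]")
        if self.m_max < 1:
            raise ValueError("m_max must be >= 1")
        if self.hierarchy not in ("strong", "weak", "none"):
            raise ValueError("hierarchy must be strong, weak or none")
        if self.stopping not in ("boosting_bic", "reestimation_bic", "fixed"):
            raise ValueError("unknown stopping rule")


@dataclass
class CandidateSets:
    """Dynamic eligibility sets for hierarchical interaction selection."""

    P: int
    hierarchy: str = "strong"
    G1: set = field(default_factory=set)
    G2: set = field(default_factory=set)

    def __post_init__(self):
        self.G2 = self._eligible_pairs()

    def _eligible_pairs(self) -> set:
        if self.hierarchy == "none":
            return {(j, jp) for j in range(self.P) for jp in range(j + 1, self.P)}
        if self.hierarchy == "strong":
            return {(j, jp) for j in self.G1 for jp in self.G1 if j < jp}
        # weak: at least one parent selected
        return {(j, jp) for j in range(self.P) for jp in range(j + 1, self.P)
                if j in self.G1 or jp in self.G1}

    def update(self, term) -> None:
        """Register a just-selected term; recompute G2 from G1."""
        cat, idx = term
        if cat in (TI, TV) and idx not in self.G1:
            self.G1.add(idx)
            self.G2 = self._eligible_pairs()


@dataclass
class BoostingTrace:
    """Per-iteration record of a boosting run."""

    records: list                       # dicts: m, term, increment, loglik, df, bic
    gamma_steps: np.ndarray             # (m_run, S) gamma_tilde per iteration
    config: BoostingConfig
    S: int
    P: int
    K1: int
    n: int
    m_stop: int | None = None           # argmin boosting BIC (if hat path ran)

    @property
    def m_run(self) -> int:
        return len(self.records)

    def structure_at(self, m: int) -> list:
        """Distinct terms selected up to and including iteration m."""
        seen, out = set(), []
        for rec in self.records[:m]:
            t = rec["term"]
            if t not in seen:
                seen.add(t)
                out.append(t)
        return out

    def state_at(self, m: int) -> ModelState:
        """Replay the path to reconstruct the model state after iteration m."""
        state = ModelState.zeros(self.S, self.P, self.K1)
        nu, nug = self.config.nu, self.config.nu_gamma
        state.gamma += nug * self.gamma_steps[:m].sum(axis=0)
        for rec in self.records[:m]:
            cat, idx = rec["term"]
            inc = rec["increment"]
            if cat == TI:
                state.phi[idx] += nu * inc
            elif cat == TV:
                state.theta[idx] += nu * inc
            else:
                state.alpha[idx] = state.alpha.get(idx, 0.0) + nu * inc
        return state

    def final_state(self) -> ModelState:
        """State at m_stop under the boosting BIC rule (else at the last iteration)."""
        m = self.m_stop if self.m_stop is not None else self.m_run
        return self.state_at(m)


# ---------------------------------------------------------------------------
# Reference implementations of the individual update operations (the fast
# path in run_boosting goes through the vectorised workspace below).
# ---------------------------------------------------------------------------

def flatten_gradient(U, data: DiscreteSurvivalData) -> np.ndarray:
    """Accept a ragged per-subject gradient or a flat one; return flat."""
    U = np.concatenate([np.asarray(u, float) for u in U]) if isinstance(U, list) else np.asarray(U, float)
    if U.shape != (data.N,):
        raise ValueError("gradient length must equal the pseudo-observation count")
    return U


def baseline_ls(U, data: DiscreteSurvivalData) -> np.ndarray:
    """Closed-form minimiser of sum_is (U_is - gamma_s)^2: risk-set means.

    Times with an empty risk set get gamma_tilde_s = 0.
    """
    Uf = _as_block_flat(U, data)
    gt = np.zeros(data.grid.S)
    sums = np.zeros(data.grid.S)
    np.add.at(sums, data.obs_s - 1, Uf)
    nz = data.risk_counts > 0
    gt[nz] = sums[nz] / data.risk_counts[nz]
    return gt


def apply_baseline(state: ModelState, U, gamma_tilde, data: DiscreteSurvivalData,
                   nu_gamma: float = 1.0):
    """gamma_s += nu_gamma * gamma_tilde_s; U_is -= gamma_tilde_s (in place on a copy)."""
    Uf = _as_block_flat(U, data).copy()
    state = state.copy()
    state.gamma = state.gamma + nu_gamma * np.asarray(gamma_tilde, float)
    Uf -= np.asarray(gamma_tilde, float)[data.obs_s - 1]
    return state, Uf


def _as_block_flat(U, data: DiscreteSurvivalData) -> np.ndarray:
    """Flat gradient in the data's time-block order."""
    if isinstance(U, list):
        # ragged per-subject -> block order
        flat_subj = np.concatenate([np.asarray(u, float) for u in U])
        order = np.lexsort((data.obs_s, data.obs_subject))
        out = np.empty(data.N)
        out[order] = flat_subj
        return out
    U = np.asarray(U, float)
    if U.shape != (data.N,):
        raise ValueError("flat gradient must have one entry per pseudo-observation")
    return U


def term_design_column(data: DiscreteSurvivalData, basis: SplineBasis, term):
    """Design column(s) of a term over the pseudo-observations (N x k)."""
    cat, idx = term
    subj = data.obs_subject
    if cat == TI:
        return data.Z[subj, idx][:, None]
    if cat == INT:
        j, jp = idx
        return (data.Z[subj, j] * data.Z[subj, jp])[:, None]
    if cat == TV:
        x = data.Z[subj, idx]
        return basis.Bmat[data.obs_s - 1] * x[:, None]
    raise ValueError(f"unknown term {term!r}")


def group_ls_fit(U, data: DiscreteSurvivalData, basis: SplineBasis, term):
    """Closed-form least-squares fit of the gradient to one term.

    Returns (coefficients, RSS): a scalar for TI/INT terms, the (K-1)-vector
    solving the spline-block normal equations for TV terms.  Raises
    ``np.linalg.LinAlgError`` if the TV cross-product matrix is singular.
    """
    Uf = _as_block_flat(U, data)
    X = term_design_column(data, basis, term)
    A = X.T @ X
    b = X.T @ Uf
    if X.shape[1] == 1:
        if A[0, 0] == 0:
            raise np.linalg.LinAlgError("degenerate design column (all zero)")
        coef = float(b[0] / A[0, 0])
        rss = float(Uf @ Uf - b[0] * coef)
        return coef, rss
    coef = np.linalg.solve(A, b)
    rss = float(Uf @ Uf - b @ coef)
    return coef, rss


def select_term(U, data: DiscreteSurvivalData, basis: SplineBasis,
                sets: CandidateSets, cfg: BoostingConfig,
                phi_current: np.ndarray | None = None):
    """argmin of RSS over eligible TI, TV and interaction candidates.

    Exact ties break by category order TI < TV < INT, then lowest index.
    """
    Uf = _as_block_flat(U, data)
    candidates = [(TI, j) for j in range(data.P)]
    if cfg.tv_hierarchy and phi_current is not None:
        candidates += [(TV, j) for j in range(data.P) if phi_current[j] != 0]
    else:
        candidates += [(TV, j) for j in range(data.P)]
    candidates += [(INT, p) for p in sorted(sets.G2)]
    best = None
    for term in candidates:
        try:
            coef, rss = group_ls_fit(Uf, data, basis, term)
        except np.linalg.LinAlgError:
            warnings.warn(f"skipping degenerate term {term}")
            continue
        key = (rss, _CATEGORY_ORDER[term[0]], term[1])
        if best is None or key < best[0]:
            best = (key, term, coef)
    if best is None:
        raise RuntimeError("no eligible candidate term")
    return best[1], best[2]


def update_state(state: ModelState, term, coef, nu: float) -> ModelState:
    """Advance only the selected term's parameters by nu times its LS fit."""
    state = state.copy()
    cat, idx = term
    if cat == TI:
        state.phi[idx] += nu * coef
    elif cat == TV:
        state.theta[idx] = state.theta[idx] + nu * np.asarray(coef)
    else:
        state.alpha[idx] = state.alpha.get(idx, 0.0) + nu * coef
    return state


def update_candidates(sets: CandidateSets, term) -> CandidateSets:
    sets.update(term)
    return sets


def boosting_bic(loglik: float, df: float, n: int) -> float:
    """BIC(m) = -2 loglik + log(n) df, n = number of subjects."""
    if df < 0:
        raise ValueError("df must be non-negative")
    return -2.0 * loglik + np.log(n) * df


# ---------------------------------------------------------------------------
# Vectorised boosting loop
# ---------------------------------------------------------------------------

class _Workspace:
    """Per-dataset precomputations for fast candidate scoring.

    The least-squares fit of U to each candidate only needs per-subject
    aggregates: with r_i = sum_s U_is and V_i = sum_s U_is B(t_s), the TI/INT
    normal equations use Z'r (or pair-product columns dotted with r) and the
    TV block systems use b_j = Z'V with a fixed cross-product matrix
    A_j = sum_i z_ij^2 C_{T_i}, C_t = sum_{s<=t} B_s B_s'.
    """

    def __init__(self, data: DiscreteSurvivalData, basis: SplineBasis):
        self.data = data
        self.basis = basis
        Z, T = data.Z, data.T_index
        self.sxx_ti = T @ (Z ** 2)                          # (P,)
        Ct = np.cumsum(np.einsum("sk,sl->skl", basis.Bmat, basis.Bmat), axis=0)
        W2 = np.zeros((data.grid.S, data.P))
        np.add.at(W2, T - 1, Z ** 2)
        A = np.einsum("tj,tkl->jkl", W2, Ct)                # (P, K1, K1)
        self.tv_ok = np.ones(data.P, dtype=bool)
        self.A_inv = np.zeros_like(A)
        for j in range(data.P):
            try:
                self.A_inv[j] = np.linalg.inv(A[j])
            except np.linalg.LinAlgError:
                self.tv_ok[j] = False
                warnings.warn(f"TV block for covariate {j} is degenerate; skipped")
        if not np.all(self.sxx_ti > 0):
            self.ti_ok = self.sxx_ti > 0
        else:
            self.ti_ok = np.ones(data.P, dtype=bool)
        # interaction pair columns, grown lazily as G2 expands
        self.pairs: list = []
        self._pair_pos: dict = {}
        self.Xp = np.empty((data.n, 0))
        self.sxx_p = np.empty(0)

    def sync_pairs(self, G2: set) -> None:
        new = [p for p in sorted(G2) if p not in self._pair_pos]
        if not new:
            return
        Z, T = self.data.Z, self.data.T_index
        cols = np.stack([Z[:, j] * Z[:, jp] for j, jp in new], axis=1)
        self.Xp = np.concatenate([self.Xp, cols], axis=1)
        self.sxx_p = np.concatenate([self.sxx_p, T @ (cols ** 2)])
        for p in new:
            self._pair_pos[p] = len(self.pairs)
            self.pairs.append(p)

    def subject_aggregates(self, U_flat: np.ndarray):
        data = self.data
        r = np.bincount(data.obs_subject, weights=U_flat, minlength=data.n)
        V = np.zeros((data.n, self.basis.K1))
        starts, counts = data.block_starts, data.risk_counts
        for s in range(data.grid.S):
            if counts[s] == 0:
                continue
            sl = slice(starts[s], starts[s] + counts[s])
            V[data.obs_subject[sl]] += U_flat[sl, None] * self.basis.Bmat[s]
        return r, V


def _score_candidates(ws: _Workspace, r, V, G2_pairs_mask, tv_mask):
    """Explained sum of squares for every candidate (higher = smaller RSS)."""
    Z = ws.data.Z
    num_ti = Z.T @ r
    score_ti = np.where(ws.ti_ok, num_ti ** 2 / np.where(ws.ti_ok, ws.sxx_ti, 1.0), -np.inf)
    b = Z.T @ V                                             # (P, K1)
    theta_t = np.einsum("jkl,jl->jk", ws.A_inv, b)
    score_tv = np.where(tv_mask & ws.tv_ok, np.einsum("jk,jk->j", b, theta_t), -np.inf)
    if ws.Xp.shape[1]:
        num_p = ws.Xp.T @ r
        with np.errstate(divide="ignore", invalid="ignore"):
            score_p = np.where(ws.sxx_p > 0, num_p ** 2 / np.where(ws.sxx_p > 0, ws.sxx_p, 1.0), -np.inf)
        score_p = np.where(G2_pairs_mask, score_p, -np.inf)
        coef_p = np.where(ws.sxx_p > 0, num_p / np.where(ws.sxx_p > 0, ws.sxx_p, 1.0), 0.0)
    else:
        score_p = np.empty(0)
        coef_p = np.empty(0)
    phi_t = np.where(ws.ti_ok, num_ti / np.where(ws.ti_ok, ws.sxx_ti, 1.0), 0.0)
    return score_ti, score_tv, score_p, phi_t, theta_t, coef_p


class _HatMatrix:
    """Dense accumulator for the approximate hat matrix B_m (float32)."""

    def __init__(self, data: DiscreteSurvivalData, cap: int):
        if data.N > cap:
            raise MemoryError(
                f"pseudo-observation count N={data.N} exceeds the hat-matrix cap "
                f"({cap}); use the re-estimation BIC stopping rule instead")
        self.data = data
        self.B = np.zeros((data.N, data.N), dtype=np.float32)
        # row-normalised block-indicator matrix of the gamma projection
        # H_gamma, kept sparse: row s averages the risk-set block at time s
        from scipy import sparse

        starts, counts = data.block_starts, data.risk_counts
        self._active = np.where(counts > 0)[0]
        indptr = [0]
        indices = []
        vals = []
        for s in self._active:
            indices.extend(range(starts[s], starts[s] + counts[s]))
            vals.extend([1.0 / counts[s]] * counts[s])
            indptr.append(len(indices))
        self._A_sp = sparse.csr_matrix(
            (np.array(vals, np.float32), np.array(indices), np.array(indptr)),
            shape=(self._active.size, data.N))

    def gamma_step(self, w: np.ndarray, nu_gamma: float) -> None:
        data = self.data
        starts, counts = data.block_starts, data.risk_counts
        G = -(self._A_sp @ self.B)              # distinct rows of -H_gamma B
        w32 = (nu_gamma * w).astype(np.float32)
        for k, s in enumerate(self._active):
            sl = slice(starts[s], starts[s] + counts[s])
            G[k, sl] += np.float32(1.0 / counts[s])      # + H_gamma I
            self.B[sl] += w32[sl, None] * G[k][None, :]

    def term_step(self, X: np.ndarray, w: np.ndarray, nu: float) -> None:
        from scipy.linalg.blas import sgemm

        X32 = np.ascontiguousarray(X, dtype=np.float32)
        A = (X.T @ X).astype(np.float64)
        XtB = X32.T @ self.B
        C = np.ascontiguousarray(
            np.linalg.solve(A, (X.T - XtB).astype(np.float64)), dtype=np.float32)
        U_ = np.ascontiguousarray(nu * w[:, None] * X, dtype=np.float32)
        # in-place rank-k accumulation B += U_ @ C via the transposed
        # Fortran views of the C-ordered buffers (avoids an N x N temporary)
        sgemm(1.0, C.T, U_.T, beta=1.0, c=self.B.T, overwrite_c=1)

    @property
    def trace(self) -> float:
        return float(np.trace(self.B, dtype=np.float64))


class _ProbeHat:
    """Randomised (Hutchinson) estimator of trace(B_m).

    Instead of the dense N x N recursion, the action of B_m on q fixed
    Rademacher probe vectors is propagated:

        Y <- Y + nu W H (V - Y)   whenever   B <- B + nu W H (I - B),

    and trace(B_m) is estimated by mean_j v_j' (B v_j) = sum(V * Y) / q.
    Cost per iteration is O(N q) rather than O(N^2), which is what makes
    BIC tracking affordable on long paths; the estimator is unbiased with
    standard error of order ||B||_F / sqrt(q).
    """

    def __init__(self, data: DiscreteSurvivalData, n_probes: int, seed: int):
        self.data = data
        rng = np.random.default_rng(seed)
        self.V = rng.choice([np.float32(-1.0), np.float32(1.0)],
                            size=(data.N, n_probes)).astype(np.float32)
        self.Y = np.zeros_like(self.V)
        self._M = np.empty_like(self.V)
        counts = data.risk_counts
        self._active = np.where(counts > 0)[0]
        self._counts_active = counts[self._active].astype(np.float32)
        self._starts_active = data.block_starts[self._active]
        self._block_of_row = np.repeat(np.arange(self._active.size),
                                       counts[self._active])

    def gamma_step(self, w: np.ndarray, nu_gamma: float) -> None:
        M = np.subtract(self.V, self.Y, out=self._M)
        G = np.add.reduceat(M, self._starts_active, axis=0)
        G /= self._counts_active[:, None]
        upd = G.take(self._block_of_row, axis=0)
        upd *= (nu_gamma * w).astype(np.float32)[:, None]
        self.Y += upd

    def term_step(self, X: np.ndarray, w: np.ndarray, nu: float) -> None:
        M = np.subtract(self.V, self.Y, out=self._M)
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        C = np.linalg.solve((X.T @ X), (X32.T @ M).astype(np.float64))
        upd = X32 @ C.astype(np.float32)
        upd *= (nu * w).astype(np.float32)[:, None]
        self.Y += upd

    @property
    def trace(self) -> float:
        return float(np.einsum("ij,ij->", self.V, self.Y,
                               dtype=np.float64) / self.V.shape[1])


def hat_matrix_update(B: np.ndarray, X: np.ndarray, w: np.ndarray, nu: float) -> np.ndarray:
    """One dense-recursion step B <- B + nu W H (I - B), reference implementation.

    H is the least-squares projection onto the columns of X; W = diag(w).
    """
    H = X @ np.linalg.solve(X.T @ X, X.T)
    return B + nu * np.diag(w) @ H @ (np.eye(B.shape[0]) - B)


def run_boosting(data: DiscreteSurvivalData, basis: SplineBasis,
                 cfg: BoostingConfig) -> BoostingTrace:
    """Run the boosting path to cfg.m_max and record the trace.

    The hat-matrix/BIC path is computed when cfg.stopping == "boosting_bic";
    m_stop is then the global argmin of BIC over the evaluated iterations
    (ties going to the smallest m) and ``trace.final_state()`` returns the
    state there.  Other stopping rules leave m_stop = None (the re-estimation
    rule is applied afterwards via ``refit.reestimation_bic_path``).
    """
    ws = _Workspace(data, basis)
    sets = CandidateSets(P=data.P, hierarchy=cfg.hierarchy)
    ws.sync_pairs(sets.G2)
    compute_hat = cfg.stopping == "boosting_bic"
    hat = None
    if compute_hat:
        if cfg.hat_method == "probe":
            hat = _ProbeHat(data, cfg.n_probes, cfg.seed)
        else:
            hat = _HatMatrix(data, cfg.hat_cap)

    S, P, K1, n = data.grid.S, data.P, basis.K1, data.n
    eta = np.zeros(data.N)
    phi = np.zeros(P)
    gamma_steps = np.zeros((cfg.m_max, S))
    records = []
    s0 = data.obs_s - 1
    subj = data.obs_subject
    best_bic, best_m = np.inf, None

    for m in range(1, cfg.m_max + 1):
        lam = expit(eta)
        U = data.y - lam
        w = lam * (1.0 - lam)
        # (c.1) baseline update: closed-form risk-set means, nu_gamma step
        gt = baseline_ls(U, data)
        gamma_steps[m - 1] = gt
        eta += cfg.nu_gamma * gt[s0]
        U -= gt[s0]
        if hat is not None and cfg.hat_include_gamma:
            hat.gamma_step(w, cfg.nu_gamma)
        # (c.2) score all candidates on the post-baseline gradient
        r, V = ws.subject_aggregates(U)
        tv_mask = (phi != 0) if cfg.tv_hierarchy else np.ones(P, dtype=bool)
        pair_mask = np.array([p in sets.G2 for p in ws.pairs], dtype=bool)
        sc_ti, sc_tv, sc_p, phi_t, theta_t, coef_p = _score_candidates(
            ws, r, V, pair_mask, tv_mask)
        scores = np.concatenate([sc_ti, sc_tv, sc_p])
        g = int(np.argmax(scores))     # first max: ties favour TI < TV < INT, low index
        if not np.isfinite(scores[g]):
            logger.warning("no eligible candidate at iteration %d; stopping", m)
            gamma_steps = gamma_steps[: m - 1]
            break
        if g < P:
            term, inc = (TI, g), float(phi_t[g])
            eta += cfg.nu * inc * data.Z[subj, g]
            phi[g] += cfg.nu * inc
        elif g < 2 * P:
            j = g - P
            term, inc = (TV, j), theta_t[j].copy()
            eta += cfg.nu * (basis.Bmat[s0] @ inc) * data.Z[subj, j]
        else:
            p = ws.pairs[g - 2 * P]
            term, inc = (INT, p), float(coef_p[g - 2 * P])
            eta += cfg.nu * inc * ws.Xp[subj, g - 2 * P]
        if hat is not None:
            hat.term_step(term_design_column(data, basis, term), w, cfg.nu)
        # (c.3) candidate-set update
        sets.update(term)
        ws.sync_pairs(sets.G2)
        ll = log_likelihood_from_eta(eta, data.y)
        rec = {"m": m, "term": term, "increment": inc, "loglik": ll}
        if hat is not None:
            df = hat.trace
            bic = boosting_bic(ll, df, n)
            rec["df"], rec["bic"] = df, bic
            if bic < best_bic:
                best_bic, best_m = bic, m
            if cfg.bic_patience is not None and best_m is not None \
                    and m - best_m >= cfg.bic_patience:
                records.append(rec)
                gamma_steps = gamma_steps[:m]
                break
        records.append(rec)
    else:
        gamma_steps = gamma_steps[: len(records)]

    trace = BoostingTrace(records=records, gamma_steps=gamma_steps, config=cfg,
                          S=S, P=P, K1=K1, n=n,
                          m_stop=best_m if compute_hat else None)
    _assert_hierarchy(trace.final_state(), cfg.hierarchy, cfg.tv_hierarchy)
    return trace


def _assert_hierarchy(state: ModelState, hierarchy: str, tv_hierarchy: bool) -> None:
    """Post-hoc safety check: the final state satisfies the declared hierarchy."""
    main = set(state.selected_main())
    for (j, jp) in state.selected_pairs():
        if hierarchy == "strong":
            assert j in main and jp in main, "strong hierarchy violated"
        elif hierarchy == "weak":
            assert j in main or jp in main, "weak hierarchy violated"
    if tv_hierarchy:
        for j in state.selected_tv():
            assert state.phi[j] != 0, "time-varying hierarchy violated"
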