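"""Core containers for discrete-time right-censored survival data.

The model operates on a grid of distinct failure times ``t_1 < ... < t_S``.
Each subject contributes an observed time index ``T_i`` in ``{1..S}`` and an
event indicator ``delta_i``.  The implied binary pseudo-responses
``y_is = 1{delta_i = 1 and s = T_i}`` for ``s = 1..T_i`` are never stored as a
long-format covariate table; instead a flat index over the ``N = sum_i T_i``
pseudo-observations (sorted by time index) is kept so that per-time risk sets
are contiguous blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeGrid:
    """Ordered distinct failure times ``t_1..t_S``."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("time grid must be a non-empty 1-d array")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def S(self) -> int:
        return int(self.times.size)


class DiscreteSurvivalData:
    """Right-censored discrete-time survival data.

    Parameters
    ----------
    Z : (n, P) float array
        Baseline covariates, no missing values.
    T_index : (n,) int array
        Observed time index per subject, 1-based, in ``{1..S}``.
    delta : (n,) int array
        Event indicator (1 = failure, 0 = censored).
    grid : TimeGrid
    names : list of str, optional
        Covariate names (defaults to ``z1..zP``).
    """

    def __init__(self, Z, T_index, delta, grid: TimeGrid, names=None):
        Z = np.asarray(Z, dtype=float)
        T_index = np.asarray(T_index, dtype=np.int64)
        delta = np.asarray(delta, dtype=np.int64)
        if Z.ndim != 2:
            raise ValueError("Z must be 2-dimensional")
        n, P = Z.shape
        if n < 1 or P < 1:
            raise ValueError("need n >= 1 subjects and P >= 1 covariates")
        if np.isnan(Z).any():
            raise ValueError("Z contains missing values")
        if T_index.shape != (n,) or delta.shape != (n,):
            raise ValueError("T_index/delta must have one entry per subject")
        if T_index.min() < 1 or T_index.max() > grid.S:
            raise ValueError("T_index out of range 1..S")
        if not np.isin(delta, (0, 1)).all():
            raise ValueError("delta must be 0/1")
        self.Z = Z
        self.T_index = T_index
        self.delta = delta
        self.grid = grid
        self.names = list(names) if names is not None else [f"z{j+1}" for j in range(P)]
        if len(self.names) != P:
            raise ValueError("names length must equal P")
        self._build_index()

    def _build_index(self):
        """Flat pseudo-observation index, sorted by time index s (1-based)."""
        n = self.n
        T = self.T_index
        # subject i contributes pseudo-obs at s = 1..T_i
        reps = T
        subj = np.repeat(np.arange(n), reps)
        sidx = np.concatenate([np.arange(1, t + 1) for t in T]) if n else np.empty(0, int)
        order = np.argsort(sidx, kind="stable")
        self.obs_subject = subj[order]          # subject of each pseudo-obs
        self.obs_s = sidx[order]                # 1-based time index of each pseudo-obs
        self.N = int(reps.sum())
        # contiguous block boundaries per s: block s holds the risk set at s
        counts = np.bincount(self.obs_s, minlength=self.grid.S + 1)[1:]
        self.risk_counts = counts               # subjects at risk at each s
        self.block_starts = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
        self.n_blocks = int(np.count_nonzero(counts))
        # pseudo-response: y = 1 at (i, T_i) when delta_i = 1
        y = np.zeros(self.N)
        is_event_row = (self.obs_s == T[self.obs_subject]) & (self.delta[self.obs_subject] == 1)
        y[is_event_row] = 1.0
        self.y = y

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def P(self) -> int:
        return self.Z.shape[1]

    def failure_set(self, s: int) -> np.ndarray:
        """Subjects failing at time index s (1-based)."""
        return np.where((self.T_index == s) & (self.delta == 1))[0]

    def censored_set(self, s: int) -> np.ndarray:
        return np.where((self.T_index == s) & (self.delta == 0))[0]


@dataclass
class ModelState:
    """Parameters of the discrete logistic hazard model.

    gamma : (S,) baseline log-odds per time index
    phi : (P,) time-independent effects
    theta : (P, K-1) spline coefficient blocks (row j all zero => effect of
        covariate j is time-independent)
    alpha : dict mapping (j, j') with j < j' (0-based) to interaction coefficients
    """

    gamma: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    alpha: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, S: int, P: int, K1: int) -> "ModelState":
        return cls(np.zeros(S), np.zeros(P), np.zeros((P, K1)), {})

    def copy(self) -> "ModelState":
        return ModelState(self.gamma.copy(), self.phi.copy(), self.theta.copy(),
                          dict(self.alpha))

    def selected_main(self) -> np.ndarray:
        """0-based covariates with phi_j != 0 or theta_j != 0."""
        return np.where((self.phi != 0) | np.any(self.theta != 0, axis=1))[0]

    def selected_tv(self) -> np.ndarray:
        return np.where(np.any(self.theta != 0, axis=1))[0]

    def selected_pairs(self) -> list:
        return sorted(k for k, v in self.alpha.items() if v != 0)
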