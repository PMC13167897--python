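"""Likelihood machinery for the discrete logistic hazard model.

Hazard: lambda(t_s; z) = expit(eta_is) with

    eta_is = gamma_s + sum_j phi_j z_ij + sum_j theta_j' B(t_s) z_ij
             + sum_{j<j'} alpha_jj' z_ij z_ij'

The log-likelihood streams over the flat pseudo-observation index of the data
(one virtual binary response per subject per at-risk interval); no long-format
covariate table is built.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit

from .basis import SplineBasis
from .data import DiscreteSurvivalData, ModelState


def hazard(eta):
    """Discrete-time hazard expit(eta), saturating for large |eta|."""
    return expit(eta)


def linear_predictor_flat(state: ModelState, data: DiscreteSurvivalData,
                          basis: SplineBasis) -> np.ndarray:
    """eta over the flat pseudo-observation index (sorted by time block)."""
    S = data.grid.S
    if state.gamma.shape != (S,):
        raise ValueError("gamma length must equal S")
    if state.phi.shape != (data.P,) or state.theta.shape[0] != data.P:
        raise ValueError("phi/theta dimensions must match P")
    if state.theta.shape[1] != basis.K1:
        raise ValueError("theta block width must equal K-1")
    subj = data.obs_subject
    s0 = data.obs_s - 1
    eta = state.gamma[s0].copy()
    lin = data.Z @ state.phi                                   # per-subject TI part
    eta += lin[subj]
    if np.any(state.theta):
        # per-subject, per-time spline part: (Z theta) rows dotted with B(t_s)
        tv = data.Z @ state.theta                              # n x (K-1)
        eta += np.einsum("ok,ok->o", tv[subj], basis.Bmat[s0])
    for (j, jp), a in state.alpha.items():
        if a != 0:
            eta += a * (data.Z[subj, j] * data.Z[subj, jp])
    return eta


def _to_ragged(data: DiscreteSurvivalData, flat: np.ndarray) -> list:
    """Regroup a flat (time-block-sorted) pseudo-obs vector per subject."""
    order = np.lexsort((data.obs_s, data.obs_subject))
    splits = np.cumsum(data.T_index)[:-1]
    return np.split(flat[order], splits)


def linear_predictor(state: ModelState, data: DiscreteSurvivalData,
                     basis: SplineBasis) -> list:
    """Ragged per-subject eta vectors [eta_i1..eta_iT_i]."""
    return _to_ragged(data, linear_predictor_flat(state, data, basis))


def log_likelihood(state: ModelState, data: DiscreteSurvivalData,
                   basis: SplineBasis) -> float:
    """sum_i sum_{s<=T_i} [y_is eta_is - log(1 + exp eta_is)]."""
    eta = linear_predictor_flat(state, data, basis)
    return log_likelihood_from_eta(eta, data.y)


def log_likelihood_from_eta(eta_flat: np.ndarray, y_flat: np.ndarray) -> float:
    # y*eta - log(1+e^eta) = y*eta + log_expit(-eta), stable everywhere
    return float(np.sum(y_flat * eta_flat + log_expit(-eta_flat)))


def gradient_eta(state: ModelState, data: DiscreteSurvivalData,
                 basis: SplineBasis) -> list:
    """Ragged per-subject gradients U_is = y_is - expit(eta_is)."""
    eta = linear_predictor_flat(state, data, basis)
    return _to_ragged(data, data.y - expit(eta))


def gradient_eta_flat(eta_flat: np.ndarray, y_flat: np.ndarray) -> np.ndarray:
    return y_flat - expit(eta_flat)


def survival_curve(state: ModelState, z, basis: SplineBasis) -> np.ndarray:
    """S(t_s) = prod_{l<=s} (1 - lambda(t_l; z)) on the basis grid."""
    z = np.asarray(z, dtype=float)
    eta = state.gamma + z @ state.phi + basis.Bmat @ (state.theta.T @ z)
    for (j, jp), a in state.alpha.items():
        eta += a * z[j] * z[jp]
    lam = expit(eta)
    return np.cumprod(1.0 - lam)
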