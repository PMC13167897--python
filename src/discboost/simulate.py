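"""Synthetic discrete-time survival data with known truth.

Covariates are multivariate normal with an AR(1) correlation structure
(optionally dichotomised), failure times are drawn sequentially from the
discrete logistic hazard evaluated at the true coefficient functions
beta_j(t) (never through the fitted spline basis), and censoring times are
discrete uniform on {1..S}.  Two presets reproduce the designs used in the
evaluation studies: a high-dimensional main-effects scenario (n=500, S=19,
five true signals of which three are genuinely time-varying) and an
interaction scenario (n=1000, P=15, S=20, five time-varying effects, seven
time-independent effects and five true interaction pairs under a strong
hierarchy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .data import DiscreteSurvivalData, TimeGrid

# Baseline log-odds of the high-dimensional scenario (S = 19)
GAMMA_HIGHDIM = np.array([
    -4.00, -3.50, -3.20, -3.12, -3.08, -3.00, -2.95, -2.87, -2.80, -2.69,
    -2.61, -2.49, -2.39, -2.25, -2.10, -1.90, -1.70, -1.35, -1.00])

# Baseline log-odds of the interaction scenario (S = 20)
GAMMA_INTERACTION = np.array([
    -4.3, -4.05, -3.8, -3.5, -3.12, -2.78, -2.32, -2.12, -1.99, -1.8,
    -1.69, -1.61, -1.49, -1.39, -1.25, -1.1, -0.9, -0.7, -0.35, 0.0])

INTERACTION_ALPHA = {(0, 1): 1.0, (0, 2): 1.0, (0, 8): 1.0,
                     (4, 9): -1.0, (5, 6): -1.0}


def true_beta_library(name: str, P: int):
    """True coefficient functions beta_j(t) for the named scenario.

    "highdim": beta_1..beta_5 = 1, cos(pi t/50), -1, sin(3 pi t/80),
    -1+exp(-0.25 t); the rest zero.  "interaction" (P=15): five time-varying
    functions followed by constants (-1,-1,-1,1,1,1,1,0,0,0).
    """
    if name == "highdim":
        if P < 5:
            raise ValueError("highdim preset needs P >= 5 (five true signals)")
        funcs = [lambda t: np.ones_like(t, dtype=float),
                 lambda t: np.cos(np.pi * t / 50),
                 lambda t: -np.ones_like(t, dtype=float),
                 lambda t: np.sin(3 * np.pi * t / 80),
                 lambda t: -1 + np.exp(-0.25 * t)]
        funcs += [_zero] * (P - 5)
        tv_truth = (1, 3, 4)             # non-constant functions (0-based)
        main_truth = (0, 1, 2, 3, 4)
        return funcs, main_truth, tv_truth
    if name == "interaction":
        if P != 15:
            raise ValueError("interaction preset is defined for P = 15")
        funcs = [lambda t: 1 + np.cos(np.pi * t / 50),
                 lambda t: -1 + np.exp(-0.25 * t),
                 lambda t: 1 - np.cos(np.pi * t / 30),
                 lambda t: np.sin(3 * np.pi * t / 80),
                 lambda t: -np.sin(np.pi * t / 30)]
        consts = (-1, -1, -1, 1, 1, 1, 1, 0, 0, 0)
        funcs += [_const(c) for c in consts]
        tv_truth = (0, 1, 2, 3, 4)
        main_truth = tuple(range(12))     # 5 TV + 7 nonzero constants
        return funcs, main_truth, tv_truth
    raise ValueError(f"unknown scenario {name!r}")


def _zero(t):
    return np.zeros_like(np.asarray(t, dtype=float))


def _const(c):
    return lambda t: np.full_like(np.asarray(t, dtype=float), float(c))


@dataclass
class ScenarioSpec:
    """Full description of one synthetic-data generating process."""

    n: int
    P: int
    gamma_true: np.ndarray
    beta_true: list                       # P callables of t
    alpha_true: dict = field(default_factory=dict)
    rho: float = 0.5
    binary: bool = False
    p0_range: tuple = (0.05, 0.15)
    times: np.ndarray | None = None       # defaults to 1..S
    censor_support: tuple | None = None   # defaults to (1, S)
    seed: int = 0

    def __post_init__(self):
        self.gamma_true = np.asarray(self.gamma_true, float)
        if len(self.beta_true) != self.P:
            raise ValueError("beta_true must have one function per covariate")
        for (j, jp) in self.alpha_true:
            if not j < jp:
                raise ValueError("alpha_true keys must satisfy j < j'")
        if self.times is None:
            self.times = np.arange(1, self.S + 1, dtype=float)

    @property
    def S(self) -> int:
        return self.gamma_true.size


def scenario_preset(name: str, n: int | None = None, P: int | None = None,
                    binary: bool = False, seed: int = 0) -> ScenarioSpec:
    if name == "highdim":
        n = 500 if n is None else n
        P = 100 if P is None else P
        funcs, _, _ = true_beta_library("highdim", P)
        return ScenarioSpec(n=n, P=P, gamma_true=GAMMA_HIGHDIM, beta_true=funcs,
                            binary=binary, seed=seed)
    if name == "interaction":
        n = 1000 if n is None else n
        P = 15 if P is None else P
        funcs, _, _ = true_beta_library("interaction", P)
        return ScenarioSpec(n=n, P=P, gamma_true=GAMMA_INTERACTION,
                            beta_true=funcs, alpha_true=dict(INTERACTION_ALPHA),
                            binary=binary, seed=seed)
    raise ValueError(f"unknown preset {name!r}")


def gen_covariates(n: int, P: int, rho: float, binary: bool, rng,
                   p0_range=(0.05, 0.15)) -> np.ndarray:
    """i.i.d. rows from N(0, Sigma), Sigma_jk = rho^|j-k| (AR(1)).

    If ``binary``, covariate j is dichotomised at the p0_j quantile of its
    latent Gaussian, with zero-probabilities p0_j equally spaced over
    ``p0_range`` across j (thresholding the latent variable preserves the
    AR(1) dependence).
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    # AR(1) via the causal recursion z_j = rho z_{j-1} + sqrt(1-rho^2) e_j
    eps = rng.standard_normal((n, P))
    Z = np.empty((n, P))
    Z[:, 0] = eps[:, 0]
    c = np.sqrt(1.0 - rho ** 2)
    for j in range(1, P):
        Z[:, j] = rho * Z[:, j - 1] + c * eps[:, j]
    if binary:
        from scipy.stats import norm
        p0 = np.linspace(p0_range[0], p0_range[1], P)
        Z = (Z > norm.ppf(p0)).astype(float)
    return Z


def true_eta_matrix(Z: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    """n x S matrix of true linear predictors gamma_s + f(t_s; z_i)."""
    t = spec.times
    B = np.stack([np.asarray(f(t), dtype=float) for f in spec.beta_true], axis=1)  # S x P
    eta = spec.gamma_true[None, :] + Z @ B.T
    for (j, jp), a in spec.alpha_true.items():
        eta += a * (Z[:, j] * Z[:, jp])[:, None]
    return eta


def gen_event_times(Z: np.ndarray, spec: ScenarioSpec, rng):
    """Sequential Bernoulli draws over s = 1..S from the true hazards.

    Returns (D, had_event): D is the failure index in 1..S, or S+1 for
    subjects event-free at the end of the grid (handled by the censoring
    step).
    """
    lam = expit(true_eta_matrix(Z, spec))
    u = rng.uniform(size=lam.shape)
    fail = u < lam
    D = np.where(fail.any(axis=1), fail.argmax(axis=1) + 1, spec.S + 1)
    return D, D <= spec.S


def gen_censoring_and_assemble(D: np.ndarray, Z: np.ndarray, spec: ScenarioSpec,
                               rng) -> DiscreteSurvivalData:
    """C ~ DiscreteUniform on the support; T = min(D, C), delta = 1{D <= C}."""
    lo, hi = spec.censor_support if spec.censor_support else (1, spec.S)
    C = rng.integers(lo, hi + 1, size=D.size)
    T = np.minimum(D, C)
    delta = (D <= C).astype(int)
    T = np.minimum(T, spec.S)      # event-free subjects are censored at <= S
    return DiscreteSurvivalData(Z, T, delta, TimeGrid(spec.times))


def make_dataset(spec: ScenarioSpec):
    """Seeded dataset plus the truth record used by the evaluation metrics."""
    rng = np.random.default_rng(spec.seed)
    Z = gen_covariates(spec.n, spec.P, spec.rho, spec.binary, rng, spec.p0_range)
    D, _ = gen_event_times(Z, spec, rng)
    data = gen_censoring_and_assemble(D, Z, spec, rng)
    t = spec.times
    beta_grid = np.stack([np.asarray(f(t), dtype=float) for f in spec.beta_true], axis=0)
    tv_truth = tuple(j for j in range(spec.P)
                     if np.ptp(beta_grid[j]) > 1e-12)
    main_truth = tuple(j for j in range(spec.P)
                       if np.max(np.abs(beta_grid[j])) > 1e-12)
    truth = {
        "main": main_truth,
        "tv": tv_truth,
        "pairs": tuple(sorted(k for k, v in spec.alpha_true.items() if v != 0)),
        "alpha": dict(spec.alpha_true),
        "beta_grid": beta_grid,            # P x S true coefficient curves
        "gamma": spec.gamma_true.copy(),
        "P": spec.P,
    }
    return data, truth
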