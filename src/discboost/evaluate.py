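"""Selection and estimation-accuracy metrics over replicated experiments.

Selection metrics count predictors against the known truth of a synthetic
scenario.  Scopes:

* ``main`` -- a covariate counts as selected if it has any non-zero main
  term (phi or theta), compared against the true-signal covariates;
* ``tv`` -- selected if the spline block theta_j is non-zero, compared
  against the truly time-varying covariates;
* ``interactions`` -- pairs with non-zero alpha against the true pairs.

With ``include_pairs=True`` the ``main`` and ``tv`` universes additionally
contain every interaction pair (the convention of the interaction-scenario
tables): for ``main`` a selected pair counts against the true-pair set, for
``tv`` pairs are never "selected" and enter purely as negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import SplineBasis, build_reduced_basis
from .boosting import BoostingConfig, run_boosting
from .data import ModelState
from .simulate import ScenarioSpec, make_dataset

logger = logging.getLogger(__name__)


@dataclass
class SelectionOutcome:
    scope: str
    TP: float
    FP: float
    FN: float
    TN: float

    def _ratio(self, a, b):
        return a / b if b > 0 else float("nan")

    @property
    def SE(self):
        return self._ratio(self.TP, self.TP + self.FN)

    @property
    def SP(self):
        return self._ratio(self.TN, self.TN + self.FP)

    @property
    def PPV(self):
        return self._ratio(self.TP, self.TP + self.FP)

    @property
    def NPV(self):
        return self._ratio(self.TN, self.TN + self.FN)

    def as_dict(self):
        return {"FP": self.FP, "FN": self.FN, "SE": self.SE, "SP": self.SP,
                "PPV": self.PPV, "NPV": self.NPV}


def _count(selected: set, truth: set, universe_size: int) -> tuple:
    tp = len(selected & truth)
    fp = len(selected - truth)
    fn = len(truth - selected)
    tn = universe_size - tp - fp - fn
    return tp, fp, fn, tn


def selection_metrics(state: ModelState, truth: dict, scope: str,
                      include_pairs: bool = False) -> SelectionOutcome:
    P = truth["P"]
    n_pairs = P * (P - 1) // 2
    if scope == "main":
        selected = set(state.selected_main())
        tset = set(truth["main"])
        universe = P
        if include_pairs:
            sel_pairs = {("pair", p) for p in state.selected_pairs()}
            selected |= sel_pairs
            tset |= {("pair", p) for p in truth["pairs"]}
            universe += n_pairs
    elif scope == "tv":
        selected = set(state.selected_tv())
        tset = set(truth["tv"])
        universe = P + (n_pairs if include_pairs else 0)
    elif scope == "interactions":
        selected = set(state.selected_pairs())
        tset = set(truth["pairs"])
        universe = n_pairs
    else:
        raise ValueError(f"unknown scope {scope!r}")
    tp, fp, fn, tn = _count(selected, tset, universe)
    return SelectionOutcome(scope, tp, fp, fn, tn)


@dataclass
class CurveAccuracy:
    """Grid-averaged absolute bias, replicate SD and replicate MSE.

    Values are stored unscaled; the evaluation tables render them x100.
    """

    scope: str
    bias: float
    SD: float
    IMSE: float

    def times100(self):
        return {"bias": 100 * self.bias, "SD": 100 * self.SD,
                "IMSE": 100 * self.IMSE}


def _curve_matrix(states, truth, basis: SplineBasis, scope: str):
    """(R, Q) estimates and (Q,) truths for the quantities of a scope."""
    if scope == "main_effects":
        cov = list(truth["main"])
        true_q = truth["beta_grid"][cov].ravel()
        est = np.stack([
            (st.phi[cov][:, None] + st.theta[cov] @ basis.Bmat.T).ravel()
            for st in states])
    elif scope == "interactions":
        pairs = list(truth["pairs"])
        true_q = np.array([truth["alpha"][p] for p in pairs])
        est = np.stack([[st.alpha.get(p, 0.0) for p in pairs] for st in states])
    elif scope == "baseline":
        true_q = np.asarray(truth["gamma"], float)
        est = np.stack([st.gamma for st in states])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return est, true_q


def curve_accuracy(states, truth, basis: SplineBasis, scope: str) -> CurveAccuracy:
    """Aggregate accuracy of per-replicate estimates against the truth.

    bias = mean over quantities of |mean_r(est) - truth|; SD = mean of the
    across-replicate standard deviation; IMSE = mean of the across-replicate
    mean squared error.
    """
    est, true_q = _curve_matrix(states, truth, basis, scope)
    if est.shape[0] < 2:
        raise ValueError("need at least two replicates")
    bias = float(np.mean(np.abs(est.mean(axis=0) - true_q)))
    sd = float(np.mean(est.std(axis=0, ddof=1)))
    imse = float(np.mean(np.mean((est - true_q) ** 2, axis=0)))
    return CurveAccuracy(scope, bias, sd, imse)


def _fit_one(spec: ScenarioSpec, method: dict):
    from . import refit as _refit

    data, truth = make_dataset(spec)
    basis = build_reduced_basis(data.grid, K=method.get("K", 7))
    stopping = method.get("stopping", "boosting_bic")
    cfg = BoostingConfig(
        nu=method.get("nu", 0.5),
        m_max=method.get("m_max", 500),
        hierarchy=method.get("hierarchy", "strong"),
        tv_hierarchy=method.get("tv_hierarchy", False),
        stopping=stopping,
        hat_cap=method.get("hat_cap", 20000),
        bic_patience=method.get("bic_patience"),
        hat_method=method.get("hat_method", "dense"),
        n_probes=method.get("n_probes", 256),
    )
    trace = run_boosting(data, basis, cfg)
    fit = None
    if stopping == "reestimation_bic":
        m_stop, fit, _ = _refit.reestimation_bic_path(
            data, basis, trace, every=method.get("every", 5),
            kind=method.get("penalty", "pspline"),
            lambda_grid=method.get("lambda_grid", _refit.DEFAULT_LAMBDA_GRID),
            patience=method.get("reest_patience"))
        state = trace.state_at(m_stop)
    else:
        state = trace.final_state()
    return state, fit, truth, trace


def replicate_experiment(spec: ScenarioSpec, method: dict, R: int,
                         base_seed: int):
    """Run simulate -> boost (-> refit) -> metrics for R seeded replicates.

    Returns (summary DataFrame with mean/sd per scope and metric,
    per-replicate DataFrame).  Per-replicate failures are logged, excluded
    and counted in ``summary.attrs["failures"]``.
    """
    scopes = method.get("scopes", ["main", "tv"])
    include_pairs = method.get("include_pairs", False)
    rows = []
    failures = 0
    for r in range(R):
        sp = ScenarioSpec(n=spec.n, P=spec.P, gamma_true=spec.gamma_true,
                          beta_true=spec.beta_true, alpha_true=spec.alpha_true,
                          rho=spec.rho, binary=spec.binary,
                          p0_range=spec.p0_range, times=spec.times,
                          censor_support=spec.censor_support,
                          seed=base_seed + r)
        try:
            state, _, truth, _ = _fit_one(sp, method)
        except Exception:                                    # noqa: BLE001
            logger.exception("replicate %d failed", r)
            failures += 1
            continue
        for scope in scopes:
            out = selection_metrics(state, truth, scope, include_pairs)
            for k, v in out.as_dict().items():
                rows.append({"replicate": r, "scope": scope, "metric": k,
                             "value": v})
    per_rep = pd.DataFrame(rows)
    summary = (per_rep.groupby(["scope", "metric"])["value"]
               .agg(["mean", "std"]).reset_index())
    summary.attrs["failures"] = failures
    return summary, per_rep
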