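"""CSV/JSON readers and writers for survival data and fitted models."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .data import DiscreteSurvivalData, ModelState, TimeGrid

MODEL_SCHEMA = 1
RESERVED = ("id", "time", "time_index", "event")


def read_survival_csv(path, time_mode: str = "index",
                      grid: TimeGrid | None = None) -> DiscreteSurvivalData:
    """Read subject-level survival data.

    Expected columns: ``id``, ``time`` (or ``time_index``), ``event`` (0/1),
    then covariate columns.  With ``time_mode="value"`` raw times are mapped
    onto the ordered distinct-time grid (supplied or derived from the data);
    with ``"index"`` the time column must already hold 1-based indices.
    """
    df = pd.read_csv(path)
    tcol = "time" if "time" in df.columns else "time_index"
    for col in ("id", tcol, "event"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    bad = df[~df["event"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"non-0/1 event codes in rows {list(bad.index[:10])}")
    cov_cols = [c for c in df.columns if c not in RESERVED]
    if not cov_cols:
        raise ValueError("no covariate columns found")
    miss = df[cov_cols].isna()
    if miss.any().any():
        rows = list(df.index[miss.any(axis=1)][:10])
        raise ValueError(f"missing covariate values in rows {rows}")
    if time_mode == "value":
        times = np.sort(df[tcol].unique()).astype(float) if grid is None else grid.times
        grid = TimeGrid(times)
        T_index = np.searchsorted(grid.times, df[tcol].to_numpy(float)) + 1
        if not np.allclose(grid.times[T_index - 1], df[tcol].to_numpy(float)):
            raise ValueError("observed times not on the supplied grid")
    elif time_mode == "index":
        T_index = df[tcol].to_numpy(int)
        if grid is None:
            grid = TimeGrid(np.arange(1, T_index.max() + 1, dtype=float))
    else:
        raise ValueError("time_mode must be 'index' or 'value'")
    return DiscreteSurvivalData(df[cov_cols].to_numpy(float), T_index,
                                df["event"].to_numpy(int), grid, names=cov_cols)


def write_survival_csv(data: DiscreteSurvivalData, path) -> None:
    df = pd.DataFrame({"id": np.arange(data.n), "time_index": data.T_index,
                       "event": data.delta})
    for j, name in enumerate(data.names):
        df[name] = data.Z[:, j]
    df.to_csv(path, index=False)


def write_grid_csv(grid: TimeGrid, path) -> None:
    pd.DataFrame({"index": np.arange(1, grid.S + 1),
                  "time": grid.times}).to_csv(path, index=False)


def read_grid_csv(path) -> TimeGrid:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("grid CSV needs a 'time' column")
    if "index" in df.columns:
        df = df.sort_values("index")
    return TimeGrid(df["time"].to_numpy(float))


def model_to_dict(state: ModelState, names) -> dict:
    return {
        "schema": MODEL_SCHEMA,
        "gamma": list(state.gamma),
        "phi": {names[j]: state.phi[j] for j in range(len(names))
                if state.phi[j] != 0},
        "theta": {names[j]: list(state.theta[j]) for j in range(len(names))
                  if np.any(state.theta[j] != 0)},
        "alpha": {f"{names[j]}:{names[jp]}": v
                  for (j, jp), v in sorted(state.alpha.items()) if v != 0},
        "names": list(names),
        "K1": state.theta.shape[1],
    }


def write_model_json(state: ModelState, names, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(state, names), fh, indent=1, sort_keys=True)


def read_model_json(path) -> tuple:
    """Returns (ModelState, covariate names)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
    names = doc["names"]
    pos = {nm: j for j, nm in enumerate(names)}
    S, P, K1 = len(doc["gamma"]), len(names), doc["K1"]
    state = ModelState.zeros(S, P, K1)
    state.gamma[:] = doc["gamma"]
    for nm, v in doc["phi"].items():
        state.phi[pos[nm]] = v
    for nm, row in doc["theta"].items():
        state.theta[pos[nm]] = row
    for key, v in doc["alpha"].items():
        a, b = key.split(":")
        j, jp = sorted((pos[a], pos[b]))
        state.alpha[(j, jp)] = v
    return state, names
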