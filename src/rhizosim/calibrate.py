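"""Trait calibration by grid search and least squares.

The workflow mirrors how the growth model is tuned against tracings:
first the branching (tip) delay against the total-length time series (the
only free parameter that controls total length), then the direction
weights (W_g, W_r, delta) against foraging area and branching density, and
finally the obstacle-response parameters: kappa from the contact/recovery
episode durations and W_oi from growth-angle trajectories per obstacle
inclination.  Errors across indices are combined with equal weight after
normalising each index by the RMS of its target series.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import compute_indices

__all__ = ["CalibrationSpec", "GridSearchResult", "index_timeseries",
           "grid_search_fit", "estimate_kappa", "fit_w_oi"]


@dataclass
class CalibrationSpec:
    """Parameter grids, targets and replication for one grid search."""

    grids: dict                     # name -> iterable of values
    targets: pd.DataFrame           # time-indexed target series per index
    seeds: tuple = (0, 1, 2)
    weights: dict | None = None     # per-index weights (default equal)

    def __post_init__(self) -> None:
        if not self.grids or any(len(list(v)) == 0 for v in self.grids.values()):
            raise ValueError("parameter grids must be non-empty")
        if len(self.seeds) < 1:
            raise ValueError("need at least one replicate seed")


@dataclass
class GridSearchResult:
    best: dict
    error: float
    surface: pd.DataFrame           # one row per grid point with its error
    ties: list = field(default_factory=list)


def index_timeseries(trajectories, times, axis_ids=None) -> pd.DataFrame:
    """Network indices per output time, with replicate mean and SD.

    ``trajectories`` is one trajectory or a list of replicates; indices are
    evaluated on the stored snapshots nearest to each requested time (which
    must be within half an output interval).  Columns: ``<index>`` (mean
    across replicates) and ``<index>_sd``.
    """
    if not isinstance(trajectories, (list, tuple)):
        trajectories = [trajectories]
    times = np.asarray(times, dtype=float)
    names = ["total_length", "foraging_area", "branching_density"]
    per_rep = []
    for traj in trajectories:
        snap_times = np.asarray([t for t, _ in traj.snapshots])
        if times.max() > snap_times.max() + 1e-9:
            raise ValueError("requested time beyond trajectory horizon")
        rows = []
        for t in times:
            i = int(np.argmin(np.abs(snap_times - t)))
            _, system = traj.snapshots[i]
            ids = axis_ids
            if ids is None:
                ids = sorted(r.id for r in system.axes())[:2]
            idx = compute_indices(system, axis_ids=ids, with_graph=False)
            rows.append([idx.total_length, idx.foraging_area,
                         idx.branching_density])
        per_rep.append(np.asarray(rows))
    stack = np.stack(per_rep)                     # (rep, time, index)
    out = pd.DataFrame(stack.mean(axis=0), columns=names, index=times)
    sd = stack.std(axis=0, ddof=0)
    for j, name in enumerate(names):
        out[f"{name}_sd"] = sd[:, j]
    out.index.name = "t"
    return out


def _series_error(sim: pd.DataFrame, targets: pd.DataFrame,
                  weights: dict | None) -> float:
    err = 0.0
    for name in targets.columns:
        tgt = targets[name].to_numpy(dtype=float)
        if name not in sim.columns:
            raise KeyError(f"simulator output lacks index {name!r}")
        s = np.interp(np.asarray(targets.index, dtype=float),
                      np.asarray(sim.index, dtype=float),
                      sim[name].to_numpy(dtype=float))
        rms = np.sqrt(np.mean(tgt ** 2))
        scale = rms if rms > 0 else 1.0
        w = 1.0 if weights is None else weights.get(name, 1.0)
        err += w * float(np.mean(((s - tgt) / scale) ** 2))
    return err


def grid_search_fit(spec: CalibrationSpec, simulator) -> GridSearchResult:
    """Exhaustive least-squares search over the parameter grids.

    ``simulator(params: dict, seed: int)`` must return a time-indexed
    DataFrame with one column per target index.  Replicate runs (one per
    seed) are averaged before comparison.  On ties the first grid point in
    iteration order wins and all tied points are reported.
    """
    names = list(spec.grids)
    rows, failures = [], []
    for combo in itertools.product(*(list(spec.grids[n]) for n in names)):
        params = dict(zip(names, combo))
        try:
            sims = [simulator(params, seed) for seed in spec.seeds]
            mean_sim = sum(s.sort_index() for s in sims) / len(sims)
            err = _series_error(mean_sim, spec.targets, spec.weights)
        except Exception as exc:  # noqa: BLE001 - diagnostics per grid point
            failures.append((params, repr(exc)))
            err = np.nan
        rows.append({**params, "error": err})
    surface = pd.DataFrame(rows)
    if surface["error"].isna().all():
        raise RuntimeError(f"all grid points failed: {failures}")
    best_err = float(np.nanmin(surface["error"].to_numpy()))
    tied = surface.index[np.isclose(surface["error"], best_err, rtol=0,
                                    atol=1e-12)].tolist()
    best_row = surface.loc[tied[0]]
    best = {n: best_row[n] for n in names}
    ties = [{n: surface.loc[i, n] for n in names} for i in tied[1:]]
    if ties:
        warnings.warn(f"grid search tie among {1 + len(ties)} points; "
                      "returning the first in grid order")
    return GridSearchResult(best=best, error=best_err, surface=surface,
                            ties=ties)


def estimate_kappa(episodes) -> float:
    """Recovery/contact proportionality from contact episodes.

    Least-squares slope through the origin of recovery duration (t2 - t1)
    against contact duration (t1 - t0).
    """
    eps = [(e["t0"], e["t1"], e["t2"]) if isinstance(e, dict) else tuple(e)
           for e in episodes]
    x = np.asarray([t1 - t0 for t0, t1, _ in eps], dtype=float)
    y = np.asarray([t2 - t1 for _, t1, t2 in eps], dtype=float)
    if len(x) == 0 or np.all(x <= 0):
        raise ValueError("need at least one episode with positive contact time")
    return float(np.sum(x * y) / np.sum(x * x))


def fit_w_oi(reference: dict, grid, simulator, seeds=(0, 1, 2)) -> dict:
    """Best initial history weight per obstacle inclination and pooled.

    ``reference[eta]`` is a DataFrame with columns ``t`` and ``beta``
    (growth angle after contact loss); ``simulator(eta, w_oi, seed)``
    returns a comparable DataFrame.  Replicates are averaged per grid
    value; the least-squares argmin is reported per inclination and for
    the pooled error.  Reference samples beyond the simulated horizon are
    dropped with a warning.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty W_oi grid")
    errors = pd.DataFrame(index=grid, columns=list(reference), dtype=float)
    for eta, ref in reference.items():
        rt = np.asarray(ref["t"], dtype=float)
        rb = np.asarray(ref["beta"], dtype=float)
        for w_oi in grid:
            sims = []
            for seed in seeds:
                sim = simulator(eta, w_oi, seed)
                sims.append((np.asarray(sim["t"], dtype=float),
                             np.asarray(sim["beta"], dtype=float)))
            t_max = min(s[0].max() for s in sims)
            keep = rt <= t_max + 1e-9
            if not keep.all():
                warnings.warn(f"reference series for eta={eta} extends past "
                              "the simulated horizon; truncating")
            if not keep.any():
                raise ValueError(f"no overlap between reference and "
                                 f"simulation for eta={eta}")
            sim_mean = np.mean(
                [np.interp(rt[keep], st, sb) for st, sb in sims], axis=0)
            errors.loc[w_oi, eta] = float(np.mean((sim_mean - rb[keep]) ** 2))
    result = {eta: float(errors[eta].astype(float).idxmin())
              for eta in reference}
    result["pooled"] = float(errors.astype(float).sum(axis=1).idxmin())
    result["errors"] = errors
    return result
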