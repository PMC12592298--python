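"""Candidate scoring by rRMSE and Part-1 selection.

Every complete per-method parameter set, plus every cross-method hybrid
(each of CL, V, Ka taken independently from any method that produced it),
is simulated on each individual's dose/observation schedule with the
closed-form one-compartment model and scored by relative RMSE.  The
lowest-rRMSE candidate becomes the recommended one-compartment initial
estimate set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ROUTE_EXTRAVASCULAR
from .simulate import Dose, StructuralParams, simulate_onecpt_closed
from .single_point import OneCptEstimate

__all__ = ["ParamSet", "ScoredCandidate", "rrmse", "score_metric",
           "candidate_rrmse", "select_base_params", "SelectionError"]

#: tie-break priority (lower = preferred) when rRMSEs agree within 1e-9
_METHOD_PRIORITY = {"nca": 0, "single_point": 1, "graphical": 2, "hybrid": 3}


class SelectionError(RuntimeError):
    """No complete candidate parameter set could be formed."""


@dataclass
class ParamSet:
    """Named structural parameters with per-parameter source labels."""

    values: dict = field(default_factory=dict)
    sources: dict = field(default_factory=dict)

    def __getitem__(self, k):
        return self.values[k]

    def get(self, k, default=None):
        return self.values.get(k, default)


@dataclass
class ScoredCandidate:
    params: ParamSet
    rrmse_pct: float
    n_obs: int
    method: str = "hybrid"


def rrmse(predicted, observed) -> float:
    """Relative RMSE in percent, pointwise-mean denominator.

    100 * sqrt( mean( (p_i - o_i)^2 / ((p_i + o_i)/2)^2 ) ), bounded by
    200%.  Pairs with p + o = 0 are excluded; an empty set raises.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    keep = (p + o) != 0
    p, o = p[keep], o[keep]
    if len(p) == 0:
        raise ValueError("rRMSE undefined: no usable pairs")
    ratio = (p - o) / ((p + o) / 2.0)
    return float(100.0 * np.sqrt(np.mean(ratio ** 2)))


def rrmse_obsmean(predicted, observed) -> float:
    """Alternative rRMSE with the observed mean as denominator."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    ob = np.mean(o)
    if ob == 0:
        raise ValueError("observed mean is zero")
    return float(100.0 * np.sqrt(np.mean((p - o) ** 2)) / ob)


def mape(predicted, observed) -> float:
    """Mean absolute percentage error."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    keep = o != 0
    if not keep.any():
        raise ValueError("MAPE undefined: all observations zero")
    return float(100.0 * np.mean(np.abs((p[keep] - o[keep]) / o[keep])))


_METRICS = {"rrmse_pairwise": rrmse, "rrmse_obsmean": rrmse_obsmean, "mape": mape}


def score_metric(name: str):
    try:
        return _METRICS[name]
    except KeyError:
        raise ValueError(
            f"unknown metric {name!r}; choose from {sorted(_METRICS)}"
        ) from None


def individual_schedules(obs: pd.DataFrame, doses: pd.DataFrame):
    """Yield (dose events, observation times, observed DV, route) per subject."""
    for sid, sub in obs.groupby("id"):
        sub_d = doses[doses["id"] == sid]
        events = [
            Dose(time=r["time"], amount=r["amount"], rate=r["rate"])
            for _, r in sub_d.iterrows()
        ]
        yield sid, events, sub["time"].to_numpy(float), sub["dv"].to_numpy(float), \
            sub["route"].iloc[-1]


def candidate_rrmse(
    cl: float, v: float, ka: float | None,
    obs: pd.DataFrame, doses: pd.DataFrame, metric="rrmse_pairwise",
) -> tuple[float, int]:
    """Score one (CL, V, Ka) candidate on all individual-level data."""
    fn = score_metric(metric) if isinstance(metric, str) else metric
    pred_all, obs_all = [], []
    for sid, events, t, dv, route in individual_schedules(obs, doses):
        p = StructuralParams(cl=cl, vc=v, ka=ka)
        pred = simulate_onecpt_closed(p, events, t, route=route)
        pred_all.append(pred)
        obs_all.append(dv)
    pred_all = np.concatenate(pred_all)
    obs_all = np.concatenate(obs_all)
    return fn(pred_all, obs_all), len(obs_all)


def select_base_params(
    estimates: dict[str, OneCptEstimate],
    obs: pd.DataFrame,
    doses: pd.DataFrame,
    route: str,
    metric: str = "rrmse_pairwise",
) -> tuple[ScoredCandidate, list[ScoredCandidate]]:
    """Score per-method sets and cross-method hybrids; return the winner.

    Candidates must be complete: CL and V, plus Ka for extravascular
    routes.  The winner is the minimum-rRMSE candidate; near-ties (within
    1e-9) are broken by method priority NCA > single-point > graphical >
    hybrid.  Raises :class:`SelectionError` when no candidate is complete.
    """
    need_ka = route == ROUTE_EXTRAVASCULAR
    cl_opts, v_opts, ka_opts = {}, {}, {}
    pure = {}
    for name, est in estimates.items():
        if est is None:
            continue
        if est.cl is not None and est.cl > 0:
            cl_opts[name] = est.cl
        if est.v is not None and est.v > 0:
            v_opts[name] = est.v
        if est.ka is not None and est.ka > 0:
            ka_opts[name] = est.ka
        if est.complete and (not need_ka or est.ka is not None):
            pure[name] = est

    candidates: list[ScoredCandidate] = []
    seen = set()

    def add(cl_src, v_src, ka_src, label):
        cl, v = cl_opts[cl_src], v_opts[v_src]
        ka = ka_opts[ka_src] if ka_src else None
        key = (round(cl, 12), round(v, 12), round(ka, 12) if ka else None)
        if key in seen:
            return
        seen.add(key)
        try:
            score, n = candidate_rrmse(cl, v, ka, obs, doses, metric)
        except (ValueError, ZeroDivisionError):
            return
        ps = ParamSet(
            values={"cl": cl, "v": v, **({"ka": ka} if ka else {})},
            sources={"cl": cl_src, "v": v_src, **({"ka": ka_src} if ka_src else {})},
        )
        candidates.append(ScoredCandidate(ps, score, n, method=label))

    # priority order so deduplicated ties keep the preferred method label
    for name in sorted(pure, key=lambda n: _METHOD_PRIORITY.get(n, 9)):
        add(name, name, name if need_ka else None, name)
    ka_iter = list(ka_opts) if need_ka else [None]
    for cl_src, v_src, ka_src in itertools.product(cl_opts, v_opts, ka_iter):
        if need_ka and ka_src is None:
            continue
        add(cl_src, v_src, ka_src, "hybrid")

    if not candidates:
        detail = {
            name: (est.messages or ["incomplete"])
            for name, est in estimates.items() if est is not None
        }
        raise SelectionError(f"no complete Part-1 candidate; diagnostics: {detail}")

    candidates.sort(
        key=lambda c: (c.rrmse_pct, _METHOD_PRIORITY.get(c.method, 9))
    )
    best = candidates[0]
    near = [c for c in candidates if c.rrmse_pct <= best.rrmse_pct + 1e-9]
    near.sort(key=lambda c: _METHOD_PRIORITY.get(c.method, 9))
    return near[0], candidates
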