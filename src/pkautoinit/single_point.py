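"""Adaptive single-point method.

The base phase computes V_d from the first post-dose sample (intravenous,
sampled within 20% of a half-life so that less than ~13% of the dose has
been eliminated) and CL from steady-state peak/trough concentrations
(CL = Dose / (C_ss,avg * tau)).  The extended phase fills in whichever of
CL / V_d the base phase could not produce using the pooled half-life, a
C_max-based central volume with accumulation-ratio correction, and Ka by
root-finding on the analytic one-compartment concentration equations.
Per-individual values are summarized by a trimmed geometric mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dataio import ROUTE_BOLUS, ROUTE_EXTRAVASCULAR, ROUTE_INFUSION

__all__ = [
    "SteadyStateWindow",
    "OneCptEstimate",
    "elimination_fraction",
    "sp_vd_first_point",
    "sp_cl_steady_state",
    "sp_extended",
    "accumulation_ratio",
    "sp_vc_from_cmax",
    "solve_ka_onecpt",
    "trimmed_geomean",
    "single_point_estimate",
]

LN2 = math.log(2.0)
#: eligibility window for "first point" sampling, as a fraction of t1/2
ELIGIBILITY_FRACTION = 0.2
KA_UPPER = 1000.0


@dataclass(frozen=True)
class SteadyStateWindow:
    """Peak/trough context of the most recent steady-state dosing interval."""

    id: object
    c_ss_max: float | None
    c_ss_min: float | None
    tau: float
    t_inf: float
    route: str

    @property
    def c_ss_avg(self) -> float | None:
        if self.c_ss_max is None or self.c_ss_min is None:
            return None
        return 0.5 * (self.c_ss_max + self.c_ss_min)


@dataclass
class OneCptEstimate:
    """Population-level one-compartment parameter set from one method."""

    method: str
    cl: float | None = None
    v: float | None = None
    ka: float | None = None
    v_source: str = "vd"  # vd | vc
    vc: float | None = None  # extended-phase central volume, kept separately
    per_individual: dict = field(default_factory=dict, repr=False)
    n_used: int = 0
    messages: list = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.cl is not None and self.v is not None


def elimination_fraction(f_halflife: float) -> float:
    """Fraction of drug eliminated after ``f_halflife`` half-lives.

    ``elimination_fraction(0.2)`` is about 0.13, the rationale for the 20%
    sampling-window rule of the base phase.
    """
    if f_halflife < 0:
        raise ValueError("f_halflife must be non-negative")
    return 1.0 - math.exp(-LN2 * f_halflife)


def sp_vd_first_point(
    dose: float, c1: float, t1_tad: float, t_half: float | None, route: str
) -> float | None:
    """V_d = Dose / C_1 from the first post-dose sample (IV only).

    Returns None (ineligible) unless the sample falls within
    ``ELIGIBILITY_FRACTION`` of the half-life after dosing.
    """
    if route not in (ROUTE_BOLUS, ROUTE_INFUSION):
        return None
    if t_half is None or t_half <= 0 or c1 <= 0:
        return None
    if t1_tad > ELIGIBILITY_FRACTION * t_half:
        return None
    return dose / c1


def sp_cl_steady_state(
    window: SteadyStateWindow, dose: float, ke: float | None = None
) -> float | None:
    """CL = Dose / (C_ss,avg * tau) from a steady-state interval.

    When only one extreme was observed the other is reconstructed with the
    mono-exponential decay over the interval (intravenous routes only):
    ``C_ss,min = C_ss,max * exp(-ke*tau)`` for a bolus and
    ``C_ss,min = C_ss,max * exp(-ke*(tau - t_inf))`` for an infusion.
    """
    cmax, cmin = window.c_ss_max, window.c_ss_min
    if cmax is None and cmin is None:
        return None
    if cmax is None or cmin is None:
        if window.route == ROUTE_EXTRAVASCULAR or ke is None or ke <= 0:
            return None
        decay = window.tau - (window.t_inf if window.route == ROUTE_INFUSION else 0.0)
        if cmin is None:
            cmin = cmax * math.exp(-ke * decay)
        else:
            cmax = cmin * math.exp(ke * decay)
    c_avg = 0.5 * (cmax + cmin)
    if c_avg <= 0 or window.tau <= 0:
        return None
    return dose / (c_avg * window.tau)


def sp_extended(cl: float, t_half: float) -> float:
    """Extended-phase volume: V_d = CL * t1/2 / ln 2."""
    if cl <= 0 or t_half <= 0:
        raise ValueError("cl and t_half must be positive")
    return cl * t_half / LN2


def accumulation_ratio(ke: float, tau: float) -> float:
    """R_ac = 1 / (1 - exp(-ke*tau)); converts C_max,ss back to C_max."""
    return 1.0 / (1.0 - math.exp(-ke * tau))


def sp_vc_from_cmax(
    dose: float,
    c_max_obs: float,
    occasion: str,
    ke: float | None,
    tau: float | None,
    tad_at_cmax: float,
    t_half: float | None,
) -> float | None:
    """Central volume from C_max: V_c = Dose / C_max.

    Multi-dose C_max,ss is first converted to the single-dose C_max with
    the accumulation ratio.  The sample must fall within 20% of the
    half-life after its dose.
    """
    if c_max_obs <= 0 or t_half is None or t_half <= 0:
        return None
    if tad_at_cmax > ELIGIBILITY_FRACTION * t_half:
        return None
    if occasion == "first_dose":
        return dose / c_max_obs
    if ke is None or tau is None or tau <= 0:
        return None
    c_max = c_max_obs / accumulation_ratio(ke, tau)
    return dose / c_max


def _onecpt_oral_conc(ka, t, dose, cl, vd, tau=None):
    ke = cl / vd
    pref = dose * ka / (vd * (ka - ke))
    if tau is None:
        return pref * (math.exp(-ke * t) - math.exp(-ka * t))
    return pref * (
        math.exp(-ke * t) / (1.0 - math.exp(-ke * tau))
        - math.exp(-ka * t) / (1.0 - math.exp(-ka * tau))
    )


def solve_ka_onecpt(
    conc: float,
    t: float,
    dose: float,
    cl: float,
    vd: float,
    tau: float | None = None,
    tol: float = 1e-8,
) -> float | None:
    """Solve the one-compartment oral equation for Ka by Brent's method.

    ``tau=None`` selects the single-dose equation, otherwise the
    steady-state multiple-dose equation.  The bracket is
    ``(ke*(1+1e-6), 1000]`` — the equations are singular at ka = ke.
    Returns None when no root exists in the bracket (the observation is
    unreachable by any admissible Ka).
    """
    ke = cl / vd
    lo = ke * (1.0 + 1e-6)
    hi = KA_UPPER
    if lo >= hi:
        return None

    def f(ka):
        return _onecpt_oral_conc(ka, t, dose, cl, vd, tau) - conc

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return None
    return float(brentq(f, lo, hi, xtol=tol))


def trimmed_geomean(values, trim: float = 0.05) -> float | None:
    """Trimmed geometric mean: drop floor(n*trim/2) values at each end.

    A trim of 0.05 removes the top and bottom 2.5% of the data.  Values
    <= 0 are excluded with a warning before trimming.
    """
    v = np.asarray(list(values), dtype=float)
    bad = ~(v > 0)
    if bad.any():
        warnings.warn(f"{bad.sum()} non-positive value(s) excluded from geometric mean")
        v = v[~bad]
    if len(v) == 0:
        return None
    v = np.sort(v)
    k = int(math.floor(len(v) * trim / 2.0))
    if 2 * k < len(v):
        v = v[k:len(v) - k] if k > 0 else v
    return float(np.exp(np.mean(np.log(v))))


def _ss_window(sub_obs: pd.DataFrame, sub_doses: pd.DataFrame):
    """Most recent steady-state dosing interval of a subject, with extremes."""
    ss = sub_obs[sub_obs["at_steady_state"] & sub_obs["tau"].notna()]
    ss = ss[ss["dv"] > 0]
    if ss.empty:
        return None, None
    dn = int(ss["dose_number"].max())
    w = ss[ss["dose_number"] == dn]
    w = w[w["tad"] <= w["tau"] + 1e-9]
    if w.empty:
        return None, None
    tau = float(w["tau"].iloc[0])
    route = w["route"].iloc[0]
    drow = sub_doses[sub_doses["number"] == dn]
    t_inf = float(drow["t_inf"].iloc[0]) if len(drow) else 0.0
    dose = float(w["dose_amount"].iloc[0])
    if len(w) >= 2:
        win = SteadyStateWindow(
            id=w["id"].iloc[0], c_ss_max=float(w["dv"].max()),
            c_ss_min=float(w["dv"].min()), tau=tau, t_inf=t_inf, route=route,
        )
    else:
        c = float(w["dv"].iloc[0])
        tad = float(w["tad"].iloc[0])
        # an isolated early sample is read as the peak, a late one as the trough
        if tad <= tau / 2.0:
            win = SteadyStateWindow(w["id"].iloc[0], c, None, tau, t_inf, route)
        else:
            win = SteadyStateWindow(w["id"].iloc[0], None, c, tau, t_inf, route)
    return win, dose


def single_point_estimate(
    obs: pd.DataFrame,
    doses: pd.DataFrame,
    t_half: float | None,
    absorption_tmax: float | None = None,
    trim: float = 0.05,
) -> OneCptEstimate:
    """Run base + extended phases of the adaptive single-point method.

    Parameters
    ----------
    obs, doses
        Annotated tables from :func:`pkautoinit.dataio.annotate_doses`
        (steady-state flags already refreshed with the pooled half-life).
    t_half
        Pooled terminal half-life (None when not estimable; half-life
        dependent steps are then skipped).
    absorption_tmax
        Pooled-profile peak TAD; observations at or before it count as
        absorption phase for Ka root-finding (extravascular only).
    """
    est = OneCptEstimate(method="single_point")
    ke = LN2 / t_half if t_half else None
    per_cl: dict = {}
    per_vd: dict = {}
    per_vc: dict = {}
    per_ka: dict = {}

    for sid, sub in obs.groupby("id"):
        sub = sub.sort_values("time")
        sub_d = doses[doses["id"] == sid]
        route = sub["route"].iloc[-1]

        # base phase: Vd from first post-initial-dose sample (IV)
        first = sub[(sub["occasion"] == "first_dose") & (sub["dv"] > 0)]
        if len(first):
            row = first.iloc[0]
            vd = sp_vd_first_point(
                row["dose_amount"], row["dv"], row["tad"], t_half, row["route"]
            )
            if vd is not None:
                per_vd[sid] = vd

        # base phase: CL from the most recent steady-state interval
        win, dose_amt = _ss_window(sub, sub_d)
        if win is not None:
            cl = sp_cl_steady_state(win, dose_amt, ke)
            if cl is not None and cl > 0:
                per_cl[sid] = cl

        # extended phase inputs: Vc from Cmax
        pos = sub[sub["dv"] > 0]
        if len(pos):
            imax = pos["dv"].idxmax()
            row = pos.loc[imax]
            vc = sp_vc_from_cmax(
                row["dose_amount"], row["dv"], row["occasion"], ke,
                row["tau"] if np.isfinite(row["tau"]) else None,
                row["tad"], t_half,
            )
            if vc is not None and vc > 0:
                per_vc[sid] = vc

    est.per_individual = {"cl": per_cl, "vd": per_vd, "vc": per_vc}
    cl_pop = trimmed_geomean(per_cl.values(), trim) if per_cl else None
    vd_pop = trimmed_geomean(per_vd.values(), trim) if per_vd else None
    est.vc = trimmed_geomean(per_vc.values(), trim) if per_vc else None

    # extended phase: derive whichever of CL/Vd is missing from t1/2
    if cl_pop is not None and vd_pop is None and t_half:
        vd_pop = sp_extended(cl_pop, t_half)
        est.messages.append("Vd derived from CL and t1/2 (extended phase)")
    elif vd_pop is not None and cl_pop is None and t_half:
        cl_pop = vd_pop * LN2 / t_half
        est.messages.append("CL derived from Vd and t1/2 (extended phase)")
    elif cl_pop is None and vd_pop is None:
        vc_pop = est.vc
        if vc_pop is not None and t_half:
            vd_pop = vc_pop
            cl_pop = vc_pop * LN2 / t_half
            est.v_source = "vc"
            est.messages.append("Vc substituted for Vd; CL = ke*Vc (extended phase)")

    est.cl, est.v = cl_pop, vd_pop

    # extended phase: Ka from absorption-phase points (extravascular)
    routes = set(obs["route"])
    if ROUTE_EXTRAVASCULAR in routes and est.complete and absorption_tmax is not None:
        for sid, sub in obs.groupby("id"):
            pts = sub[
                (sub["route"] == ROUTE_EXTRAVASCULAR)
                & (sub["dv"] > 0)
                & (sub["tad"] <= absorption_tmax + 1e-9)
            ]
            roots = []
            for _, row in pts.iterrows():
                tau = None
                if row["occasion"] == "multi_dose" and row["at_steady_state"] \
                        and np.isfinite(row["tau"]):
                    tau = float(row["tau"])
                elif row["occasion"] == "multi_dose":
                    continue  # non-steady-state multi-dose points are skipped
                ka = solve_ka_onecpt(
                    row["dv"], row["tad"], row["dose_amount"], est.cl, est.v, tau
                )
                if ka is not None and ka > 0:
                    roots.append(ka)
            if roots:
                per_ka[sid] = float(np.exp(np.mean(np.log(roots))))
        est.per_individual["ka"] = per_ka
        if per_ka:
            est.ka = trimmed_geomean(per_ka.values(), trim)

    est.n_used = len(set(per_cl) | set(per_vd) | set(per_vc) | set(per_ka))
    return est
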