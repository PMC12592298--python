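"""Forward simulation of compartmental PK models.

Two engines are provided:

* :func:`simulate_onecpt_closed` — analytic one-compartment solutions
  (bolus, zero-order infusion, first-order absorption) with multiple
  dosing handled by superposition.  Used for candidate scoring in Part 1
  and as the linear reference everywhere.
* :func:`simulate_ode` — numeric integration of 1/2/3-compartment models
  with linear or Michaelis-Menten elimination, used by the parameter
  sweeps and the fixture generator.

Bioavailability is fixed at 1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dataio import ROUTE_BOLUS, ROUTE_EXTRAVASCULAR, ROUTE_INFUSION

__all__ = [
    "ModelSpec",
    "StructuralParams",
    "Dose",
    "simulate_onecpt_closed",
    "simulate_ode",
]


@dataclass(frozen=True)
class ModelSpec:
    """Structural model descriptor."""

    n_compartments: int = 1
    elimination: str = "linear"  # linear | michaelis_menten
    route: str = ROUTE_BOLUS
    f_bio: float = 1.0

    def __post_init__(self):
        if self.n_compartments not in (1, 2, 3):
            raise ValueError("n_compartments must be 1, 2 or 3")
        if self.elimination not in ("linear", "michaelis_menten"):
            raise ValueError(f"unknown elimination: {self.elimination}")


@dataclass(frozen=True)
class StructuralParams:
    """Named structural parameters; only the subset the model needs is used.

    Units: cl, q, q2 [L/h]; vc, vp, vp2 [L]; ka [1/h]; vmax [mass/h];
    km [mass/volume].
    """

    cl: float | None = None
    vc: float | None = None
    ka: float | None = None
    vmax: float | None = None
    km: float | None = None
    vp: float | None = None
    q: float | None = None
    vp2: float | None = None
    q2: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass(frozen=True)
class Dose:
    """One administered dose; ``rate > 0`` means a zero-order infusion."""

    time: float
    amount: float
    rate: float = 0.0

    @property
    def t_inf(self) -> float:
        return self.amount / self.rate if self.rate > 0 else 0.0


def _onecpt_bolus(t, dose, ke, v):
    c = np.zeros_like(t, dtype=float)
    m = t >= 0
    c[m] = dose / v * np.exp(-ke * t[m])
    return c


def _onecpt_infusion(t, dose, rate, ke, v):
    cl = ke * v
    tinf = dose / rate
    c = np.zeros_like(t, dtype=float)
    during = (t >= 0) & (t <= tinf)
    after = t > tinf
    c[during] = rate / cl * (1.0 - np.exp(-ke * t[during]))
    c[after] = (
        rate / cl * (1.0 - np.exp(-ke * tinf)) * np.exp(-ke * (t[after] - tinf))
    )
    return c


def _onecpt_oral(t, dose, ka, ke, v, f_bio=1.0):
    c = np.zeros_like(t, dtype=float)
    m = t >= 0
    tm = t[m]
    if abs(ka - ke) < 1e-12 * max(ka, ke):
        # limiting form as ka -> ke
        c[m] = f_bio * dose / v * ke * tm * np.exp(-ke * tm)
    else:
        c[m] = (
            f_bio * dose * ka / (v * (ka - ke))
            * (np.exp(-ke * tm) - np.exp(-ka * tm))
        )
    return c


def simulate_onecpt_closed(
    params: StructuralParams | dict,
    doses: Sequence[Dose],
    obs_times: Sequence[float],
    route: str = ROUTE_BOLUS,
    f_bio: float = 1.0,
) -> np.ndarray:
    """Analytic one-compartment concentrations at ``obs_times``.

    Multiple doses are handled by superposition of time-shifted
    single-dose solutions, which is exact for linear kinetics.
    """
    if isinstance(params, dict):
        params = StructuralParams(**params)
    cl, v = params.cl, params.vc
    ke = cl / v
    t = np.asarray(obs_times, dtype=float)
    c = np.zeros_like(t)
    for d in doses:
        rel = t - d.time
        if route == ROUTE_EXTRAVASCULAR:
            c += _onecpt_oral(rel, d.amount, params.ka, ke, v, f_bio)
        elif route == ROUTE_INFUSION or d.rate > 0:
            c += _onecpt_infusion(rel, d.amount, d.rate, ke, v)
        else:
            c += _onecpt_bolus(rel, d.amount, ke, v)
    return c


def _rhs_factory(spec: ModelSpec, p: StructuralParams):
    vc = p.vc
    ka = p.ka or 0.0
    q = p.q or 0.0
    vp = p.vp or 1.0
    q2 = p.q2 or 0.0
    vp2 = p.vp2 or 1.0
    linear = spec.elimination == "linear"
    cl = p.cl or 0.0
    vmax, km = p.vmax or 0.0, p.km or 1.0

    def rhs(t, y, rate_in):
        a_d, a_c, a_p, a_p2 = y
        conc = a_c / vc
        elim = cl * conc if linear else vmax * conc / (km + conc)
        d_ad = -ka * a_d
        d_ac = ka * a_d + rate_in - elim - q * conc + q * a_p / vp \
            - q2 * conc + q2 * a_p2 / vp2
        d_ap = q * conc - q * a_p / vp
        d_ap2 = q2 * conc - q2 * a_p2 / vp2
        return (d_ad, d_ac, d_ap, d_ap2)

    return rhs


def simulate_ode(
    spec: ModelSpec,
    params: StructuralParams | dict,
    doses: Sequence[Dose],
    obs_times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Numerically integrate the model and return concentrations.

    Doses enter the depot compartment for extravascular routes and the
    central compartment otherwise; infusions are zero-order inputs over
    their duration.  Integration proceeds piecewise between dose events
    with a stiff-capable method (LSODA); observation times are evaluated
    from dense output.  An integration failure raises ``RuntimeError``
    (sweep callers catch it and mark the candidate failed).
    """
    if isinstance(params, dict):
        params = StructuralParams(**params)
    t_obs = np.asarray(obs_times, dtype=float)
    if len(t_obs) == 0:
        return np.empty(0)
    rhs = _rhs_factory(spec, params)

    # breakpoints: dose starts, infusion ends, start/end of horizon
    brk = {0.0, float(np.max(t_obs))}
    for d in doses:
        brk.add(float(d.time))
        if d.rate > 0:
            brk.add(float(d.time + d.t_inf))
    brk = sorted(b for b in brk if b <= float(np.max(t_obs)) + 1e-12)
    if brk[-1] < float(np.max(t_obs)):
        brk.append(float(np.max(t_obs)))

    y = np.zeros(4)
    out = np.full_like(t_obs, np.nan)
    depot = spec.route == ROUTE_EXTRAVASCULAR

    def apply_bolus(t0):
        for d in doses:
            if abs(d.time - t0) < 1e-12 and d.rate == 0:
                if depot:
                    y[0] += spec.f_bio * d.amount
                else:
                    y[1] += d.amount

    def infusion_rate(tmid):
        r = 0.0
        for d in doses:
            if d.rate > 0 and d.time - 1e-12 <= tmid < d.time + d.t_inf - 1e-12:
                r += d.rate
        return r

    # convention matching the closed form: C at a bolus time is post-dose
    apply_bolus(brk[0])
    out[np.isclose(t_obs, brk[0])] = y[1] / params.vc
    for a, b in zip(brk[:-1], brk[1:]):
        if b <= a + 1e-15:
            continue
        rate = infusion_rate(0.5 * (a + b))
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", args=(rate,),
            rtol=rtol, atol=atol, dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{a}, {b}]: {sol.message}")
        inside = (t_obs > a) & (t_obs < b) & ~np.isclose(t_obs, b)
        if inside.any():
            out[inside] = sol.sol(t_obs[inside])[1] / params.vc
        y = sol.y[:, -1].copy()
        apply_bolus(b)
        out[np.isclose(t_obs, b)] = y[1] / params.vc
    out[t_obs < brk[0]] = 0.0
    return np.clip(out, 0.0, None)
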