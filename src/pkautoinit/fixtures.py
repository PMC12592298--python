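"""Synthetic dataset generator for the simulated study designs.

Generates NONMEM-convention datasets from a :class:`DesignSpec`:
per-subject parameters are drawn lognormally (variance omega^2 on the
log scale), concentrations come from the closed-form or ODE simulators,
and observations get combined residual error
``y = f*(1 + eps_prop) + eps_add`` truncated at zero.

Sampling templates mirror the simulated designs used to exercise the
pipeline: a rich schedule; a semi-sparse design splitting subjects into
three groups with two samples each within one post-multiple-dose
interval (times drawn from 2, 4, 6, 8, 12, 24 h); sparse1 (samples at
2 h [oral only], 20 and 24 h after the last of multiple doses) and
sparse2 (the same times after a single dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import ROUTE_EXTRAVASCULAR, ROUTE_INFUSION
from .simulate import Dose, ModelSpec, StructuralParams, simulate_ode, \
    simulate_onecpt_closed

__all__ = ["DesignSpec", "SAMPLING_TEMPLATES", "generate_dataset", "sampling_times"]

RICH_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)
SEMI_SPARSE_GROUPS = ((2.0, 8.0), (4.0, 12.0), (6.0, 24.0))
SPARSE_TIMES_IV = (20.0, 24.0)
SPARSE_TIMES_ORAL = (2.0, 20.0, 24.0)

SAMPLING_TEMPLATES = ("rich", "semi_sparse", "sparse1", "sparse2", "custom")


@dataclass
class DesignSpec:
    """One simulated study design.

    ``dosing`` is (amount, tau, n_doses); ``sampling`` names a template
    (``custom`` uses ``custom_times`` as TADs after the last dose).
    ``iiv_omega2`` maps parameter names to log-scale variances.
    """

    route: str = "bolus"
    model: ModelSpec = field(default_factory=ModelSpec)
    true_params: StructuralParams = field(
        default_factory=lambda: StructuralParams(cl=4.0, vc=70.0)
    )
    n_subjects: int = 30
    dosing: tuple = (100.0, 24.0, 1)
    sampling: str = "rich"
    custom_times: tuple = ()
    iiv_omega2: dict = field(default_factory=dict)
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    seed: int = 0
    infusion_duration: float = 1.0


def sampling_times(spec: DesignSpec, subject_index: int) -> tuple[float, int]:
    """TADs sampled for one subject and the dose they follow.

    Returns (times after the reference dose, reference dose number).
    Rich schedules sample after the first dose; semi-sparse and sparse1
    after the last of multiple doses; sparse2 after a single dose.
    """
    amount, tau, n_doses = spec.dosing
    oral = spec.route == ROUTE_EXTRAVASCULAR
    if spec.sampling == "rich":
        return tuple(t for t in RICH_TIMES if t <= tau or n_doses == 1), 1
    if spec.sampling == "semi_sparse":
        # deterministic round-robin group assignment
        return SEMI_SPARSE_GROUPS[subject_index % 3], n_doses
    if spec.sampling == "sparse1":
        return (SPARSE_TIMES_ORAL if oral else SPARSE_TIMES_IV), n_doses
    if spec.sampling == "sparse2":
        return (SPARSE_TIMES_ORAL if oral else SPARSE_TIMES_IV), 1
    if spec.sampling == "custom":
        return tuple(spec.custom_times), n_doses
    raise ValueError(
        f"unknown sampling template {spec.sampling!r}; "
        f"valid templates: {', '.join(SAMPLING_TEMPLATES)}"
    )


def _draw_params(spec: DesignSpec, rng: np.random.Generator) -> StructuralParams:
    base = spec.true_params.as_dict()
    for name, om2 in spec.iiv_omega2.items():
        if name in base and om2 > 0:
            base[name] = base[name] * float(
                np.exp(rng.normal(0.0, np.sqrt(om2)))
            )
    return StructuralParams(**base)


def generate_dataset(spec: DesignSpec) -> pd.DataFrame:
    """Simulate a design into a NONMEM-convention event table.

    Columns: ID, TIME, AMT, RATE, EVID, CMT, DV.  Doses go to CMT 1;
    observations are read from CMT 2 for extravascular designs (depot
    convention) and CMT 1 otherwise.  Randomness is fully determined by
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    amount, tau, n_doses = spec.dosing
    if spec.sampling == "sparse2" and n_doses != 1:
        n_doses = 1
    oral = spec.route == ROUTE_EXTRAVASCULAR
    infusion = spec.route == ROUTE_INFUSION
    rate = amount / spec.infusion_duration if infusion else 0.0
    obs_cmt = 2 if oral else 1
    model = replace(spec.model, route=spec.route)

    rows = []
    for i in range(spec.n_subjects):
        sid = i + 1
        params = _draw_params(spec, rng)
        doses = [
            Dose(time=k * tau, amount=amount, rate=rate) for k in range(n_doses)
        ]
        tads, ref_dose = sampling_times(spec, i)
        t_obs = np.asarray(tads, float) + (ref_dose - 1) * tau
        if model.n_compartments == 1 and model.elimination == "linear":
            f = simulate_onecpt_closed(params, doses, t_obs, route=spec.route)
        else:
            f = simulate_ode(model, params, doses, t_obs)
        eps_p = rng.normal(0.0, spec.sigma_prop, len(t_obs)) if spec.sigma_prop else 0.0
        eps_a = rng.normal(0.0, spec.sigma_add, len(t_obs)) if spec.sigma_add else 0.0
        y = np.clip(f * (1.0 + eps_p) + eps_a, 0.0, None)
        for k, d in enumerate(doses):
            rows.append(dict(ID=sid, TIME=d.time, AMT=d.amount, RATE=d.rate,
                             EVID=1, CMT=1, DV=np.nan))
        for t, yv in zip(t_obs, y):
            rows.append(dict(ID=sid, TIME=float(t), AMT=0.0, RATE=0.0,
                             EVID=0, CMT=obs_cmt, DV=float(yv)))
    df = pd.DataFrame(rows).sort_values(
        ["ID", "TIME", "EVID"], ascending=[True, True, False], kind="stable"
    )
    return df.reset_index(drop=True)
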