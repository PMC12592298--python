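"""End-to-end orchestration: data prep -> Part 1 -> sweeps -> error model.

The public surface follows the model/results idiom: build a
:class:`PKInitModel` from a dataset, call :meth:`PKInitModel.fit`, and
read the recommended initial estimates, per-method diagnostics and sweep
outputs off the returned :class:`PKInitResults` (or its ``summary()``
table / JSON report).  :func:`run_pipeline` is a thin functional wrapper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataio import (
    ROUTE_EXTRAVASCULAR,
    annotate_doses,
    flag_steady_state,
    parse_dataset,
    pool_observations,
)
from .error_model import ErrorInit, initialize_error
from .graphical import graphical_estimate
from .nca import modal_tau, nca_onecpt, wagner_nelson_ka
from .selection import ScoredCandidate, SelectionError, select_base_params
from .single_point import single_point_estimate
from .sweep import build_cpt_grid, build_mm_grid, run_sweep
from .terminal_phase import TerminalPhaseError, fit_lambda_z

__all__ = ["PipelineConfig", "InitReport", "PKInitModel", "PKInitResults",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """Tunable knobs of the pipeline, mirrored by the CLI/config file."""

    n_bins: int = 10
    metric: str = "rrmse_pairwise"  # selection.metric
    route: str | None = None  # override: bolus | infusion | extravascular
    models: tuple = ("1cmpt",)  # subset of 1cmpt, 2cmpt, 3cmpt, mm
    trim: float = 0.05
    error_cv_fallback: float = 0.20
    error_n_terminal_points: int = 3
    omega2: float = 0.1
    sweep_km_ratios: tuple | None = None
    sweep_c_fractions: tuple | None = None
    sweep_vp_ratios: tuple | None = None
    sweep_q_folds: tuple | None = None
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for k, v in raw.items():
            if isinstance(v, dict):  # allow nested sections like selection:
                for k2, v2 in v.items():
                    flat[f"{k}_{k2}" if f"{k}_{k2}" in cls.__dataclass_fields__
                         else k2] = v2
            else:
                flat[k] = v
        known = {k: v for k, v in flat.items() if k in cls.__dataclass_fields__}
        if "models" in known and isinstance(known["models"], (list, str)):
            m = known["models"]
            known["models"] = tuple([m] if isinstance(m, str) else m)
        return cls(**known)


@dataclass
class InitReport:
    """Machine-readable initial-estimates report."""

    selected: dict
    per_method: dict
    sweeps: dict
    error_init: dict
    warnings: list
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, indent: int = 2):
        payload = json.dumps(self.to_dict(), indent=indent, default=float)
        if path is None:
            return payload
        with open(path, "w") as fh:
            fh.write(payload)

    def to_flat_frame(self) -> pd.DataFrame:
        """Flat parameter/value/source rows for export."""
        rows = [
            {"parameter": k, "value": v,
             "source": self.selected["sources"].get(k, "")}
            for k, v in self.selected["values"].items()
        ]
        for model, res in self.sweeps.items():
            if not isinstance(res, dict) or "values" not in res:
                continue
            for k, v in res["values"].items():
                rows.append({"parameter": f"{model}.{k}", "value": v,
                             "source": res["sources"].get(k, "sweep")})
        for k in ("sigma_add", "sigma_prop"):
            rows.append({"parameter": k, "value": self.error_init[k],
                         "source": self.error_init["source"]})
        for p, v in self.error_init["omega2"].items():
            rows.append({"parameter": f"omega2.{p}", "value": v,
                         "source": "default"})
        return pd.DataFrame(rows)


class PKInitModel:
    """Initial-estimates model bound to one longitudinal PK dataset.

    Parameters
    ----------
    data : DataFrame or path or delimited text
        NONMEM-convention events (ID, TIME, AMT, RATE, EVID, CMT, DV,
        optional ADDL/II).
    config : PipelineConfig, optional
    """

    def __init__(self, data, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.records = parse_dataset(data)
        self.doses, self.obs = annotate_doses(
            self.records, route=self.config.route
        )
        if self.doses.empty:
            raise SelectionError("no dose records in dataset")
        if self.obs.empty:
            raise SelectionError("no usable observation records in dataset")

    @classmethod
    def from_csv(cls, path, config: PipelineConfig | None = None):
        return cls(path, config=config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: PipelineConfig | None = None):
        return cls(df, config=config)

    @property
    def route(self) -> str:
        """Dominant administration route of the dataset."""
        return self.obs["route"].mode().iloc[0]

    def fit(self, models: tuple | None = None) -> "PKInitResults":
        """Run the three-part pipeline and return the results object."""
        cfg = self.config
        models = tuple(models) if models is not None else cfg.models
        warnings_out: list[str] = []
        route = self.route
        multiple = bool((self.obs["occasion"] == "multi_dose").any())

        # ---- pooled profiles ------------------------------------------------
        prof_first = pool_observations(self.obs, "first_dose", cfg.n_bins)
        prof_multi = pool_observations(self.obs, "multi_dose", cfg.n_bins)
        prof_mixed = pool_observations(self.obs, "mixed", cfg.n_bins)

        # ---- terminal phase / half-life ------------------------------------
        fit = None
        for prof in (prof_first, prof_mixed):
            if prof.is_empty:
                continue
            try:
                fit = fit_lambda_z(prof, route=route)
                fit_profile = prof
                break
            except TerminalPhaseError as exc:
                warnings_out.append(f"terminal fit on {prof.group} group: {exc}")
        t_half = fit.t_half if fit else None
        if fit is None:
            warnings_out.append(
                "terminal phase not estimable; half-life dependent methods skipped"
            )
        else:
            self.obs = flag_steady_state(self.obs, self.doses, t_half)

        # ---- Part 1: three candidate methods -------------------------------
        abs_tmax = None
        if route == ROUTE_EXTRAVASCULAR:
            ref = prof_first if not prof_first.is_empty else prof_mixed
            abs_tmax = ref.tmax_tad if not ref.is_empty else None

        sp = single_point_estimate(
            self.obs, self.doses, t_half, absorption_tmax=abs_tmax, trim=cfg.trim
        )

        nca_est = None
        if fit is not None:
            if multiple and not prof_multi.is_empty:
                nca_est = nca_onecpt(
                    prof_multi, fit, route, multiple=True, tau=modal_tau(self.doses)
                )
            else:
                prof = prof_first if not prof_first.is_empty else prof_mixed
                nca_est = nca_onecpt(prof, fit, route, multiple=False)
            if route == ROUTE_EXTRAVASCULAR and nca_est is not None:
                wn_prof = prof_first if not prof_first.is_empty else prof_mixed
                nca_est.ka = wagner_nelson_ka(wn_prof, fit.lambda_z)
                if nca_est.ka is None:
                    nca_est.messages.append("Wagner-Nelson Ka unavailable")

        gr = None
        if fit is not None and not prof_first.is_empty:
            gr = graphical_estimate(prof_first, fit, route)

        estimates = {"single_point": sp, "nca": nca_est, "graphical": gr}
        for name, est in estimates.items():
            if est is None:
                warnings_out.append(f"{name}: unavailable (no terminal fit)")
            elif not est.complete:
                warnings_out.append(
                    f"{name}: incomplete ({'; '.join(est.messages) or 'missing CL/V'})"
                )

        selected, candidates = select_base_params(
            estimates, self.obs, self.doses, route, metric=cfg.metric
        )

        # ---- Part 2: sweeps -------------------------------------------------
        sweeps: dict = {}
        c_max = float(self.obs["dv"].max())
        ka_sel = selected.params.get("ka")
        sweep_kw = dict(metric=cfg.metric, rtol=cfg.ode_rtol, atol=cfg.ode_atol)
        for model in models:
            if model == "1cmpt":
                continue
            try:
                if model == "mm":
                    mm_kw = {}
                    if cfg.sweep_km_ratios:
                        mm_kw["km_ratios"] = tuple(cfg.sweep_km_ratios)
                    if cfg.sweep_c_fractions:
                        mm_kw["c_fractions"] = tuple(cfg.sweep_c_fractions)
                    grid = build_mm_grid(
                        selected.params["cl"], c_max, selected.params["v"],
                        ka=ka_sel, route=route, **mm_kw,
                    )
                elif model in ("2cmpt", "3cmpt"):
                    # two Vc candidates: the selected Part-1 V and, when it
                    # differs, the single-point extended-phase Vc
                    v_cands = [selected.params["v"]]
                    if sp.vc is not None:
                        v_cands.append(sp.vc)
                    cpt_kw = {}
                    if cfg.sweep_vp_ratios:
                        cpt_kw["vp_ratios"] = tuple(cfg.sweep_vp_ratios)
                    if cfg.sweep_q_folds:
                        cpt_kw["q_folds"] = tuple(cfg.sweep_q_folds)
                    grid = build_cpt_grid(
                        selected.params["cl"], v_cands,
                        n_compartments=2 if model == "2cmpt" else 3,
                        ka=ka_sel, route=route, **cpt_kw,
                    )
                else:
                    warnings_out.append(f"unknown model {model!r} skipped")
                    continue
                winner, table = run_sweep(grid, self.obs, self.doses, **sweep_kw)
                sweeps[model] = {
                    "values": winner.params.values,
                    "sources": winner.params.sources,
                    "rrmse_pct": winner.rrmse_pct,
                    "grid_size": len(grid),
                }
            except Exception as exc:  # sweep failures degrade, never abort
                sweeps[model] = {"error": str(exc)}
                warnings_out.append(f"sweep {model}: {exc}")

        # ---- Part 3: error model -------------------------------------------
        struct_names = list(selected.params.values)
        err = initialize_error(
            self.obs, struct_names,
            n_terminal_points=cfg.error_n_terminal_points,
            cv_fallback=cfg.error_cv_fallback,
            omega2_override=None if cfg.omega2 == 0.1
            else {k: cfg.omega2 for k in struct_names},
        )
        if err.source == "fallback":
            warnings_out.append(
                "RUV regression had insufficient data; fixed-fraction fallback used"
            )

        report = InitReport(
            selected={
                "values": selected.params.values,
                "sources": selected.params.sources,
                "rrmse_pct": selected.rrmse_pct,
                "n_obs": selected.n_obs,
                "method": selected.method,
            },
            per_method={
                name: (
                    {"cl": est.cl, "v": est.v, "ka": est.ka,
                     "v_source": est.v_source, "n_used": est.n_used,
                     "messages": est.messages}
                    if est is not None else None
                )
                for name, est in estimates.items()
            },
            sweeps=sweeps,
            error_init={
                "sigma_add": err.sigma_add, "sigma_prop": err.sigma_prop,
                "omega2": err.omega2, "source": err.source,
                "n_subjects_used": err.n_subjects_used,
            },
            warnings=warnings_out,
            provenance={
                "version": __version__, "route": route,
                "multiple_dose": multiple, "n_subjects": int(self.obs["id"].nunique()),
                "n_observations": int(len(self.obs)),
                "metric": cfg.metric, "n_bins": cfg.n_bins,
            },
        )
        return PKInitResults(self, report, fit, candidates, err)


class PKInitResults:
    """Fitted initial-estimates results.

    Attributes
    ----------
    report : InitReport
    terminal_fit : TerminalFit or None
    candidates : list of ScoredCandidate
        Every Part-1 candidate with its rRMSE.
    error_init : ErrorInit
    """

    def __init__(self, model, report, terminal_fit, candidates, error_init):
        self.model = model
        self.report = report
        self.terminal_fit = terminal_fit
        self.candidates = candidates
        self.error_init = error_init

    @property
    def params(self) -> dict:
        return dict(self.report.selected["values"])

    @property
    def sources(self) -> dict:
        return dict(self.report.selected["sources"])

    @property
    def rrmse_pct(self) -> float:
        return self.report.selected["rrmse_pct"]

    @property
    def t_half(self) -> float | None:
        return self.terminal_fit.t_half if self.terminal_fit else None

    def summary(self) -> str:
        """Human-readable summary table of the recommended estimates."""
        rep = self.report
        lines = [
            "PK initial estimates",
            "=" * 64,
            f"route: {rep.provenance['route']}   subjects: "
            f"{rep.provenance['n_subjects']}   observations: "
            f"{rep.provenance['n_observations']}",
            f"selected method: {rep.selected['method']}   "
            f"rRMSE: {rep.selected['rrmse_pct']:.3g}%",
            "-" * 64,
            f"{'parameter':<12}{'value':>14}    source",
        ]
        for k, v in rep.selected["values"].items():
            lines.append(f"{k:<12}{v:>14.5g}    {rep.selected['sources'][k]}")
        if self.terminal_fit:
            lines.append(
                f"{'t_half':<12}{self.terminal_fit.t_half:>14.5g}    terminal fit"
            )
        for model, res in rep.sweeps.items():
            if "values" in res:
                vals = ", ".join(f"{k}={v:.4g}" for k, v in res["values"].items())
                lines.append(f"[{model} sweep] {vals} (rRMSE {res['rrmse_pct']:.3g}%)")
            else:
                lines.append(f"[{model} sweep] failed: {res.get('error')}")
        e = rep.error_init
        lines.append(
            f"sigma_add={e['sigma_add']:.4g}  sigma_prop={e['sigma_prop']:.4g}"
            f"  ({e['source']});  omega^2 defaults: "
            + ", ".join(f"{k}={v:g}" for k, v in e["omega2"].items())
        )
        if rep.warnings:
            lines.append("-" * 64)
            lines.extend(f"warning: {w}" for w in rep.warnings)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Plot the pooled profile and the selected model's prediction."""
        import matplotlib.pyplot as plt

        from .selection import individual_schedules
        from .simulate import StructuralParams, simulate_onecpt_closed

        if ax is None:
            _, ax = plt.subplots()
        prof = pool_observations(self.model.obs, "mixed", self.model.config.n_bins)
        ax.plot(prof.tad, prof.conc, "o", label="pooled (per unit dose)")
        p = self.params
        sp = StructuralParams(cl=p["cl"], vc=p["v"], ka=p.get("ka"))
        t = np.linspace(0, float(prof.tad.max()), 200)
        from .simulate import Dose
        pred = simulate_onecpt_closed(
            sp, [Dose(0.0, 1.0)], t, route=self.model.route
        )
        ax.plot(t, pred, "-", label="selected 1-cpt model")
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel("dose-normalized concentration")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def to_json(self, path=None, indent: int = 2):
        return self.report.to_json(path, indent)


def run_pipeline(dataset, config: PipelineConfig | None = None) -> InitReport:
    """Parse a dataset, run all three pipeline parts, return the report."""
    model = PKInitModel(dataset, config=config)
    return model.fit().report
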