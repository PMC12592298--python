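"""Dataset parsing, dose annotation and naive pooled binning.

Input datasets follow the NONMEM/nlmixr2 column convention: one row per
event, with ``EVID=1`` dose records carrying ``AMT`` (and optionally
``RATE``, ``ADDL``, ``II``) and ``EVID=0`` observation records carrying the
measured concentration in ``DV``.  Everything downstream works on two
tables produced by :func:`annotate_doses`: a dose-event table and an
observation table enriched with time after dose (TAD), route, dosing
occasion and a steady-state flag.

Pooling follows the naive pooled approach: concentrations are normalized
by their governing dose amount, all subjects are treated as one profile,
and unique TADs are divided into quantile bins whose per-bin medians form
a :class:`PooledProfile`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PKRecord",
    "DoseEvent",
    "AnnotatedObservation",
    "PooledProfile",
    "ParseError",
    "parse_dataset",
    "annotate_doses",
    "flag_steady_state",
    "pool_observations",
    "write_annotated",
]

ROUTE_BOLUS = "bolus"
ROUTE_INFUSION = "infusion"
ROUTE_EXTRAVASCULAR = "extravascular"

#: columns recognised in input files (case-insensitive)
_KNOWN_COLUMNS = {
    "id", "time", "amt", "rate", "evid", "cmt", "dv", "addl", "ii", "dur",
    "route", "mdv",
}


class ParseError(ValueError):
    """Raised when a dataset cannot be interpreted."""


@dataclass(frozen=True)
class PKRecord:
    """One event row of a PK dataset (dose or observation)."""

    id: object
    time: float
    amt: float = 0.0
    rate: float = 0.0
    evid: int = 0
    cmt: int = 1
    dv: float | None = None
    addl: int = 0
    ii: float = 0.0


@dataclass(frozen=True)
class DoseEvent:
    """A single administered dose with its route and interval context."""

    id: object
    time: float
    amount: float
    rate: float
    t_inf: float
    route: str
    tau: float | None  # interval to the next dose; None for the last dose
    number: int  # ordinal of this dose within the subject (1-based)


@dataclass(frozen=True)
class AnnotatedObservation:
    """A concentration record enriched with dose context."""

    id: object
    time: float
    dv: float
    tad: float
    dose_amount: float
    dose_number: int
    route: str
    occasion: str  # first_dose | multi_dose
    at_steady_state: bool
    tau: float


@dataclass
class PooledProfile:
    """Quantile-binned, dose-normalized median concentration-time profile."""

    group: str  # first_dose | multi_dose | mixed
    tad: np.ndarray = field(default_factory=lambda: np.empty(0))
    conc: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_points: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_bins_requested: int = 10

    def __len__(self) -> int:
        return len(self.tad)

    @property
    def is_empty(self) -> bool:
        return len(self.tad) == 0

    @property
    def peak_index(self) -> int:
        """Index of the maximum-concentration bin."""
        return int(np.argmax(self.conc))

    @property
    def tmax_tad(self) -> float:
        return float(self.tad[self.peak_index])


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return pd.read_csv(source, sep=None, engine="python")
    if isinstance(source, str):
        return pd.read_csv(io.StringIO(source), sep=None, engine="python")
    return pd.read_csv(source, sep=None, engine="python")


def parse_dataset(source) -> pd.DataFrame:
    """Parse a NONMEM-convention delimited dataset into an event table.

    Parameters
    ----------
    source : path, file-like, str or DataFrame
        Comma- or tab-delimited text with case-insensitive headers
        containing at least ID, TIME, DV and one of AMT/EVID.

    Returns
    -------
    DataFrame
        Columns ``id, time, amt, rate, evid, cmt, dv, addl, ii`` ordered
        by ``(id, time)`` with ADDL/II dose series expanded into explicit
        dose rows.  Dose rows have ``dv`` = NaN.
    """
    df = _read_table(source)
    df.columns = [str(c).strip().lower() for c in df.columns]
    df = df[[c for c in df.columns if c in _KNOWN_COLUMNS]]

    for col in ("id", "time"):
        if col not in df.columns:
            raise ParseError(f"missing mandatory column: {col.upper()}")
    if "dv" not in df.columns:
        raise ParseError("missing mandatory column: DV")
    if "amt" not in df.columns and "evid" not in df.columns:
        raise ParseError("missing mandatory column: AMT or EVID")

    for col, default in (
        ("amt", 0.0), ("rate", 0.0), ("cmt", 1), ("addl", 0), ("ii", 0.0),
        ("dur", 0.0),
    ):
        if col not in df.columns:
            df[col] = default
    df[["amt", "rate", "ii", "dur"]] = (
        df[["amt", "rate", "ii", "dur"]].apply(pd.to_numeric, errors="coerce").fillna(0.0)
    )
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["dv"] = pd.to_numeric(df["dv"], errors="coerce")
    df["addl"] = pd.to_numeric(df["addl"], errors="coerce").fillna(0).astype(int)
    df["cmt"] = pd.to_numeric(df["cmt"], errors="coerce").fillna(1).astype(int)
    if "evid" not in df.columns:
        df["evid"] = np.where(df["amt"] > 0, 1, 0)
    df["evid"] = pd.to_numeric(df["evid"], errors="coerce").fillna(0).astype(int)

    if (df["time"] < 0).any():
        bad = df.loc[df["time"] < 0].index[0]
        raise ParseError(f"negative TIME at row {bad}")

    # expand ADDL/II into explicit dose rows (NONMEM convention: ADDL extra
    # doses at intervals of II after the recorded dose)
    expanded = []
    for _, row in df.iterrows():
        expanded.append(row)
        if row["evid"] in (1, 4) and row["addl"] > 0 and row["ii"] > 0:
            for k in range(1, int(row["addl"]) + 1):
                extra = row.copy()
                extra["time"] = row["time"] + k * row["ii"]
                extra["addl"] = 0
                expanded.append(extra)
    out = pd.DataFrame(expanded).reset_index(drop=True)
    out["addl"] = 0
    out = out.sort_values(
        ["id", "time", "evid"], ascending=[True, True, False], kind="stable"
    ).reset_index(drop=True)
    cols = ["id", "time", "amt", "rate", "evid", "cmt", "dv", "addl", "ii", "dur"]
    if "route" in out.columns:
        cols.append("route")
    return out[cols]


def _detect_route(dose_row, obs_cmt: int, route_override: str | None) -> str:
    if route_override:
        return route_override
    if "route" in dose_row.index and isinstance(dose_row["route"], str) and dose_row["route"]:
        r = dose_row["route"].strip().lower()
        if r in {"iv", "bolus"}:
            return ROUTE_INFUSION if dose_row["rate"] > 0 else ROUTE_BOLUS
        if r in {"infusion"}:
            return ROUTE_INFUSION
        if r in {"oral", "po", "ev", "extravascular", "depot"}:
            return ROUTE_EXTRAVASCULAR
    if dose_row["rate"] > 0 or dose_row.get("dur", 0) > 0:
        return ROUTE_INFUSION
    if dose_row["cmt"] != obs_cmt:
        return ROUTE_EXTRAVASCULAR
    return ROUTE_BOLUS


def _regular_suffix(times: np.ndarray, amounts: np.ndarray) -> int:
    """Length of the longest trailing run of doses that is 'regular'.

    Regular means every inter-dose interval and every dose amount in the run
    lies within +/-25% of the run's respective median.
    """
    n = len(times)
    for start in range(n):
        t = times[start:]
        a = amounts[start:]
        if len(t) < 2:
            return len(t)
        iv = np.diff(t)
        med_iv = np.median(iv)
        med_a = np.median(a)
        if med_iv <= 0:
            continue
        ok_iv = np.all(np.abs(iv - med_iv) <= 0.25 * med_iv)
        ok_a = np.all(np.abs(a - med_a) <= 0.25 * med_a) if med_a > 0 else True
        if ok_iv and ok_a:
            return len(t)
    return 1


def annotate_doses(
    records: pd.DataFrame,
    t_half: float | None = None,
    route: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign dose context to every observation.

    Returns ``(doses, observations)`` DataFrames.  Doses carry
    ``id, time, amount, rate, t_inf, route, tau, number``; observations carry
    ``id, time, dv, tad, dose_amount, dose_number, route, occasion,
    at_steady_state, tau``.

    Subjects with no dose records are dropped with a warning; observations
    recorded before any dose are excluded from TAD-based analyses.  The
    steady-state flag uses the regularity rule (intervals and amounts within
    +/-25% of the median) combined with coverage of >=5 doses, or >=5
    half-lives when ``t_half`` is supplied; it can be recomputed lazily with
    :func:`flag_steady_state` once a half-life estimate exists.
    """
    doses_out: list[dict] = []
    obs_out: list[dict] = []
    obs_rows = records[records["evid"] == 0]
    obs_cmt = int(obs_rows["cmt"].mode().iloc[0]) if len(obs_rows) else 1

    for sid, sub in records.groupby("id", sort=True):
        dose_rows = sub[(sub["evid"].isin([1, 4])) & (sub["amt"] > 0)]
        o_rows = sub[sub["evid"] == 0]
        if dose_rows.empty:
            if not o_rows.empty:
                warnings.warn(f"subject {sid!r} has no dose records; dropped")
            continue
        dt = dose_rows["time"].to_numpy(float)
        da = dose_rows["amt"].to_numpy(float)
        dr = dose_rows["rate"].to_numpy(float)
        ddur = dose_rows["dur"].to_numpy(float) if "dur" in dose_rows else np.zeros_like(dt)
        routes = [
            _detect_route(dose_rows.iloc[k], obs_cmt, route)
            for k in range(len(dose_rows))
        ]
        taus = [float(dt[k + 1] - dt[k]) if k + 1 < len(dt) else None
                for k in range(len(dt))]
        median_tau = float(np.median(np.diff(dt))) if len(dt) > 1 else None
        for k in range(len(dt)):
            t_inf = da[k] / dr[k] if dr[k] > 0 else (ddur[k] if ddur[k] > 0 else 0.0)
            doses_out.append(dict(
                id=sid, time=dt[k], amount=da[k], rate=dr[k], t_inf=t_inf,
                route=routes[k], tau=taus[k], number=k + 1,
            ))
        n_predose = 0
        for _, orow in o_rows.iterrows():
            t = float(orow["time"])
            k = int(np.searchsorted(dt, t, side="right")) - 1
            if k < 0:
                n_predose += 1
                continue
            tau_k = taus[k] if taus[k] is not None else (
                float(dose_rows.iloc[k]["ii"]) if dose_rows.iloc[k]["ii"] > 0
                else median_tau
            )
            obs_out.append(dict(
                id=sid, time=t, dv=orow["dv"], tad=t - dt[k],
                dose_amount=da[k], dose_number=k + 1, route=routes[k],
                occasion="first_dose" if k == 0 else "multi_dose",
                at_steady_state=False,
                tau=tau_k if tau_k is not None else np.nan,
            ))
        if n_predose:
            warnings.warn(
                f"subject {sid!r}: {n_predose} observation(s) before the first "
                "dose excluded from TAD-based analyses"
            )

    doses = pd.DataFrame(doses_out)
    obs = pd.DataFrame(obs_out)
    if obs.empty or doses.empty:
        return doses, obs
    return doses, flag_steady_state(obs, doses, t_half)


def flag_steady_state(
    obs: pd.DataFrame, doses: pd.DataFrame, t_half: float | None = None
) -> pd.DataFrame:
    """(Re)compute the ``at_steady_state`` flag on an observation table.

    Steady state requires a regular preceding regimen (intervals and amounts
    within +/-25% of the median) covering at least five doses or, when
    ``t_half`` is known, at least five half-lives.
    """
    obs = obs.copy()
    flags = np.zeros(len(obs), dtype=bool)
    for sid, sub in doses.groupby("id"):
        dt = sub["time"].to_numpy(float)
        da = sub["amount"].to_numpy(float)
        mask = obs["id"] == sid
        for i in np.flatnonzero(mask.to_numpy()):
            k = int(obs.iloc[i]["dose_number"])
            run = _regular_suffix(dt[:k], da[:k])
            if run < 2:
                continue
            if run >= 5:
                flags[i] = True
            elif t_half is not None and t_half > 0:
                span = dt[k - 1] - dt[k - run]
                if span >= 5.0 * t_half:
                    flags[i] = True
    obs["at_steady_state"] = flags
    return obs


def pool_observations(
    obs: pd.DataFrame, group: str = "mixed", n_bins: int = 10
) -> PooledProfile:
    """Build a naive pooled, quantile-binned, dose-normalized profile.

    Concentrations are normalized by the governing dose amount before
    pooling.  Unique TADs are split into at most ``n_bins`` quantile groups
    (type-7 quantile edges; a TAD tied with an edge goes to the lower bin)
    and each bin is represented by the median TAD and the median normalized
    concentration of its points.
    """
    if group == "first_dose":
        sel = obs[obs["occasion"] == "first_dose"] if len(obs) else obs
    elif group == "multi_dose":
        sel = obs[obs["occasion"] == "multi_dose"] if len(obs) else obs
    elif group == "mixed":
        sel = obs
    else:
        raise ValueError(f"unknown pooling group: {group!r}")
    sel = sel.dropna(subset=["dv", "tad"]) if len(sel) else sel
    if len(sel) == 0:
        return PooledProfile(group=group, n_bins_requested=n_bins)

    tad = sel["tad"].to_numpy(float)
    norm = sel["dv"].to_numpy(float) / sel["dose_amount"].to_numpy(float)
    uniq = np.unique(tad)
    k = min(n_bins, len(uniq))
    edges = np.quantile(uniq, np.linspace(0, 1, k + 1), method="linear")
    # side='left' on interior edges sends a TAD equal to an edge to the lower bin
    idx = np.searchsorted(edges[1:-1], tad, side="left")

    b_tad, b_conc, b_n = [], [], []
    for b in range(k):
        m = idx == b
        if not m.any():
            continue
        b_tad.append(float(np.median(tad[m])))
        b_conc.append(float(np.median(norm[m])))
        b_n.append(int(m.sum()))
    order = np.argsort(b_tad, kind="stable")
    return PooledProfile(
        group=group,
        tad=np.asarray(b_tad)[order],
        conc=np.asarray(b_conc)[order],
        n_points=np.asarray(b_n, dtype=int)[order],
        n_bins_requested=n_bins,
    )


def write_annotated(obs: pd.DataFrame, path) -> None:
    """Write the annotated observation table as delimited text."""
    out = obs.rename(columns={
        "tad": "TAD", "route": "ROUTE", "occasion": "OCCASION",
        "at_steady_state": "SS_FLAG",
    })
    out.to_csv(path, index=False)
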