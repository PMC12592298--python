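"""Terminal elimination phase regression (lambda_z / half-life).

The terminal elimination rate constant is the negative slope of the
log-linear regression of the pooled concentration-time profile's terminal
portion.  A best-fit strategy is used: all trailing windows of at least
``min_points`` post-peak bins are fitted and the window maximizing the
adjusted R^2 (subject to a negative slope) is returned, ties going to the
window with more points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import PooledProfile, ROUTE_EXTRAVASCULAR

__all__ = ["TerminalFit", "TerminalPhaseError", "fit_lambda_z"]

LN2 = float(np.log(2.0))


class TerminalPhaseError(RuntimeError):
    """Terminal phase not estimable (no negative-slope window)."""


@dataclass
class TerminalFit:
    """Log-linear terminal-phase regression result.

    ``lambda_z`` is the terminal elimination rate constant (1/h, equal to
    Ke under a one-compartment model), ``beta0`` the log-concentration
    intercept at TAD 0, ``t_half = ln(2)/lambda_z``.
    """

    lambda_z: float
    beta0: float
    n_points: int
    adj_r2: float
    point_indices: np.ndarray
    #: True when (extravascular) sparsity forced the absorption-peak bin into
    #: the regression window; such a lambda_z is a rough half-life, not a
    #: clean terminal slope, and AUC-extrapolating methods refuse it
    includes_peak: bool = False
    windows: list = field(default_factory=list, repr=False)

    @property
    def t_half(self) -> float:
        return LN2 / self.lambda_z

    @property
    def ke(self) -> float:
        return self.lambda_z


def _adj_r2(r2: float, n: int) -> float:
    if n <= 2:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_lambda_z(
    profile: PooledProfile,
    min_points: int = 3,
    route: str | None = None,
) -> TerminalFit:
    """Best-fit log-linear regression of the terminal phase.

    Candidate windows are the trailing k bins (k = ``min_points`` ... all
    post-peak bins) of the log-positive portion of the profile.  For
    extravascular routes the peak bin itself is excluded (its neighbourhood
    is contaminated by absorption).  The window with the highest adjusted
    R^2 among negative-slope fits wins; near-ties (within 1e-9) prefer
    more points for a stabler extrapolation.

    Raises
    ------
    TerminalPhaseError
        If no candidate window has a negative slope.
    """
    if profile.is_empty:
        raise TerminalPhaseError("empty profile")
    pos = profile.conc > 0
    tad = profile.tad[pos]
    conc = profile.conc[pos]
    idx_all = np.flatnonzero(pos)
    if len(tad) == 0:
        raise TerminalPhaseError("no positive concentrations")
    peak = int(np.argmax(conc))
    start = peak
    if route == ROUTE_EXTRAVASCULAR and len(conc) - (peak + 1) >= min_points:
        # drop the absorption-contaminated peak bin when enough bins remain
        start = peak + 1
    t_post = tad[start:]
    c_post = conc[start:]
    idx_post = idx_all[start:]
    n_post = len(t_post)
    if n_post < min_points:
        raise TerminalPhaseError(
            f"only {n_post} post-peak bins; need >= {min_points}"
        )

    best = None
    windows = []
    for k in range(min_points, n_post + 1):
        t = t_post[-k:]
        y = np.log(c_post[-k:])
        res = stats.linregress(t, y)
        a2 = _adj_r2(res.rvalue ** 2, k)
        windows.append((k, res.slope, res.intercept, a2))
        if res.slope >= 0:
            continue
        if (
            best is None
            or a2 > best[3] + 1e-9
            or (abs(a2 - best[3]) <= 1e-9 and k > best[0])
        ):
            best = (k, res.slope, res.intercept, a2)
    if best is None:
        raise TerminalPhaseError("terminal phase not estimable")
    k, slope, intercept, a2 = best
    win_idx = idx_post[-k:]
    return TerminalFit(
        lambda_z=-float(slope),
        beta0=float(intercept),
        n_points=k,
        adj_r2=float(a2),
        point_indices=win_idx,
        includes_peak=(
            route == ROUTE_EXTRAVASCULAR and idx_all[peak] in win_idx
        ),
        windows=windows,
    )
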