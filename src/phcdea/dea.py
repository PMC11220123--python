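"""Input-oriented radial DEA: CCR (CRS) and BCC (VRS) envelopment models.

For DMU ``o`` with inputs ``x_o`` and outputs ``y_o`` evaluated against a
technology spanned by peer columns (X, Y), the input-oriented envelopment
program is

    min theta  s.t.  X lam <= theta * x_o,   Y lam >= y_o,   lam >= 0,

with the convexity constraint ``sum(lam) = 1`` added under variable returns
to scale (BCC).  Technical efficiency TE is the CRS score, pure technical
efficiency PTE the VRS score, and scale efficiency SE = TE / PTE, so that
TE = PTE * SE.  A second LP maximizes total slack at the fixed radial score
to resolve non-unique phase-1 solutions; the slack table it yields is the
dependent variable of the stage-2 SFA regressions.

All programs are solved with HiGHS via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

#: score within EFF_TOL of 1 is reported as exactly efficient
EFF_TOL = 1e-6
#: tolerance band for the CRS lambda-sum RTS classification
RTS_TOL = 1e-6


class DEAError(RuntimeError):
    """An envelopment LP failed where feasibility is guaranteed."""


@dataclass
class EfficiencyRecord:
    """Radial scores and phase-2 detail for one DMU-year."""

    dmu: object
    year: int
    te: float
    pte: float
    se: float
    rts: str
    lambdas: np.ndarray  # CRS reference weights over peers
    input_slacks: np.ndarray
    output_slacks: np.ndarray


def _validate_year(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("inputs and outputs must be 2-D with matching DMU rows")
    if np.any(X <= 0) or np.any(Y <= 0):
        raise ValueError("DEA requires strictly positive inputs and outputs")
    return X, Y


def solve_radial(X, Y, target: int, frontier: str = "crs",
                 peers: tuple[np.ndarray, np.ndarray] | None = None):
    """Radial input contraction factor of one DMU against a technology.

    Parameters
    ----------
    X, Y : (n, m) and (n, s) arrays
        The evaluated sample; row ``target`` is the DMU under evaluation.
    frontier : {"crs", "vrs"}
    peers : optional (Xf, Yf)
        Evaluate against a different technology (used for cross-period
        Malmquist distances).  Defaults to (X, Y) itself, in which case the
        optimum lies in (0, 1].

    Returns
    -------
    theta : float
    lambdas : ndarray of reference weights over the peer rows, or None if
        the VRS cross-period program is infeasible.
    """
    X, Y = _validate_year(X, Y)
    if not 0 <= target < X.shape[0]:
        raise ValueError(f"target index {target} out of range")
    x0, y0 = X[target], Y[target]
    Xf, Yf = (X, Y) if peers is None else _validate_year(*peers)
    n, m = Xf.shape
    s = Yf.shape[1]
    if frontier not in ("crs", "vrs"):
        raise ValueError(f"unknown frontier {frontier!r}")

    # variables: [theta, lam_1..lam_n]
    c = np.r_[1.0, np.zeros(n)]
    A_ub = np.zeros((m + s, n + 1))
    A_ub[:m, 0] = -x0                       # Xf lam - theta x0 <= 0
    A_ub[:m, 1:] = Xf.T
    A_ub[m:, 1:] = -Yf.T                    # -Yf lam <= -y0
    b_ub = np.r_[np.zeros(m), -y0]
    A_eq = b_eq = None
    if frontier == "vrs":
        A_eq = np.r_[0.0, np.ones(n)][None, :]
        b_eq = [1.0]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(None, None)] + [(0, None)] * n, method="highs")
    if not res.success:
        if frontier == "vrs" and peers is not None:
            return np.nan, None            # known cross-period pathology
        raise DEAError(f"envelopment LP failed: {res.message}")
    theta = float(res.x[0])
    lam = np.clip(res.x[1:], 0.0, None)
    if peers is None:
        theta = min(theta, 1.0)
        if theta >= 1.0 - EFF_TOL:
            theta = 1.0
    return theta, lam


def max_slacks(X, Y, target: int, theta: float, frontier: str = "crs"):
    """Phase-2 LP: maximize total slack at the fixed radial score.

    Solves ``max sum(s_in) + sum(s_out)`` subject to
    ``X lam + s_in = theta x_o`` and ``Y lam - s_out = y_o``.
    """
    X, Y = _validate_year(X, Y)
    x0, y0 = X[target], Y[target]
    n, m = X.shape
    s = Y.shape[1]
    # variables: [lam (n), s_in (m), s_out (s)]
    c = np.r_[np.zeros(n), -np.ones(m + s)]
    A_eq = np.zeros((m + s, n + m + s))
    A_eq[:m, :n] = X.T
    A_eq[:m, n:n + m] = np.eye(m)
    A_eq[m:, :n] = Y.T
    A_eq[m:, n + m:] = -np.eye(s)
    b_eq = np.r_[theta * x0, y0]
    if frontier == "vrs":
        A_eq = np.vstack([A_eq, np.r_[np.ones(n), np.zeros(m + s)]])
        b_eq = np.r_[b_eq, 1.0]
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise DEAError(f"slack LP failed: {res.message}")
    sol = np.clip(res.x, 0.0, None)
    return sol[n:n + m], sol[n + m:]


def classify_rts(lambdas_crs: np.ndarray, tol: float = RTS_TOL) -> str:
    """Returns-to-scale class from the CRS reference-weight sum.

    ``sum(lam) < 1`` means the DMU is benchmarked against a scaled-down
    frontier point (increasing returns available); ``> 1`` the reverse.
    """
    lam = np.asarray(lambdas_crs, dtype=float)
    if np.any(lam < -tol):
        raise ValueError("negative reference weights")
    s = float(lam.sum())
    if s < 1.0 - tol:
        return "irs"
    if s > 1.0 + tol:
        return "drs"
    return "crs"


def run_dea_by_year(panel, slack_definition: str = "radial_plus_slack"):
    """Contemporaneous-frontier DEA over every year of a panel.

    Each year is its own technology: every DMU is scored under CRS (TE)
    and VRS (PTE) against that year's sample, SE = TE/PTE, and RTS is
    classified from the CRS weight sum.  The slack table reports, per
    DMU-year-input, the total input excess used as the stage-2 dependent
    variable: by default the radial contraction shortfall ``(1-theta)*x``
    plus the VRS phase-2 slack; ``slack_only`` keeps just the phase-2 part.

    Returns
    -------
    records : list of EfficiencyRecord
    slack_table : DataFrame with columns dmu, year, input, slack
    """
    if slack_definition not in ("radial_plus_slack", "slack_only"):
        raise ValueError(f"unknown slack definition {slack_definition!r}")
    records = []
    slack_rows = []
    dmus = panel.dmu_ids
    for year in panel.years:
        X = panel.inputs_matrix(year)
        Y = panel.outputs_matrix(year)
        for i, dmu in enumerate(dmus):
            te, lam_crs = solve_radial(X, Y, i, "crs")
            pte, _ = solve_radial(X, Y, i, "vrs")
            s_in, s_out = max_slacks(X, Y, i, pte, "vrs")
            records.append(EfficiencyRecord(
                dmu=dmu, year=int(year), te=te, pte=pte, se=te / pte,
                rts=classify_rts(lam_crs), lambdas=lam_crs,
                input_slacks=s_in, output_slacks=s_out))
            radial = (1.0 - pte) * X[i] if slack_definition == "radial_plus_slack" else 0.0
            total = radial + s_in
            for k, name in enumerate(panel.input_cols):
                slack_rows.append((dmu, int(year), name, float(total[k])))
    slack_table = pd.DataFrame(slack_rows, columns=["dmu", "year", "input", "slack"])
    return records, slack_table


def records_frame(records) -> pd.DataFrame:
    """Tidy score table from a list of :class:`EfficiencyRecord`."""
    return pd.DataFrame(
        [(r.dmu, r.year, r.te, r.pte, r.se, r.rts) for r in records],
        columns=["dmu", "year", "te", "pte", "se", "rts"])


def mean_scores(records, by_dmu: bool = False) -> pd.DataFrame:
    """Arithmetic mean TE/PTE/SE, per DMU (period-averaged) or overall.

    The overall mean is the mean over DMUs of per-DMU period averages —
    the convention of the published per-province summary tables.
    """
    df = records_frame(records) if not isinstance(records, pd.DataFrame) else records
    if df.empty:
        raise ValueError("no records")
    per_dmu = df.groupby("dmu", sort=False)[["te", "pte", "se"]].mean()
    if by_dmu:
        return per_dmu
    return per_dmu.mean().to_frame().T
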