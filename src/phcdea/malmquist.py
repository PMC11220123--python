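"""Malmquist total-factor-productivity index between adjacent years.

The geometric-mean (Fare-Grosskopf-Norris-Zhang) input-oriented index for
a DMU observed at (x^t, y^t) and (x^{t+1}, y^{t+1}) is built from four CRS
radial distances D^a(x^b, y^b) — period-a technology, period-b data — and
two VRS own-period distances:

    EFFCH  = D^{t+1}(x^{t+1}, y^{t+1}) / D^t(x^t, y^t)
    TECHCH = sqrt[ D^t(x^{t+1},y^{t+1}) / D^{t+1}(x^{t+1},y^{t+1})
                 * D^t(x^t,y^t)         / D^{t+1}(x^t,y^t) ]
    TFPCH  = EFFCH * TECHCH
    PECH   = VRS efficiency ratio;  SECH = EFFCH / PECH

so TFPCH = EFFCH x TECHCH = (PECH x SECH) x TECHCH by construction.
Cross-period distances may exceed one (the observation lies outside the
other period's frontier).  VRS cross-period programs can be infeasible;
the affected record is flagged and excluded from summaries rather than
silently replaced by a CRS fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dea import solve_radial

COMPONENTS = ("effch", "techch", "pech", "sech", "tfpch")


@dataclass
class MalmquistRecord:
    dmu: object
    period_pair: tuple
    d_t_t: float        # D^t(x^t, y^t), CRS
    d_t_t1: float       # D^t(x^{t+1}, y^{t+1}), CRS
    d_t1_t: float       # D^{t+1}(x^t, y^t), CRS
    d_t1_t1: float      # D^{t+1}(x^{t+1}, y^{t+1}), CRS
    v_t: float          # VRS own-period, year t
    v_t1: float         # VRS own-period, year t+1
    effch: float
    techch: float
    pech: float
    sech: float
    tfpch: float
    feasible: bool = True


def cross_distance(point_inputs, point_outputs, frontier_inputs, frontier_outputs,
                   frontier: str = "crs") -> float:
    """Radial input distance of one observation to a given period's frontier.

    Returns the input-oriented score of ``point`` against the technology
    spanned by the frontier sample.  Own-period evaluations lie in (0, 1];
    cross-period ones may exceed 1.  NaN signals a VRS infeasibility.
    """
    x0 = np.atleast_2d(np.asarray(point_inputs, dtype=float))
    y0 = np.atleast_2d(np.asarray(point_outputs, dtype=float))
    theta, _ = solve_radial(x0, y0, 0, frontier,
                            peers=(np.asarray(frontier_inputs, dtype=float),
                                   np.asarray(frontier_outputs, dtype=float)))
    return theta


def malmquist_components(X_t, Y_t, X_t1, Y_t1, dmu_index: int, dmu=None,
                         period_pair=(0, 1)) -> MalmquistRecord:
    """All five Malmquist components for one DMU between two periods."""
    i = dmu_index
    d_t_t = cross_distance(X_t[i], Y_t[i], X_t, Y_t, "crs")
    d_t1_t1 = cross_distance(X_t1[i], Y_t1[i], X_t1, Y_t1, "crs")
    d_t_t1 = cross_distance(X_t1[i], Y_t1[i], X_t, Y_t, "crs")
    d_t1_t = cross_distance(X_t[i], Y_t[i], X_t1, Y_t1, "crs")
    v_t = cross_distance(X_t[i], Y_t[i], X_t, Y_t, "vrs")
    v_t1 = cross_distance(X_t1[i], Y_t1[i], X_t1, Y_t1, "vrs")
    feasible = all(np.isfinite([d_t_t, d_t1_t1, d_t_t1, d_t1_t, v_t, v_t1]))
    if feasible:
        effch = d_t1_t1 / d_t_t
        techch = float(np.sqrt((d_t_t1 / d_t1_t1) * (d_t_t / d_t1_t)))
        pech = v_t1 / v_t
        sech = effch / pech
        tfpch = effch * techch
    else:
        effch = techch = pech = sech = tfpch = np.nan
    return MalmquistRecord(dmu=dmu if dmu is not None else i,
                           period_pair=tuple(period_pair),
                           d_t_t=d_t_t, d_t_t1=d_t_t1, d_t1_t=d_t1_t, d_t1_t1=d_t1_t1,
                           v_t=v_t, v_t1=v_t1, effch=effch, techch=techch,
                           pech=pech, sech=sech, tfpch=tfpch, feasible=feasible)


def run_malmquist(panel) -> list[MalmquistRecord]:
    """Adjacent-year Malmquist records for every DMU of a panel."""
    records = []
    years = panel.years
    dmus = panel.dmu_ids
    for t, t1 in zip(years[:-1], years[1:]):
        X_t, Y_t = panel.inputs_matrix(t), panel.outputs_matrix(t)
        X_t1, Y_t1 = panel.inputs_matrix(t1), panel.outputs_matrix(t1)
        for i, dmu in enumerate(dmus):
            records.append(malmquist_components(
                X_t, Y_t, X_t1, Y_t1, i, dmu=dmu, period_pair=(int(t), int(t1))))
    return records


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        {"dmu": r.dmu, "year_pair": f"{r.period_pair[0]}-{r.period_pair[1]}",
         **{c: getattr(r, c) for c in COMPONENTS}, "feasible": r.feasible}
        for r in records])


def summarize_malmquist(records, by: str = "overall") -> pd.DataFrame:
    """Geometric-mean component summary; infeasible records are dropped.

    The multiplicative identities survive geometric averaging, so the
    summary rows satisfy TFPCH = EFFCH x TECHCH and EFFCH = PECH x SECH
    exactly as well.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    df = df[df.get("feasible", True) == True] if "feasible" in df else df  # noqa: E712
    if df.empty:
        raise ValueError("no feasible records to summarize")
    if (df[list(COMPONENTS)] <= 0).any().any():
        raise ValueError("nonpositive Malmquist component")
    logs = np.log(df[list(COMPONENTS)])
    if by == "overall":
        return np.exp(logs.mean()).to_frame().T
    key = {"year_pair": "year_pair", "dmu": "dmu"}[by]
    return np.exp(logs.groupby(df[key]).mean()).reset_index()
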