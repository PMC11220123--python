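"""Published benchmark tables for China's provincial PHC system, 2012-2020.

A published three-stage DEA study of China's 31 provincial primary-
healthcare systems reports per-province stage-1 and stage-3 efficiency
scores (TE/PTE/SE with returns-to-scale class and rank) and annual
Malmquist components, but not the underlying yearbook panel.  The printed
tables are packaged here as data so that every aggregate the study reports
— stage means, regional means, geometric-mean Malmquist components, and
the multiplicative identities — can be recomputed from them by this
package's own summary code.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .malmquist import COMPONENTS


def _load(name: str) -> pd.DataFrame:
    with resources.files("phcdea.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def provincial_efficiency() -> pd.DataFrame:
    """Per-province stage-1/stage-3 TE, PTE, SE, RTS, rank and region."""
    return _load("provincial_efficiency.csv")


def malmquist_annual() -> pd.DataFrame:
    """Adjacent-year Malmquist components (stage-3 inputs), 2012-2020."""
    return _load("malmquist_annual.csv")


def stage_means(round_to: int = 3) -> pd.DataFrame:
    """Arithmetic mean TE/PTE/SE per stage over the 31 provinces."""
    df = provincial_efficiency()
    out = {}
    for stage in ("stage1", "stage3"):
        out[stage] = {m: round(df[f"{stage}_{m}"].mean(), round_to)
                      for m in ("te", "pte", "se")}
    return pd.DataFrame(out).T


def regional_means(round_to: int = 3) -> pd.DataFrame:
    """Per-region arithmetic means, before (stage 1) and after (stage 3)."""
    df = provincial_efficiency()
    cols = [f"{s}_{m}" for s in ("stage1", "stage3") for m in ("te", "pte", "se")]
    return df.groupby("region")[cols].mean().round(round_to)


def malmquist_geomeans(round_to: int = 3) -> pd.Series:
    """Geometric mean of each printed annual Malmquist component."""
    df = malmquist_annual()
    return np.exp(np.log(df[list(COMPONENTS)]).mean()).round(round_to)


def identity_deviations() -> pd.DataFrame:
    """Printed-table identity audit: TE vs PTE*SE and TFPCH vs EFFCH*TECHCH.

    The printed values are rounded to 3 decimals, so products match the
    printed TE / TFPCH columns only to rounding error; this returns the
    per-row products for inspection.
    """
    eff = provincial_efficiency()
    mal = malmquist_annual()
    a = pd.DataFrame({
        "row": eff["province"],
        "identity": "te=pte*se (stage3)",
        "reported": eff["stage3_te"],
        "product": (eff["stage3_pte"] * eff["stage3_se"]).round(3)})
    b = pd.DataFrame({
        "row": mal["year_pair"],
        "identity": "tfpch=effch*techch",
        "reported": mal["tfpch"],
        "product": (mal["effch"] * mal["techch"]).round(3)})
    return pd.concat([a, b], ignore_index=True)
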