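"""Balanced DMU x year panel container and CSV round-trip.

The panel holds, for every decision-making unit (DMU, here a provincial
primary-healthcare system) and every year, three positive inputs
(institutions, personnel, beds), two positive outputs (consultations and
admissions, in units of ten thousand) and four environmental covariates
(GDP per capita, population density, urbanization rate, government health
expenditure).  Everything downstream — the DEA envelopment programs, the
SFA slack regressions, the Malmquist decomposition and the Moran
statistics — consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical long-format column order (dea_core External Interfaces)
INPUT_COLS = ("institutions", "personnel", "beds")
OUTPUT_COLS = ("consultations", "admissions")
ENV_COLS = ("gdp_pc", "pop_density", "urbanization", "gov_health_exp")
ID_COLS = ("dmu", "year", "region")


class PanelValidationError(ValueError):
    """Raised when a panel violates the balanced-positive contract."""


@dataclass
class PanelDataset:
    """A balanced panel of DMU-year observations.

    Parameters
    ----------
    data : pandas.DataFrame
        Long format, one row per DMU-year, columns ``dmu, year, region``
        followed by input, output and environment columns.
    input_cols, output_cols, env_cols : tuple of str
        Which columns play which role.  Defaults follow the provincial
        primary-healthcare indicator system.
    """

    data: pd.DataFrame
    input_cols: tuple = INPUT_COLS
    output_cols: tuple = OUTPUT_COLS
    env_cols: tuple = ENV_COLS

    def __post_init__(self) -> None:
        self.input_cols = tuple(self.input_cols)
        self.output_cols = tuple(self.output_cols)
        self.env_cols = tuple(self.env_cols)
        self.validate()

    # -- contract ---------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        needed = set(ID_COLS) | set(self.input_cols) | set(self.output_cols) | set(self.env_cols)
        missing = needed - set(df.columns)
        if missing:
            raise PanelValidationError(f"panel missing columns: {sorted(missing)}")
        if df.duplicated(["dmu", "year"]).any():
            dup = df[df.duplicated(["dmu", "year"])].iloc[0]
            raise PanelValidationError(f"duplicate cell dmu={dup['dmu']} year={dup['year']}")
        years = self.years
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise PanelValidationError(f"years not consecutive: {list(years)}")
        # balanced: every DMU observed every year
        counts = df.groupby("dmu")["year"].nunique()
        bad = counts[counts != len(years)]
        if len(bad):
            raise PanelValidationError(
                f"unbalanced panel: {bad.index[0]!r} observed {bad.iloc[0]}/{len(years)} years"
            )
        if len(self.dmu_ids) < 2:
            raise PanelValidationError("need at least 2 DMUs")
        for col in self.input_cols + self.output_cols:
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                i = int(np.argmin(np.where(np.isfinite(vals), vals, -np.inf)))
                raise PanelValidationError(
                    f"nonpositive or nonfinite value in {col!r} at "
                    f"dmu={df['dmu'].iloc[i]} year={df['year'].iloc[i]}"
                )
        env = df[list(self.env_cols)].to_numpy(dtype=float)
        if not np.all(np.isfinite(env)):
            raise PanelValidationError("nonfinite environmental value")

    # -- views ------------------------------------------------------------

    @property
    def dmu_ids(self) -> list:
        """DMU labels in first-appearance order."""
        return list(dict.fromkeys(self.data["dmu"]))

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    @property
    def regions(self) -> dict:
        return dict(self.data.drop_duplicates("dmu")[["dmu", "region"]].itertuples(index=False))

    def year_slice(self, year: int) -> pd.DataFrame:
        """Rows of one year, ordered by ``dmu_ids``."""
        sl = self.data[self.data["year"] == year].set_index("dmu")
        return sl.loc[self.dmu_ids].reset_index()

    def inputs_matrix(self, year: int) -> np.ndarray:
        return self.year_slice(year)[list(self.input_cols)].to_numpy(dtype=float)

    def outputs_matrix(self, year: int) -> np.ndarray:
        return self.year_slice(year)[list(self.output_cols)].to_numpy(dtype=float)

    def env_matrix(self) -> np.ndarray:
        """Pooled DMU-year environment matrix, rows sorted (year, dmu order)."""
        return self.sorted_data()[list(self.env_cols)].to_numpy(dtype=float)

    def sorted_data(self) -> pd.DataFrame:
        order = {d: i for i, d in enumerate(self.dmu_ids)}
        return self.data.assign(_o=self.data["dmu"].map(order)).sort_values(
            ["year", "_o"]).drop(columns="_o").reset_index(drop=True)

    def with_inputs(self, new_inputs: pd.DataFrame) -> "PanelDataset":
        """Return a copy whose input columns are replaced.

        ``new_inputs`` must carry dmu, year and the input columns.
        """
        merged = self.data.drop(columns=list(self.input_cols)).merge(
            new_inputs[["dmu", "year", *self.input_cols]], on=["dmu", "year"], validate="1:1"
        )
        cols = [*ID_COLS, *self.input_cols, *self.output_cols, *self.env_cols]
        return replace(self, data=merged[cols])

    def drop_input(self, name: str) -> "PanelDataset":
        if name not in self.input_cols:
            raise KeyError(name)
        remaining = tuple(c for c in self.input_cols if c != name)
        if not remaining:
            raise PanelValidationError("cannot drop the last input")
        return replace(self, data=self.data.drop(columns=[name]), input_cols=remaining)

    def drop_env(self, name: str) -> "PanelDataset":
        if name not in self.env_cols:
            raise KeyError(name)
        return replace(self, data=self.data.drop(columns=[name]),
                       env_cols=tuple(c for c in self.env_cols if c != name))


def read_panel(path, input_cols=INPUT_COLS, output_cols=OUTPUT_COLS, env_cols=ENV_COLS) -> PanelDataset:
    """Read a long-format panel CSV; schema violations raise with the cell named."""
    df = pd.read_csv(path)
    return PanelDataset(df, input_cols, output_cols, env_cols)


def write_panel(panel: PanelDataset, path) -> None:
    cols = [*ID_COLS, *panel.input_cols, *panel.output_cols, *panel.env_cols]
    panel.sorted_data()[cols].to_csv(path, index=False)
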