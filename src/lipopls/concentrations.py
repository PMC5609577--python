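"""Concentration tables: sample x (lipoprotein class, lipid) values.

A :class:`ConcentrationTable` wraps a pandas DataFrame whose columns are
a two-level MultiIndex ``(class, lipid)`` with a single unit system for
the whole table (mg/dL or mmol/L). Conversion between the two systems
uses the molar masses from :mod:`lipopls.registry`:

    mmol/L = mg/dL * 10 / molar_mass
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import SPECIES, LpCategory, subclasses_of

__all__ = ["ConcentrationTable", "convert_units", "sum_category"]

VALID_UNITS = ("mg/dL", "mmol/L")


@dataclass
class ConcentrationTable:
    """Non-negative concentrations per sample, class and lipid species."""

    data: pd.DataFrame  # index: sample_id; columns: MultiIndex (class, lipid)
    units: str

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        if not isinstance(self.data.columns, pd.MultiIndex) or self.data.columns.nlevels != 2:
            raise ValueError("columns must be a (class, lipid) MultiIndex")
        vals = self.data.to_numpy(float)
        if vals.size and (not np.all(np.isfinite(vals)) or (vals < 0).any()):
            raise ValueError("concentrations must be finite and non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, lp_class: str, lipid: str) -> np.ndarray:
        return self.data[(lp_class, lipid)].to_numpy(float)

    def to_tidy(self) -> pd.DataFrame:
        """Long format: sample_id, class, lipid, value, units."""
        long = self.data.stack([0, 1], future_stack=True).reset_index()
        long.columns = ["sample_id", "class", "lipid", "value"]
        long["units"] = self.units
        return long

    def to_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "ConcentrationTable":
        units = tidy["units"].unique()
        if len(units) != 1:
            raise ValueError(f"units not uniform: {sorted(units)}")
        wide = tidy.pivot_table(
            index="sample_id", columns=["class", "lipid"], values="value", sort=False
        )
        wide = wide.loc[pd.unique(tidy["sample_id"])]
        return cls(wide, units=str(units[0]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConcentrationTable":
        return cls.from_tidy(pd.read_csv(path))


def convert_units(table: ConcentrationTable, target: str) -> ConcentrationTable:
    """Convert between mg/dL and mmol/L using species molar masses.

    Idempotent when ``target`` equals the table's current units; exact
    round trip (the map is linear and invertible per species).
    """
    if target not in VALID_UNITS:
        raise ValueError(f"unknown units {target!r}; expected one of {VALID_UNITS}")
    if target == table.units:
        return ConcentrationTable(table.data.copy(), units=table.units)
    out = table.data.copy()
    for (lp_class, lipid) in out.columns:
        mm = SPECIES[lipid].molar_mass
        factor = 10.0 / mm if target == "mmol/L" else mm / 10.0
        out[(lp_class, lipid)] = out[(lp_class, lipid)] * factor
    return ConcentrationTable(out, units=target)


def sum_category(table: ConcentrationTable, category: LpCategory | str) -> pd.DataFrame:
    """Per-sample totals over the subclasses of one category.

    Returns a DataFrame indexed by sample with one column per lipid
    species present, in the table's units. All member subclasses must be
    present.
    """
    members = [c.name for c in subclasses_of(category)]
    present = {cls for cls, _ in table.data.columns}
    missing = [m for m in members if m not in present]
    if missing:
        raise ValueError(f"missing subclasses for {LpCategory(category).value}: {missing}")
    lipids = sorted({lip for cls, lip in table.data.columns if cls in members})
    out = {}
    for lip in lipids:
        cols = [(m, lip) for m in members if (m, lip) in table.data.columns]
        out[lip] = table.data[cols].sum(axis=1)
    return pd.DataFrame(out, index=table.data.index)
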