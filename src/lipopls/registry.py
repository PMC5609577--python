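"""Registry of lipid species and lipoprotein subclasses.

Serum lipoproteins are indexed by decreasing particle diameter: two
chylomicron fractions (CM01, CM02), five VLDL (VLDL03-07), six LDL
(LDL08-13) and seven HDL (HDL14-20) subclasses, plus four category
totals. Only triglycerides (TG) and cholesterol (CH) are tracked; their
molar masses (884 and 385 g/mol) drive mg/dL <-> mmol/L conversion.

Diameters for five small/edge subclasses are not part of the reference
panel; they are filled in by log-linear extrapolation from their
category neighbours and flagged ``interpolated`` so downstream code can
distinguish measured from imputed sizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

__all__ = [
    "LipidSpecies",
    "TG",
    "CH",
    "LpCategory",
    "LpClass",
    "subclass_registry",
    "modeled_classes",
    "registry_frame",
    "export_registry",
]


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid analyte with the molar mass used for unit conversion."""

    code: str
    molar_mass: float  # g/mol

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")


TG = LipidSpecies("TG", 884.0)
CH = LipidSpecies("CH", 385.0)

SPECIES: dict[str, LipidSpecies] = {"TG": TG, "CH": CH}


class LpCategory(str, Enum):
    CM = "CM"
    VLDL = "VLDL"
    LDL = "LDL"
    HDL = "HDL"


@dataclass(frozen=True)
class LpClass:
    """One lipoprotein subclass or category total.

    ``diameter_nm`` is a scalar for subclasses (None for totals, which
    carry only a ``size_range_nm``); ``modeled`` marks the 15 subclasses
    and 3 totals with significant calibration models; ``interpolated``
    marks diameters imputed rather than taken from the reference panel.
    """

    name: str
    category: LpCategory
    diameter_nm: float | None
    modeled: bool
    interpolated: bool = False
    censored_bound: bool = False
    size_range_nm: tuple[float, float] | None = None
    is_total: bool = field(default=False)


def _extrapolate(diam: list[float], steps: int) -> list[float]:
    """Log-linear continuation using the mean log-ratio of neighbours."""
    slopes = [math.log(b / a) for a, b in zip(diam[:-1], diam[1:])]
    slope = sum(slopes) / len(slopes)
    out, d = [], diam[-1]
    for _ in range(steps):
        d *= math.exp(slope)
        out.append(round(d, 2))
    return out


# Measured diameters (nm), largest to smallest, per category.
_CM = {"CM01": 95.0, "CM02": 78.0}  # CM01 printed as ">90 nm"; stored as 95
_VLDL = {"VLDL03": 64.0, "VLDL04": 53.6, "VLDL05": 44.5, "VLDL06": 36.8, "VLDL07": 31.3}
_LDL = {"LDL08": 28.6, "LDL09": 25.5, "LDL10": 23.0, "LDL11": 20.7}
_HDL = {"HDL15": 13.5, "HDL16": 12.1, "HDL17": 10.9, "HDL18": 9.8}

_LDL12, _LDL13 = _extrapolate(list(_LDL.values()), 2)
_HDL14 = round(_HDL["HDL15"] / (_extrapolate(list(_HDL.values()), 1)[0] / _HDL["HDL18"]), 2)
_HDL19, _HDL20 = _extrapolate(list(_HDL.values()), 2)

_MODELED_SUBCLASSES = set(_CM) | set(_VLDL) | set(_LDL) | set(_HDL)


def subclass_registry() -> list[LpClass]:
    """Full 24-entry registry (20 subclasses + 4 totals), large to small.

    Subclasses come first in strictly decreasing diameter order; the four
    category totals follow, carrying size ranges as metadata only.
    """
    entries: list[LpClass] = []

    def sub(name: str, cat: LpCategory, d: float, interp: bool = False, cens: bool = False):
        entries.append(
            LpClass(name, cat, d, modeled=name in _MODELED_SUBCLASSES,
                    interpolated=interp, censored_bound=cens)
        )

    sub("CM01", LpCategory.CM, _CM["CM01"], cens=True)
    sub("CM02", LpCategory.CM, _CM["CM02"])
    for n, d in _VLDL.items():
        sub(n, LpCategory.VLDL, d)
    for n, d in _LDL.items():
        sub(n, LpCategory.LDL, d)
    sub("LDL12", LpCategory.LDL, _LDL12, interp=True)
    sub("LDL13", LpCategory.LDL, _LDL13, interp=True)
    sub("HDL14", LpCategory.HDL, _HDL14, interp=True)
    for n, d in _HDL.items():
        sub(n, LpCategory.HDL, d)
    sub("HDL19", LpCategory.HDL, _HDL19, interp=True)
    sub("HDL20", LpCategory.HDL, _HDL20, interp=True)

    entries.sort(key=lambda c: -c.diameter_nm)

    totals = [
        LpClass("CM_tot", LpCategory.CM, None, modeled=False,
                size_range_nm=(78.0, 95.0), is_total=True),
        LpClass("VLDL_tot", LpCategory.VLDL, None, modeled=True,
                size_range_nm=(30.0, 80.0), is_total=True),
        LpClass("LDL_tot", LpCategory.LDL, None, modeled=True,
                size_range_nm=(16.0, 30.0), is_total=True),
        LpClass("HDL_tot", LpCategory.HDL, None, modeled=True,
                size_range_nm=(8.0, 16.0), is_total=True),
    ]
    return entries + totals


def modeled_classes() -> list[LpClass]:
    """The 18 classes (15 subclasses + 3 totals) with calibration models."""
    return [c for c in subclass_registry() if c.modeled]


def registry_lookup() -> dict[str, LpClass]:
    return {c.name: c for c in subclass_registry()}


def subclasses_of(category: LpCategory | str) -> list[LpClass]:
    cat = LpCategory(category)
    return [c for c in subclass_registry() if c.category is cat and not c.is_total]


def registry_frame():
    """Registry as a pandas DataFrame (for CSV export and reports)."""
    import pandas as pd

    rows = []
    for c in subclass_registry():
        rows.append(
            {
                "name": c.name,
                "category": c.category.value,
                "diameter_nm": c.diameter_nm,
                "size_range_lo_nm": c.size_range_nm[0] if c.size_range_nm else None,
                "size_range_hi_nm": c.size_range_nm[1] if c.size_range_nm else None,
                "modeled": c.modeled,
                "interpolated": c.interpolated,
                "is_total": c.is_total,
            }
        )
    return pd.DataFrame(rows)


def export_registry(path_csv: str | Path | None = None, path_json: str | Path | None = None) -> None:
    df = registry_frame()
    if path_csv is not None:
        df.to_csv(path_csv, index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps(df.to_dict(orient="records"), indent=1))
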