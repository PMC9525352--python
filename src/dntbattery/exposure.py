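"""Biomonitoring conversions and crude in vitro-to-exposure margins.

Flame-retardant concentrations measured in human breast milk or cord blood
are reported either per gram of matrix lipid (ng/g lw) or per volume
(ng/mL).  Lipid-based values convert to molarity through the matrix fat
content — 5.8 g/L for serum/cord blood and 33 g/L for breast milk — and the
compound's molar mass; volume-based values are µg/L divided by g/mol
directly.  A nursing infant's intake assumes 1 L of breast milk per day.

The margin between in vitro hazard and exposure is expressed in orders of
magnitude, ``log10(BMC / exposure)``: positive values mean the benchmark
concentration sits above the estimated internal exposure.

These comparisons are deliberately crude (100% bioavailability, no
metabolism, 1:1 blood-brain transfer); outputs carry that caveat as
metadata rather than attempting kinetic modelling.

Note on the bundled survey table: applying the lipid formula
``value x fat / molar_mass / 1000`` lands a consistent factor ~10 below the
µM column transcribed from the source compilation (kept as ``um_reported``),
and the TCIPP 0.22 ng/mL entry likewise disagrees with its standard molar
mass.  Computed and reported molarities are therefore carried side by side;
intake headlines derive from the reported column they were published with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError

IVIVE_CAVEAT = (
    "crude IVIVE: assumes 100% bioavailability, no metabolism, 1:1 blood-brain transfer"
)

#: literature formula weights, g/mol
MOLAR_MASS_G_MOL: dict[str, float] = {
    "BDE-47": 485.79,
    "BDE-99": 564.69,
    "TBBPA": 543.87,
    "TPHP": 326.28,
    "TBOEP": 398.47,
    "BBOEP": 298.31,
    "IDDPHP": 390.46,
    "IPPHP": 368.37,
    "TCP": 368.37,
    "TOCP": 368.37,
    "TDCIPP": 430.90,
    "t-BPDPHP": 382.39,
    "EHDPHP": 362.41,
    "TCIPP": 327.57,
    "TCEP": 285.49,
}

MATRICES = ("breast_milk", "cord_blood", "other_fluid")
UNITS = ("ng_per_g_lipid", "ng_per_mL")


@dataclass(frozen=True)
class ExposureRecord:
    compound_id: str
    matrix: str
    value: float
    unit: str
    region: str = ""

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.value < 0:
            raise ValueError("exposure value must be >= 0")


@dataclass(frozen=True)
class ConversionParams:
    serum_fat_g_per_L: float = 5.8
    milk_fat_g_per_L: float = 33.0
    intake_L_per_day: float = 1.0
    molar_mass: dict[str, float] = field(default_factory=lambda: dict(MOLAR_MASS_G_MOL))

    def __post_init__(self) -> None:
        if min(self.serum_fat_g_per_L, self.milk_fat_g_per_L, self.intake_L_per_day) <= 0:
            raise ValueError("fat contents and intake must be strictly positive")

    def fat_content(self, matrix: str) -> float:
        if matrix == "breast_milk":
            return self.milk_fat_g_per_L
        if matrix == "cord_blood":
            return self.serum_fat_g_per_L
        raise ConfigurationError(f"no fat content defined for matrix {matrix!r}")


def to_molar(record: ExposureRecord, params: ConversionParams | None = None) -> float:
    """Convert one biomonitoring record to µM.

    ng/g lipid: ``value x fat(g/L) / molar_mass(g/mol) / 1000``;
    ng/mL (= µg/L): ``value / molar_mass``.  Rounding happens only at
    reporting time.
    """
    params = params or ConversionParams()
    m = params.molar_mass.get(record.compound_id)
    if m is None:
        raise KeyError(f"no molar mass on file for {record.compound_id!r}")
    if record.unit == "ng_per_g_lipid":
        return record.value * params.fat_content(record.matrix) / m / 1000.0
    return record.value / m


def from_molar(conc_um: float, record: ExposureRecord, params: ConversionParams | None = None) -> float:
    """Inverse of :func:`to_molar` (round-trip support)."""
    params = params or ConversionParams()
    m = params.molar_mass[record.compound_id]
    if record.unit == "ng_per_g_lipid":
        return conc_um * 1000.0 * m / params.fat_content(record.matrix)
    return conc_um * m


def daily_intake(conc_um: float, params: ConversionParams | None = None) -> float:
    """nmol/day ingested at ``conc_um`` µM: conc x intake (L/day) x 1000."""
    if conc_um < 0:
        raise ValueError("concentration must be >= 0")
    params = params or ConversionParams()
    return conc_um * params.intake_L_per_day * 1000.0


def round_intake(nmol_per_day: float) -> int:
    """Report intakes as integers (half away from zero)."""
    return int(np.floor(nmol_per_day + 0.5))


def exposure_margin(bmc_um: float, exposure_um: float) -> float:
    """Orders of magnitude between hazard and exposure: log10(BMC/exposure)."""
    if bmc_um <= 0 or exposure_um <= 0:
        raise ValueError("margin requires strictly positive concentrations")
    return float(np.log10(bmc_um / exposure_um))


def load_exposure_table() -> pd.DataFrame:
    """Bundled compilation of published FR biomonitoring measurements."""
    with resources.files("dntbattery.data").joinpath(
        "flame_retardant_biomonitoring.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def summarize_exposure(
    table: pd.DataFrame | None = None, params: ConversionParams | None = None
) -> pd.DataFrame:
    """Add computed µM and nmol/day columns to an exposure table.

    ``um_computed`` applies the stated conversion formulas; ``um_reported``
    (when present) is the molarity column published alongside the raw values.
    Breast-milk rows get a daily-intake estimate from each µM column.
    """
    params = params or ConversionParams()
    df = (table if table is not None else load_exposure_table()).copy()
    df["um_computed"] = [
        to_molar(ExposureRecord(r.compound, r.matrix, r.value, r.unit, getattr(r, "region", "")), params)
        for r in df.itertuples()
    ]
    milk = df["matrix"] == "breast_milk"
    df["intake_nmol_day_computed"] = np.where(
        milk, [round_intake(daily_intake(u, params)) for u in df["um_computed"]], np.nan
    )
    if "um_reported" in df.columns:
        df["intake_nmol_day_reported"] = np.where(
            milk, [round_intake(daily_intake(u, params)) for u in df["um_reported"]], np.nan
        )
    df.attrs["caveat"] = IVIVE_CAVEAT
    return df


def headline_intakes(
    table: pd.DataFrame | None = None,
    params: ConversionParams | None = None,
    use_reported: bool = True,
) -> dict[str, int]:
    """Highest breast-milk daily intake per compound (nmol/day, integer)."""
    params = params or ConversionParams()
    df = summarize_exposure(table, params)
    df = df[df["matrix"] == "breast_milk"]
    col = "um_reported" if use_reported and "um_reported" in df.columns else "um_computed"
    out = {}
    for comp, grp in df.groupby("compound"):
        out[comp] = round_intake(daily_intake(float(grp[col].max()), params))
    return out
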