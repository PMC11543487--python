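"""Screening-table data model, validation and CSV round-tripping.

A screening table holds one record per solvent system: the deep eutectic
solvent (DES) composition (hydrogen-bond acceptor, donor, molar ratio,
diluent and its mass fraction) together with the measured physicochemical
properties (pH, viscosity, density), the saturated dissolved-CO2
concentration, the pH after CO2 saturation, the short-term NADH degradation
constant in the CO2-saturated solvent (min^-1) and the 14-day residual
enzyme activity (%).

The study's screening table ships as the builtin fixture ``"table1"``; the
published piecewise-linear QSAR coefficients ship as ``"table3_models"``
(consumed by :mod:`descreen.plr_qsar`).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator

__all__ = [
    "SolventSystem",
    "ScreeningTable",
    "SchemaError",
    "ParseError",
    "load_screening_table",
    "write_screening_table",
    "load_reported_kinetics",
]

_COLUMNS = [
    "system_id",
    "hba",
    "hbd",
    "ratio_hba",
    "ratio_hbd",
    "diluent",
    "diluent_mass_fraction",
    "ph",
    "viscosity_mpa_s",
    "density_g_per_cm3",
    "co2_saturation_mg_per_l",
    "k_nadh_star_per_min",
    "ph_after_co2",
    "residual_activity_14d_pct",
]

_DILUENTS = ("water", "buffer")


class SchemaError(ValueError):
    """The input table is structurally invalid (missing column, bad value)."""


class ParseError(ValueError):
    """A cell could not be parsed as a number; carries row and column."""


def _parse_number(text: str, *, row: int, column: str) -> float:
    """Parse a numeric cell, accepting thousands separators ("1,057")."""
    cleaned = text.strip().replace(",", "")
    try:
        return float(cleaned)
    except ValueError:
        raise ParseError(
            f"unparseable numeric cell {text!r} at row {row}, column {column!r}"
        ) from None


@dataclass
class SolventSystem:
    """One screening record for a solvent system (a DES dilution or the buffer)."""

    system_id: str
    hba: str
    hbd: str
    molar_ratio_hba_hbd: tuple[int, int]
    diluent: str
    diluent_mass_fraction: float
    ph: float
    viscosity: float            # mPa s
    density: float              # g/cm^3
    co2_saturation: float       # mg/L
    k_nadh_star: float          # min^-1, short-term NADH degradation after CO2
    ph_after_co2: float
    residual_activity_14d: float  # percent

    def __post_init__(self) -> None:
        if not self.system_id:
            raise SchemaError("system_id must be non-empty")
        if self.diluent not in _DILUENTS:
            raise SchemaError(
                f"{self.system_id}: diluent must be one of {_DILUENTS}, got {self.diluent!r}"
            )
        a, b = self.molar_ratio_hba_hbd
        if self.hba == "none" and self.hbd == "none":
            # reference medium (pure diluent): ratio is irrelevant, stored as 0:0
            if self.diluent_mass_fraction != 1.0:
                raise SchemaError(
                    f"{self.system_id}: a component-free record must have "
                    "diluent_mass_fraction 1.0"
                )
        elif a <= 0 or b <= 0:
            raise SchemaError(f"{self.system_id}: molar ratio must be positive integers")
        if not 0.0 <= self.diluent_mass_fraction <= 1.0:
            raise SchemaError(f"{self.system_id}: diluent_mass_fraction outside [0, 1]")
        if self.viscosity <= 0:
            raise SchemaError(f"{self.system_id}: viscosity must be > 0")
        if self.density <= 0:
            raise SchemaError(f"{self.system_id}: density must be > 0")
        if self.co2_saturation < 0:
            raise SchemaError(f"{self.system_id}: co2_saturation must be >= 0")
        if self.k_nadh_star < 0:
            raise SchemaError(f"{self.system_id}: k_nadh_star must be >= 0")
        if self.residual_activity_14d < 0:
            raise SchemaError(f"{self.system_id}: residual_activity_14d must be >= 0")


@dataclass
class ScreeningTable:
    """An ordered, id-unique collection of :class:`SolventSystem` records."""

    records: list[SolventSystem]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise SchemaError("screening table must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.system_id in seen:
                raise SchemaError(f"duplicate system_id {rec.system_id!r}")
            seen.add(rec.system_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolventSystem]:
        return iter(self.records)

    def __getitem__(self, system_id: str) -> SolventSystem:
        for rec in self.records:
            if rec.system_id == system_id:
                return rec
        raise KeyError(system_id)

    @property
    def system_ids(self) -> list[str]:
        return [rec.system_id for rec in self.records]

    def to_frame(self):
        """Return the table as a pandas DataFrame indexed by system id."""
        import pandas as pd

        rows = []
        for rec in self.records:
            rows.append(
                {
                    "system_id": rec.system_id,
                    "hba": rec.hba,
                    "hbd": rec.hbd,
                    "ratio_hba": rec.molar_ratio_hba_hbd[0],
                    "ratio_hbd": rec.molar_ratio_hba_hbd[1],
                    "diluent": rec.diluent,
                    "diluent_mass_fraction": rec.diluent_mass_fraction,
                    "ph": rec.ph,
                    "viscosity_mpa_s": rec.viscosity,
                    "density_g_per_cm3": rec.density,
                    "co2_saturation_mg_per_l": rec.co2_saturation,
                    "k_nadh_star_per_min": rec.k_nadh_star,
                    "ph_after_co2": rec.ph_after_co2,
                    "residual_activity_14d_pct": rec.residual_activity_14d,
                }
            )
        return pd.DataFrame(rows).set_index("system_id")


def _data_path(name: str):
    return importlib.resources.files("descreen.data").joinpath(name)


_FIXTURES = {"table1": "table1.csv"}

#: Provenance note attached to the builtin screening fixture.
TABLE1_PROVENANCE = (
    "Glycerol-DES screening table (20 DES dilutions + reference phosphate "
    "buffer). Dissolved-CO2 concentrations are stored in mg/L as tabulated; "
    "the methods text restates the same numbers with mg/mL units, which is a "
    "units slip in the source. Zero short-term NADH degradation constants "
    "mean no detectable absorbance loss over the 90-min window, not missing "
    "data. Values preserve the printed precision."
)


def load_screening_table(source: str | Path) -> ScreeningTable:
    """Load and validate a screening table from a CSV file or builtin fixture id.

    Numeric cells may use thousands separators ("1,057" parses as 1057).

    Raises
    ------
    SchemaError
        If a required column is missing or the table is empty/invalid.
    ParseError
        If a numeric cell cannot be parsed (names the row and column).
    """
    provenance = str(source)
    if str(source) in _FIXTURES:
        path = _data_path(_FIXTURES[str(source)])
        provenance = TABLE1_PROVENANCE
        text = path.read_text(encoding="utf-8")
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"no such file or fixture id: {source}")
        text = path.read_text(encoding="utf-8")

    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None:
        raise SchemaError("empty file: no header row")
    missing = [c for c in _COLUMNS if c not in reader.fieldnames]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[SolventSystem] = []
    for i, row in enumerate(reader, start=2):
        num = lambda col: _parse_number(row[col], row=i, column=col)  # noqa: E731
        records.append(
            SolventSystem(
                system_id=row["system_id"].strip(),
                hba=row["hba"].strip(),
                hbd=row["hbd"].strip(),
                molar_ratio_hba_hbd=(int(num("ratio_hba")), int(num("ratio_hbd"))),
                diluent=row["diluent"].strip(),
                diluent_mass_fraction=num("diluent_mass_fraction"),
                ph=num("ph"),
                viscosity=num("viscosity_mpa_s"),
                density=num("density_g_per_cm3"),
                co2_saturation=num("co2_saturation_mg_per_l"),
                k_nadh_star=num("k_nadh_star_per_min"),
                ph_after_co2=num("ph_after_co2"),
                residual_activity_14d=num("residual_activity_14d_pct"),
            )
        )
    if not records:
        raise SchemaError("table contains a header but no records")
    return ScreeningTable(records=records, provenance=provenance)


def _format_number(x: float) -> str:
    """Format preserving value exactly (repr round-trips floats)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x)) if float(int(x)) == x else repr(x)
    return repr(x)


def write_screening_table(table: ScreeningTable, dest: str | Path) -> None:
    """Write a validated table as RFC-4180 CSV with a fixed header order.

    ``load_screening_table(write_screening_table(t))`` reproduces ``t``
    field-for-field.
    """
    if not isinstance(table, ScreeningTable):
        raise TypeError("expected a ScreeningTable")
    dest = Path(dest)
    with dest.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in table.records:
            writer.writerow(
                [
                    rec.system_id,
                    rec.hba,
                    rec.hbd,
                    rec.molar_ratio_hba_hbd[0],
                    rec.molar_ratio_hba_hbd[1],
                    rec.diluent,
                    _format_number(rec.diluent_mass_fraction),
                    _format_number(rec.ph),
                    _format_number(rec.viscosity),
                    _format_number(rec.density),
                    _format_number(rec.co2_saturation),
                    _format_number(rec.k_nadh_star),
                    _format_number(rec.ph_after_co2),
                    _format_number(rec.residual_activity_14d),
                ]
            )


def load_reported_kinetics() -> "pd.DataFrame":  # noqa: F821
    """Half-lives and relative activities printed in the study narrative.

    Returns a DataFrame indexed by system id with columns
    ``fdh_half_life_d``, ``nadh_half_life_d`` and ``relative_activity_pct``;
    cells the narrative does not print are NaN.
    """
    import pandas as pd

    with importlib.resources.as_file(_data_path("reported_kinetics.csv")) as p:
        return pd.read_csv(p, comment="#").set_index("system_id")
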