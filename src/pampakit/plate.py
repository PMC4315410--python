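"""Domain types and delimited-text I/O for PAMPA sandwich-plate data.

The sandwich assay stacks a donor microtiter plate, a lipid-coated filter,
and an acceptor plate.  Everything downstream works from per-well
concentration measurements; only concentration *ratios* enter the math, so
the concentration unit is arbitrary as long as the three measurements of a
well share it.  Volumes are cm^3 (1 ml = 1 cm^3), areas cm^2, times s, and
permeabilities cm/s throughout the package.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SandwichGeometry",
    "ConcentrationRecord",
    "DrugInfo",
    "PermeabilityResult",
    "PlateSchemaError",
    "PlateValidationError",
    "PLATE_COLUMNS",
    "RESULT_COLUMNS",
    "read_plate_table",
    "write_plate_table",
    "write_results_table",
]

#: Column order of a plate file (header row is mandatory).
PLATE_COLUMNS = (
    "compound",
    "lipid",
    "ph_donor",
    "ph_acceptor",
    "t_seconds",
    "cd0",
    "cd_t",
    "ca_t",
)

#: Column order of a results file.
RESULT_COLUMNS = ("compound", "lipid", "pe_cm_per_s", "s_factor", "retention", "flag")

IONIZATION_CLASSES = ("acid", "base", "ampholyte", "neutral")


class PlateSchemaError(ValueError):
    """A plate file is missing mandatory columns or has a malformed header."""


class PlateValidationError(ValueError):
    """A plate file row holds values that violate the well invariants."""


@dataclass(frozen=True)
class SandwichGeometry:
    """Plate constants shared by every well of a sandwich.

    Defaults are the instrument constants used throughout: 0.2 ml acceptor
    wells, 0.3 ml donor wells, 0.2826 cm^2 filter area and an average
    steady-state lag of 1140 s for the membrane to saturate before net
    acceptor flux begins.
    """

    acceptor_volume_cm3: float = 0.2
    donor_volume_cm3: float = 0.3
    filter_area_cm2: float = 0.2826
    steady_state_lag_s: float = 1140.0

    def __post_init__(self) -> None:
        for name in (
            "acceptor_volume_cm3",
            "donor_volume_cm3",
            "filter_area_cm2",
            "steady_state_lag_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"SandwichGeometry.{name} must be strictly positive")

    @property
    def hybrid_volume_cm3(self) -> float:
        """V_a V_d / (V_a + V_d) — the reduced volume of the well pair."""
        va, vd = self.acceptor_volume_cm3, self.donor_volume_cm3
        return va * vd / (va + vd)


@dataclass(frozen=True)
class ConcentrationRecord:
    """One well's measured concentrations at a single sampling time."""

    compound_name: str
    lipid_label: str
    donor_pH: float
    acceptor_pH: float
    incubation_time_s: float
    donor_conc_initial: float
    donor_conc_final: float
    acceptor_conc_final: float

    def __post_init__(self) -> None:
        if self.incubation_time_s <= 0:
            raise ValueError("incubation_time_s must be > 0")
        if self.donor_conc_initial <= 0:
            raise ValueError("donor_conc_initial C_d(0) must be > 0")
        if self.donor_conc_final < 0 or self.acceptor_conc_final < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class DrugInfo:
    """Physicochemical metadata of a model drug.

    ``pKa_values`` is ascending; ``fraction_absorbed_percent`` is the human
    fraction absorbed (%FA) on the 0–100 scale.
    """

    name: str
    molecular_weight: float
    pKa_values: tuple[float, ...]
    ionization_class: str
    fraction_absorbed_percent: float
    water_solubility_mg_per_L: float | None = None

    def __post_init__(self) -> None:
        if self.ionization_class not in IONIZATION_CLASSES:
            raise ValueError(f"unknown ionization class {self.ionization_class!r}")
        if not 0 <= self.fraction_absorbed_percent <= 100:
            raise ValueError("%FA must lie in [0, 100]")
        if list(self.pKa_values) != sorted(self.pKa_values):
            raise ValueError("pKa_values must be ascending")
        if self.ionization_class == "ampholyte" and len(self.pKa_values) < 2:
            raise ValueError("an ampholyte needs at least two pKa values")


@dataclass(frozen=True)
class PermeabilityResult:
    """Effective permeability of one well with its mass-balance diagnostics.

    ``mass_fraction_remaining`` is the S factor (fraction of the dose still
    recoverable from the two wells); ``membrane_retention`` is 1 - S.
    ``quality_flag`` is one of ``ok``, ``no_transport``, ``at_equilibrium``
    or ``mass_balance_violation``; a numeric P_e is only meaningful for
    ``ok`` and ``no_transport`` (where it is exactly 0).
    """

    compound_name: str
    lipid_label: str
    pe_cm_per_s: float
    mass_fraction_remaining: float
    membrane_retention: float
    quality_flag: str = "ok"


def _parse_row(row: dict[str, str], line_no: int) -> ConcentrationRecord:
    numeric: dict[str, float] = {}
    for col in PLATE_COLUMNS[2:]:
        cell = (row.get(col) or "").strip()
        if cell == "":
            raise PlateValidationError(f"row {line_no}: empty value in column {col!r}")
        try:
            numeric[col] = float(cell)
        except ValueError as exc:
            raise PlateValidationError(
                f"row {line_no}: cannot parse {cell!r} in column {col!r}"
            ) from exc
    for col in ("cd0", "cd_t", "ca_t"):
        if numeric[col] < 0:
            raise PlateValidationError(
                f"row {line_no}: negative concentration in column {col!r}"
            )
    try:
        return ConcentrationRecord(
            compound_name=row["compound"].strip(),
            lipid_label=row["lipid"].strip(),
            donor_pH=numeric["ph_donor"],
            acceptor_pH=numeric["ph_acceptor"],
            incubation_time_s=numeric["t_seconds"],
            donor_conc_initial=numeric["cd0"],
            donor_conc_final=numeric["cd_t"],
            acceptor_conc_final=numeric["ca_t"],
        )
    except ValueError as exc:
        raise PlateValidationError(f"row {line_no}: {exc}") from exc


def _sniff_delimiter(sample: str, explicit: str | None) -> str:
    if explicit is not None:
        return explicit
    header = sample.splitlines()[0] if sample else ""
    return "\t" if "\t" in header else ","


def read_plate_table(path: str | Path, delimiter: str | None = None) -> list[ConcentrationRecord]:
    """Read a UTF-8 delimited plate file into concentration records.

    Comma is the default delimiter; tab is auto-detected from the header.
    The header must contain every column in :data:`PLATE_COLUMNS`.
    Unparseable or negative numeric cells raise
    :class:`PlateValidationError` naming the offending row.
    """
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text, delimiter)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None:
        raise PlateSchemaError(f"{path}: empty file, header row required")
    fields = [f.strip() for f in reader.fieldnames]
    missing = [c for c in PLATE_COLUMNS if c not in fields]
    if missing:
        raise PlateSchemaError(f"{path}: missing mandatory column(s) {missing}")
    records = []
    for line_no, row in enumerate(reader, start=2):
        row = {(k or "").strip(): (v or "") for k, v in row.items()}
        records.append(_parse_row(row, line_no))
    return records


def write_plate_table(
    records: Iterable[ConcentrationRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records in the plate schema; inverse of :func:`read_plate_table`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(PLATE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.compound_name,
                    r.lipid_label,
                    repr(float(r.donor_pH)),
                    repr(float(r.acceptor_pH)),
                    repr(float(r.incubation_time_s)),
                    repr(float(r.donor_conc_initial)),
                    repr(float(r.donor_conc_final)),
                    repr(float(r.acceptor_conc_final)),
                ]
            )


def write_results_table(
    results: Iterable[PermeabilityResult], path: str | Path, delimiter: str = ","
) -> None:
    """Write permeability results as delimited text (RESULT_COLUMNS order)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.compound_name,
                    r.lipid_label,
                    f"{r.pe_cm_per_s:.10g}",
                    f"{r.mass_fraction_remaining:.10g}",
                    f"{r.membrane_retention:.10g}",
                    r.quality_flag,
                ]
            )
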