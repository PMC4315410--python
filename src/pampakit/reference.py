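"""Loaders for the packaged reference tables of the ten model drugs.

Two tables ship with the package (see ``data/MANIFEST.md``): the 16 h
single-pH permeability screen with drug metadata, and the five-point
pH-gradient permeability profiles.  All stored permeabilities are in cm/s
with the printed scale factors already applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .plate import DrugInfo

__all__ = [
    "LIPIDS",
    "Table1Entry",
    "PHProfilePoint",
    "load_drug_info",
    "load_table1_fixture",
    "load_table2_fixture",
]

#: Membrane labels by hydrophobic carbon-chain length, in ascending order.
LIPIDS = ("C8", "C10", "C12")


@dataclass(frozen=True)
class Table1Entry:
    """One (drug, lipid) cell of the 16 h permeability screen."""

    drug: DrugInfo
    lipid_label: str
    pe_cm_per_s: float
    sd_cm_per_s: float


@dataclass(frozen=True)
class PHProfilePoint:
    """One point of a P_e versus donor-pH profile."""

    pH: float
    pe_cm_per_s: float
    sd_cm_per_s: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pH <= 14:
            raise ValueError("pH must lie in [0, 14]")
        if self.pe_cm_per_s <= 0:
            raise ValueError("pe_cm_per_s must be > 0")


def _read_packaged_csv(filename: str) -> list[dict[str, str]]:
    text = resources.files("pampakit.data").joinpath(filename).read_text("utf-8")
    return list(csv.DictReader(text.splitlines()))


def load_drug_info() -> dict[str, DrugInfo]:
    """Return the ten model drugs keyed by name."""
    drugs: dict[str, DrugInfo] = {}
    for row in _read_packaged_csv("table1_drugs.csv"):
        sol = row["water_solubility_mg_per_L"]
        drugs[row["name"]] = DrugInfo(
            name=row["name"],
            molecular_weight=float(row["molecular_weight"]),
            pKa_values=tuple(float(x) for x in row["pka_values"].split(";")),
            ionization_class=row["ionization_class"],
            fraction_absorbed_percent=float(row["fa_percent"]),
            water_solubility_mg_per_L=float(sol) if sol else None,
        )
    return drugs


def load_table1_fixture() -> list[Table1Entry]:
    """The 16 h screen: 30 entries (10 drugs x 3 lipids) with %FA metadata."""
    drugs = load_drug_info()
    return [
        Table1Entry(
            drug=drugs[row["name"]],
            lipid_label=row["lipid"],
            pe_cm_per_s=float(row["pe_cm_per_s"]),
            sd_cm_per_s=float(row["sd_cm_per_s"]),
        )
        for row in _read_packaged_csv("table1_permeability.csv")
    ]


def load_table2_fixture() -> dict[tuple[str, str], list[PHProfilePoint]]:
    """pH-gradient profiles keyed by (drug name, lipid label).

    Cells printed as dashes in the source (atenolol pH 4.6, famotidine
    pH 8.2) are absent, never imputed, so profiles have 4 or 5 points.
    """
    profiles: dict[tuple[str, str], list[PHProfilePoint]] = {}
    for row in _read_packaged_csv("table2_ph_profiles.csv"):
        key = (row["name"], row["lipid"])
        profiles.setdefault(key, []).append(
            PHProfilePoint(
                pH=float(row["ph"]),
                pe_cm_per_s=float(row["pe_cm_per_s"]),
                sd_cm_per_s=float(row["sd_cm_per_s"]),
            )
        )
    for points in profiles.values():
        points.sort(key=lambda p: p.pH)
    return profiles
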