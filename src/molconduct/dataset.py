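"""Packaged reference tables and their validation.

Every numeric table of the study is shipped as a CSV fixture: the E-series
catalogue (T1), the order-6 set (T2), the three structural series used to fit
the boiling-point models (T3 normal-alkanes, T4 2-methyl, T5 2,2-dimethyl),
and the three prediction tables (T7, T8, T9 for orders 6, 7, 8).  Printed
values are stored verbatim as decimal strings so that comparisons happen at
the printed precision; :func:`validate_conduction` recomputes every
conduction exactly and reports the rows whose printed value disagrees beyond
half a unit in the last printed digit (two such errata exist).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

from .conduction import conduction
from .molgraph import MolecularGraph, parse_smiles

__all__ = [
    "AlkaneRecord",
    "Discrepancy",
    "TABLE_IDS",
    "PREDICTED_ERRATA",
    "load_table",
    "validate_conduction",
    "printed_tolerance",
]

TABLE_IDS = ("T1", "T2", "T3", "T4", "T5", "T7", "T8", "T9")

#: Printed *predicted* boiling points that are inconsistent with the linear
#: model that generated their own table (all predictions within one table lie
#: on a single line; these cells do not, by far more than rounding).  Keyed by
#: (table_id, name).  Distinct from the conduction errata, which the
#: ``erratum`` column flags.
PREDICTED_ERRATA = {("T9", "2,4-Dimethylhexane")}


@dataclass(frozen=True)
class AlkaneRecord:
    table_id: str
    row_index: int
    name: str
    smiles: str
    conduction_printed: str | None  # verbatim decimal string
    bp_experimental: float | None
    bp_predicted: float | None
    missing_bp: bool
    erratum: bool

    @property
    def conduction_printed_value(self) -> float | None:
        return float(self.conduction_printed) if self.conduction_printed else None

    @property
    def conduction_printed_exact(self) -> Fraction | None:
        return Fraction(self.conduction_printed) if self.conduction_printed else None

    def graph(self) -> MolecularGraph:
        return parse_smiles(self.smiles, label=self.name)

    @property
    def order(self) -> int:
        return self.smiles.count("C")


@dataclass(frozen=True)
class Discrepancy:
    table_id: str
    name: str
    printed: str
    recomputed: Fraction

    def __str__(self) -> str:
        return (
            f"{self.table_id} {self.name}: printed {self.printed}, "
            f"recomputed {self.recomputed} = {float(self.recomputed):.5f}"
        )


def printed_tolerance(printed: str) -> Fraction:
    """Half a unit in the last printed digit, as an exact rational."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return Fraction(1, 2) * Fraction(10) ** (-decimals)


def _read_csv(table_id: str) -> list[AlkaneRecord]:
    text = resources.files("molconduct.data.tables").joinpath(f"{table_id}.csv").read_text()
    records = []
    for row in csv.DictReader(text.splitlines()):
        records.append(
            AlkaneRecord(
                table_id=row["table_id"],
                row_index=int(row["row_index"]),
                name=row["name"],
                smiles=row["smiles"],
                conduction_printed=row["conduction_printed"] or None,
                bp_experimental=float(row["bp_experimental"]) if row["bp_experimental"] else None,
                bp_predicted=float(row["bp_predicted"]) if row["bp_predicted"] else None,
                missing_bp=row["missing_bp"] == "true",
                erratum=row["erratum"] == "true",
            )
        )
    return records


_CACHE: dict[str, list[AlkaneRecord]] = {}


def load_table(table_id: str) -> list[AlkaneRecord]:
    """Records of one packaged table, in printed row order."""
    if table_id not in TABLE_IDS:
        raise ValueError(f"unknown table {table_id!r}; expected one of {TABLE_IDS}")
    if table_id not in _CACHE:
        _CACHE[table_id] = _read_csv(table_id)
    return list(_CACHE[table_id])


def validate_conduction(table_id: str) -> list[Discrepancy]:
    """Rows whose printed conduction disagrees with exact recomputation.

    Comparison is exact-rational at the printed precision; rows without a
    printed conduction are skipped.  A non-empty result marks printed errata,
    not computation failures.
    """
    out = []
    for rec in load_table(table_id):
        if not rec.conduction_printed:
            continue
        exact = conduction(rec.graph()).exact
        if abs(exact - rec.conduction_printed_exact) > printed_tolerance(rec.conduction_printed):
            out.append(Discrepancy(table_id, rec.name, rec.conduction_printed, exact))
    return out
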