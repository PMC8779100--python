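"""Packaged experimental reference fractions and comparison logic.

The reference table collects published backbone-conformer populations for
aspartic/glutamic acid residues from vibrational and NMR spectroscopy:
the Gly-Glu-Gly tripeptide, the Asp and Glu dipeptides in neutral (N) and
ionized (I) states, and ionized poly(glutamic acid) (PGA) from two sources.
Bound rows ("<0.20") are compared directionally; "~" values carry an
``approximate`` flag.  Empty cells of the published table are absent rows,
and comparisons against them are skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .regions import FractionTable

__all__ = ["ReferenceRow", "ReferenceTable", "ComparisonRow", "ComparisonReport",
           "load_reference", "compare_to_reference"]

MOLECULES = ("GA", "di-ASA", "di-GA", "PGA")
CONFORMATIONS = ("PPII", "beta", "3.10", "alpha", "alpha+beta")


@dataclass(frozen=True)
class ReferenceRow:
    molecule: str          # GA | di-ASA | di-GA | PGA
    protonation: str       # N | I
    conformation: str      # PPII | beta | 3.10 | alpha | alpha+beta
    value: float
    bound: str = "eq"      # eq | lt
    approximate: bool = False
    source: str = ""       # citation key of the original measurement

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("reference fractions lie in [0, 1]")
        if self.bound not in ("eq", "lt"):
            raise ValueError(f"unknown bound {self.bound!r}")
        if self.molecule not in MOLECULES or self.conformation not in CONFORMATIONS:
            raise ValueError(f"unknown row {self.molecule}/{self.conformation}")


@dataclass
class ReferenceTable:
    rows: tuple

    def select(self, molecule: str, protonation: str | None = None,
               conformation: str | None = None) -> list:
        out = [r for r in self.rows if r.molecule == molecule]
        if protonation is not None:
            out = [r for r in out if r.protonation == protonation]
        if conformation is not None:
            out = [r for r in out if r.conformation == conformation]
        return out

    def to_json(self, path: str | Path) -> None:
        data = [r.__dict__ for r in self.rows]
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceTable":
        data = json.loads(Path(path).read_text())
        return cls(rows=tuple(ReferenceRow(**row) for row in data))


def _rows() -> tuple:
    R = ReferenceRow
    rows = []
    # Gly-Glu-Gly tripeptide; one published value covers both protonation states.
    for prot in ("N", "I"):
        rows += [
            R("GA", prot, "PPII", 0.54, source="hagarman2010"),
            R("GA", prot, "beta", 0.26, source="hagarman2010"),
            R("GA", prot, "alpha", 0.08, source="hagarman2010"),
        ]
    # Asp and Glu dipeptides, IR/Raman populations.
    rows += [
        R("di-ASA", "N", "PPII", 0.43, source="grdadolnik2011"),
        R("di-ASA", "N", "beta", 0.55, source="grdadolnik2011"),
        R("di-ASA", "N", "alpha", 0.02, source="grdadolnik2011"),
        R("di-ASA", "I", "PPII", 0.49, source="grdadolnik2011"),
        R("di-ASA", "I", "beta", 0.46, source="grdadolnik2011"),
        R("di-ASA", "I", "alpha", 0.05, source="grdadolnik2011"),
        R("di-GA", "N", "PPII", 0.59, source="grdadolnik2011"),
        R("di-GA", "N", "beta", 0.36, source="grdadolnik2011"),
        R("di-GA", "N", "alpha", 0.05, source="grdadolnik2011"),
        R("di-GA", "I", "PPII", 0.47, source="grdadolnik2011"),
        R("di-GA", "I", "beta", 0.48, source="grdadolnik2011"),
        R("di-GA", "I", "alpha", 0.05, source="grdadolnik2011"),
    ]
    # Ionized PGA; the two sources disagree on the alpha-helix content and
    # are both retained with their citation keys.
    rows += [
        R("PGA", "I", "PPII", 0.40, source="uvrr"),
        R("PGA", "I", "3.10", 0.09, source="uvrr"),
        R("PGA", "I", "alpha", 0.20, bound="lt", source="uvrr"),
        R("PGA", "I", "alpha+beta", 0.51, source="uvrr"),
        R("PGA", "I", "beta", 0.42, source="cd_ftir"),
        R("PGA", "I", "alpha", 0.01, approximate=True, source="cd_ftir"),
    ]
    return tuple(rows)


def load_reference() -> ReferenceTable:
    """The packaged experimental reference table."""
    return ReferenceTable(rows=_rows())


@dataclass
class ComparisonRow:
    conformation: str
    computed: float
    computed_sd: float
    reference: float
    bound: str
    deviation: float | None      # |computed - reference| for value rows
    within_bound: bool | None    # for bound rows
    source: str


@dataclass
class ComparisonReport:
    molecule: str
    protonation: str
    rows: list

    def to_dict(self) -> dict:
        return {"molecule": self.molecule, "protonation": self.protonation,
                "rows": [r.__dict__ for r in self.rows]}


#: Computed-state labels feeding each reference conformation.  The alpha
#: row compares against the right-handed helical basin.
_CONFORMATION_STATES = {
    "PPII": ("PPII",),
    "beta": ("beta",),
    "3.10": ("3.10",),
    "alpha": ("alphaR",),
    "alpha+beta": ("alphaR", "beta"),
}


def compare_to_reference(fractions: FractionTable, molecule: str,
                         protonation: str = "I",
                         reference: ReferenceTable | None = None,
                         ) -> ComparisonReport:
    """Compare computed state fractions against the experimental table.

    Value rows report the absolute deviation; bound rows a directional
    pass/fail.  Conformations absent from both the computed table and the
    reference are skipped.
    """
    reference = reference or load_reference()
    ref_rows = reference.select(molecule, protonation)
    if not ref_rows:
        raise KeyError(f"no reference rows for {molecule} ({protonation})")
    out = []
    for row in ref_rows:
        states = _CONFORMATION_STATES[row.conformation]
        if not all(s in fractions.fractions for s in states):
            continue
        computed = sum(fractions.fractions[s] for s in states)
        sd = sum(fractions.errors.get(s, 0.0) for s in states)
        if row.bound == "lt":
            out.append(ComparisonRow(row.conformation, computed, sd, row.value,
                                     "lt", None, computed < row.value, row.source))
        else:
            out.append(ComparisonRow(row.conformation, computed, sd, row.value,
                                     "eq", abs(computed - row.value), None,
                                     row.source))
    return ComparisonReport(molecule=molecule, protonation=protonation, rows=out)
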