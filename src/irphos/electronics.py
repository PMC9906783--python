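"""Ligand electronic descriptors (the tight-binding / DFT feature family).

Each ligand carries six descriptors — HOMO and LUMO energies, vertical
ionization potential (IP) and electron affinity (EA), all in eV, and the
Mulliken partial charges of its two metal-coordinating atoms in atomic units.
A complex is featurized as the 12-vector [CN block | NN block] where each
block is (HOMO, LUMO, IP, EA, donor1 charge, donor2 charge); for CN ligands
donor1 is the carbon and donor2 the nitrogen, for NN ligands donor1/donor2
follow the ligand record's coordinating-atom order (N1, N2).

Computing these numbers ab initio is outside this package; ``ingest_external``
defines the boundary contract for engine output, and the synthetic-data
generator produces statistically realistic tables for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import ComplexRecord, LigandLibrary
from .periodic import HARTREE_EV
from .racs import FeatureVector

_BLOCK_FIELDS = ("homo", "lumo", "ip", "ea", "donor1_charge", "donor2_charge")


@dataclass(frozen=True)
class LigandElectronics:
    homo: float          # eV
    lumo: float          # eV
    ip: float            # eV
    ea: float            # eV
    donor1_charge: float  # a.u.
    donor2_charge: float  # a.u.

    def violations(self) -> list[str]:
        out = []
        vals = [self.homo, self.lumo, self.ip, self.ea,
                self.donor1_charge, self.donor2_charge]
        if any(not math.isfinite(v) for v in vals):
            out.append("non-finite entry")
        elif self.homo >= self.lumo:
            out.append(f"HOMO ({self.homo}) >= LUMO ({self.lumo})")
        return out


class ElectronicFeatureTable:
    """Per-ligand electronic descriptors keyed by ligand id."""

    def __init__(self, records: dict[str, LigandElectronics], provenance: str = "synthetic"):
        self.records = dict(records)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, ligand_id: str) -> bool:
        return ligand_id in self.records

    def get(self, ligand_id: str) -> LigandElectronics:
        try:
            return self.records[ligand_id]
        except KeyError:
            raise KeyError(
                f"no electronic descriptors for ligand {ligand_id!r}"
            ) from None

    # -- I/O ----------------------------------------------------------------

    COLUMNS = [
        "ligand_id", "role", "homo_eV", "lumo_eV", "ip_eV", "ea_eV",
        "donor1_charge_au", "donor2_charge_au", "provenance",
    ]

    def to_frame(self, library: Optional[LigandLibrary] = None) -> pd.DataFrame:
        rows = []
        for lid, rec in self.records.items():
            role = ""
            if library is not None:
                try:
                    role = library.get(lid).role
                except KeyError:
                    pass
            rows.append(
                [lid, role, rec.homo, rec.lumo, rec.ip, rec.ea,
                 rec.donor1_charge, rec.donor2_charge, self.provenance]
            )
        return pd.DataFrame(rows, columns=self.COLUMNS)

    def write_csv(self, path: str | Path, library: Optional[LigandLibrary] = None) -> None:
        self.to_frame(library).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ElectronicFeatureTable":
        df = pd.read_csv(path)
        records = {
            str(row.ligand_id): LigandElectronics(
                homo=float(row.homo_eV),
                lumo=float(row.lumo_eV),
                ip=float(row.ip_eV),
                ea=float(row.ea_eV),
                donor1_charge=float(row.donor1_charge_au),
                donor2_charge=float(row.donor2_charge_au),
            )
            for row in df.itertuples()
        }
        provenance = str(df["provenance"].iloc[0]) if len(df) else "unknown"
        return cls(records, provenance=provenance)


def electronic_feature_names() -> list[str]:
    return [f"el_CN_{f}" for f in _BLOCK_FIELDS] + [f"el_NN_{f}" for f in _BLOCK_FIELDS]


def complex_electronic_features(
    complex_: ComplexRecord, table: ElectronicFeatureTable
) -> FeatureVector:
    """12-vector of ligand electronic descriptors, CN block then NN block."""
    missing = [lid for lid in (complex_.cn_id, complex_.nn_id) if lid not in table]
    if missing:
        raise KeyError(f"no electronic descriptors for ligand(s) {missing}")
    values = []
    for lid in (complex_.cn_id, complex_.nn_id):
        rec = table.get(lid)
        values.extend([rec.homo, rec.lumo, rec.ip, rec.ea,
                       rec.donor1_charge, rec.donor2_charge])
    return FeatureVector(electronic_feature_names(), np.array(values))


def validate_table(
    table: ElectronicFeatureTable,
    library: LigandLibrary,
    strict: bool = False,
) -> list[str]:
    """Report missing ligands, HOMO/LUMO ordering violations, non-finite entries."""
    report: list[str] = []
    for lid in library.ids():
        if lid not in table:
            report.append(f"missing ligand: {lid}")
    for lid, rec in table.records.items():
        for v in rec.violations():
            report.append(f"{lid}: {v}")
    if strict and report:
        raise ValueError("electronic table validation failed:\n" + "\n".join(report))
    return report


def ingest_external(
    raw_records: list[dict],
    library: LigandLibrary,
    provenance: str = "xtb",
) -> ElectronicFeatureTable:
    """Normalize engine output into an electronic feature table.

    Each raw record needs: ligand_id, unit ("eV" or "hartree"), homo, lumo,
    ip, ea, and atom_charges (per-atom Mulliken charges, a.u., in the ligand's
    atom order).  Donor charges are picked out via the ligand's coordinating
    atom indices; for CN ligands the carbon is reported first.
    """
    records: dict[str, LigandElectronics] = {}
    for raw in raw_records:
        lid = raw["ligand_id"]
        unit = raw.get("unit")
        if unit not in ("eV", "hartree"):
            raise ValueError(f"{lid}: missing or unknown energy unit tag {unit!r}")
        scale = 1.0 if unit == "eV" else HARTREE_EV
        lig = library.get(lid)
        charges = raw["atom_charges"]
        idx = list(lig.coordinating_atoms)
        if any(i >= len(charges) for i in idx):
            raise ValueError(f"{lid}: coordinating atom index out of charge-array range")
        if lig.role == "CN":
            # carbon first, nitrogen second
            idx.sort(key=lambda i: lig.graph.atoms[i].element != "C")
        records[lid] = LigandElectronics(
            homo=raw["homo"] * scale,
            lumo=raw["lumo"] * scale,
            ip=raw["ip"] * scale,
            ea=raw["ea"] * scale,
            donor1_charge=charges[idx[0]],
            donor2_charge=charges[idx[1]],
        )
    return ElectronicFeatureTable(records, provenance=provenance)
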