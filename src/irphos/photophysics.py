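"""Radiative rates and Boltzmann-averaged phosphorescence lifetimes.

Spin-orbit coupling splits the emitting triplet T1 of an iridium phosphor
into three sublevels (zero-field splitting).  Given each sublevel's
excitation energy dE_i and transition dipole M^i (both in atomic units, from
a SOC-TDDFT calculation), the radiative rate of sublevel i is the standard
spontaneous-emission expression

    k_i = (4/3) * alpha^3 * dE_i^3 * sum_a |M_a^i|^2 / t0     [s^-1]

with alpha the fine-structure constant and t0 the atomic unit of time.  The
observable lifetime is the Boltzmann average over the thermally populated
sublevels,

    tau(T) = (1 + e^(-dE12/kT) + e^(-dE13/kT))
             / (k1 + k2 e^(-dE12/kT) + k3 e^(-dE13/kT)),

where dE12 and dE13 are the gaps from the lowest sublevel (T = 300 K by
default).  Nonradiative decay is deliberately excluded.  Solvent is accounted
for through the Strickler-Berg relationship: the vacuum lifetime is divided
by the squared refractive index (DMSO, n = 1.4793, by default).  The mean
emission energy proxy is the arithmetic mean of the three sublevel energies.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .periodic import (
    ATOMIC_TIME_S,
    BOLTZMANN_HARTREE_PER_K,
    DMSO_REFRACTIVE_INDEX,
    FINE_STRUCTURE,
    HARTREE_EV,
)


@dataclass(frozen=True)
class TripletSublevel:
    """One SOC sublevel: excitation energy (hartree) and transition dipole (a.u.)."""

    energy: float
    dipole: tuple[float, float, float]

    def __post_init__(self):
        if self.energy <= 0:
            raise ValueError(f"sublevel excitation energy must be > 0, got {self.energy}")
        if not all(math.isfinite(m) for m in self.dipole):
            raise ValueError("non-finite transition dipole component")

    @classmethod
    def from_ev(cls, energy_ev: float, dipole) -> "TripletSublevel":
        return cls(energy_ev / HARTREE_EV, tuple(dipole))


@dataclass
class TripletSublevelSet:
    """The three T1 sublevels, sorted ascending in energy."""

    sublevels: tuple[TripletSublevel, TripletSublevel, TripletSublevel]
    complex_id: str = ""

    def __post_init__(self):
        if len(self.sublevels) != 3:
            raise ValueError(
                f"exactly three sublevels required, got {len(self.sublevels)}"
            )
        self.sublevels = tuple(sorted(self.sublevels, key=lambda s: s.energy))

    @property
    def gaps(self) -> tuple[float, float]:
        """(dE_1,2, dE_1,3) in hartree."""
        e = [s.energy for s in self.sublevels]
        return (e[1] - e[0], e[2] - e[0])


def radiative_rate(sublevel: TripletSublevel) -> float:
    """Radiative rate of one sublevel in s^-1 (zero dipole -> rate 0)."""
    m2 = sum(m * m for m in sublevel.dipole)
    return (4.0 / 3.0) * FINE_STRUCTURE**3 * sublevel.energy**3 * m2 / ATOMIC_TIME_S


def sublevel_lifetime(sublevel: TripletSublevel) -> float:
    """tau_i = 1/k_i in seconds (inf for a dark sublevel)."""
    k = radiative_rate(sublevel)
    return math.inf if k == 0 else 1.0 / k


def boltzmann_lifetime(sset: TripletSublevelSet, temperature: float = 300.0) -> float:
    """Boltzmann-averaged radiative lifetime in seconds.

    Returns inf (non-emissive) when all three sublevels are dark.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    k = [radiative_rate(s) for s in sset.sublevels]
    d12, d13 = sset.gaps
    kt = BOLTZMANN_HARTREE_PER_K * temperature
    w = np.array([1.0, math.exp(-d12 / kt), math.exp(-d13 / kt)])
    denom = float(np.dot(w, k))
    if denom == 0.0:
        return math.inf
    return float(w.sum() / denom)


def strickler_berg_correct(
    tau_vacuum: float, refractive_index: float = DMSO_REFRACTIVE_INDEX
) -> float:
    """Solvent correction: divide the lifetime by the squared refractive index."""
    if refractive_index <= 0:
        raise ValueError("refractive index must be > 0")
    return tau_vacuum / refractive_index**2


def mean_emission_energy(sset: TripletSublevelSet) -> float:
    """Arithmetic mean of the three sublevel excitation energies, in eV."""
    return float(np.mean([s.energy for s in sset.sublevels])) * HARTREE_EV


# ---------------------------------------------------------------------------
# I/O


def read_sublevel_table(path: str | Path) -> list[TripletSublevelSet]:
    """Read the sublevel TSV contract.

    Columns: complex_id, sublevel, energy, unit ("hartree" or "eV"), mx, my,
    mz.  Exactly three rows per complex; energies in eV are converted.
    """
    groups: dict[str, list[TripletSublevel]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            unit = row["unit"].strip()
            energy = float(row["energy"])
            if unit == "eV":
                energy /= HARTREE_EV
            elif unit != "hartree":
                raise ValueError(f"unknown energy unit tag {unit!r}")
            dipole = (float(row["mx"]), float(row["my"]), float(row["mz"]))
            cid = row["complex_id"]
            if cid not in groups:
                groups[cid] = []
                order.append(cid)
            groups[cid].append(TripletSublevel(energy, dipole))
    out = []
    for cid in order:
        subs = groups[cid]
        if len(subs) != 3:
            raise ValueError(f"{cid}: expected 3 sublevels, got {len(subs)}")
        out.append(TripletSublevelSet(tuple(subs), complex_id=cid))
    return out


def lifetime_table(
    sets: Sequence[TripletSublevelSet],
    temperature: float = 300.0,
    refractive_index: float = DMSO_REFRACTIVE_INDEX,
) -> pd.DataFrame:
    """Per-complex rates (s^-1), solvent-corrected lifetime (us) and mean
    emission energy (eV)."""
    rows = []
    for sset in sets:
        k = [radiative_rate(s) for s in sset.sublevels]
        tau = boltzmann_lifetime(sset, temperature)
        tau_solv = strickler_berg_correct(tau, refractive_index)
        rows.append(
            {
                "complex_id": sset.complex_id,
                "k1_s": k[0],
                "k2_s": k[1],
                "k3_s": k[2],
                "lifetime_us": tau_solv * 1e6,
                "mean_emission_eV": mean_emission_energy(sset),
            }
        )
    return pd.DataFrame(rows)
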