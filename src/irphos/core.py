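"""Molecular graphs, ligands and octahedral [Ir(CN)2(NN)]+ complexes.

The chemistry handled here is deliberately narrow: bidentate ligands that bind
iridium either through one carbon and one nitrogen (cyclometalating, "CN") or
through two nitrogens (ancillary, "NN"), and the homoleptic-in-CN complexes
[Ir(CN)2(NN)]+ assembled from them.  CN ligands are stored in their neutral,
protonated form; assembly removes the proton on the coordinating carbon, so a
complex built from two neutral CN ligands and a neutral NN ligand carries an
overall +1 charge (Ir(III) +3, two cyclometalated carbanions -1 each).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx
import numpy as np

from . import periodic

Role = Literal["CN", "NN"]

#: Ir-donor bond length used by the idealized octahedral placement (Angstrom)
IR_DONOR_BOND = 2.0


class UnsupportedLigandError(ValueError):
    """Raised when coordinating atoms do not define a CN or NN ligand."""


@dataclass(frozen=True)
class AtomNode:
    """One vertex of a molecular graph with its heuristic properties."""

    element: str
    partial_charge: Optional[float] = None

    @property
    def atomic_number(self) -> int:
        return periodic.atomic_number(self.element)

    @property
    def electronegativity(self) -> float:
        return periodic.electronegativity(self.element)

    @property
    def covalent_radius(self) -> float:
        return periodic.covalent_radius(self.element)

    @property
    def group_number(self) -> int:
        return periodic.group_number(self.element)


class MolecularGraph:
    """Connectivity-only molecular graph (optionally with 3D coordinates).

    Edges are unweighted: no bond order or length information enters the graph
    itself; geometry, when present, lives in ``coordinates``.
    """

    def __init__(
        self,
        atoms: Sequence[AtomNode],
        bonds: Iterable[tuple[int, int]],
        coordinates: Optional[np.ndarray] = None,
        parent_degrees: Optional[Sequence[int]] = None,
    ):
        self.atoms = list(atoms)
        n = len(self.atoms)
        norm = set()
        for i, j in bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            norm.add((min(i, j), max(i, j)))
        self.bonds: frozenset[tuple[int, int]] = frozenset(norm)
        if coordinates is not None:
            coordinates = np.asarray(coordinates, dtype=float)
            if coordinates.shape != (n, 3):
                raise ValueError("coordinates must be (n_atoms, 3)")
        self.coordinates = coordinates
        self._degrees = [0] * n
        for i, j in self.bonds:
            self._degrees[i] += 1
            self._degrees[j] += 1
        # degree of each atom in the structure this graph was cut from; for a
        # free-standing graph that is the graph itself
        self.parent_degrees = (
            list(parent_degrees) if parent_degrees is not None else list(self._degrees)
        )

    # -- basic queries ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degree(self, i: int) -> int:
        return self._degrees[i]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return True
        return nx.is_connected(self.to_networkx())

    def distance_matrix(self) -> np.ndarray:
        """All-pairs shortest-path (bond-count) distances; -1 if unreachable."""
        n = self.n_atoms
        dist = np.full((n, n), -1, dtype=int)
        g = self.to_networkx()
        for src, lengths in nx.all_pairs_shortest_path_length(g):
            for dst, d in lengths.items():
                dist[src, dst] = d
        return dist

    def subgraph(self, indices: Sequence[int]) -> "MolecularGraph":
        """Induced subgraph; parent degrees are inherited from this graph."""
        index = {old: new for new, old in enumerate(indices)}
        atoms = [self.atoms[i] for i in indices]
        bonds = [
            (index[i], index[j])
            for i, j in self.bonds
            if i in index and j in index
        ]
        coords = self.coordinates[list(indices)] if self.coordinates is not None else None
        parent = [self.parent_degrees[i] for i in indices]
        return MolecularGraph(atoms, bonds, coordinates=coords, parent_degrees=parent)


# ---------------------------------------------------------------------------
# ligands


@dataclass
class LigandRecord:
    ligand_id: str
    role: Role
    graph: MolecularGraph
    coordinating_atoms: tuple[int, int]
    formal_charge: int = 0
    smiles: Optional[str] = None

    def __post_init__(self):
        a, b = self.coordinating_atoms
        if a == b:
            raise UnsupportedLigandError("coordinating atoms must be distinct")
        expected = classify_ligand_role(self.graph, self.coordinating_atoms)
        if expected != self.role:
            raise UnsupportedLigandError(
                f"ligand {self.ligand_id}: coordinating atoms imply role "
                f"{expected}, record says {self.role}"
            )

    @property
    def donor_elements(self) -> tuple[str, str]:
        a, b = self.coordinating_atoms
        return (self.graph.atoms[a].element, self.graph.atoms[b].element)


def classify_ligand_role(
    graph: MolecularGraph, coordinating_atoms: Sequence[int]
) -> Role:
    """CN if the two donors are {C, N}, NN if {N, N}; anything else errors."""
    if len(coordinating_atoms) != 2:
        raise UnsupportedLigandError(
            f"expected exactly 2 coordinating atoms, got {len(coordinating_atoms)}"
        )
    elems = sorted(graph.atoms[i].element for i in coordinating_atoms)
    if elems == ["C", "N"]:
        return "CN"
    if elems == ["N", "N"]:
        return "NN"
    raise UnsupportedLigandError(
        f"coordinating atom elements {elems} do not define a CN or NN ligand"
    )


@dataclass
class LigandLibrary:
    cn_ligands: list[LigandRecord] = field(default_factory=list)
    nn_ligands: list[LigandRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [l.ligand_id for l in self.cn_ligands + self.nn_ligands]
        if len(ids) != len(set(ids)):
            raise ValueError("ligand ids must be unique within a library")
        for lig in self.cn_ligands:
            if lig.role != "CN":
                raise ValueError(f"{lig.ligand_id} in CN partition but role {lig.role}")
        for lig in self.nn_ligands:
            if lig.role != "NN":
                raise ValueError(f"{lig.ligand_id} in NN partition but role {lig.role}")

    def __len__(self) -> int:
        return len(self.cn_ligands) + len(self.nn_ligands)

    def get(self, ligand_id: str) -> LigandRecord:
        for lig in self.cn_ligands + self.nn_ligands:
            if lig.ligand_id == ligand_id:
                return lig
        raise KeyError(f"unknown ligand id {ligand_id!r}")

    def ids(self) -> list[str]:
        return [l.ligand_id for l in self.cn_ligands + self.nn_ligands]

    def union(self, other: "LigandLibrary") -> "LigandLibrary":
        overlap = set(self.ids()) & set(other.ids())
        if overlap:
            raise ValueError(f"ligand id collision: {sorted(overlap)}")
        return LigandLibrary(
            cn_ligands=self.cn_ligands + other.cn_ligands,
            nn_ligands=self.nn_ligands + other.nn_ligands,
        )


# ---------------------------------------------------------------------------
# complexes


@dataclass
class LigandInstance:
    """One ligand copy inside an assembled complex."""

    ligand_id: str
    role: Role
    atom_indices: list[int]          # whole-graph indices of this copy's atoms
    donor_indices: tuple[int, int]   # whole-graph indices of the two donors
    donor_sites: tuple[str, str]     # "eq" / "ax" octahedral site class per donor


@dataclass
class ComplexRecord:
    complex_id: str
    cn_id: str
    nn_id: str
    overall_charge: int
    whole_graph: MolecularGraph
    ir_index: int
    ligand_instances: list[LigandInstance]
    properties: Optional[dict[str, float]] = None

    def __post_init__(self):
        if self.whole_graph.degree(self.ir_index) != 6:
            raise ValueError(
                f"{self.complex_id}: Ir vertex degree is "
                f"{self.whole_graph.degree(self.ir_index)}, expected 6"
            )
        if self.properties is not None:
            for key, val in self.properties.items():
                if val is not None and val < 0:
                    raise ValueError(f"{self.complex_id}: property {key} < 0")


def _strip_donor_proton(lig: LigandRecord) -> tuple[MolecularGraph, tuple[int, int]]:
    """Remove one H bonded to the coordinating carbon of a CN ligand."""
    g = lig.graph
    a, b = lig.coordinating_atoms
    carbon = a if g.atoms[a].element == "C" else b
    h_index = None
    for i, j in g.bonds:
        other = None
        if i == carbon and g.atoms[j].element == "H":
            other = j
        elif j == carbon and g.atoms[i].element == "H":
            other = i
        if other is not None:
            h_index = other
            break
    if h_index is None:
        raise UnsupportedLigandError(
            f"ligand {lig.ligand_id}: coordinating carbon carries no proton to "
            "remove on assembly (CN ligands must be supplied protonated)"
        )
    keep = [i for i in range(g.n_atoms) if i != h_index]
    remap = {old: new for new, old in enumerate(keep)}
    sub = g.subgraph(keep)
    # the deprotonated-carbon degree in the parent should not count the lost H
    sub.parent_degrees = list(sub._degrees)
    return sub, (remap[a], remap[b])


# octahedral template: NN spans +x/+y equatorial; each CN puts its carbon in
# the equatorial plane and its nitrogen on an axial site
_SITE_DIRECTIONS = {
    "nn1": np.array([1.0, 0.0, 0.0]),
    "nn2": np.array([0.0, 1.0, 0.0]),
    "cnA_eq": np.array([-1.0, 0.0, 0.0]),
    "cnA_ax": np.array([0.0, 0.0, 1.0]),
    "cnB_eq": np.array([0.0, -1.0, 0.0]),
    "cnB_ax": np.array([0.0, 0.0, -1.0]),
}


def _rigid_place(
    coords: np.ndarray,
    donors: tuple[int, int],
    targets: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Rigidly move a ligand so its donors sit on two template sites.

    The transform maps the donor midpoint onto the target midpoint, the donor
    axis onto the target axis, and pushes the ligand body away from the metal;
    exact octahedral geometry is not attempted (connectivity features never see
    it, only the Coulomb-decay ones do, and those need only sane distances).
    """
    d1, d2 = donors
    t1, t2 = targets
    src_mid = (coords[d1] + coords[d2]) / 2.0
    tgt_mid = (t1 + t2) / 2.0

    def frame(axis_vec, out_vec):
        ax = axis_vec / (np.linalg.norm(axis_vec) + 1e-12)
        out = out_vec - np.dot(out_vec, ax) * ax
        nrm = np.linalg.norm(out)
        if nrm < 1e-9:  # degenerate: pick any perpendicular
            out = np.array([ax[1] - ax[2], ax[2] - ax[0], ax[0] - ax[1]])
            out -= np.dot(out, ax) * ax
            nrm = np.linalg.norm(out)
        out /= nrm
        return np.stack([ax, out, np.cross(ax, out)])

    centroid = coords.mean(axis=0)
    src = frame(coords[d2] - coords[d1], centroid - src_mid)
    tgt = frame(t2 - t1, tgt_mid)  # push body outward from the metal at origin
    rot = tgt.T @ src
    return (coords - src_mid) @ rot.T + tgt_mid


def assemble_complex(
    cn: LigandRecord, nn: LigandRecord, properties: Optional[dict[str, float]] = None
) -> ComplexRecord:
    """Assemble [Ir(CN)2(NN)]+ from one CN type (used twice) and one NN ligand."""
    if cn.role != "CN":
        raise UnsupportedLigandError(f"{cn.ligand_id} is not a CN ligand")
    if nn.role != "NN":
        raise UnsupportedLigandError(f"{nn.ligand_id} is not an NN ligand")

    cn_graph, cn_donors = _strip_donor_proton(cn)
    atoms: list[AtomNode] = [AtomNode("Ir")]
    bonds: list[tuple[int, int]] = []
    parent_degrees: list[int] = [6]
    instances: list[LigandInstance] = []
    coords_blocks: list[Optional[np.ndarray]] = [np.zeros((1, 3))]

    def donor_order(graph, donors, first_element):
        a, b = donors
        if graph.atoms[a].element == first_element:
            return a, b
        return b, a

    have_coords = cn.graph.coordinates is not None and nn.graph.coordinates is not None

    def add_ligand(graph, donors, lig, sites, site_keys):
        offset = len(atoms)
        atoms.extend(graph.atoms)
        bonds.extend((i + offset, j + offset) for i, j in graph.bonds)
        # inside the complex each donor gains the Ir bond
        pdeg = list(graph.parent_degrees)
        for d in donors:
            pdeg[d] += 1
        parent_degrees.extend(pdeg)
        d_global = (donors[0] + offset, donors[1] + offset)
        bonds.append((0, d_global[0]))
        bonds.append((0, d_global[1]))
        instances.append(
            LigandInstance(
                ligand_id=lig.ligand_id,
                role=lig.role,
                atom_indices=list(range(offset, offset + graph.n_atoms)),
                donor_indices=d_global,
                donor_sites=sites,
            )
        )
        if have_coords:
            targets = tuple(
                IR_DONOR_BOND * _SITE_DIRECTIONS[k] for k in site_keys
            )
            coords_blocks.append(_rigid_place(graph.coordinates, donors, targets))
        else:
            coords_blocks.append(None)

    # two CN copies: carbon equatorial, nitrogen axial
    for tag in ("A", "B"):
        c_idx, n_idx = donor_order(cn_graph, cn_donors, "C")
        add_ligand(
            cn_graph,
            (c_idx, n_idx),
            cn,
            sites=("eq", "ax"),
            site_keys=(f"cn{tag}_eq", f"cn{tag}_ax"),
        )
    add_ligand(
        nn.graph,
        nn.coordinating_atoms,
        nn,
        sites=("eq", "eq"),
        site_keys=("nn1", "nn2"),
    )

    overall_charge = 3 + 2 * (cn.formal_charge - 1) + nn.formal_charge
    coordinates = (
        np.vstack(coords_blocks) if have_coords else None
    )
    graph = MolecularGraph(
        atoms, bonds, coordinates=coordinates, parent_degrees=parent_degrees
    )
    complex_id = f"[Ir({cn.ligand_id})2({nn.ligand_id})]{overall_charge:+d}"
    return ComplexRecord(
        complex_id=complex_id,
        cn_id=cn.ligand_id,
        nn_id=nn.ligand_id,
        overall_charge=overall_charge,
        whole_graph=graph,
        ir_index=0,
        ligand_instances=instances,
        properties=properties,
    )


def enumerate_combinatorial(library: LigandLibrary) -> list[ComplexRecord]:
    """All CN x NN pairings, CN index major, NN index minor."""
    out = []
    for cn in library.cn_ligands:
        for nn in library.nn_ligands:
            out.append(assemble_complex(cn, nn))
    return out


def enumerate_hypothetical(
    hls: LigandLibrary, novel: LigandLibrary
) -> list[ComplexRecord]:
    """All pairings over the union library that use at least one novel ligand."""
    union = hls.union(novel)  # raises on id collision
    hls_cn = {l.ligand_id for l in hls.cn_ligands}
    hls_nn = {l.ligand_id for l in hls.nn_ligands}
    out = []
    for cn in union.cn_ligands:
        for nn in union.nn_ligands:
            if cn.ligand_id in hls_cn and nn.ligand_id in hls_nn:
                continue
            out.append(assemble_complex(cn, nn))
    return out


# ---------------------------------------------------------------------------
# rdkit / file ingestion


def graph_from_rdkit(mol, with_coordinates: bool = False) -> MolecularGraph:
    """Convert an RDKit molecule (hydrogens made explicit) to a graph."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    molH = Chem.AddHs(mol)
    if with_coordinates:
        AllChem.Compute2DCoords(molH)
    atoms = [AtomNode(a.GetSymbol()) for a in molH.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in molH.GetBonds()
    ]
    coords = None
    if with_coordinates:
        conf = molH.GetConformer()
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, 0.0]
             for i in range(molH.GetNumAtoms())]
        )
    return MolecularGraph(atoms, bonds, coordinates=coords)


def ligand_from_smiles(
    ligand_id: str,
    smiles: str,
    coordinating_atoms: tuple[int, int],
    formal_charge: int = 0,
    with_coordinates: bool = True,
) -> LigandRecord:
    """Build a ligand record from SMILES (indices refer to SMILES atom order)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"ligand {ligand_id}: could not parse SMILES {smiles!r}")
    graph = graph_from_rdkit(mol, with_coordinates=with_coordinates)
    role = classify_ligand_role(graph, coordinating_atoms)
    return LigandRecord(
        ligand_id=ligand_id,
        role=role,
        graph=graph,
        coordinating_atoms=tuple(coordinating_atoms),
        formal_charge=formal_charge,
        smiles=smiles,
    )


def read_xyz_with_bonds(xyz_path: str | Path, bonds_path: str | Path) -> MolecularGraph:
    """Standard XYZ plus an adjacency sidecar of 0-based ``i j`` pairs per line."""
    lines = Path(xyz_path).read_text().splitlines()
    n = int(lines[0].split()[0])
    atoms, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        atoms.append(AtomNode(parts[0]))
        coords.append([float(x) for x in parts[1:4]])
    bonds = []
    for line in Path(bonds_path).read_text().splitlines():
        parts = line.split()
        if parts:
            bonds.append((int(parts[0]), int(parts[1])))
    return MolecularGraph(atoms, bonds, coordinates=np.array(coords))


def read_ligand_library(path: str | Path) -> LigandLibrary:
    """Library CSV: ligand_id, role, smiles, xyz_path, coordinating_atom_indices,
    formal_charge.  Indices are 0-based and semicolon-separated."""
    cn, nn = [], []
    base = Path(path).parent
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            donors = tuple(int(x) for x in row["coordinating_atom_indices"].split(";"))
            charge = int(row.get("formal_charge") or 0)
            if row.get("smiles"):
                lig = ligand_from_smiles(
                    row["ligand_id"], row["smiles"], donors, formal_charge=charge
                )
            else:
                graph = read_xyz_with_bonds(
                    base / row["xyz_path"], base / (row["xyz_path"] + ".bonds")
                )
                role = classify_ligand_role(graph, donors)
                lig = LigandRecord(row["ligand_id"], role, graph, donors, charge)
            if row["role"] != lig.role:
                raise UnsupportedLigandError(
                    f"{lig.ligand_id}: declared role {row['role']} but donors imply {lig.role}"
                )
            (cn if lig.role == "CN" else nn).append(lig)
    return LigandLibrary(cn_ligands=cn, nn_ligands=nn)


def write_ligand_library(library: LigandLibrary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["ligand_id", "role", "smiles", "xyz_path",
             "coordinating_atom_indices", "formal_charge"]
        )
        for lig in library.cn_ligands + library.nn_ligands:
            writer.writerow(
                [
                    lig.ligand_id,
                    lig.role,
                    lig.smiles or "",
                    "",
                    ";".join(str(i) for i in lig.coordinating_atoms),
                    lig.formal_charge,
                ]
            )
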