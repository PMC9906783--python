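"""Graph autocorrelation descriptors for ligands and whole complexes.

An autocorrelation at depth ``d`` sums, over ordered atom pairs (i, j) with i
in a start set and shortest-path distance(i, j) = d, either the product
``P_i * P_j`` or the difference ``P_i - P_j`` of a heuristic atomic property P.
Full-scope products therefore count each unordered pair twice, matching the
convention of the reference implementations.

Seven properties are used throughout: identity (I, constant 1), nuclear charge
(Z), Pauling electronegativity (chi), topology (T, degree in the graph being
featurized), covalent radius (S), group number (G) and bond count (NB, degree
of the atom in its parent structure — inside a complex a donor atom's NB
counts the bond to iridium, which is how NB and T carry distinct information).

The Coulomb-decay variants divide each pair term by the Euclidean distance
r_ij (depth-0 self terms are left undecayed), so geometry enters the otherwise
connectivity-only descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ComplexRecord, LigandRecord, MolecularGraph

PROPERTIES: tuple[str, ...] = ("I", "Z", "chi", "T", "S", "G", "NB")

Operation = Literal["product", "difference"]

#: depth ceilings: whole-complex scopes stop at 3, isolated ligands go to 4
D_MAX_COMPLEX = 3
D_MAX_LIGAND = 4


@dataclass
class FeatureVector:
    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.names)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def property_values(graph: MolecularGraph, prop: str) -> np.ndarray:
    """Vector of one heuristic property over all atoms of a graph."""
    if prop == "I":
        return np.ones(graph.n_atoms)
    if prop == "Z":
        return np.array([a.atomic_number for a in graph.atoms], dtype=float)
    if prop == "chi":
        return np.array([a.electronegativity for a in graph.atoms])
    if prop == "T":
        return np.array([graph.degree(i) for i in range(graph.n_atoms)], dtype=float)
    if prop == "S":
        return np.array([a.covalent_radius for a in graph.atoms])
    if prop == "G":
        return np.array([a.group_number for a in graph.atoms], dtype=float)
    if prop == "NB":
        return np.array(graph.parent_degrees, dtype=float)
    raise ValueError(f"unknown atomic property {prop!r}")


def _euclidean_matrix(graph: MolecularGraph) -> np.ndarray:
    if graph.coordinates is None:
        raise ValueError("graph has no coordinates; Coulomb-decay features need them")
    diff = graph.coordinates[:, None, :] - graph.coordinates[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def autocorrelation(
    graph: MolecularGraph,
    start_set: Sequence[int],
    operation: Operation,
    prop: str,
    depth: int,
    dist: Optional[np.ndarray] = None,
    decay: bool = False,
    rmat: Optional[np.ndarray] = None,
) -> float:
    """One autocorrelation value (see module docstring for the convention)."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if len(start_set) == 0:
        raise ValueError("start set must be non-empty")
    p = property_values(graph, prop)
    if dist is None:
        dist = graph.distance_matrix()
    start = np.asarray(list(start_set), dtype=int)
    mask = (dist[start, :] == depth).astype(float)
    if decay:
        if rmat is None:
            rmat = _euclidean_matrix(graph)
        r = rmat[start, :]
        with np.errstate(divide="ignore"):
            inv = np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0), 0.0)
        if depth == 0:
            # self terms are undecayed by convention
            inv = inv + (dist[start, :] == 0).astype(float) * (r == 0)
        weight = mask * inv
    else:
        weight = mask
    if operation == "product":
        return float(np.einsum("i,ij,j->", p[start], weight, p))
    if operation == "difference":
        diff = p[start][:, None] - p[None, :]
        return float((weight * diff).sum())
    raise ValueError(f"unknown operation {operation!r}")


# ---------------------------------------------------------------------------
# ligand-only descriptor set


def ligand_racs(
    cn: LigandRecord, nn: LigandRecord, d_max: int = D_MAX_LIGAND
) -> FeatureVector:
    """Full-scope product autocorrelations on the isolated CN and NN ligands.

    CN block first, then NN; 7 properties x depths 0..d_max per ligand, hence
    70 features at the default depth ceiling of 4.
    """
    names, values = [], []
    for tag, lig in (("CN", cn), ("NN", nn)):
        g = lig.graph
        dist = g.distance_matrix()
        all_atoms = range(g.n_atoms)
        for prop in PROPERTIES:
            for d in range(d_max + 1):
                names.append(f"lrac_{tag}_prod_{prop}_{d}")
                values.append(
                    autocorrelation(g, all_atoms, "product", prop, d, dist=dist)
                )
    return FeatureVector(names, np.array(values))


# ---------------------------------------------------------------------------
# whole-complex descriptor sets


def assign_ligand_planes(complex_: ComplexRecord) -> dict[str, dict[int, float]]:
    """Fractional axial/equatorial membership per ligand instance.

    A ligand's raw weight in a class is the fraction of its donors occupying
    sites of that class; weights are normalized to sum to one within the class.
    With the fixed template (NN donors both equatorial, each CN one equatorial
    + one axial) the CN ligands appear in both classes.
    """
    out: dict[str, dict[int, float]] = {"axial": {}, "equatorial": {}}
    for cls, tag in (("axial", "ax"), ("equatorial", "eq")):
        raw = {
            k: sum(1 for s in inst.donor_sites if s == tag) / len(inst.donor_sites)
            for k, inst in enumerate(complex_.ligand_instances)
        }
        total = sum(raw.values())
        out[cls] = {k: w / total for k, w in raw.items() if w > 0}
    return out


def _ligand_scope_value(
    complex_: ComplexRecord,
    weights: dict[int, float],
    operation: Operation,
    prop: str,
    depth: int,
    start: str,
    decay: bool,
    cache: dict,
) -> float:
    """Weighted average over ligand instances of a subgraph autocorrelation.

    ``start`` selects the start set: "donors" (ligand-centered) or "all"
    (whole-ligand full scope).
    """
    total = 0.0
    for k, w in weights.items():
        inst = complex_.ligand_instances[k]
        key = (k,)
        if key not in cache:
            sub = complex_.whole_graph.subgraph(inst.atom_indices)
            local = {g: i for i, g in enumerate(inst.atom_indices)}
            donors = [local[d] for d in inst.donor_indices]
            dist = sub.distance_matrix()
            rmat = _euclidean_matrix(sub) if decay else None
            cache[key] = (sub, donors, dist, rmat)
        sub, donors, dist, rmat = cache[key]
        if rmat is None and decay:
            rmat = _euclidean_matrix(sub)
            cache[key] = (sub, donors, dist, rmat)
        start_set = donors if start == "donors" else range(sub.n_atoms)
        total += w * autocorrelation(
            sub, start_set, operation, prop, depth, dist=dist, decay=decay, rmat=rmat
        )
    return total


def _complex_feature_table(
    complex_: ComplexRecord, decay: bool
) -> tuple[list[str], list[float]]:
    g = complex_.whole_graph
    if not any(a.element == "Ir" for a in g.atoms):
        raise ValueError(f"{complex_.complex_id}: no Ir vertex in whole graph")
    dist = g.distance_matrix()
    rmat = _euclidean_matrix(g) if decay else None
    planes = assign_ligand_planes(complex_)
    cache: dict = {}
    prefix = "cdrac" if decay else "rac"
    names: list[str] = []
    values: list[float] = []

    def whole(scope_tag, start_set, operation, prop, d):
        names.append(f"{prefix}_{scope_tag}_{operation[:4]}_{prop}_{d}")
        values.append(
            autocorrelation(
                g, start_set, operation, prop, d, dist=dist, decay=decay, rmat=rmat
            )
        )

    def lig(scope_tag, weights, operation, prop, d, start):
        names.append(f"{prefix}_{scope_tag}_{operation[:4]}_{prop}_{d}")
        values.append(
            _ligand_scope_value(
                complex_, weights, operation, prop, d, start, decay, cache
            )
        )

    all_atoms = range(g.n_atoms)
    metal = [complex_.ir_index]
    ax_w = planes["axial"]
    eq_w = planes["equatorial"]
    depths = range(D_MAX_COMPLEX + 1)

    if not decay:
        # connectivity set: 7 scope-operation grids x 7 properties x 4 depths = 196
        for prop in PROPERTIES:
            for d in depths:
                whole("f", all_atoms, "product", prop, d)
        for op in ("product", "difference"):
            for prop in PROPERTIES:
                for d in depths:
                    whole("mc", metal, op, prop, d)
        for scope_tag, w in (("ax", ax_w), ("eq", eq_w)):
            for op in ("product", "difference"):
                for prop in PROPERTIES:
                    for d in depths:
                        lig(scope_tag, w, op, prop, d, start="donors")
    else:
        # geometry-aware set: products over six scopes (adding per-role
        # whole-ligand blocks), differences over the three centered scopes with
        # identically-zero terms pruned -> 168 + 54 = 222
        for prop in PROPERTIES:
            for d in depths:
                whole("f", all_atoms, "product", prop, d)
        for prop in PROPERTIES:
            for d in depths:
                whole("mc", metal, "product", prop, d)
        for scope_tag, w in (("ax", ax_w), ("eq", eq_w)):
            for prop in PROPERTIES:
                for d in depths:
                    lig(scope_tag, w, "product", prop, d, start="donors")
        cn_keys = [
            k for k, inst in enumerate(complex_.ligand_instances) if inst.role == "CN"
        ]
        nn_keys = [
            k for k, inst in enumerate(complex_.ligand_instances) if inst.role == "NN"
        ]
        cn_w = {k: 1.0 / len(cn_keys) for k in cn_keys}
        nn_w = {k: 1.0 / len(nn_keys) for k in nn_keys}
        for scope_tag, w in (("ligcn", cn_w), ("lignn", nn_w)):
            for prop in PROPERTIES:
                for d in depths:
                    lig(scope_tag, w, "product", prop, d, start="all")
        # differences: skip depth 0 (P_i - P_i = 0) and the identity property
        # (P constant), both identically zero
        for scope_tag, w, kind in (
            ("mc", None, "metal"),
            ("ax", ax_w, "lig"),
            ("eq", eq_w, "lig"),
        ):
            for prop in PROPERTIES:
                if prop == "I":
                    continue
                for d in range(1, D_MAX_COMPLEX + 1):
                    if kind == "metal":
                        whole(scope_tag, metal, "difference", prop, d)
                    else:
                        lig(scope_tag, w, "difference", prop, d, start="donors")
    return names, values


def complex_racs(complex_: ComplexRecord) -> FeatureVector:
    """The 196-feature connectivity autocorrelation set for a whole complex."""
    names, values = _complex_feature_table(complex_, decay=False)
    return FeatureVector(names, np.array(values))


def cd_racs(complex_: ComplexRecord) -> FeatureVector:
    """The 222-feature Coulomb-decay autocorrelation set (requires coordinates)."""
    names, values = _complex_feature_table(complex_, decay=True)
    return FeatureVector(names, np.array(values))
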