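"""Morgan fingerprints and fingerprint-similarity feature sets.

Fingerprints are computed with RDKit on the isolated (neutral, protonated)
ligands, radius 3 and 2048 bits by default.  The similarity feature set for a
complex is the vector of Dice (or Tanimoto) similarities of its CN ligand to
every reference CN ligand, followed by its NN ligand against every reference
NN ligand; the reference schema is fixed at training time, which is what makes
the feature count drop when held-out ligands are excluded (83 -> 78 for the
five-ligand grouped split of an 60+23 library).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ComplexRecord, LigandLibrary, LigandRecord
from .racs import FeatureVector

DEFAULT_RADIUS = 3
DEFAULT_NBITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    nbits: int
    radius: int

    @property
    def popcount(self) -> int:
        return len(self.bits)


def morgan_fingerprint(
    ligand: LigandRecord, radius: int = DEFAULT_RADIUS, nbits: int = DEFAULT_NBITS
) -> Fingerprint:
    """Circular-substructure hash fingerprint of the isolated ligand."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    if ligand.smiles is None:
        raise ValueError(
            f"ligand {ligand.ligand_id} has no SMILES; Morgan fingerprints need "
            "perceived aromaticity and atom invariants"
        )
    mol = Chem.MolFromSmiles(ligand.smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"ligand {ligand.ligand_id}: empty or unparsable molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits, radius=radius)


def _check_compatible(a: Fingerprint, b: Fingerprint) -> None:
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """2|a&b| / (|a|+|b|); two empty fingerprints count as identical (1.0)."""
    _check_compatible(a, b)
    denom = a.popcount + b.popcount
    if denom == 0:
        return 1.0
    return 2.0 * len(a.bits & b.bits) / denom


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """|a&b| / |a|b|; two empty fingerprints count as identical (1.0)."""
    _check_compatible(a, b)
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


@dataclass
class SimilarityFeatureSchema:
    """Ordered reference ligand ids fixing the similarity feature layout."""

    reference_cn_ids: list[str]
    reference_nn_ids: list[str]
    metric: str = "dice"
    radius: int = DEFAULT_RADIUS
    nbits: int = DEFAULT_NBITS
    _cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.reference_cn_ids) + len(self.reference_nn_ids)

    @classmethod
    def from_library(
        cls,
        library: LigandLibrary,
        exclude: tuple[str, ...] = (),
        metric: str = "dice",
    ) -> "SimilarityFeatureSchema":
        """Schema over the library's ligands, minus any held-out ids."""
        return cls(
            reference_cn_ids=[
                l.ligand_id for l in library.cn_ligands if l.ligand_id not in exclude
            ],
            reference_nn_ids=[
                l.ligand_id for l in library.nn_ligands if l.ligand_id not in exclude
            ],
            metric=metric,
        )

    def _fp(self, ligand: LigandRecord) -> Fingerprint:
        if ligand.ligand_id not in self._cache:
            self._cache[ligand.ligand_id] = morgan_fingerprint(
                ligand, radius=self.radius, nbits=self.nbits
            )
        return self._cache[ligand.ligand_id]

    def feature_names(self) -> list[str]:
        return [f"{self.metric}_CN_{r}" for r in self.reference_cn_ids] + [
            f"{self.metric}_NN_{r}" for r in self.reference_nn_ids
        ]


def similarity_features(
    complex_: ComplexRecord,
    schema: SimilarityFeatureSchema,
    library: LigandLibrary,
) -> FeatureVector:
    """Similarity of the complex's ligands to every reference ligand."""
    sim = dice_similarity if schema.metric == "dice" else tanimoto_similarity
    cn_fp = schema._fp(library.get(complex_.cn_id))
    nn_fp = schema._fp(library.get(complex_.nn_id))
    values = [
        sim(cn_fp, schema._fp(library.get(rid))) for rid in schema.reference_cn_ids
    ] + [
        sim(nn_fp, schema._fp(library.get(rid))) for rid in schema.reference_nn_ids
    ]
    return FeatureVector(schema.feature_names(), np.array(values))


# kept under the name the field uses for this feature family
dice_features = similarity_features


def morgan_features(
    complex_: ComplexRecord,
    library: LigandLibrary,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> FeatureVector:
    """Concatenated CN and NN fingerprint bit vectors (2 * nbits columns)."""
    cn_fp = morgan_fingerprint(library.get(complex_.cn_id), radius, nbits)
    nn_fp = morgan_fingerprint(library.get(complex_.nn_id), radius, nbits)
    values = np.zeros(2 * nbits)
    for b in cn_fp.bits:
        values[b] = 1.0
    for b in nn_fp.bits:
        values[nbits + b] = 1.0
    names = [f"morgan_CN_{i}" for i in range(nbits)] + [
        f"morgan_NN_{i}" for i in range(nbits)
    ]
    return FeatureVector(names, values)
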