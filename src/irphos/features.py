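"""Feature-matrix assembly: one named family -> one DataFrame per dataset.

The eight representations compared by the workflow fall into three families:
graph autocorrelations (``rac``, ``ligand-rac``, ``cd-rac``), fingerprint /
similarity sets (``morgan``, ``dice``, ``tanimoto``) and ligand electronic
descriptors (``electronic`` — the consumer decides whether the table came
from tight binding, DFT or the synthetic generator).
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .core import ComplexRecord, LigandLibrary
from .electronics import ElectronicFeatureTable, complex_electronic_features
from .racs import cd_racs, complex_racs, ligand_racs
from .similarity import SimilarityFeatureSchema, morgan_features, similarity_features

FEATURE_SETS = (
    "rac", "ligand-rac", "cd-rac", "morgan", "dice", "tanimoto", "electronic",
)


def featurize_complexes(
    complexes: Sequence[ComplexRecord],
    feature_set: str,
    library: Optional[LigandLibrary] = None,
    electronics: Optional[ElectronicFeatureTable] = None,
    schema: Optional[SimilarityFeatureSchema] = None,
) -> pd.DataFrame:
    """Feature matrix indexed by complex id with a stable column order."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(
            f"unknown feature set {feature_set!r}; choose from {FEATURE_SETS}"
        )
    rows, index = [], []
    for c in complexes:
        if feature_set == "rac":
            fv = complex_racs(c)
        elif feature_set == "cd-rac":
            fv = cd_racs(c)
        elif feature_set == "ligand-rac":
            _need(library, "ligand-rac needs the ligand library")
            fv = ligand_racs(library.get(c.cn_id), library.get(c.nn_id))
        elif feature_set == "morgan":
            _need(library, "morgan needs the ligand library")
            fv = morgan_features(c, library)
        elif feature_set in ("dice", "tanimoto"):
            _need(library, f"{feature_set} needs the ligand library")
            if schema is None:
                schema = SimilarityFeatureSchema.from_library(
                    library, metric=feature_set
                )
            fv = similarity_features(c, schema, library)
        else:
            _need(electronics, "electronic needs a descriptor table")
            fv = complex_electronic_features(c, electronics)
        rows.append(fv.values)
        index.append(c.complex_id)
        names = fv.names
    return pd.DataFrame(rows, index=pd.Index(index, name="complex_id"), columns=names)


def ligand_id_frame(complexes: Sequence[ComplexRecord]) -> pd.DataFrame:
    """cn_id / nn_id lookup aligned with a feature matrix."""
    return pd.DataFrame(
        {"cn_id": [c.cn_id for c in complexes], "nn_id": [c.nn_id for c in complexes]},
        index=pd.Index([c.complex_id for c in complexes], name="complex_id"),
    )


def _need(obj, message: str) -> None:
    if obj is None:
        raise ValueError(message)
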