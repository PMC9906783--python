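"""Train/validation/test split protocols and the dim-complex filter.

Two protocols are provided.  The random split partitions complexes uniformly
(default 70/15/15).  The grouped split holds out every complex containing one
of a designated set of ligands, probing generalization to unseen ligand
chemistry; the held-out ligands are by default the most dissimilar ones in the
library as measured by mean Dice similarity of Morgan fingerprints to their
same-role peers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ComplexRecord, LigandLibrary
from .similarity import dice_similarity, morgan_fingerprint


@dataclass
class SplitSpec:
    mode: str                    # "random" | "grouped"
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int
    held_out_ligand_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("split partitions overlap")
        if self.mode == "grouped" and not self.held_out_ligand_ids:
            raise ValueError("grouped split requires a non-empty held-out ligand set")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "held_out_ligand_ids": self.held_out_ligand_ids,
            "train_ids": self.train_ids,
            "val_ids": self.val_ids,
            "test_ids": self.test_ids,
        }


def make_random_split(
    complex_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitSpec:
    """Disjoint exhaustive random partition; sizes are floors with the
    remainder assigned to the test partition (1380 at 70/15/15 -> 966/207/207)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(complex_ids)
    if n < 3:
        raise ValueError("need at least 3 complexes to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(fractions[0] * n + 1e-9))
    n_val = int(np.floor(fractions[1] * n + 1e-9))
    ids = np.asarray(complex_ids, dtype=object)
    return SplitSpec(
        mode="random",
        train_ids=list(ids[order[:n_train]]),
        val_ids=list(ids[order[n_train : n_train + n_val]]),
        test_ids=list(ids[order[n_train + n_val :]]),
        seed=seed,
    )


def make_grouped_split(
    complexes: Sequence[ComplexRecord],
    held_out_ligand_ids: Sequence[str],
    val_fraction: float = 0.15,
    seed: int = 0,
) -> SplitSpec:
    """Hold out every complex containing a designated ligand.

    The test set is exactly the held-out complexes; the remainder is split
    into train and validation.
    """
    held = set(held_out_ligand_ids)
    if not held:
        raise ValueError("held-out ligand set must be non-empty")
    test, rest = [], []
    for c in complexes:
        (test if (c.cn_id in held or c.nn_id in held) else rest).append(c.complex_id)
    if not rest:
        raise ValueError("held-out ligands cover the entire dataset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rest))
    n_val = int(np.floor(val_fraction * len(rest)))
    rest_arr = np.asarray(rest, dtype=object)
    return SplitSpec(
        mode="grouped",
        train_ids=list(rest_arr[order[n_val:]]),
        val_ids=list(rest_arr[order[:n_val]]),
        test_ids=test,
        seed=seed,
        held_out_ligand_ids=sorted(held),
    )


def select_dissimilar_ligands(
    library: LigandLibrary, k_cn: int, k_nn: int
) -> list[str]:
    """The k ligands per role with lowest mean Dice similarity to same-role
    peers; ties broken lexicographically by ligand id."""
    out: list[str] = []
    for ligands, k in ((library.cn_ligands, k_cn), (library.nn_ligands, k_nn)):
        if k > len(ligands):
            raise ValueError("k exceeds the number of ligands of that role")
        fps = {l.ligand_id: morgan_fingerprint(l) for l in ligands}
        scores = []
        for lig in ligands:
            peers = [
                dice_similarity(fps[lig.ligand_id], fps[o.ligand_id])
                for o in ligands
                if o.ligand_id != lig.ligand_id
            ]
            mean = float(np.mean(peers)) if peers else 0.0
            scores.append((mean, lig.ligand_id))
        scores.sort()
        out.extend(lid for _, lid in scores[:k])
    return out


def filter_dim(
    complexes: Sequence[ComplexRecord],
    target: str,
    threshold: float = 1e5,
) -> list[ComplexRecord]:
    """Drop dim complexes (spectral integral below threshold) when modeling
    emission energy or lifetime; spectral-integral models keep everything."""
    if target not in ("em5050", "lifetime"):
        return list(complexes)
    kept = []
    for c in complexes:
        if c.properties is None or "spectral_integral" not in c.properties:
            raise ValueError(f"{c.complex_id}: no spectral integral to filter on")
        if c.properties["spectral_integral"] >= threshold:
            kept.append(c)
    return kept
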