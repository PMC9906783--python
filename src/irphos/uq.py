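"""Latent-space distance uncertainty quantification and gated screening.

The uncertainty metric for a query is the mean Euclidean distance of its
last-hidden-layer embedding to its k nearest neighbors among the training-set
embeddings (k = 10 by default).  Distances are normalized so the largest
reference-set metric equals 1, and predictions are only trusted below a
cutoff placed ``n_sd`` standard deviations above the reference mean (2 by
default, capped at the normalization point).  Screening a library of
hypothetical complexes accepts a candidate only when every property model's
gate passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .regression import PhosphorPropertyResults


@dataclass
class CutoffPolicy:
    k: int = 10
    n_sd: float = 2.0
    max_cutoff: float = 1.0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("neighbor count k must be >= 1")
        if self.n_sd <= 0:
            raise ValueError("n_sd must be > 0")


@dataclass
class UQCalibration:
    normalization: float
    cutoff: float


@dataclass
class UQAssessment:
    raw_distance: float
    normalized_distance: float
    accepted: bool


def latent_embed(results: PhosphorPropertyResults, X: pd.DataFrame) -> np.ndarray:
    return results.latent(X)


def uq_distance(
    query_latents: np.ndarray, training_latents: np.ndarray, k: int = 10
) -> np.ndarray:
    """Mean Euclidean distance to the k nearest training latents, per query row."""
    query = np.atleast_2d(np.asarray(query_latents, dtype=float))
    train = np.asarray(training_latents, dtype=float)
    if len(train) < k:
        raise ValueError(
            f"need at least k={k} training latents, have {len(train)}"
        )
    nn = NearestNeighbors(n_neighbors=k).fit(train)
    dists, _ = nn.kneighbors(query)
    return dists.mean(axis=1)


def calibrate_cutoff(
    reference_distances: Sequence[float], policy: CutoffPolicy = CutoffPolicy()
) -> UQCalibration:
    """Normalization (max reference distance -> 1) and acceptance cutoff
    (reference mean + n_sd standard deviations, capped)."""
    ref = np.asarray(reference_distances, dtype=float)
    if len(ref) == 0:
        raise ValueError("reference distance set is empty")
    norm = float(ref.max())
    if norm <= 0:
        raise ValueError("degenerate reference set: all distances are zero")
    scaled = ref / norm
    cutoff = float(min(scaled.mean() + policy.n_sd * scaled.std(), policy.max_cutoff))
    return UQCalibration(normalization=norm, cutoff=cutoff)


def assess(
    raw_distances: Sequence[float], calibration: UQCalibration
) -> list[UQAssessment]:
    out = []
    for d in np.asarray(raw_distances, dtype=float):
        nd = d / calibration.normalization
        out.append(UQAssessment(float(d), float(nd), bool(nd <= calibration.cutoff)))
    return out


def error_vs_cutoff(
    results: PhosphorPropertyResults,
    X_test: pd.DataFrame,
    y_test,
    policy: CutoffPolicy = CutoffPolicy(),
    grid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """MAE and retained fraction over a grid of normalized-distance cutoffs.

    The test set itself is the normalization reference, as in the protocol
    this mirrors; empty bins carry NaN MAE.
    """
    y = np.asarray(y_test, dtype=float)
    lat = results.latent(X_test)
    raw = uq_distance(lat, results.training_latents, k=policy.k)
    norm = calibrate_cutoff(raw, policy).normalization
    nd = raw / norm
    err = np.abs(results.predict(X_test) - y)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 21)
    rows = []
    for c in grid:
        mask = nd <= c
        rows.append(
            {
                "cutoff": float(c),
                "retained_fraction": float(mask.mean()),
                "mae": float(err[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScreeningReport:
    """Per-candidate predictions, gates and the extreme-property bookkeeping."""

    table: pd.DataFrame
    calibrations: dict[str, UQCalibration]
    extremes: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    ligand_frequencies: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def accepted_ids(self) -> list[str]:
        return list(self.table.index[self.table["accepted"]])


def screen(
    features: pd.DataFrame,
    ligand_ids: pd.DataFrame,
    models: dict[str, PhosphorPropertyResults],
    policies: Optional[dict[str, CutoffPolicy]] = None,
    calibrations: Optional[dict[str, UQCalibration]] = None,
    reference_features: Optional[pd.DataFrame] = None,
    extreme_quantile: float = 0.025,
) -> ScreeningReport:
    """UQ-gated screening of hypothetical complexes.

    Parameters
    ----------
    features : feature matrix indexed by complex id.
    ligand_ids : DataFrame (same index) with ``cn_id`` and ``nn_id`` columns,
        used for the ligand frequency tables among extremes.
    models : one fitted ANN results object per target property.
    calibrations : per-target calibration; if absent it is computed from the
        distances of ``reference_features`` (typically the random-split test
        set of each model).
    extreme_quantile : tail fraction defining "extreme" predictions among the
        accepted candidates.
    """
    policies = policies or {}
    calibrations = dict(calibrations or {})
    table = pd.DataFrame(index=features.index)
    gates = []
    for target, results in models.items():
        policy = policies.get(target, CutoffPolicy())
        if target not in calibrations:
            if reference_features is None:
                raise ValueError(
                    f"no calibration for {target!r} and no reference features"
                )
            ref_raw = uq_distance(
                results.latent(reference_features),
                results.training_latents,
                k=policy.k,
            )
            calibrations[target] = calibrate_cutoff(ref_raw, policy)
        cal = calibrations[target]
        raw = uq_distance(
            results.latent(features), results.training_latents, k=policy.k
        )
        nd = raw / cal.normalization
        table[f"{target}_pred"] = results.predict(features)
        table[f"{target}_uq"] = nd
        gate = nd <= cal.cutoff
        table[f"{target}_accepted"] = gate
        gates.append(gate)
    table["accepted"] = np.logical_and.reduce(gates) if gates else False

    report = ScreeningReport(table=table, calibrations=calibrations)
    accepted = table[table["accepted"]]
    n_tail = max(int(round(extreme_quantile * len(accepted))), 1) if len(accepted) else 0
    for target in models:
        if n_tail == 0:
            report.extremes[target] = {"top": [], "bottom": []}
            report.ligand_frequencies[target] = pd.Series(dtype=int)
            continue
        ranked = accepted[f"{target}_pred"].sort_values()
        bottom = list(ranked.index[:n_tail])
        top = list(ranked.index[-n_tail:])
        report.extremes[target] = {"top": top, "bottom": bottom}
        ids = ligand_ids.loc[top + bottom]
        freq = pd.concat([ids["cn_id"], ids["nn_id"]]).value_counts()
        report.ligand_frequencies[target] = freq
    return report
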