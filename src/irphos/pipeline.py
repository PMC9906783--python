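"""End-to-end orchestration: simulate -> featurize -> split -> train -> UQ -> screen.

Every run writes a self-describing directory (resolved config snapshot, split
manifest, metrics, stage-tagged log), so any artifact can be regenerated from
the snapshot plus the master seed.  All randomness fans out from that one
seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .features import featurize_complexes, ligand_id_frame
from .regression import HyperparamSpace, PhosphorPropertyModel
from .splits import filter_dim, make_grouped_split, make_random_split
from .synthetic import SyntheticConfig, SyntheticDataset, TrendModel, make_dataset
from .uq import CutoffPolicy, error_vs_cutoff, screen, uq_distance, calibrate_cutoff

_SCHEMA = {
    "seed": None,
    "output_dir": None,
    "synthetic": {
        "n_cn", "n_nn", "n_ood_cn", "n_ood_nn", "ood_ip_shift",
        "ood_noise_scale", "grouped_emulation", "held_out_cn", "held_out_nn",
    },
    "feature_set": None,
    "target": None,
    "split": {"mode", "fractions", "val_fraction", "held_out_ligand_ids"},
    "model": {"kind", "budget", "ridge_alpha", "rf_n_estimators"},
    "uq": {"k", "n_sd", "max_cutoff"},
    "screen": {"extreme_quantile"},
}


def validate_config(config: dict) -> dict:
    """Reject unknown keys (naming them) and fill defaults."""
    for key, val in config.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key: {key!r}")
        allowed = _SCHEMA[key]
        if isinstance(allowed, set):
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            for sub in val:
                if sub not in allowed:
                    raise ValueError(f"unknown config key: {key}.{sub}")
    merged = {
        "seed": config.get("seed", 0),
        "output_dir": config.get("output_dir", "irphos_run"),
        "synthetic": dict(config.get("synthetic", {})),
        "feature_set": config.get("feature_set", "electronic"),
        "target": config.get("target", "em5050"),
        "split": {"mode": "random", "fractions": [0.70, 0.15, 0.15],
                  "val_fraction": 0.15, **config.get("split", {})},
        "model": {"kind": "ann", "budget": 0, **config.get("model", {})},
        "uq": dict(config.get("uq", {})),
        "screen": {"extreme_quantile": 0.025, **config.get("screen", {})},
    }
    return merged


_PROP_COLUMN = {
    "em5050": "em5050_eV",
    "lifetime": "lifetime_us",
    "spectral_integral": "spectral_integral_counts",
}


def run_pipeline(config: dict, dataset: Optional[SyntheticDataset] = None) -> Path:
    """Run the full workflow on synthetic data; returns the run directory."""
    cfg = validate_config(config)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "log.txt"
    log = open(log_path, "w")

    def stage(tag, msg):
        log.write(f"[{time.strftime('%H:%M:%S')}] [{tag}] {msg}\n")
        log.flush()

    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    s_data, s_split, s_fit = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    try:
        # -- simulate ----------------------------------------------------
        if dataset is None:
            stage("simulate", f"generating synthetic dataset (seed {s_data})")
            dataset = make_dataset(SyntheticConfig(**cfg["synthetic"]), seed=s_data)
        dataset.write(outdir / "data")
        target = cfg["target"]

        # -- featurize ---------------------------------------------------
        stage("featurize", f"feature set {cfg['feature_set']}")
        modeled = filter_dim(dataset.complexes, target)
        stage("featurize", f"{len(dataset.complexes) - len(modeled)} dim complexes filtered")
        X = featurize_complexes(
            modeled, cfg["feature_set"],
            library=dataset.library, electronics=dataset.electronics,
        )
        X.to_csv(outdir / "features.csv")
        props = dataset.properties.set_index("complex_id")

        # -- split -------------------------------------------------------
        mode = cfg["split"]["mode"]
        stage("split", f"{mode} split")
        if mode == "random":
            split = make_random_split(
                list(X.index), tuple(cfg["split"]["fractions"]), seed=s_split
            )
        elif mode == "grouped":
            held = cfg["split"].get("held_out_ligand_ids") or dataset.held_out_ligand_ids
            if not held:
                from .splits import select_dissimilar_ligands

                held = select_dissimilar_ligands(dataset.library, 3, 2)
            split = make_grouped_split(
                modeled, held, cfg["split"]["val_fraction"], seed=s_split
            )
        else:
            raise ValueError(f"unknown split mode {mode!r}")
        (outdir / "split.json").write_text(json.dumps(split.to_dict(), indent=2))

        # -- train -------------------------------------------------------
        kind = cfg["model"]["kind"]
        budget = int(cfg["model"].get("budget", 0))
        stage("train", f"{kind} on {target} (search budget {budget})")
        space = HyperparamSpace(budget=budget) if (kind == "ann" and budget) else None
        model = PhosphorPropertyModel.from_dataframe(
            X, dataset.properties, target, split, kind=kind, space=space
        )
        results = model.fit(seed=s_fit)
        results.save(outdir / "model")

        # -- evaluate ----------------------------------------------------
        col = _PROP_COLUMN[target]
        test_ids = [i for i in split.test_ids if i in X.index]
        metrics = results.evaluate(X.loc[test_ids], props.loc[test_ids, col])
        metrics["n_test"] = len(test_ids)
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        stage("evaluate", f"test MAE {metrics['mae']:.4g} "
                          f"(scaled {metrics['scaled_mae']:.4g})")
        (outdir / "summary.txt").write_text(results.summary() + "\n")

        # -- uq ----------------------------------------------------------
        if kind == "ann":
            stage("uq", "error-vs-cutoff table on the test set")
            policy = CutoffPolicy(**cfg["uq"])
            table = error_vs_cutoff(
                results, X.loc[test_ids], props.loc[test_ids, col], policy
            )
            table.to_csv(outdir / "uq.csv", index=False)

        # -- screen ------------------------------------------------------
        if kind == "ann" and dataset.ood_complexes:
            stage("screen", f"{len(dataset.ood_complexes)} hypothetical complexes")
            policy = CutoffPolicy(**cfg["uq"])
            Xh = featurize_complexes(
                dataset.ood_complexes, cfg["feature_set"],
                library=dataset.library.union(dataset.ood_library),
                electronics=dataset.merged_electronics(),
            )
            report = screen(
                Xh,
                ligand_id_frame(dataset.ood_complexes),
                models={target: results},
                policies={target: policy},
                reference_features=X.loc[test_ids],
                extreme_quantile=cfg["screen"]["extreme_quantile"],
            )
            report.table.to_csv(outdir / "screening.csv")
            freq = {
                t: s.to_dict() for t, s in report.ligand_frequencies.items()
            }
            (outdir / "ligand_frequencies.json").write_text(json.dumps(freq, indent=2))

        # -- snapshot ----------------------------------------------------
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg))
        stage("done", "all artifacts written")
    except Exception as exc:  # tag the failing stage in the log, then re-raise
        log.write(f"[FAILED] {type(exc).__name__}: {exc}\n")
        raise
    finally:
        log.close()
    return outdir


def compare_feature_sets(
    dataset: SyntheticDataset,
    feature_sets: Sequence[str],
    targets: Sequence[str],
    split_modes: Sequence[str] = ("random", "grouped"),
    kind: str = "ann",
    seed: int = 0,
) -> pd.DataFrame:
    """MAE / scaled MAE grid over (feature set, target, split mode)."""
    ss = np.random.SeedSequence(seed)
    s_split, s_fit = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    props = dataset.properties.set_index("complex_id")
    rows = []
    for fs in feature_sets:
        for target in targets:
            modeled = filter_dim(dataset.complexes, target)
            held = dataset.held_out_ligand_ids
            if not held and "grouped" in split_modes:
                from .splits import select_dissimilar_ligands

                held = select_dissimilar_ligands(dataset.library, 3, 2)
            for mode in split_modes:
                if mode == "grouped":
                    from .similarity import SimilarityFeatureSchema

                    schema = (
                        SimilarityFeatureSchema.from_library(
                            dataset.library, exclude=tuple(held), metric=fs
                        )
                        if fs in ("dice", "tanimoto")
                        else None
                    )
                    split = make_grouped_split(modeled, held, seed=s_split)
                else:
                    schema = None
                    split = make_random_split(
                        [c.complex_id for c in modeled], seed=s_split
                    )
                X = featurize_complexes(
                    modeled, fs, library=dataset.library,
                    electronics=dataset.electronics, schema=schema,
                )
                results = PhosphorPropertyModel.from_dataframe(
                    X, dataset.properties, target, split, kind=kind
                ).fit(seed=s_fit)
                col = _PROP_COLUMN[target]
                test_ids = [i for i in split.test_ids if i in X.index]
                metrics = results.evaluate(X.loc[test_ids], props.loc[test_ids, col])
                rows.append(
                    {
                        "feature_set": fs,
                        "target": target,
                        "split": mode,
                        "mae": metrics["mae"],
                        "scaled_mae": metrics["scaled_mae"],
                        "n_test": len(test_ids),
                    }
                )
    return pd.DataFrame(rows)
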