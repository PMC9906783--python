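"""Property regressors: ANN, random forest and ridge, in a Model/Results idiom.

``PhosphorPropertyModel`` holds the (already split) training data and model
configuration; ``fit()`` runs preprocessing, optional hyperparameter search
(validation-MAE selection followed by a refit on train+validation, the
protocol used for the experimental models) and returns a
``PhosphorPropertyResults`` carrying the fitted estimator, the preprocessor,
the training-set latent cache used for uncertainty quantification, metrics and
a ``summary()``.

All predictions are floored at zero: negative emission energies, lifetimes or
photon counts are unphysical.  The ANN backend is a multilayer perceptron
(Adam with early stopping); its last hidden layer is the latent space used by
the distance-based uncertainty metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor


@dataclass
class Preprocessor:
    """Column-wise standardization fit on train+validation; invariant
    (zero-variance) columns are dropped."""

    feature_names: list[str] = field(default_factory=list)
    mean_: Optional[np.ndarray] = None
    std_: Optional[np.ndarray] = None
    kept_: Optional[np.ndarray] = None
    dropped_names: list[str] = field(default_factory=list)

    def fit(self, X: pd.DataFrame) -> "Preprocessor":
        arr = X.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite feature values")
        std = arr.std(axis=0)
        # invariant up to float round-off counts as invariant
        tol = 1e-12 * np.maximum(1.0, np.abs(arr).max(axis=0))
        self.kept_ = np.flatnonzero(std > tol)
        self.dropped_names = [X.columns[i] for i in np.flatnonzero(std <= tol)]
        self.feature_names = [X.columns[i] for i in self.kept_]
        self.mean_ = arr[:, self.kept_].mean(axis=0)
        self.std_ = std[self.kept_]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        arr = X.to_numpy(dtype=float)[:, self.kept_]
        return (arr - self.mean_) / self.std_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.std_ + self.mean_

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "mean": self.mean_.tolist(),
            "std": self.std_.tolist(),
            "kept": self.kept_.tolist(),
            "dropped_names": self.dropped_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        p = cls()
        p.feature_names = d["feature_names"]
        p.mean_ = np.array(d["mean"])
        p.std_ = np.array(d["std"])
        p.kept_ = np.array(d["kept"], dtype=int)
        p.dropped_names = d["dropped_names"]
        return p


@dataclass
class HyperparamSpace:
    """Search ranges for the ANN.  Width and rates are sampled log-uniformly.

    The perceptron backend regularizes through the L2 penalty and early
    stopping; the dropout field is retained in the schema for configs written
    against backends that support it, and is ignored here.
    """

    n_layers: tuple[int, int] = (1, 3)
    width: tuple[int, int] = (32, 256)
    learning_rate: tuple[float, float] = (1e-4, 1e-2)
    l2: tuple[float, float] = (1e-6, 1e-2)
    batch_size: tuple[int, int] = (16, 128)
    dropout: tuple[float, float] = (0.0, 0.5)
    budget: int = 20

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("search budget must be >= 1")

    def sample(self, rng: np.random.Generator) -> dict:
        n_layers = int(rng.integers(self.n_layers[0], self.n_layers[1] + 1))
        def log_u(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        widths = tuple(
            int(round(log_u(self.width[0], self.width[1]))) for _ in range(n_layers)
        )
        return {
            "hidden_layer_sizes": widths,
            "learning_rate_init": log_u(*self.learning_rate),
            "alpha": log_u(*self.l2),
            "batch_size": int(round(log_u(self.batch_size[0], self.batch_size[1]))),
        }


_DEFAULT_ANN = {
    "hidden_layer_sizes": (64, 64),
    "learning_rate_init": 1e-3,
    "alpha": 1e-4,
    "batch_size": 32,
}

_MAX_EPOCHS = 2000
_PATIENCE = 100


def _make_mlp(params: dict, seed: int, n_obs: int, early_stopping: bool = True) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=params["hidden_layer_sizes"],
        learning_rate_init=params["learning_rate_init"],
        alpha=params["alpha"],
        batch_size=max(1, min(params["batch_size"], int(0.8 * n_obs))),
        solver="adam",
        activation="relu",
        max_iter=_MAX_EPOCHS,
        early_stopping=early_stopping,
        n_iter_no_change=_PATIENCE if early_stopping else 50,
        validation_fraction=0.1,
        random_state=seed,
    )


def _mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(y_true) - np.asarray(y_pred))))


class PhosphorPropertyModel:
    """A property regressor specified on split data, ready to ``fit()``.

    Parameters
    ----------
    X, y : training features (DataFrame, named columns) and target.
    kind : "ann", "rf" or "ridge".
    X_val, y_val : validation partition.  For the ANN it drives hyperparameter
        selection; for every kind it is folded into the final fit, and the
        preprocessor statistics are computed over train+validation.
    space : hyperparameter search space (ANN only; ``budget`` evaluations of
        random candidates judged by validation MAE).
    target : property name, carried through to results and summaries.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series | np.ndarray,
        kind: str = "ann",
        target: str = "em5050",
        X_val: Optional[pd.DataFrame] = None,
        y_val: Optional[pd.Series] = None,
        space: Optional[HyperparamSpace] = None,
        ridge_alpha: float = 1e-3,
        rf_n_estimators: int = 200,
    ):
        if kind not in ("ann", "rf", "ridge"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.X = X
        self.y = np.asarray(y, dtype=float)
        self.kind = kind
        self.target = target
        self.X_val = X_val
        self.y_val = None if y_val is None else np.asarray(y_val, dtype=float)
        self.space = space
        self.ridge_alpha = ridge_alpha
        self.rf_n_estimators = rf_n_estimators

    @classmethod
    def from_dataframe(
        cls,
        features: pd.DataFrame,
        properties: pd.DataFrame,
        target: str,
        split,
        kind: str = "ann",
        **kwargs,
    ) -> "PhosphorPropertyModel":
        """Build from a feature matrix and property table indexed by complex id.

        ``properties`` must hold a column named after the target (or its CSV
        alias); ``split`` is a SplitSpec whose train/val ids select the rows.
        """
        col = {
            "em5050": "em5050_eV",
            "lifetime": "lifetime_us",
            "spectral_integral": "spectral_integral_counts",
        }.get(target, target)
        props = properties.set_index("complex_id") if "complex_id" in properties else properties
        train_ids = [i for i in split.train_ids if i in features.index]
        val_ids = [i for i in split.val_ids if i in features.index]
        return cls(
            X=features.loc[train_ids],
            y=props.loc[train_ids, col],
            X_val=features.loc[val_ids] if val_ids else None,
            y_val=props.loc[val_ids, col] if val_ids else None,
            kind=kind,
            target=target,
            **kwargs,
        )

    # ------------------------------------------------------------------

    def fit(self, seed: int = 0) -> "PhosphorPropertyResults":
        if self.X_val is not None:
            X_all = pd.concat([self.X, self.X_val], axis=0)
            y_all = np.concatenate([self.y, self.y_val])
        else:
            X_all, y_all = self.X, self.y
        prep = Preprocessor().fit(X_all)

        chosen = None
        val_mae = None
        if self.kind == "ann":
            chosen = dict(_DEFAULT_ANN)
            if self.space is not None and self.X_val is not None:
                rng = np.random.default_rng(seed)
                Zt, Zv = prep.transform(self.X), prep.transform(self.X_val)
                best = np.inf
                for trial in range(self.space.budget):
                    params = self.space.sample(rng)
                    est = _make_mlp(params, seed=seed + trial, n_obs=len(Zt))
                    est.fit(Zt, self.y)
                    mae = _mae(self.y_val, np.clip(est.predict(Zv), 0, None))
                    if mae < best:
                        best, chosen = mae, params
                val_mae = best
            Z_all = prep.transform(X_all)
            # validation-R2 early stopping is undefined for a (near-)constant
            # target; fall back to loss-based stopping there
            es = float(np.std(y_all)) > 1e-12 * max(1.0, float(np.abs(y_all).max()))
            estimator = _make_mlp(chosen, seed=seed, n_obs=len(Z_all), early_stopping=es)
            estimator.fit(Z_all, y_all)
        elif self.kind == "rf":
            estimator = RandomForestRegressor(
                n_estimators=self.rf_n_estimators, random_state=seed, n_jobs=1
            )
            estimator.fit(prep.transform(X_all), y_all)
            chosen = {"n_estimators": self.rf_n_estimators}
        else:
            estimator = Ridge(alpha=self.ridge_alpha)
            estimator.fit(prep.transform(X_all), y_all)
            chosen = {"alpha": self.ridge_alpha}

        results = PhosphorPropertyResults(
            kind=self.kind,
            target=self.target,
            estimator=estimator,
            preprocessor=prep,
            hyperparams=chosen,
            seed=seed,
            n_train=len(X_all),
            y_fit_range=(float(np.min(y_all)), float(np.max(y_all))),
            val_mae=val_mae,
        )
        results.train_mae = results.evaluate(X_all, y_all)["mae"]
        if self.kind == "ann":
            results.training_latents = results.latent(X_all)
        return results


class PhosphorPropertyResults:
    """Fitted regressor with preprocessing, metrics and the latent cache."""

    def __init__(
        self,
        kind: str,
        target: str,
        estimator,
        preprocessor: Preprocessor,
        hyperparams: dict,
        seed: int,
        n_train: int,
        y_fit_range: tuple[float, float],
        val_mae: Optional[float] = None,
    ):
        self.kind = kind
        self.target = target
        self.estimator = estimator
        self.preprocessor = preprocessor
        self.hyperparams = hyperparams
        self.seed = seed
        self.n_train = n_train
        self.y_fit_range = y_fit_range
        self.val_mae = val_mae
        self.train_mae: Optional[float] = None
        self.training_latents: Optional[np.ndarray] = None

    # -- prediction ------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predictions floored at zero (negative values are unphysical)."""
        Z = self.preprocessor.transform(X)
        return np.clip(self.estimator.predict(Z), 0.0, None)

    def latent(self, X: pd.DataFrame) -> np.ndarray:
        """Last-hidden-layer activations (ANN only)."""
        if self.kind != "ann":
            raise ValueError("latent space is defined only for the ANN model")
        Z = self.preprocessor.transform(X)
        act = Z
        coefs, intercepts = self.estimator.coefs_, self.estimator.intercepts_
        for W, b in zip(coefs[:-1], intercepts[:-1]):
            act = np.maximum(act @ W + b, 0.0)
        return act

    # -- evaluation ------------------------------------------------------

    def evaluate(
        self,
        X: pd.DataFrame,
        y: pd.Series | np.ndarray,
        y_range: Optional[float] = None,
    ) -> dict[str, float]:
        """MAE in native units and scaled MAE (MAE over the target's range
        across the modeled data; pass ``y_range`` to fix the denominator)."""
        y = np.asarray(y, dtype=float)
        if len(y) == 0:
            raise ValueError("empty evaluation set")
        mae = _mae(y, self.predict(X))
        if y_range is None:
            lo = min(self.y_fit_range[0], float(np.min(y)))
            hi = max(self.y_fit_range[1], float(np.max(y)))
            y_range = hi - lo
        return {"mae": mae, "scaled_mae": mae / y_range if y_range > 0 else np.nan}

    # -- interpretation --------------------------------------------------

    def importances(self) -> pd.Series:
        """Impurity (mean-decrease-in-impurity) importances, summing to 1."""
        if self.kind != "rf":
            raise ValueError("impurity importances are defined for the random forest")
        return pd.Series(
            self.estimator.feature_importances_,
            index=self.preprocessor.feature_names,
        ).sort_values(ascending=False)

    def importance_by_block(self) -> dict[str, float]:
        """Importance mass aggregated over CN-ligand vs NN-ligand features."""
        imp = self.importances()
        out = {"CN": 0.0, "NN": 0.0, "other": 0.0}
        for name, v in imp.items():
            if "_CN_" in name or name.startswith("CN"):
                out["CN"] += v
            elif "_NN_" in name or name.startswith("NN"):
                out["NN"] += v
            else:
                out["other"] += v
        return out

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Phosphor property regression results",
            "=" * 44,
            f"target:          {self.target}",
            f"model kind:      {self.kind}",
            f"n(train+val):    {self.n_train}",
            f"n features:      {len(self.preprocessor.feature_names)}"
            + (f" ({len(self.preprocessor.dropped_names)} invariant dropped)"
               if self.preprocessor.dropped_names else ""),
            f"hyperparameters: {self.hyperparams}",
        ]
        if self.val_mae is not None:
            lines.append(f"validation MAE:  {self.val_mae:.4g}")
        if self.train_mae is not None:
            lines.append(f"train MAE:       {self.train_mae:.4g}")
        if self.kind == "rf":
            lines.append("top features by impurity importance:")
            for name, v in self.importances().head(5).items():
                lines.append(f"  {name:<28s} {v:.3f}")
            blocks = self.importance_by_block()
            lines.append(
                f"importance mass: CN {blocks['CN']:.3f} | NN {blocks['NN']:.3f}"
            )
        return "\n".join(lines)

    def plot_parity(self, X: pd.DataFrame, y, ax=None):
        """Predicted-vs-observed scatter with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        pred = self.predict(X)
        ax.scatter(y, pred, s=12, alpha=0.6)
        lo = min(np.min(y), pred.min())
        hi = max(np.max(y), pred.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel(f"observed {self.target}")
        ax.set_ylabel(f"predicted {self.target}")
        return ax

    # -- persistence -----------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": self.kind,
            "target": self.target,
            "hyperparams": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.hyperparams.items()
            },
            "seed": self.seed,
            "n_train": self.n_train,
            "y_fit_range": list(self.y_fit_range),
            "val_mae": self.val_mae,
            "train_mae": self.train_mae,
            "preprocessor": self.preprocessor.to_dict(),
        }
        if self.kind == "ann":
            meta["weights"] = [w.tolist() for w in self.estimator.coefs_]
            meta["biases"] = [b.tolist() for b in self.estimator.intercepts_]
            if self.training_latents is not None:
                np.savetxt(outdir / "training_latents.csv",
                           self.training_latents, delimiter=",")
        elif self.kind == "ridge":
            meta["coef"] = self.estimator.coef_.tolist()
            meta["intercept"] = float(self.estimator.intercept_)
        else:
            import joblib

            joblib.dump(self.estimator, outdir / "forest.joblib")
        (outdir / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, outdir: str | Path) -> "PhosphorPropertyResults":
        outdir = Path(outdir)
        meta = json.loads((outdir / "model.json").read_text())
        prep = Preprocessor.from_dict(meta["preprocessor"])
        kind = meta["kind"]
        if kind == "ann":
            estimator = _RehydratedMLP(
                [np.array(w) for w in meta["weights"]],
                [np.array(b) for b in meta["biases"]],
            )
        elif kind == "ridge":
            estimator = Ridge(alpha=meta["hyperparams"]["alpha"])
            estimator.coef_ = np.array(meta["coef"])
            estimator.intercept_ = meta["intercept"]
        else:
            import joblib

            estimator = joblib.load(outdir / "forest.joblib")
        res = cls(
            kind=kind,
            target=meta["target"],
            estimator=estimator,
            preprocessor=prep,
            hyperparams=meta["hyperparams"],
            seed=meta["seed"],
            n_train=meta["n_train"],
            y_fit_range=tuple(meta["y_fit_range"]),
            val_mae=meta["val_mae"],
        )
        res.train_mae = meta["train_mae"]
        latents = outdir / "training_latents.csv"
        if latents.exists():
            res.training_latents = np.loadtxt(latents, delimiter=",", ndmin=2)
        return res


class _RehydratedMLP:
    """Forward-pass-only stand-in for a saved perceptron (relu hidden layers,
    identity output), duck-typing the fitted-estimator surface we use."""

    def __init__(self, coefs, intercepts):
        self.coefs_ = coefs
        self.intercepts_ = intercepts

    def predict(self, Z: np.ndarray) -> np.ndarray:
        act = Z
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            act = np.maximum(act @ W + b, 0.0)
        return (act @ self.coefs_[-1] + self.intercepts_[-1]).ravel()


# ---------------------------------------------------------------------------
# thin functional wrappers


def train_ann(X, y, X_val=None, y_val=None, space=None, seed=0, target="em5050"):
    return PhosphorPropertyModel(
        X, y, kind="ann", target=target, X_val=X_val, y_val=y_val, space=space
    ).fit(seed=seed)


def train_rf(X, y, seed=0, target="em5050", **kw):
    return PhosphorPropertyModel(X, y, kind="rf", target=target, **kw).fit(seed=seed)


def train_ridge(X, y, alpha=1e-3, target="em5050", **kw):
    return PhosphorPropertyModel(
        X, y, kind="ridge", target=target, ridge_alpha=alpha, **kw
    ).fit()


def evaluate(results: PhosphorPropertyResults, X_test, y_test, y_range=None):
    return results.evaluate(X_test, y_test, y_range=y_range)


def rf_importances(results: PhosphorPropertyResults) -> pd.Series:
    return results.importances()


def aggregate_importance_by_ligand(results: PhosphorPropertyResults) -> dict[str, float]:
    return results.importance_by_block()
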