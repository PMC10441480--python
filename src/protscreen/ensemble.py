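"""Property-scale sweep, per-family grid search, and the stacked ensemble.

For each (property scale, model family) pair the library is encoded with the
scale, the top-k features are selected on the training rows, every grid point
is fit and scored on the held-out split, and the best point is retained.
Scales are then ranked per family by held-out R^2 and the top five per family
are stacked into an ensemble whose prediction is the plain mean of its
contributors (3 families x 5 scales = 15 contributors by default).

Grid points are scored on the same held-out split used for final reporting —
a single-split protocol that is optimistically biased; see the project
documentation before interpreting sweep R^2 values as generalization
estimates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import f_regression
from sklearn.model_selection import ParameterGrid
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .aa_encoding import PropertyDictionary, PropertyScale, encode_property
from .library_io import SplitLibrary, VariantLibrary

logger = logging.getLogger(__name__)

TREE_FAMILY = "tree_ensemble_regressor"
NEIGHBOR_FAMILY = "nearest_neighbor_regressor"
NETWORK_FAMILY = "feedforward_network_regressor"
DEFAULT_FAMILIES = (TREE_FAMILY, NEIGHBOR_FAMILY, NETWORK_FAMILY)

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    TREE_FAMILY: {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20]},
    NEIGHBOR_FAMILY: {"n_neighbors": [2, 5, 10, 20], "weights": ["uniform", "distance"]},
    NETWORK_FAMILY: {"hidden_layer_sizes": [(64,), (128, 64)], "alpha": [1e-4, 1e-3]},
}


def make_estimator(family: str, params: Mapping[str, Any], seed: int):
    """Instantiate a fresh estimator for a family at one grid point.

    The feedforward family standardizes its inputs internally (fit on the
    training rows only); tree and neighbor families consume raw encodings.
    """
    if family == TREE_FAMILY:
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if family == NEIGHBOR_FAMILY:
        return KNeighborsRegressor(**params)
    if family == NETWORK_FAMILY:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPRegressor(random_state=seed, max_iter=500, **params),
                ),
            ]
        )
    raise ValueError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class SweepResult:
    """Outcome of tuning one family on one scale's encoding."""

    family: str
    scale_id: str
    best_params: dict
    test_r2: float
    test_mse: float
    selected_features: tuple[int, ...]

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "scale_id": self.scale_id,
            "best_params": _jsonable_params(self.best_params),
            "test_r2": self.test_r2,
            "test_mse": self.test_mse,
            "selected_features": list(self.selected_features),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SweepResult":
        return cls(
            family=d["family"],
            scale_id=d["scale_id"],
            best_params=_unjsonable_params(d["best_params"]),
            test_r2=d["test_r2"],
            test_mse=d["test_mse"],
            selected_features=tuple(d["selected_features"]),
        )


def _jsonable_params(params: Mapping[str, Any]) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()}


def _unjsonable_params(params: Mapping[str, Any]) -> dict:
    # hidden_layer_sizes round-trips through JSON as a list
    return {
        k: (tuple(v) if k == "hidden_layer_sizes" and isinstance(v, list) else v)
        for k, v in params.items()
    }


@dataclass
class ContributorModel:
    """One fitted (family, scale) predictor inside the stacked ensemble."""

    family: str
    scale_id: str
    estimator: Any
    selected_features: tuple[int, ...]
    best_params: dict
    seed: int

    def predict(self, library: VariantLibrary, dictionary: PropertyDictionary) -> np.ndarray:
        scale = dictionary.get(self.scale_id)
        X = encode_property(library, scale).matrix[:, list(self.selected_features)]
        return np.asarray(self.estimator.predict(X), dtype=float)


@dataclass
class StackedEnsemble:
    contributors: list[ContributorModel]
    target_attribute: str
    dictionary: PropertyDictionary
    sequence_length: int | None = None  # training base length, when known

    def __len__(self) -> int:
        return len(self.contributors)

    def contributor_names(self) -> list[str]:
        return [f"{c.family}:{c.scale_id}" for c in self.contributors]


@dataclass(frozen=True)
class PredictionRecord:
    """Per-variant contributor predictions and their mean."""

    variant_id: str
    contributor_predictions: tuple[float, ...]
    mean_prediction: float


def evaluate(predictions: Sequence[float], truth: Sequence[float]) -> tuple[float, float]:
    """Coefficient of determination and mean squared error.

    Zero-variance truth makes R^2 undefined: NaN is returned as a sentinel.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size < 2:
        raise ValueError("predictions and truth must be equal-length with n >= 2")
    mse = float(np.mean((p - t) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("zero-variance truth: R^2 undefined, reporting NaN")
        return float("nan"), mse
    ss_res = float(np.sum((t - p) ** 2))
    return 1.0 - ss_res / ss_tot, mse


def select_features(X: np.ndarray, y: np.ndarray, k: int) -> tuple[int, ...]:
    """Indices of the k features with the largest univariate F-statistic vs y.

    Ties (including constant columns, which score NaN -> treated as -inf)
    break toward the lowest feature index; the result is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must be in [1, {X.shape[1]}], got {k}")
    if np.ptp(y) == 0:
        raise ValueError("constant target: univariate F-scores undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns emit divide warnings
        scores, _ = f_regression(X, y)
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    # stable sort on (-score, index)
    order = np.lexsort((np.arange(scores.size), -scores))
    return tuple(int(i) for i in order[:k])


def tune_and_fit(
    family: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int,
    grid: Mapping[str, list] | None = None,
) -> tuple[Any, dict, float, float]:
    """Exhaustive grid search scored by held-out R^2.

    Returns (fitted best estimator, best params, test R^2, test MSE).
    A grid point whose fit fails scores -inf and is logged, not fatal.
    """
    if len(y_train) < 10:
        raise ValueError(f"need >= 10 training rows, have {len(y_train)}")
    if not np.all(np.isfinite(y_train)) or not np.all(np.isfinite(y_test)):
        raise ValueError("non-finite target values")
    grid = dict(grid if grid is not None else DEFAULT_GRIDS[family])
    best: tuple[float, float, dict, Any] | None = None
    for params in ParameterGrid(grid):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est = make_estimator(family, params, seed)
                est.fit(X_train, y_train)
                r2, mse = evaluate(est.predict(X_test), y_test)
        except Exception as exc:  # noqa: BLE001 - grid point failure is non-fatal
            logger.warning("grid point %s failed for %s: %s", params, family, exc)
            continue
        score = r2 if np.isfinite(r2) else -np.inf
        if best is None or score > best[0]:
            best = (score, mse, dict(params), est)
    if best is None:
        raise RuntimeError(f"all grid points failed for family {family!r}")
    score, mse, params, est = best
    r2 = score if np.isfinite(score) else float("nan")
    return est, params, r2, mse


def _split_matrices(
    library: VariantLibrary, split: SplitLibrary, scale: PropertyScale, feature_k: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, tuple[int, ...]]:
    enc = encode_property(library, scale)
    idx = {vid: i for i, vid in enumerate(enc.variant_ids)}
    train_rows = [idx[i] for i in split.train_ids]
    test_rows = [idx[i] for i in split.test_ids]
    y = library.target_values()
    X_train, y_train = enc.matrix[train_rows], y[train_rows]
    X_test, y_test = enc.matrix[test_rows], y[test_rows]
    d = X_train.shape[1]
    k = d if feature_k is None else min(feature_k, d)
    feats = select_features(X_train, y_train, k)
    return X_train[:, list(feats)], y_train, X_test[:, list(feats)], y_test, feats


def _cache_key(
    split: SplitLibrary, scale: PropertyScale, family: str, grid: Mapping, seed: int, feature_k: int | None
) -> str:
    payload = json.dumps(
        {
            "train": list(split.train_ids),
            "test": list(split.test_ids),
            "scale": {k: scale.values[k] for k in sorted(scale.values)},
            "scale_id": scale.scale_id,
            "family": family,
            "grid": _jsonable_params({k: list(v) for k, v in grid.items()}),
            "seed": seed,
            "feature_k": feature_k,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


class SweepCache:
    """Append-only JSONL cache of sweep results keyed by a content hash."""

    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path else None
        self._mem: dict[str, SweepResult] = {}
        if self.path and self.path.exists():
            for line in self.path.read_text().splitlines():
                if not line.strip():
                    continue
                d = json.loads(line)
                self._mem[d["key"]] = SweepResult.from_dict(d["result"])

    def get(self, key: str) -> SweepResult | None:
        return self._mem.get(key)

    def put(self, key: str, result: SweepResult) -> None:
        self._mem[key] = result
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            with open(self.path, "a") as fh:
                fh.write(json.dumps({"key": key, "result": result.to_dict()}) + "\n")


def enumerate_sweep_jobs(
    dictionary: PropertyDictionary, families: Sequence[str] = DEFAULT_FAMILIES
) -> list[tuple[str, str]]:
    """The (scale_id, family) job list a sweep would run, without fitting."""
    return [(s.scale_id, fam) for s in dictionary for fam in families]


def run_property_sweep(
    library: VariantLibrary,
    split: SplitLibrary,
    dictionary: PropertyDictionary,
    families: Sequence[str] = DEFAULT_FAMILIES,
    *,
    seed: int = 42,
    feature_k: int | None = 100,
    grids: Mapping[str, Mapping[str, list]] | None = None,
    cache: SweepCache | None = None,
) -> list[SweepResult]:
    """Tune every family on every complete scale; one SweepResult per pair."""
    if len(dictionary) == 0:
        raise ValueError("empty property dictionary")
    grids = grids or DEFAULT_GRIDS
    cache = cache or SweepCache(None)
    results: list[SweepResult] = []
    n_fit = 0
    for scale in dictionary:
        mats: dict | None = None
        for family in families:
            grid = grids.get(family, DEFAULT_GRIDS[family])
            key = _cache_key(split, scale, family, grid, seed, feature_k)
            hit = cache.get(key)
            if hit is not None:
                results.append(hit)
                continue
            if mats is None:
                Xtr, ytr, Xte, yte, feats = _split_matrices(library, split, scale, feature_k)
                mats = dict(Xtr=Xtr, ytr=ytr, Xte=Xte, yte=yte, feats=feats)
            _, params, r2, mse = tune_and_fit(
                family, mats["Xtr"], mats["ytr"], mats["Xte"], mats["yte"], seed, grid
            )
            res = SweepResult(
                family=family,
                scale_id=scale.scale_id,
                best_params=params,
                test_r2=r2,
                test_mse=mse,
                selected_features=mats["feats"],
            )
            cache.put(key, res)
            results.append(res)
            n_fit += 1
    logger.info(
        "sweep complete: %d results (%d fitted, %d from cache)",
        len(results), n_fit, len(results) - n_fit,
    )
    return results


def rank_scales(sweep: Iterable[SweepResult], family: str) -> list[SweepResult]:
    """Family's results sorted by test R^2 descending, ties by scale_id."""
    fam = [r for r in sweep if r.family == family and np.isfinite(r.test_r2)]
    return sorted(fam, key=lambda r: (-r.test_r2, r.scale_id))


def build_stacked_ensemble(
    sweep: Sequence[SweepResult],
    library: VariantLibrary,
    split: SplitLibrary,
    dictionary: PropertyDictionary,
    *,
    top_n: int = 5,
    seed: int = 42,
) -> StackedEnsemble:
    """Refit the top-n scales of each family and stack the contributors."""
    families = sorted({r.family for r in sweep}, key=DEFAULT_FAMILIES.index)
    contributors: list[ContributorModel] = []
    for family in families:
        ranked = rank_scales(sweep, family)
        if len(ranked) < top_n:
            raise ValueError(
                f"family {family!r} has {len(ranked)} ranked scales, need {top_n}"
            )
        for res in ranked[:top_n]:
            scale = dictionary.get(res.scale_id)
            enc = encode_property(library, scale)
            idx = {vid: i for i, vid in enumerate(enc.variant_ids)}
            rows = [idx[i] for i in split.train_ids]
            X = enc.matrix[np.ix_(rows, list(res.selected_features))]
            y = library.target_values()[rows]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est = make_estimator(family, res.best_params, seed)
                est.fit(X, y)
            contributors.append(
                ContributorModel(
                    family=family,
                    scale_id=res.scale_id,
                    estimator=est,
                    selected_features=res.selected_features,
                    best_params=res.best_params,
                    seed=seed,
                )
            )
    return StackedEnsemble(
        contributors=contributors,
        target_attribute=library.target_attribute,
        dictionary=dictionary,
        sequence_length=len(library.base),
    )


def predict_ensemble(ensemble: StackedEnsemble, variants: VariantLibrary) -> list[PredictionRecord]:
    """Mean-of-contributors predictions, retaining each contributor's value."""
    if len(variants.records) == 0:
        return []
    expected_len = ensemble.sequence_length or len(variants.base)
    if any(len(r.sequence) != expected_len for r in variants.records):
        raise ValueError(
            f"variant sequence length mismatch: ensemble expects L={expected_len}"
        )
    per_model = np.vstack(
        [c.predict(variants, ensemble.dictionary) for c in ensemble.contributors]
    )  # shape (n_contributors, n_variants)
    means = per_model.mean(axis=0)
    return [
        PredictionRecord(
            variant_id=vid,
            contributor_predictions=tuple(float(v) for v in per_model[:, i]),
            mean_prediction=float(means[i]),
        )
        for i, vid in enumerate(variants.ids())
    ]


def predictions_to_frame(records: Sequence[PredictionRecord], contributor_names: Sequence[str]):
    """Wide table: id, mean, one column per contributor."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"id": r.variant_id, "mean": r.mean_prediction}
        row.update(dict(zip(contributor_names, r.contributor_predictions)))
        rows.append(row)
    return pd.DataFrame(rows)
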