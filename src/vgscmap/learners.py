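"""Base learners: gradient-boosted trees, random forest, neural network.

Each learner predicts per-sample allele-class frequencies from the
assembled design.  Allele-count labels are handled as weighted categorical
observations: every (sample, class) pair with a positive count becomes one
training row with weight equal to the count (equivalent likelihood to row
replication, far smaller memory).  The MLP learner instead fits the
per-sample frequency vector directly by least squares, since its backend
takes no observation weights; its output is projected back to the simplex.

Out-of-sample predictions for the stacking meta-model come from K-fold
cross-validation: each sample's prediction is produced by a model that
never saw that sample's label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPRegressor
from xgboost import XGBClassifier

from .features import Design

__all__ = [
    "LearnerSpec",
    "DEFAULT_SPECS",
    "DEFAULT_GRIDS",
    "make_learner",
    "assign_folds",
    "fit_predict_out_of_sample",
    "fit_full",
    "tune_learner",
    "TuneResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearnerSpec:
    """One learner family plus its hyperparameters and seed."""

    family: str
    params: tuple = ()
    seed: int = 0

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    @staticmethod
    def of(family: str, seed: int = 0, **params) -> "LearnerSpec":
        return LearnerSpec(family, tuple(sorted(params.items())), seed)

    def with_seed(self, seed: int) -> "LearnerSpec":
        return LearnerSpec(self.family, self.params, seed)


#: desk-scale defaults used by the pipeline when no tuning is requested
DEFAULT_SPECS = {
    "xgb": LearnerSpec.of("xgb", max_depth=3, learning_rate=0.1, n_estimators=60),
    "rf": LearnerSpec.of(
        "rf", n_estimators=60, max_features="sqrt", min_samples_leaf=3
    ),
    "nn": LearnerSpec.of("nn", hidden=16, max_iter=300),
}

#: small per-family tuning grids (trees: depth x learning rate; forest:
#: feature subsampling; network: hidden-layer width)
DEFAULT_GRIDS = {
    "xgb": [
        {"max_depth": d, "learning_rate": lr, "n_estimators": 100}
        for d in (3, 6)
        for lr in (0.05, 0.1)
    ],
    "rf": [
        {"n_estimators": 300, "max_features": mf} for mf in ("sqrt", 0.333)
    ],
    "nn": [{"hidden": h, "max_iter": 300} for h in (16, 64)],
}


def _encode(X: pd.DataFrame, columns: list[str] | None = None):
    """One-hot encode the species factor; return (matrix, column names)."""
    enc = pd.get_dummies(X, columns=["species"] if "species" in X else [])
    enc = enc.astype(float)
    if columns is not None:
        missing = [c for c in columns if c not in enc.columns]
        for c in missing:
            enc[c] = 0.0
        extra = [c for c in enc.columns if c not in columns]
        if extra:
            raise ValueError(f"prediction rows carry unknown columns: {extra}")
        enc = enc[columns]
    return enc.to_numpy(), list(enc.columns)


def _expand_weighted(Xe: np.ndarray, counts: np.ndarray):
    """(sample, class) rows with weight = allele count, zero counts dropped."""
    n, J = counts.shape
    rows, labels, weights = [], [], []
    for j in range(J):
        mask = counts[:, j] > 0
        rows.append(Xe[mask])
        labels.append(np.full(mask.sum(), j))
        weights.append(counts[mask, j].astype(float))
    return np.vstack(rows), np.concatenate(labels), np.concatenate(weights)


def _spread_to_full(proba: np.ndarray, present: np.ndarray, J: int) -> np.ndarray:
    """Place probabilities over present classes into all-J columns."""
    out = np.zeros((proba.shape[0], J))
    out[:, present] = proba
    return out


def _renormalize(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    s = p.sum(axis=1, keepdims=True)
    uniform = np.full_like(p, 1.0 / p.shape[1])
    return np.where(s > 0, p / np.where(s > 0, s, 1.0), uniform)


class FrequencyLearner:
    """Common fit/predict surface over the learner families."""

    def __init__(self, spec: LearnerSpec):
        self.spec = spec
        self._columns: list[str] | None = None
        self._J: int | None = None

    def fit(self, X: pd.DataFrame, counts: pd.DataFrame) -> "FrequencyLearner":
        raise NotImplementedError

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


class _WeightedClassifierLearner(FrequencyLearner):
    """Shared machinery for count-weighted sklearn/xgboost classifiers."""

    def _build(self):  # -> estimator
        raise NotImplementedError

    def fit(self, X, counts):
        self._J = counts.shape[1]
        Xe, self._columns = _encode(X)
        c = counts.to_numpy()
        totals = c.sum(axis=0)
        self._present = np.flatnonzero(totals > 0)
        self._train_dist = _renormalize(totals[None, :].astype(float))[0]
        if len(self._present) < 2:
            logger.warning(
                "degenerate training set: single class %s; using training "
                "class distribution",
                self._present,
            )
            self._model = None
            return self
        Xr, y, w = _expand_weighted(Xe, c)
        # relabel to consecutive ids over present classes
        relabel = {j: k for k, j in enumerate(self._present)}
        y = np.array([relabel[j] for j in y])
        self._model = self._build()
        self._model.fit(Xr, y, sample_weight=w)
        return self

    def predict(self, X):
        Xe, _ = _encode(X, self._columns)
        if self._model is None:
            return np.tile(self._train_dist, (Xe.shape[0], 1))
        proba = self._model.predict_proba(Xe)
        full = _spread_to_full(proba, self._present, self._J)
        return _renormalize(full)


class XGBLearner(_WeightedClassifierLearner):
    def _build(self):
        p = self.spec.param_dict
        return XGBClassifier(
            max_depth=p.get("max_depth", 3),
            learning_rate=p.get("learning_rate", 0.1),
            n_estimators=p.get("n_estimators", 60),
            tree_method="hist",
            n_jobs=1,
            random_state=self.spec.seed,
            verbosity=0,
        )

    def gain_importance(self) -> pd.Series:
        """Per-feature gain (fractional training-error reduction at splits)."""
        if self._model is None:
            return pd.Series(0.0, index=self._feature_names())
        booster = self._model.get_booster()
        booster.feature_names = self._columns
        raw = booster.get_score(importance_type="gain")
        s = pd.Series({c: raw.get(c, 0.0) for c in self._columns})
        return _collapse_species(s).sort_index()

    def _feature_names(self):
        return _collapse_species(pd.Series(0.0, index=self._columns)).index


class RFLearner(_WeightedClassifierLearner):
    def _build(self):
        p = self.spec.param_dict
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_features=p.get("max_features", "sqrt"),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            n_jobs=1,
            random_state=self.spec.seed,
        )

    def gini_importance(self) -> pd.Series:
        """Mean-decrease-in-impurity importance from the fitted forest."""
        if self._model is None:
            cols = _collapse_species(pd.Series(0.0, index=self._columns)).index
            return pd.Series(0.0, index=cols)
        s = pd.Series(self._model.feature_importances_, index=self._columns)
        return _collapse_species(s).sort_index()


def _collapse_species(s: pd.Series) -> pd.Series:
    """Sum one-hot species columns back into a single 'species' feature."""
    mask = s.index.str.startswith("species_")
    if not mask.any():
        return s
    collapsed = s[~mask].copy()
    collapsed["species"] = s[mask].sum()
    return collapsed


class NNLearner(FrequencyLearner):
    """Single-hidden-layer MLP fitted to per-sample frequency vectors."""

    def fit(self, X, counts):
        self._J = counts.shape[1]
        Xe, self._columns = _encode(X)
        self._mu = Xe.mean(axis=0)
        self._sd = Xe.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        freqs = counts.div(counts.sum(axis=1), axis=0).to_numpy()
        p = self.spec.param_dict
        self._model = MLPRegressor(
            hidden_layer_sizes=(p.get("hidden", 16),),
            max_iter=p.get("max_iter", 300),
            solver="lbfgs",
            random_state=self.spec.seed,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # the lbfgs iteration cap doubles as early stopping here
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._model.fit((Xe - self._mu) / self._sd, freqs)
        return self

    def predict(self, X):
        Xe, _ = _encode(X, self._columns)
        raw = self._model.predict((Xe - self._mu) / self._sd)
        if raw.ndim == 1:
            raw = raw[:, None]
        return _renormalize(np.clip(raw, 0.0, 1.0))


class MeanLearner(FrequencyLearner):
    """Constant predictor at the count-weighted training class frequency.

    Deliberately label-blind at prediction time; used as a stub in tests
    and as a floor baseline.
    """

    def fit(self, X, counts):
        self._J = counts.shape[1]
        totals = counts.to_numpy().sum(axis=0).astype(float)
        self._dist = _renormalize(totals[None, :])[0]
        return self

    def predict(self, X):
        return np.tile(self._dist, (len(X), 1))


class LookupLearner(FrequencyLearner):
    """Oracle that returns pre-computed frequencies by row index.

    For validation experiments only (e.g. a perfect-oracle bound); the
    lookup table is supplied at construction, not learned.
    """

    def __init__(self, spec: LearnerSpec, table: pd.DataFrame):
        super().__init__(spec)
        self._table = table

    def fit(self, X, counts):
        self._J = counts.shape[1]
        return self

    def predict(self, X):
        return _renormalize(self._table.loc[X.index].to_numpy())


_FAMILIES = {
    "xgb": XGBLearner,
    "rf": RFLearner,
    "nn": NNLearner,
    "mean": MeanLearner,
}


def register_family(name: str, cls) -> None:
    """Register a custom learner family (used by tests for stubs)."""
    _FAMILIES[name] = cls


def make_learner(spec: LearnerSpec) -> FrequencyLearner:
    try:
        cls = _FAMILIES[spec.family]
    except KeyError:
        raise ValueError(
            f"unknown learner family {spec.family!r}; known: {sorted(_FAMILIES)}"
        ) from None
    return cls(spec)


# ---------------------------------------------------------------------------
# folds and cross-fitting


def assign_folds(sample_ids, K: int = 10, seed: int = 0) -> pd.Series:
    """Balanced random partition of samples into K folds (1..K).

    Random sampling without replacement; fold sizes differ by at most one.
    """
    ids = pd.Index(sample_ids)
    n = len(ids)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, K), start=1):
        folds[chunk] = f
    return pd.Series(folds, index=ids, name="fold")


def fit_predict_out_of_sample(
    spec: LearnerSpec, design: Design, folds: pd.Series
) -> pd.DataFrame:
    """K-fold cross-fitted class-frequency predictions.

    For each fold the learner trains on all other folds and predicts the
    held-out rows, so no sample's prediction is informed by its own label.
    """
    X, counts = design.X, design.counts
    if not folds.index.equals(X.index):
        folds = folds.loc[X.index]
    out = np.full((len(X), counts.shape[1]), np.nan)
    for f in sorted(folds.unique()):
        hold = folds == f
        learner = make_learner(spec).fit(X[~hold], counts[~hold])
        out[hold.to_numpy()] = learner.predict(X[hold])
    assert not np.isnan(out).any(), "every sample must receive a prediction"
    return pd.DataFrame(out, index=X.index, columns=counts.columns)


def fit_full(spec: LearnerSpec, design: Design) -> FrequencyLearner:
    """Single fit on all data, for in-sample-refit ensemble prediction."""
    return make_learner(spec).fit(design.X, design.counts)


def _weighted_multinomial_score(counts: np.ndarray, proba: np.ndarray) -> float:
    """Sum_ij y_ij log p_ij; the validation selection criterion."""
    p = np.clip(proba, 1e-12, 1.0)
    return float((counts * np.log(p)).sum())


@dataclass
class TuneResult:
    spec: LearnerSpec
    trace: pd.DataFrame = field(repr=False)


def tune_learner(
    family: str,
    design: Design,
    grid: list[dict] | None = None,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> TuneResult:
    """Small grid search scored on a held-out validation subset.

    Data are split train/validation/test; candidates are fitted on the
    training subset and scored by validation multinomial log-likelihood.
    The test subset is never touched during selection (it is reserved for
    downstream reporting by the caller).
    """
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    if not grid:
        raise ValueError("empty tuning grid")
    if not np.isclose(sum(split), 1.0):
        raise ValueError("split proportions must sum to 1")
    n = len(design.X)
    if n < 3:
        raise ValueError("need at least 3 samples for a 3-way split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = max(int(round(split[0] * n)), 1)
    n_val = max(int(round(split[1] * n)), 1)
    tr = design.X.index[perm[:n_train]]
    va = design.X.index[perm[n_train : n_train + n_val]]
    d_tr = Design(design.X.loc[tr], design.counts.loc[tr])
    rows = []
    best, best_score = None, -np.inf
    for params in grid:
        spec = LearnerSpec.of(family, seed=seed, **params)
        learner = make_learner(spec).fit(d_tr.X, d_tr.counts)
        score = _weighted_multinomial_score(
            design.counts.loc[va].to_numpy(), learner.predict(design.X.loc[va])
        )
        rows.append({**params, "val_loglik": score})
        if score > best_score:
            best, best_score = spec, score
    trace = pd.DataFrame(rows)
    logger.info("tuning trace for %s:\n%s", family, trace)
    return TuneResult(spec=best, trace=trace)
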