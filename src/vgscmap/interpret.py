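"""Variable importance and individual conditional expectation (ICE).

Importance is reported per learner with the measure native to each
family: split gain for the gradient-boosted trees, Gini (mean decrease in
impurity) for the random forest, and permutation importance — computed
here — for the neural network.  Gain and Gini are consumed from the tree
learners' own accessors, not re-derived.

The ICE traces the ensemble's predicted 995F frequency at a single map
location as ITN coverage is varied while every other feature is held
fixed; because the design carries three annual lags of coverage, the
focal value is written into all four lag slots (years t-3..t) together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import prediction_points
from .learners import FrequencyLearner

__all__ = [
    "permutation_importance",
    "collect_importance",
    "ice_curve",
    "ICEResult",
]


def permutation_importance(
    learner: FrequencyLearner,
    X: pd.DataFrame,
    counts: pd.DataFrame,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Mean increase in prediction error when one feature is shuffled.

    The metric is the mean absolute error between predicted and observed
    per-allele frequencies over all data points.  Each repeat shuffles
    exactly one column (all others untouched); the score is the mean over
    repeats of (shuffled error - baseline error).  A feature the model
    ignores, or one that is constant across observations, scores exactly 0
    for every permutation.
    """
    obs = counts.div(counts.sum(axis=1), axis=0).to_numpy()

    def err(Xd):
        p = learner.predict(Xd)
        if not np.isfinite(p).all():
            raise ValueError("non-finite predictions; cannot score importance")
        return float(np.abs(p - obs).mean())

    baseline = err(X)
    rng = np.random.default_rng(seed)
    scores = {}
    for col in X.columns:
        deltas = []
        for _ in range(n_repeats):
            Xs = X.copy()
            Xs[col] = X[col].to_numpy()[rng.permutation(len(X))]
            deltas.append(err(Xs) - baseline)
        scores[col] = float(np.mean(deltas))
    return pd.Series(scores, name="permutation")


def collect_importance(scores: dict[str, pd.Series]) -> pd.DataFrame:
    """Unified ranked table across learners (rank x learner layout).

    ``scores`` maps learner name -> per-feature score series (gain, Gini
    or permutation).  All learners must score the same feature set; a
    mismatch raises, listing the symmetric difference.  Ranks are complete
    permutations of 1..n_features per learner; ties break by feature name.
    """
    names = list(scores)
    base = set(scores[names[0]].index)
    for n in names[1:]:
        diff = base ^ set(scores[n].index)
        if diff:
            raise ValueError(
                f"feature sets differ between {names[0]} and {n}: {sorted(diff)}"
            )
    rows = []
    for learner, s in scores.items():
        order = sorted(s.index, key=lambda f: (-s[f], f))
        for rank, feat in enumerate(order, start=1):
            rows.append(
                {
                    "learner": learner,
                    "feature": feat,
                    "score": float(s[feat]),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


def importance_table(long: pd.DataFrame, top: int = 10) -> pd.DataFrame:
    """Pivot the long importance frame into the rank-by-learner layout."""
    wide = long.pivot(index="rank", columns="learner", values="feature")
    return wide.loc[wide.index <= top]


@dataclass
class ICEResult:
    """ICE of predicted 995F frequency under varying ITN coverage."""

    pixel_id: int
    longitude: float
    latitude: float
    year: int
    species: str
    curve: pd.DataFrame  # columns: coverage, f_995F
    baseline: float  # prediction at the unmodified (observed) features

    def to_frame(self) -> pd.DataFrame:
        out = self.curve.copy()
        out["pixel_id"] = self.pixel_id
        out["year"] = self.year
        out["species"] = self.species
        out["baseline"] = self.baseline
        return out

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve["coverage"], self.curve["f_995F"], marker="o")
        ax.axhline(self.baseline, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("ITN coverage (years t-3..t)")
        ax.set_ylabel("predicted 995F frequency")
        ax.set_title(f"ICE at pixel {self.pixel_id}, {self.species}, {self.year}")
        return ax


def ice_curve(
    results,
    feature_table: pd.DataFrame,
    pixel_id: int,
    year: int,
    species: str,
    coverage_values: np.ndarray | None = None,
    itn_variable: str = "itn_coverage",
    allele: str = "f_995F",
) -> ICEResult:
    """Predicted 995F frequency across a grid of ITN coverage values.

    For each coverage value c the ITN feature and its three lagged copies
    are all set to c; everything else keeps its observed value.  The
    baseline prediction uses the unmodified feature row through the same
    code path, so the ICE at the observed coverage (when all lag slots
    already equal it) coincides with the standard grid prediction exactly.
    """
    if coverage_values is None:
        coverage_values = np.round(np.arange(0.0, 0.91, 0.1), 10)
    coverage_values = np.asarray(coverage_values, dtype=float)
    if len(coverage_values) > 1 and not np.all(np.diff(coverage_values) > 0):
        raise ValueError("coverage grid must be strictly increasing")
    pts = prediction_points(feature_table, [year], [species])
    try:
        row = pts.loc[[(pixel_id, year, species)]]
    except KeyError:
        raise ValueError(
            f"no features for pixel {pixel_id} at year {year}"
        ) from None
    itn_cols = [c for c in row.columns if c == itn_variable or
                c.startswith(f"{itn_variable}(-")]
    if not itn_cols:
        raise ValueError(f"feature table has no {itn_variable} columns")
    # every evaluation is a one-row call through the same predict path, so
    # a curve point whose features equal the observed row reproduces the
    # grid prediction bit for bit
    baseline = float(results.predict(row)[allele].iloc[0])
    pred = []
    for c_val in coverage_values:
        modified = row.copy()
        modified[itn_cols] = c_val
        pred.append(float(results.predict(modified)[allele].iloc[0]))
    curve = pd.DataFrame({"coverage": coverage_values, allele: pred})
    return ICEResult(
        pixel_id=pixel_id,
        longitude=float(row.get("longitude", pd.Series([np.nan])).iloc[0])
        if "longitude" in row
        else np.nan,
        latitude=float(row.get("latitude", pd.Series([np.nan])).iloc[0])
        if "latitude" in row
        else np.nan,
        year=year,
        species=species,
        curve=curve,
        baseline=baseline,
    )
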