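"""Design-matrix construction: time lags, monthly PCs, sample assembly.

Feature construction is a pure function of (covariate grid, samples,
lags): repeated calls produce identical output, and lag columns satisfy
the shift identity ``v(-k)[t] == v(-0)[t-k]`` wherever both exist.
Lagged columns follow the ``name(-k)`` suffix convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .synth import ALL_SPECIES, CovariateGrid

__all__ = [
    "DEFAULT_LAGS",
    "Design",
    "build_lagged_features",
    "monthly_principal_components",
    "assemble_design",
    "prediction_points",
]

DEFAULT_LAGS = (0, 1, 2, 3)


def lag_column_name(variable: str, lag: int) -> str:
    return variable if lag == 0 else f"{variable}(-{lag})"


def build_lagged_features(
    grid: CovariateGrid,
    lags: tuple[int, ...] = DEFAULT_LAGS,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Expand annually varying covariates into lagged columns.

    Returns a frame indexed by (pixel_id, year) covering ``years`` (by
    default every year for which all requested lags exist).  For each
    annual variable v and lag k the column ``v(-k)`` at (pixel, t) holds v
    at (pixel, t - k); static variables appear once, unlagged.
    """
    available = grid.years
    max_lag = max(lags)
    if years is None:
        years = [y for y in available if y - max_lag >= min(available)]
    missing = {
        (v, y - k)
        for y in years
        for k in lags
        for v in grid.annual
        if y - k not in available
    }
    if missing:
        detail = ", ".join(f"{v}@{y}" for v, y in sorted(missing)[:10])
        raise ValueError(f"covariate grid lacks lag years: {detail}")

    pieces = []
    for k in lags:
        sub = grid.table[grid.annual].copy()
        # value at (pixel, t) becomes the value of v(-k) at (pixel, t + k)
        sub.index = sub.index.set_levels(sub.index.levels[1] + k, level="year")
        sub.columns = [lag_column_name(v, k) for v in grid.annual]
        pieces.append(sub)
    static = grid.table[grid.static]
    out = pd.concat(pieces + [static], axis=1)
    out = out.loc[(slice(None), years), :].sort_index()
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values after lag expansion in {bad}")
    return out


def monthly_principal_components(
    monthly_stack: np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Summarise a 12-month per-pixel profile with its leading PCs.

    ``monthly_stack`` has shape (n_pixels, 12): pixels are observations,
    months variables.  Returns (scores, explained_variance_ratio, info)
    where scores has one column per retained axis, axes are ordered by
    decreasing explained variance, and each axis is oriented so that its
    largest-magnitude loading is positive (decomposition signs are
    otherwise arbitrary).  If the centred profile matrix has rank below
    ``n_components`` only the non-degenerate axes are returned and
    ``info["rank_deficient"]`` is set.
    """
    x = np.asarray(monthly_stack, dtype=float)
    if x.ndim != 2 or x.shape[1] != 12:
        raise ValueError("monthly_stack must have shape (n_pixels, 12)")
    if not np.isfinite(x).all():
        raise ValueError("monthly_stack contains non-finite values")
    centred = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(centred, tol=1e-10)
    k = min(n_components, rank)
    info = {"rank": int(rank), "rank_deficient": rank < n_components}
    if k == 0:
        return np.zeros((x.shape[0], 0)), np.zeros(0), info
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    # fixed sign convention so scores are reproducible across solvers
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            scores[:, j] = -scores[:, j]
    return scores, pca.explained_variance_ratio_, info


@dataclass
class Design:
    """Assembled design matrix plus aligned per-sample allele counts.

    ``X`` carries the numeric features, the ``species`` factor and
    ``year``; rows are indexed by sample_id (stable, recorded order).
    ``counts`` is the aligned N x J matrix of observed allele counts.
    """

    X: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.counts.index):
            raise ValueError("X and counts must share a row index")

    @property
    def n(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.n, axis=0)


def assemble_design(
    samples: pd.DataFrame,
    feature_table: pd.DataFrame,
    count_cols: list[str] | None = None,
) -> Design:
    """Join sample metadata to grid features, one design row per sample.

    Each sample's (pixel_id, year) must resolve to a feature row; the
    species factor and collection year are appended as features.  Labels
    are exported alongside as per-allele counts — the learner wrapper
    expands them to weighted categorical observations.
    """
    if count_cols is None:
        count_cols = [c for c in samples.columns if c.startswith("count_")]
    unknown = set(samples["species"]) - set(ALL_SPECIES)
    if unknown:
        raise ValueError(
            f"unknown species {sorted(unknown)}; accepted: {list(ALL_SPECIES)}"
        )
    key = pd.MultiIndex.from_frame(samples[["pixel_id", "year"]])
    missing = [k for k in key.unique() if k not in feature_table.index]
    if missing:
        raise ValueError(f"no features for (pixel, year) keys: {missing[:10]}")
    feats = feature_table.loc[key]
    feats.index = samples.index
    X = feats.copy()
    X["species"] = pd.Categorical(samples["species"], categories=ALL_SPECIES)
    X["year"] = samples["year"].astype(float)
    counts = samples[count_cols].astype(int)
    return Design(X=X, counts=counts)


def prediction_points(
    feature_table: pd.DataFrame,
    years: list[int],
    species: list[str],
) -> pd.DataFrame:
    """Feature rows for every (pixel, year, species) prediction point."""
    bad = [s for s in species if s not in ALL_SPECIES]
    if bad:
        raise ValueError(f"unknown species {bad}")
    blocks = []
    for y in years:
        try:
            at_year = feature_table.xs(y, level="year")
        except KeyError:
            raise ValueError(f"feature table has no rows for year {y}") from None
        for sp in species:
            b = at_year.copy()
            b["species"] = pd.Categorical([sp] * len(b), categories=ALL_SPECIES)
            b["year"] = float(y)
            b.index = pd.MultiIndex.from_product(
                [at_year.index, [y], [sp]], names=["pixel_id", "year", "species"]
            )
            blocks.append(b)
    return pd.concat(blocks)
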