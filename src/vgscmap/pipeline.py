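"""Orchestration: ingest -> features -> learners -> meta-model -> maps.

`StackedEnsemble` is the model object a user fits: it wires the base
learners' K-fold out-of-sample predictions into the constrained
multinomial stacking meta-model, and its results object predicts allele
frequencies for arbitrary feature rows or whole (pixel, year, species)
grids.  `cross_validate` implements posterior validation with full
nesting: test folds are withheld from the base learners *and* the
meta-model, and stacking covariates are regenerated inside each outer
training set, which is the only leak-free reading of that protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import Design, assemble_design, build_lagged_features, prediction_points
from .learners import (
    DEFAULT_SPECS,
    LearnerSpec,
    assign_folds,
    fit_full,
    fit_predict_out_of_sample,
)
from .metamodel import DEFAULT_EPS, MultinomialStacking
from .synth import ALL_SPECIES, CovariateGrid

__all__ = [
    "RunConfig",
    "IngestReport",
    "ingest_allele_samples",
    "match_samples_to_grid",
    "collapse_to_binary",
    "StackedEnsemble",
    "StackedEnsembleResults",
    "cross_validate",
    "stacking_benchmark",
    "run_stacked_ensemble",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "longitude",
    "latitude",
    "year",
    "species",
    "n_alleles",
    "count_995L",
    "count_995F",
    "count_995S",
]


@dataclass
class RunConfig:
    """Declarative run settings for the end-to-end pipeline."""

    allele_path: str | None = None
    covariate_path: str | None = None
    out_dir: str = "vgscmap_run"
    K_outer: int = 10
    K_inner: int = 10
    seed: int = 0
    eps: float = DEFAULT_EPS
    lags: tuple[int, ...] = (0, 1, 2, 3)
    learner_specs: dict[str, LearnerSpec] = field(
        default_factory=lambda: dict(DEFAULT_SPECS)
    )
    J: int = 3
    #: pool validation errors over 'all' classes or only the 'resistance' alleles
    pool: str = "all"

    def __post_init__(self):
        if self.K_outer < 2 or self.K_inner < 2:
            raise ValueError("fold counts must be >= 2")
        if self.J not in (2, 3):
            raise ValueError("J must be 2 or 3")


@dataclass
class IngestReport:
    """Per-rule accounting of dropped rows, for reproducible filtering."""

    n_read: int
    n_retained: int
    dropped: dict[str, int]
    malformed: list[str]

    def __str__(self) -> str:
        rules = ", ".join(f"{k}: {v}" for k, v in self.dropped.items()) or "none"
        return (
            f"read {self.n_read} rows, retained {self.n_retained} "
            f"(dropped by rule: {rules})"
        )


def ingest_allele_samples(
    path, min_mosquitoes: int = 5
) -> tuple[pd.DataFrame, IngestReport]:
    """Read and filter an allele-sample CSV.

    Applies the inclusion rules: at least ``min_mosquitoes`` mosquitoes per
    sample (alleles / 2 at a diploid locus if no mosquito column is
    present), representative sampling (a falsy ``representative`` column
    drops the row), count conservation (per-allele counts must sum to
    n_alleles) and coordinate validity.  Malformed rows are collected with
    line numbers; dropping every row is a hard error.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"allele CSV lacks required columns: {missing}")
    n_read = len(df)
    dropped: dict[str, int] = {}
    malformed: list[str] = []
    count_cols = ["count_995L", "count_995F", "count_995S"]

    conserved = df[count_cols].sum(axis=1) == df["n_alleles"]
    for i in df.index[~conserved]:
        malformed.append(
            f"line {i + 2}: allele counts sum to "
            f"{int(df.loc[i, count_cols].sum())} but n_alleles="
            f"{int(df.loc[i, 'n_alleles'])} (conservation violation)"
        )
    dropped["count_conservation"] = int((~conserved).sum())
    df = df[conserved]

    coords_ok = (
        df["longitude"].between(-180, 180)
        & df["latitude"].between(-90, 90)
        & np.isfinite(df["longitude"])
        & np.isfinite(df["latitude"])
    )
    for i in df.index[~coords_ok]:
        malformed.append(f"line {i + 2}: invalid coordinates")
    dropped["invalid_coordinates"] = int((~coords_ok).sum())
    df = df[coords_ok]

    species_ok = df["species"].isin(ALL_SPECIES)
    for i in df.index[~species_ok]:
        malformed.append(
            f"line {i + 2}: unknown species {df.loc[i, 'species']!r}; "
            f"accepted: {list(ALL_SPECIES)}"
        )
    dropped["unknown_species"] = int((~species_ok).sum())
    df = df[species_ok]

    if "n_mosquitoes" in df.columns:
        mosquitoes = df["n_mosquitoes"]
    else:
        mosquitoes = df["n_alleles"] // 2
    enough = mosquitoes >= min_mosquitoes
    dropped[f"fewer_than_{min_mosquitoes}_mosquitoes"] = int((~enough).sum())
    df = df[enough]

    if "representative" in df.columns:
        rep = df["representative"].astype(bool)
        dropped["non_representative"] = int((~rep).sum())
        df = df[rep]

    if df.empty:
        raise ValueError(
            f"all {n_read} rows were dropped during ingest; "
            + "; ".join(malformed[:5])
        )
    df = df.drop(columns="sample_id", errors="ignore").reset_index(drop=True)
    df.index.name = "sample_id"
    report = IngestReport(n_read, len(df), dropped, malformed)
    logger.info("ingest: %s", report)
    return df, report


def match_samples_to_grid(samples: pd.DataFrame, grid: CovariateGrid) -> pd.DataFrame:
    """Attach the nearest grid pixel to each sample (Euclidean in degrees)."""
    out = samples.copy()
    pix = grid.coords[["longitude", "latitude"]].to_numpy()
    pts = samples[["longitude", "latitude"]].to_numpy()
    d2 = ((pts[:, None, :] - pix[None, :, :]) ** 2).sum(-1)
    out["pixel_id"] = grid.coords.index.to_numpy()[d2.argmin(axis=1)]
    return out


def collapse_to_binary(
    counts: pd.DataFrame, positive: str = "count_995F"
) -> pd.DataFrame:
    """Collapse J=3 counts to the binary (not-995F, 995F) labelling."""
    other = counts.drop(columns=positive).sum(axis=1)
    return pd.DataFrame(
        {"count_other": other, positive: counts[positive]}, index=counts.index
    )


# ---------------------------------------------------------------------------
# the model / results pair


class StackedEnsemble:
    """Stacked-generalization ensemble over allele-frequency samples.

    Parameters
    ----------
    design : Design
        Assembled feature matrix plus per-sample allele counts (J = 3 for
        the three-allele model, J = 2 for the binary 995F variant).
    learner_specs : mapping name -> LearnerSpec
        The base learner families; coefficients are reported per name.
    K : int
        Folds for the stacking covariates (out-of-sample base predictions).
    """

    def __init__(
        self,
        design: Design,
        learner_specs: dict[str, LearnerSpec] | None = None,
        K: int = 10,
        eps: float = DEFAULT_EPS,
        seed: int = 0,
    ):
        self.design = design
        self.learner_specs = dict(learner_specs or DEFAULT_SPECS)
        if not self.learner_specs:
            raise ValueError("need at least one base learner")
        self.K = K
        self.eps = eps
        self.seed = seed

    def fit(self) -> "StackedEnsembleResults":
        folds = assign_folds(self.design.X.index, self.K, self.seed)
        oos, full = {}, {}
        for off, (name, spec) in enumerate(sorted(self.learner_specs.items())):
            spec = spec.with_seed(self.seed + 1000 * (off + 1))
            logger.info("cross-fitting learner %s", name)
            oos[name] = fit_predict_out_of_sample(spec, self.design, folds)
            full[name] = fit_full(spec, self.design)
        meta = MultinomialStacking(
            self.design.counts,
            {name: oos[name].to_numpy() for name in oos},
            eps=self.eps,
        ).fit()
        return StackedEnsembleResults(self, folds, oos, full, meta)


class StackedEnsembleResults:
    """Fitted ensemble: base learners, stacking coefficients, predictions."""

    def __init__(self, model, folds, oos_predictions, full_learners, meta):
        self.model = model
        self.folds = folds
        self.oos_predictions = oos_predictions
        self.full_learners = full_learners
        self.meta = meta

    @property
    def coefficients(self) -> pd.DataFrame:
        return self.meta.params

    def predict_base(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        """In-sample-refit base-learner predictions for new feature rows."""
        return {name: lrn.predict(X) for name, lrn in self.full_learners.items()}

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Ensemble simplex predictions for new feature rows."""
        base = self.predict_base(X)
        p = self.meta.predict({n: base[n] for n in self.meta.model.learner_names})
        cols = [c.replace("count_", "f_") for c in self.model.design.counts.columns]
        return pd.DataFrame(p, index=X.index, columns=cols)

    def predict_grid(
        self,
        feature_table: pd.DataFrame,
        years: list[int],
        species: list[str],
    ) -> pd.DataFrame:
        """Per-(pixel, year, species) allele-frequency surface.

        The species list is configurable per region (e.g. only two species
        are mapped in the east).  Missing lag years surface as an error
        from the feature table construction naming the earliest feasible
        year.
        """
        pts = prediction_points(feature_table, years, species)
        return self.predict(pts.drop(columns=[]))

    def summary(self) -> str:
        names = ", ".join(sorted(self.model.learner_specs))
        return (
            f"Stacked ensemble: learners [{names}], "
            f"K={self.model.K} stacking folds, N={len(self.model.design.X)}\n\n"
            + self.meta.summary()
        )

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.meta.to_json(out / "metafit.json")
        self.folds.to_csv(out / "folds.csv")
        stacked = pd.concat(
            {n: df for n, df in self.oos_predictions.items()}, names=["learner"]
        )
        stacked.to_csv(out / "base_predictions_oos.csv")


# ---------------------------------------------------------------------------
# posterior validation


def _error_rows(
    observed: pd.DataFrame, predicted: np.ndarray, pool: str = "all"
) -> tuple[float, float, int]:
    obs = observed.to_numpy()
    if pool == "resistance":
        keep = [j for j, c in enumerate(observed.columns) if "995L" not in c]
        obs, predicted = obs[:, keep], predicted[:, keep]
    err = predicted - obs
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    return mae, rmse, err.size


def cross_validate(
    design: Design,
    learner_specs: dict[str, LearnerSpec] | None = None,
    K_outer: int = 10,
    K_inner: int = 10,
    eps: float = DEFAULT_EPS,
    seed: int = 0,
    pool: str = "all",
) -> pd.DataFrame:
    """Nested 10-fold posterior validation of ensemble and base learners.

    Outer folds are withheld from everything; inner folds (drawn only from
    the outer training set) generate the stacking covariates.  Withheld
    observations are scored on predicted vs observed per-allele
    frequencies, pooled over alleles and samples: MAE = mean |pred - obs|,
    RMSE = root mean square.  Returns one row per (model, fold) plus
    pooled rows; RMSE >= MAE holds on every row.
    """
    specs = dict(learner_specs or DEFAULT_SPECS)
    outer = assign_folds(design.X.index, K_outer, seed)
    rows = []
    all_err: dict[str, list[tuple[pd.DataFrame, np.ndarray]]] = {
        name: [] for name in list(specs) + ["ensemble"]
    }
    for f in sorted(outer.unique()):
        hold = outer == f
        train = Design(design.X[~hold], design.counts[~hold])
        obs_freq = Design(design.X[hold], design.counts[hold]).frequencies
        fit = StackedEnsemble(
            train, specs, K=K_inner, eps=eps, seed=seed + f
        ).fit()
        X_hold = design.X[hold]
        base = fit.predict_base(X_hold)
        preds = dict(base)
        preds["ensemble"] = fit.predict(X_hold).to_numpy()
        for name, p in preds.items():
            mae, rmse, nsz = _error_rows(obs_freq, np.asarray(p), pool)
            rows.append(
                {"model": name, "fold": f, "mae": mae, "rmse": rmse, "n": nsz}
            )
            all_err[name].append((obs_freq, np.asarray(p)))
    for name, pairs in all_err.items():
        obs = pd.concat([o for o, _ in pairs])
        pred = np.vstack([p for _, p in pairs])
        mae, rmse, nsz = _error_rows(obs, pred, pool)
        rows.append(
            {"model": name, "fold": "pooled", "mae": mae, "rmse": rmse, "n": nsz}
        )
    report = pd.DataFrame(rows)
    bad = report[report["rmse"] < report["mae"] - 1e-12]
    assert bad.empty, "power-mean inequality violated"
    return report


def stacking_benchmark(
    n_seeds: int = 20,
    n_samples: int = 500,
    K_outer: int = 10,
    K_inner: int = 5,
    learner_specs: dict[str, LearnerSpec] | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Repeated-seed no-worse benchmark on the default synthetic study.

    For each seed a fresh synthetic dataset of ``n_samples`` allele
    samples is generated, the nested 10-fold validation is run, and the
    pooled RMSE of the ensemble and of each base learner is recorded.
    ``K_inner`` defaults to 5 here as the benchmark's desk-scale sizing.
    """
    from .synth import SynthConfig, generate_covariate_fields, \
        generate_latent_frequencies, sample_allele_counts

    specs = dict(learner_specs or DEFAULT_SPECS)
    out = []
    for s in range(n_seeds):
        seed = (base_seed * 10007 + s) % (2**31)
        cfg = SynthConfig(n_samples=n_samples, seed=seed)
        grid = generate_covariate_fields(cfg)
        truth = generate_latent_frequencies(cfg, grid)
        samples = sample_allele_counts(truth, cfg)
        feats = build_lagged_features(grid)
        design = assemble_design(samples, feats)
        report = cross_validate(
            design, specs, K_outer=K_outer, K_inner=K_inner, seed=seed
        )
        pooled_rows = report[report["fold"] == "pooled"].set_index("model")
        pooled = pooled_rows["rmse"]
        row = {
            "seed": seed,
            "ensemble_rmse": pooled["ensemble"],
            "ensemble_mae": pooled_rows.loc["ensemble", "mae"],
        }
        for name in specs:
            row[f"{name}_rmse"] = pooled[name]
        row["min_base_rmse"] = min(pooled[name] for name in specs)
        row["no_worse"] = row["ensemble_rmse"] <= row["min_base_rmse"] + 0.005
        out.append(row)
        logger.info("benchmark seed %d: %s", seed, row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# end-to-end driver


def run_stacked_ensemble(
    config: RunConfig,
    grid: CovariateGrid | None = None,
    samples: pd.DataFrame | None = None,
):
    """Ingest -> features -> stacked fit; writes artifacts to out_dir.

    Either pass in-memory ``grid`` and ``samples`` or give CSV paths in
    the config.  Any stage failure aborts with the stage name; artifacts
    written before the failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if samples is None:
            samples, report = ingest_allele_samples(config.allele_path)
            (out / "ingest_report.txt").write_text(str(report) + "\n")
        if grid is None:
            grid = CovariateGrid.from_long_csv(config.covariate_path)
        if "pixel_id" not in samples.columns:
            samples = match_samples_to_grid(samples, grid)
        stage = "features"
        feats = build_lagged_features(grid, config.lags)
        design = assemble_design(samples, feats)
        if config.J == 2:
            design = Design(design.X, collapse_to_binary(design.counts))
        stage = "stacked_fit"
        results = StackedEnsemble(
            design,
            config.learner_specs,
            K=config.K_inner,
            eps=config.eps,
            seed=config.seed,
        ).fit()
        results.save(out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results, feats
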