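"""Synthetic spatiotemporal data generator.

Emulates the statistical structure of a continental target-site-resistance
survey: spatially autocorrelated environmental covariate fields, an annual
insecticide-treated-net (ITN) coverage trajectory with pixel-level
deviations, species-specific latent allele-frequency surfaces on the
3-simplex (wild-type 995L and the two resistance alleles 995F / 995S)
driven by a logistic-scale linear process, multinomial allele sampling at
realistic depths, and bioassay mortality linked to the species-complex
995F frequency with heavy measurement noise.

Every quantity is drawn from a single master seed via
:class:`numpy.random.SeedSequence` spawning, so each generation step is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SPECIES",
    "GAMBIAE_SL",
    "ALL_SPECIES",
    "ALLELES",
    "SpeciesEffects",
    "SynthConfig",
    "CovariateGrid",
    "TrueProcess",
    "generate_covariate_fields",
    "generate_latent_frequencies",
    "sample_allele_counts",
    "sample_bioassay_mortality",
    "generate_dataset",
]

#: the three individually identified vector species of the complex
SPECIES = ("gambiae", "coluzzii", "arabiensis")
#: label for samples not resolved below the species complex
GAMBIAE_SL = "gambiae_sl"
ALL_SPECIES = SPECIES + (GAMBIAE_SL,)
#: codon-995 alleles, wild type first
ALLELES = ("995L", "995F", "995S")

_COUNT_COLS = ["count_995L", "count_995F", "count_995S"]


@dataclass(frozen=True)
class SpeciesEffects:
    """Logistic-scale coefficients for one species' two allele contrasts.

    The latent allele-frequency triple is a softmax over the linear
    predictors ``(0, eta_F, eta_S)`` where, for contrast c in {F, S},

        eta_c = intercept_c + itn_c * mean(ITN over lags 0..3)
                + sum_v covariates[v][c] * x_v

    ``itn`` therefore measures selection pressure from bed-net coverage on
    the log-odds of the resistance allele against wild type.
    """

    intercept: tuple[float, float]
    itn: tuple[float, float]
    covariates: dict[str, tuple[float, float]] = field(default_factory=dict)


def _default_itn_trajectory() -> dict[int, float]:
    # near-zero coverage through 2004, then the continental ITN scale-up
    years = range(2002, 2018)
    traj = {}
    for y in years:
        if y <= 2004:
            traj[y] = 0.01
        else:
            traj[y] = min(0.65, 0.05 + 0.05 * (y - 2005) * 1.0)
    return traj


def _default_effects() -> dict[str, SpeciesEffects]:
    # Species-segregated structure: strong ITN-driven 995F selection in
    # gambiae/coluzzii, weak in arabiensis; 995S largely confined to
    # gambiae.  cov_01 is a planted environmental driver shared by all.
    driver = {"cov_01": (0.8, 0.4)}
    return {
        "gambiae": SpeciesEffects((-0.5, -1.5), (3.0, 1.5), dict(driver)),
        "coluzzii": SpeciesEffects((-1.5, -3.0), (2.5, 0.3), dict(driver)),
        "arabiensis": SpeciesEffects((-2.5, -3.5), (0.8, 0.1), dict(driver)),
    }


@dataclass
class SynthConfig:
    """Configuration for one synthetic study.

    Defaults describe a desk-scale survey with the structure of the real
    2002-2017 data: 16 calendar years so that three-year lags exist for the
    first mapped year (2005), a dozen covariates, multinomial sampling
    depths of tens of alleles per sample, and bioassay mortality observed
    with measurement noise of sd 0.25 on the empirical-logit scale.
    """

    n_sites: int = 150
    n_samples: int = 500
    years: tuple[int, int] = (2002, 2017)
    n_covariates: int = 12
    spatial_range: float = 1.0
    species_mix: dict[str, float] = field(
        default_factory=lambda: {
            "gambiae": 0.35,
            "coluzzii": 0.25,
            "arabiensis": 0.25,
            "gambiae_sl": 0.15,
        }
    )
    effect_sizes: dict[str, SpeciesEffects] = field(default_factory=_default_effects)
    itn_trajectory: dict[int, float] = field(default_factory=_default_itn_trajectory)
    #: mean total alleles per sample (diploid: 2 x mosquitoes); min 10
    depth_mean: float = 40.0
    depth_dispersion: float = 5.0
    n_bioassays: int = 300
    #: generating mortality model on the empirical-logit scale
    mortality_intercept: float = 1.37
    mortality_slope: float = -0.65
    mortality_noise_sd: float = 0.25
    #: fraction of covariates that vary year to year (the rest are static)
    annual_fraction: float = 0.5
    itn_deviation_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        mix = sum(self.species_mix.values())
        if not np.isclose(mix, 1.0):
            raise ValueError(f"species_mix must sum to 1, got {mix}")
        if any(not np.isfinite(v) for v in self.species_mix.values()):
            raise ValueError("non-finite species_mix entry")
        for y, v in self.itn_trajectory.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"itn_trajectory[{y}]={v} outside [0, 1]")
        if not self.mortality_noise_sd > 0:
            raise ValueError("mortality_noise_sd must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (np.isfinite(self.spatial_range) and self.spatial_range > 0) and not np.isinf(
            self.spatial_range
        ):
            raise ValueError("spatial_range must be positive")
        if self.depth_mean < 10:
            raise ValueError("depth_mean must be >= 10 alleles (5 mosquitoes)")
        if self.years[0] > self.years[1]:
            raise ValueError("years must be an inclusive (first, last) range")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def predict_years(self) -> list[int]:
        """Years for which three-year lags exist inside the grid."""
        return [y for y in self.year_list if y - 3 >= self.years[0]]

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["effect_sizes"] = {
            s: {
                "intercept": list(e["intercept"]),
                "itn": list(e["itn"]),
                "covariates": {k: list(v) for k, v in e["covariates"].items()},
            }
            for s, e in d["effect_sizes"].items()
        }
        d["years"] = list(d["years"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["years"] = tuple(d["years"])
        d["effect_sizes"] = {
            s: SpeciesEffects(
                tuple(e["intercept"]),
                tuple(e["itn"]),
                {k: tuple(v) for k, v in e["covariates"].items()},
            )
            for s, e in d["effect_sizes"].items()
        }
        d["itn_trajectory"] = {int(k): float(v) for k, v in d["itn_trajectory"].items()}
        return cls(**d)

    def _child_rngs(self) -> dict[str, np.random.Generator]:
        names = ["sites", "covariates", "latent", "alleles", "bioassay"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class CovariateGrid:
    """Per-pixel, per-year covariate values (wide layout).

    ``table`` is indexed by (pixel_id, year) with one column per variable;
    ``coords`` maps pixel_id to (longitude, latitude).  ``annual`` lists the
    variables that vary year to year (and are therefore lag-expanded
    downstream); the remainder are static.
    """

    table: pd.DataFrame
    coords: pd.DataFrame
    annual: list[str]
    static: list[str]

    @property
    def variables(self) -> list[str]:
        return self.annual + self.static

    @property
    def years(self) -> list[int]:
        return sorted(self.table.index.get_level_values("year").unique())

    def to_long_csv(self, path) -> None:
        long = (
            self.table.stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_2": "variable"})
        )
        long = long.merge(self.coords.reset_index(), on="pixel_id")
        cols = ["pixel_id", "longitude", "latitude", "year", "variable", "value"]
        long[cols].to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path, annual=None) -> "CovariateGrid":
        long = pd.read_csv(path)
        table = long.pivot_table(
            index=["pixel_id", "year"], columns="variable", values="value"
        )
        table.columns.name = None
        coords = (
            long.groupby("pixel_id")[["longitude", "latitude"]].first().sort_index()
        )
        if annual is None:
            # a variable is annual if it changes over years for some pixel
            annual = [
                v
                for v in table.columns
                if table[v].groupby(level="pixel_id").nunique().gt(1).any()
            ]
        static = [v for v in table.columns if v not in annual]
        return cls(table=table, coords=coords, annual=list(annual), static=static)


@dataclass
class TrueProcess:
    """Ground truth of one synthetic study.

    ``latent`` holds the per-(pixel, year, species) allele-frequency triple
    on the 3-simplex, including the complex-level ``gambiae_sl`` surface
    mixed with weights (R_a, (1-R_a)/2, (1-R_a)/2).  ``relative_abundance``
    is the per-pixel abundance of An. arabiensis relative to the complex.
    """

    latent: pd.DataFrame  # index (pixel_id, year, species), cols f_995L/F/S
    relative_abundance: pd.Series  # index pixel_id, values in [0, 1]
    coefficients: dict[str, SpeciesEffects]
    grid: CovariateGrid

    def frequencies(self, pixel_id: int, year: int, species: str) -> np.ndarray:
        return self.latent.loc[(pixel_id, year, species)].to_numpy()


# ---------------------------------------------------------------------------
# covariate fields


def _exp_cov_cholesky(coords: np.ndarray, spatial_range: float) -> np.ndarray:
    """Cholesky factor of an exponential-covariance GRF over site coords."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if np.isinf(spatial_range):
        cov = np.ones_like(d)
    else:
        cov = np.exp(-d / spatial_range)
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


def generate_covariate_fields(config: SynthConfig) -> CovariateGrid:
    """Draw spatially autocorrelated covariate fields and the ITN surface.

    Each covariate is a zero-mean, unit-variance Gaussian random field with
    exponential covariance exp(-d / spatial_range) over site coordinates.
    Annual covariates evolve as an AR(1) process (lag-1 correlation 0.6)
    across years; static covariates are drawn once.  ITN coverage equals
    the configured national trajectory plus a spatially correlated pixel
    deviation, clipped to [0, 1].
    """
    config.validate()
    rngs = config._child_rngs()
    n = config.n_sites
    coords_xy = rngs["sites"].uniform(0.0, 10.0, size=(n, 2))
    coords = pd.DataFrame(
        coords_xy, columns=["longitude", "latitude"], index=pd.RangeIndex(n, name="pixel_id")
    )
    chol = _exp_cov_cholesky(coords_xy, config.spatial_range)
    rng = rngs["covariates"]
    years = config.year_list
    n_annual = int(round(config.annual_fraction * config.n_covariates))
    names = [f"cov_{i + 1:02d}" for i in range(config.n_covariates)]
    annual_vars = names[:n_annual]
    static_vars = names[n_annual:]

    def grf() -> np.ndarray:
        return chol @ rng.standard_normal(n)

    frames = {}
    rho = 0.6
    for v in names:
        if v in annual_vars:
            cols = {}
            z = grf()
            for y in years:
                if cols:
                    z = rho * z + np.sqrt(1 - rho**2) * grf()
                cols[y] = z.copy()
            frames[v] = pd.DataFrame(cols, index=coords.index)
        else:
            z = grf()
            frames[v] = pd.DataFrame({y: z for y in years}, index=coords.index)

    # ITN coverage: national trajectory + static spatial deviation field
    dev = config.itn_deviation_sd * grf()
    itn = pd.DataFrame(
        {y: np.clip(config.itn_trajectory.get(y, 0.0) + dev, 0.0, 1.0) for y in years},
        index=coords.index,
    )
    frames["itn_coverage"] = itn
    annual_vars = ["itn_coverage"] + annual_vars

    table = pd.concat(
        {v: f.stack() for v, f in frames.items()}, axis=1
    )
    table.index.names = ["pixel_id", "year"]
    table = table.sort_index()
    if not np.isfinite(table.to_numpy()).all():
        raise ValueError("non-finite covariate values generated; check config")
    return CovariateGrid(
        table=table, coords=coords, annual=annual_vars, static=static_vars
    )


# ---------------------------------------------------------------------------
# latent frequencies


def _softmax_triple(eta_f: np.ndarray, eta_s: np.ndarray) -> np.ndarray:
    """Two-contrast softmax onto the 3-simplex with 995L as reference."""
    eta = np.stack([np.zeros_like(eta_f), eta_f, eta_s], axis=-1)
    eta = eta - eta.max(axis=-1, keepdims=True)
    g = np.exp(eta)
    return g / g.sum(axis=-1, keepdims=True)


def species_linear_predictors(
    effects: SpeciesEffects, grid: CovariateGrid, year: int
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (eta_F, eta_S) for all pixels at one year.

    The ITN term uses the mean coverage over lags 0..3 years, mirroring the
    lag structure the learners are offered downstream.
    """
    tbl = grid.table
    lag_years = [year - k for k in range(4)]
    missing = [y for y in lag_years if y not in grid.years]
    if missing:
        raise ValueError(
            f"covariate grid lacks years {missing} needed for lags at {year}"
        )
    itn = np.mean(
        [tbl.xs(y, level="year")["itn_coverage"].to_numpy() for y in lag_years], axis=0
    )
    eta_f = np.full(itn.shape, effects.intercept[0], dtype=float)
    eta_s = np.full(itn.shape, effects.intercept[1], dtype=float)
    eta_f += effects.itn[0] * itn
    eta_s += effects.itn[1] * itn
    at_year = tbl.xs(year, level="year")
    for v, (bf, bs) in effects.covariates.items():
        x = at_year[v].to_numpy()
        eta_f += bf * x
        eta_s += bs * x
    return eta_f, eta_s


def generate_latent_frequencies(
    config: SynthConfig, grid: CovariateGrid
) -> TrueProcess:
    """Map covariates to species-specific allele-frequency surfaces.

    For each identified species a logistic-scale linear model produces two
    contrasts (995F vs 995L, 995S vs 995L) which a softmax maps to the
    3-simplex.  The unresolved ``gambiae_sl`` surface mixes the three
    species surfaces with weights (R_a, (1-R_a)/2, (1-R_a)/2), where R_a is
    a static logistic-transformed Gaussian random field.
    """
    config.validate()
    rngs = config._child_rngs()
    chol = _exp_cov_cholesky(
        grid.coords[["longitude", "latitude"]].to_numpy(), config.spatial_range
    )
    r_a = pd.Series(
        1.0 / (1.0 + np.exp(-(chol @ rngs["latent"].standard_normal(config.n_sites)))),
        index=grid.coords.index,
        name="relative_abundance",
    )

    rows = []
    index = []
    for year in config.predict_years:
        per_species = {}
        for sp in SPECIES:
            eta_f, eta_s = species_linear_predictors(
                config.effect_sizes[sp], grid, year
            )
            per_species[sp] = _softmax_triple(eta_f, eta_s)
            for i, pid in enumerate(grid.coords.index):
                index.append((pid, year, sp))
                rows.append(per_species[sp][i])
        w_a = r_a.to_numpy()[:, None]
        sl = (
            w_a * per_species["arabiensis"]
            + (1.0 - w_a) / 2.0 * (per_species["gambiae"] + per_species["coluzzii"])
        )
        for i, pid in enumerate(grid.coords.index):
            index.append((pid, year, GAMBIAE_SL))
            rows.append(sl[i])

    latent = pd.DataFrame(
        rows,
        columns=[f"f_{a}" for a in ALLELES],
        index=pd.MultiIndex.from_tuples(index, names=["pixel_id", "year", "species"]),
    ).sort_index()
    sums = latent.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-12), "latent triples must lie on the simplex"
    return TrueProcess(
        latent=latent,
        relative_abundance=r_a,
        coefficients=config.effect_sizes,
        grid=grid,
    )


# ---------------------------------------------------------------------------
# observation models


def _draw_depths(rng: np.random.Generator, config: SynthConfig, size: int) -> np.ndarray:
    """Total alleles per sample: 10 + 2 * NegBin, i.e. >= 5 mosquitoes."""
    extra_mean = max((config.depth_mean - 10.0) / 2.0, 1e-9)
    r = config.depth_dispersion
    p = r / (r + extra_mean)
    extra = rng.negative_binomial(r, p, size=size)
    return 10 + 2 * extra


def sample_allele_counts(
    true_process: TrueProcess, config: SynthConfig
) -> pd.DataFrame:
    """Draw the observed allele-sample table from the latent surfaces.

    Each sample picks a site, a year with full lag coverage, and a species
    from the configured mix; its allele counts are multinomial draws of the
    latent frequency triple at configurable depth (minimum 10 alleles, the
    diploid equivalent of the five-mosquito inclusion rule).
    """
    rng = config._child_rngs()["alleles"]
    grid = true_process.grid
    years = config.predict_years
    species_names = list(config.species_mix)
    species_p = np.array([config.species_mix[s] for s in species_names])
    n = config.n_samples
    pix = rng.integers(0, config.n_sites, size=n)
    yr = rng.choice(years, size=n)
    sp = rng.choice(species_names, size=n, p=species_p)
    depth = _draw_depths(rng, config, n)
    pids = grid.coords.index.to_numpy()
    recs = []
    for i in range(n):
        pid = pids[pix[i]]
        f = true_process.frequencies(pid, int(yr[i]), sp[i])
        counts = rng.multinomial(depth[i], f)
        lon, lat = grid.coords.loc[pid]
        recs.append(
            (i, pid, lon, lat, int(yr[i]), sp[i], int(depth[i]), *counts.tolist())
        )
    out = pd.DataFrame(
        recs,
        columns=[
            "sample_id",
            "pixel_id",
            "longitude",
            "latitude",
            "year",
            "species",
            "n_alleles",
            *_COUNT_COLS,
        ],
    ).set_index("sample_id")
    assert (out[_COUNT_COLS].sum(axis=1) == out["n_alleles"]).all()
    return out


def empirical_logit_transform(p, eps: float = 1e-3):
    """Smoothed log-odds ln((p + eps) / (1 - p + eps)); finite at 0 and 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.log((p + eps) / (1.0 - p + eps))


def inverse_empirical_logit(x, eps: float = 1e-3):
    """Inverse of :func:`empirical_logit_transform`, clipped to [0, 1]."""
    e = np.exp(np.asarray(x, dtype=float))
    return np.clip((e * (1.0 + eps) - eps) / (1.0 + e), 0.0, 1.0)


def sample_bioassay_mortality(
    true_process: TrueProcess, config: SynthConfig
) -> pd.DataFrame:
    """Generate deltamethrin-bioassay mortality linked to 995F frequency.

    The complex-level 995F frequency f_C mixes the three species surfaces
    by relative abundance; true mean mortality is linear in the
    empirical-logit of f_C, Gaussian noise of sd ``mortality_noise_sd`` is
    added on that scale, and the result is mapped back to (0, 1).
    """
    from .phenotype import complex_frequency

    rng = config._child_rngs()["bioassay"]
    grid = true_process.grid
    years = config.predict_years
    n = config.n_bioassays
    pids = grid.coords.index.to_numpy()
    pix = pids[rng.integers(0, config.n_sites, size=n)]
    yr = rng.choice(years, size=n)
    lat = true_process.latent
    f_a = np.array([lat.loc[(p, int(y), "arabiensis"), "f_995F"] for p, y in zip(pix, yr)])
    f_g = np.array([lat.loc[(p, int(y), "gambiae"), "f_995F"] for p, y in zip(pix, yr)])
    f_z = np.array([lat.loc[(p, int(y), "coluzzii"), "f_995F"] for p, y in zip(pix, yr)])
    r_a = true_process.relative_abundance.loc[pix].to_numpy()
    f_c = complex_frequency(f_a, f_g, f_z, r_a)
    lin = config.mortality_intercept + config.mortality_slope * empirical_logit_transform(f_c)
    noisy = lin + rng.normal(0.0, config.mortality_noise_sd, size=n)
    mortality = np.clip(inverse_empirical_logit(noisy), 1e-6, 1.0 - 1e-6)
    n_tested = rng.integers(50, 151, size=n)
    coords = grid.coords.loc[pix]
    return pd.DataFrame(
        {
            "pixel_id": pix,
            "longitude": coords["longitude"].to_numpy(),
            "latitude": coords["latitude"].to_numpy(),
            "year": yr.astype(int),
            "n_tested": n_tested,
            "mortality": mortality,
            "f_C_true": f_c,
        }
    )


def generate_dataset(config: SynthConfig):
    """Convenience wrapper: grid, truth, allele samples, bioassays."""
    grid = generate_covariate_fields(config)
    truth = generate_latent_frequencies(config, grid)
    samples = sample_allele_counts(truth, config)
    bioassays = sample_bioassay_mortality(truth, config)
    return grid, truth, samples, bioassays


def write_allele_csv(samples: pd.DataFrame, path) -> None:
    cols = ["longitude", "latitude", "year", "species", "n_alleles", *_COUNT_COLS]
    samples.reset_index()[["sample_id"] + cols].to_csv(path, index=False)


def write_bioassay_csv(bioassays: pd.DataFrame, path) -> None:
    bioassays[["longitude", "latitude", "year", "n_tested", "mortality"]].to_csv(
        path, index=False
    )
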