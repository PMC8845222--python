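"""Linking allele frequencies to bioassay mortality.

Two pieces: (i) aggregation of species-specific 995F frequencies to the
An. gambiae complex level using the relative abundance of An. arabiensis,

    f_C = R_a f_a + (1 - R_a) (f_g + f_z) / 2,

and (ii) an OLS regression of empirical-logit mean mortality on the
empirical-logit of f_C with Newey-West (HAC, Bartlett-kernel)
standard errors to allow for serial autocorrelation.  Observations are
ordered by (year, location) before the HAC step — time is the only
natural serial axis in these data, and the HAC weights depend on that
ordering (point estimates do not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metamodel import DEFAULT_EPS, empirical_logit

__all__ = [
    "complex_frequency",
    "newey_west_bandwidth",
    "newey_west_1994_bandwidth",
    "newey_west_cov",
    "MortalityRegression",
    "MortalityRegressionResults",
]


def complex_frequency(f_a, f_g, f_z, r_a):
    """Complex-level 995F frequency as an abundance-weighted mixture.

    ``r_a`` is the abundance of An. arabiensis relative to the combined
    abundance of An. gambiae and An. coluzzii; the latter two enter with
    equal weight since their relative split is not mapped.  The output is
    a convex combination, so it stays within [min, max] of the inputs.
    """
    f_a, f_g, f_z, r_a = (np.asarray(v, dtype=float) for v in (f_a, f_g, f_z, r_a))
    for name, v in (("f_a", f_a), ("f_g", f_g), ("f_z", f_z), ("R_a", r_a)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    return r_a * f_a + (1.0 - r_a) * (f_g + f_z) / 2.0


def newey_west_bandwidth(n: int) -> int:
    """Plug-in truncation lag L = floor(4 (n/100)^(2/9))."""
    return int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))


def newey_west_1994_bandwidth(design: np.ndarray, residuals: np.ndarray) -> int:
    """Data-driven bandwidth by the weighted-autocovariance procedure.

    Uses the Bartlett-kernel automatic rule: score autocovariances of the
    (weight-one combined) estimating equations up to a pilot lag feed a
    plug-in for the optimal truncation lag, gamma = 1.1447 (s1/s0)^(2/3)
    n^(1/3).
    """
    X = np.asarray(design, dtype=float)
    u = np.asarray(residuals, dtype=float)
    n = len(u)
    # combined score with unit weight on each regressor, intercept excluded
    # from the weighting per the standard implementation
    w = np.ones(X.shape[1])
    const = np.all(X == X[0, :], axis=0)
    w[const] = 0.0
    h = (X * u[:, None]) @ w
    pilot = int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))
    s0 = float(h @ h) / n
    s1 = 0.0
    for l in range(1, pilot + 1):
        gamma_l = float(h[l:] @ h[:-l]) / n
        s0 += 2.0 * gamma_l
        s1 += 2.0 * l * gamma_l
    if s0 <= 0:
        return 0
    gamma = 1.1447 * (abs(s1 / s0)) ** (2.0 / 3.0)
    return max(int(np.floor(gamma * n ** (1.0 / 3.0))), 0)


def newey_west_cov(
    design: np.ndarray, residuals: np.ndarray, bandwidth: int | str = "auto"
) -> np.ndarray:
    """HAC coefficient covariance with Bartlett-kernel weights.

    ``bandwidth`` is the truncation lag L (an integer >= 0), ``"auto"``
    for the plug-in rule L = floor(4 (n/100)^(2/9)), or ``"nw1994"`` for
    the data-driven weighted-autocovariance rule.  Lag weights are
    w_l = 1 - l/(L+1).  L = 0 reduces to the lag-free
    heteroskedasticity-robust (HC0) sandwich.  The output is symmetric
    positive semidefinite.
    """
    X = np.asarray(design, dtype=float)
    u = np.asarray(residuals, dtype=float)
    n, k = X.shape
    if u.shape[0] != n:
        raise ValueError("residuals and design must be conformable")
    if bandwidth == "auto":
        L = newey_west_bandwidth(n)
    elif bandwidth == "nw1994":
        L = newey_west_1994_bandwidth(X, u)
    else:
        L = int(bandwidth)
    if L < 0 or L >= n:
        raise ValueError(f"bandwidth L={L} must satisfy 0 <= L < n={n}")
    scores = X * u[:, None]  # estimating-equation contributions
    S = scores.T @ scores
    for l in range(1, L + 1):
        w = 1.0 - l / (L + 1.0)
        gamma = scores[l:].T @ scores[:-l]
        S += w * (gamma + gamma.T)
    bread = np.linalg.inv(X.T @ X)
    cov = bread @ S @ bread
    return (cov + cov.T) / 2.0


@dataclass
class MortalityRegressionResults:
    """Table-style regression output on the empirical-logit scale."""

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    rsquared_adj: float
    df_resid: int
    bandwidth: int
    nobs: int
    resid: np.ndarray
    cov_params: pd.DataFrame

    @property
    def significant(self) -> pd.Series:
        """Whether each 95% CI excludes zero."""
        return (self.conf_int["lower"] > 0) | (self.conf_int["upper"] < 0)

    def to_table(self) -> pd.DataFrame:
        """One-row frame mirroring the published per-country layout."""
        def fmt(name):
            star = "*" if self.significant[name] else ""
            lo, hi = self.conf_int.loc[name]
            return f"{self.params[name]:.2f}{star} ({lo:.2f}, {hi:.2f})"

        return pd.DataFrame(
            {
                "Intercept (95% CI)": [fmt("intercept")],
                "Vgsc-995F (95% CI)": [fmt("slope")],
                "Adjusted R2": [round(self.rsquared_adj, 2)],
                "Degrees of freedom (df)": [self.df_resid],
                "HAC bandwidth": [self.bandwidth],
            }
        )

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "coef": self.params,
                "NW se": self.bse,
                "ci lower": self.conf_int["lower"],
                "ci upper": self.conf_int["upper"],
            }
        )
        return (
            "OLS of empirical-logit mortality on empirical-logit f_C\n"
            f"  n = {self.nobs}, df = {self.df_resid}, "
            f"adj R2 = {self.rsquared_adj:.3f}, HAC bandwidth = {self.bandwidth}\n"
            + rows.round(4).to_string()
        )


class MortalityRegression:
    """OLS of transformed mean mortality on transformed f_C.

    Both sides pass through the empirical logit with a shared ``eps``.
    Confidence intervals use Newey-West standard errors with normal
    (z = 1.96) critical values, matching large-n practice.
    """

    def __init__(
        self,
        mortality,
        f_c,
        eps: float = DEFAULT_EPS,
        sort_keys: pd.DataFrame | None = None,
    ):
        mortality = np.asarray(mortality, dtype=float)
        f_c = np.asarray(f_c, dtype=float)
        if mortality.shape != f_c.shape or mortality.ndim != 1:
            raise ValueError("mortality and f_C must be 1-D and aligned")
        if len(mortality) < 3:
            raise ValueError("need at least 3 paired observations")
        order = np.arange(len(mortality))
        if sort_keys is not None:
            order = sort_keys.reset_index(drop=True).sort_values(
                list(sort_keys.columns), kind="mergesort"
            ).index.to_numpy()
        self.y = empirical_logit(mortality[order], eps)
        self.x = empirical_logit(f_c[order], eps)
        if np.allclose(self.x, self.x[0]):
            raise np.linalg.LinAlgError("constant covariate: design is rank deficient")
        self.eps = eps

    @classmethod
    def from_tables(
        cls,
        bioassays: pd.DataFrame,
        f_c,
        eps: float = DEFAULT_EPS,
        mortality_col: str = "mortality",
    ) -> "MortalityRegression":
        """Build from a bioassay table; orders by (year, location) for HAC."""
        keys = bioassays[["year", "longitude", "latitude"]]
        return cls(
            bioassays[mortality_col].to_numpy(), np.asarray(f_c), eps=eps,
            sort_keys=keys,
        )

    def fit(self, bandwidth: int | str = "auto") -> MortalityRegressionResults:
        n = len(self.y)
        X = np.column_stack([np.ones(n), self.x])
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ beta
        cov = newey_west_cov(X, resid, bandwidth)
        if bandwidth == "auto":
            L = newey_west_bandwidth(n)
        elif bandwidth == "nw1994":
            L = newey_west_1994_bandwidth(X, resid)
        else:
            L = int(bandwidth)
        se = np.sqrt(np.diag(cov))
        names = ["intercept", "slope"]
        params = pd.Series(beta, index=names)
        bse = pd.Series(se, index=names)
        ci = pd.DataFrame(
            {"lower": beta - 1.96 * se, "upper": beta + 1.96 * se}, index=names
        )
        tss = float(((self.y - self.y.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        return MortalityRegressionResults(
            params=params,
            bse=bse,
            conf_int=ci,
            rsquared_adj=r2_adj,
            df_resid=n - 2,
            bandwidth=L,
            nobs=n,
            resid=resid,
            cov_params=pd.DataFrame(cov, index=names, columns=names),
        )
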