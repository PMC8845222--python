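"""Multinomial-logit stacking meta-model via the multinomial-Poisson trick.

The generalizer combines the out-of-sample allele-frequency predictions of
Q base learners.  Predictions are mapped through the empirical logit and
stored in matrices X^q (q = 1..Q), each N x J.  The linear predictor for
sample i and allele class j is

    V_ij = sum_q beta_j^q X_ij^q,      beta_j^q >= 0,

and class probabilities are the softmax p_ij = exp(V_ij) / sum_j' exp(V_ij').
The multinomial likelihood of the observed allele counts y_ij is fitted
through its Poisson re-expression

    L(y | B, phi) = prod_ij (g_ij exp(phi_i))^{y_ij} exp(-g_ij exp(phi_i)),

with g_ij = exp(V_ij) and one free intercept phi_i per sample.  The phi
maximiser is available in closed form, exp(phi_i) = n_i / G_i(B), and
substituting it recovers the multinomial log-likelihood up to a constant
in B — so the model is fitted by box-constrained quasi-Newton maximisation
of the profiled likelihood, with every coefficient constrained
nonnegative.  Exact zeros are attainable (bound constraints, not an
exp-reparameterisation).

With alternative-specific covariates and no intercepts inside V no
reference-category constraint is needed; any common shift of a sample's
V row is absorbed by phi_i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = [
    "empirical_logit",
    "inverse_empirical_logit",
    "linear_predictor",
    "class_probabilities",
    "poisson_loglik",
    "profile_intercepts",
    "multinomial_loglik",
    "MultinomialStacking",
    "MultinomialStackingResults",
]

DEFAULT_EPS = 1e-3


def empirical_logit(p, eps: float = DEFAULT_EPS):
    """Smoothed log-odds ln((p + eps) / (1 - p + eps)).

    Finite at p = 0 and p = 1, strictly increasing, and antisymmetric
    about p = 0.5.  ``eps`` must be shared between fitting and prediction.
    """
    p = np.asarray(p, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.log((p + eps) / (1.0 - p + eps))


def inverse_empirical_logit(x, eps: float = DEFAULT_EPS):
    e = np.exp(np.asarray(x, dtype=float))
    return np.clip((e * (1.0 + eps) - eps) / (1.0 + e), 0.0, 1.0)


def _as_stack(X) -> np.ndarray:
    """Normalise base-prediction input to a (Q, N, J) float array."""
    if isinstance(X, dict):
        X = [X[k] for k in sorted(X)]
    arrs = [np.asarray(x, dtype=float) for x in X]
    stack = np.stack(arrs, axis=0)
    if stack.ndim != 3:
        raise ValueError("expected Q matrices of shape (N, J)")
    if not np.isfinite(stack).all():
        raise ValueError("transformed base predictions must be finite")
    return stack


def linear_predictor(B: np.ndarray, X_stack: np.ndarray) -> np.ndarray:
    """V_ij = sum_q beta_j^q X_ij^q for all samples; shape (N, J)."""
    B = np.asarray(B, dtype=float)
    X_stack = np.asarray(X_stack, dtype=float)
    if B.shape != (X_stack.shape[0], X_stack.shape[2]):
        raise ValueError(
            f"coefficient shape {B.shape} does not match (Q, J)="
            f"{(X_stack.shape[0], X_stack.shape[2])}"
        )
    return np.einsum("qj,qnj->nj", B, X_stack)


def class_probabilities(V: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction; rows sum to 1 within 1e-12."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if not np.isfinite(V).all():
        raise ValueError("linear predictor must be finite")
    g = np.exp(V - V.max(axis=1, keepdims=True))
    return g / g.sum(axis=1, keepdims=True)


def poisson_loglik(Y, B, phi, X_stack, include_constant: bool = False) -> float:
    """Log of the Poisson-form likelihood.

    sum_ij [ y_ij (V_ij + phi_i) - exp(V_ij + phi_i) ]; the ln y_ij! terms
    are constant in (B, phi) and dropped unless ``include_constant``.
    """
    Y = np.asarray(Y, dtype=float)
    X_stack = _as_stack(X_stack) if np.ndim(X_stack) != 3 else np.asarray(X_stack)
    phi = np.asarray(phi, dtype=float)
    V = linear_predictor(B, X_stack)
    eta = V + phi[:, None]
    ll = float((Y * eta - np.exp(eta)).sum())
    if include_constant:
        ll -= float(gammaln(Y + 1.0).sum())
    return ll


def profile_intercepts(Y, B, X_stack) -> np.ndarray:
    """Closed-form phi maximiser of the Poisson likelihood: n_i / G_i(B).

    Substituting the profile into the Poisson log-likelihood recovers the
    multinomial log-likelihood up to a B-free constant — the defining
    identity of the multinomial-Poisson transformation.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.sum(axis=1)
    if np.any(n <= 0):
        raise ValueError("every sample needs a positive allele total")
    V = linear_predictor(B, X_stack)
    # log G_i computed stably via the softmax shift
    m = V.max(axis=1)
    logG = m + np.log(np.exp(V - m[:, None]).sum(axis=1))
    return np.log(n) - logG


def multinomial_loglik(Y, B, X_stack) -> float:
    """sum_ij y_ij ln p_ij(B) (multinomial kernel, no binomial constant)."""
    Y = np.asarray(Y, dtype=float)
    V = linear_predictor(B, X_stack)
    m = V.max(axis=1, keepdims=True)
    logp = V - m - np.log(np.exp(V - m).sum(axis=1, keepdims=True))
    return float((Y * logp).sum())


@dataclass
class _FitDiagnostics:
    converged: bool
    n_iter: int
    grad_norm: float
    message: str


class MultinomialStacking:
    """Stacking generalizer over base-learner allele-frequency predictions.

    Parameters
    ----------
    counts : (N, J) DataFrame or array
        Observed allele counts y_ij per sample; row sums are the totals n_i.
    base_predictions : mapping or sequence of (N, J) frequency matrices
        One matrix per base learner, on the probability scale; they are
        passed through the empirical logit internally.  A mapping is
        ordered by key so coefficients are reported per learner.
    eps : float
        Empirical-logit smoothing constant, shared with prediction.
    penalty : float
        Optional ridge penalty on the coefficients (default 0 = off).
    """

    def __init__(self, counts, base_predictions, eps: float = DEFAULT_EPS,
                 penalty: float = 0.0):
        if isinstance(base_predictions, dict):
            self.learner_names = list(base_predictions)
            mats = list(base_predictions.values())
        else:
            mats = list(base_predictions)
            self.learner_names = [f"learner_{q + 1}" for q in range(len(mats))]
        if isinstance(counts, pd.DataFrame):
            self.class_names = list(counts.columns)
            self.sample_index = counts.index
            Y = counts.to_numpy(dtype=float)
        else:
            Y = np.asarray(counts, dtype=float)
            self.class_names = [f"class_{j + 1}" for j in range(Y.shape[1])]
            self.sample_index = pd.RangeIndex(Y.shape[0])
        if np.any(Y < 0) or not np.allclose(Y, np.round(Y)):
            raise ValueError("counts must be non-negative integers")
        self.Y = Y
        self.eps = float(eps)
        self.penalty = float(penalty)
        raw = _as_stack(mats)
        if raw.shape[1:] != Y.shape:
            raise ValueError(
                f"base prediction shape {raw.shape[1:]} != counts shape {Y.shape}"
            )
        if Y.shape[0] < Y.shape[1]:
            raise ValueError("need at least J samples")
        if np.any(Y.sum(axis=0) <= 0):
            # fitting still proceeds; the corresponding betas gain no signal
            pass
        self.X = empirical_logit(raw, eps)
        self.Q, self.N, self.J = self.X.shape

    # -- objective --------------------------------------------------------
    def _negloglik_grad(self, b_flat: np.ndarray):
        """Negative profiled Poisson log-likelihood and its B-gradient.

        phi is profiled out in closed form (exp(phi_i) = n_i / G_i), so the
        objective is the Poisson form evaluated at its phi maximiser; its
        gradient equals the multinomial score sum_i (y_ij - n_i p_ij) X^q_ij.
        Both are scaled by the total allele count so the gradient tolerance
        is size-independent.
        """
        B = b_flat.reshape(self.Q, self.J)
        V = linear_predictor(B, self.X)
        m = V.max(axis=1, keepdims=True)
        expV = np.exp(V - m)
        sumexp = expV.sum(axis=1, keepdims=True)
        P = expV / sumexp
        n = self.Y.sum(axis=1)
        phi = np.log(n) - (m[:, 0] + np.log(sumexp[:, 0]))
        eta = V + phi[:, None]  # log Poisson rates at the profile
        nll = -float((self.Y * eta - n[:, None] * P).sum())
        resid = self.Y - n[:, None] * P  # (N, J)
        grad = -np.einsum("nj,qnj->qj", resid, self.X)
        if self.penalty > 0:
            nll += 0.5 * self.penalty * float((B**2).sum())
            grad = grad + self.penalty * B
        w = self.Y.sum()
        return nll / w, grad.ravel() / w

    def fit(
        self,
        start: np.ndarray | None = None,
        tol: float = 1e-7,
        maxiter: int = 500,
    ) -> "MultinomialStackingResults":
        """Maximise the profiled likelihood over B subject to B >= 0.

        Deterministic given the fixed starting point (all beta = 1/3 by
        default).  Raises on non-convergence, carrying the optimizer
        diagnostics; an all-zero coefficient solution is valid output and
        is flagged in the diagnostics message.
        """
        if start is None:
            start = np.full(self.Q * self.J, 1.0 / 3.0)
        res = minimize(
            self._negloglik_grad,
            np.asarray(start, dtype=float).ravel(),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (self.Q * self.J),
            options={"maxiter": maxiter, "gtol": tol, "ftol": 1e-12},
        )
        B = res.x.reshape(self.Q, self.J)
        _, grad = self._negloglik_grad(res.x)
        # projected gradient: at an active bound a positive gradient is fine
        proj = np.where((res.x <= 0) & (grad > 0), 0.0, grad)
        grad_norm = float(np.abs(proj).max())
        converged = bool(res.success or grad_norm < 1e-5)
        if not converged:
            raise RuntimeError(
                f"meta-model failed to converge: {res.message} "
                f"(iter={res.nit}, projected grad={grad_norm:.3g})"
            )
        msg = res.message if np.any(B > 0) else f"{res.message} [all-zero solution]"
        phi = profile_intercepts(self.Y, B, self.X)
        diagnostics = _FitDiagnostics(converged, int(res.nit), grad_norm, str(msg))
        out = MultinomialStackingResults(
            self, B, phi, multinomial_loglik(self.Y, B, self.X), diagnostics
        )
        out.objective = -res.fun * self.Y.sum()  # profiled Poisson log-lik
        return out


class MultinomialStackingResults:
    """Fitted stacking coefficients, profiled intercepts and diagnostics."""

    def __init__(self, model, B, phi, llf, diagnostics):
        self.model = model
        self.B = np.asarray(B)
        self.phi = np.asarray(phi)
        self.llf = float(llf)
        self.diagnostics = diagnostics
        self.bse_: pd.DataFrame | None = None

    @property
    def params(self) -> pd.DataFrame:
        """Coefficients beta_j^q, rows = learners, columns = classes."""
        return pd.DataFrame(
            self.B, index=self.model.learner_names, columns=self.model.class_names
        )

    @property
    def n_coefficients(self) -> int:
        return self.B.size

    @property
    def fittedvalues(self) -> pd.DataFrame:
        """In-design predicted class probabilities."""
        P = class_probabilities(linear_predictor(self.B, self.model.X))
        return pd.DataFrame(
            P, index=self.model.sample_index, columns=self.model.class_names
        )

    def predict(self, base_predictions) -> np.ndarray:
        """Ensemble simplex predictions for new base-learner frequencies.

        For final mapping the inputs are the learners' in-sample-refit
        predictions; the same empirical-logit eps as fitting is applied.
        """
        if isinstance(base_predictions, dict):
            base_predictions = [base_predictions[k] for k in self.model.learner_names]
        raw = _as_stack(base_predictions)
        X = empirical_logit(raw, self.model.eps)
        return class_probabilities(linear_predictor(self.B, X))

    def bootstrap_se(self, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
        """Nonparametric bootstrap over samples as uncertainty surrogate."""
        rng = np.random.default_rng(seed)
        m = self.model
        draws = np.empty((n_boot, m.Q, m.J))
        raw = inverse_empirical_logit(m.X, m.eps)
        for b in range(n_boot):
            idx = rng.integers(0, m.N, size=m.N)
            boot = MultinomialStacking(
                m.Y[idx], [raw[q][idx] for q in range(m.Q)], eps=m.eps,
                penalty=m.penalty,
            )
            draws[b] = boot.fit().B
        self.bse_ = pd.DataFrame(
            draws.std(axis=0, ddof=1), index=m.learner_names, columns=m.class_names
        )
        return self.bse_

    def summary(self) -> str:
        lines = [
            "Multinomial stacking meta-model (multinomial-Poisson profile fit)",
            f"  samples: {self.model.N}   classes: {self.model.J}   "
            f"learners: {self.model.Q}",
            f"  log-likelihood: {self.llf:.4f}   eps: {self.model.eps}",
            f"  converged: {self.diagnostics.converged} "
            f"(iter={self.diagnostics.n_iter}, "
            f"|proj grad|={self.diagnostics.grad_norm:.2e})",
            "",
            "Nonnegative stacking coefficients beta_j^q:",
            self.params.round(4).to_string(),
        ]
        if self.bse_ is not None:
            lines += ["", "Bootstrap standard errors:", self.bse_.round(4).to_string()]
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "eps": self.model.eps,
            "penalty": self.model.penalty,
            "learners": self.model.learner_names,
            "classes": self.model.class_names,
            "B": self.B.tolist(),
            "llf": self.llf,
            "converged": self.diagnostics.converged,
            "n_iter": self.diagnostics.n_iter,
            "grad_norm": self.diagnostics.grad_norm,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def load_coefficients(path) -> tuple[pd.DataFrame, float]:
        """Read back (coefficients, eps) for prediction-only runs."""
        with open(path) as fh:
            d = json.load(fh)
        B = pd.DataFrame(d["B"], index=d["learners"], columns=d["classes"])
        return B, float(d["eps"])
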