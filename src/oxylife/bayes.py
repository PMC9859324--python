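"""Bayesian ecological regression with spatial (CAR) or exchangeable noise.

Two models for a regional outcome y (life expectancy, years):

* CAR model:  y_i = alpha + x_i' beta + u_i + v_i, where u follows an
  intrinsic conditional-autoregressive (GMRF) prior with joint precision
  tau_u * (D - W) built from the raw symmetric inverse-distance weights W
  (D = diag of row sums), and v_i ~ N(0, sigma_v^2) is exchangeable noise.
* IID model:  y_i = alpha + x_i' beta + v_i (no spatial term).

The intercept and slopes carry hierarchical Gaussian priors centred at zero
whose precisions, like the two noise precisions, get Gamma hyperpriors
(shape 1, rate 0.1 for coefficients; shape 1, rate 0.05 for u and v) — the
log-Gamma convention on log-precisions familiar from latent Gaussian
modelling. All full conditionals are conjugate (Gaussian or Gamma), so the
posterior is explored by a blocked Gibbs sampler: (alpha, beta) jointly,
u jointly from its n-dimensional Gaussian conditional with a sum-to-zero
constraint applied by centring (the intrinsic CAR is improper; the intercept
absorbs the level), then the precisions.

Model choice is gated by Moran's I (spatial autocorrelation present ->
CAR) and models are compared by DIC; fit quality is summarised by the
adjusted R^2 of posterior-mean fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.sparse.csgraph import connected_components

from .spatial import MoranResult, WeightMatrix

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_iid",
    "fit_car",
    "fit",
    "scaled_car_structure",
    "dic",
    "adjusted_r2",
    "adjusted_r2_score",
    "select_spatial_model",
    "sample_coefficients",
    "sample_spatial_effects",
    "sample_precision",
    "split_rhat",
]


@dataclass
class ModelSpec:
    """Sampler configuration: model family, priors and MCMC schedule.

    Priors are (shape, rate) pairs for Gamma hyperpriors on precisions.
    ``fixed_tau_*`` pin a precision to a constant instead of sampling it
    (used for closed-form checks and for the CAR -> IID nesting limit).
    """

    model: str = "car"
    covariate_names: tuple | None = None
    prior_coef: tuple = (1.0, 0.1)    # tau_alpha and tau_beta hyperprior
    prior_u: tuple = (1.0, 0.05)
    prior_v: tuple = (1.0, 0.05)
    n_chains: int = 4
    n_iter: int = 15000
    n_burnin: int = 5000
    thin: int = 1
    seed: int = 0
    fixed_tau_coef: float | None = None
    fixed_tau_v: float | None = None
    fixed_tau_u: float | None = None

    def __post_init__(self):
        if self.model not in ("car", "iid"):
            raise ValueError("model must be 'car' or 'iid'")
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        for pair in (self.prior_coef, self.prior_u, self.prior_v):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError("prior shapes and rates must be positive")


@dataclass
class FitResult:
    """Posterior draws and summaries from a Gibbs fit."""

    model: str
    covariate_names: tuple
    draws: dict                      # name -> (chains, kept[, dim]) arrays
    summaries: pd.DataFrame          # mean, sd, q2.5, q97.5, rhat
    y: np.ndarray
    X: np.ndarray
    dic: float = np.nan
    p_d: float = np.nan
    adjusted_r2_fixed: float = np.nan
    adjusted_r2_full: float = np.nan

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains: (total_kept[, dim])."""
        d = self.draws[name]
        return d.reshape(d.shape[0] * d.shape[1], *d.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.draws["alpha"].shape[0] * self.draws["alpha"].shape[1]

    def posterior_mean(self, name: str):
        return self.stacked(name).mean(axis=0)

    def fitted_values(self, include_spatial: bool = True) -> np.ndarray:
        mu = self.posterior_mean("alpha") + self.X @ self.posterior_mean("beta")
        if include_spatial and "u" in self.draws:
            mu = mu + self.posterior_mean("u")
        return mu

    def draws_frame(self, include_spatial: bool = False) -> pd.DataFrame:
        """Pooled draws, one column per scalar parameter."""
        cols = {"alpha": self.stacked("alpha")}
        beta = self.stacked("beta")
        for j, name in enumerate(self.covariate_names):
            cols[f"beta[{name}]"] = beta[:, j]
        cols["precision_v"] = self.stacked("tau_v")
        if "tau_u" in self.draws:
            cols["precision_u"] = self.stacked("tau_u")
            if include_spatial:
                u = self.stacked("u")
                for i in range(u.shape[1]):
                    cols[f"u[{i}]"] = u[:, i]
        return pd.DataFrame(cols)

    def summaries_json(self) -> dict:
        out = {
            "model": self.model,
            "covariates": list(self.covariate_names),
            "dic": self.dic,
            "p_d": self.p_d,
            "adjusted_r2_fixed": self.adjusted_r2_fixed,
            "adjusted_r2_full": self.adjusted_r2_full,
            "parameters": {
                str(k): {c: float(v) for c, v in row.items()}
                for k, row in self.summaries.iterrows()
            },
        }
        return out


# ---------------------------------------------------------------------------
# full-conditional samplers (exposed so conjugacy can be verified directly)

def sample_coefficients(rng, y_partial, Z, tau_v, prior_prec):
    """Draw (alpha, beta) from their joint Gaussian full conditional.

    y_partial is the outcome minus all other mean components (u for the CAR
    model); Z is the design [1 X]; prior_prec the diagonal prior precisions
    of the coefficients. Posterior precision A = tau_v Z'Z + P, mean
    A^{-1} tau_v Z'y_partial.
    """
    A = tau_v * (Z.T @ Z) + np.diag(prior_prec)
    c, low = cho_factor(A, lower=True)
    mean = cho_solve((c, low), tau_v * (Z.T @ y_partial))
    z = rng.standard_normal(Z.shape[1])
    return mean + solve_triangular(c, z, lower=True, trans="T")


def sample_spatial_effects(rng, resid_fixed, tau_v, tau_u, Qstar):
    """Draw the CAR vector u from its Gaussian full conditional, centred.

    Conditional precision Qc = tau_u (D - W) + tau_v I and mean
    Qc^{-1} tau_v (y - Z theta); the draw is centred to satisfy the
    sum-to-zero identifiability constraint of the intrinsic CAR.
    """
    n = resid_fixed.size
    Qc = tau_u * Qstar + tau_v * np.eye(n)
    c, low = cho_factor(Qc, lower=True)
    mean = cho_solve((c, low), tau_v * resid_fixed)
    draw = mean + solve_triangular(c, rng.standard_normal(n), lower=True,
                                   trans="T")
    return draw - draw.mean()


def sample_precision(rng, shape, rate):
    """Gamma(shape, rate) draw (rate parameterisation)."""
    return rng.gamma(shape, 1.0 / rate)


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over a (n_chains, n_kept) array of scalar draws."""
    c, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    seqs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    B = n * means.var(ddof=1)
    W = seqs.var(axis=1, ddof=1).mean()
    if W == 0:
        return np.nan
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


# ---------------------------------------------------------------------------

def _validate_design(y, X):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("y and X must be finite (no missing values)")
    if X.shape[1] and np.any(X.std(axis=0) == 0):
        bad = int(np.argmax(X.std(axis=0) == 0))
        raise ValueError(f"covariate column {bad} has zero variance")
    Z = np.column_stack([np.ones(y.size), X])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    return y, X, Z


def _gibbs(y, X, spec: ModelSpec, Qstar=None):
    y, X, Z = _validate_design(y, X)
    n, p = X.shape
    car = Qstar is not None
    # Sample on centred covariates: with zero-centred hierarchical priors a
    # raw-scale covariate of large mean can act as a surrogate intercept
    # (an unidentified mode the spatial term happily supports). Centring
    # removes that mode; the intercept is translated back per draw.
    x_means = X.mean(axis=0)
    Z = np.column_stack([np.ones(n), X - x_means])
    names = tuple(spec.covariate_names) if spec.covariate_names \
        else tuple(f"x{j}" for j in range(p))
    if len(names) != p:
        raise ValueError("covariate_names length mismatch")

    a_c, b_c = spec.prior_coef
    a_u, b_u = spec.prior_u
    a_v, b_v = spec.prior_v

    kept = (spec.n_iter - spec.n_burnin) // spec.thin
    shapes = {"alpha": (spec.n_chains, kept),
              "beta": (spec.n_chains, kept, p),
              "tau_v": (spec.n_chains, kept),
              "tau_alpha": (spec.n_chains, kept),
              "tau_beta": (spec.n_chains, kept)}
    if car:
        shapes["u"] = (spec.n_chains, kept, n)
        shapes["tau_u"] = (spec.n_chains, kept)
    draws = {k: np.empty(s) for k, s in shapes.items()}

    # deterministic per-chain streams derived from the configured seed
    seed_seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)

    # OLS starting values shared across chains
    theta0, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid0 = y - Z @ theta0
    tau_v0 = 1.0 / max(resid0.var(), 1e-6)

    for chain, ss in enumerate(seed_seqs):
        rng = np.random.default_rng(ss)
        theta = theta0.copy()
        u = np.zeros(n)
        tau_v = spec.fixed_tau_v if spec.fixed_tau_v is not None else tau_v0
        tau_u = spec.fixed_tau_u if spec.fixed_tau_u is not None else 1.0
        tau_a = spec.fixed_tau_coef if spec.fixed_tau_coef is not None else 1.0
        tau_b = spec.fixed_tau_coef if spec.fixed_tau_coef is not None else 1.0

        k = 0
        for it in range(spec.n_iter):
            prior_prec = np.concatenate([[tau_a], np.full(p, tau_b)])
            theta = sample_coefficients(rng, y - u, Z, tau_v, prior_prec)
            if car:
                u = sample_spatial_effects(rng, y - Z @ theta, tau_v, tau_u,
                                           Qstar)
                if spec.fixed_tau_u is None:
                    tau_u = sample_precision(
                        rng, a_u + 0.5 * (n - 1), b_u + 0.5 * (u @ Qstar @ u))
            resid = y - Z @ theta - u
            if spec.fixed_tau_v is None:
                tau_v = sample_precision(rng, a_v + 0.5 * n,
                                         b_v + 0.5 * (resid @ resid))
            if spec.fixed_tau_coef is None:
                tau_a = sample_precision(rng, a_c + 0.5,
                                         b_c + 0.5 * theta[0] ** 2)
                if p:
                    tau_b = sample_precision(
                        rng, a_c + 0.5 * p, b_c + 0.5 * (theta[1:] @ theta[1:]))
            if it >= spec.n_burnin and (it - spec.n_burnin) % spec.thin == 0:
                # intercept on the original covariate scale
                draws["alpha"][chain, k] = theta[0] - x_means @ theta[1:]
                draws["beta"][chain, k] = theta[1:]
                draws["tau_v"][chain, k] = tau_v
                draws["tau_alpha"][chain, k] = tau_a
                draws["tau_beta"][chain, k] = tau_b
                if car:
                    draws["u"][chain, k] = u
                    draws["tau_u"][chain, k] = tau_u
                k += 1

    result = FitResult(model="car" if car else "iid", covariate_names=names,
                       draws=draws, summaries=_summaries(draws, names),
                       y=y, X=X)
    if result.n_draws >= 100:
        result.dic, result.p_d = dic(result)
    if n > p + 1:
        result.adjusted_r2_fixed = adjusted_r2(result, include_spatial=False)
        result.adjusted_r2_full = adjusted_r2(result, include_spatial=True)
    return result


def _summaries(draws, names) -> pd.DataFrame:
    rows = {}

    def add(label, chains):
        flat = chains.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows[label] = {"mean": flat.mean(), "sd": flat.std(ddof=1),
                       "q2.5": lo, "q97.5": hi, "rhat": split_rhat(chains)}

    add("alpha", draws["alpha"])
    for j, name in enumerate(names):
        add(f"beta[{name}]", draws["beta"][:, :, j])
    add("precision_v", draws["tau_v"])
    if "tau_u" in draws:
        add("precision_u", draws["tau_u"])
        for i in range(draws["u"].shape[2]):
            add(f"u[{i}]", draws["u"][:, :, i])
    return pd.DataFrame.from_dict(rows, orient="index")


def scaled_car_structure(W: WeightMatrix) -> np.ndarray:
    """Intrinsic-CAR structure matrix D - W_raw, scaled to unit field size.

    The raw structure matrix's generalized inverse has an arbitrary overall
    scale (inverse-distance weights carry units of 1/km), so the precision
    parameter would be uninterpretable. Following standard GMRF practice the
    structure is multiplied by the geometric mean of the marginal variances
    of its generalized inverse on the sum-to-zero subspace, making a unit
    precision correspond to a unit-sized spatial field.
    """
    raw = W.raw
    Q = np.diag(raw.sum(axis=1)) - raw
    lam, vec = np.linalg.eigh(Q)
    keep = lam > 1e-10 * lam.max()
    marg_var = ((vec[:, keep] ** 2) / lam[keep]).sum(axis=1)
    c = float(np.exp(np.log(marg_var).mean()))
    return Q * c


def fit_iid(y, X, spec: ModelSpec | None = None, **kwargs) -> FitResult:
    """Fit the exchangeable-noise (IID) model by Gibbs sampling."""
    spec = replace(spec, model="iid") if spec else ModelSpec(model="iid", **kwargs)
    return _gibbs(y, X, spec)


def fit_car(y, X, W: WeightMatrix, spec: ModelSpec | None = None,
            scale_structure: bool = True, **kwargs) -> FitResult:
    """Fit the intrinsic-CAR spatial model by Gibbs sampling.

    The CAR structure matrix is D - W_raw from the symmetric raw weights
    (scaled to unit field size unless ``scale_structure=False``); its null
    space is the constant vector, so the graph of positive weights must be
    connected for the model to be identified up to level.
    """
    spec = replace(spec, model="car") if spec else ModelSpec(model="car", **kwargs)
    raw = W.raw
    n_comp, _ = connected_components((raw > 0).astype(int), directed=False)
    if n_comp > 1:
        raise ValueError(
            f"weight graph has {n_comp} connected components; the intrinsic "
            "CAR prior requires a connected graph")
    if scale_structure:
        Qstar = scaled_car_structure(W)
    else:
        Qstar = np.diag(raw.sum(axis=1)) - raw
    return _gibbs(y, X, spec, Qstar=Qstar)


def fit(y, X, W: WeightMatrix | None, spec: ModelSpec) -> FitResult:
    if spec.model == "car":
        if W is None:
            raise ValueError("CAR model needs a weight matrix")
        return fit_car(y, X, W, spec)
    return fit_iid(y, X, spec)


def dic(result: FitResult) -> tuple:
    """Deviance information criterion and effective parameter count.

    Deviance D = -2 log N(y | mu, sigma_v^2) summed over regions, with mu the
    model mean including the spatial term when present. DIC = mean D over
    draws + p_D, p_D = mean D - D at the posterior means (plug-in uses the
    posterior means of mu and of sigma_v^2).
    """
    if result.n_draws < 100:
        raise ValueError("need at least 100 retained draws for DIC")
    y, X = result.y, result.X
    alpha = result.stacked("alpha")
    beta = result.stacked("beta")
    mu = alpha[:, None] + beta @ X.T
    if "u" in result.draws:
        mu = mu + result.stacked("u")
    sigma2 = 1.0 / result.stacked("tau_v")
    n = y.size
    sse = ((y[None, :] - mu) ** 2).sum(axis=1)
    dev = n * np.log(2 * np.pi * sigma2) + sse / sigma2
    d_bar = dev.mean()
    mu_hat = mu.mean(axis=0)
    s2_hat = sigma2.mean()
    d_hat = n * np.log(2 * np.pi * s2_hat) + ((y - mu_hat) ** 2).sum() / s2_hat
    p_d = d_bar - d_hat
    return float(d_bar + p_d), float(p_d)


def adjusted_r2_score(y, fitted, p: int) -> float:
    """Adjusted R^2 of fitted values against y with p fixed-effect covariates.

    R^2 = 1 - SSE/SST; adjusted = 1 - (1 - R^2)(n - 1)/(n - p - 1).
    Requires n > p + 1.
    """
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = y.size
    if n <= p + 1:
        raise ValueError("adjusted R^2 needs n > p + 1")
    sse = float(((y - fitted) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def adjusted_r2(result: FitResult, include_spatial: bool = True) -> float:
    """Adjusted R^2 of posterior-mean fitted values; p counts covariates."""
    mu = result.fitted_values(include_spatial=include_spatial)
    return adjusted_r2_score(result.y, mu, result.X.shape[1])


def select_spatial_model(moran: MoranResult, alpha: float = 0.05) -> str:
    """Model gate: CAR when the Moran test rejects at level alpha (strict)."""
    return "car" if moran.p_value < alpha else "iid"
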