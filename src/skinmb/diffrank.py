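"""Bayesian negative-binomial differential ranking.

Each feature j is modelled as

    y_ij ~ NB(mu_ij, phi_j),   log mu_ij = log depth_i + x_i' beta_j

with sequencing depth as a fixed offset, Normal(0, prior_sd) priors on the
coefficients and a log-Normal prior on the inverse-dispersion phi_j.
Posterior draws come from several independent MCMC chains per feature
(random-walk Metropolis initialised at the MAP with a Laplace-approximation
proposal covariance); convergence is diagnosed with the Gelman-Rubin R-hat,
model fit with the log pointwise predictive density (lppd) and posterior
predictive coverage.

Because microbiome counts are compositional, the per-covariate
coefficients are reported mean-centered across features ("differentials"):
only their ordering and differences are identified, which is what the
downstream log-ratio panel selection consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "NBModelSpec",
    "DesignMatrix",
    "DifferentialResult",
    "prevalence_filter",
    "build_design",
    "fit_nb_differentials",
    "compute_rhat",
    "rank_features",
]


# --------------------------------------------------------------------------- #
# filtering and design
# --------------------------------------------------------------------------- #

def prevalence_filter(table: pd.DataFrame, min_prevalence: int = 15) -> pd.DataFrame:
    """Keep features observed (count > 0) in at least ``min_prevalence``
    samples (inclusive threshold)."""
    if min_prevalence < 1:
        raise ValueError("min_prevalence must be >= 1")
    if min_prevalence > len(table):
        raise ValueError(
            f"min_prevalence={min_prevalence} exceeds the number of samples ({len(table)})"
        )
    prevalence = (table > 0).sum(axis=0)
    return table.loc[:, prevalence >= min_prevalence]


@dataclass(frozen=True)
class DesignMatrix:
    """Covariate design with intercept, reference-coded study dummies and
    standardized continuous covariates; standardization constants are kept
    for back-transformation to natural units."""

    X: pd.DataFrame  # samples x design columns (includes Intercept)
    scaling: dict[str, tuple[float, float]]  # covariate -> (mean, sd)
    n_dropped: int

    @property
    def sample_ids(self) -> pd.Index:
        return self.X.index

    def covariate_columns(self) -> list[str]:
        return [c for c in self.X.columns if c != "Intercept"]


def build_design(metadata: pd.DataFrame, covariates: list[str]) -> DesignMatrix:
    """Build the model design from metadata.

    ``study_id`` (or any non-numeric field) is reference-coded into
    dummies; numeric fields are standardized to mean 0, SD 1.  Samples
    missing any listed covariate are dropped (count logged)."""
    missing_cols = [c for c in covariates if c not in metadata.columns]
    if missing_cols:
        raise KeyError(f"covariate column(s) absent from metadata: {missing_cols}")
    sub = metadata[covariates].copy()
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info("build_design: dropped %d sample(s) with missing covariates", n_dropped)

    parts = [pd.Series(1.0, index=complete.index, name="Intercept")]
    scaling: dict[str, tuple[float, float]] = {}
    for cov in covariates:
        col = complete[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True).astype(float)
            for c in dummies.columns:
                parts.append(dummies[c])
        else:
            mean, sd = float(col.mean()), float(col.std(ddof=0))
            if sd == 0:
                raise ValueError(f"covariate {cov!r} is constant")
            scaling[cov] = (mean, sd)
            parts.append(((col - mean) / sd).rename(cov))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns involved: those whose removal restores full rank
        culprits = []
        arr = X.to_numpy()
        for i, c in enumerate(X.columns):
            reduced = np.delete(arr, i, axis=1)
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                culprits.append(c)
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {culprits}")
    return DesignMatrix(X=X, scaling=scaling, n_dropped=n_dropped)


# --------------------------------------------------------------------------- #
# model spec and posterior
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class NBModelSpec:
    """Sampler configuration.  ``num_iter`` post-warmup draws per chain,
    ``chains`` independent chains (>= 2, required by R-hat)."""

    prior_sd_coef: float = 5.0
    dispersion_prior: tuple[float, float] = (0.0, 1.0)  # mean, sd of log phi
    num_iter: int = 200
    num_warmup: int = 50
    chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2 (R-hat is undefined for a single chain)")
        if self.num_iter < 1:
            raise ValueError("num_iter must be >= 1")
        if self.num_warmup < 0:
            raise ValueError("num_warmup must be >= 0")
        if self.prior_sd_coef <= 0:
            raise ValueError("prior_sd_coef must be > 0")


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    return (
        gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )


def _log_post_and_grad(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                       offset: np.ndarray, spec: NBModelSpec):
    beta, log_phi = theta[:-1], theta[-1]
    phi = np.exp(log_phi)
    eta = offset + X @ beta
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)
    ll = float(_nb_logpmf(y, mu, phi).sum())
    mu_p, sd_p = spec.dispersion_prior
    lp = (
        ll
        - 0.5 * float(beta @ beta) / spec.prior_sd_coef ** 2
        - 0.5 * ((log_phi - mu_p) / sd_p) ** 2
    )
    w = phi / (phi + mu)
    g_beta = X.T @ ((y - mu) * w) - beta / spec.prior_sd_coef ** 2
    g_logphi = phi * float(
        (digamma(y + phi) - digamma(phi) + np.log(w) + 1.0 - (y + phi) / (phi + mu)).sum()
    ) - (log_phi - mu_p) / sd_p ** 2
    return lp, np.append(g_beta, g_logphi)


def _log_post(theta, y, X, offset, spec) -> float:
    return _log_post_and_grad(theta, y, X, offset, spec)[0]


def _map_and_laplace(y, X, offset, spec):
    """Posterior mode and a Cholesky factor of the Laplace covariance."""
    from scipy.optimize import minimize

    p = X.shape[1]
    x0 = np.zeros(p + 1)
    with np.errstate(over="ignore", divide="ignore"):
        base = np.log(max(float(np.mean(y / np.exp(offset))), 1e-8))
    x0[0] = base  # intercept column is first

    def neg(theta):
        lp, g = _log_post_and_grad(theta, y, X, offset, spec)
        return -lp, -g

    res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-10})
    theta_map = res.x
    # numerical Hessian of -log posterior from the analytic gradient
    d = len(theta_map)
    H = np.zeros((d, d))
    eps = 1e-4
    for i in range(d):
        tp = theta_map.copy(); tp[i] += eps
        tm = theta_map.copy(); tm[i] -= eps
        H[:, i] = (-_log_post_and_grad(tp, y, X, offset, spec)[1]
                   + _log_post_and_grad(tm, y, X, offset, spec)[1]) / (2 * eps)
    H = 0.5 * (H + H.T)
    # regularize to the prior curvature if ill-conditioned
    try:
        jitter = 1e-6 * max(1.0, float(np.abs(np.diag(H)).max()))
        L_cov = np.linalg.cholesky(np.linalg.inv(H + jitter * np.eye(d)))
    except np.linalg.LinAlgError:
        L_cov = np.eye(d) * spec.prior_sd_coef / 10.0
    return theta_map, L_cov


def _run_chain(theta_map, L_cov, theta0, y, X, offset, spec, rng):
    """Metropolis sampler mixing two proposal kernels: an independence
    proposal from a slightly widened Laplace approximation N(MAP, (1.2 L)
    (1.2 L)') — near-IID draws when the Laplace fit is good — and a
    Laplace-preconditioned random walk whose global scale adapts toward
    ~30% acceptance during warmup (robustness when it is not)."""
    d = len(theta0)
    scale = 2.38 / np.sqrt(d)
    ind_scale = 1.2
    L_ind = ind_scale * L_cov
    # solve L_ind z = (theta - map) for the independence-proposal density
    from scipy.linalg import solve_triangular

    def log_q(theta):
        z = solve_triangular(L_ind, theta - theta_map, lower=True)
        return -0.5 * float(z @ z)

    theta = theta0.copy()
    lp = _log_post(theta, y, X, offset, spec)
    lq = log_q(theta)
    draws = np.empty((spec.num_iter, d))
    n_total = spec.num_warmup + spec.num_iter
    for t in range(n_total):
        if rng.random() < 0.5:  # independence move
            prop = theta_map + L_ind @ rng.standard_normal(d)
            lp_prop = _log_post(prop, y, X, offset, spec)
            lq_prop = log_q(prop)
            if np.log(rng.random()) < (lp_prop - lp) - (lq_prop - lq):
                theta, lp, lq = prop, lp_prop, lq_prop
        else:  # random-walk move
            prop = theta + scale * (L_cov @ rng.standard_normal(d))
            lp_prop = _log_post(prop, y, X, offset, spec)
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                theta, lp = prop, lp_prop
                lq = log_q(theta)
            if t < spec.num_warmup:
                scale *= np.exp(0.05 * ((1.0 if accept else 0.0) - 0.3))
        if t >= spec.num_warmup:
            draws[t - spec.num_warmup] = theta
    return draws


@dataclass
class DifferentialResult:
    """Per-feature, per-covariate posterior summaries plus model-level
    diagnostics.  Differentials are mean-centered across features within
    each covariate (identified only up to an additive constant)."""

    differentials: pd.DataFrame  # features x covariates, posterior means (centered)
    ci_low: pd.DataFrame  # centered 2.5% bounds
    ci_high: pd.DataFrame  # centered 97.5% bounds
    r_hat: pd.DataFrame  # features x covariates
    lppd: float
    ppc_coverage: float
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        out = self.differentials.copy()
        for c in self.r_hat.columns:
            out[f"rhat_{c}"] = self.r_hat[c]
        out.to_csv(path, sep="\t", index_label="feature_id")

    def diagnostics(self) -> dict:
        return {
            "lppd": float(self.lppd),
            "ppc_coverage": float(self.ppc_coverage),
            "max_r_hat": float(np.nanmax(self.r_hat.to_numpy())),
            "frac_r_hat_below_1.1": float((self.r_hat.to_numpy() < 1.1).mean()),
        }


def fit_nb_differentials(
    table: pd.DataFrame,
    design: DesignMatrix,
    spec: NBModelSpec,
    depths: pd.Series | None = None,
) -> DifferentialResult:
    """Fit the per-feature NB regression and summarize the posterior.

    ``table`` holds unrarefied counts (samples x features); sequencing
    depth enters as a log offset, taken from ``depths`` if given, else from
    the table's row sums.  Fixed ``spec.seed`` gives identical draws."""
    common = design.sample_ids.intersection(table.index)
    if len(common) != len(design.sample_ids):
        missing = design.sample_ids.difference(table.index)
        raise KeyError(f"design rows absent from table: {list(missing)[:5]}")
    table = table.loc[design.sample_ids]
    counts = table.to_numpy()
    if not np.allclose(counts, np.rint(counts)) or (counts < 0).any():
        raise ValueError("feature table must hold non-negative integer counts")
    counts = np.rint(counts).astype(np.int64)

    if depths is None:
        depth_vec = counts.sum(axis=1).astype(float)
    else:
        depth_vec = depths.loc[design.sample_ids].to_numpy(dtype=float)
    if (depth_vec <= 0).any():
        raise ValueError("every sample needs positive depth")
    offset = np.log(depth_vec)

    X = design.X.to_numpy(dtype=float)
    cov_cols = design.covariate_columns()
    cov_ix = [design.X.columns.get_loc(c) for c in cov_cols]
    features = list(table.columns)

    means = np.zeros((len(features), len(cov_cols)))
    lo = np.zeros_like(means)
    hi = np.zeros_like(means)
    rhat = np.zeros_like(means)
    lppd_total = 0.0
    ppc_inside = 0
    ppc_n = 0

    for j, feat in enumerate(features):
        y = counts[:, j].astype(float)
        theta_map, L_cov = _map_and_laplace(y, X, offset, spec)
        chain_draws = []
        for c in range(spec.chains):
            rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, j, c])
            theta0 = theta_map + 0.3 * (L_cov @ rng.standard_normal(len(theta_map)))
            chain_draws.append(_run_chain(theta_map, L_cov, theta0, y, X, offset, spec, rng))
        stacked = np.stack(chain_draws)  # chains x iter x dim
        pooled = stacked.reshape(-1, stacked.shape[-1])
        for k, ix in enumerate(cov_ix):
            draws_k = pooled[:, ix]
            means[j, k] = draws_k.mean()
            lo[j, k], hi[j, k] = np.percentile(draws_k, [2.5, 97.5])
            rhat[j, k] = compute_rhat(stacked[:, :, ix])

        # model diagnostics on a thinned subset of draws
        thin = pooled[:: max(1, len(pooled) // 100)]
        etas = np.clip(offset[None, :] + thin[:, :-1] @ X.T, -30, 30)
        mus = np.exp(etas)
        phis = np.exp(thin[:, -1])[:, None]
        logp = _nb_logpmf(y[None, :], mus, phis)  # draws x samples
        m = logp.shape[0]
        lppd_total += float((np.logaddexp.reduce(logp, axis=0) - np.log(m)).sum())
        rng_ppc = np.random.default_rng([spec.seed & 0x7FFFFFFF, j, 10_007])
        y_rep = rng_ppc.negative_binomial(phis, phis / (phis + mus))
        lo_rep = np.percentile(y_rep, 2.5, axis=0)
        hi_rep = np.percentile(y_rep, 97.5, axis=0)
        ppc_inside += int(((y >= lo_rep) & (y <= hi_rep)).sum())
        ppc_n += len(y)

    # mean-center per covariate across features
    center = means.mean(axis=0, keepdims=True)
    means -= center
    lo -= center
    hi -= center

    idx = pd.Index(features, name="feature_id")
    return DifferentialResult(
        differentials=pd.DataFrame(means, index=idx, columns=cov_cols),
        ci_low=pd.DataFrame(lo, index=idx, columns=cov_cols),
        ci_high=pd.DataFrame(hi, index=idx, columns=cov_cols),
        r_hat=pd.DataFrame(rhat, index=idx, columns=cov_cols),
        lppd=lppd_total,
        ppc_coverage=ppc_inside / max(ppc_n, 1),
        scaling=dict(design.scaling),
    )


# --------------------------------------------------------------------------- #
# diagnostics and ranking
# --------------------------------------------------------------------------- #

def compute_rhat(chains) -> float:
    """Gelman-Rubin potential scale reduction,
    R-hat = sqrt(((n-1)/n * W + B/n) / W), with W the mean within-chain
    variance and B = n * var(chain means).  Returns NaN (with a warning)
    when every chain is constant."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = arr.shape
    within = arr.var(axis=1, ddof=1)
    W = within.mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W == 0:
        warnings.warn("R-hat undefined: zero within-chain variance", RuntimeWarning)
        return float("nan")
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def rank_features(result: DifferentialResult, covariate: str) -> list[str]:
    """Feature ids ordered by descending posterior-mean differential for
    ``covariate``; ties broken lexicographically by feature id."""
    if covariate not in result.differentials.columns:
        raise KeyError(f"covariate {covariate!r} not in result "
                       f"(have {list(result.differentials.columns)})")
    s = result.differentials[covariate]
    order = sorted(s.index, key=lambda f: (-s[f], str(f)))
    return list(order)
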