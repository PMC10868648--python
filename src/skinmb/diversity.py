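"""Rarefaction, Shannon diversity, and diversity-phenotype association
statistics: Spearman rank correlation (exact permutation p at small n),
random-intercept linear mixed models, Bray-Curtis distances, and a
single-term PERMANOVA supporting both categorical and continuous
variables."""

from __future__ import annotations

import itertools
import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "PermanovaResult",
    "rarefy",
    "shannon_diversity",
    "spearman_association",
    "lmm_association",
    "bray_curtis_distance",
    "permanova",
]


@dataclass(frozen=True)
class AssociationResult:
    method: str  # "spearman" or "lmm"
    estimate: float  # Spearman rho, or fixed-effect slope beta
    p_value: float
    n: int
    ci: tuple[float, float]  # 95% interval

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": float(self.estimate),
            "p_value": float(self.p_value),
            "n": int(self.n),
            "ci": [float(self.ci[0]), float(self.ci[1])],
        }


@dataclass(frozen=True)
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "r_squared": float(self.r_squared),
            "pseudo_f": float(self.pseudo_f),
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
        }


# --------------------------------------------------------------------------- #
# rarefaction and alpha diversity
# --------------------------------------------------------------------------- #

def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # keyed on the sample id, so rarefaction of a given sample does not
    # depend on the presence or order of other samples
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(str(sample_id).encode())])


def rarefy(table: pd.DataFrame, depth: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample without replacement to exactly ``depth`` reads;
    samples with fewer total reads are dropped."""
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = len(table) - len(keep)
    if dropped:
        logger.info("rarefy: dropped %d sample(s) below depth %d", dropped, depth)
    rows = []
    for sid in keep:
        counts = table.loc[sid].to_numpy(dtype=np.int64)
        rng = _sample_rng(seed, sid)
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(rows, index=keep, columns=table.columns, dtype=np.int64)
    out.index.name = table.index.name
    return out


def shannon_diversity(table: pd.DataFrame, base: float = 2.0) -> pd.Series:
    """Shannon index per sample, H = -sum p_i log_base p_i over nonzero
    features (bits for the default base 2)."""
    totals = table.sum(axis=1)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    p = table.div(totals, axis=0).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1) / np.log(base)
    return pd.Series(h, index=table.index, name="shannon")


# --------------------------------------------------------------------------- #
# Spearman with exact small-n permutation p
# --------------------------------------------------------------------------- #

def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else 0.0


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all n! orderings of y's ranks."""
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    if denom == 0:
        return 1.0
    hits = 0
    total = 0
    chunk = []
    thr = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 40320:
            P = ry_c[np.array(chunk)]
            rhos = (P * rx_c).sum(axis=1) / denom
            hits += int((np.abs(rhos) >= thr).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        P = ry_c[np.array(chunk)]
        rhos = (P * rx_c).sum(axis=1) / denom
        hits += int((np.abs(rhos) >= thr).sum())
        total += len(chunk)
    return hits / total


def spearman_association(x, y) -> AssociationResult:
    """Spearman rank correlation with mid-ranks for ties.

    Two-sided p by exhaustive permutation for n <= 10, by the t
    approximation otherwise; 95% CI by the Fisher z transform."""
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= 10:
        p = _exact_perm_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = 2 * scipy.stats.t.sf(abs(t), df=n - 2)
    if n > 3 and abs(rho) < 1.0:
        z = np.arctanh(rho)
        half = scipy.stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (-1.0, 1.0)
    return AssociationResult("spearman", rho, float(p), n, ci)


# --------------------------------------------------------------------------- #
# random-intercept mixed model
# --------------------------------------------------------------------------- #

def lmm_association(y, x, group) -> AssociationResult:
    """Fit ``y = b0 + b*x + u_group + e`` with a Gaussian random intercept
    per group (REML).  Returns the fixed slope, its Wald two-sided p, and
    95% CI.  With a single group, falls back to ordinary least squares with
    a logged warning."""
    df = pd.DataFrame({
        "y": np.asarray(y, dtype=float),
        "x": np.asarray(x, dtype=float),
        "g": np.asarray(group).astype(str),
    }).dropna()
    n = len(df)
    if n < 3:
        raise ValueError(f"need >= 3 complete observations, got {n}")
    if df["g"].nunique() < 2:
        logger.warning("lmm_association: single group; falling back to OLS")
        fit = smf.ols("y ~ x", data=df).fit()
        lo, hi = fit.conf_int().loc["x"]
        return AssociationResult("lmm", float(fit.params["x"]), float(fit.pvalues["x"]), n, (float(lo), float(hi)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("y ~ x", groups="g", data=df)
        fit = model.fit(reml=True, method="lbfgs")
    beta = float(fit.fe_params["x"])
    se = float(fit.bse_fe["x"])
    if se > 0 and np.isfinite(se):
        z = beta / se
        p = float(2 * scipy.stats.norm.sf(abs(z)))
        half = scipy.stats.norm.ppf(0.975) * se
        ci = (beta - half, beta + half)
    else:  # degenerate fit (e.g. constant response)
        p = 1.0
        ci = (beta, beta)
    return AssociationResult("lmm", beta, p, n, ci)


# --------------------------------------------------------------------------- #
# Bray-Curtis + PERMANOVA
# --------------------------------------------------------------------------- #

def bray_curtis_distance(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity,
    d(a, b) = 1 - 2 * sum_i min(a_i, b_i) / (sum_i a_i + sum_i b_i).
    Zero-total samples are excluded."""
    totals = table.sum(axis=1)
    kept = table.loc[totals > 0]
    data = kept.to_numpy(dtype=float)
    condensed = scipy.spatial.distance.pdist(data, metric="braycurtis")
    return DistanceMatrix(scipy.spatial.distance.squareform(condensed), ids=[str(i) for i in kept.index])


def _design_columns(variable: pd.Series) -> tuple[np.ndarray, int]:
    """Centered design columns (no intercept) for a single term and its df."""
    if variable.dtype.kind in "OUSb" or isinstance(variable.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(variable.astype(str), drop_first=True)
        if dummies.shape[1] == 0:
            raise ValueError("variable has a single unique value")
        X = dummies.to_numpy(dtype=float)
    else:
        v = variable.to_numpy(dtype=float)
        if np.unique(v).size < 2:
            raise ValueError("variable has a single unique value")
        X = v.reshape(-1, 1)
    X = X - X.mean(axis=0)
    return X, X.shape[1]


def _permanova_stats(G: np.ndarray, X: np.ndarray, ss_total: float, df_model: int):
    """Pseudo-F and R^2 of a single centered term via the hat-matrix trace
    decomposition of the Gower-centered matrix G."""
    n = G.shape[0]
    XtX = X.T @ X
    H_core = X @ np.linalg.pinv(XtX) @ X.T
    ss_model = float(np.trace(H_core @ G))
    ss_resid = ss_total - ss_model
    df_resid = n - df_model - 1
    f = (ss_model / df_model) / (ss_resid / df_resid) if ss_resid > 0 else np.inf
    r2 = ss_model / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dm: DistanceMatrix,
    variable,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Single-term permutational multivariate ANOVA.

    The distance matrix is Gower-centered (G = -1/2 C D^2 C); the term's
    sum of squares is tr(H G) for the hat matrix H of the centered design,
    giving pseudo-F and R^2.  Categorical variables are dummy-coded
    (k - 1 df), continuous variables enter as one column.  The permutation
    p-value is (1 + #{F_perm >= F_obs}) / (1 + n_permutations)."""
    variable = pd.Series(variable).reset_index(drop=True)
    D = dm.data
    n = D.shape[0]
    if len(variable) != n:
        raise ValueError("variable length does not match distance matrix")
    if variable.isna().any():
        raise ValueError("variable must be complete for all samples in the distance matrix")

    A = -0.5 * D ** 2
    C = np.eye(n) - np.ones((n, n)) / n
    G = C @ A @ C
    ss_total = float(np.trace(G))

    X, df_model = _design_columns(variable)
    f_obs, r2 = _permanova_stats(G, X, ss_total, df_model)

    rng = np.random.default_rng(seed)
    if df_model == 1:
        # vectorized: F is monotone in z' G z for a fixed-norm single column
        z = X[:, 0]
        perms = np.stack([rng.permutation(z) for _ in range(n_permutations)])
        ztz = float(z @ z)
        ss_model_perm = np.einsum("pi,ij,pj->p", perms, G, perms) / ztz
        ss_resid_perm = ss_total - ss_model_perm
        df_resid = n - 2
        with np.errstate(divide="ignore"):
            f_perm = ss_model_perm / (ss_resid_perm / df_resid)
        exceed = int((f_perm >= f_obs - 1e-12).sum())
    else:
        exceed = 0
        for _ in range(n_permutations):
            Xp = X[rng.permutation(n)]
            f_p, _ = _permanova_stats(G, Xp, ss_total, df_model)
            if f_p >= f_obs - 1e-12:
                exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(r2, f_obs, p, n_permutations)
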