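"""The multivariate omnibus test (MOSTest) core.

Given observed z-scores z_j (one K-vector per variant) and their
counterparts under genotype permutation, the test statistic is the
Mahalanobis norm

    X^2_j = z_j^T R~^-1 z_j,

where R~ is the K x K correlation matrix of the permuted z-scores. Under
the multivariate-normal null with covariance R~ the statistic is
chi-square with K degrees of freedom, i.e. gamma(K/2, 2); instead of the
theoretical law, a two-parameter gamma(a, b) is fitted to the permuted
statistics and the p-value is the fitted upper-tail probability,
evaluated in log space so extreme tails stay representable.

When the trait set is (near) rank-deficient, R~ is regularized before
inversion by replacing its r smallest eigenvalues with the next smallest
one (spectral floor).

The min-P comparator takes the per-variant minimum univariate p and
corrects it for the effective number of independent traits Meff, which is
calibrated on the same permutation null by fitting Beta(1, Meff) to the
permuted minimum p-values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .genotype_io import GenotypeMatrix
from .phenotype_prep import PhenotypeMatrix
from .univariate_gwas import (ZScoreMatrix, gwas_correlation, min_p_statistic,
                              permute_genotypes)

_LOG10E = np.log10(np.e)


class DegenerateTraitError(ValueError):
    """A z-score column is constant; its correlation is undefined."""


@dataclass
class NullCalibration:
    """Everything needed to score new z-vectors against the permutation null."""

    R_tilde: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    r_reg: int
    R_inv_reg: np.ndarray
    gamma_shape: float
    gamma_scale: float
    minp_meff: float
    K: int
    M_perm: int

    def to_json(self, path) -> None:
        payload = {
            "K": self.K, "M_perm": self.M_perm, "r_reg": self.r_reg,
            "gamma_shape": self.gamma_shape, "gamma_scale": self.gamma_scale,
            "minp_meff": self.minp_meff,
            "R_tilde": self.R_tilde.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NullCalibration":
        with open(path) as fh:
            d = json.load(fh)
        R = np.asarray(d["R_tilde"], float)
        cal = build_calibration_matrix(R, r_reg=d["r_reg"])
        return cls(R_tilde=R, eigvals=cal.eigvals, eigvecs=cal.eigvecs,
                   r_reg=d["r_reg"], R_inv_reg=cal.R_inv_reg,
                   gamma_shape=d["gamma_shape"], gamma_scale=d["gamma_scale"],
                   minp_meff=d["minp_meff"], K=d["K"], M_perm=d["M_perm"])


@dataclass
class MultivariateResult:
    """Per-variant omnibus and min-P results plus variant metadata."""

    table: pd.DataFrame
    calibration: NullCalibration
    zscores: ZScoreMatrix | None = None
    zscores_perm: ZScoreMatrix | None = None


def estimate_correlation(Z_tilde: np.ndarray) -> np.ndarray:
    """Correlation of trait columns of the permuted z-score matrix (M x K)."""
    Z = np.atleast_2d(np.asarray(Z_tilde, float))
    Z = Z[np.isfinite(Z).all(axis=1)]
    m, k = Z.shape
    if m < 10 * k:
        warnings.warn(f"only {m} permuted z rows for {k} traits; "
                      "correlation estimate may be noisy", stacklevel=2)
    if np.any(Z.std(axis=0) == 0):
        raise DegenerateTraitError("constant z-score column")
    R = np.corrcoef(Z, rowvar=False)
    return np.atleast_2d(R)


def estimate_correlation_from_phenotypes(Y: PhenotypeMatrix) -> np.ndarray:
    """Trait-by-trait Pearson correlation of the prepared phenotypes.

    Under the permutation scheme the correlation of null z-scores equals
    the phenotype correlation, so either source can calibrate the test;
    this one does not require running a permuted GWAS.
    """
    if np.any(Y.values.std(axis=0) == 0):
        raise DegenerateTraitError("constant trait column")
    return np.atleast_2d(np.corrcoef(Y.values, rowvar=False))


def regularize(R: np.ndarray, r: int) -> np.ndarray:
    """Spectral floor: replace the r smallest eigenvalues of R with the
    (r+1)-th smallest, and reconstruct. r = 0 returns R unchanged;
    r = K-1 yields lambda_max * I."""
    R = np.asarray(R, float)
    k = R.shape[0]
    if not 0 <= r <= k - 1:
        raise ValueError(f"r={r} outside [0, {k - 1}]")
    if r == 0:
        return R.copy()
    vals, vecs = np.linalg.eigh(R)  # ascending
    vals = vals.copy()
    vals[:r] = vals[r]
    return (vecs * vals) @ vecs.T


@dataclass
class _CalMatrix:
    eigvals: np.ndarray
    eigvecs: np.ndarray
    R_inv_reg: np.ndarray


def build_calibration_matrix(R: np.ndarray, r_reg: int = 0,
                             cond_warn: float = 1e4) -> _CalMatrix:
    """Eigendecompose R, apply the spectral floor, and invert."""
    vals, vecs = np.linalg.eigh(R)
    if vals[0] < -1e-10:
        raise ValueError(f"correlation matrix has eigenvalue {vals[0]:.3g} < 0")
    if r_reg == 0 and vals[0] > 0 and vals[-1] / vals[0] > cond_warn:
        warnings.warn(
            f"condition number {vals[-1] / vals[0]:.3g} exceeds {cond_warn:.0e}; "
            "consider spectral regularization (r_reg > 0)", stacklevel=2)
    R_reg = regularize(R, r_reg)
    vals_r, vecs_r = np.linalg.eigh(R_reg)
    R_inv = (vecs_r / vals_r) @ vecs_r.T
    return _CalMatrix(eigvals=vals, eigvecs=vecs, R_inv_reg=R_inv)


def mostest_statistic(z: np.ndarray, R_inv: np.ndarray) -> np.ndarray:
    """Mahalanobis norm z^T R^-1 z per row of z (vectorized over variants)."""
    z = np.atleast_2d(np.asarray(z, float))
    stat = np.einsum("ij,jk,ik->i", z, R_inv, z)
    stat[np.isnan(z).any(axis=1)] = np.nan
    return stat


def fit_gamma_null(x2_perm: np.ndarray, tail_fraction: float = 1.0,
                   method: str = "mle") -> tuple[float, float]:
    """Fit gamma(shape a, scale b) to permuted omnibus statistics.

    MLE with method-of-moments initialization by default; ``method``
    "moments" skips the likelihood step. ``tail_fraction`` < 1 restricts
    the fit to the largest fraction of the sample (tail emphasis).
    """
    x = np.asarray(x2_perm, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite statistics to fit")
    if np.any(x < 0):
        raise ValueError("omnibus statistics must be non-negative")
    if x.size < 10_000:
        warnings.warn(f"only {x.size} permuted statistics; gamma fit may be "
                      "unstable in the tail", stacklevel=2)
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must lie in (0, 1]")
    if tail_fraction < 1.0:
        x = np.sort(x)[int(np.floor((1 - tail_fraction) * x.size)):]
    mean, var = x.mean(), x.var()
    if var == 0:
        raise ValueError("degenerate (constant) statistics; cannot fit gamma")
    a0, b0 = mean ** 2 / var, var / mean
    if method == "moments":
        return float(a0), float(b0)
    # profile likelihood in the shape: b_hat(a) = mean/a
    mean_log = np.log(x[x > 0]).mean()
    def score(a):  # d/da of profile log-likelihood, up to n
        return np.log(a) - special.digamma(a) - np.log(mean) + mean_log
    lo, hi = a0 / 10, a0 * 10
    while score(lo) < 0:
        lo /= 10
    while score(hi) > 0:
        hi *= 10
    a = optimize.brentq(score, lo, hi, xtol=1e-10)
    return float(a), float(mean / a)


def gamma_mle_stderr(a: float, b: float, n: int) -> tuple[float, float]:
    """Asymptotic standard errors of the gamma MLE (inverse Fisher info)."""
    tri = special.polygamma(1, a)
    det = a * tri - 1.0
    var_a = a / (n * det)
    var_b = b ** 2 * tri / (n * det)
    return float(np.sqrt(var_a)), float(np.sqrt(var_b))


def _log_gamma_sf(s: np.ndarray, a: float) -> np.ndarray:
    """log of the regularized upper incomplete gamma Q(a, s).

    Uses scipy's gammaincc where it is representable and switches to the
    asymptotic expansion Q(a,s) ~ s^(a-1) e^-s / Gamma(a) * sum_k
    (a-1)...(a-k)/s^k once the direct value underflows, so log p stays
    finite for arbitrarily extreme statistics.
    """
    s = np.asarray(s, float)
    q = special.gammaincc(a, s)
    out = np.full(s.shape, -np.inf)
    ok = q > 1e-280
    out[ok] = np.log(q[ok])
    far = ~ok & (s > 0)
    if far.any():
        sf = s[far]
        series = np.ones_like(sf)
        term = np.ones_like(sf)
        for k in range(1, 60):
            term *= (a - k) / sf
            series += term
            if np.max(np.abs(term)) < 1e-18:
                break
        out[far] = (-sf + (a - 1.0) * np.log(sf) - special.gammaln(a)
                    + np.log(np.maximum(series, 1e-300)))
    return out


def mostest_pvalue(x2: np.ndarray, a: float, b: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Upper-tail gamma(a, b) probability of the omnibus statistic.

    Returns (p, log10 p); the log10 values remain exact below float
    underflow. Strictly decreasing in the statistic.
    """
    if a <= 0 or b <= 0:
        raise ValueError("gamma parameters must be positive")
    x2 = np.asarray(x2, float)
    log_p = _log_gamma_sf(np.atleast_1d(x2) / b, a)
    if x2.shape == ():
        log_p = float(log_p[0])
    else:
        log_p = log_p.reshape(x2.shape)
    return np.exp(log_p), log_p * _LOG10E


def calibrate_minp(minp_perm: np.ndarray, K: int) -> float:
    """Effective number of independent traits from permuted minimum p-values.

    The minimum of K independent uniforms is Beta(1, K); fitting
    Beta(1, Meff) by maximum likelihood, Meff = -n / sum(log(1 - p)),
    clipped to [1, K], absorbs the trait correlation.
    """
    p = np.asarray(minp_perm, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no permuted minimum p-values to calibrate on")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("minimum p-values must lie in (0, 1]")
    meff = -p.size / np.sum(np.log1p(-np.minimum(p, 1 - 1e-16)))
    return float(np.clip(meff, 1.0, K))


def minp_corrected(minp: np.ndarray, meff: float) -> np.ndarray:
    """Sidak-style correction 1 - (1 - p)^Meff, accurate for tiny p."""
    p = np.asarray(minp, float)
    return -np.expm1(meff * np.log1p(-np.minimum(p, 1 - 1e-16)))


@dataclass
class MostestConfig:
    """Options for :func:`run_mostest`."""

    r_reg: int = 0
    seed: int = 0
    correlation_source: str = "permutation"  # or "phenotypes"
    tail_fraction: float = 1.0
    gamma_method: str = "mle"
    theoretical_null: bool = False  # use gamma(K/2, 2) instead of the fit


def run_mostest(G: GenotypeMatrix, Y: PhenotypeMatrix,
                config: MostestConfig | None = None) -> MultivariateResult:
    """Full omnibus analysis on prepared inputs.

    Runs the observed GWAS, one genotype-permutation GWAS, calibrates the
    null (correlation matrix, gamma fit, Meff), and scores every variant
    with the omnibus statistic and the corrected min-P comparator.
    Deterministic for a fixed ``config.seed``.
    """
    cfg = config or MostestConfig()
    Z_obs = gwas_correlation(G, Y)
    G_perm = permute_genotypes(G, seed=cfg.seed)
    Z_perm = gwas_correlation(G_perm, Y)

    K = Y.n_traits
    if cfg.correlation_source == "phenotypes":
        R = estimate_correlation_from_phenotypes(Y)
    else:
        R = estimate_correlation(Z_perm.z)
    cal = build_calibration_matrix(R, r_reg=cfg.r_reg)

    x2_obs = mostest_statistic(Z_obs.z, cal.R_inv_reg)
    x2_perm = mostest_statistic(Z_perm.z, cal.R_inv_reg)
    if cfg.theoretical_null:
        a, b = K / 2.0, 2.0
    else:
        a, b = fit_gamma_null(x2_perm[np.isfinite(x2_perm)],
                              tail_fraction=cfg.tail_fraction,
                              method=cfg.gamma_method)
    p_most, log10p_most = mostest_pvalue(x2_obs, a, b)

    minp_raw = min_p_statistic(Z_obs.pvals)
    minp_perm = min_p_statistic(Z_perm.pvals)
    meff = calibrate_minp(minp_perm[np.isfinite(minp_perm)], K)
    minp_corr = minp_corrected(minp_raw, meff)

    calibration = NullCalibration(
        R_tilde=R, eigvals=cal.eigvals, eigvecs=cal.eigvecs, r_reg=cfg.r_reg,
        R_inv_reg=cal.R_inv_reg, gamma_shape=a, gamma_scale=b,
        minp_meff=meff, K=K, M_perm=int(np.isfinite(x2_perm).sum()))
    table = pd.DataFrame({
        "variant_id": G.variants["variant_id"].to_numpy(),
        "chrom": G.variants["chrom"].to_numpy(),
        "pos": G.variants["pos"].to_numpy(),
        "a1": G.variants["allele1"].to_numpy(),
        "a2": G.variants["allele2"].to_numpy(),
        "mostest_stat": x2_obs,
        "mostest_p": p_most,
        "mostest_log10p": log10p_most,
        "minp_raw": minp_raw,
        "minp_corrected_p": minp_corr,
        "nan_traits": np.isnan(Z_obs.z).any(axis=1),
    })
    return MultivariateResult(table=table, calibration=calibration,
                              zscores=Z_obs, zscores_perm=Z_perm)
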