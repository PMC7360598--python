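"""Mass-univariate correlation GWAS and the genotype-permutation scheme.

For each variant j and trait i the association is tested through the
Pearson correlation r_ij between dosage and trait, converted to

    t_j = r sqrt(N-2) / sqrt(1-r^2),    p = 2 tcdf(-|t|, N-2),

which is identical to the t-test on the OLS regression slope (and hence
to PLINK's additive ``--assoc`` model). Signed z-scores are recovered
through the p-value, z = sign(r) Phi^-1(1 - p/2), evaluated in log space
so that tails stay exact at any sample size.

The permutation scheme shuffles each variant's dosage vector once and
reuses it for all traits, preserving the cross-trait correlation of the
resulting null z-scores — the quantity the omnibus test calibrates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .genotype_io import GenotypeMatrix
from .phenotype_prep import PhenotypeMatrix

_LN2 = np.log(2.0)
_LOG10E = np.log10(np.e)


@dataclass
class ZScoreMatrix:
    """Signed per-variant, per-trait association statistics.

    Attributes
    ----------
    z : ndarray (M, K)
        Signed z-scores; sign matches the dosage-trait correlation.
    pvals : ndarray (M, K)
        Two-tailed p-values (may underflow to 0; see ``log10_pvals``).
    log10_pvals : ndarray (M, K)
        log10 of the p-values, exact far beyond float underflow.
    r : ndarray (M, K)
        Pearson correlations.
    n_effective : ndarray (M,)
        Samples used per variant (after mean imputation, the full N).
    """

    z: np.ndarray
    pvals: np.ndarray
    log10_pvals: np.ndarray
    r: np.ndarray
    n_effective: np.ndarray


def z_from_p(p: np.ndarray, sign: np.ndarray = 1.0,
             log_p: np.ndarray | None = None) -> np.ndarray:
    """Signed z with the given two-tailed p: z = sign * Phi^-1(1 - p/2).

    When ``log_p`` (natural log of p) is supplied it is used instead of
    ``p``, keeping the conversion exact for p far below float underflow.
    """
    lp = np.log(p) if log_p is None else np.asarray(log_p, float)
    return np.asarray(sign) * -special.ndtri_exp(lp - _LN2)


def p_from_z(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed normal (p, log10 p) for signed z-scores."""
    log_p = _LN2 + special.log_ndtr(-np.abs(z))
    return np.exp(log_p), log_p * _LOG10E


def gwas_correlation(G: GenotypeMatrix, Y: PhenotypeMatrix) -> ZScoreMatrix:
    """Correlation GWAS of every trait against every variant.

    Missing dosages are mean-imputed per variant so all traits share the
    same N (required by the shared-permutation null). Monomorphic
    variants yield NaN rows with a warning.
    """
    n = G.n_samples
    if n != Y.n_samples:
        raise ValueError("genotypes and phenotypes not row-aligned")
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    Yv = Y.values
    if np.any(Yv.std(axis=0) == 0):
        raise ValueError("constant trait column")

    D = G.dosages.copy()
    mask = np.isnan(D)
    if mask.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(D, axis=0)
        D[mask] = np.broadcast_to(means, D.shape)[mask]
    D = D - D.mean(axis=0)
    g_norm = np.sqrt((D ** 2).sum(axis=0))
    mono = g_norm == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic variants yield NaN",
                      stacklevel=2)
    g_norm[mono] = np.nan

    Yc = Yv - Yv.mean(axis=0)
    y_norm = np.sqrt((Yc ** 2).sum(axis=0))
    r = (D.T @ Yc) / np.outer(g_norm, y_norm)
    r = np.clip(r, -1.0, 1.0)
    if np.any(np.abs(r[np.isfinite(r)]) >= 1.0):
        warnings.warn("perfect dosage-trait correlation encountered", stacklevel=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    log_p = _LN2 + stats.t.logsf(np.abs(t), df=n - 2)
    z = z_from_p(None, sign=np.sign(r), log_p=log_p)
    z[r == 0] = 0.0
    return ZScoreMatrix(z=z, pvals=np.exp(log_p), log10_pvals=log_p * _LOG10E,
                        r=r, n_effective=np.full(G.n_variants, n))


def permute_genotypes(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Independently shuffle each variant's dosage vector, once per variant.

    Per-variant RNG streams are spawned from one master seed, so the
    result does not depend on processing order or chunking. Allele counts
    per variant are conserved by construction.
    """
    children = np.random.SeedSequence(seed).spawn(G.n_variants)
    out = np.empty_like(G.dosages)
    for j, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        out[:, j] = G.dosages[rng.permutation(G.n_samples), j]
    return GenotypeMatrix(out, G.variants.copy(), list(G.samples))


def min_p_statistic(pvals: np.ndarray) -> np.ndarray:
    """Per-variant minimum p across traits (raw, uncorrected).

    Rows containing NaN propagate NaN.
    """
    pvals = np.atleast_2d(np.asarray(pvals, float))
    out = np.min(pvals, axis=1)
    out[np.isnan(pvals).any(axis=1)] = np.nan
    return out
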