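"""Phenotype preparation: covariate residualization and rank-based INT.

Multivariate omnibus testing assumes the per-trait z-scores are normally
distributed under the null; heavy-tailed raw traits violate this and
inflate type-I error. The standard remedy is to regress out nuisance
covariates (age, sex, site, genetic principal components, a global
measure, ...) and then force marginal normality with the rank-based
inverse-normal transformation

    y'_i = Phi^-1((r_i - c) / (N - 2c + 1)),   c = 0.5 by default,

where r_i is the rank of sample i within the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """Covariate matrix is rank-deficient after adding the intercept."""


class DegenerateTraitError(ValueError):
    """A trait is constant and cannot be ranked."""


@dataclass
class CovariateMatrix:
    """N x C design of continuous and dummy-coded covariates (no intercept)."""

    values: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.names:
            self.names = [f"cov_{i}" for i in range(self.values.shape[1])]

    @classmethod
    def from_table(cls, path) -> "CovariateMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.columns))


@dataclass
class PhenotypeMatrix:
    """N x K matrix of quantitative traits aligned to the genotype samples."""

    values: np.ndarray
    trait_names: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.trait_names:
            self.trait_names = [f"trait_{i}" for i in range(self.values.shape[1])]
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i}" for i in range(self.values.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_table(cls, path) -> "PhenotypeMatrix":
        """Read a tab-separated table: first column sample id, header row."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.columns), [str(s) for s in df.index])

    def to_table(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.trait_names).to_csv(path, sep="\t",
                                                      index_label="sample_id")


def _design(X: CovariateMatrix | None, n: int) -> tuple[np.ndarray, list]:
    if X is None:
        return np.ones((n, 1)), ["intercept"]
    return np.column_stack([np.ones(n), X.values]), ["intercept", *X.names]


def residualize(Y: PhenotypeMatrix, X: CovariateMatrix | None) -> PhenotypeMatrix:
    """OLS-residualize every trait on [intercept, covariates].

    Raises :class:`CollinearityError`, naming offending columns, when the
    design is rank-deficient.
    """
    D, names = _design(X, Y.n_samples)
    if D.shape[0] != Y.n_samples:
        raise ValueError("covariates not row-aligned with phenotypes")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify columns whose removal restores full rank
        bad = [names[j] for j in range(D.shape[1])
               if np.linalg.matrix_rank(np.delete(D, j, axis=1)) == rank]
        raise CollinearityError(f"collinear covariate columns: {bad}")
    beta, *_ = np.linalg.lstsq(D, Y.values, rcond=None)
    resid = Y.values - D @ beta
    return PhenotypeMatrix(resid, list(Y.trait_names), list(Y.sample_ids))


def inverse_normal_transform(v: np.ndarray, c: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform of a vector.

    Ranks (average ranks for ties) are mapped to standard-normal quantiles
    of (r - c)/(N - 2c + 1). Depends on the input only through its ranks.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if v.size < 3:
        raise ValueError("need at least 3 observations to rank-transform")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values in trait")
    if np.ptp(v) == 0:
        raise DegenerateTraitError("trait is constant; ranks undefined")
    r = rankdata(v, method="average")
    return ndtri((r - c) / (v.size - 2.0 * c + 1.0))


def prepare(Y: PhenotypeMatrix, X: CovariateMatrix | None = None,
            global_covariate: np.ndarray | None = None,
            c: float = 0.5) -> PhenotypeMatrix:
    """Full preparation pipeline: drop incomplete samples, residualize, INT.

    ``global_covariate`` (e.g. intracranial volume for subcortical traits)
    is appended to the covariate design and regressed out jointly with the
    other covariates in a single OLS fit.
    """
    cols = [Y.values]
    if X is not None:
        cols.append(X.values)
    if global_covariate is not None:
        cols.append(np.asarray(global_covariate, float).reshape(-1, 1))
    complete = np.isfinite(np.column_stack(cols)).all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("dropping %d samples with missing trait/covariate values", n_drop)
    keep = np.where(complete)[0]
    Yc = PhenotypeMatrix(Y.values[keep], list(Y.trait_names),
                         [Y.sample_ids[i] for i in keep])
    Xc = None
    xparts, xnames = [], []
    if X is not None:
        xparts.append(X.values[keep])
        xnames.extend(X.names)
    if global_covariate is not None:
        xparts.append(np.asarray(global_covariate, float).reshape(-1, 1)[keep])
        xnames.append("global_covariate")
    if xparts:
        Xc = CovariateMatrix(np.column_stack(xparts), xnames)
    resid = residualize(Yc, Xc)
    out = np.column_stack([inverse_normal_transform(resid.values[:, k], c=c)
                           for k in range(resid.n_traits)])
    return PhenotypeMatrix(out, list(Y.trait_names), resid.sample_ids)
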