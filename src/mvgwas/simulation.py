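"""Synthetic multivariate GWAS studies for type-I error and power checks.

One scenario draws genotypes, places all genetic effects on a designated
"causal" chromosome, and builds T quantitative traits as

    y = f(G beta + eps),

where f is the identity or an exponent (a heavy-tail stressor), beta has
per-trait sparsity t (number of traits each causal variant touches) and
cross-trait correlation, and eps is multivariate normal with its own
correlation. Per-trait residual variance is set so each heritable trait
attains the target h2 = Var(G beta)/Var(y), evaluated before the link.
Because effects live on one chromosome, all other chromosomes are exact
nulls — the basis of the type-I checks — while power is measured at the
causal variants themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .genotype_io import GenotypeMatrix, simulate_genotypes
from .phenotype_prep import PhenotypeMatrix, prepare
from .multivariate_test import MostestConfig, MultivariateResult, run_mostest


def ar1_correlation(T: int, rho: float = 0.5) -> np.ndarray:
    """AR(1) correlation matrix, a parametric stand-in for the empirical
    covariance of real anatomical trait panels."""
    idx = np.arange(T)
    return rho ** np.abs(np.subtract.outer(idx, idx))


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study.

    Defaults define the reduced-scale reference scenario: 2,000 samples,
    20,000 variants across 2 chromosomes with the first one (1,000
    variants) carrying all effects, 10 traits with AR(1) residual
    correlation, distributed effects (t = T) and identity link.
    """

    n_samples: int = 2000
    n_variants: int = 20000
    chrom_sizes: tuple = (1000, 19000)
    causal_chrom: int = 1
    maf_spec: tuple = (0.05, 0.5)
    ld_decay: float = 0.0
    n_causal: int = 10            # causal variants per trait (nc)
    h2: float = 0.05              # per-trait heritability of the causal chrom
    T: int = 10                   # number of traits
    t: int = 10                   # traits touched by each causal variant
    beta_dist: str = "normal"     # or "cauchy"
    beta_corr: np.ndarray | None = None   # None -> identity
    eps_corr: np.ndarray | None = None    # None -> AR(1) rho=0.5
    link: str = "identity"        # or "exp"
    rank_deficient: bool = False  # expand to T(T-1)/2 pairwise-sum features
    n_heritable: int | None = None  # traits with signal; rest pure noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.t <= self.T:
            raise ValueError(f"t={self.t} must lie in [1, T={self.T}]")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if self.beta_dist not in ("normal", "cauchy"):
            raise ValueError(f"unknown beta_dist {self.beta_dist!r}")
        if self.link not in ("identity", "exp"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.causal_chrom > len(self.chrom_sizes):
            raise ValueError("causal_chrom beyond chrom_sizes")

    def resolved_eps_corr(self) -> np.ndarray:
        return ar1_correlation(self.T) if self.eps_corr is None \
            else np.asarray(self.eps_corr, float)

    def resolved_beta_corr(self) -> np.ndarray:
        return np.eye(self.T) if self.beta_corr is None \
            else np.asarray(self.beta_corr, float)


@dataclass
class SimulatedStudy:
    """One realization of a scenario."""

    G: GenotypeMatrix
    Y: PhenotypeMatrix                 # raw traits (pre-INT truth)
    B: np.ndarray                      # M x T sparse effect matrix
    causal_ids: dict                   # trait index -> variant indices
    realized_h2: np.ndarray            # per trait, pre-link
    config: SimulationConfig


def draw_effects(config: SimulationConfig, causal_chrom_index: np.ndarray,
                 rng: np.random.Generator, n_variants: int) -> np.ndarray:
    """Sparse M x T effect matrix with balanced trait allocation.

    ceil(nc*T/t) causal variants are drawn without replacement from the
    causal chromosome; trait subsets of size t are dealt round-robin from
    a random trait permutation so every trait receives exactly nc
    non-zero effects (up to rounding, with a warning). Non-zero values
    are drawn from the configured distribution with cross-trait
    correlation ``beta_corr`` (Gaussian copula for Cauchy effects).
    """
    nc, T, t = config.n_causal, config.T, config.t
    total = nc * T / t
    n_causal_variants = int(np.ceil(total))
    if n_causal_variants != total:
        warnings.warn(f"nc*T/t = {total} not integer; last causal variant "
                      "gets fewer traits", stacklevel=2)
    if causal_chrom_index.size < n_causal_variants:
        raise ValueError(f"causal chromosome has {causal_chrom_index.size} "
                         f"variants, need {n_causal_variants}")
    chosen = rng.choice(causal_chrom_index, size=n_causal_variants, replace=False)

    perm = rng.permutation(T)
    slots = np.resize(perm, nc * T)          # each trait appears exactly nc times
    L = config.resolved_beta_corr()
    Lchol = np.linalg.cholesky(L + 1e-12 * np.eye(T))
    B = np.zeros((n_variants, T))
    for i, v in enumerate(chosen):
        traits = slots[i * t:(i + 1) * t]
        g = Lchol @ rng.standard_normal(T)   # correlated normals, full T
        if config.beta_dist == "cauchy":
            vals = stats.cauchy.ppf(ndtr(g))
        else:
            vals = g
        B[v, traits] = vals[traits]
    return B


def simulate_phenotypes(G: GenotypeMatrix, B: np.ndarray,
                        config: SimulationConfig,
                        rng: np.random.Generator) -> SimulatedStudy:
    """Build traits y = f(G beta + eps) at the configured heritability.

    Residual variance per heritable trait is Var(G beta)*(1-h2)/h2;
    pure-noise traits (beyond ``n_heritable``) get unit-variance residuals.
    Realized heritability is recorded pre-link.
    """
    T = config.T
    heritable = np.ones(T, dtype=bool)
    if config.n_heritable is not None:
        heritable[config.n_heritable:] = False
        B = B.copy()
        B[:, ~heritable] = 0.0  # pure-noise traits carry no genetic signal
    genetic = G.dosages @ B
    var_g = genetic.var(axis=0)
    if np.any((var_g == 0) & heritable):
        raise ValueError("zero genetic variance for a heritable trait with h2 > 0")

    sd_eps = np.ones(T)
    sd_eps[heritable] = np.sqrt(var_g[heritable] * (1 - config.h2) / config.h2)
    if config.h2 == 1.0:
        sd_eps[heritable] = 0.0
    C = config.resolved_eps_corr()
    eps = rng.multivariate_normal(np.zeros(T), C, size=G.n_samples,
                                  method="cholesky") * sd_eps
    lin = genetic + eps
    var_y = lin.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        realized = np.where(var_y > 0, var_g / var_y, 0.0)
    y = np.exp(lin) if config.link == "exp" else lin

    causal_ids = {k: np.flatnonzero(B[:, k]) for k in range(T)}
    Y = PhenotypeMatrix(y, [f"trait_{k}" for k in range(T)], list(G.samples))
    return SimulatedStudy(G=G, Y=Y, B=B, causal_ids=causal_ids,
                          realized_h2=realized, config=config)


def make_rank_deficient(Y: PhenotypeMatrix) -> PhenotypeMatrix:
    """Replace T traits with all T(T-1)/2 pairwise sums.

    Sums (not products) create exact linear dependence among the derived
    features, so the output correlation matrix has rank at most T — the
    stress case for an unregularized omnibus test.
    """
    T = Y.n_traits
    if T < 3:
        raise ValueError("need at least 3 traits for pairwise expansion")
    cols, names = [], []
    for i in range(T):
        for j in range(i + 1, T):
            cols.append(Y.values[:, i] + Y.values[:, j])
            names.append(f"{Y.trait_names[i]}+{Y.trait_names[j]}")
    return PhenotypeMatrix(np.column_stack(cols), names, list(Y.sample_ids))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw genotypes, effects and traits for one scenario realization."""
    rng = np.random.default_rng(config.seed)
    G = simulate_genotypes(config.n_samples, config.n_variants,
                           maf_spec=config.maf_spec, ld_decay=config.ld_decay,
                           chrom_sizes=list(config.chrom_sizes),
                           seed=int(rng.integers(2 ** 31)))
    causal_index = np.flatnonzero(
        G.variants["chrom"].to_numpy() == config.causal_chrom)
    B = draw_effects(config, causal_index, rng, G.n_variants)
    study = simulate_phenotypes(G, B, config, rng)
    if config.rank_deficient:
        study.Y = make_rank_deficient(study.Y)
    return study


def run_study(study: SimulatedStudy,
              mostest_config: MostestConfig | None = None) -> MultivariateResult:
    """Prepare the study's traits (INT) and run the omnibus analysis."""
    cfg = mostest_config or MostestConfig(seed=study.config.seed)
    Y_prep = prepare(study.Y)
    return run_mostest(study.G, Y_prep, cfg)


def binomial_ci(alpha: float, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Two-sided binomial proportion CI (Clopper-Pearson) around alpha."""
    lo, hi = stats.binom.interval(conf, n, alpha)
    return lo / n, hi / n


def evaluate_type1(result: MultivariateResult, causal_chrom: int,
                   alphas=(0.05, 1e-3)) -> pd.DataFrame:
    """Empirical type-I error on the null (non-causal) chromosomes.

    Per test and per alpha: the fraction of null-chromosome variants
    declared significant, with a 99% binomial CI around the nominal rate.
    """
    tab = result.table
    null_mask = (tab["chrom"] != causal_chrom).to_numpy()
    if null_mask.sum() == 0:
        raise ValueError("no null-chromosome variants")
    chroms = tab["chrom"].to_numpy()
    if np.unique(chroms).size < 2:
        raise ValueError("results must span at least 2 chromosomes")
    rows = []
    for test, col in (("mostest", "mostest_p"), ("minp", "minp_corrected_p")):
        p = tab.loc[null_mask, col].to_numpy()
        p = p[np.isfinite(p)]
        for a in alphas:
            lo, hi = binomial_ci(a, p.size)
            frac = float((p < a).mean())
            rows.append((test, a, frac, lo, hi, p.size,
                         bool(lo <= frac <= hi)))
    return pd.DataFrame(rows, columns=["test", "alpha", "fraction", "ci_lo",
                                       "ci_hi", "n_null", "within_ci"])


def evaluate_power(result: MultivariateResult, B: np.ndarray,
                   alpha: float = 5e-8, ld_window: int = 0) -> pd.DataFrame:
    """Detection power at the causal variants.

    Primary metric: fraction of causal variants with p < alpha at the
    variant itself; with ``ld_window`` > 0 a secondary metric counts a
    causal variant detected if any variant within that many base pairs is
    significant.
    """
    tab = result.table
    causal = np.flatnonzero(np.abs(B).sum(axis=1) > 0)
    pos = tab["pos"].to_numpy()
    chrom = tab["chrom"].to_numpy()
    rows = []
    for test, col in (("mostest", "mostest_p"), ("minp", "minp_corrected_p")):
        p = tab[col].to_numpy()
        exact = float((p[causal] < alpha).mean()) if causal.size else np.nan
        if ld_window > 0:
            sig = p < alpha
            hits = [bool(np.any(sig & (chrom == chrom[c])
                                & (np.abs(pos - pos[c]) <= ld_window)))
                    for c in causal]
            window = float(np.mean(hits)) if causal.size else np.nan
        else:
            window = exact
        rows.append((test, alpha, exact, window, causal.size))
    return pd.DataFrame(rows, columns=["test", "alpha", "power_exact",
                                       "power_window", "n_causal"])


def qq_data(pvals: np.ndarray) -> pd.DataFrame:
    """(expected, observed) -log10 p pairs for a QQ plot."""
    p = np.sort(np.asarray(pvals, float))
    p = p[np.isfinite(p)]
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.maximum(p, 1e-320))
    return pd.DataFrame({"expected_log10p": expected,
                         "observed_log10p": observed})


def run_scenario_suite(scenarios, n_repeats: int = 10,
                       master_seed: int = 0, alphas=(0.05, 1e-3),
                       power_alpha: float = 5e-8,
                       mostest_config: MostestConfig | None = None) -> dict:
    """Run each scenario ``n_repeats`` times and aggregate type-I and power.

    Returns a dict with a ``metrics`` DataFrame (per scenario and test:
    mean and SD of type-I error at each alpha and of power across
    repeats) and ``qq`` data (null and permutation) from the first repeat
    of each scenario.
    """
    root = np.random.SeedSequence(master_seed)
    metrics_rows, qq_frames = [], {}
    for s_idx, base in enumerate(scenarios):
        child_seeds = root.spawn(1)[0].generate_state(n_repeats) % (2 ** 31)
        t1_acc, pow_acc = [], []
        for rep in range(n_repeats):
            cfg_fields = asdict(base) if isinstance(base, SimulationConfig) else dict(base)
            cfg_fields["seed"] = int(child_seeds[rep])
            cfg = SimulationConfig(**cfg_fields)
            study = simulate_study(cfg)
            mcfg = mostest_config or MostestConfig(seed=cfg.seed)
            result = run_study(study, mcfg)
            t1_acc.append(evaluate_type1(result, cfg.causal_chrom, alphas))
            pow_acc.append(evaluate_power(result, study.B, alpha=power_alpha))
            if rep == 0:
                null_mask = result.table["chrom"] != cfg.causal_chrom
                qq_frames[f"scenario{s_idx}_null"] = qq_data(
                    result.table.loc[null_mask, "mostest_p"].to_numpy())
                perm_p, _ = _perm_pvals(result)
                qq_frames[f"scenario{s_idx}_perm"] = qq_data(perm_p)
        t1 = pd.concat(t1_acc)
        pw = pd.concat(pow_acc)
        g1 = t1.groupby(["test", "alpha"])["fraction"].agg(["mean", "std"])
        g2 = pw.groupby("test")["power_exact"].agg(["mean", "std"])
        for (test, a), row in g1.iterrows():
            metrics_rows.append((s_idx, test, f"type1@{a:g}",
                                 row["mean"], row["std"]))
        for test, row in g2.iterrows():
            metrics_rows.append((s_idx, test, f"power@{power_alpha:g}",
                                 row["mean"], row["std"]))
    metrics = pd.DataFrame(metrics_rows, columns=["scenario", "test", "metric",
                                                  "mean", "sd"])
    return {"metrics": metrics, "qq": qq_frames}


def _perm_pvals(result: MultivariateResult) -> tuple[np.ndarray, np.ndarray]:
    """Omnibus p-values of the permuted statistics under the fitted null."""
    from .multivariate_test import mostest_statistic, mostest_pvalue
    cal = result.calibration
    x2 = mostest_statistic(result.zscores_perm.z, cal.R_inv_reg)
    return mostest_pvalue(x2, cal.gamma_shape, cal.gamma_scale)


def genomewide_scaling(per_chrom_value: float, m_genomewide: int,
                       m_chrom: int) -> float:
    """Scale a per-chromosome simulation default (heritability or causal
    count) to its genome-wide equivalent by the SNP-count ratio."""
    if m_chrom <= 0:
        raise ValueError("m_chrom must be positive")
    return per_chrom_value * m_genomewide / m_chrom
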