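"""Reading, QC-filtering and synthesis of PLINK-style genotype matrices.

Genotypes are additive dosages — the number of copies of allele1 (the A1
column of the .bim file) carried by each individual, in {0, 1, 2} — stored
as a dense ``float64`` matrix with :data:`MISSING` (NaN) marking no-calls.
The 2-bit .bed decode follows the PLINK 1.9 convention: code ``0b00`` is
two copies of A1, ``0b11`` is zero copies, ``0b10`` is heterozygous and
``0b01`` is missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = np.nan

_BED_MAGIC = b"\x6c\x1b"
_VARIANT_MAJOR = b"\x01"

# dosage value for each 2-bit code, PLINK 1.9 orientation (A1 counts)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLUMNS = ["chrom", "variant_id", "cm", "pos", "allele1", "allele2"]


class BedFormatError(ValueError):
    """Raised when a .bed file has invalid magic bytes or mode."""


class BedIntegrityError(ValueError):
    """Raised when .bed payload size disagrees with .bim/.fam dimensions."""


@dataclass
class QcThresholds:
    """Quality-control cutoffs applied by :func:`apply_qc`.

    Defaults mirror a standard imputed-data pipeline: drop samples with
    >10% missing genotypes, variants with >5% missingness, variants
    failing the Hardy-Weinberg exact test at p < 1e-9, and variants with
    minor allele frequency below 0.005.
    """

    max_sample_missing_frac: float = 0.10
    max_variant_missing_frac: float = 0.05
    hwe_p_floor: float = 1e-9
    maf_min: float = 0.005

    def __post_init__(self) -> None:
        for name in ("max_sample_missing_frac", "max_variant_missing_frac",
                     "hwe_p_floor", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """N-samples x M-variants additive dosage matrix with variant metadata.

    Attributes
    ----------
    dosages : ndarray of shape (N, M)
        Counts of allele1 in {0, 1, 2}, NaN for missing.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom`` (int), ``variant_id``,
        ``pos`` (1-based bp), ``allele1``, ``allele2``; within each
        chromosome rows are sorted by position.
    samples : list of str
        Sample identifiers, aligned to the rows of ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} columns")
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        pos = self.variants["pos"].to_numpy()
        chrom = self.variants["chrom"].to_numpy()
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"variants on chromosome {c} not sorted by position")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, from non-missing calls only."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def take_variants(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given variant (column) indices."""
        return GenotypeMatrix(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            list(self.samples),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given sample (row) indices."""
        return GenotypeMatrix(
            self.dosages[index, :],
            self.variants.copy().reset_index(drop=True),
            [self.samples[i] for i in np.atleast_1d(np.arange(self.n_samples)[index])],
        )


def read_plink(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a PLINK 1.9 binary triplet into a :class:`GenotypeMatrix`.

    Only the variant-major layout (mode byte ``0x01``) is supported.
    """
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chrom": int, "variant_id": str, "pos": int,
                             "allele1": str, "allele2": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, usecols=[0, 1],
                      names=["fid", "iid"], dtype=str)
    samples = fam["iid"].tolist()
    n, m = len(samples), len(bim)

    with open(bed_path, "rb") as fh:
        raw = fh.read()
    if raw[:2] != _BED_MAGIC:
        raise BedFormatError(f"{bed_path}: invalid .bed magic bytes {raw[:2]!r}")
    if raw[2:3] != _VARIANT_MAJOR:
        raise BedFormatError(f"{bed_path}: only variant-major mode supported")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * m:
        raise BedIntegrityError(
            f"{bed_path}: payload of {payload.size} bytes, expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants")

    blocks = payload.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):  # sample order is little-endian within each byte
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    return GenotypeMatrix(dosages, bim[["chrom", "variant_id", "pos",
                                        "allele1", "allele2"]].copy(), samples)


def write_plink(G: GenotypeMatrix, prefix: str) -> None:
    """Write a GenotypeMatrix as a PLINK 1.9 binary triplet (variant-major)."""
    n, m = G.dosages.shape
    code_of = {2.0: 0, 1.0: 2, 0.0: 3}
    codes = np.full((m, n), 1, dtype=np.uint8)  # 0b01 = missing
    for dosage, code in code_of.items():
        codes[(G.dosages.T == dosage)] = code
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    packed = (codes[:, 0::4] | (codes[:, 1::4] << 2)
              | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6))
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC + _VARIANT_MAJOR + packed.astype(np.uint8).tobytes())
    bim = G.variants.assign(cm=0)[["chrom", "variant_id", "cm", "pos",
                                   "allele1", "allele2"]]
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    with open(f"{prefix}.fam", "w") as fh:
        for s in G.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")


def hardy_weinberg_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value (Wigginton et al. 2005).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that do not exceed the observed
    configuration's probability. Returns a value in (0, 1].
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("Hardy-Weinberg test undefined for zero total count")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (gammaln(n + 1) - gammaln(rare_hom + 1) - gammaln(hets + 1)
            - gammaln(common_hom + 1) + hets * np.log(2.0)
            + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(G: GenotypeMatrix, thresholds: QcThresholds | None = None):
    """Apply sample-then-variant QC filters; returns (filtered, report).

    Samples exceeding the missingness cap are dropped first; then variants
    are dropped for missingness, Hardy-Weinberg failure, or low MAF,
    evaluated on the surviving samples. ``report`` is a DataFrame with one
    row per filter and the number of samples/variants removed.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    rows = []

    sample_miss = np.isnan(G.dosages).mean(axis=1)
    keep_s = sample_miss <= thresholds.max_sample_missing_frac
    rows.append(("sample_missingness", "samples", int((~keep_s).sum())))
    G = G.take_samples(np.where(keep_s)[0]) if not keep_s.all() else G

    miss = np.isnan(G.dosages).mean(axis=0) if G.n_samples else np.zeros(G.n_variants)
    fail_miss = miss > thresholds.max_variant_missing_frac

    hwe_p = np.ones(G.n_variants)
    for j in range(G.n_variants):
        col = G.dosages[:, j]
        col = col[np.isfinite(col)]
        if col.size:
            hwe_p[j] = hardy_weinberg_p(int((col == 2).sum()), int((col == 1).sum()),
                                        int((col == 0).sum()))
    fail_hwe = (hwe_p < thresholds.hwe_p_floor) & ~fail_miss

    maf = G.maf()
    fail_maf = (np.nan_to_num(maf) < thresholds.maf_min) & ~fail_miss & ~fail_hwe

    rows.append(("variant_missingness", "variants", int(fail_miss.sum())))
    rows.append(("hardy_weinberg", "variants", int(fail_hwe.sum())))
    rows.append(("maf", "variants", int(fail_maf.sum())))
    keep_v = ~(fail_miss | fail_hwe | fail_maf)
    out = G.take_variants(np.where(keep_v)[0]) if not keep_v.all() else G
    if out.n_variants == 0 or out.n_samples == 0:
        warnings.warn("QC removed all samples or all variants", stacklevel=2)
    report = pd.DataFrame(rows, columns=["filter", "unit", "removed"])
    return out, report


def simulate_genotypes(n_samples: int, n_variants: int,
                       maf_spec=(0.05, 0.5), ld_decay: float = 0.0,
                       chrom_sizes=None, seed=0) -> GenotypeMatrix:
    """Draw synthetic biallelic hard-call genotypes.

    Each variant's MAF is drawn uniformly from ``maf_spec = (low, high)``
    (or taken from an explicit array of length ``n_variants``). With
    ``ld_decay`` > 0, local LD is induced per chromosome by a latent AR(1)
    Gaussian per haplotype, thresholded at the quantile matching each
    variant's MAF, so adjacent variants share correlated allele states;
    ``ld_decay`` is the AR coefficient. Chromosomes are independent.

    Parameters
    ----------
    chrom_sizes : sequence of int, optional
        Number of variants per chromosome (must sum to ``n_variants``);
        default is a single chromosome.
    """
    if n_samples <= 0 or n_variants <= 0:
        raise ValueError("n_samples and n_variants must be positive")
    if not 0.0 <= ld_decay < 1.0:
        raise ValueError("ld_decay must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    if isinstance(maf_spec, np.ndarray):  # explicit per-variant MAFs
        mafs = maf_spec.astype(float)
        if mafs.shape != (n_variants,):
            raise ValueError("maf_spec array must have length n_variants")
    elif np.ndim(maf_spec) == 0:
        mafs = np.full(n_variants, float(maf_spec))
    else:  # (low, high) uniform bounds
        lo, hi = map(float, maf_spec)
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"MAF bounds ({lo}, {hi}) must satisfy 0 < lo <= hi <= 0.5")
        mafs = rng.uniform(lo, hi, size=n_variants)
    if mafs.size and not (0.0 < mafs.min() and mafs.max() <= 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")

    if chrom_sizes is None:
        chrom_sizes = [n_variants]
    if sum(chrom_sizes) != n_variants:
        raise ValueError("chrom_sizes must sum to n_variants")

    from scipy.special import ndtri
    thresholds = ndtri(mafs)  # latent < threshold  ->  allele present

    dosages = np.zeros((n_samples, n_variants))
    start = 0
    for size in chrom_sizes:
        for _hap in range(2):
            z = rng.standard_normal((n_samples, size))
            if ld_decay > 0.0:
                innov = np.sqrt(1.0 - ld_decay ** 2)
                for j in range(1, size):
                    z[:, j] = ld_decay * z[:, j - 1] + innov * z[:, j]
            dosages[:, start:start + size] += (
                z < thresholds[start:start + size]).astype(float)
        start += size

    chrom = np.concatenate([np.full(s, i + 1, dtype=int)
                            for i, s in enumerate(chrom_sizes)])
    pos = np.concatenate([np.arange(1, s + 1) * 1000 for s in chrom_sizes])
    variants = pd.DataFrame({
        "chrom": chrom,
        "variant_id": [f"snp_{c}_{p}" for c, p in zip(chrom, pos)],
        "pos": pos, "allele1": "A", "allele2": "G",
    })
    return GenotypeMatrix(dosages, variants, [f"sample_{i}" for i in range(n_samples)])
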