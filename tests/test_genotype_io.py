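"""Genotype I/O: bed codec, Hardy-Weinberg exact test, QC, synthesis."""

import math

import numpy as np
import pandas as pd
import pytest

from mvgwas import (QcThresholds, apply_qc, hardy_weinberg_p, read_plink,
                    simulate_genotypes, write_plink)
from mvgwas.genotype_io import BedFormatError, BedIntegrityError

from conftest import make_genotypes


# ---------------------------------------------------------------- bed codec

def _write_triplet(tmp_path, bed_bytes, n_samples, n_variants):
    prefix = tmp_path / "toy"
    (prefix.with_suffix(".bed")).write_bytes(bed_bytes)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(n_variants):
            fh.write(f"1\tv{j}\t0\t{1000 * (j + 1)}\tA\tG\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n_samples):
            fh.write(f"s{i}\ts{i}\t0\t0\t0\t-9\n")
    return prefix


def test_bed_decode_hand_encoded_codes(tmp_path):
    """Hand-packed 2-bit codes decode to the PLINK 1.9 dosages.

    Codes per sample (little-endian within the byte): 00->2 copies of A1,
    10->het, 11->0 copies, 01->missing.
    """
    # samples s0..s3 carry codes 00, 10, 11, 01 -> dosages 2, 1, 0, NaN
    byte = 0b00 | (0b10 << 2) | (0b11 << 4) | (0b01 << 6)
    prefix = _write_triplet(tmp_path, b"\x6c\x1b\x01" + bytes([byte]), 4, 1)
    G = read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")
    np.testing.assert_array_equal(G.dosages[:3, 0], [2.0, 1.0, 0.0])
    assert np.isnan(G.dosages[3, 0])


def test_bed_all_heterozygous(tmp_path):
    byte = 0b10 | (0b10 << 2) | (0b10 << 4) | (0b10 << 6)
    prefix = _write_triplet(tmp_path, b"\x6c\x1b\x01" + bytes([byte]), 4, 1)
    G = read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")
    np.testing.assert_array_equal(G.dosages[:, 0], np.ones(4))


def test_bed_bad_magic_and_dimension_mismatch(tmp_path):
    prefix = _write_triplet(tmp_path, b"\x00\x00\x01\x00", 4, 1)
    with pytest.raises(BedFormatError):
        read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")
    # fam lists 3 samples but payload is sized for 4 variants' worth
    prefix2 = _write_triplet(tmp_path / "..", b"", 0, 0)  # unused
    prefix3 = _write_triplet(tmp_path, b"\x6c\x1b\x01" + b"\x00\x00", 3, 1)
    with pytest.raises(BedIntegrityError):
        read_plink(f"{prefix3}.bed", f"{prefix3}.bim", f"{prefix3}.fam")


def test_bed_roundtrip_identity(tmp_path, rng):
    """encode -> decode is the identity on all four genotype states."""
    d = rng.choice([0.0, 1.0, 2.0, np.nan], size=(17, 5))
    G = make_genotypes(d)
    write_plink(G, str(tmp_path / "rt"))
    G2 = read_plink(tmp_path / "rt.bed", tmp_path / "rt.bim", tmp_path / "rt.fam")
    np.testing.assert_array_equal(np.isnan(G.dosages), np.isnan(G2.dosages))
    np.testing.assert_array_equal(np.nan_to_num(G.dosages),
                                  np.nan_to_num(G2.dosages))
    pd.testing.assert_frame_equal(G.variants, G2.variants)


# ---------------------------------------------------- Hardy-Weinberg exact

def hwe_exact_oracle(n_hom1, n_het, n_hom2):
    """Brute-force conditional enumeration over heterozygote counts,
    in exact rational arithmetic."""
    from fractions import Fraction
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het  # allele1 count
    n_b = 2 * n - n_a

    # conditional P(h | n, n_a) = n! 2^h n_a! n_b! / (ha! h! hb! (2n)!)
    def prob(h):
        ha = (n_a - h) // 2
        hb = (n_b - h) // 2
        if ha < 0 or hb < 0 or (n_a - h) % 2:
            return Fraction(0)
        return Fraction(
            math.factorial(n) * 2 ** h * math.factorial(n_a) * math.factorial(n_b),
            math.factorial(ha) * math.factorial(h) * math.factorial(hb)
            * math.factorial(2 * n))

    probs = [prob(h) for h in range(0, min(n_a, n_b) + 1)]
    p_obs = probs[n_het]
    assert sum(probs) == 1
    return float(sum(p for p in probs if p <= p_obs))


@pytest.mark.parametrize("counts", [(25, 50, 25), (57, 14, 50), (0, 100, 0),
                                    (10, 3, 2), (1, 1, 1), (0, 1, 0),
                                    (40, 20, 40), (3, 60, 3)])
def test_hwe_matches_enumeration_oracle(counts):
    assert hardy_weinberg_p(*counts) == pytest.approx(
        hwe_exact_oracle(*counts), abs=1e-12)


def test_hwe_edge_values():
    assert hardy_weinberg_p(25, 50, 25) == pytest.approx(1.0)
    assert hardy_weinberg_p(0, 100, 0) < 1e-9  # extreme heterozygote excess
    with pytest.raises(ValueError):
        hardy_weinberg_p(0, 0, 0)


# ------------------------------------------------------------------- QC

def test_apply_qc_hand_built_case():
    """One sample 20% missing and one variant 10% missing are removed, in
    that order; everything else survives."""
    rng = np.random.default_rng(5)
    d = rng.binomial(2, 0.5, size=(10, 20)).astype(float)
    d[0, 10:14] = np.nan  # sample 0: 4/20 = 20% missing
    d[5, 1] = np.nan      # sample 5 stays (5%); variant 1: 1/9 > 5% after drop
    G = make_genotypes(d)
    thr = QcThresholds(max_sample_missing_frac=0.10,
                       max_variant_missing_frac=0.05,
                       hwe_p_floor=0.0, maf_min=0.0)
    out, report = apply_qc(G, thr)
    assert out.n_samples == 9 and "s0" not in out.samples
    assert out.n_variants == 19 and "v1" not in list(out.variants["variant_id"])
    rep = dict(zip(report["filter"], report["removed"]))
    assert rep["sample_missingness"] == 1 and rep["variant_missingness"] == 1


def test_apply_qc_maf_threshold():
    """A variant with MAF 0.004 fails the 0.005 floor."""
    n = 1000
    d = np.zeros((n, 2))
    d[:8, 0] = 1.0   # MAF 0.004
    d[:200, 1] = 1.0  # MAF 0.1
    out, _ = apply_qc(make_genotypes(d),
                      QcThresholds(hwe_p_floor=0.0, maf_min=0.005))
    assert list(out.variants["variant_id"]) == ["v1"]


def test_apply_qc_idempotent_and_noop(rng):
    d = rng.binomial(2, 0.5, size=(50, 6)).astype(float)
    G = make_genotypes(d)
    once, _ = apply_qc(G, QcThresholds())
    twice, rep2 = apply_qc(once, QcThresholds())
    np.testing.assert_array_equal(once.dosages, twice.dosages)
    assert rep2["removed"].sum() == 0


# ------------------------------------------------------------- synthesis

def test_simulate_genotypes_determinism_and_independence():
    G1 = simulate_genotypes(2000, 40, seed=11)
    G2 = simulate_genotypes(2000, 40, seed=11)
    np.testing.assert_array_equal(G1.dosages, G2.dosages)
    # ld_decay = 0: adjacent-variant correlation is sampling noise only
    r = [np.corrcoef(G1.dosages[:, j], G1.dosages[:, j + 1])[0, 1]
         for j in range(39)]
    assert np.max(np.abs(r)) < 4 / np.sqrt(2000)
    assert not np.array_equal(simulate_genotypes(2000, 40, seed=12).dosages,
                              G1.dosages)


def test_simulate_genotypes_ld_matches_latent_monte_carlo():
    """Adjacent-pair r^2 under ld_decay=0.9 agrees with an independent
    Monte-Carlo of the latent thresholded-Gaussian rule."""
    maf = 0.3
    rho = 0.9
    mc = np.random.default_rng(99)
    from scipy.special import ndtri
    thr = ndtri(maf)
    # oracle: 1e6 independent draws of two adjacent latent pairs, 2 haplotypes
    z1 = mc.standard_normal(10 ** 6)
    z2 = rho * z1 + np.sqrt(1 - rho ** 2) * mc.standard_normal(10 ** 6)
    w1 = mc.standard_normal(10 ** 6)
    w2 = rho * w1 + np.sqrt(1 - rho ** 2) * mc.standard_normal(10 ** 6)
    d1 = (z1 < thr).astype(float) + (w1 < thr)
    d2 = (z2 < thr).astype(float) + (w2 < thr)
    expected_r2 = np.corrcoef(d1, d2)[0, 1] ** 2

    G = simulate_genotypes(10_000, 60, maf_spec=np.full(60, maf),
                           ld_decay=rho, seed=3)
    r2 = [np.corrcoef(G.dosages[:, j], G.dosages[:, j + 1])[0, 1] ** 2
          for j in range(59)]
    assert np.mean(r2) == pytest.approx(expected_r2, abs=0.05)


def test_simulate_genotypes_config_errors():
    with pytest.raises(ValueError):
        simulate_genotypes(10, 5, maf_spec=(0.0, 0.6))
    with pytest.raises(ValueError):
        simulate_genotypes(10, 5, chrom_sizes=[2, 2])
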