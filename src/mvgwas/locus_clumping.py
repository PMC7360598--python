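"""FUMA SNP2GENE-style locus definition from summary statistics.

The procedure, applied per summary table with an LD reference panel:

1. Greedily clump genome-wide significant SNPs (p < 5e-8) at r^2 >= 0.6,
   ascending p, to obtain *independent significant SNPs*.
2. Clump those again at r^2 >= 0.1 to obtain *lead SNPs*.
3. *Candidate SNPs* are all panel SNPs with r^2 >= 0.1 to any lead SNP;
   each lead's locus spans the contiguous region covering its candidates.
4. Loci closer than 250 kb (between span boundaries) are merged.

Any :class:`~mvgwas.genotype_io.GenotypeMatrix` serves as LD panel, so
the in-sample genotypes can stand in for an external reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix


class UndefinedLDError(ValueError):
    """LD requested for a monomorphic variant."""


@dataclass
class Locus:
    """A merged genomic risk locus."""

    chrom: int
    start_bp: int
    end_bp: int
    lead_snp: str
    lead_p: float
    independent_significant_snps: list = field(default_factory=list)
    candidate_snps: list = field(default_factory=list)
    n_merged: int = 1


def _standardized_dosages(G: GenotypeMatrix) -> np.ndarray:
    D = G.dosages.copy()
    mask = np.isnan(D)
    if mask.any():
        means = np.nanmean(D, axis=0)
        D[mask] = np.broadcast_to(means, D.shape)[mask]
    D -= D.mean(axis=0)
    sd = D.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        D /= sd
    return D


def ld_r2(G: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation between dosage vectors of variants i, j.

    Symmetric under allele-coding flips (2 - dosage) since r^2 ignores
    sign. Raises :class:`UndefinedLDError` for monomorphic variants.
    """
    a, b = G.dosages[:, i], G.dosages[:, j]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise UndefinedLDError(f"monomorphic variant in pair ({i}, {j})")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _greedy_clump(order: np.ndarray, r2: np.ndarray, threshold: float
                  ) -> tuple[list, dict]:
    """Pick index-set representatives in the given priority order; each
    picked SNP absorbs all not-yet-assigned SNPs with r2 >= threshold."""
    picked, members = [], {}
    assigned = np.zeros(r2.shape[0], dtype=bool)
    for idx in order:
        if assigned[idx]:
            continue
        group = np.flatnonzero((r2[idx] >= threshold) & ~assigned)
        group = np.union1d(group, [idx])
        assigned[group] = True
        picked.append(idx)
        members[idx] = group
    return picked, members


def clump(sumstats: pd.DataFrame, G: GenotypeMatrix, p_col: str = "mostest_p",
          p_thresh: float = 5e-8, r2_indep: float = 0.6, r2_lead: float = 0.1,
          merge_kb: float = 250.0) -> list[Locus]:
    """FUMA-style locus definition (see module docstring for the stages).

    ``sumstats`` needs columns ``variant_id``, ``chrom``, ``pos`` and
    ``p_col``; variant ids are matched against the panel ``G``. Returns
    an empty list when nothing is genome-wide significant.
    """
    panel_ids = {vid: k for k, vid in
                 enumerate(G.variants["variant_id"].to_numpy())}
    ss = sumstats[sumstats["variant_id"].isin(panel_ids)].copy()
    ss["panel_idx"] = ss["variant_id"].map(panel_ids)
    sig = ss[ss[p_col] < p_thresh]
    if sig.empty:
        return []

    # deterministic priority: ascending p, ties by (chrom, pos, id)
    sig = sig.sort_values([p_col, "chrom", "pos", "variant_id"],
                          kind="mergesort").reset_index(drop=True)
    sig_idx = sig["panel_idx"].to_numpy()
    D = _standardized_dosages(G)
    n = G.n_samples
    Dsig = D[:, sig_idx]
    r2_sig = (Dsig.T @ Dsig / n) ** 2
    same_chrom = np.equal.outer(sig["chrom"].to_numpy(), sig["chrom"].to_numpy())
    r2_sig = np.where(same_chrom, r2_sig, 0.0)  # LD only within chromosomes

    order = np.arange(len(sig))
    indep_local, _ = _greedy_clump(order, r2_sig, r2_indep)
    indep = sig.iloc[indep_local].reset_index(drop=True)

    r2_indep_mat = r2_sig[np.ix_(indep_local, indep_local)]
    lead_local, lead_members = _greedy_clump(np.arange(len(indep)),
                                             r2_indep_mat, r2_lead)

    panel_chrom = G.variants["chrom"].to_numpy()
    panel_pos = G.variants["pos"].to_numpy()
    panel_id_arr = G.variants["variant_id"].to_numpy()

    loci: list[Locus] = []
    for ll in lead_local:
        lead_row = indep.iloc[ll]
        lidx = int(lead_row["panel_idx"])
        r2_to_lead = (D[:, lidx] @ D / n) ** 2
        cand = np.flatnonzero((r2_to_lead >= r2_lead)
                              & (panel_chrom == lead_row["chrom"]))
        cand = np.union1d(cand, [lidx])
        member_rows = indep.iloc[lead_members[ll]]
        loci.append(Locus(
            chrom=int(lead_row["chrom"]),
            start_bp=int(panel_pos[cand].min()),
            end_bp=int(panel_pos[cand].max()),
            lead_snp=str(lead_row["variant_id"]),
            lead_p=float(lead_row[p_col]),
            independent_significant_snps=member_rows["variant_id"].tolist(),
            candidate_snps=panel_id_arr[cand].tolist(),
        ))

    loci.sort(key=lambda l: (l.chrom, l.start_bp))
    merged: list[Locus] = []
    for loc in loci:
        if merged and loc.chrom == merged[-1].chrom \
                and loc.start_bp - merged[-1].end_bp < merge_kb * 1000:
            prev = merged[-1]
            keep, other = (prev, loc) if prev.lead_p <= loc.lead_p else (loc, prev)
            merged[-1] = Locus(
                chrom=prev.chrom,
                start_bp=min(prev.start_bp, loc.start_bp),
                end_bp=max(prev.end_bp, loc.end_bp),
                lead_snp=keep.lead_snp, lead_p=keep.lead_p,
                independent_significant_snps=sorted(
                    set(prev.independent_significant_snps)
                    | set(loc.independent_significant_snps)),
                candidate_snps=sorted(set(prev.candidate_snps)
                                      | set(loc.candidate_snps)),
                n_merged=prev.n_merged + loc.n_merged,
            )
        else:
            merged.append(loc)
    return merged


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Tabular view mirroring FUMA's GenomicRiskLoci layout."""
    return pd.DataFrame(
        [(l.chrom, l.start_bp, l.end_bp, l.lead_snp, l.lead_p,
          len(l.independent_significant_snps), len(l.candidate_snps),
          l.n_merged) for l in loci],
        columns=["chrom", "start", "end", "lead_snp", "lead_p",
                 "n_indep_sig", "n_candidates", "n_merged"])
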