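"""Report artifacts: headered tables, QQ and Miami plot data.

All emitted text tables carry a comment header recording the tool
version, the random seed and a hash of the effective configuration, so
two runs with identical configuration produce identical files.
"""

from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np
import pandas as pd

from . import __version__

MIAMI_LOG10P_CAP = 100.0


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed, config: dict | None = None,
                float_format: str = "%.6g") -> None:
    """Write a tab-separated table with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# mvgwas {__version__}\n# seed: {seed}\n")
        fh.write(f"# config_hash: {config_hash(config or {})}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_univariate_sumstats(G, Z, trait_names, path, seed="n/a") -> None:
    """Long-format per-trait GWAS summary, gzip tab-separated.

    One row per (variant, trait): variant_id, chrom, pos, a1, a2, n, r, z, p.
    """
    import gzip

    m = G.n_variants
    frames = []
    for k, name in enumerate(trait_names):
        frames.append(pd.DataFrame({
            "variant_id": G.variants["variant_id"].to_numpy(),
            "chrom": G.variants["chrom"].to_numpy(),
            "pos": G.variants["pos"].to_numpy(),
            "a1": G.variants["allele1"].to_numpy(),
            "a2": G.variants["allele2"].to_numpy(),
            "trait": name, "n": Z.n_effective,
            "r": Z.r[:, k], "z": Z.z[:, k], "p": Z.pvals[:, k],
        }))
    long = pd.concat(frames, ignore_index=True)
    with gzip.open(path, "wt") as fh:
        fh.write(f"# mvgwas {__version__}\n# seed: {seed}\n")
        long.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def export_miami(sumstats_a: pd.DataFrame, sumstats_b: pd.DataFrame,
                 log10p_col: str = "mostest_log10p") -> pd.DataFrame:
    """Long-format Miami-plot data contrasting two sets of results.

    Rows carry (variant_id, chrom, pos, neg_log10p, panel); the shared
    variant universe is the id intersection (a warning is raised when the
    sets differ) and -log10 p is capped at 100 for display.
    """
    ids_a = set(sumstats_a["variant_id"])
    ids_b = set(sumstats_b["variant_id"])
    shared = ids_a & ids_b
    if shared != ids_a or shared != ids_b:
        warnings.warn("variant sets differ; using the intersection",
                      stacklevel=2)
    frames = []
    for panel, ss in (("top", sumstats_a), ("bottom", sumstats_b)):
        sub = ss[ss["variant_id"].isin(shared)]
        frames.append(pd.DataFrame({
            "variant_id": sub["variant_id"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "neg_log10p": np.minimum(-sub[log10p_col].to_numpy(),
                                     MIAMI_LOG10P_CAP),
            "panel": panel,
        }))
    return pd.concat(frames, ignore_index=True)
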