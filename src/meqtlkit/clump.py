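"""LD computation, greedy clumping of meQTL SNPs, connectivity statistics.

Clumping rule: SNPs are sorted by number of associated CpGs (descending;
ties broken by the p-value of the best association, then by position).
The top unclumped SNP becomes a region representative and absorbs every
unclumped SNP on the same chromosome within +/- 2 Mbp with dosage
r^2 > 0.1 against it; this repeats until all SNPs are assigned, so the
regions partition the SNP set. cis and trans meQTL sets are clumped
separately, and clumping is chromosome-local.

Connectivity: per CpG, the number of distinct clumped regions containing
an associated SNP; per region, the number of distinct associated CpGs.
"Highly regulated" CpGs and "key regulatory" regions are outliers with
counts strictly above Q3 + 3*IQR of the respective distribution
(linear-interpolation quantiles).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from meqtlkit.datatypes import GenotypeMatrix


def ld_r2(geno: GenotypeMatrix, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of dosages, pairwise-complete."""
    x = geno.dosages[snp_i].to_numpy(dtype=float)
    y = geno.dosages[snp_j].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("monomorphic SNP in r^2 computation")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_matrix(geno: GenotypeMatrix, snps=None, impute: bool = True) -> pd.DataFrame:
    """Dosage correlation (r, signed) matrix over the pooled samples."""
    d = geno.dosages if snps is None else geno.dosages[list(snps)]
    G = d.to_numpy(dtype=float)
    if impute and np.isnan(G).any():
        G = G.copy()
        mu = np.nanmean(G, axis=0)
        nan = np.isnan(G)
        G[nan] = np.take(mu, np.nonzero(nan)[1])
    sd = G.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic SNP in LD matrix")
    R = np.corrcoef(G, rowvar=False)
    return pd.DataFrame(np.atleast_2d(R), index=d.columns, columns=d.columns)


def clump(
    snp_stats: pd.DataFrame,
    r2: pd.DataFrame,
    r2_min: float = 0.1,
    window: int = 2_000_000,
    r_is_signed: bool = False,
) -> pd.DataFrame:
    """Greedy LD clumping of meQTL SNPs.

    ``snp_stats`` is indexed by SNP id with columns ``chrom``, ``pos``,
    ``n_cpgs`` (associated-CpG count) and ``best_p`` (p of the SNP's most
    significant association, used only for tie-breaks). ``r2`` is a square
    r^2 DataFrame covering the SNPs (pass ``r_is_signed=True`` for a
    signed correlation matrix, which is then squared).

    Returns one row per region: ``region``, ``representative``,
    ``members`` (list), ``chrom``, ``span_start``, ``span_end``.
    """
    if snp_stats.empty:
        return pd.DataFrame(
            columns=["region", "representative", "members", "chrom",
                     "span_start", "span_end"]
        ).set_index("region")
    r2m = r2.loc[snp_stats.index, snp_stats.index].to_numpy(dtype=float)
    if r_is_signed:
        r2m = r2m**2
    order = snp_stats.sort_values(
        by=["n_cpgs", "best_p", "pos"], ascending=[False, True, True], kind="stable"
    ).index
    pos = snp_stats["pos"].to_numpy(dtype=float)
    chrom = snp_stats["chrom"].to_numpy()
    loc = {s: i for i, s in enumerate(snp_stats.index)}
    unclumped = np.ones(len(snp_stats), dtype=bool)
    regions = []
    for snp in order:
        i = loc[snp]
        if not unclumped[i]:
            continue
        near = (
            unclumped
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
            & (r2m[i] > r2_min)
        )
        near[i] = True
        members = snp_stats.index[near].tolist()
        unclumped[near] = False
        regions.append({
            "region": f"clump{len(regions)}",
            "representative": snp,
            "members": members,
            "chrom": chrom[i],
            "span_start": int(pos[near].min()),
            "span_end": int(pos[near].max()),
        })
    return pd.DataFrame(regions).set_index("region")


def snp_stats_from_pairs(pairs: pd.DataFrame, snp_info: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP associated-CpG counts and best p from significant pairs."""
    grouped = pairs.groupby("snp").agg(
        n_cpgs=("cpg", "nunique"), best_p=("p", "min")
    )
    out = grouped.join(snp_info[["chrom", "pos"]], how="left")
    return out[["chrom", "pos", "n_cpgs", "best_p"]]


def per_cpg_clumped_counts(
    pairs: pd.DataFrame,
    clumps: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effective (clump-level) meQTL counts per CpG, and CpGs per region.

    ``pairs`` holds significant associations (columns ``snp, cpg, p``);
    every SNP must belong to a clump. Returns (per-CpG table with columns
    ``count`` and the representative SNP chosen as the most significant
    association within each region, per-region table with distinct
    associated-CpG ``count``).
    """
    snp_to_region = {}
    for region, row in clumps.iterrows():
        for s in row["members"]:
            snp_to_region[s] = region
    missing = set(pairs["snp"]) - set(snp_to_region)
    if missing:
        raise ValueError(f"pairs reference SNPs outside the clump set: {sorted(missing)[:5]}")
    df = pairs.copy()
    df["region"] = df["snp"].map(snp_to_region)
    best = df.sort_values("p", kind="stable").drop_duplicates(["cpg", "region"])
    per_cpg = best.groupby("cpg").agg(count=("region", "nunique"))
    reps = best.set_index(["cpg", "region"])["snp"]
    per_cpg["representatives"] = [
        {r: reps[(c, r)] for r in best.loc[best["cpg"] == c, "region"]}
        for c in per_cpg.index
    ]
    per_region = df.groupby("region").agg(count=("cpg", "nunique"))
    return per_cpg, per_region


def outlier_threshold(counts) -> tuple[float, np.ndarray]:
    """Q3 + 3*IQR outlier rule with linear-interpolation quantiles.

    Returns the threshold and a boolean flag per input marking counts
    strictly above it.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation (type 7)
    threshold = q3 + 3.0 * (q3 - q1)
    return float(threshold), x > threshold


def connectivity_stats(
    per_cpg: pd.DataFrame,
    per_region: pd.DataFrame,
) -> dict:
    """Outlier thresholds and flags for CpG and region connectivity."""
    out = {}
    cpg_thr, cpg_flags = outlier_threshold(per_cpg["count"])
    reg_thr, reg_flags = outlier_threshold(per_region["count"])
    out["cpg_threshold"] = cpg_thr
    out["highly_regulated"] = per_cpg.index[cpg_flags]
    out["region_threshold"] = reg_thr
    out["key_regulatory"] = per_region.index[reg_flags]
    return out
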