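"""Per-cohort SNP x CpG association scans with cis/trans classification.

Each SNP-CpG pair is tested by simple linear regression of residualized
methylation on alternative-allele dose; two-sided p-values use the t
reference with n - 2 degrees of freedom (n - 4 for the interaction
model). Pairs within 1 Mbp on the same chromosome are cis (inclusive
boundary), all others trans, and only pairs meeting the type-specific
candidate threshold (p <= 5e-3 cis, p <= 5e-6 trans by default) are
retained for meta-analysis.

Sporadically missing dosages are mean-imputed per SNP within the cohort
for the scan only; scans stream blocks of CpGs so memory stays bounded,
and the output is independent of the block size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from meqtlkit.datatypes import GenotypeMatrix, MethylationMatrix, check_aligned

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000
P_FLOOR = 1e-300  # underflow guard; p stays in (0, 1]

RECORD_COLUMNS = ["snp", "cpg", "cohort", "type", "beta", "se", "p", "n"]


def classify_cis_trans(snp: tuple[str, int], cpg: tuple[str, int],
                       window: int = CIS_WINDOW) -> str:
    """cis iff same chromosome and |pos_snp - pos_cpg| <= window (inclusive)."""
    if snp[1] <= 0 or cpg[1] <= 0:
        raise ValueError("positions must be positive")
    if snp[0] == cpg[0] and abs(snp[1] - cpg[1]) <= window:
        return "cis"
    return "trans"


def cis_mask(snp_info: pd.DataFrame, cpg_info: pd.DataFrame,
             window: int = CIS_WINDOW) -> np.ndarray:
    """Boolean (n_snps x n_cpgs) matrix marking cis pairs."""
    same = snp_info["chrom"].to_numpy()[:, None] == cpg_info["chrom"].to_numpy()[None, :]
    dist = np.abs(snp_info["pos"].to_numpy()[:, None] - cpg_info["pos"].to_numpy()[None, :])
    return same & (dist <= window)


def _impute_and_center(dosages: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages, center columns; flag zero-variance SNPs."""
    G = dosages.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    G -= G.mean(axis=0)
    sxx = (G**2).sum(axis=0)
    return G, sxx


def scan_cohort(
    geno: GenotypeMatrix,
    meth: MethylationMatrix,
    cohort: str,
    p_cis: float = 5e-3,
    p_trans: float = 5e-6,
    window: int = CIS_WINDOW,
    block_size: int = 2000,
) -> pd.DataFrame:
    """Scan all SNP x CpG pairs in one cohort, retaining candidates.

    Returns a DataFrame with columns ``snp, cpg, cohort, type, beta, se,
    p, n`` containing every pair whose two-sided p meets its type-specific
    threshold (inclusive).
    """
    check_aligned(geno, meth)
    if meth.stage != "residual":
        raise ValueError("scan expects residual-stage methylation")
    n = geno.n_samples
    if n < 10:
        raise ValueError("cohort too small to scan (n < 10)")
    G, sxx = _impute_and_center(geno.dosages)
    poly = sxx > 0
    if not poly.all():
        logger.warning("%s: skipping %d zero-variance SNP(s) in cohort %s",
                       cohort, int((~poly).sum()), cohort)
    full_cis = cis_mask(geno.snp_info, meth.cpg_info, window=window)

    dof = n - 2
    out_frames = []
    Yfull = meth.values.to_numpy(dtype=float)
    for start in range(0, meth.n_cpgs, block_size):
        stop = min(start + block_size, meth.n_cpgs)
        Y = Yfull[:, start:stop]
        Y = Y - Y.mean(axis=0)
        syy = (Y**2).sum(axis=0)
        sxy = G.T @ Y  # (snps x cpgs)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx[:, None]
            rss = syy[None, :] - beta * sxy
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / dof / sxx[:, None])
            tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        p = np.clip(2.0 * stats.t.sf(np.abs(tstat), dof), P_FLOOR, 1.0)
        blk_cis = full_cis[:, start:stop]
        keep = poly[:, None] & np.where(blk_cis, p <= p_cis, p <= p_trans)
        si, ci = np.nonzero(keep)
        if len(si) == 0:
            continue
        out_frames.append(pd.DataFrame({
            "snp": geno.snp_ids.to_numpy()[si],
            "cpg": meth.cpg_ids.to_numpy()[start:stop][ci],
            "cohort": cohort,
            "type": np.where(blk_cis[si, ci], "cis", "trans"),
            "beta": beta[si, ci],
            "se": np.where(se[si, ci] > 0, se[si, ci], np.nan),
            "p": p[si, ci],
            "n": n,
        }))
    if not out_frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(out_frames, ignore_index=True)


def interaction_scan(
    geno: GenotypeMatrix,
    meth: MethylationMatrix,
    cell_prop: pd.Series,
    cohort: str,
    p_keep: float = 5e-3,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Cell-proportion interaction scan over cis pairs.

    Fits ``meth ~ G + prop + G x prop`` per cis SNP-CpG pair and records
    the interaction term; methylation must have been adjusted WITHOUT the
    focal cell proportion. Pairs with interaction p <= ``p_keep`` are
    retained.
    """
    check_aligned(geno, meth)
    prop = cell_prop.loc[geno.sample_ids].to_numpy(dtype=float)
    if np.ptp(prop) == 0:
        raise ValueError("cell proportion is constant")
    n = geno.n_samples
    dof = n - 4
    G, sxx = _impute_and_center(geno.dosages)
    full_cis = cis_mask(geno.snp_info, meth.cpg_info, window=window)
    Y = meth.values.to_numpy(dtype=float)
    rows = []
    for j in range(geno.n_snps):
        if sxx[j] == 0:
            logger.warning("skipping zero-variance SNP %s", geno.snp_ids[j])
            continue
        cpg_idx = np.nonzero(full_cis[j])[0]
        if len(cpg_idx) == 0:
            continue
        g = G[:, j]
        X = np.column_stack([np.ones(n), g, prop, g * prop])
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T
        Yj = Y[:, cpg_idx]
        coef = H @ Yj  # 4 x m
        resid = Yj - X @ coef
        sigma2 = (resid**2).sum(axis=0) / dof
        se_int = np.sqrt(sigma2 * XtX_inv[3, 3])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = coef[3] / se_int
        p = np.clip(2.0 * stats.t.sf(np.abs(tstat), dof), P_FLOOR, 1.0)
        keep = p <= p_keep
        for m_i, k in zip(np.nonzero(keep)[0], range(int(keep.sum()))):
            rows.append({
                "snp": geno.snp_ids[j],
                "cpg": meth.cpg_ids[cpg_idx[m_i]],
                "cohort": cohort,
                "type": "cis",
                "beta": coef[3, m_i],
                "se": se_int[m_i],
                "p": p[m_i],
                "n": n,
            })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
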