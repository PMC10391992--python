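"""Genotype and probe QC, inverse normal transformation, covariate adjustment.

QC defaults follow common array-meQTL practice: SNPs are dropped at
MAF < 0.01 (strict), Hardy-Weinberg exact P < 1e-6, or missingness > 3%;
samples at missingness > 5%. Samples are filtered first, then per-SNP
statistics are recomputed. Methylation probes are dropped at missingness
> 5% (strict) or via an externally supplied mask list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import gammaln, ndtri

from meqtlkit.datatypes import CovariateTable, GenotypeMatrix, MethylationMatrix

logger = logging.getLogger(__name__)

BLOM_OFFSET = 3.0 / 8.0


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count (two-sided exact convention).

    Parameters are the three genotype counts; returns the exact p-value.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = int(sum(counts))
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = int(min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa))
    if n_rare == 0:  # monomorphic: a single attainable configuration
        return 1.0
    # Support: heterozygote counts h with the parity of the rare-allele
    # count; the rare homozygote count is (n_rare - h) / 2 >= 0.
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    n_rare_hom = (n_rare - hs) // 2
    n_common_hom = n - hs - n_rare_hom
    ok = n_common_hom >= 0
    hs, n_rare_hom, n_common_hom = hs[ok], n_rare_hom[ok], n_common_hom[ok]
    # P(h | n, n_rare) proportional to 2^h * n! / (h! n_rare_hom! n_common_hom!)
    logw = (
        hs * np.log(2.0)
        - gammaln(hs + 1.0)
        - gammaln(n_rare_hom + 1.0)
        - gammaln(n_common_hom + 1.0)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    obs = int(n_Aa)
    p_obs = probs[hs == obs][0]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


@dataclass
class FilterReport:
    """Counts of removed entities per QC reason, with per-id details."""

    removed: dict = field(default_factory=dict)
    details: pd.DataFrame | None = None

    def __getitem__(self, key):
        return self.removed[key]


def _hwe_counts_from_dosages(col: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts by rounding dosages; NaN excluded."""
    obs = col[~np.isnan(col)]
    g = np.clip(np.rint(obs), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def filter_genotypes(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    snp_miss_max: float = 0.03,
    sample_miss_max: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply sample- then SNP-level genotype QC.

    Samples with missingness > ``sample_miss_max`` are removed first; SNP
    statistics (MAF, HWE, missingness) are then recomputed on the retained
    samples. Exclusion thresholds are strict (< for MAF, > for
    missingness, < for the HWE p-value).
    """
    if geno.n_samples == 0 or geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    sample_miss = geno.missingness(axis=1)
    bad_samples = sample_miss.index[sample_miss > sample_miss_max]
    kept = geno.subset(samples=geno.sample_ids.difference(bad_samples, sort=False))

    maf = kept.observed_maf()
    snp_miss = kept.missingness(axis=0)
    dos = kept.dosages.to_numpy(dtype=float)
    hwe_p = np.ones(kept.n_snps)
    for j in range(kept.n_snps):
        n_AA, n_Aa, n_aa = _hwe_counts_from_dosages(dos[:, j])
        if n_AA + n_Aa + n_aa > 0:
            hwe_p[j] = hwe_exact_test(n_AA, n_Aa, n_aa)
    hwe_p = pd.Series(hwe_p, index=kept.snp_ids)

    fail_maf = maf < maf_min
    fail_hwe = hwe_p < hwe_p_min
    fail_miss = snp_miss > snp_miss_max
    drop = fail_maf | fail_hwe | fail_miss
    out = kept.subset(snps=kept.snp_ids[~drop.to_numpy()])
    if out.n_snps == 0:
        raise ValueError("all SNPs removed by QC filters")
    details = pd.DataFrame(
        {"maf": maf, "hwe_p": hwe_p, "missingness": snp_miss,
         "fail_maf": fail_maf, "fail_hwe": fail_hwe, "fail_missingness": fail_miss}
    )
    report = FilterReport(
        removed={
            "samples": int(len(bad_samples)),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
            "missingness": int(fail_miss.sum()),
            "snps_total": int(drop.sum()),
        },
        details=details,
    )
    return out, report


def filter_probes(
    meth: MethylationMatrix,
    probe_miss_max: float = 0.05,
    sample_miss_max: float = 0.05,
    mask_list=None,
) -> tuple[MethylationMatrix, FilterReport]:
    """Remove masked probes, high-missingness probes, and high-missingness samples."""
    if meth.stage != "raw":
        raise ValueError("probe QC expects raw-stage methylation")
    mask_list = frozenset(mask_list or ())
    sample_miss = meth.missingness(axis=1)
    bad_samples = sample_miss.index[sample_miss > sample_miss_max]
    kept = meth.subset(samples=meth.sample_ids.difference(bad_samples, sort=False))

    probe_miss = kept.missingness(axis=0)
    fail_miss = probe_miss > probe_miss_max
    fail_mask = kept.cpg_ids.isin(mask_list)
    drop = fail_miss.to_numpy() | fail_mask
    out = kept.subset(cpgs=kept.cpg_ids[~drop])
    if out.n_cpgs == 0:
        raise ValueError("all probes removed by QC filters")
    report = FilterReport(
        removed={
            "samples": int(len(bad_samples)),
            "missingness": int(fail_miss.sum()),
            "masked": int(fail_mask.sum()),
            "probes_total": int(drop.sum()),
        }
    )
    return out, report


def inverse_normal_transform(values, c: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transformation with the Blom offset.

    Maps value with rank r (average ranks for ties) among n non-missing
    observations to ``Phi^{-1}((r - c) / (n - 2c + 1))``; missing entries
    are preserved as NaN.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    xo = x[obs]
    if np.nanmax(xo) == np.nanmin(xo):
        raise ValueError("constant vector: ranks undefined")
    ranks = stats.rankdata(xo, method="average")
    out[obs] = ndtri((ranks - c) / (n - 2.0 * c + 1.0))
    return out


def transform_methylation(meth: MethylationMatrix, c: float = BLOM_OFFSET) -> MethylationMatrix:
    """Apply the INT column-wise, tagging the result as INT stage."""
    vals = meth.values.to_numpy(dtype=float)
    out = np.column_stack([inverse_normal_transform(vals[:, j], c=c)
                           for j in range(vals.shape[1])])
    return MethylationMatrix(
        pd.DataFrame(out, index=meth.sample_ids, columns=meth.cpg_ids),
        meth.cpg_info,
        stage="INT",
    )


def _design_matrix(covars: pd.DataFrame, fixed, grouping) -> np.ndarray:
    """Intercept + numeric fixed effects + one-hot factors (reference dropped)."""
    cols = [np.ones(len(covars))]
    for name in fixed:
        col = covars[name]
        if col.dtype.kind in "biufc":
            cols.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(dtype=float))
    for name in grouping:
        dummies = pd.get_dummies(covars[name].astype("category"), drop_first=True)
        for d in dummies.columns:
            cols.append(dummies[d].to_numpy(dtype=float))
    return np.column_stack(cols)


def _drop_aliased(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent design columns (pivoted QR), warning once."""
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        warnings.warn(
            f"design is rank-deficient: dropping {X.shape[1] - rank} aliased column(s)",
            stacklevel=3,
        )
        keep = np.sort(piv[:rank])
        X = X[:, keep]
    return X


def _residualize_fixed(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of Y on X; NaNs preserved."""
    Q, _ = np.linalg.qr(X)
    out = np.empty_like(Y)
    complete = ~np.isnan(Y).any(axis=0)
    if complete.any():
        Yc = Y[:, complete]
        out[:, complete] = Yc - Q @ (Q.T @ Yc)
    for j in np.nonzero(~complete)[0]:
        y = Y[:, j]
        obs = ~np.isnan(y)
        Xo = X[obs]
        beta, *_ = np.linalg.lstsq(Xo, y[obs], rcond=None)
        col = np.full_like(y, np.nan)
        col[obs] = y[obs] - Xo @ beta
        out[:, j] = col
    return out


def _shrink_group_means(resid: np.ndarray, groups: pd.Series) -> np.ndarray:
    """One-way random-intercept adjustment by method of moments.

    For each grouping level, the group mean is shrunk by the BLUP factor
    ``lambda_g = sigma_b^2 / (sigma_b^2 + sigma_e^2 / n_g)`` with variance
    components from the one-way ANOVA decomposition (pooled across CpGs).
    A level of size 1 still receives shrinkage < 1 (unlike the fixed-effect
    mode, which removes its mean entirely).
    """
    codes, _ = pd.factorize(groups)
    n = len(codes)
    k = codes.max() + 1
    if k < 2:
        return resid
    counts = np.bincount(codes, minlength=k).astype(float)
    out = resid.copy()
    group_sums = np.zeros((k, resid.shape[1]))
    np.add.at(group_sums, codes, resid)
    group_means = group_sums / counts[:, None]
    grand = resid.mean(axis=0)
    ss_between = (counts[:, None] * (group_means - grand) ** 2).sum(axis=0)
    ss_within = ((resid - group_means[codes]) ** 2).sum(axis=0)
    ms_between = ss_between / max(k - 1, 1)
    df_within = max(n - k, 1)
    ms_within = ss_within / df_within
    # Pool across CpGs for stable component estimates.
    n0 = (n - (counts**2).sum() / n) / max(k - 1, 1)
    sigma_e2 = float(np.mean(ms_within))
    sigma_b2 = max(0.0, float(np.mean(ms_between - ms_within)) / n0)
    if sigma_b2 == 0.0:
        return resid
    lam = sigma_b2 / (sigma_b2 + sigma_e2 / counts)
    out -= (lam[:, None] * (group_means - grand))[codes]
    return out


def adjust_methylation(
    meth: MethylationMatrix,
    covars: CovariateTable,
    fixed: list[str],
    grouping: list[str] | None = None,
    random_intercept: list[str] | None = None,
) -> MethylationMatrix:
    """Residualize INT-stage methylation on covariates.

    ``fixed`` columns enter as fixed effects (numeric as-is, categorical
    one-hot with the reference level dropped). ``grouping`` factors are by
    default also treated as categorical fixed effects — a deterministic
    approximation to a mixed model that removes all between-level signal.
    Factors listed in ``random_intercept`` instead receive a one-way
    method-of-moments random-intercept fit with BLUP shrinkage of level
    means.
    """
    if meth.stage != "INT":
        raise ValueError("adjustment expects INT-stage methylation")
    grouping = list(grouping or [])
    random_intercept = list(random_intercept or [])
    fixed_grouping = [g for g in grouping if g not in random_intercept]
    cov = covars.table.loc[meth.sample_ids]
    for name in fixed:
        if cov[name].isna().any():
            raise ValueError(f"fixed covariate {name!r} has missing values")
    X = _design_matrix(cov, fixed, fixed_grouping)
    X = _drop_aliased(X)
    Y = meth.values.to_numpy(dtype=float)
    resid = _residualize_fixed(Y, X)
    for factor in random_intercept:
        resid = _shrink_group_means(resid, cov[factor])
    return MethylationMatrix(
        pd.DataFrame(resid, index=meth.sample_ids, columns=meth.cpg_ids),
        meth.cpg_info,
        stage="residual",
    )
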