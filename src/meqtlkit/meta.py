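"""Random-effects meta-analysis, permutation FDR, and integration summaries.

The meta-analysis is DerSimonian-Laird inverse-variance weighting: with
per-cohort estimates (b_i, se_i), fixed weights w_i = 1/se_i^2 give the
heterogeneity statistic Q = sum w_i (b_i - b_fixed)^2 and

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),

after which random-effects weights w*_i = 1/(se_i^2 + tau^2) pool the
estimate; the pooled p-value uses the normal reference.

FDR is estimated from permutations: methylation sample labels are
shuffled (families moved as blocks), the identical scan + meta +
consistency pipeline is run on each of B permuted datasets, and
FDR(t) = mean_b #{p_null,b <= t} / #{p_obs <= t} is evaluated on the grid
of observed p-values; the selected threshold is the largest t with
FDR(t) <= target, separately per cis/trans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from meqtlkit.datatypes import MethylationMatrix, Pedigree

logger = logging.getLogger(__name__)

META_COLUMNS = ["snp", "cpg", "type", "beta", "se", "p", "tau2", "k", "directions"]


def dl_meta(betas, ses) -> dict:
    """DerSimonian-Laird random-effects pooling of one SNP-CpG pair."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no studies to meta-analyse")
    if np.any(s <= 0) or not (np.isfinite(b).all() and np.isfinite(s).all()):
        raise ValueError("standard errors must be positive and finite")
    k = b.size
    w = 1.0 / s**2
    b_fixed = (w * b).sum() / w.sum()
    Q = (w * (b - b_fixed) ** 2).sum()
    if k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom)
    else:
        tau2 = 0.0
    w_star = 1.0 / (s**2 + tau2)
    beta = (w_star * b).sum() / w_star.sum()
    se = w_star.sum() ** -0.5
    z = beta / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))
    return {"beta": float(beta), "se": float(se), "p": p,
            "tau2": float(tau2), "k": int(k), "Q": float(Q)}


def meta_analyse(records: pd.DataFrame) -> pd.DataFrame:
    """Pool per-cohort association records pair-by-pair (vectorised DL).

    ``records`` is the concatenation of per-cohort scan outputs (columns
    ``snp, cpg, cohort, type, beta, se, p``). Each (snp, cpg) pair is
    pooled across the cohorts in which it was retained. Returns columns
    ``snp, cpg, type, beta, se, p, tau2, k, directions`` where
    ``directions`` is the per-cohort sign string in cohort-sorted order
    (as in GWAMA-style outputs).
    """
    if records.empty:
        return pd.DataFrame(columns=META_COLUMNS)
    df = records.sort_values(["snp", "cpg", "cohort"], kind="stable")
    key, first = np.unique(
        df["snp"].astype(str).to_numpy() + "\x1f" + df["cpg"].astype(str).to_numpy(),
        return_index=True,
    )
    codes = np.searchsorted(
        key, df["snp"].astype(str).to_numpy() + "\x1f" + df["cpg"].astype(str).to_numpy()
    )
    n_pairs = len(key)
    b = df["beta"].to_numpy(dtype=float)
    s = df["se"].to_numpy(dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    sw = np.bincount(codes, weights=w, minlength=n_pairs)
    swb = np.bincount(codes, weights=w * b, minlength=n_pairs)
    sw2 = np.bincount(codes, weights=w**2, minlength=n_pairs)
    k = np.bincount(codes, minlength=n_pairs)
    b_fixed = swb / sw
    Q = np.bincount(codes, weights=w * b**2, minlength=n_pairs) - sw * b_fixed**2
    Q = np.maximum(Q, 0.0)
    denom = sw - sw2 / sw
    with np.errstate(divide="ignore", invalid="ignore"):
        tau2 = np.where(k > 1, np.maximum(0.0, (Q - (k - 1)) / denom), 0.0)
    w_star = 1.0 / (s**2 + tau2[codes])
    sws = np.bincount(codes, weights=w_star, minlength=n_pairs)
    swsb = np.bincount(codes, weights=w_star * b, minlength=n_pairs)
    beta = swsb / sws
    se = sws**-0.5
    p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)

    signs = np.where(b > 0, "+", np.where(b < 0, "-", "0"))
    dir_strings = pd.Series(signs).groupby(codes).agg("".join).to_numpy()

    snps, cpgs = zip(*(kk.split("\x1f") for kk in key))
    types = df["type"].to_numpy()[first]
    return pd.DataFrame({
        "snp": snps, "cpg": cpgs, "type": types,
        "beta": beta, "se": se, "p": p, "tau2": tau2,
        "k": k, "directions": dir_strings,
    })


def consistency_filter(meta_results: pd.DataFrame) -> pd.DataFrame:
    """Keep pairs found in >= 2 cohorts with the same direction everywhere.

    Uses the ``k`` and ``directions`` columns produced by
    :func:`meta_analyse`; never increases the result set and is
    idempotent.
    """
    if meta_results.empty:
        return meta_results
    d = meta_results["directions"].astype(str)
    same_dir = d.map(lambda x: len(set(x)) == 1 and x[0] in "+-")
    return meta_results[(meta_results["k"] >= 2) & same_dir].reset_index(drop=True)


def permute_cohort(
    meth: MethylationMatrix,
    pedigree: Pedigree | None,
    rng: np.random.Generator,
) -> MethylationMatrix:
    """Family-preserving shuffle of methylation sample labels.

    Families are moved as blocks: within each family-size class, whole
    families are randomly reassigned to the sample slots of other families
    of the same size. With only singletons this reduces to a full sample
    shuffle. If a size class contains a single family (nothing can move
    within it) a within-size-class rotation is attempted and the
    degenerate case is logged.
    """
    idx = meth.sample_ids
    n = len(idx)
    if pedigree is None or pedigree.table.empty:
        perm = rng.permutation(n)
    else:
        fam = pedigree.table.loc[idx, "family_id"].to_numpy()
        families: dict[str, list[int]] = {}
        for i, f in enumerate(fam):
            families.setdefault(f, []).append(i)
        by_size: dict[int, list[list[int]]] = {}
        for slots in families.values():
            by_size.setdefault(len(slots), []).append(slots)
        perm = np.empty(n, dtype=int)
        for size, fam_list in by_size.items():
            if len(fam_list) == 1 and size > 1 and len(families) > 1:
                logger.warning(
                    "family-size class %d has a single family; rotation is identity", size
                )
            order = rng.permutation(len(fam_list))
            for dest, src in enumerate(order):
                for slot_pos, member in zip(fam_list[dest], fam_list[src]):
                    perm[slot_pos] = member
    values = meth.values.to_numpy()[perm]
    return MethylationMatrix(
        pd.DataFrame(values, index=idx, columns=meth.cpg_ids),
        meth.cpg_info,
        stage=meth.stage,
    )


@dataclass
class FdrCurve:
    """Permutation-FDR curve over the grid of observed p-values."""

    thresholds: np.ndarray
    fdr: np.ndarray
    n_permutations: int
    target: float
    selected_threshold: float | None = None
    n_significant: int = 0
    defined: bool = True
    extras: dict = field(default_factory=dict)


def permutation_fdr(
    observed_p,
    null_p_sets: list,
    target: float = 0.05,
) -> FdrCurve:
    """Select a significance threshold controlling permutation FDR.

    ``FDR(t) = [(1/B) sum_b #{p_null,b <= t}] / #{p_obs <= t}`` on the
    ascending grid of observed p-values; the selected threshold is the
    largest grid point with FDR <= target.
    """
    obs = np.sort(np.asarray(observed_p, dtype=float))
    B = len(null_p_sets)
    if B < 1:
        raise ValueError("need at least one permutation null set")
    if obs.size == 0:
        return FdrCurve(np.array([]), np.array([]), B, target,
                        selected_threshold=None, defined=False)
    nulls = [np.sort(np.asarray(s, dtype=float)) for s in null_p_sets]
    n_obs_le = np.arange(1, obs.size + 1, dtype=float)
    mean_null_le = np.zeros(obs.size)
    for s in nulls:
        mean_null_le += np.searchsorted(s, obs, side="right")
    mean_null_le /= B
    fdr = mean_null_le / n_obs_le
    ok = fdr <= target
    if ok.any():
        sel = float(obs[np.nonzero(ok)[0].max()])
        n_sig = int(np.nonzero(ok)[0].max() + 1)
        return FdrCurve(obs, fdr, B, target, selected_threshold=sel,
                        n_significant=n_sig)
    return FdrCurve(obs, fdr, B, target, selected_threshold=None,
                    n_significant=0, defined=True)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / n."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def variance_explained(beta: float, maf: float) -> float:
    """Methylation variance explained by a meQTL on a unit-variance trait.

    Under Hardy-Weinberg the dosage variance is 2 maf (1 - maf), so
    R^2 = 2 maf (1 - maf) beta^2, capped at 1.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    return float(min(1.0, 2.0 * maf * (1.0 - maf) * beta**2))


def heritability_meqtl_regression(
    ace: pd.DataFrame,
    meqtl_status: pd.DataFrame,
) -> dict:
    """Regress per-CpG heritability (A) on meQTL-presence indicators.

    ``ace`` must have an ``A`` column indexed by CpG; ``meqtl_status`` has
    boolean ``has_cis`` / ``has_trans`` columns on the same index. Returns
    the OLS R^2, F statistic and p-value plus the four group means
    (none / cis-only / trans-only / both).
    """
    df = ace.join(meqtl_status, how="inner").dropna(subset=["A"])
    if len(df) < 3:
        raise ValueError("need at least 3 CpGs")
    has_cis = df["has_cis"].astype(float).to_numpy()
    has_trans = df["has_trans"].astype(float).to_numpy()
    groups = np.unique(np.column_stack([has_cis, has_trans]), axis=0)
    if len(groups) < 2:
        raise ValueError("need at least 2 meQTL status groups")
    y = df["A"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), has_cis, has_trans])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    p_params = X.shape[1] - 1
    df_resid = len(df) - X.shape[1]
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        fstat, pval = np.inf, 0.0
    else:
        fstat = (r2 / p_params) / ((1.0 - r2) / df_resid)
        pval = float(stats.f.sf(fstat, p_params, df_resid))
    means = {
        "none": float(y[(has_cis == 0) & (has_trans == 0)].mean())
        if ((has_cis == 0) & (has_trans == 0)).any() else np.nan,
        "cis_only": float(y[(has_cis == 1) & (has_trans == 0)].mean())
        if ((has_cis == 1) & (has_trans == 0)).any() else np.nan,
        "trans_only": float(y[(has_cis == 0) & (has_trans == 1)].mean())
        if ((has_cis == 0) & (has_trans == 1)).any() else np.nan,
        "both": float(y[(has_cis == 1) & (has_trans == 1)].mean())
        if ((has_cis == 1) & (has_trans == 1)).any() else np.nan,
    }
    return {"coef": coef, "r2": float(r2), "f": float(fstat), "p": pval,
            "group_means": means, "n": len(df)}
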