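"""Classical-twin ACE variance decomposition by maximum likelihood.

For each CpG, MZ and DZ twin-pair values are modelled as bivariate normal
with a common mean, variance sigma^2 = a2 + c2 + e2 and covariances
cov_MZ = a2 + c2, cov_DZ = a2/2 + c2 (additive genetics is fully shared
in MZ pairs, half-shared in DZ pairs; common environment fully shared in
both). The likelihood is maximised over (a2, c2, e2, mu) with the
variance components bound at zero, from two starting points (the Falconer
plug-in and equal thirds). Reported quantities are the variance shares
A = a2/sigma^2 etc.; narrow-sense heritability is the A share.

Input values are standardized per CpG before fitting, so estimates are
invariant to affine rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

E_FLOOR = 1e-6  # keeps the pair covariance matrix positive definite


@dataclass
class AceEstimate:
    """Variance shares for one CpG; shares are missing when not converged."""

    cpg: str
    A: float
    C: float
    E: float
    loglik: float
    converged: bool


def falconer_estimate(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Falconer plug-in shares: A = 2(r_MZ - r_DZ), C = r_MZ - A, E = rest.

    Shares are clipped at zero and renormalised to sum to one.
    """
    if not (-1.0 <= r_mz <= 1.0 and -1.0 <= r_dz <= 1.0):
        raise ValueError("correlations must be in [-1, 1]")
    A = max(0.0, 2.0 * (r_mz - r_dz))
    C = max(0.0, r_mz - A)
    E = max(0.0, 1.0 - A - C)
    total = A + C + E
    if total == 0.0:
        return (0.0, 0.0, 1.0)
    return (A / total, C / total, E / total)


def _pair_nll(params: np.ndarray, mz: np.ndarray, dz: np.ndarray) -> float:
    a2, c2, e2, mu = params
    v = a2 + c2 + e2
    out = 0.0
    for pairs, cov in ((mz, a2 + c2), (dz, 0.5 * a2 + c2)):
        if len(pairs) == 0:
            continue
        det = v * v - cov * cov
        if det <= 0 or v <= 0:
            return np.inf
        d1 = pairs[:, 0] - mu
        d2 = pairs[:, 1] - mu
        quad = (v * (d1**2 + d2**2) - 2.0 * cov * d1 * d2) / det
        out += 0.5 * (len(pairs) * np.log(det) + quad.sum()) + len(pairs) * np.log(2 * np.pi)
    return float(out)


def _empirical_pair_corr(pairs: np.ndarray) -> float:
    """Intraclass-style correlation using both orderings of each pair."""
    if len(pairs) < 2:
        return 0.0
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    sx = x.std()
    if sx == 0:
        return 0.0
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def fit_ace(mz_pairs, dz_pairs, cpg: str = "") -> AceEstimate:
    """Maximum-likelihood ACE fit from MZ and DZ twin-pair values.

    ``mz_pairs`` and ``dz_pairs`` are (n, 2) arrays of co-twin values.
    Returns shares on the variance scale; ``converged=False`` (with NaN
    shares) marks critical optimisation failures, mirroring the practice
    of discarding such CpGs.
    """
    mz = np.asarray(mz_pairs, dtype=float).reshape(-1, 2)
    dz = np.asarray(dz_pairs, dtype=float).reshape(-1, 2)
    mz = mz[~np.isnan(mz).any(axis=1)]
    dz = dz[~np.isnan(dz).any(axis=1)]
    allv = np.concatenate([mz.ravel(), dz.ravel()])
    if allv.size < 8 or allv.std() == 0:
        return AceEstimate(cpg, np.nan, np.nan, np.nan, np.nan, False)
    # Standardize: shares are scale-free, and unit variance conditions the fit.
    loc, scale = allv.mean(), allv.std()
    mz = (mz - loc) / scale
    dz = (dz - loc) / scale

    r_mz = _empirical_pair_corr(mz)
    r_dz = _empirical_pair_corr(dz)
    falc = falconer_estimate(r_mz, r_dz)
    starts = [
        np.array([falc[0], falc[1], max(falc[2], 0.05), 0.0]),
        np.array([1 / 3, 1 / 3, 1 / 3, 0.0]),
    ]
    bounds = [(0.0, 10.0), (0.0, 10.0), (E_FLOOR, 10.0), (-10.0, 10.0)]
    best = None
    for x0 in starts:
        try:
            res = optimize.minimize(
                _pair_nll, x0, args=(mz, dz), method="L-BFGS-B", bounds=bounds,
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        return AceEstimate(cpg, np.nan, np.nan, np.nan, np.nan, False)
    a2, c2, e2, _ = best.x
    total = a2 + c2 + e2
    return AceEstimate(
        cpg=cpg,
        A=float(a2 / total),
        C=float(c2 / total),
        E=float(e2 / total),
        loglik=float(-best.fun),
        converged=bool(best.success or np.isfinite(best.fun)),
    )


def extract_twin_pairs(values: pd.Series | np.ndarray, pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Arrange a per-sample vector into (n_MZ, 2) and (n_DZ, 2) pair arrays."""
    s = pd.Series(values) if not isinstance(values, pd.Series) else values
    mz = np.array([[s[a], s[b]] for a, b in pedigree.pairs("MZ")], dtype=float)
    dz = np.array([[s[a], s[b]] for a, b in pedigree.pairs("DZ")], dtype=float)
    return mz.reshape(-1, 2), dz.reshape(-1, 2)


def fit_ace_matrix(meth, pedigree) -> pd.DataFrame:
    """Fit the ACE model for every CpG of a residual-stage matrix."""
    rows = []
    for cpg in meth.cpg_ids:
        mz, dz = extract_twin_pairs(meth.values[cpg], pedigree)
        est = fit_ace(mz, dz, cpg=cpg)
        rows.append(vars(est))
    return pd.DataFrame(rows).set_index("cpg")


def summarize_heritability(
    estimates: pd.DataFrame,
    annotations: pd.Series | None = None,
    variability: pd.Series | None = None,
    sd_threshold: float = 0.025,
    zero_inflation_cut: float = 0.01,
) -> tuple[pd.DataFrame, list]:
    """Stratified summary of heritability estimates.

    Strata are annotation categories (optional) crossed with a
    variability split at ``sd_threshold`` on the per-CpG raw beta-value
    sd (optional). Reports mean, sd, median, IQR and the 95% CI of the
    mean of A, plus the zero-inflation rate (share of converged CpGs with
    A < ``zero_inflation_cut``). CpGs with annotation categories unknown
    to the estimate table are returned, not silently dropped.
    """
    conv = estimates[estimates["converged"].astype(bool)].dropna(subset=["A"])
    if conv.empty:
        raise ValueError("no converged estimates to summarise")
    unknown: list = []
    strata: dict[str, pd.Index] = {"all": conv.index}
    if annotations is not None:
        unknown = sorted(set(annotations.index) - set(estimates.index))
        ann = annotations.loc[annotations.index.intersection(conv.index)]
        for cat, ids in ann.groupby(ann).groups.items():
            strata[f"annotation:{cat}"] = pd.Index(ids)
    if variability is not None:
        var = variability.loc[variability.index.intersection(conv.index)]
        strata[f"variability:sd>{sd_threshold}"] = var.index[var > sd_threshold]
        strata[f"variability:sd<={sd_threshold}"] = var.index[var <= sd_threshold]
    rows = []
    for name, ids in strata.items():
        a = conv.loc[conv.index.intersection(ids), "A"].to_numpy(dtype=float)
        if a.size == 0:
            continue
        mean = a.mean()
        sd = a.std(ddof=1) if a.size > 1 else 0.0
        half = 1.96 * sd / np.sqrt(a.size)
        q1, q3 = np.percentile(a, [25, 75])
        rows.append({
            "stratum": name, "n": int(a.size),
            "mean_A": mean, "sd_A": sd,
            "median_A": float(np.median(a)), "iqr_A": float(q3 - q1),
            "ci_low": mean - half, "ci_high": mean + half,
            "zero_inflation": float((a < zero_inflation_cut).mean()),
        })
    return pd.DataFrame(rows).set_index("stratum"), unknown


def compare_strata(estimates: pd.DataFrame, group_a, group_b) -> dict:
    """One-tailed Welch t-test that mean A in group_a exceeds group_b."""
    a = estimates.loc[estimates.index.intersection(group_a), "A"].dropna()
    b = estimates.loc[estimates.index.intersection(group_b), "A"].dropna()
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return {"t": float(t), "p": float(p), "n_a": len(a), "n_b": len(b)}
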