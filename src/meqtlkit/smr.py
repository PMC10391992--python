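"""Summary-based Mendelian randomisation (SMR) with the HEIDI test.

SMR uses the exposure's most significant SNP as instrument: with
exposure effect b_zx (se_zx) and outcome effect b_zy (se_zy) at that SNP,
the ratio (2SLS) estimate is b_xy = b_zy / b_zx with

    var(b_xy) = se_zy^2 / b_zx^2 + b_zy^2 se_zx^2 / b_zx^4

and T_SMR = b_xy^2 / var(b_xy) ~ chi^2_1 (two-sided p).

HEIDI asks whether the ratio estimate is homogeneous across SNPs in LD
with the instrument. For up to twenty alternative SNPs (default
eligibility: exposure p below a relaxed threshold and 0.05 < r^2 < 0.9
with the top SNP), the deviations d_i = b_xy(i) - b_xy(top) are
standardised using a first-order delta-method covariance with
cov(b_i, b_j) ~ r_ij se_i se_j within each trait; the statistic
T = sum z_i^2 is referred to a moment-matched (Satterthwaite) scaled
chi-square using the eigenvalues of the correlation matrix of the d
vector. A small HEIDI p flags heterogeneity, i.e. linkage of distinct
causal variants rather than one shared causal variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from meqtlkit.meta import bonferroni_threshold

logger = logging.getLogger(__name__)

AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

HEIDI_R2_LOW = 0.05
HEIDI_R2_HIGH = 0.9
HEIDI_MAX_SNPS = 20
HEIDI_MIN_SNPS = 3
HEIDI_P_ELIGIBLE = 1.57e-3  # ~ chi^2_1 > 10, the conventional relaxed cut

SUMMARY_COLUMNS = ["id", "chrom", "pos", "A1", "A2", "freq", "b", "se", "p", "n"]


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    freq_diff_max: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Align outcome effect alleles to the exposure's A1/A2 coding.

    Rows are merged on SNP id; swapped alleles flip the outcome beta and
    frequency, strand-ambiguous (A/T, C/G) SNPs are dropped, as are
    allele-incompatible SNPs and those whose A1 frequencies differ by
    more than ``freq_diff_max`` after alignment. Returns the merged table
    (exposure columns suffixed ``_zx``, outcome ``_zy``) and exclusion
    counts.
    """
    merged = exposure.merge(outcome, on="id", suffixes=("_zx", "_zy"))
    if merged.empty:
        raise ValueError("no shared SNPs between exposure and outcome")
    counts = {"ambiguous": 0, "mismatch": 0, "freq": 0}
    a1x = merged["A1_zx"].str.upper()
    a2x = merged["A2_zx"].str.upper()
    a1y = merged["A1_zy"].str.upper()
    a2y = merged["A2_zy"].str.upper()

    ambiguous = [
        (x1, x2) in AMBIGUOUS for x1, x2 in zip(a1x, a2x)
    ]
    ambiguous = np.asarray(ambiguous)
    counts["ambiguous"] = int(ambiguous.sum())
    same = (a1x == a1y) & (a2x == a2y)
    swapped = (a1x == a2y) & (a2x == a1y)
    mismatch = ~(same | swapped)
    counts["mismatch"] = int((mismatch & ~ambiguous).sum())
    keep = ~ambiguous & ~mismatch
    merged = merged[keep].copy()
    flip = swapped[keep].to_numpy()
    merged.loc[flip, "b_zy"] = -merged.loc[flip, "b_zy"]
    merged.loc[flip, "freq_zy"] = 1.0 - merged.loc[flip, "freq_zy"]
    bad_freq = (merged["freq_zx"] - merged["freq_zy"]).abs() > freq_diff_max
    counts["freq"] = int(bad_freq.sum())
    merged = merged[~bad_freq].reset_index(drop=True)
    return merged, counts


def smr_test(b_zx: float, se_zx: float, b_zy: float, se_zy: float) -> dict:
    """Ratio (2SLS) estimate and chi-square p for one instrument SNP."""
    if b_zx == 0:
        raise ValueError("instrument has zero exposure effect")
    if b_zy == 0 and se_zy == 0:
        raise ValueError("degenerate outcome statistics")
    b_xy = b_zy / b_zx
    var = se_zy**2 / b_zx**2 + (b_zy**2 * se_zx**2) / b_zx**4
    T = b_xy**2 / var if var > 0 else np.inf
    p = float(np.clip(stats.chi2.sf(T, df=1), 1e-300, 1.0))
    return {"b_xy": float(b_xy), "se_xy": float(np.sqrt(var)), "T": float(T), "p": p}


def select_heidi_snps(
    region: pd.DataFrame,
    top_snp: str,
    ld_r: pd.DataFrame,
    r2_low: float = HEIDI_R2_LOW,
    r2_high: float = HEIDI_R2_HIGH,
    p_eligible: float = HEIDI_P_ELIGIBLE,
    max_snps: int = HEIDI_MAX_SNPS,
) -> list[str]:
    """Alternative instruments for HEIDI, ranked by exposure significance.

    ``region`` is an exposure summary table (columns ``id``, ``p``);
    ``ld_r`` a signed-correlation DataFrame covering the region. SNPs
    with exposure p < ``p_eligible`` and ``r2_low < r^2(snp, top) <
    r2_high`` qualify; the list is truncated at ``max_snps``.
    """
    r2_top = ld_r.loc[region["id"], top_snp].to_numpy(dtype=float) ** 2
    eligible = (
        (region["id"] != top_snp).to_numpy()
        & (region["p"].to_numpy(dtype=float) < p_eligible)
        & (r2_top > r2_low)
        & (r2_top < r2_high)
    )
    sub = region[eligible].sort_values("p", kind="stable")
    return sub["id"].head(max_snps).tolist()


def _nearest_pd(M: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(M)
    if w.min() > 0:
        return M
    shift = abs(w.min()) + 1e-10
    logger.warning("HEIDI covariance not positive definite; shifting eigenvalues by %.3e", shift)
    return M + shift * np.eye(M.shape[0])


def heidi_test(
    top_snp: str,
    alt_snps: list[str],
    merged: pd.DataFrame,
    ld_r: pd.DataFrame,
) -> tuple[float, int]:
    """Heterogeneity-in-dependent-instruments p-value.

    ``merged`` is a harmonised table (columns ``id, b_zx, se_zx, b_zy,
    se_zy``) containing the top SNP and the alternatives; ``ld_r`` is the
    signed LD correlation. Returns (p_HEIDI, n_snps_used).
    """
    if len(alt_snps) < HEIDI_MIN_SNPS:
        return np.nan, len(alt_snps)
    snps = [top_snp] + list(alt_snps)
    sub = merged.set_index("id").loc[snps]
    bzx = sub["b_zx"].to_numpy(float)
    sezx = sub["se_zx"].to_numpy(float)
    bzy = sub["b_zy"].to_numpy(float)
    sezy = sub["se_zy"].to_numpy(float)
    R = ld_r.loc[snps, snps].to_numpy(float)
    bxy = bzy / bzx
    # Delta-method covariance of the ratio estimates:
    # cov(bxy_i, bxy_j) = r_ij se_zy_i se_zy_j / (bzx_i bzx_j)
    #                   + bzy_i bzy_j r_ij se_zx_i se_zx_j / (bzx_i^2 bzx_j^2)
    term_y = R * np.outer(sezy, sezy) / np.outer(bzx, bzx)
    term_x = (
        R * np.outer(sezx, sezx)
        * np.outer(bzy, bzy) / np.outer(bzx**2, bzx**2)
    )
    V = term_y + term_x
    m = len(alt_snps)
    # cov(d_i, d_j) with d_i = bxy_i - bxy_top (top is index 0)
    Vd = V[1:, 1:] - V[1:, [0]] - V[[0], 1:] + V[0, 0]
    Vd = _nearest_pd(0.5 * (Vd + Vd.T))
    d = bxy[1:] - bxy[0]
    sd = np.sqrt(np.diag(Vd))
    z = d / sd
    T = float((z**2).sum())
    corr = Vd / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(corr)
    lam = lam[lam > 1e-12]
    s1, s2 = lam.sum(), (lam**2).sum()
    scale = s2 / s1
    dof = s1**2 / s2
    p = float(np.clip(stats.chi2.sf(T / scale, dof), 1e-300, 1.0))
    return p, m


@dataclass
class ColocDesign:
    """Pairing rules and Bonferroni denominator for one SMR design."""

    name: str
    min_distance: int = 0  # targeted trans: only pairs farther than this
    n_classes: int = 1  # GWAS design: phenotype classes in the denominator


DESIGNS = {
    "cis_eqtl": ColocDesign("cis_eqtl"),
    "trans_eqtl": ColocDesign("trans_eqtl"),
    "targeted_trans": ColocDesign("targeted_trans", min_distance=5_000_000),
    "gwas": ColocDesign("gwas", n_classes=7),
}


def run_coloc(
    design: str,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    pairs: pd.DataFrame,
    ld_r: pd.DataFrame,
    alpha: float = 0.05,
    heidi_p_min: float = 0.05,
    n_classes: int | None = None,
) -> pd.DataFrame:
    """SMR + HEIDI over exposure-outcome pairs under one study design.

    ``exposure`` holds per-(exposure_id, SNP) summary stats (columns
    ``exposure_id`` + the summary dialect), ``outcome`` the same with
    ``outcome_id`` (plus ``class`` for the gwas design); ``pairs`` lists
    the exposure_id/outcome_id combinations to test. The instrument is
    the exposure's most significant harmonised SNP (ties by |b|/se, then
    position). Significance requires p_SMR at or below the design's
    Bonferroni threshold AND p_HEIDI > ``heidi_p_min``. The
    targeted_trans design drops instrument SNPs within 5 Mbp of the
    exposure CpG (requires ``cpg_pos``/``cpg_chrom`` columns in pairs).
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    rules = DESIGNS[design]
    rows = []
    for rec in pairs.itertuples(index=False):
        exp = exposure[exposure["exposure_id"] == rec.exposure_id]
        out = outcome[outcome["outcome_id"] == rec.outcome_id]
        if exp.empty or out.empty:
            continue
        merged, _ = harmonize(exp.drop(columns="exposure_id"),
                              out.drop(columns=[c for c in ("outcome_id", "class")
                                                if c in out.columns]))
        if rules.min_distance:
            same = merged["chrom_zx"] == getattr(rec, "cpg_chrom")
            dist = (merged["pos_zx"] - getattr(rec, "cpg_pos")).abs()
            merged = merged[~(same & (dist <= rules.min_distance))]
        if merged.empty:
            continue
        merged = merged.assign(score=merged["b_zx"].abs() / merged["se_zx"])
        top = merged.sort_values(
            ["p_zx", "score", "pos_zx"], ascending=[True, False, True], kind="stable"
        ).iloc[0]
        res = smr_test(top["b_zx"], top["se_zx"], top["b_zy"], top["se_zy"])
        region = merged.rename(columns={"p_zx": "p"})[["id", "p"]]
        alts = select_heidi_snps(region, top["id"], ld_r)
        p_heidi, n_heidi = heidi_test(top["id"], alts, merged, ld_r)
        rows.append({
            "exposure_id": rec.exposure_id,
            "outcome_id": rec.outcome_id,
            "instrument": top["id"],
            "b_SMR": res["b_xy"], "se_SMR": res["se_xy"], "p_SMR": res["p"],
            "p_HEIDI": p_heidi, "nsnp_HEIDI": n_heidi,
        })
    results = pd.DataFrame(rows)
    if results.empty:
        return results
    k = n_classes if n_classes is not None else rules.n_classes
    if design == "gwas":
        n_tests = pairs["exposure_id"].nunique() * k
    else:
        n_tests = len(results)
    cutoff = bonferroni_threshold(alpha, n_tests)
    results["significant"] = (
        (results["p_SMR"] <= cutoff)
        & (results["p_HEIDI"].fillna(1.0) > heidi_p_min)
    )
    results.attrs["bonferroni_cutoff"] = cutoff
    return results
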