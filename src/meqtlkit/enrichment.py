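"""Annotation mapping, two-tailed Fisher enrichment, matched resampling, TADs.

Interval conventions: annotation tracks use the BED 0-based half-open
convention; genomic points (SNPs, CpGs) are 1-based, so point ``p`` lies
inside interval ``[start, end)`` iff ``start <= p - 1 < end``.

The two-tailed Fisher exact p sums, over all 2x2 tables with the observed
margins, the hypergeometric probabilities not exceeding that of the
observed table (point-probability convention). Odds ratios use the
Haldane-Anscombe +0.5 correction on all cells when any cell is zero; the
exact-mode confidence interval is the Woolf logit interval, while the
resampled mode reports the 2.5%/97.5% percentiles of the resampling OR
distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MHC_REGION = ("chr6", 28_477_797, 33_448_354)  # GRCh37, 1-based inclusive

DEFAULT_MAF_BIN_WIDTH = 0.05
DEFAULT_DISTANCE_BINS = (0.0, 1e3, 1e4, 1e5, 1e6, np.inf)


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (BED 0-based half-open)."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.intervals = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def merged(self, merge_touching: bool = True) -> dict[str, np.ndarray]:
        """Per-chromosome merged interval arrays (n x 2), overlap-free.

        With ``merge_touching=False`` intervals that abut (end == next
        start) stay distinct — required for TADs, where adjacency matters.
        """
        out = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            iv = grp[["start", "end"]].to_numpy(dtype=np.int64)
            merged = [list(iv[0])]
            for s, e in iv[1:]:
                joins = s <= merged[-1][1] if merge_touching else s < merged[-1][1]
                if joins:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return out


def map_to_annotations(points: pd.DataFrame, track: AnnotationTrack) -> np.ndarray:
    """Membership flags for 1-based points against a BED track.

    ``points`` needs ``chrom`` and ``pos`` columns. Points on chromosomes
    absent from the track are non-members (counted in a log summary).
    """
    merged = track.merged()
    flags = np.zeros(len(points), dtype=bool)
    unknown = 0
    chroms = points["chrom"].to_numpy()
    pos0 = points["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        if chrom not in merged:
            unknown += int(sel.sum())
            continue
        iv = merged[chrom]
        idx = np.searchsorted(iv[:, 0], pos0[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(int(sel.sum()), dtype=bool)
        inside[ok] = pos0[sel][ok] < iv[idx[ok], 1]
        flags[sel] = inside
    if unknown:
        logger.info("%d point(s) on chromosomes absent from track %r", unknown, track.name)
    return flags


def _hypergeom_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Exact two-tailed p by point-probability enumeration (vectorised).

    Uses log-gamma hypergeometric probabilities directly (cheap for the
    exhaustive small-table checks this test backs).
    """
    from scipy.special import gammaln

    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log C(r1, k) + log C(n - r1, c1 - k) - log C(n, c1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - support + 1)
        - gammaln(n - r1 - c1 + support + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, float, float, float]:
    """OR with Haldane-Anscombe correction and Woolf CI; returns (OR, lo, hi, corr)."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    orx = (a_ * d_) / (b_ * c_)
    se_log = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    lo = float(np.exp(np.log(orx) - 1.96 * se_log))
    hi = float(np.exp(np.log(orx) + 1.96 * se_log))
    return float(orx), lo, hi, float(cells[0] - a)


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> dict:
    """Two-tailed Fisher exact test with OR and Woolf CI.

    Returns a dict with keys ``or``, ``ci_low``, ``ci_high``, ``p`` and
    the (uncorrected) cell counts.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0:
        raise ValueError("each row of the 2x2 table must be non-empty")
    orx, lo, hi, _ = odds_ratio(a, b, c, d)
    p = _hypergeom_two_tailed(int(a), int(b), int(c), int(d))
    return {"or": orx, "ci_low": lo, "ci_high": hi, "p": p,
            "a": a, "b": b, "c": c, "d": d}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserved."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrichment_table(
    interest_flags: np.ndarray,
    background_flags: np.ndarray,
) -> tuple[int, int, int, int]:
    """2x2 counts: (interest-in, interest-out, background-in, background-out)."""
    a = int(np.sum(interest_flags))
    b = int(len(interest_flags) - a)
    c = int(np.sum(background_flags))
    d = int(len(background_flags) - c)
    return a, b, c, d


def assign_matching_bins(
    maf: np.ndarray,
    distance: np.ndarray,
    maf_bin_width: float = DEFAULT_MAF_BIN_WIDTH,
    distance_bins=DEFAULT_DISTANCE_BINS,
) -> np.ndarray:
    """Joint (MAF x distance-to-nearest-CpG) category codes for matching."""
    maf_edges = np.arange(0.0, 0.5 + maf_bin_width, maf_bin_width)
    maf_idx = np.clip(np.digitize(maf, maf_edges, right=True) - 1, 0, len(maf_edges) - 2)
    dist_idx = np.clip(np.digitize(distance, distance_bins, right=False) - 1,
                       0, len(distance_bins) - 2)
    return maf_idx * (len(distance_bins) - 1) + dist_idx


def matched_background_resample(
    interest: pd.DataFrame,
    universe: pd.DataFrame,
    membership: pd.Series,
    B: int = 1000,
    maf_bin_width: float = DEFAULT_MAF_BIN_WIDTH,
    distance_bins=DEFAULT_DISTANCE_BINS,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Enrichment against MAF/distance-matched resampled backgrounds.

    ``interest`` and ``universe`` are SNP tables with ``maf`` and
    ``distance`` (to the nearest CpG) columns, indexed by SNP id;
    ``membership`` is a boolean Series over the universe marking
    annotation membership. Each of B iterations draws a background of the
    interest set's size matching its (MAF x distance) category
    composition — without replacement within a category, with replacement
    across categories — and records the interest-vs-background OR. The
    point estimate is the mean OR; the CI is the 2.5%/97.5% percentiles.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cats_interest = assign_matching_bins(
        interest["maf"].to_numpy(float), interest["distance"].to_numpy(float),
        maf_bin_width, distance_bins)
    cats_universe = assign_matching_bins(
        universe["maf"].to_numpy(float), universe["distance"].to_numpy(float),
        maf_bin_width, distance_bins)
    member_universe = membership.loc[universe.index].to_numpy(bool)
    member_interest = membership.loc[interest.index].to_numpy(bool)

    want = {}
    for cat, cnt in zip(*np.unique(cats_interest, return_counts=True)):
        pool = np.nonzero(cats_universe == cat)[0]
        if len(pool) < cnt:
            raise ValueError(
                f"universe category {cat} holds {len(pool)} SNPs, need {cnt}"
            )
        want[int(cat)] = (pool, int(cnt))

    a = int(member_interest.sum())
    b = len(member_interest) - a
    ors = np.empty(B)
    for it in range(B):
        hits = 0
        total = 0
        for pool, cnt in want.values():
            draw = rng.choice(pool, size=cnt, replace=False)
            hits += int(member_universe[draw].sum())
            total += cnt
        c, d = hits, total - hits
        cells = np.array([a, b, c, d], dtype=float)
        if (cells == 0).any():
            cells += 0.5
        ors[it] = (cells[0] * cells[3]) / (cells[1] * cells[2])
    lo, hi = np.percentile(ors, [2.5, 97.5])
    return {
        "or": float(ors.mean()), "ci_low": float(lo), "ci_high": float(hi),
        "ors": ors, "B": B, "method": "resampled",
        "a": a, "b": b,
    }


def tad_overlap(pairs: pd.DataFrame, tads: AnnotationTrack) -> dict:
    """Share of SNP-CpG pairs falling inside one common TAD.

    ``pairs`` needs columns ``chrom_cpg, pos_cpg, chrom_snp, pos_snp``
    and optionally ``type`` (cis/trans) for the per-type breakdown.
    Cross-chromosome pairs count as not-same-TAD (tallied). Sizes of the
    TADs containing same-TAD pairs are collected per type and compared
    with a Welch two-sided t-test when both types are present.
    """
    iv_df = tads.intervals
    overlapping = (
        iv_df.groupby("chrom")["start"].apply(
            lambda s: (s.to_numpy()[1:] < iv_df.loc[s.index, "end"].to_numpy()[:-1]).any()
        ).any()
        if len(iv_df) > 1 else False
    )
    if overlapping:
        warnings.warn("TAD track has overlapping intervals; merging", stacklevel=2)
    merged = tads.merged(merge_touching=False)
    n = len(pairs)
    same = np.zeros(n, dtype=bool)
    sizes = np.full(n, np.nan)
    cross = 0
    chrom_c = pairs["chrom_cpg"].to_numpy()
    chrom_s = pairs["chrom_snp"].to_numpy()
    pos_c = pairs["pos_cpg"].to_numpy(np.int64) - 1
    pos_s = pairs["pos_snp"].to_numpy(np.int64) - 1
    for i in range(n):
        if chrom_c[i] != chrom_s[i]:
            cross += 1
            continue
        iv = merged.get(chrom_c[i])
        if iv is None:
            continue
        ic = np.searchsorted(iv[:, 0], pos_c[i], side="right") - 1
        isnp = np.searchsorted(iv[:, 0], pos_s[i], side="right") - 1
        if ic >= 0 and ic == isnp and pos_c[i] < iv[ic, 1] and pos_s[i] < iv[ic, 1]:
            same[i] = True
            sizes[i] = iv[ic, 1] - iv[ic, 0]
    out = {"share_same_tad": float(same.mean()) if n else np.nan,
           "n_pairs": n, "n_cross_chromosome": cross, "same_tad": same,
           "tad_sizes": sizes}
    if "type" in pairs.columns:
        per_type = {}
        for t, grp_idx in pairs.groupby("type").groups.items():
            loc = pairs.index.get_indexer(grp_idx)
            per_type[t] = {
                "share_same_tad": float(same[loc].mean()),
                "n": len(loc),
                "tad_sizes": sizes[loc][~np.isnan(sizes[loc])],
            }
        out["per_type"] = per_type
        if {"cis", "trans"} <= set(per_type):
            s_cis = per_type["cis"]["tad_sizes"]
            s_trans = per_type["trans"]["tad_sizes"]
            if len(s_cis) > 1 and len(s_trans) > 1:
                t, p = stats.ttest_ind(s_trans, s_cis, equal_var=False)
                out["size_ttest"] = {"t": float(t), "p": float(p)}
    return out
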