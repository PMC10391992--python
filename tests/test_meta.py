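"""Meta-analysis, permutation FDR, consistency filter and integration stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meqtlkit.datatypes import MethylationMatrix, Pedigree
from meqtlkit.meta import (
    bonferroni_threshold,
    consistency_filter,
    dl_meta,
    heritability_meqtl_regression,
    meta_analyse,
    permutation_fdr,
    permute_cohort,
    variance_explained,
)


def dl_oracle(betas, ses):
    """Independent step-by-step DerSimonian-Laird implementation."""
    k = len(betas)
    w = [1.0 / s**2 for s in ses]
    bf = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
    Q = sum(wi * (bi - bf) ** 2 for wi, bi in zip(w, betas))
    if k > 1:
        tau2 = max(0.0, (Q - (k - 1)) / (sum(w) - sum(wi**2 for wi in w) / sum(w)))
    else:
        tau2 = 0.0
    ws = [1.0 / (s**2 + tau2) for s in ses]
    beta = sum(wi * bi for wi, bi in zip(ws, betas)) / sum(ws)
    se = sum(ws) ** -0.5
    return beta, se, tau2


class TestDlMeta:
    def test_homogeneous_studies_reduce_to_fixed_effect(self):
        res = dl_meta([1.0, 1.0], [0.5, 0.5])
        assert res["tau2"] == 0.0
        assert res["beta"] == pytest.approx(1.0)
        assert res["se"] == pytest.approx(0.5 / np.sqrt(2))

    def test_single_study_is_identity(self):
        res = dl_meta([0.7], [0.2])
        assert res["beta"] == pytest.approx(0.7)
        assert res["se"] == pytest.approx(0.2)
        assert res["k"] == 1

    def test_heterogeneous_hand_example(self):
        # b=(0,2), se=(1,1): Q=2, tau2=1, pooled b=1, pooled se=1
        res = dl_meta([0.0, 2.0], [1.0, 1.0])
        assert res["Q"] == pytest.approx(2.0)
        assert res["tau2"] == pytest.approx(1.0)
        assert res["beta"] == pytest.approx(1.0)
        assert res["se"] == pytest.approx(1.0)

    def test_matches_oracle_on_random_configs(self, rng):
        for _ in range(1000):
            k = rng.integers(1, 6)
            b = rng.normal(0, 1, k)
            s = rng.uniform(0.05, 2.0, k)
            res = dl_meta(b, s)
            ob, os_, ot = dl_oracle(list(b), list(s))
            assert abs(res["beta"] - ob) < 1e-10
            assert abs(res["se"] - os_) < 1e-10
            assert abs(res["tau2"] - ot) < 1e-10

    def test_rejects_bad_se(self):
        with pytest.raises(ValueError):
            dl_meta([1.0], [0.0])
        with pytest.raises(ValueError):
            dl_meta([], [])


class TestMetaAnalyse:
    def test_vectorised_agrees_with_scalar(self, rng):
        rows = []
        for pair in range(50):
            k = rng.integers(1, 6)
            for c in range(k):
                rows.append({"snp": f"s{pair}", "cpg": f"cg{pair}",
                             "cohort": f"c{c}", "type": "cis",
                             "beta": rng.normal(), "se": rng.uniform(0.1, 1.0),
                             "p": 0.5, "n": 100})
        records = pd.DataFrame(rows)
        pooled = meta_analyse(records)
        for row in pooled.itertuples(index=False):
            sub = records[(records["snp"] == row.snp) & (records["cpg"] == row.cpg)]
            ref = dl_meta(sub["beta"].to_numpy(), sub["se"].to_numpy())
            assert row.beta == pytest.approx(ref["beta"], abs=1e-10)
            assert row.se == pytest.approx(ref["se"], abs=1e-10)
            assert row.tau2 == pytest.approx(ref["tau2"], abs=1e-10)
            assert row.k == ref["k"]

    def test_direction_string_is_cohort_sorted_signs(self):
        records = pd.DataFrame({
            "snp": ["s0"] * 3, "cpg": ["cg0"] * 3,
            "cohort": ["c2", "c0", "c1"], "type": ["cis"] * 3,
            "beta": [-0.5, 0.4, 0.6], "se": [0.1] * 3, "p": [0.1] * 3, "n": 50,
        })
        pooled = meta_analyse(records)
        assert pooled["directions"].iloc[0] == "++-"


class TestConsistencyFilter:
    def _meta_row(self, k, directions):
        return {"snp": "s0", "cpg": "cg0", "type": "cis", "beta": 0.1,
                "se": 0.1, "p": 0.01, "tau2": 0.0, "k": k, "directions": directions}

    def test_single_cohort_dropped(self):
        out = consistency_filter(pd.DataFrame([self._meta_row(1, "+")]))
        assert out.empty

    def test_sign_conflict_dropped(self):
        out = consistency_filter(pd.DataFrame([self._meta_row(3, "++-")]))
        assert out.empty

    def test_two_cohorts_same_sign_kept(self):
        out = consistency_filter(pd.DataFrame([self._meta_row(2, "--")]))
        assert len(out) == 1

    def test_never_grows_and_idempotent(self, rng):
        rows = [dict(self._meta_row(int(k), d), snp=f"s{i}")
                for i, (k, d) in enumerate(zip(
                    rng.integers(1, 5, 30),
                    ["+", "++", "+-", "--", "-+-", "+++"] * 5))]
        df = pd.DataFrame(rows)
        once = consistency_filter(df)
        twice = consistency_filter(once)
        assert len(once) <= len(df)
        pd.testing.assert_frame_equal(once, twice)


def _meth_for_permute(values, sample_ids):
    cpgs = [f"cg{j}" for j in range(values.shape[1])]
    info = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, len(cpgs) + 1)},
                        index=cpgs)
    return MethylationMatrix(
        pd.DataFrame(values, index=sample_ids, columns=cpgs), info, stage="residual")


class TestPermuteCohort:
    def test_singletons_preserve_value_multiset(self, rng):
        ids = [f"i{k}" for k in range(10)]
        ped = Pedigree(pd.DataFrame(
            {"family_id": [f"f{k}" for k in range(10)], "zygosity": "singleton"},
            index=ids))
        meth = _meth_for_permute(rng.normal(size=(10, 3)), ids)
        out = permute_cohort(meth, ped, np.random.default_rng(0))
        for j in range(3):
            np.testing.assert_allclose(
                np.sort(out.values.iloc[:, j]), np.sort(meth.values.iloc[:, j]))

    def test_twins_never_separated(self, rng):
        ids = ["a1", "a2", "b1", "b2"]
        ped = Pedigree(pd.DataFrame(
            {"family_id": ["fa", "fa", "fb", "fb"], "zygosity": "MZ"}, index=ids))
        vals = np.arange(8.0).reshape(4, 2)
        meth = _meth_for_permute(vals, ids)
        for s in range(10):
            out = permute_cohort(meth, ped, np.random.default_rng(s)).values.to_numpy()
            # either identity or whole-pair swap
            assert (np.allclose(out, vals)
                    or np.allclose(out, vals[[2, 3, 0, 1]]))

    def test_null_pvalues_uniform(self, rng):
        # permuted scans of null data give uniform p-values
        from meqtlkit.datatypes import GenotypeMatrix
        from meqtlkit.scan import scan_cohort

        n = 100
        ids = [f"i{k}" for k in range(n)]
        ped = Pedigree(pd.DataFrame(
            {"family_id": [f"f{k}" for k in range(n)], "zygosity": "singleton"},
            index=ids))
        g = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
        snps = [f"s{j}" for j in range(20)]
        geno = GenotypeMatrix(
            pd.DataFrame(g, index=ids, columns=snps),
            pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 21) * 100,
                          "ref": "A", "alt": "G", "maf": 0.3}, index=snps))
        meth = _meth_for_permute(rng.normal(size=(n, 20)), ids)
        pvals = []
        gen = np.random.default_rng(5)
        for _ in range(20):
            perm = permute_cohort(meth, ped, gen)
            rec = scan_cohort(geno, perm, "c0", p_cis=1.0, p_trans=1.0)
            pvals.append(rec["p"].to_numpy())
        ks = stats.kstest(np.concatenate(pvals), "uniform")
        assert ks.pvalue > 0.01


class TestPermutationFdr:
    def test_hand_evaluated_ratio(self):
        observed = [1e-6, 0.002, 0.004, 0.2]
        nulls = [[0.001, 0.3, 0.6, 0.9], [0.05, 0.4, 0.7, 0.95]]
        curve = permutation_fdr(observed, nulls, target=0.05)
        fdr_at = dict(zip(curve.thresholds, curve.fdr))
        assert fdr_at[1e-6] == 0.0
        assert fdr_at[0.002] == pytest.approx(0.25)  # (0.5 avg null) / 2 observed
        assert curve.selected_threshold == 1e-6
        assert curve.n_significant == 1

    def test_null_never_below_observed_all_pass(self):
        curve = permutation_fdr([0.01, 0.02], [[0.5, 0.9]], target=0.05)
        assert np.all(curve.fdr == 0.0)
        assert curve.selected_threshold == 0.02
        assert curve.n_significant == 2

    def test_duplicating_null_sets_changes_nothing(self, rng):
        obs = rng.random(50)
        nulls = [rng.random(50) for _ in range(3)]
        a = permutation_fdr(obs, nulls)
        b = permutation_fdr(obs, nulls + nulls)
        np.testing.assert_allclose(a.fdr, b.fdr)
        assert a.selected_threshold == b.selected_threshold

    def test_no_observed_discoveries_flagged(self):
        curve = permutation_fdr([], [[0.1]], target=0.05)
        assert not curve.defined


class TestBonferroni:
    def test_known_cutoffs(self):
        assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestVarianceExplained:
    def test_plug_in_value(self):
        assert variance_explained(0.4, 0.5) == pytest.approx(0.08)

    def test_zero_beta(self):
        assert variance_explained(0.0, 0.25) == 0.0

    def test_agrees_with_empirical_r2(self, rng):
        # unit-variance trait y = beta*g + e with matching residual variance:
        # the squared correlation of (g, y) estimates the same quantity
        n, maf, beta = 200_000, 0.3, 0.4
        expected = variance_explained(beta, maf)
        g = rng.binomial(2, maf, n).astype(float)
        e = rng.normal(0, np.sqrt(1 - expected), n)
        y = beta * g + e
        emp = np.corrcoef(g, y)[0, 1] ** 2
        assert expected == pytest.approx(emp, abs=0.01)

    def test_maf_validation(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.6)


class TestHeritabilityMeqtlRegression:
    def _status(self, n, rng):
        return pd.DataFrame({
            "has_cis": rng.random(n) < 0.4,
            "has_trans": rng.random(n) < 0.1,
        }, index=[f"cg{i}" for i in range(n)])

    def test_constant_outcome_gives_zero_r2(self, rng):
        status = self._status(100, rng)
        ace = pd.DataFrame({"A": 0.3}, index=status.index)
        res = heritability_meqtl_regression(ace, status)
        assert res["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_function_gives_r2_one(self, rng):
        status = self._status(200, rng)
        a = 0.1 + 0.2 * status["has_cis"] + 0.3 * status["has_trans"]
        res = heritability_meqtl_regression(pd.DataFrame({"A": a}), status)
        assert res["r2"] == pytest.approx(1.0)

    def test_recovers_planted_group_means(self, rng):
        # group means in the spirit of a zero-inflated heritability landscape
        n = 100_000
        means = {"none": 0.085, "cis_only": 0.238, "trans_only": 0.295, "both": 0.435}
        status = self._status(n, rng)
        key = np.select(
            [~status["has_cis"] & ~status["has_trans"],
             status["has_cis"] & ~status["has_trans"],
             ~status["has_cis"] & status["has_trans"]],
            ["none", "cis_only", "trans_only"], default="both")
        a = np.array([means[k] for k in key]) + rng.normal(0, 0.15, n)
        res = heritability_meqtl_regression(pd.DataFrame({"A": a}, index=status.index),
                                            status)
        for k, v in means.items():
            assert res["group_means"][k] == pytest.approx(v, abs=0.02)
        assert res["p"] < 1e-10

    def test_single_group_errors(self):
        status = pd.DataFrame({"has_cis": [True] * 5, "has_trans": [False] * 5},
                              index=[f"cg{i}" for i in range(5)])
        ace = pd.DataFrame({"A": np.linspace(0, 1, 5)}, index=status.index)
        with pytest.raises(ValueError, match="group"):
            heritability_meqtl_regression(ace, status)
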