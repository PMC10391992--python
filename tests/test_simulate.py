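"""Synthetic-data generator: LD structure, twin sharing, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from meqtlkit.scan import classify_cis_trans
from meqtlkit.simulate import (
    RegionConfig,
    SimConfig,
    cpg_position_map,
    plant_effects,
    simulate_genotypes,
    simulate_methylation,
    simulate_summary_stats,
)


def _singleton_config(**kw):
    base = dict(
        n_cohorts=1, samples_per_cohort=[kw.pop("n", 400)],
        n_snps=40, n_cpgs=30, ld_block_size=10, ld_rho=0.0,
        n_cis_effects=0, n_trans_effects=0,
        n_mz_pairs=0, n_dz_pairs=0, seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


def mc_adjacent_dosage_corr(rho, maf_a, maf_b, n=200_000, seed=99):
    """Brute-force Monte-Carlo oracle for the AR(1) threshold scheme."""
    rng = np.random.default_rng(seed)
    dose = np.zeros((n, 2))
    for _ in range(2):  # two haplotypes
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        dose[:, 0] += z1 < ndtri(maf_a)
        dose[:, 1] += z2 < ndtri(maf_b)
    return np.corrcoef(dose[:, 0], dose[:, 1])[0, 1]


class TestSimulateGenotypes:
    def test_independent_snps_have_no_ld(self):
        cfg = _singleton_config(n=2000, ld_rho=0.0)
        geno, _ = simulate_genotypes(cfg)
        G = geno.dosages.to_numpy()
        R = np.corrcoef(G, rowvar=False)
        off = R[np.triu_indices_from(R, k=1)]
        assert np.mean(off**2) < 3.0 / cfg.samples_per_cohort[0]

    def test_mz_pairs_are_clonal(self):
        cfg = SimConfig(n_cohorts=1, samples_per_cohort=[60], n_snps=30,
                        n_cpgs=10, ld_block_size=5, n_cis_effects=0,
                        n_trans_effects=0, n_mz_pairs=15, n_dz_pairs=10, seed=5)
        geno, ped = simulate_genotypes(cfg)
        for a, b in ped.pairs("MZ"):
            np.testing.assert_array_equal(
                geno.dosages.loc[a].to_numpy(), geno.dosages.loc[b].to_numpy()
            )

    def test_dz_allele_sharing_is_half(self):
        cfg = SimConfig(n_cohorts=1, samples_per_cohort=[2000], n_snps=50,
                        n_cpgs=10, ld_block_size=5, ld_rho=0.0,
                        n_cis_effects=0, n_trans_effects=0,
                        n_mz_pairs=0, n_dz_pairs=1000, seed=7)
        geno, ped = simulate_genotypes(cfg)
        # genotype correlation within DZ pairs approximates 1/2 per SNP
        corrs = []
        D = geno.dosages
        pairs = ped.pairs("DZ")
        A = np.array([D.loc[a].to_numpy() for a, b in pairs])
        B = np.array([D.loc[b].to_numpy() for a, b in pairs])
        for j in range(geno.n_snps):
            if A[:, j].std() > 0 and B[:, j].std() > 0:
                corrs.append(np.corrcoef(A[:, j], B[:, j])[0, 1])
        assert np.mean(corrs) == pytest.approx(0.5, abs=0.02)

    def test_adjacent_ld_matches_mc_oracle(self):
        cfg = _singleton_config(n=2000, ld_rho=0.9, ld_block_size=10, seed=1)
        geno, _ = simulate_genotypes(cfg)
        G = geno.dosages.to_numpy()
        mafs = geno.snp_info["target_maf"].to_numpy()
        # within-block adjacent pairs only
        diffs = []
        for j in range(cfg.n_snps - 1):
            if (j + 1) % cfg.ld_block_size == 0:
                continue
            obs = np.corrcoef(G[:, j], G[:, j + 1])[0, 1]
            oracle = mc_adjacent_dosage_corr(0.9, mafs[j], mafs[j + 1], seed=j)
            diffs.append(obs - oracle)
        assert np.max(np.abs(diffs)) < 0.05 * 1.5  # MC + sample noise margin
        assert abs(np.mean(diffs)) < 0.02

    def test_maf_within_requested_range(self):
        cfg = _singleton_config(n=3000, maf_range=(0.1, 0.4))
        geno, _ = simulate_genotypes(cfg)
        maf = geno.observed_maf().to_numpy()
        # binomial sampling tolerance at n=3000 (6000 alleles)
        slack = 3 * np.sqrt(0.4 * 0.6 / 6000)
        assert maf.min() > 0.1 - slack and maf.max() < 0.4 + slack

    def test_dosages_bounded(self):
        cfg = _singleton_config(n=200, dosage_noise_sd=0.2)
        geno, _ = simulate_genotypes(cfg)
        vals = geno.dosages.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 2.0

    def test_block_size_validation(self):
        with pytest.raises(ValueError, match="ld_block_size"):
            _singleton_config(ld_block_size=100, n_snps=40)

    def test_degenerate_maf_range(self):
        with pytest.raises(ValueError, match="maf_range"):
            _singleton_config(maf_range=(0.3, 0.1))


class TestPlantEffects:
    def test_zero_requests_give_empty_truth(self):
        cfg = _singleton_config(n=50)
        geno, _ = simulate_genotypes(cfg)
        truth = plant_effects(geno, cpg_position_map(cfg), cfg)
        assert truth.empty

    def test_cis_effects_respect_window(self):
        cfg = SimConfig(n_cohorts=1, samples_per_cohort=[50], n_snps=80,
                        n_cpgs=60, ld_block_size=5, n_chroms=1,
                        n_cis_effects=5, n_trans_effects=0,
                        n_mz_pairs=0, n_dz_pairs=0, seed=9)
        geno, _ = simulate_genotypes(cfg)
        cpg_pos = cpg_position_map(cfg)
        truth = plant_effects(geno, cpg_pos, cfg)
        assert len(truth) == 5
        for rec in truth.itertuples(index=False):
            d = abs(int(geno.snp_info.loc[rec.snp_id, "pos"])
                    - int(cpg_pos.loc[rec.cpg_id, "pos"]))
            assert d <= 1_000_000

    def test_truth_labels_match_classifier(self, small_study):
        geno = small_study.geno_pooled
        cpg_pos = small_study.cpg_positions
        for rec in small_study.truth.itertuples(index=False):
            snp = geno.snp_info.loc[rec.snp_id]
            cpg = cpg_pos.loc[rec.cpg_id]
            assert classify_cis_trans(
                (snp["chrom"], int(snp["pos"])), (cpg["chrom"], int(cpg["pos"]))
            ) == rec.type

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_cohorts=1, samples_per_cohort=[50], n_snps=80,
                        n_cpgs=60, ld_block_size=5, n_cis_effects=6,
                        n_trans_effects=3, n_mz_pairs=0, n_dz_pairs=0, seed=13)
        geno, _ = simulate_genotypes(cfg)
        cpg_pos = cpg_position_map(cfg)
        t1 = plant_effects(geno, cpg_pos, cfg)
        t2 = plant_effects(geno, cpg_pos, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unique_pairs_and_per_cpg_cap(self, small_study):
        truth = small_study.truth
        pairs = list(zip(truth["snp_id"], truth["cpg_id"]))
        assert len(pairs) == len(set(pairs))
        assert truth["cpg_id"].value_counts().max() <= small_study.config.max_effects_per_cpg

    def test_insufficient_candidates_error(self):
        cfg = SimConfig(n_cohorts=1, samples_per_cohort=[50], n_snps=10,
                        n_cpgs=4, ld_block_size=5, n_cis_effects=0,
                        n_trans_effects=0, n_mz_pairs=0, n_dz_pairs=0,
                        max_effects_per_cpg=1, seed=1)
        geno, _ = simulate_genotypes(cfg)
        cfg2 = SimConfig(**{**cfg.__dict__, "n_cis_effects": 50})
        with pytest.raises(ValueError, match="insufficient"):
            plant_effects(geno, cpg_position_map(cfg2), cfg2)


class TestSimulateMethylation:
    @staticmethod
    def _latent_cross_twin_corr(ace, n_pairs=1000, seed=21):
        """Empirical cross-twin correlation of the simulated values after
        undoing the logistic link (logit returns the latent + offset)."""
        cfg = SimConfig(
            n_cohorts=1, samples_per_cohort=[4 * n_pairs], n_snps=10,
            n_cpgs=40, ld_block_size=5, n_cis_effects=0, n_trans_effects=0,
            n_mz_pairs=n_pairs, n_dz_pairs=n_pairs, ace_params=ace,
            covariate_effect_sd=0.0, batch_effect_sd=0.0, seed=seed,
        )
        geno, ped = simulate_genotypes(cfg)
        truth = plant_effects(geno, cpg_position_map(cfg), cfg)
        meth, _ = simulate_methylation(geno, truth, ped, cfg)
        latent = np.log(meth.values / (1 - meth.values))
        out = {}
        for zyg in ("MZ", "DZ"):
            pairs = ped.pairs(zyg)
            a = latent.loc[[p[0] for p in pairs]].to_numpy()
            b = latent.loc[[p[1] for p in pairs]].to_numpy()
            rs = [np.corrcoef(a[:, j], b[:, j])[0, 1] for j in range(a.shape[1])]
            out[zyg] = float(np.mean(rs))
        return out

    def test_no_genetics_means_equal_twin_correlations(self):
        corr = self._latent_cross_twin_corr((0.0, 0.3, 0.7))
        assert corr["MZ"] == pytest.approx(0.3, abs=0.04)
        assert corr["DZ"] == pytest.approx(0.3, abs=0.04)

    def test_ace_cross_twin_closed_form(self):
        # rMZ = A + C, rDZ = A/2 + C
        corr = self._latent_cross_twin_corr((0.6, 0.2, 0.2))
        assert corr["MZ"] == pytest.approx(0.8, abs=0.04)
        assert corr["DZ"] == pytest.approx(0.5, abs=0.04)

    def test_beta_values_strictly_inside_unit_interval(self, small_study):
        vals = small_study.meth_raw.values.to_numpy()
        assert vals.min() > 0.0 and vals.max() < 1.0

    def test_planted_effect_visible_in_raw_data(self, small_study):
        rec = small_study.truth.iloc[0]
        g = small_study.geno_pooled.dosages[rec["snp_id"]].to_numpy()
        latent = np.log(small_study.meth_raw.values[rec["cpg_id"]]
                        / (1 - small_study.meth_raw.values[rec["cpg_id"]]))
        slope = np.polyfit(g, latent, 1)[0]
        assert np.sign(slope) == np.sign(rec["true_beta"])


class TestSimulateSummaryStats:
    def test_pleiotropy_zero_noise_constant_ratio(self):
        region = RegionConfig(noise=False)
        exp, out, R, ratio = simulate_summary_stats("pleiotropy", region, seed=1)
        mask = exp["b"].abs() > 1e-12
        ratios = out.loc[mask, "b"] / exp.loc[mask, "b"]
        np.testing.assert_allclose(ratios, ratio, rtol=1e-10)

    def test_linkage_ratio_differs_between_causal_snps(self):
        # analytic plug-in of the marginal-beta formula at the two causal SNPs
        region = RegionConfig(noise=False, ld_rho=0.9, causal_index=10,
                              outcome_causal_index=17)
        exp, out, R, _ = simulate_summary_stats("linkage", region, seed=1)
        r = 0.9 ** 7  # LD between the two causal variants
        b1, b2 = region.b_exposure, region.causal_ratio * region.b_exposure
        ratio_at_exp_causal = (r * b2) / b1
        ratio_at_out_causal = b2 / (r * b1)
        assert out["b"][10] / exp["b"][10] == pytest.approx(ratio_at_exp_causal, rel=1e-9)
        assert out["b"][17] / exp["b"][17] == pytest.approx(ratio_at_out_causal, rel=1e-9)
        assert ratio_at_exp_causal != pytest.approx(ratio_at_out_causal, rel=1e-3)

    def test_fixed_seed_reproducible(self):
        a = simulate_summary_stats("pleiotropy", RegionConfig(), seed=42)
        b = simulate_summary_stats("pleiotropy", RegionConfig(), seed=42)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_unknown_scenario_errors(self):
        with pytest.raises(ValueError, match="scenario"):
            simulate_summary_stats("both", RegionConfig(), seed=0)

    def test_region_requires_25_snps(self):
        with pytest.raises(ValueError, match="25"):
            RegionConfig(n_snps=10)
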