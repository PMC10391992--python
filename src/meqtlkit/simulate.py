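"""Synthetic multi-cohort meQTL study generator with known ground truth.

The generator emulates the design of a multi-cohort blood-methylation QTL
study: several cohorts of unequal size, the first containing MZ/DZ twin
pairs and the rest unrelated singletons; genotypes with block-wise LD;
methylation driven by planted cis/trans SNP effects plus an ACE
(additive genetic / shared environment / unique environment) covariance
structure within twin pairs, cell-composition, smoking and batch
covariates; and QTL/GWAS summary statistics under pleiotropy vs. linkage
for colocalisation testing.

LD model: within each block of ``ld_block_size`` SNPs, each haplotype is
thresholded from a latent Gaussian AR(1) process with parameter
``ld_rho`` — SNP j carries the alternative allele iff
``z_j < Phi^{-1}(p_j)``, where p_j is the allele frequency. This gives a
closed-form latent correlation rho^|i-j| between SNPs of the same block,
convenient for brute-force oracles. Blocks (and chromosomes) are
independent.

Twin genotypes: MZ pairs share both haplotypes exactly; DZ pairs draw two
haplotypes per parent and each twin inherits one per parent independently,
so transmissions are shared with probability 1/2.

A single integer seed fans out deterministically to per-stage child
streams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from meqtlkit.datatypes import (
    CovariateTable,
    GenotypeMatrix,
    MethylationMatrix,
    Pedigree,
    folded_maf,
)

CIS_WINDOW = 1_000_000

# SeedSequence spawn-key slots, one per generator stage.
_STAGE = {"genotypes": 0, "effects": 1, "methylation": 2, "summary": 3}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror a desk-scale version of a five-cohort UK study design:
    five cohorts with twins only in the first, biallelic SNPs in LD blocks,
    and an ACE structure with a moderately heritable methylome.
    """

    n_cohorts: int = 5
    samples_per_cohort: list[int] = field(default_factory=lambda: [150] * 5)
    n_snps: int = 300
    n_cpgs: int = 400
    ld_block_size: int = 10
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cis_effects: int = 60
    n_trans_effects: int = 0
    effect_size_sd: float = 0.5
    effect_r2: float | None = None
    max_effects_per_cpg: int = 2
    ace_params: tuple[float, float, float] = (0.3, 0.2, 0.5)
    n_mz_pairs: int = 25
    n_dz_pairs: int = 25
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    covariate_effect_sd: float = 0.2
    batch_effect_sd: float = 0.2
    dosage_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValueError("samples_per_cohort length must equal n_cohorts")
        for name in ("n_cohorts", "n_snps", "n_cpgs", "ld_block_size", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.samples_per_cohort):
            raise ValueError("cohort sizes must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        A, C, E = self.ace_params
        if min(A, C, E) < 0 or abs(A + C + E - 1.0) > 1e-9:
            raise ValueError("ace_params must be non-negative and sum to 1")
        if self.ld_block_size > self.n_snps:
            raise ValueError("ld_block_size exceeds n_snps")
        n_twin = 2 * (self.n_mz_pairs + self.n_dz_pairs)
        if n_twin > self.samples_per_cohort[0]:
            raise ValueError(
                "twin pairs do not fit in the first cohort: "
                f"need {n_twin} slots, have {self.samples_per_cohort[0]}"
            )

    def stage_rng(self, stage: str) -> np.random.Generator:
        key = _STAGE[stage]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


def _positions(config: SimConfig, n: int, rng: np.random.Generator):
    """Even chromosome assignment with sorted uniform positions per chrom."""
    per = np.array_split(np.arange(n), config.n_chroms)
    chroms, poss = [], []
    for c, idx in enumerate(per, start=1):
        p = np.sort(rng.integers(1, config.chrom_length + 1, size=len(idx)))
        chroms.extend([f"chr{c}"] * len(idx))
        poss.extend(p.tolist())
    return np.array(chroms), np.array(poss, dtype=int)


def _ar1_latent(rng, n_hap: int, n_snps: int, block_size: int, rho: float) -> np.ndarray:
    """Latent Gaussian with AR(1) correlation inside LD blocks."""
    z = np.empty((n_hap, n_snps))
    innov = rng.standard_normal((n_hap, n_snps))
    scale = np.sqrt(1.0 - rho**2)
    for j in range(n_snps):
        if j % block_size == 0:
            z[:, j] = innov[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j]
    return z


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, Pedigree]:
    """Simulate multi-cohort dosages with LD blocks and twin structure.

    Returns a pooled :class:`GenotypeMatrix` over all cohorts (sample ids
    prefixed by cohort) and the matching :class:`Pedigree`. Per-SNP
    metadata records the realized folded MAF. The ``cohort`` assignment is
    available via :func:`cohort_of_sample`.
    """
    rng = config.stage_rng("genotypes")
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    thresholds = ndtri(mafs)
    snp_chrom, snp_pos = _positions(config, config.n_snps, rng)

    sample_ids: list[str] = []
    fam_ids: list[str] = []
    zygosity: list[str] = []
    dosage_rows: list[np.ndarray] = []

    def haps(k: int) -> np.ndarray:
        z = _ar1_latent(rng, k, config.n_snps, config.ld_block_size, config.ld_rho)
        return (z < thresholds[None, :]).astype(float)

    fam_counter = 0
    for c in range(config.n_cohorts):
        n = config.samples_per_cohort[c]
        n_twin_pairs_mz = config.n_mz_pairs if c == 0 else 0
        n_twin_pairs_dz = config.n_dz_pairs if c == 0 else 0
        n_singletons = n - 2 * (n_twin_pairs_mz + n_twin_pairs_dz)
        for _ in range(n_twin_pairs_mz):
            fam_counter += 1
            h = haps(2)
            dose = h[0] + h[1]
            for t in (1, 2):
                sample_ids.append(f"c{c}_f{fam_counter}_t{t}")
                fam_ids.append(f"fam{fam_counter}")
                zygosity.append("MZ")
                dosage_rows.append(dose)
        for _ in range(n_twin_pairs_dz):
            fam_counter += 1
            parental = haps(4)  # maternal pair then paternal pair
            pick = rng.integers(0, 2, size=(2, 2))  # twin x parent
            for t in (1, 2):
                m = parental[pick[t - 1, 0]]
                p = parental[2 + pick[t - 1, 1]]
                sample_ids.append(f"c{c}_f{fam_counter}_t{t}")
                fam_ids.append(f"fam{fam_counter}")
                zygosity.append("DZ")
                dosage_rows.append(m + p)
        for _ in range(n_singletons):
            fam_counter += 1
            h = haps(2)
            sample_ids.append(f"c{c}_s{fam_counter}")
            fam_ids.append(f"fam{fam_counter}")
            zygosity.append("singleton")
            dosage_rows.append(h[0] + h[1])

    dosages = np.array(dosage_rows)
    if config.dosage_noise_sd > 0:
        dosages = np.clip(
            dosages + rng.normal(0.0, config.dosage_noise_sd, size=dosages.shape),
            0.0, 2.0,
        )
    snp_ids = [f"snp{j}" for j in range(config.n_snps)]
    dosage_df = pd.DataFrame(dosages, index=sample_ids, columns=snp_ids)
    realized = folded_maf(dosage_df.mean(axis=0).to_numpy() / 2.0)
    snp_info = pd.DataFrame(
        {"chrom": snp_chrom, "pos": snp_pos, "ref": "A", "alt": "G",
         "maf": realized, "target_maf": folded_maf(mafs)},
        index=pd.Index(snp_ids, name="snp"),
    )
    ped = Pedigree(pd.DataFrame(
        {"family_id": fam_ids, "zygosity": zygosity},
        index=pd.Index(sample_ids, name="sample"),
    ))
    return GenotypeMatrix(dosage_df, snp_info), ped


def cohort_of_sample(sample_ids) -> pd.Series:
    """Cohort label parsed from the generator's sample-id convention."""
    idx = pd.Index(sample_ids)
    return pd.Series([s.split("_")[0] for s in idx], index=idx, name="cohort")


def cpg_position_map(config: SimConfig) -> pd.DataFrame:
    """CpG positions on the same genome layout as the SNPs."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STAGE["effects"], 0))
    )
    chrom, pos = _positions(config, config.n_cpgs, rng)
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": "+"},
        index=pd.Index([f"cg{j}" for j in range(config.n_cpgs)], name="cpg"),
    )


def plant_effects(
    geno: GenotypeMatrix,
    cpg_positions: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Choose SNP-CpG effect pairs and draw their latent-scale betas.

    cis pairs satisfy |pos_snp - pos_cpg| <= 1 Mbp on the same chromosome;
    trans pairs violate it. Betas are N(0, effect_size_sd^2), or of fixed
    latent variance-explained ``effect_r2`` with random sign when that
    option is set. No CpG receives more than ``max_effects_per_cpg``
    planted effects.
    """
    rng = config.stage_rng("effects")
    snp_info = geno.snp_info
    same_chrom = snp_info["chrom"].to_numpy()[:, None] == cpg_positions["chrom"].to_numpy()[None, :]
    dist = np.abs(snp_info["pos"].to_numpy()[:, None] - cpg_positions["pos"].to_numpy()[None, :])
    cis_mask = same_chrom & (dist <= CIS_WINDOW)

    chosen: list[tuple[int, int, str]] = []
    used_pairs: set[tuple[int, int]] = set()
    cpg_load = np.zeros(len(cpg_positions), dtype=int)

    def draw(mask: np.ndarray, want: int, label: str) -> None:
        si, ci = np.nonzero(mask)
        order = rng.permutation(len(si))
        got = 0
        for k in order:
            if got == want:
                break
            pair = (int(si[k]), int(ci[k]))
            if pair in used_pairs or cpg_load[pair[1]] >= config.max_effects_per_cpg:
                continue
            used_pairs.add(pair)
            cpg_load[pair[1]] += 1
            chosen.append((*pair, label))
            got += 1
        if got < want:
            raise ValueError(
                f"insufficient candidate {label} pairs: requested {want}, placed {got}"
            )

    draw(cis_mask, config.n_cis_effects, "cis")
    draw(~cis_mask, config.n_trans_effects, "trans")

    rows = []
    for si, ci, label in chosen:
        if config.effect_r2 is not None:
            maf = float(snp_info["maf"].iloc[si])
            var_dose = max(2.0 * maf * (1.0 - maf), 1e-12)
            beta = np.sqrt(config.effect_r2 / var_dose) * rng.choice([-1.0, 1.0])
        else:
            beta = rng.normal(0.0, config.effect_size_sd)
        rows.append({
            "snp_id": snp_info.index[si],
            "cpg_id": cpg_positions.index[ci],
            "true_beta": float(beta),
            "type": label,
        })
    truth = pd.DataFrame(rows, columns=["snp_id", "cpg_id", "true_beta", "type"])
    return truth


def _twin_correlated(rng, ped: Pedigree, n_cpgs: int, r_dz: float = 0.5) -> np.ndarray:
    """Standard-normal matrix with within-pair correlation 1 (MZ) / r_dz (DZ)."""
    n = len(ped.table)
    out = rng.standard_normal((n, n_cpgs))
    pos = {s: i for i, s in enumerate(ped.table.index)}
    for a, b in ped.pairs("MZ"):
        out[pos[b]] = out[pos[a]]
    c = np.sqrt(1.0 - r_dz**2)
    for a, b in ped.pairs("DZ"):
        out[pos[b]] = r_dz * out[pos[a]] + c * rng.standard_normal(n_cpgs)
    return out


def _family_shared(rng, ped: Pedigree, n_cpgs: int) -> np.ndarray:
    """Standard-normal matrix constant within family."""
    fams, codes = np.unique(ped.table["family_id"].to_numpy(), return_inverse=True)
    per_fam = rng.standard_normal((len(fams), n_cpgs))
    return per_fam[codes]


def simulate_covariates(config: SimConfig, ped: Pedigree) -> CovariateTable:
    """Sex, age, smoking, cell proportions and batch covariates.

    Cell proportions emulate blood deconvolution output: CD4+ T cells
    (mean 0.20, sd 0.07) and monocytes (mean 0.05, sd 0.026), clipped to
    [0.01, 0.6]; smoking prevalence 21.5%; plate (4 per cohort) and chip
    position (8 levels) as categorical batch factors.
    """
    rng = config.stage_rng("methylation")
    idx = ped.table.index
    n = len(idx)
    cohort = cohort_of_sample(idx)
    # Twins share sex; assign per family then broadcast.
    fams, codes = np.unique(ped.table["family_id"].to_numpy(), return_inverse=True)
    fam_sex = rng.choice(["F", "M"], size=len(fams), p=[0.6, 0.4])
    sex = fam_sex[codes]
    cohort_ages = {c: rng.uniform(45, 65) for c in cohort.unique()}
    age = np.array([cohort_ages[c] for c in cohort]) + rng.normal(0, 2, size=n)
    smoking = rng.random(n) < 0.215
    cd4 = np.clip(rng.normal(0.20, 0.07, size=n), 0.01, 0.6)
    mono = np.clip(rng.normal(0.05, 0.026, size=n), 0.01, 0.6)
    gran = np.clip(rng.normal(0.55, 0.08, size=n), 0.05, 0.9)
    plate = np.array([f"{c}_plate{p}" for c, p in zip(cohort, rng.integers(0, 4, size=n))])
    chip_pos = np.array([f"pos{p}" for p in rng.integers(0, 8, size=n)])
    table = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "smoking": smoking.astype(int),
            "prop_cd4t": cd4,
            "prop_mono": mono,
            "prop_gran": gran,
            "plate": plate,
            "chip_position": chip_pos,
            "family_id": ped.table["family_id"].to_numpy(),
            "zygosity": ped.table["zygosity"].to_numpy(),
            "cohort": cohort.to_numpy(),
        },
        index=idx,
    )
    return CovariateTable(table)


def simulate_methylation(
    geno: GenotypeMatrix,
    truth: pd.DataFrame,
    pedigree: Pedigree,
    config: SimConfig,
    cpg_positions: pd.DataFrame | None = None,
) -> tuple[MethylationMatrix, CovariateTable]:
    """Simulate beta-values from planted effects, ACE structure and covariates.

    The latent value of CpG j for sample i is::

        L_ij = sum_k beta_jk * dose_ik            (planted meQTL effects)
             + sqrt(A) * a_ij                     (polygenic; r=1 MZ, 0.5 DZ)
             + sqrt(C) * c_ij                     (family-shared)
             + sqrt(E) * e_ij                     (independent noise)
             + covariate effects                  (cells, smoking, batch)

    and the emitted beta-value is ``logistic(L_ij + offset_j)`` with a
    per-CpG baseline offset, hence strictly inside (0, 1). Planted betas
    act on the latent (pre-link) scale.
    """
    covars = simulate_covariates(config, pedigree)
    rng = config.stage_rng("methylation")
    # simulate_covariates consumed the head of this stream; re-spawn a
    # dedicated child so methylation draws do not depend on covariate count.
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STAGE["methylation"], 1))
    )
    if cpg_positions is None:
        cpg_positions = cpg_position_map(config)
    n = geno.n_samples
    n_cpgs = len(cpg_positions)
    A, C, E = config.ace_params

    latent = np.zeros((n, n_cpgs))
    if len(truth):
        cpg_index = {c: j for j, c in enumerate(cpg_positions.index)}
        dose = geno.dosages.to_numpy()
        snp_col = {s: j for j, s in enumerate(geno.snp_ids)}
        for rec in truth.itertuples(index=False):
            g = dose[:, snp_col[rec.snp_id]]
            latent[:, cpg_index[rec.cpg_id]] += rec.true_beta * (g - g.mean())

    latent += np.sqrt(A) * _twin_correlated(rng, pedigree, n_cpgs)
    latent += np.sqrt(C) * _family_shared(rng, pedigree, n_cpgs)
    latent += np.sqrt(E) * rng.standard_normal((n, n_cpgs))

    # Covariate effects on a subset of CpGs, coefficients ~ N(0, sd^2).
    tab = covars.table
    numeric = np.column_stack([
        tab["prop_cd4t"], tab["prop_mono"], tab["prop_gran"],
        tab["smoking"].astype(float),
        (tab["age"] - tab["age"].mean()) / tab["age"].std(),
    ])
    coefs = rng.normal(0.0, config.covariate_effect_sd, size=(numeric.shape[1], n_cpgs))
    latent += numeric @ coefs
    plates, plate_codes = np.unique(tab["plate"].to_numpy(), return_inverse=True)
    plate_eff = rng.normal(0.0, config.batch_effect_sd, size=(len(plates), n_cpgs))
    latent += plate_eff[plate_codes]

    offsets = rng.normal(0.0, 1.5, size=n_cpgs)
    betavals = expit(latent + offsets)
    meth = MethylationMatrix(
        pd.DataFrame(betavals, index=geno.sample_ids, columns=cpg_positions.index),
        cpg_positions[["chrom", "pos"]].copy(),
        stage="raw",
    )
    return meth, covars


@dataclass
class RegionConfig:
    """One genomic region for summary-statistic simulation."""

    n_snps: int = 30
    ld_rho: float = 0.9
    n_exposure: int = 20_000
    n_outcome: int = 20_000
    b_exposure: float = 0.3
    causal_ratio: float = 0.5
    causal_index: int | None = None
    outcome_causal_index: int | None = None
    noise: bool = True
    chrom: str = "chr1"
    start_pos: int = 1_000_000
    spacing: int = 10_000

    def __post_init__(self) -> None:
        if self.n_snps < 25:
            raise ValueError("region must have at least 25 SNPs")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")


def simulate_summary_stats(
    scenario: str,
    region: RegionConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, float]:
    """Exposure and outcome summary statistics under pleiotropy or linkage.

    Pleiotropy: a single causal SNP drives both traits, so the marginal
    effect of SNP j is ``r(j, causal) * b_causal`` for each trait and the
    ratio ``b_outcome / b_exposure`` is constant across SNPs. Linkage: two
    distinct causal SNPs in LD drive exposure and outcome separately.
    Standard errors are 1/sqrt(n); estimation noise (if enabled) is drawn
    with the LD correlation structure.

    Returns ``(exposure, outcome, ld_correlation, true_ratio)`` where the
    tables follow the (id, chrom, pos, A1, A2, freq, b, se, p, n) summary
    dialect and ``true_ratio`` is the causal outcome/exposure ratio.
    """
    if scenario not in ("pleiotropy", "linkage"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE["summary"],)))
    m = region.n_snps
    idx = np.arange(m)
    R = region.ld_rho ** np.abs(idx[:, None] - idx[None, :])
    c_exp = region.causal_index if region.causal_index is not None else m // 2
    if scenario == "pleiotropy":
        c_out = c_exp
    else:
        c_out = (
            region.outcome_causal_index
            if region.outcome_causal_index is not None
            else min(m - 1, c_exp + max(1, int(round(np.log(0.5) / np.log(max(region.ld_rho, 1e-6))))))
        )
    b_exp_causal = region.b_exposure
    b_out_causal = region.causal_ratio * region.b_exposure
    mu_exp = R[:, c_exp] * b_exp_causal
    mu_out = R[:, c_out] * b_out_causal
    se_exp = np.full(m, 1.0 / np.sqrt(region.n_exposure))
    se_out = np.full(m, 1.0 / np.sqrt(region.n_outcome))
    if region.noise:
        L = np.linalg.cholesky(R + 1e-10 * np.eye(m))
        b_exp = mu_exp + se_exp * (L @ rng.standard_normal(m))
        b_out = mu_out + se_out * (L @ rng.standard_normal(m))
    else:
        b_exp, b_out = mu_exp.copy(), mu_out.copy()

    def table(b, se, n):
        from scipy import stats as _st

        z = b / se
        return pd.DataFrame({
            "id": [f"snp{j}" for j in idx],
            "chrom": region.chrom,
            "pos": region.start_pos + idx * region.spacing,
            "A1": "G",
            "A2": "A",
            "freq": 0.3,
            "b": b,
            "se": se,
            "p": np.clip(2.0 * _st.norm.sf(np.abs(z)), 1e-300, 1.0),
            "n": n,
        })

    exp_df = table(b_exp, se_exp, region.n_exposure)
    out_df = table(b_out, se_out, region.n_outcome)
    true_ratio = region.causal_ratio if scenario == "pleiotropy" else b_out_causal / b_exp_causal
    return exp_df, out_df, R, true_ratio
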