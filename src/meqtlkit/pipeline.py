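"""End-to-end orchestration: two-stage meQTL discovery and the demo study.

`run_discovery` is the in-memory core: per-cohort candidate scans, pooled
DerSimonian-Laird meta-analysis, B family-preserving permutations feeding
the permutation-FDR threshold (selected separately for cis and trans),
and the >= 2-cohort direction-consistency filter. The permutation null is
produced by the *identical* scan + meta + consistency pipeline, so null
and observed candidate distributions are exchangeable.

`synthetic_study` assembles a complete multi-cohort in-memory study from
a `SimConfig` (genotypes, planted truth, methylation, covariates,
INT + covariate residualization per cohort).

`run_pipeline` is the file-based wrapper used by the CLI: it executes the
stages on a configuration, writes each stage's TSV and a manifest with
input hashes, parameters and the seed, so identical configurations
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from meqtlkit import io as mio
from meqtlkit.datatypes import GenotypeMatrix, MethylationMatrix, Pedigree
from meqtlkit.meta import (
    FdrCurve,
    consistency_filter,
    meta_analyse,
    permutation_fdr,
    permute_cohort,
)
from meqtlkit.qc import adjust_methylation, filter_genotypes, filter_probes, transform_methylation
from meqtlkit.scan import scan_cohort
from meqtlkit.simulate import (
    SimConfig,
    cohort_of_sample,
    cpg_position_map,
    plant_effects,
    simulate_genotypes,
    simulate_methylation,
)

logger = logging.getLogger(__name__)


@dataclass
class CohortData:
    """One cohort's aligned genotype, residual methylation and pedigree."""

    name: str
    geno: GenotypeMatrix
    meth: MethylationMatrix
    pedigree: Pedigree | None = None


@dataclass
class DiscoveryResult:
    """Everything the two-stage scan produces."""

    records: pd.DataFrame  # per-cohort candidates
    meta: pd.DataFrame  # pooled, all candidate pairs
    filtered: pd.DataFrame  # after consistency filter
    significant: pd.DataFrame  # after permutation-FDR thresholds
    fdr_curves: dict[str, FdrCurve] = field(default_factory=dict)


def run_discovery(
    cohorts: list[CohortData],
    p_cis: float = 5e-3,
    p_trans: float = 5e-6,
    window: int = 1_000_000,
    n_permutations: int = 20,
    fdr_target: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> DiscoveryResult:
    """Per-cohort scans, meta-analysis, permutation FDR, consistency filter."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def one_pass(meths: dict[str, MethylationMatrix]) -> pd.DataFrame:
        recs = []
        for c in cohorts:
            recs.append(scan_cohort(c.geno, meths[c.name], c.name,
                                    p_cis=p_cis, p_trans=p_trans, window=window))
        non_empty = [r for r in recs if not r.empty]
        if not non_empty:
            return recs[0]
        return pd.concat(non_empty, ignore_index=True)

    observed_records = one_pass({c.name: c.meth for c in cohorts})
    meta = meta_analyse(observed_records)
    filtered = consistency_filter(meta)

    null_p: dict[str, list[np.ndarray]] = {"cis": [], "trans": []}
    for b in range(n_permutations):
        perm_meths = {
            c.name: permute_cohort(c.meth, c.pedigree, rng) for c in cohorts
        }
        null_records = one_pass(perm_meths)
        null_meta = meta_analyse(null_records)
        null_filtered = consistency_filter(null_meta)
        for t in ("cis", "trans"):
            null_p[t].append(
                null_filtered.loc[null_filtered["type"] == t, "p"].to_numpy()
            )

    curves: dict[str, FdrCurve] = {}
    sig_frames = []
    for t in ("cis", "trans"):
        obs = filtered.loc[filtered["type"] == t, "p"].to_numpy()
        if obs.size == 0:
            continue
        curve = permutation_fdr(obs, null_p[t], target=fdr_target)
        curves[t] = curve
        if curve.selected_threshold is not None:
            sig_frames.append(
                filtered[(filtered["type"] == t)
                         & (filtered["p"] <= curve.selected_threshold)]
            )
    significant = (
        pd.concat(sig_frames, ignore_index=True) if sig_frames
        else filtered.iloc[0:0]
    )
    return DiscoveryResult(observed_records, meta, filtered, significant, curves)


@dataclass
class SyntheticStudy:
    """A fully prepared multi-cohort synthetic study."""

    config: SimConfig
    geno_pooled: GenotypeMatrix
    pedigree: Pedigree
    truth: pd.DataFrame
    cpg_positions: pd.DataFrame
    cohorts: list[CohortData]
    covariates: pd.DataFrame
    meth_raw: MethylationMatrix


def synthetic_study(config: SimConfig, adjust: bool = True) -> SyntheticStudy:
    """Generate and prepare a complete study from one configuration.

    Per cohort: INT on the raw beta-values, then residualization on sex,
    age, smoking and cell proportions (fixed) plus plate and chip
    position (categorical). Family/zygosity are deliberately NOT removed,
    preserving the twin covariance for heritability and the family
    structure for permutations.
    """
    geno, ped = simulate_genotypes(config)
    cpg_pos = cpg_position_map(config)
    truth = plant_effects(geno, cpg_pos, config)
    meth, covars = simulate_methylation(geno, truth, ped, config, cpg_positions=cpg_pos)
    cohort = cohort_of_sample(geno.sample_ids)
    cohorts = []
    for name in sorted(cohort.unique()):
        ids = cohort.index[cohort == name]
        sub_geno = geno.subset(samples=ids)
        sub_meth = meth.subset(samples=ids)
        sub_ped = ped.subset(ids)
        if adjust:
            sub_int = transform_methylation(sub_meth)
            sub_cov = covars.subset(ids)
            fixed = ["sex", "age", "smoking", "prop_cd4t", "prop_mono", "prop_gran"]
            resid = adjust_methylation(sub_int, sub_cov, fixed=fixed,
                                       grouping=["plate", "chip_position"])
        else:
            resid = MethylationMatrix(sub_meth.values, sub_meth.cpg_info, stage="raw")
        cohorts.append(CohortData(name, sub_geno, resid, sub_ped))
    return SyntheticStudy(config, geno, ped, truth, cpg_pos, cohorts, covars.table, meth)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """File-based pipeline: simulate (or load), QC, adjust, scan, meta, FDR.

    ``config`` mirrors the YAML structure consumed by the CLI: a
    ``simulate`` section (SimConfig fields) or an ``inputs`` section with
    paths, plus optional ``parameters`` overriding thresholds. Outputs
    are TSVs under ``outdir`` along with ``manifest.json`` describing
    stages, parameters, seed and output hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {
        "window": 1_000_000, "p_cis": 5e-3, "p_trans": 5e-6,
        "n_permutations": 20, "fdr_target": 0.05, "seed": 0,
    }
    params.update(config.get("parameters", {}))
    manifest = {"stages": [], "parameters": params, "seed": params["seed"]}
    t0 = time.time()

    if "simulate" in config:
        sim = SimConfig(**{**config["simulate"], "seed": params["seed"]})
        study = synthetic_study(sim)
        cohorts = study.cohorts
        mio.write_genotypes_tsv(study.geno_pooled, outdir / "genotypes.tsv")
        mio.write_positions_tsv(study.geno_pooled.snp_info, outdir / "snp_positions.tsv")
        mio.write_positions_tsv(study.cpg_positions, outdir / "cpg_positions.tsv")
        mio.write_methylation(study.meth_raw, outdir / "methylation_raw.tsv")
        study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        mio.write_pedigree(study.pedigree, outdir / "pedigree.tsv")
        study.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index_label="sample")
        manifest["stages"].append({"stage": "simulate", "config": config["simulate"]})
    else:
        inputs = config["inputs"]
        snp_pos = mio.read_positions_tsv(inputs["snp_positions"])
        cpg_pos = mio.read_positions_tsv(inputs["cpg_positions"])
        covars = mio.read_covariates(inputs["covariates"])
        ped = mio.read_pedigree(inputs["pedigree"]) if "pedigree" in inputs else None
        geno = mio.read_genotypes(inputs["genotypes"],
                                  dialect=inputs.get("genotype_dialect", "tsv"),
                                  positions=snp_pos)
        meth = mio.read_methylation(inputs["methylation"], cpg_pos, stage="raw")
        geno, geno_report = filter_genotypes(geno)
        meth, meth_report = filter_probes(meth)
        common = geno.sample_ids.intersection(meth.sample_ids)
        geno = geno.subset(samples=common)
        meth = meth.subset(samples=common)
        manifest["stages"].append({"stage": "qc",
                                   "genotype_removed": geno_report.removed,
                                   "probe_removed": meth_report.removed})
        meth_int = transform_methylation(meth)
        fixed = [c for c in ("sex", "age", "smoking", "prop_cd4t", "prop_mono",
                             "prop_gran") if c in covars.table.columns]
        grouping = [c for c in ("plate", "chip_position") if c in covars.table.columns]
        resid = adjust_methylation(meth_int, covars.subset(common),
                                   fixed=fixed, grouping=grouping)
        manifest["stages"].append({"stage": "adjust", "fixed": fixed,
                                   "grouping": grouping})
        cohort_col = covars.table.loc[common, "cohort"] if "cohort" in covars.table.columns \
            else pd.Series("cohort0", index=common)
        cohorts = []
        for name in sorted(cohort_col.unique()):
            ids = cohort_col.index[cohort_col == name]
            cohorts.append(CohortData(
                name, geno.subset(samples=ids), resid.subset(samples=ids),
                ped.subset(ids) if ped is not None else None,
            ))

    result = run_discovery(
        cohorts,
        p_cis=params["p_cis"], p_trans=params["p_trans"], window=params["window"],
        n_permutations=params["n_permutations"], fdr_target=params["fdr_target"],
        seed=np.random.default_rng(params["seed"]),
    )
    result.records.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    result.meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    result.filtered.to_csv(outdir / "meta_consistent.tsv", sep="\t", index=False)
    result.significant.to_csv(outdir / "significant.tsv", sep="\t", index=False)
    curve_rows = []
    for t, curve in result.fdr_curves.items():
        for thr, f in zip(curve.thresholds, curve.fdr):
            curve_rows.append({"type": t, "threshold": thr, "fdr": f})
    pd.DataFrame(curve_rows).to_csv(outdir / "fdr_curves.tsv", sep="\t", index=False)
    manifest["stages"].append({
        "stage": "discovery",
        "n_candidates": int(len(result.records)),
        "n_significant": int(len(result.significant)),
        "thresholds": {t: c.selected_threshold for t, c in result.fdr_curves.items()},
        "runtime_s": round(time.time() - t0, 2),
    })
    manifest["outputs"] = {
        p.name: _hash_file(p) for p in sorted(outdir.glob("*.tsv"))
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
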