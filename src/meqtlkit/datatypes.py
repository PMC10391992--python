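"""Core in-memory containers for the meQTL pipeline.

All containers are thin, validated wrappers around pandas objects:

* samples are rows, features (SNPs or CpGs) are columns;
* genomic positions are 1-based inclusive (VCF convention); conversion to
  the 0-based half-open BED convention happens only at the BED boundary
  (see :mod:`meqtlkit.enrichment`);
* dosages count copies of the alternative allele in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STAGES = ("raw", "INT", "residual")


def folded_maf(freq: np.ndarray) -> np.ndarray:
    """Fold allele frequencies onto [0, 0.5]."""
    freq = np.asarray(freq, dtype=float)
    return np.minimum(freq, 1.0 - freq)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x SNPs) plus per-SNP metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id with one column per SNP id; values
        are alternative-allele doses in [0, 2], NaN for missing.
    snp_info
        DataFrame indexed by SNP id with columns ``chrom``, ``pos``
        (1-based), ``ref``, ``alt`` and ``maf`` (folded, in [0, 0.5]).
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snp_info.index):
            self.snp_info = self.snp_info.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 2))
        if bad:
            raise ValueError(f"{int(bad)} dosage values outside [0, 2]")
        if (self.snp_info["pos"] <= 0).any():
            raise ValueError("SNP positions must be positive (1-based)")
        if not self.dosages.columns.is_unique:
            raise ValueError("duplicate SNP ids")
        if not self.dosages.index.is_unique:
            raise ValueError("duplicate sample ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def observed_maf(self) -> pd.Series:
        """Folded minor-allele frequency from the observed dosages."""
        freq = self.dosages.mean(axis=0, skipna=True) / 2.0
        return pd.Series(folded_maf(freq.to_numpy()), index=self.snp_ids, name="maf")

    def missingness(self, axis: int = 0) -> pd.Series:
        """Fraction missing per SNP (axis=0) or per sample (axis=1)."""
        return self.dosages.isna().mean(axis=axis)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        d = self.dosages
        if samples is not None:
            d = d.loc[samples]
        if snps is not None:
            d = d[snps]
        return GenotypeMatrix(d, self.snp_info.loc[d.columns])


@dataclass
class MethylationMatrix:
    """Methylation values (samples x CpGs) plus per-CpG positions.

    ``stage`` tracks the processing state: ``raw`` beta-values in [0, 1],
    ``INT`` after rank-based inverse normal transformation, ``residual``
    after covariate adjustment (unbounded).
    """

    values: pd.DataFrame
    cpg_info: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in VALID_STAGES:
            raise ValueError(f"stage must be one of {VALID_STAGES}")
        if not self.values.columns.equals(self.cpg_info.index):
            self.cpg_info = self.cpg_info.loc[self.values.columns]
        if not self.values.columns.is_unique:
            raise ValueError("duplicate CpG ids")
        if not self.values.index.is_unique:
            raise ValueError("duplicate sample ids")
        if self.stage == "raw":
            vals = self.values.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                bad = np.nansum((vals < 0) | (vals > 1))
            if bad:
                raise ValueError(f"{int(bad)} raw beta-values outside [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def missingness(self, axis: int = 0) -> pd.Series:
        return self.values.isna().mean(axis=axis)

    def subset(self, samples=None, cpgs=None) -> "MethylationMatrix":
        v = self.values
        if samples is not None:
            v = v.loc[samples]
        if cpgs is not None:
            v = v[cpgs]
        return MethylationMatrix(v, self.cpg_info.loc[v.columns], stage=self.stage)


@dataclass
class CovariateTable:
    """Per-sample covariates: one row per sample.

    Conventional columns are ``sex``, ``age``, ``smoking``, cell
    proportions (``prop_*``, each in [0, 1]), ``plate``, ``chip_position``,
    ``family_id`` and ``zygosity``; extra columns are allowed.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError("duplicate sample ids in covariate table")
        for col in self.table.columns:
            if col.startswith("prop_"):
                vals = self.table[col].to_numpy(dtype=float)
                if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                    raise ValueError(f"cell proportion column {col!r} outside [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, samples) -> "CovariateTable":
        return CovariateTable(self.table.loc[samples])


@dataclass
class Pedigree:
    """Family structure: sample -> (family_id, zygosity).

    Zygosity is one of ``MZ``, ``DZ`` or ``singleton``; MZ/DZ families
    contain exactly two members.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"family_id", "zygosity"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pedigree requires columns {sorted(required)}")
        bad = set(self.table["zygosity"]) - {"MZ", "DZ", "singleton"}
        if bad:
            raise ValueError(f"unknown zygosity values: {sorted(bad)}")
        twin = self.table[self.table["zygosity"].isin(["MZ", "DZ"])]
        sizes = twin.groupby("family_id").size()
        if (sizes != 2).any():
            raise ValueError("MZ/DZ families must have exactly two members")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def pairs(self, zygosity: str) -> list[tuple[str, str]]:
        """Return (member1, member2) tuples for MZ or DZ families."""
        twin = self.table[self.table["zygosity"] == zygosity]
        out = []
        for _, grp in twin.groupby("family_id"):
            ids = list(grp.index)
            out.append((ids[0], ids[1]))
        return out

    def subset(self, samples) -> "Pedigree":
        return Pedigree(self.table.loc[self.table.index.intersection(samples)])


def check_aligned(*objs) -> pd.Index:
    """Verify that containers share an identical sample index."""
    idx = objs[0].sample_ids
    for o in objs[1:]:
        if not idx.equals(o.sample_ids):
            raise ValueError("sample ids are not aligned across inputs")
    return idx
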