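"""Readers and writers for the pipeline's on-disk formats.

Genotypes: VCF (DS preferred, GT summed otherwise; read via cyvcf2) or a
TSV dosage dialect (rows = samples, columns = SNP ids). Methylation,
covariates, positions, association/meta tables and LD matrices are TSV.
Annotation tracks are BED (0-based half-open); everything else uses
1-based positions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from meqtlkit.datatypes import (
    CovariateTable,
    GenotypeMatrix,
    MethylationMatrix,
    Pedigree,
    folded_maf,
)
from meqtlkit.enrichment import AnnotationTrack

logger = logging.getLogger(__name__)


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    geno.dosages.to_csv(path, sep="\t", index_label="sample", float_format="%.6g")


def write_positions_tsv(info: pd.DataFrame, path, id_label: str = "id") -> None:
    cols = [c for c in ("chrom", "pos", "strand") if c in info.columns]
    out = info[cols].copy()
    if "strand" not in out.columns:
        out["strand"] = "+"
    out.to_csv(path, sep="\t", index_label=id_label)


def read_positions_tsv(path, id_label: str = "id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_genotypes_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF with GT (rounded) and DS fields."""
    info = geno.snp_info
    samples = list(geno.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in pd.unique(info["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        D = geno.dosages.to_numpy(dtype=float)
        order = info.sort_values(["chrom", "pos"], kind="stable").index
        col = {s: j for j, s in enumerate(geno.snp_ids)}
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for snp in order:
            j = col[snp]
            row = info.loc[snp]
            fields = []
            for i in range(len(samples)):
                ds = D[i, j]
                if np.isnan(ds):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[int(round(ds))]}:{ds:.6g}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row.get('ref', 'A')}\t"
                f"{row.get('alt', 'G')}\t.\tPASS\t.\tGT:DS\t" + "\t".join(fields) + "\n"
            )


def read_genotypes(path, dialect: str = "tsv", positions: pd.DataFrame | None = None,
                   skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Load a GenotypeMatrix from VCF or TSV dosage file.

    For VCF, the DS field is preferred and GT (allele-count sum) is the
    fallback; multi-allelic records are skipped (or an error is raised
    when ``skip_multiallelic`` is false). For TSV, SNP metadata comes
    from ``positions`` (index = SNP id, columns chrom/pos) when given.
    """
    if dialect == "tsv":
        dos = pd.read_csv(path, sep="\t", index_col=0)
        if positions is not None:
            info = positions.loc[dos.columns].copy()
        else:
            info = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, dos.shape[1] + 1)},
                                index=dos.columns)
        if "maf" not in info.columns:
            info["maf"] = folded_maf(dos.mean(axis=0).to_numpy() / 2.0)
        for c, v in (("ref", "A"), ("alt", "G")):
            if c not in info.columns:
                info[c] = v
        return GenotypeMatrix(dos, info)
    if dialect != "vcf":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts = [], [], [], [], []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                logger.warning("skipping multi-allelic record %s", var.ID or var.POS)
                continue
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        ds = None
        try:
            fmt = var.format("DS")
            if fmt is not None:
                ds = np.asarray(fmt, dtype=float).reshape(-1)
        except KeyError:
            ds = None
        if ds is None:
            gts = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, gts.clip(0).sum(axis=1)).astype(float)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        columns.append(ds)
    dos = pd.DataFrame(np.column_stack(columns), index=samples, columns=snp_ids)
    info = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
                        index=snp_ids)
    info["maf"] = folded_maf(dos.mean(axis=0).to_numpy() / 2.0)
    return GenotypeMatrix(dos, info)


def write_methylation(meth: MethylationMatrix, path) -> None:
    meth.values.to_csv(path, sep="\t", index_label="sample", float_format="%.8g")


def read_methylation(path, positions: pd.DataFrame, stage: str = "raw") -> MethylationMatrix:
    vals = pd.read_csv(path, sep="\t", index_col=0)
    return MethylationMatrix(vals, positions.loc[vals.columns], stage=stage)


def write_covariates(covars: CovariateTable, path) -> None:
    covars.table.to_csv(path, sep="\t", index_label="sample")


def read_covariates(path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t", index_col=0))


def write_pedigree(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, sep="\t", index_label="sample")


def read_pedigree(path) -> Pedigree:
    return Pedigree(pd.read_csv(path, sep="\t", index_col=0))


def read_bed_track(path, name: str | None = None) -> AnnotationTrack:
    """Load a BED3(+) file as an AnnotationTrack (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return AnnotationTrack(name or Path(path).stem, df[["chrom", "start", "end"]])


def write_bed_track(track: AnnotationTrack, path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t", float_format="%.8g")
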