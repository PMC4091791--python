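"""Readers and writers for the package's text formats.

Genotypes travel either as a VCF with a per-sample dosage FORMAT field
(``DS``) or as a TSV dialect: four metadata columns (``variant_id``,
``chromosome``, ``position``, ``variant_type``) followed by one dosage
column per sample, the header carrying the sample ids.  Expression is a
probes x samples TSV (first column ``probe_id``); probe annotation is a
BED-like TSV.  All floats are serialized with 10 significant digits,
which round-trips the analysis losslessly at output precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    CNV,
    SNP,
    ExpressionMatrix,
    GenotypeTable,
    NO_GENE_DISTANCE,
    ProbeAnnotation,
    cnv_maf,
    snp_maf,
)

_FLOAT_FMT = "%.10g"

_GENO_META = ["variant_id", "chromosome", "position", "variant_type"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotype_table(path: str, format: str = "tsv") -> GenotypeTable:
    """Load a genotype table from ``tsv`` or ``vcf_dosage`` format.

    MAF is always recomputed from the dosages on load: SNPs as
    min(mean/2, 1-mean/2), CNVs as the pooled frequency of non-modal
    rounded copy classes.
    """
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf_dosage":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {format!r} (tsv, vcf_dosage)")


def _read_genotype_tsv(path: str) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_GENO_META)] != _GENO_META:
            raise ValueError(
                f"{path}: header must start with {_GENO_META}, got {header[:4]}"
            )
        sample_ids = header[len(_GENO_META):]
        if not sample_ids:
            raise ValueError(f"{path}: no sample columns in header")
        meta_rows, dose_rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            vid, chrom, pos, vtype = fields[:4]
            if vtype not in (SNP, CNV):
                raise ValueError(f"{path}:{lineno}: bad variant_type {vtype!r}")
            try:
                position = int(pos)
                dose = np.array([float(x) for x in fields[4:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if vtype == SNP and (dose.min() < 0 or dose.max() > 2):
                raise ValueError(
                    f"{path}:{lineno}: SNP dosage outside [0, 2] for {vid}"
                )
            meta_rows.append((vid, chrom, position, vtype))
            dose_rows.append(dose)
    if not meta_rows:
        raise ValueError(f"{path}: no variants")
    variants = pd.DataFrame(meta_rows, columns=_GENO_META)
    dosages = np.vstack(dose_rows)
    variants["maf"] = _compute_maf(variants["variant_type"], dosages)
    return GenotypeTable(variants=variants, dosages=dosages, sample_ids=sample_ids)


def _read_genotype_vcf(path: str) -> GenotypeTable:
    """Read dosages from the ``DS`` FORMAT field of a VCF.

    Variants with an ``SVTYPE`` INFO entry (or a ``<CNV>`` ALT) are
    treated as CNVs; everything else as a biallelic SNP.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    meta_rows, dose_rows = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        is_cnv = rec.INFO.get("SVTYPE") is not None or "<CNV>" in (rec.ALT or [])
        dose = rec.format("DS")
        if dose is None:
            raise ValueError(f"{path}: record {vid} lacks a DS dosage field")
        dose = np.asarray(dose, dtype=float).reshape(-1)
        vtype = CNV if is_cnv else SNP
        if vtype == SNP and (dose.min() < 0 or dose.max() > 2):
            raise ValueError(f"{path}: SNP dosage outside [0, 2] for {vid}")
        meta_rows.append((vid, rec.CHROM, rec.POS, vtype))
        dose_rows.append(dose)
    if not meta_rows:
        raise ValueError(f"{path}: no variants")
    variants = pd.DataFrame(meta_rows, columns=_GENO_META)
    ids = variants["variant_id"]
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate variant_id {ids[ids.duplicated()].iloc[0]!r}")
    dosages = np.vstack(dose_rows)
    variants["maf"] = _compute_maf(variants["variant_type"], dosages)
    return GenotypeTable(variants=variants, dosages=dosages, sample_ids=sample_ids)


def _compute_maf(vtypes: pd.Series, dosages: np.ndarray) -> np.ndarray:
    return np.array([
        snp_maf(dosages[i]) if t == SNP else cnv_maf(dosages[i])
        for i, t in enumerate(vtypes)
    ])


def write_genotype_table(geno: GenotypeTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENO_META + list(geno.sample_ids)) + "\n")
        for i in range(geno.n_variants):
            row = geno.variants.iloc[i]
            dose = "\t".join(_FLOAT_FMT % d for d in geno.dosages[i])
            fh.write(
                f"{row.variant_id}\t{row.chromosome}\t{row.position}\t"
                f"{row.variant_type}\t{dose}\n"
            )


def write_genotype_vcf(geno: GenotypeTable, path: str) -> None:
    """Write a minimal VCF with dosages in the DS FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for i in range(geno.n_variants):
            row = geno.variants.iloc[i]
            if row.variant_type == CNV:
                alt, info = "<CNV>", "SVTYPE=CNV"
            else:
                alt, info = "G", "."
            dose = "\t".join(_FLOAT_FMT % d for d in geno.dosages[i])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.variant_id}\tA\t{alt}"
                f"\t.\t.\t{info}\tDS\t{dose}\n"
            )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "probe_id":
            raise ValueError(f"{path}: first header column must be 'probe_id'")
        sample_ids = header[1:]
        probe_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            probe_ids.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not probe_ids:
        raise ValueError(f"{path}: no probes")
    values = pd.DataFrame(rows, index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    return ExpressionMatrix(values=values)


def write_expression_matrix(expr: ExpressionMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\t" + "\t".join(expr.sample_ids) + "\n")
        mat = expr.matrix()
        for pid, row in zip(expr.probe_ids, mat):
            fh.write(pid + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["chromosome", "tss", "probe_id", "gene_id",
               "contains_common_snp", "multi_mapped"]


def read_probe_annotation(path: str) -> ProbeAnnotation:
    """BED-like TSV: chrom, tss, probe_id, gene_id, contains_common_snp, multi_mapped."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["contains_common_snp"] = df["contains_common_snp"].astype(int).astype(bool)
    df["multi_mapped"] = df["multi_mapped"].astype(int).astype(bool)
    df["tss"] = df["tss"].astype(int)
    df["chromosome"] = df["chromosome"].astype(str)
    return ProbeAnnotation(table=df[["probe_id", "gene_id", "chromosome", "tss",
                                     "contains_common_snp", "multi_mapped"]])


def write_probe_annotation(annot: ProbeAnnotation, path: str) -> None:
    df = annot.table.copy()
    df["contains_common_snp"] = df["contains_common_snp"].astype(int)
    df["multi_mapped"] = df["multi_mapped"].astype(int)
    df[_ANNOT_COLS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# derived variant metadata
# ---------------------------------------------------------------------------

def distance_to_closest_gene(
    position: int, chromosome: str, annot: ProbeAnnotation
) -> float:
    """Distance (bp) from a position to the nearest annotated TSS on the
    same chromosome; +inf if the chromosome carries no annotated gene."""
    tss = annot.table.loc[annot.table["chromosome"] == str(chromosome), "tss"]
    if tss.empty:
        return NO_GENE_DISTANCE
    return float(np.abs(tss.to_numpy() - int(position)).min())


def distances_to_closest_gene(geno: GenotypeTable, annot: ProbeAnnotation) -> np.ndarray:
    """Vectorized :func:`distance_to_closest_gene` over a genotype table."""
    out = np.empty(geno.n_variants)
    # one gene per gene_id: distance is to the nearest TSS of any gene
    by_chrom = {
        chrom: np.sort(sub["tss"].to_numpy())
        for chrom, sub in annot.table.groupby("chromosome")
    }
    for i, (chrom, pos) in enumerate(
        zip(geno.variants["chromosome"], geno.variants["position"])
    ):
        tss = by_chrom.get(str(chrom))
        if tss is None or len(tss) == 0:
            out[i] = NO_GENE_DISTANCE
            continue
        j = np.searchsorted(tss, pos)
        best = np.inf
        if j < len(tss):
            best = min(best, abs(int(tss[j]) - pos))
        if j > 0:
            best = min(best, abs(int(tss[j - 1]) - pos))
        out[i] = best
    return out
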