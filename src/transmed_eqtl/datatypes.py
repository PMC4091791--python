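"""Core in-memory containers shared by every analysis stage.

Genotypes are stored as per-sample additive dosages: expected alternate
allele count in [0, 2] for SNPs, or a (possibly continuous) copy-number
dose for CNVs.  Both variant classes flow through the same rank-based
statistics, so the dosage abstraction is the only genotype encoding the
package ever uses.  Coordinates are 1-based and windows are closed on
both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SNP = "SNP"
CNV = "CNV"

#: Sentinel distance for a variant on a chromosome with no annotated gene.
NO_GENE_DISTANCE = np.inf


def snp_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from additive dosages in [0, 2]."""
    f = float(np.mean(dosages)) / 2.0
    return min(f, 1.0 - f)


def cnv_maf(dosages: np.ndarray) -> float:
    """CNV 'MAF': frequency of the less common rounded copy-number class.

    CNV allele frequency is not well defined for a continuous dose, so the
    dose is rounded to integer copy classes and the frequency of all
    non-modal classes pooled (capped at 0.5) is reported.
    """
    classes, counts = np.unique(np.rint(np.asarray(dosages)), return_counts=True)
    if len(classes) == 1:
        return 0.0
    minor = 1.0 - counts.max() / counts.sum()
    return min(float(minor), 0.5)


@dataclass
class GenotypeTable:
    """Variants x samples dosage matrix plus per-variant metadata.

    ``variants`` holds one row per variant with columns ``variant_id``,
    ``chromosome``, ``position`` (1-based bp), ``variant_type`` (SNP/CNV)
    and ``maf``; row order matches the rows of ``dosages``.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    # -- views ---------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant_id {variant_id!r}")
        return int(idx[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[self.index_of(variant_id)]

    def subset_variants(self, variant_ids: Iterable[str]) -> "GenotypeTable":
        wanted = list(variant_ids)
        pos = {v: i for i, v in enumerate(self.variants["variant_id"])}
        rows = [pos[v] for v in wanted]
        return GenotypeTable(
            variants=self.variants.iloc[rows].reset_index(drop=True),
            dosages=self.dosages[rows],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in sample_ids]
        return GenotypeTable(
            variants=self.variants.copy(),
            dosages=self.dosages[:, cols],
            sample_ids=list(sample_ids),
        )

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.dosages.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.sample_ids)} samples"
            )
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant_id {dup!r}")
        if np.isnan(self.dosages).any():
            raise ValueError("missing dosages are not supported")
        is_snp = (self.variants["variant_type"] == SNP).to_numpy()
        if is_snp.any():
            snp_dose = self.dosages[is_snp]
            if snp_dose.min() < 0 or snp_dose.max() > 2:
                raise ValueError("SNP dosages must lie within [0, 2]")

    def computed_maf(self) -> np.ndarray:
        out = np.empty(self.n_variants)
        for i, vtype in enumerate(self.variants["variant_type"]):
            row = self.dosages[i]
            out[i] = snp_maf(row) if vtype == SNP else cnv_maf(row)
        return out


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values with a probe-to-gene map."""

    values: pd.DataFrame  # index: probe_id, columns: sample_ids
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id {dup!r}")
        if self.values.isna().any().any():
            raise ValueError("missing expression values are not supported")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], dict(self.probe_to_gene))

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = list(probe_ids)
        return ExpressionMatrix(
            self.values.loc[keep],
            {p: g for p, g in self.probe_to_gene.items() if p in set(keep)},
        )


@dataclass
class ProbeAnnotation:
    """One annotation row per probe: genomic anchor and QC flags.

    ``contains_common_snp`` marks probes whose sequence overlaps a common
    SNP (excluded from cis scans); ``multi_mapped`` marks probes mapping
    to multiple genomic locations (excluded from trans scans).
    """

    table: pd.DataFrame  # probe_id, gene_id, chromosome, tss, contains_common_snp, multi_mapped

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id", "chromosome", "tss",
                    "contains_common_snp", "multi_mapped"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            dup = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id {dup!r}")
        if (self.table["tss"] < 1).any():
            raise ValueError("tss must be >= 1 (1-based coordinates)")
        self.table = self.table.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def row_for(self, probe_id: str) -> pd.Series:
        sub = self.table[self.table["probe_id"] == probe_id]
        if sub.empty:
            raise KeyError(f"probe {probe_id!r} not annotated")
        return sub.iloc[0]

    def join_check(self, expr: ExpressionMatrix) -> None:
        """Every probe in the expression matrix must be annotated exactly once."""
        missing = set(expr.probe_ids) - set(self.table["probe_id"])
        if missing:
            raise ValueError(
                f"{len(missing)} expression probes lack annotation, "
                f"e.g. {sorted(missing)[:3]}"
            )


@dataclass(frozen=True)
class AssociationRecord:
    """A single variant-probe Spearman test."""

    variant_id: str
    probe_id: str
    rho: float
    p: float
    n: int
    scope: str  # "cis" | "trans"


def intersect_samples(
    geno: GenotypeTable, expr: ExpressionMatrix
) -> tuple[GenotypeTable, ExpressionMatrix]:
    """Restrict both tables to shared samples, in genotype-table order.

    Ordering by the genotype table makes the result independent of the
    expression file's column order.
    """
    shared = [s for s in geno.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise ValueError("genotype and expression tables share no samples")
    return geno.subset_samples(shared), expr.subset_samples(shared)
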