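"""Conditional regression for independent cis-eQTLs and heritability accounting.

A gene's primary cis-eQTL rarely exhausts the local genetic signal.  To
find additional independent signals, the standard-normalized expression
is regressed jointly on all previously accepted variants' dosages, the
residuals are re-scanned over the cis window with Spearman rank
correlation, and the best variant is accepted while it passes the gene's
permutation threshold from the primary analysis.  Variance explained by
the accepted variants, divided by the gene's heritability (capped at 1),
gives the fraction of heritable expression variance the cis signals
account for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import CIS_HALF_WINDOW, cis_window_mask, p_from_rho, rank_standardize_rows
from .datatypes import ExpressionMatrix, GenotypeTable, ProbeAnnotation, intersect_samples
from .preprocess import standard_normalize

COLLINEARITY_R2 = 0.999


@dataclass
class EqtlCall:
    """Ordered independent cis-eQTLs for one gene (discovery order)."""

    gene: str
    probe_id: str
    variant_ids: list[str] = field(default_factory=list)
    rhos: list[float] = field(default_factory=list)
    pvalues: list[float] = field(default_factory=list)
    gene_threshold: float = 0.0

    @property
    def n_independent(self) -> int:
        return len(self.variant_ids)


@dataclass
class HeritabilityRecord:
    gene: str
    r2_best: float
    r2_all: float
    h2: float
    herit_explained_best: float
    herit_explained_all: float


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, X]."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def variance_explained(expr_std: np.ndarray, dosages: np.ndarray) -> float:
    """Coefficient of determination of expression on one or more dosages."""
    y = np.asarray(expr_std, dtype=float)
    X = np.atleast_2d(np.asarray(dosages, dtype=float))
    if X.shape[0] == y.size and X.ndim == 2 and X.shape[1] != y.size:
        X = X.T  # accept samples-in-rows layout
    k = X.shape[0]
    n = y.size
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    design = np.column_stack([np.ones(n), X.T])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("constant response")
    return float(1.0 - np.sum(resid**2) / tss)


def heritability_explained(r2: float, h2: float) -> float:
    """min(r2 / h2, 1): fraction of heritable variance explained.

    Variance explained exceeding the (independently estimated)
    heritability is capped at 1.  With h2 = 0, any positive r2 also
    reports 1, and r2 = 0 reports 0.
    """
    if not (0 <= r2 <= 1) or not (0 <= h2 <= 1):
        raise ValueError("r2 and h2 must lie in [0, 1]")
    if h2 == 0:
        return 1.0 if r2 > 0 else 0.0
    return min(r2 / h2, 1.0)


def conditional_scan(
    gene: str,
    geno: GenotypeTable,
    expr: ExpressionMatrix,
    annot: ProbeAnnotation,
    gene_threshold: float,
    half_window: int = CIS_HALF_WINDOW,
    max_iter: int | None = None,
) -> EqtlCall:
    """Iteratively call independent cis-eQTLs for one gene.

    Each round regresses the standard-normalized expression on all
    accepted dosages jointly, Spearman-scans the residuals over the cis
    window, and accepts the best variant while its p stays below
    ``gene_threshold`` (the gene's permutation threshold from the primary
    analysis, reused verbatim for every round).  The first round's best
    variant is accepted unconditionally: this scan is only run for genes
    whose primary eQTL already passed FDR control.  Variants nearly
    collinear (r^2 > 0.999) with the accepted set are never accepted.
    """
    geno, expr = intersect_samples(geno, expr)
    prow = None
    for _, row in annot.table.iterrows():
        if row["gene_id"] == gene or row["probe_id"] == gene:
            prow = row
            break
    if prow is None:
        raise KeyError(f"gene {gene!r} not in annotation")
    mask = cis_window_mask(geno.variants, prow["chromosome"], prow["tss"], half_window)
    if not mask.any():
        return EqtlCall(gene=gene, probe_id=prow["probe_id"],
                        gene_threshold=gene_threshold)
    window_idx = np.flatnonzero(mask)
    window_dose = geno.dosages[window_idx]
    window_ids = geno.variants["variant_id"].to_numpy()[window_idx]
    g_ranks = rank_standardize_rows(window_dose)
    n = geno.n_samples

    y = standard_normalize(expr.values.loc[prow["probe_id"]].to_numpy())
    call = EqtlCall(gene=gene, probe_id=prow["probe_id"],
                    gene_threshold=gene_threshold)
    accepted_rows: list[int] = []
    limit = max_iter if max_iter is not None else len(window_idx)

    for _ in range(limit):
        resid = _residualize(y, window_dose[accepted_rows].T) if accepted_rows else y
        if np.ptp(resid) == 0:
            break
        ry = rank_standardize_rows(resid)[0]
        rho = np.clip(g_ranks @ ry, -1.0, 1.0)
        order = np.argsort(-np.abs(rho))
        best = None
        for j in order:
            if j in accepted_rows:
                continue
            if accepted_rows:
                r2 = variance_explained(
                    (window_dose[j] - window_dose[j].mean())
                    / max(window_dose[j].std(), np.finfo(float).tiny),
                    window_dose[accepted_rows],
                )
                if r2 > COLLINEARITY_R2:
                    continue
            best = j
            break
        if best is None:
            warnings.warn(
                f"{gene}: remaining window variants collinear with accepted set",
                stacklevel=2,
            )
            break
        p = p_from_rho(float(rho[best]), n)
        # the primary eQTL already passed FDR control upstream; the gene
        # threshold gates only the conditional (secondary) rounds
        if accepted_rows and p >= gene_threshold:
            break
        accepted_rows.append(best)
        call.variant_ids.append(str(window_ids[best]))
        call.rhos.append(float(rho[best]))
        call.pvalues.append(float(p))
    return call


def heritability_record(
    gene: str,
    expr_std: np.ndarray,
    best_dosage: np.ndarray,
    all_dosages: np.ndarray,
    h2: float,
) -> HeritabilityRecord:
    r2_best = variance_explained(expr_std, best_dosage)
    r2_all = variance_explained(expr_std, all_dosages)
    return HeritabilityRecord(
        gene=gene,
        r2_best=r2_best,
        r2_all=r2_all,
        h2=h2,
        herit_explained_best=heritability_explained(max(r2_best, 0.0), h2),
        herit_explained_all=heritability_explained(max(r2_all, 0.0), h2),
    )


def allelic_concordance(
    main_dosage: np.ndarray,
    secondary_dosage: np.ndarray,
    cis_expr: np.ndarray,
    trans_expr: np.ndarray,
) -> bool:
    """Do two independent cis-eQTLs push the trans gene the same way?

    Each variant's dosage is oriented so that it increases cis
    expression.  The main variant's trans effect sign is then compared
    with the secondary variant's sign on the trans expression
    residualized on the main dosage.  Returns True when the
    cis-increasing alleles agree in their trans direction.
    """
    g1 = np.asarray(main_dosage, dtype=float)
    g2 = np.asarray(secondary_dosage, dtype=float)
    c = np.asarray(cis_expr, dtype=float)
    t = np.asarray(trans_expr, dtype=float)

    def orient(g):
        rho = np.corrcoef(g, c)[0, 1]
        if not np.isfinite(rho) or abs(rho) < 1e-12:
            raise ValueError("undefined direction: no cis effect")
        return g if rho > 0 else -g

    g1o, g2o = orient(g1), orient(g2)
    if np.allclose(g1o, g2o):
        return True  # same oriented variant: trivially concordant
    s_main = np.corrcoef(g1o, t)[0, 1]
    t_resid = _residualize(t, g1o[:, None])
    s_sec = np.corrcoef(g2o, t_resid)[0, 1]
    if abs(s_main) < 1e-12 or abs(s_sec) < 1e-12:
        raise ValueError("undefined direction: zero trans effect")
    return bool(np.sign(s_main) == np.sign(s_sec))
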