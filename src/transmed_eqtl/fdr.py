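"""Permutation null distributions and FDR threshold selection.

Two null schemes are used.  For cis scans the null is gene-based: sample
labels of the expression matrix are permuted (one shared permutation per
round, preserving inter-probe correlation), the cis scan is re-run and
the minimum p per probe recorded; ranking these minima yields per-gene
thresholds.  For trans scans the null is genome-wide: a set of probes is
permuted and scanned, and all per-probe-per-permutation minimum p-values
are pooled into a single reference distribution whose quantiles are swept
as genome-wide thresholds.

In both cases the expected number of false discoveries at rank r (or
threshold tau) uses the standard permutation convention with an (n_perm
+ 1) denominator, and the selected threshold is the most permissive one
whose estimated FDR stays at or below the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import (
    CIS_HALF_WINDOW,
    TRANS_EXCLUSION,
    ScanResult,
    cis_window_mask,
    p_from_rho,
    rank_standardize_rows,
    trans_mask,
    _eligible_probes,
)
from .datatypes import ExpressionMatrix, GenotypeTable, ProbeAnnotation, intersect_samples


@dataclass
class CisNull:
    """Per-probe sorted vectors of permuted best (minimum) p-values."""

    min_p: dict[str, np.ndarray]  # probe -> ascending vector, length n_perm
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        for probe, vec in self.min_p.items():
            if len(vec) != self.n_perm:
                raise ValueError(f"null vector for {probe} has wrong length")


@dataclass
class TransNull:
    """Pooled sorted minimum p-values across probes and permutations."""

    pooled: np.ndarray  # ascending, length n_probes * n_perm
    n_probes: int
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.pooled) != self.n_probes * self.n_perm:
            raise ValueError("pooled null has wrong length")


@dataclass
class ThresholdResult:
    """Selected permutation threshold and the discoveries it admits."""

    threshold: dict[str, float] | float  # per-probe (cis) or genome-wide (trans)
    discoveries: set[str]               # probe ids
    achieved_fdr: float
    rank_used: int
    records: pd.DataFrame | None = None  # trans: individual records passing


# ---------------------------------------------------------------------------
# cis null
# ---------------------------------------------------------------------------

def cis_permutation_null(
    geno: GenotypeTable,
    expr: ExpressionMatrix,
    annot: ProbeAnnotation,
    n_perm: int = 1000,
    seed: int = 0,
    half_window: int = CIS_HALF_WINDOW,
) -> CisNull:
    """Best permuted cis p-value per probe over ``n_perm`` label permutations.

    One sample-label permutation is drawn per round and applied to every
    probe, so the null preserves correlation between probes.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable permutation thresholds",
                      stacklevel=2)
    geno, expr = intersect_samples(geno, expr)
    n = geno.n_samples
    probes = _eligible_probes(expr, annot, "cis")
    g_ranks = rank_standardize_rows(geno.dosages)
    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])  # n_perm x n

    min_p: dict[str, np.ndarray] = {}
    for _, prow in probes.iterrows():
        mask = cis_window_mask(geno.variants, prow.chromosome, prow.tss, half_window)
        if not mask.any():
            continue
        ry = rank_standardize_rows(expr.values.loc[prow.probe_id].to_numpy())[0]
        # columns: the probe's rank vector under each permutation
        permuted = ry[perm_idx].T                       # n x n_perm
        rho = g_ranks[mask] @ permuted                  # m x n_perm
        max_abs_rho = np.clip(np.abs(rho).max(axis=0), 0.0, 1.0)
        min_p[prow.probe_id] = np.sort(p_from_rho(max_abs_rho, n))
    return CisNull(min_p=min_p, n_perm=n_perm, seed=seed)


def cis_fdr_select(
    observed: ScanResult, null: CisNull, target_fdr: float = 0.05
) -> ThresholdResult:
    """Pick the most permissive per-gene permutation rank controlling FDR.

    At rank r the per-probe threshold is the r-th smallest null minimum;
    a probe is discovered when its observed best p falls below its own
    threshold.  Expected false discoveries at rank r are G*r/(n_perm+1)
    over G tested probes; the largest r with estimated FDR <= target is
    returned (r = 0 and an empty set when none qualifies).
    """
    best_p = observed.best_p_per_probe()
    probes = [p for p in best_p.index if p in null.min_p]
    missing = set(best_p.index) - set(probes)
    if missing:
        raise ValueError(f"null does not cover {len(missing)} observed probes")
    if not probes:
        return ThresholdResult({}, set(), 0.0, 0)
    G = len(probes)
    obs = best_p.loc[probes].to_numpy()
    null_mat = np.vstack([null.min_p[p] for p in probes])  # G x n_perm (sorted rows)
    n_perm = null.n_perm

    # D(r) for all ranks at once: count observed below the r-th order statistic
    below = obs[:, None] < null_mat                         # G x n_perm
    D = below.sum(axis=0).astype(float)                     # D(r) for r = 1..n_perm
    ranks = np.arange(1, n_perm + 1)
    E = G * ranks / (n_perm + 1)
    fdr = E / np.maximum(D, 1.0)
    ok = np.flatnonzero(fdr <= target_fdr)
    if ok.size == 0:
        return ThresholdResult({p: 0.0 for p in probes}, set(), 0.0, 0)
    r = int(ok[-1]) + 1
    thresholds = {p: float(null_mat[i, r - 1]) for i, p in enumerate(probes)}
    disc = {p for i, p in enumerate(probes) if obs[i] < null_mat[i, r - 1]}
    return ThresholdResult(thresholds, disc, float(fdr[r - 1]), r)


# ---------------------------------------------------------------------------
# trans null
# ---------------------------------------------------------------------------

def trans_permutation_null(
    geno: GenotypeTable,
    expr: ExpressionMatrix,
    annot: ProbeAnnotation,
    n_probes: int | None = 288,
    n_perm: int = 1000,
    seed: int = 0,
    exclusion: int = TRANS_EXCLUSION,
) -> TransNull:
    """Pooled genome-wide minimum p-values from permuted trans scans.

    ``n_probes`` probes (one per gene) are sampled; each is scanned
    against its eligible trans variants under ``n_perm`` label
    permutations and its genome-wide minimum p recorded.  Because every
    probe faces approximately the same number of variants, the pooled
    n_probes * n_perm minima act as a single reference null.  Pass
    ``n_probes=None`` to permute every eligible probe (used for the
    trans-of-cis analysis).
    """
    geno, expr = intersect_samples(geno, expr)
    n = geno.n_samples
    probes = _eligible_probes(expr, annot, "trans")
    rng = np.random.default_rng(seed)

    if n_probes is None:
        chosen = probes
    else:
        # one probe per gene, then sample genes without replacement
        one_per_gene = probes.groupby("gene_id", sort=True).head(1)
        if len(one_per_gene) < n_probes:
            raise ValueError(
                f"only {len(one_per_gene)} eligible genes for {n_probes} requested"
            )
        pick = rng.choice(len(one_per_gene), size=n_probes, replace=False)
        chosen = one_per_gene.iloc[np.sort(pick)].reset_index(drop=True)

    g_ranks = rank_standardize_rows(geno.dosages)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])

    minima = []
    for _, prow in chosen.iterrows():
        mask = trans_mask(geno.variants, prow.chromosome, prow.tss, exclusion)
        if not mask.any():
            continue
        ry = rank_standardize_rows(expr.values.loc[prow.probe_id].to_numpy())[0]
        permuted = ry[perm_idx].T
        rho = g_ranks[mask] @ permuted
        max_abs_rho = np.clip(np.abs(rho).max(axis=0), 0.0, 1.0)
        minima.append(p_from_rho(max_abs_rho, n))
    pooled = np.sort(np.concatenate(minima))
    return TransNull(pooled=pooled, n_probes=len(minima), n_perm=n_perm, seed=seed)


def trans_fdr_select(
    observed: ScanResult,
    null: TransNull,
    n_probes_tested: int,
    target_fdr: float = 0.05,
) -> ThresholdResult:
    """Sweep the pooled null for the largest genome-wide p threshold with
    estimated FDR <= target.

    At threshold tau the expected false discoveries are the null
    exceedance fraction times the number of probes tested; discoveries
    are probes whose observed minimum p is <= tau.  The returned tau is
    always an element of the pooled null (or 0 when nothing qualifies),
    and all records with p <= tau are attached.
    """
    best_p = observed.best_p_per_probe()
    obs = np.sort(best_p.to_numpy())
    pooled = null.pooled
    M = len(pooled)

    # candidate thresholds: each pooled null value
    counts_null = np.arange(1, M + 1, dtype=float)          # #null <= pooled[k]
    E = counts_null / M * n_probes_tested
    D = np.searchsorted(obs, pooled, side="right").astype(float)
    fdr = E / np.maximum(D, 1.0)
    ok = np.flatnonzero(fdr <= target_fdr)
    if ok.size == 0:
        empty = observed.records.iloc[0:0]
        return ThresholdResult(0.0, set(), 0.0, 0, records=empty)
    k = int(ok[-1])
    tau = float(pooled[k])
    disc = set(best_p.index[best_p.to_numpy() <= tau])
    recs = observed.records[observed.records["p"] <= tau].reset_index(drop=True)
    return ThresholdResult(tau, disc, float(fdr[k]), k + 1, records=recs)
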