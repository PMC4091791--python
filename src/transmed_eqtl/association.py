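"""Spearman rank association engine with cis/trans scan geometry.

Every association in the package is a Spearman rank correlation between
a variant's dosage and a probe's expression, with the two-sided p-value
taken from the t-distribution approximation
``t = rho * sqrt((n-2) / (1 - rho^2))`` on ``n - 2`` degrees of freedom.
Ties (ubiquitous in SNP dosages) receive average ranks, making rho the
Pearson correlation of mid-ranks.

Scan geometry: a *cis* test pairs a probe with variants within a closed
window of ``half_window`` bp around its TSS (default 1 Mb, i.e. a 2 Mb
window); a *trans* test pairs it with variants on another chromosome or
strictly farther than ``exclusion`` bp (default 5 Mb) from the TSS.  The
1-5 Mb band on the same chromosome is deliberately tested by neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CNV,
    SNP,
    AssociationRecord,
    ExpressionMatrix,
    GenotypeTable,
    ProbeAnnotation,
    intersect_samples,
)

CIS_HALF_WINDOW = 1_000_000
TRANS_EXCLUSION = 5_000_000

_RECORD_COLS = ["variant_id", "probe_id", "rho", "p", "n", "scope"]


# ---------------------------------------------------------------------------
# primitive test
# ---------------------------------------------------------------------------

def rank_standardize_rows(mat: np.ndarray) -> np.ndarray:
    """Average-rank each row, center it and scale to unit Euclidean norm.

    After this transform the Spearman rho of rows i of A and j of B is
    simply ``A[i] @ B[j]``.  Constant rows raise (rho undefined).
    """
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    ranks = stats.rankdata(mat, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("constant vector: Spearman correlation undefined")
    return ranks / norms


def p_from_rho(rho, n: int):
    """Two-sided p-value of Spearman rho via the t approximation.

    ``|rho| = 1`` is reported as the smallest positive normal float
    rather than zero.
    """
    rho = np.asarray(rho, dtype=float)
    sat = np.abs(rho) >= 1.0
    safe = np.where(sat, 0.0, rho)
    t = safe * np.sqrt((n - 2) / (1.0 - safe**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(sat, np.finfo(float).tiny, p)
    return p if p.ndim else float(p)


def _t_log_sf_tail(t: float, df: float) -> float:
    """log of the Student-t survival function, stable deep in the tail.

    Uses sf(t) = 0.5 * I_x(df/2, 1/2) with x = df/(df + t^2) and the
    small-x series of the regularized incomplete beta (A&S 26.5.4),
    evaluated in log space, so it never underflows.
    """
    from scipy.special import betaln

    a, b = df / 2.0, 0.5
    x = df / (df + t * t)
    # series 1 + sum_{n>=0} [B(a+1, n+1)/B(a+b, n+1)] x^{n+1}
    term = (a + b) / (a + 1.0) * x
    total = 1.0 + term
    nn = 0.0
    while term > 1e-16 * total and nn < 10_000:
        term *= (a + b + nn + 1.0) / (a + nn + 2.0) * x
        total += term
        nn += 1.0
    return (np.log(0.5) + a * np.log(x) + b * np.log1p(-x)
            - np.log(a) - betaln(a, b) + np.log(total))


def neglog10_p_from_rho(rho: float, n: int) -> float:
    """-log10 of the two-sided t-approximation p-value, in log space.

    Stays accurate far below the double-precision underflow limit
    (|t| up to ~60 corresponds to -log10 p in the hundreds).
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1 for the t approximation")
    if n < 4:
        raise ValueError("need n >= 4")
    t = abs(rho) * np.sqrt((n - 2) / (1.0 - rho**2))
    log_sf = stats.t.logsf(t, df=n - 2)
    if not np.isfinite(log_sf):  # scipy underflows around |t| ~ 40
        log_sf = _t_log_sf_tail(t, n - 2)
    log_p = np.log(2.0) + log_sf
    return float(-log_p / np.log(10.0))


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho, two-sided p and n for one dosage/expression pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    rx = rank_standardize_rows(x)[0]
    ry = rank_standardize_rows(y)[0]
    rho = float(np.clip(rx @ ry, -1.0, 1.0))
    return rho, p_from_rho(rho, n), n


# ---------------------------------------------------------------------------
# scan results
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """All association records of a scan plus per-probe summaries."""

    records: pd.DataFrame  # columns _RECORD_COLS
    tested_counts: dict[str, int] = field(default_factory=dict)

    @property
    def best_per_probe(self) -> dict[str, AssociationRecord]:
        best: dict[str, AssociationRecord] = {}
        if self.records.empty:
            return best
        idx = self.records.groupby("probe_id")["p"].idxmin()
        for i in idx:
            row = self.records.loc[i]
            best[row["probe_id"]] = AssociationRecord(
                variant_id=row["variant_id"], probe_id=row["probe_id"],
                rho=float(row["rho"]), p=float(row["p"]),
                n=int(row["n"]), scope=row["scope"],
            )
        return best

    def best_p_per_probe(self) -> pd.Series:
        if self.records.empty:
            return pd.Series(dtype=float)
        return self.records.groupby("probe_id")["p"].min()

    def subset_probes(self, probe_ids) -> "ScanResult":
        keep = self.records["probe_id"].isin(set(probe_ids))
        return ScanResult(
            records=self.records[keep].reset_index(drop=True),
            tested_counts={p: c for p, c in self.tested_counts.items()
                           if p in set(probe_ids)},
        )


# ---------------------------------------------------------------------------
# window geometry
# ---------------------------------------------------------------------------

def cis_window_mask(
    variants: pd.DataFrame, chromosome: str, tss: int,
    half_window: int = CIS_HALF_WINDOW,
) -> np.ndarray:
    same = variants["chromosome"].to_numpy() == str(chromosome)
    dist = np.abs(variants["position"].to_numpy() - int(tss))
    return same & (dist <= half_window)


def trans_mask(
    variants: pd.DataFrame, chromosome: str, tss: int,
    exclusion: int = TRANS_EXCLUSION,
) -> np.ndarray:
    other = variants["chromosome"].to_numpy() != str(chromosome)
    dist = np.abs(variants["position"].to_numpy() - int(tss))
    return other | (dist > exclusion)


def _eligible_probes(
    expr: ExpressionMatrix, annot: ProbeAnnotation, scope: str
) -> pd.DataFrame:
    annot.join_check(expr)
    tab = annot.table.set_index("probe_id").loc[list(expr.probe_ids)].reset_index()
    flag = "contains_common_snp" if scope == "cis" else "multi_mapped"
    return tab[~tab[flag]].reset_index(drop=True)


def _scan(
    geno: GenotypeTable, expr: ExpressionMatrix, annot: ProbeAnnotation,
    scope: str, window_param: int,
) -> ScanResult:
    geno, expr = intersect_samples(geno, expr)
    n = geno.n_samples
    if n < 4:
        raise ValueError("need at least 4 shared samples")
    probes = _eligible_probes(expr, annot, scope)
    g_ranks = rank_standardize_rows(geno.dosages)
    e_mat = expr.matrix()
    vids = geno.variants["variant_id"].to_numpy()

    chunks = []
    tested_counts: dict[str, int] = {}
    for _, prow in probes.iterrows():
        if scope == "cis":
            mask = cis_window_mask(geno.variants, prow.chromosome, prow.tss,
                                   window_param)
        else:
            mask = trans_mask(geno.variants, prow.chromosome, prow.tss,
                              window_param)
        if not mask.any():
            continue
        y = expr.values.loc[prow.probe_id].to_numpy()
        ry = rank_standardize_rows(y)[0]
        rho = np.clip(g_ranks[mask] @ ry, -1.0, 1.0)
        p = p_from_rho(rho, n)
        m = int(mask.sum())
        tested_counts[prow.probe_id] = m
        chunks.append(pd.DataFrame({
            "variant_id": vids[mask], "probe_id": prow.probe_id,
            "rho": rho, "p": p, "n": n, "scope": scope,
        }))
    if chunks:
        records = pd.concat(chunks, ignore_index=True)
    else:
        records = pd.DataFrame(columns=_RECORD_COLS)
    return ScanResult(records=records, tested_counts=tested_counts)


def cis_scan(
    geno: GenotypeTable, expr: ExpressionMatrix, annot: ProbeAnnotation,
    half_window: int = CIS_HALF_WINDOW,
) -> ScanResult:
    """Test every probe (without a common SNP in its sequence) against all
    variants within ``half_window`` bp of its TSS on the same chromosome."""
    return _scan(geno, expr, annot, "cis", half_window)


def trans_scan(
    geno: GenotypeTable, expr: ExpressionMatrix, annot: ProbeAnnotation,
    exclusion: int = TRANS_EXCLUSION,
) -> ScanResult:
    """Test every uniquely-mapping probe against all variants on another
    chromosome or farther than ``exclusion`` bp from its TSS."""
    return _scan(geno, expr, annot, "trans", exclusion)


# ---------------------------------------------------------------------------
# CNV trans artifact filter
# ---------------------------------------------------------------------------

def cnv_trans_filter(
    result: ScanResult,
    geno: GenotypeTable,
    annot: ProbeAnnotation,
    sex: np.ndarray | None = None,
    ld_r2: float = 0.1,
    sex_alpha: float | None = None,
) -> tuple[ScanResult, pd.DataFrame]:
    """Remove CNV trans associations that are likely mapping artifacts.

    A CNV-probe record is discarded when (a) the probe lies on the CNV's
    own chromosome, (b) the probe's chromosome harbors a SNP whose dosage
    has squared Pearson correlation > ``ld_r2`` with the CNV (the CNV
    signal may really come from that locus), or (c) the CNV's dosage
    differs between males and females (rank-sum p < ``sex_alpha``), which
    couples it to any sex-differential probe.  ``sex_alpha`` defaults to
    a Bonferroni 0.05 / n_cnvs.  Returns the filtered result and a
    removal log with reason codes.
    """
    records = result.records
    cnv_ids = set(geno.variants.loc[geno.variants["variant_type"] == CNV,
                                    "variant_id"])
    is_cnv_rec = records["variant_id"].isin(cnv_ids)
    if not is_cnv_rec.any():
        return result, pd.DataFrame(columns=["variant_id", "probe_id", "reason"])

    cnvs_in_records = sorted(set(records.loc[is_cnv_rec, "variant_id"]))
    if sex_alpha is None:
        sex_alpha = 0.05 / max(len(cnv_ids), 1)

    # sex imbalance per CNV
    sex_flagged: set[str] = set()
    if sex is not None:
        sex = np.asarray(sex)
        if sex.size != geno.n_samples:
            raise ValueError("sex vector length does not match sample count")
        male = sex == 1
        for cid in cnvs_in_records:
            d = geno.dosage_of(cid)
            if np.ptp(d) == 0:
                continue
            p = stats.mannwhitneyu(d[male], d[~male],
                                   alternative="two-sided").pvalue
            if p < sex_alpha:
                sex_flagged.add(cid)

    # chromosomes with an LD-proxy SNP, per CNV
    snp_mask = (geno.variants["variant_type"] == SNP).to_numpy()
    snp_chroms = geno.variants.loc[snp_mask, "chromosome"].to_numpy()
    snp_dose = geno.dosages[snp_mask]
    snp_centered = snp_dose - snp_dose.mean(axis=1, keepdims=True)
    snp_norm = np.linalg.norm(snp_centered, axis=1)
    ld_chroms: dict[str, set[str]] = {}
    for cid in cnvs_in_records:
        d = geno.dosage_of(cid)
        dc = d - d.mean()
        dn = np.linalg.norm(dc)
        if dn == 0 or snp_dose.size == 0:
            ld_chroms[cid] = set()
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (snp_centered @ dc) / (snp_norm * dn)
        r2 = np.nan_to_num(r) ** 2
        ld_chroms[cid] = set(snp_chroms[r2 > ld_r2])

    probe_chrom = annot.table.set_index("probe_id")["chromosome"].to_dict()
    cnv_chrom = geno.variants.set_index("variant_id")["chromosome"].to_dict()

    reasons = []
    drop = np.zeros(len(records), dtype=bool)
    for i in np.flatnonzero(is_cnv_rec.to_numpy()):
        row = records.iloc[i]
        cid, pid = row["variant_id"], row["probe_id"]
        pchrom = str(probe_chrom[pid])
        if pchrom == str(cnv_chrom[cid]):
            reason = "same_chrom"
        elif pchrom in ld_chroms.get(cid, set()):
            reason = "ld_proxy_snp"
        elif cid in sex_flagged:
            reason = "sex_imbalance"
        else:
            continue
        drop[i] = True
        reasons.append((cid, pid, reason))

    removal_log = pd.DataFrame(reasons, columns=["variant_id", "probe_id", "reason"])
    kept = records[~drop].reset_index(drop=True)
    tested = dict(result.tested_counts)
    return ScanResult(records=kept, tested_counts=tested), removal_log
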