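"""Storey pi1 estimation, replication of eQTL lists, and sharing curves.

pi1 = 1 - pi0 estimates the proportion of true alternatives in a p-value
collection.  It is used three ways: to quantify how much of a discovery
cohort's eQTL list is shared with a second dataset, to trace that
sharing as a function of the second cohort's sample size, and to profile
how many probes a single variant touches in trans (its "trans load")
without calling individual associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .association import TRANS_EXCLUSION, p_from_rho, rank_standardize_rows, spearman_test, trans_mask, _eligible_probes
from .datatypes import ExpressionMatrix, GenotypeTable, ProbeAnnotation, intersect_samples

LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


@dataclass
class Pi1Estimate:
    pi0: float
    pi1: float
    lambda_grid: np.ndarray
    pi0_at_lambda: np.ndarray
    m: int


@lru_cache(maxsize=4)
def _spline_penalty_for_df(grid: tuple[float, ...], df: float = 3.0) -> float:
    """Penalty for a natural cubic smoothing spline with given effective df.

    The effective degrees of freedom are the trace of the linear
    smoother; the penalty is found by bisection on the fixed lambda
    grid, so the smoother matches the heavily-smoothed (df = 3) fit of
    the reference pi0 estimator.
    """
    x = np.asarray(grid)

    def effective_df(alpha: float) -> float:
        tr = 0.0
        for i in range(len(x)):
            e = np.zeros(len(x))
            e[i] = 1.0
            tr += float(make_smoothing_spline(x, e, lam=alpha)(x[i]))
        return tr

    lo, hi = 1e-8, 1e3
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if effective_df(mid) > df:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def storey_pi1(pvalues: np.ndarray) -> Pi1Estimate:
    """Storey's pi1 with natural cubic smoothing-spline pi0(lambda).

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid of
    0.05..0.95; a natural cubic smoothing spline (effective df = 3, as
    in the reference estimator) is evaluated at the largest lambda and
    clamped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 50:
        raise ValueError("need at least 50 p-values for a stable pi1 estimate")
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    lam = LAMBDA_GRID
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    alpha = _spline_penalty_for_df(tuple(lam))
    spline = make_smoothing_spline(lam, pi0_lam, lam=alpha)
    pi0 = float(np.clip(spline(lam[-1]), 0.0, 1.0))
    return Pi1Estimate(pi0=pi0, pi1=1.0 - pi0, lambda_grid=lam,
                       pi0_at_lambda=pi0_lam, m=m)


# ---------------------------------------------------------------------------
# replication of an association list in a second dataset
# ---------------------------------------------------------------------------

@dataclass
class ReplicationSummary:
    table: pd.DataFrame  # variant_id, probe_id, discovery_rho, rho, p, replicated
    n_tested: int
    n_replicated: int          # p < alpha and same rho sign
    n_untestable: int
    frac_opposite_sign: float  # among p < alpha


def replication_test(
    pairs: pd.DataFrame,  # columns: variant_id, probe_id, rho (discovery)
    replication_geno: GenotypeTable,
    replication_expr: ExpressionMatrix,
    alpha: float = 0.05,
) -> ReplicationSummary:
    """Re-test discovered variant-probe pairs in a second cohort.

    A pair replicates when its replication p < ``alpha`` with the same
    rho sign as at discovery.  Pairs whose variant or probe is absent
    from the replication data are counted separately and excluded from
    the denominator.
    """
    geno, expr = intersect_samples(replication_geno, replication_expr)
    have_v = set(geno.variants["variant_id"])
    have_p = set(expr.probe_ids)
    rows = []
    n_untestable = 0
    for _, pair in pairs.iterrows():
        vid, pid = pair["variant_id"], pair["probe_id"]
        if vid not in have_v or pid not in have_p:
            n_untestable += 1
            continue
        rho, p, _ = spearman_test(geno.dosage_of(vid),
                                  expr.values.loc[pid].to_numpy())
        rows.append({
            "variant_id": vid, "probe_id": pid,
            "discovery_rho": float(pair["rho"]), "rho": rho, "p": p,
            "replicated": p < alpha and np.sign(rho) == np.sign(pair["rho"]),
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return ReplicationSummary(table, 0, 0, n_untestable, 0.0)
    sig = table[table["p"] < alpha]
    opposite = 0.0
    if len(sig):
        opposite = float(
            (np.sign(sig["rho"]) != np.sign(sig["discovery_rho"])).mean()
        )
    return ReplicationSummary(
        table=table,
        n_tested=len(table),
        n_replicated=int(table["replicated"].sum()),
        n_untestable=n_untestable,
        frac_opposite_sign=opposite,
    )


def _pairs_pvalues(
    pairs: pd.DataFrame, geno: GenotypeTable, expr: ExpressionMatrix
) -> np.ndarray:
    """Replication p-values for all testable pairs (vectorized)."""
    have_v = set(geno.variants["variant_id"])
    have_p = set(expr.probe_ids)
    usable = pairs[pairs["variant_id"].isin(have_v)
                   & pairs["probe_id"].isin(have_p)]
    n = geno.n_samples
    ps = []
    for _, pair in usable.iterrows():
        rx = rank_standardize_rows(geno.dosage_of(pair["variant_id"]))[0]
        ry = rank_standardize_rows(expr.values.loc[pair["probe_id"]].to_numpy())[0]
        rho = float(np.clip(rx @ ry, -1, 1))
        ps.append(p_from_rho(rho, n))
    return np.asarray(ps)


def sharing_curve(
    pairs: pd.DataFrame,
    target_geno: GenotypeTable,
    target_expr: ExpressionMatrix,
    sample_sizes: list[int],
    n_draws: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """pi1 sharing of an association list versus target sample size.

    For each n, individuals are repeatedly subsampled from the target
    cohort, the pairs re-tested, and pi1 computed; the mean and the 5%
    and 95% quantiles across draws are reported.
    """
    geno, expr = intersect_samples(target_geno, target_expr)
    total = geno.n_samples
    if max(sample_sizes) > total:
        raise ValueError("requested sample size exceeds target cohort")
    rng = np.random.default_rng(seed)
    out = []
    for n in sample_sizes:
        if n < 50:
            warnings.warn(f"pi1 is unstable at n={n} < 50", stacklevel=2)
        pi1s = []
        for _ in range(n_draws):
            keep = (list(geno.sample_ids) if n == total and n_draws == 1
                    else [geno.sample_ids[i]
                          for i in rng.choice(total, size=n, replace=False)])
            sub_g = geno.subset_samples(keep)
            sub_e = expr.subset_samples(keep)
            ps = _pairs_pvalues(pairs, sub_g, sub_e)
            pi1s.append(storey_pi1(ps).pi1)
        pi1s = np.asarray(pi1s)
        out.append({
            "n": n, "pi1_mean": float(pi1s.mean()),
            "pi1_q05": float(np.quantile(pi1s, 0.05)),
            "pi1_q95": float(np.quantile(pi1s, 0.95)),
            "n_draws": n_draws,
        })
    return pd.DataFrame(out)


def pi1_trans_profile(
    variant_id: str,
    geno: GenotypeTable,
    expr: ExpressionMatrix,
    annot: ProbeAnnotation,
    exclusion: int = TRANS_EXCLUSION,
) -> Pi1Estimate:
    """pi1 of one variant's p-values against all eligible trans probes.

    Estimates the fraction of the transcriptome the variant perturbs in
    trans, without calling individual associations.
    """
    geno, expr = intersect_samples(geno, expr)
    vrow = geno.variants[geno.variants["variant_id"] == variant_id]
    if vrow.empty:
        raise KeyError(f"variant {variant_id!r} not found")
    vrow = vrow.iloc[0]
    probes = _eligible_probes(expr, annot, "trans")
    # trans geometry from the variant's side: probe TSS far from the variant
    dist_ok = (
        (probes["chromosome"].astype(str) != str(vrow.chromosome))
        | ((probes["tss"] - int(vrow.position)).abs() > exclusion)
    )
    eligible = probes[dist_ok]
    if len(eligible) < 50:
        raise ValueError("need at least 50 eligible trans probes")
    rx = rank_standardize_rows(geno.dosage_of(variant_id))[0]
    e_ranks = rank_standardize_rows(
        expr.values.loc[eligible["probe_id"]].to_numpy()
    )
    rho = np.clip(e_ranks @ rx, -1, 1)
    return storey_pi1(p_from_rho(rho, geno.n_samples))
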