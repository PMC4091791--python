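"""Causal classification of (variant, cis gene, trans gene) triplets.

A variant G associated with a nearby gene C *and* a distant gene T
admits three anchored explanations: the cis transcript mediates the
trans effect (SCT: G -> C -> T), the trans transcript mediates the cis
effect (STC: G -> T -> C), or the two effects are independent
(INDEP: C <- G -> T).  Genotype is always the first node: it cannot be
caused by expression, which is what lets a three-node likelihood
comparison carry causal meaning.

Two methods vote.  Gaussian Bayesian networks score each DAG by maximum
likelihood (the joint density factorizes over nodes given parents) and
AIC; the best model must be at least ten times more likely than the
runner-up.  The causal inference test (CIT) instead tests the chain of
regression conditions a mediation model implies, per direction, and
reports an omnibus p = max of the component p-values.  A consensus call
requires both methods to name the same model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MODELS = ("SCT", "STC", "INDEP")
BN_K = 5  # parameter count used in AIC for every model
REL_LIK_CUTOFF = 0.1  # best model must be >= 10x more likely


@dataclass
class CausalTriplet:
    """Aligned (G, C, T) vectors; C and T standard-normalized."""

    G: np.ndarray
    C: np.ndarray
    T: np.ndarray
    variant_id: str = "G"
    cis_id: str = "C"
    trans_id: str = "T"

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if not (len(self.G) == len(self.C) == len(self.T)):
            raise ValueError("G, C, T must have equal lengths")

    @property
    def n(self) -> int:
        return len(self.G)


@dataclass
class BnResult:
    lnL: dict[str, float]
    aic: dict[str, float]
    k: int
    best_model: str
    rel_lik_second_vs_best: float
    bn_call: str  # SCT | STC | INDEP | none


@dataclass
class CitResult:
    """Component p-values per mediation direction and the direction calls."""

    p_c_mediates: dict[str, float]  # p1..p4, omnibus (tests SCT)
    p_t_mediates: dict[str, float]  # p1..p4, omnibus (tests STC)
    cit_call: str                   # SCT | STC | INDEP | nocall
    alpha_used: float


@dataclass
class ConsensusCall:
    bn_call: str
    cit_call: str
    consensus: str  # SCT | STC | INDEP | none


# ---------------------------------------------------------------------------
# Gaussian Bayesian networks
# ---------------------------------------------------------------------------

def _gauss_marginal_lnl(x: np.ndarray) -> float:
    """Max log-likelihood of a Gaussian with ML mean/variance."""
    n = x.size
    var = float(np.var(x))  # ML variance (divide by n)
    if var <= 0:
        raise ValueError("degenerate node: zero variance")
    return -0.5 * n * (np.log(2 * np.pi * var) + 1.0)


def _gauss_conditional_lnl(child: np.ndarray, parent: np.ndarray) -> float:
    """Max log-likelihood of child | parent under a linear-Gaussian link."""
    n = child.size
    X = np.column_stack([np.ones(n), parent])
    coef, *_ = np.linalg.lstsq(X, child, rcond=None)
    rss = float(np.sum((child - X @ coef) ** 2))
    var = rss / n
    if var <= 1e-12 * float(np.var(child)):
        raise ValueError("degenerate fit: zero residual variance")
    return -0.5 * n * (np.log(2 * np.pi * var) + 1.0)


def bn_fit(triplet: CausalTriplet) -> BnResult:
    """Score the three anchored DAGs by Gaussian maximum likelihood + AIC.

    Each network's log-likelihood is the sum of its node terms: the root
    genotype term ln N(G) (identical across models, so it cancels in
    comparisons but keeps likelihoods on a common variable set) plus
    linear-Gaussian child terms with ML variance RSS/n.  AIC = 2k - 2lnL
    with k = 5 for every model, so AIC ranking equals lnL ranking.  The
    call follows the relative-likelihood rule: the best model is called
    only when exp((AIC_best - AIC_second)/2) <= 0.1.
    """
    if triplet.n < 30:
        raise ValueError("need n >= 30 for network scoring")
    G, C, T = triplet.G, triplet.C, triplet.T
    for name, v in (("G", G), ("C", C), ("T", T)):
        if np.ptp(v) == 0:
            raise ValueError(f"constant vector {name}")
    ln_g = _gauss_marginal_lnl(G)
    lnL = {
        "SCT": ln_g + _gauss_conditional_lnl(C, G) + _gauss_conditional_lnl(T, C),
        "STC": ln_g + _gauss_conditional_lnl(T, G) + _gauss_conditional_lnl(C, T),
        "INDEP": ln_g + _gauss_conditional_lnl(C, G) + _gauss_conditional_lnl(T, G),
    }
    aic = {m: 2 * BN_K - 2 * lnL[m] for m in MODELS}
    order = sorted(MODELS, key=lambda m: aic[m])
    best, second = order[0], order[1]
    rel = float(np.exp((aic[best] - aic[second]) / 2.0))
    call = best if rel <= REL_LIK_CUTOFF else "none"
    return BnResult(lnL=lnL, aic=aic, k=BN_K, best_model=best,
                    rel_lik_second_vs_best=rel, bn_call=call)


# ---------------------------------------------------------------------------
# causal inference test
# ---------------------------------------------------------------------------

def _f_one_predictor(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """F statistic for x in y ~ x (vs intercept-only)."""
    n = y.size
    yc, xc = y - y.mean(), x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("degenerate regression: constant predictor")
    rss0 = yc @ yc
    rss1 = rss0 - (yc @ xc) ** 2 / sxx
    df2 = n - 2
    return float((rss0 - rss1) / (rss1 / df2)), df2


def _rss_two_predictors(yc, ac, bc):
    """RSS of centered y on centered predictors a and b (with intercept).

    ``bc`` may be a matrix of columns; broadcasting gives one RSS per
    column.
    """
    saa = ac @ ac
    sbb = np.einsum("i...,i...->...", bc, bc)
    sab = ac @ bc
    say = ac @ yc
    sby = yc @ bc
    det = saa * sbb - sab**2
    beta_a = (sbb * say - sab * sby) / det
    beta_b = (saa * sby - sab * say) / det
    syy = yc @ yc
    return syy - beta_a * say - beta_b * sby


def _f_added_predictor(y: np.ndarray, x_new: np.ndarray, x_base):
    """F for adding x_new to y ~ x_base.

    ``x_base`` may be an n x B matrix of base predictors, giving one F
    per column (used for the p4 permutation reference).
    """
    n = y.size
    yc = y - y.mean()
    xn = np.asarray(x_new, dtype=float)
    xn = xn - xn.mean()
    bc = np.asarray(x_base, dtype=float)
    bc = bc - bc.mean(axis=0)
    sbb = np.einsum("i...,i...->...", bc, bc)
    rss_base = yc @ yc - (yc @ bc) ** 2 / sbb
    rss_full = _rss_two_predictors(yc, xn, bc)
    df2 = n - 3
    return (rss_base - rss_full) / (rss_full / df2), df2


def _strata_permutations(g: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """B index permutations that shuffle only within rounded-dosage strata."""
    idx = np.tile(np.arange(g.size), (B, 1))
    for value in np.unique(np.rint(g)):
        members = np.flatnonzero(np.rint(g) == value)
        if members.size < 2:
            continue
        shuffled = np.tile(members, (B, 1))
        rng.permuted(shuffled, axis=1, out=shuffled)
        idx[:, members] = shuffled
    return idx


def cit_direction(
    G: np.ndarray,
    M: np.ndarray,
    O: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Component p-values of the causal inference test for G -> M -> O.

    p1: G is associated with the outcome O.
    p2: G is associated with the mediator M given O.
    p3: M is associated with O given G.
    p4: equivalence component - supports G independent of O given M.  The
        observed conditional F of G in O ~ G + M is referred to a
        noncentral F whose noncentrality is estimated from B replicates
        in which M is permuted within rounded-G strata (preserving the
        G-O and G-M marginals while severing M's mediation); p4 =
        P(F_noncentral <= F_obs), small when the conditional association
        is significantly weaker than a direct effect would produce.

    The omnibus p-value is the maximum of the four components: every
    condition must hold for the mediation model in this direction.
    """
    G = np.asarray(G, dtype=float)
    M = np.asarray(M, dtype=float)
    O = np.asarray(O, dtype=float)
    n = G.size
    if n < 30:
        raise ValueError("need n >= 30")
    if B < 100:
        raise ValueError("need B >= 100 permutations for p4")

    f1, df1_2 = _f_one_predictor(O, G)
    p1 = float(stats.f.sf(f1, 1, df1_2))

    f2, df2_2 = _f_added_predictor(M, G, O)
    p2 = float(stats.f.sf(f2, 1, df2_2))

    f3, df3_2 = _f_added_predictor(O, M, G)
    p3 = float(stats.f.sf(f3, 1, df3_2))

    # p4: conditional F of G given M, against its permutation reference
    f_obs, df4_2 = _f_added_predictor(O, G, M)
    rng = np.random.default_rng(seed)
    perms = _strata_permutations(G, B, rng)
    M_perm = M[perms].T  # n x B
    f_ref, _ = _f_added_predictor(O, G, M_perm)
    # method-of-moments noncentrality: E[F(1, v, ncp)] = v (1 + ncp) / (v - 2)
    mean_f = float(np.mean(f_ref))
    ncp = max(mean_f * (df4_2 - 2) / df4_2 - 1.0, 0.0)
    p4 = float(stats.ncf.cdf(f_obs, 1, df4_2, ncp)) if ncp > 0 else \
        float(stats.f.cdf(f_obs, 1, df4_2))

    parts = {"p1": p1, "p2": p2, "p3": p3, "p4": p4}
    parts["omnibus"] = max(parts.values())
    return parts


def cit(
    triplet: CausalTriplet, B: int = 1000, seed: int = 0
) -> tuple[dict[str, float], dict[str, float]]:
    """CIT component p-values for both mediation directions.

    Returns (C-mediates, T-mediates) dictionaries; the first tests SCT
    (C between G and T), the second STC.
    """
    c_med = cit_direction(triplet.G, triplet.C, triplet.T, B=B, seed=seed)
    t_med = cit_direction(triplet.G, triplet.T, triplet.C, B=B, seed=seed + 1)
    return c_med, t_med


def causal_call(
    bn: BnResult,
    cit_results: tuple[dict[str, float], dict[str, float]],
    n_triplets_tested: int,
    alpha: float = 0.05,
) -> ConsensusCall:
    """Combine the BN and CIT verdicts into a consensus.

    CIT calling uses a Bonferroni-corrected level alpha /
    n_triplets_tested on the omnibus p-values: SCT when only the
    C-mediation direction is significant, STC when only the T-mediation
    direction is, INDEP when neither, and no call when both are.  The
    consensus is the shared call when BN and CIT agree, else none.
    """
    if n_triplets_tested < 1:
        raise ValueError("n_triplets_tested must be >= 1")
    alpha_used = alpha / n_triplets_tested
    c_med, t_med = cit_results
    c_sig = c_med["omnibus"] < alpha_used
    t_sig = t_med["omnibus"] < alpha_used
    if c_sig and t_sig:
        cit_verdict = "nocall"
    elif c_sig:
        cit_verdict = "SCT"
    elif t_sig:
        cit_verdict = "STC"
    else:
        cit_verdict = "INDEP"
    consensus = bn.bn_call if bn.bn_call == cit_verdict else "none"
    return ConsensusCall(bn_call=bn.bn_call, cit_call=cit_verdict,
                         consensus=consensus)


def cit_result(
    triplet: CausalTriplet,
    n_triplets_tested: int,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CitResult:
    """Convenience wrapper bundling both directions and the CIT call."""
    c_med, t_med = cit(triplet, B=B, seed=seed)
    alpha_used = alpha / n_triplets_tested
    c_sig = c_med["omnibus"] < alpha_used
    t_sig = t_med["omnibus"] < alpha_used
    verdict = ("nocall" if (c_sig and t_sig)
               else "SCT" if c_sig else "STC" if t_sig else "INDEP")
    return CitResult(p_c_mediates=c_med, p_t_mediates=t_med,
                     cit_call=verdict, alpha_used=alpha_used)


# ---------------------------------------------------------------------------
# attenuation of the trans association by the cis transcript
# ---------------------------------------------------------------------------

def trans_assoc_variance_explained(triplet: CausalTriplet) -> float:
    """Fraction of the variant's trans-association variance removed by
    conditioning on the cis transcript.

    1 - (beta_cond / beta_marg)^2, clamped to [0, 1], where beta_marg is
    the coefficient of G in T ~ G and beta_cond its coefficient in
    T ~ G + C.  Full mediation drives the conditional coefficient to
    zero (value 1); an independent trans effect leaves it untouched
    (value ~0), because C carries no information about T beyond G.
    (Residualizing T on C *unconditionally* would instead strip part of
    the G signal even under independence, since C correlates with G.)
    """
    G, C, T = triplet.G, triplet.C, triplet.T
    yc, gc, cc = T - T.mean(), G - G.mean(), C - C.mean()
    sgg = gc @ gc
    if sgg == 0:
        raise ValueError("constant genotype")
    tss = yc @ yc
    r2_full = (yc @ gc) ** 2 / (sgg * tss)
    if r2_full < 1e-12:
        raise ValueError("no trans association: R^2(T ~ G) is zero")
    beta_marg = (yc @ gc) / sgg
    scc, sgc = cc @ cc, gc @ cc
    det = sgg * scc - sgc**2
    if det <= 0:
        raise ValueError("degenerate design: C collinear with G")
    beta_cond = (scc * (yc @ gc) - sgc * (yc @ cc)) / det
    return float(np.clip(1.0 - (beta_cond / beta_marg) ** 2, 0.0, 1.0))
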