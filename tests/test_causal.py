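"""Causal triplet classification: BN likelihoods, CIT, consensus."""

import numpy as np
import pytest
from scipy import stats

from transmed_eqtl.causal import (
    BN_K,
    CausalTriplet,
    bn_fit,
    causal_call,
    cit,
    cit_direction,
    cit_result,
    trans_assoc_variance_explained,
)
from transmed_eqtl.preprocess import standard_normalize
from transmed_eqtl.simulate import make_scenario, simulate_cohort


def planted_triplet(model, seed, n=800, r2=0.2, strength=0.2):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, n).astype(float)
    z = (g - g.mean()) / g.std()
    noise = lambda: rng.standard_normal(n)  # noqa: E731
    if model == "SCT":
        c = np.sqrt(r2) * z + np.sqrt(1 - r2) * noise()
        t = np.sqrt(strength) * (c - c.mean()) / c.std() \
            + np.sqrt(1 - strength) * noise()
    elif model == "STC":
        t = np.sqrt(r2) * z + np.sqrt(1 - r2) * noise()
        c = np.sqrt(strength) * (t - t.mean()) / t.std() \
            + np.sqrt(1 - strength) * noise()
    else:  # INDEP
        c = np.sqrt(r2) * z + np.sqrt(1 - r2) * noise()
        t = np.sqrt(strength) * z + np.sqrt(1 - strength) * noise()
    return CausalTriplet(G=g, C=standard_normalize(c), T=standard_normalize(t))


class TestBnFit:
    def test_aic_identity_and_ranking(self):
        trip = planted_triplet("SCT", 0)
        bn = bn_fit(trip)
        for m in ("SCT", "STC", "INDEP"):
            assert bn.aic[m] == 2 * BN_K - 2 * bn.lnL[m]
        # equal k across models: AIC ranking equals lnL ranking
        assert max(bn.lnL, key=bn.lnL.get) == min(bn.aic, key=bn.aic.get)
        assert 0 < bn.rel_lik_second_vs_best <= 1

    def test_likelihood_matches_joint_density_oracle(self):
        """Factorized node likelihoods vs the implied trivariate Gaussian."""
        for model in ("SCT", "STC", "INDEP"):
            trip = planted_triplet(model, 1)
            bn = bn_fit(trip)
            G, C, T = trip.G, trip.C, trip.T
            n = trip.n

            def ols(y, x):
                X = np.column_stack([np.ones(n), x])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
                return beta, float(resid @ resid) / n

            # SCT: G ~ N(mu_g, v_g); C = a + bG + e1; T = c + dC + e2
            mu_g, v_g = G.mean(), G.var()
            (a, b), v1 = ols(C, G)
            (c0, d), v2 = ols(T, C)
            mean = np.array([mu_g, a + b * mu_g, c0 + d * (a + b * mu_g)])
            cov = np.empty((3, 3))
            cov[0, 0] = v_g
            cov[0, 1] = cov[1, 0] = b * v_g
            cov[1, 1] = b**2 * v_g + v1
            cov[0, 2] = cov[2, 0] = d * b * v_g
            cov[1, 2] = cov[2, 1] = d * cov[1, 1]
            cov[2, 2] = d**2 * cov[1, 1] + v2
            oracle = stats.multivariate_normal(mean, cov).logpdf(
                np.column_stack([G, C, T])).sum()
            assert bn.lnL["SCT"] == pytest.approx(oracle, abs=1e-8)

    def test_swapping_c_and_t_swaps_sct_and_stc(self):
        trip = planted_triplet("SCT", 2)
        swapped = CausalTriplet(G=trip.G, C=trip.T, T=trip.C)
        a, b = bn_fit(trip), bn_fit(swapped)
        assert a.lnL["SCT"] == pytest.approx(b.lnL["STC"], abs=1e-9)
        assert a.lnL["STC"] == pytest.approx(b.lnL["SCT"], abs=1e-9)
        assert a.lnL["INDEP"] == pytest.approx(b.lnL["INDEP"], abs=1e-9)

    def test_affine_rescaling_preserves_ranking(self):
        trip = planted_triplet("SCT", 3)
        scaled = CausalTriplet(G=trip.G, C=3.0 * trip.C - 1.0,
                               T=0.5 * trip.T + 4.0)
        a, b = bn_fit(trip), bn_fit(scaled)
        assert a.best_model == b.best_model
        assert a.rel_lik_second_vs_best == pytest.approx(
            b.rel_lik_second_vs_best, rel=1e-9)
        # likelihood differences between models are scale-invariant
        for m in ("STC", "INDEP"):
            assert a.lnL[m] - a.lnL["SCT"] == pytest.approx(
                b.lnL[m] - b.lnL["SCT"], abs=1e-6)

    def test_exact_copy_is_degenerate(self):
        trip = planted_triplet("SCT", 4)
        with pytest.raises(ValueError, match="degenerate|zero"):
            bn_fit(CausalTriplet(G=trip.G, C=trip.C, T=trip.C.copy()))

    def test_recovery_of_planted_models(self):
        hits = {m: 0 for m in ("SCT", "STC", "INDEP")}
        for seed in range(30):
            for model in hits:
                bn = bn_fit(planted_triplet(model, 100 + seed))
                hits[model] += bn.bn_call == model
        for model, count in hits.items():
            assert count >= 27, (model, count)


class TestCit:
    def test_directionality_on_planted_sct(self):
        right = 0
        for seed in range(30):
            trip = planted_triplet("SCT", 200 + seed)
            c_med, t_med = cit(trip, B=200, seed=seed)
            if c_med["omnibus"] < 0.05 and t_med["omnibus"] >= 0.05:
                right += 1
        assert right >= 26

    def test_specificity_on_planted_indep(self):
        right = 0
        for seed in range(30):
            trip = planted_triplet("INDEP", 300 + seed)
            c_med, t_med = cit(trip, B=200, seed=seed)
            if c_med["omnibus"] >= 0.05 and t_med["omnibus"] >= 0.05:
                right += 1
        assert right >= 26

    def test_marginal_test_is_calibrated_under_the_null(self):
        """p1 should be uniform when G has no effect on the outcome."""
        rng = np.random.default_rng(5)
        n = 100
        p1s = []
        for _ in range(500):
            g = rng.binomial(2, 0.3, n).astype(float)
            o = rng.standard_normal(n)
            m = rng.standard_normal(n)
            yc, gc = o - o.mean(), g - g.mean()
            rss0 = yc @ yc
            rss1 = rss0 - (yc @ gc) ** 2 / (gc @ gc)
            f = (rss0 - rss1) / (rss1 / (n - 2))
            p1s.append(stats.f.sf(f, 1, n - 2))
        assert stats.kstest(p1s, "uniform").pvalue > 0.01

    def test_omnibus_is_the_componentwise_maximum(self):
        parts = cit_direction(*(planted_triplet("SCT", 6).G,
                                planted_triplet("SCT", 6).C,
                                planted_triplet("SCT", 6).T), B=150, seed=0)
        assert parts["omnibus"] == max(parts["p1"], parts["p2"],
                                       parts["p3"], parts["p4"])

    def test_input_validation(self):
        trip = planted_triplet("SCT", 7, n=20)
        with pytest.raises(ValueError, match="n >= 30"):
            cit(trip, B=200)
        trip = planted_triplet("SCT", 8)
        with pytest.raises(ValueError, match="B >= 100"):
            cit(trip, B=10)


class TestCausalCall:
    def test_agreement_gives_consensus(self):
        trip = planted_triplet("SCT", 9)
        bn = bn_fit(trip)
        res = cit(trip, B=200, seed=1)
        call = causal_call(bn, res, n_triplets_tested=1)
        assert call.consensus == "SCT" == call.bn_call == call.cit_call

    def test_disagreement_gives_none(self):
        from transmed_eqtl.causal import BnResult
        bn = BnResult(lnL={"SCT": 0, "STC": -60, "INDEP": -50},
                      aic={"SCT": 10, "STC": 130, "INDEP": 110},
                      k=5, best_model="SCT", rel_lik_second_vs_best=1e-20,
                      bn_call="SCT")
        res = ({"omnibus": 0.9}, {"omnibus": 0.9})  # CIT says INDEP
        call = causal_call(bn, res, n_triplets_tested=1)
        assert call.cit_call == "INDEP" and call.consensus == "none"

    def test_both_directions_significant_is_nocall(self):
        from transmed_eqtl.causal import BnResult
        bn = BnResult(lnL={}, aic={}, k=5, best_model="SCT",
                      rel_lik_second_vs_best=0.01, bn_call="SCT")
        res = ({"omnibus": 1e-9}, {"omnibus": 1e-9})
        call = causal_call(bn, res, n_triplets_tested=1)
        assert call.cit_call == "nocall" and call.consensus == "none"

    def test_scenario_confusion_matrix(self, mediation_cohort):
        co = mediation_cohort
        truth = co.truth.triplets
        correct = 0
        for i, row in truth.iterrows():
            trip = CausalTriplet(
                G=co.genotypes.dosage_of(row.variant_id),
                C=standard_normalize(
                    co.expression.values.loc[row.cis_probe].to_numpy()),
                T=standard_normalize(
                    co.expression.values.loc[row.trans_probe].to_numpy()))
            bn = bn_fit(trip)
            res = cit_result(trip, n_triplets_tested=len(truth), B=200,
                             seed=500 + i)
            call = causal_call(bn, (res.p_c_mediates, res.p_t_mediates),
                               n_triplets_tested=len(truth))
            assert (row.model, call.consensus) not in (
                ("SCT", "STC"), ("STC", "SCT"))
            correct += call.consensus == row.model
        assert correct / len(truth) >= 0.8


class TestTransAssocVarianceExplained:
    def test_perfect_mediation_is_fully_explained(self):
        rng = np.random.default_rng(10)
        g = rng.binomial(2, 0.3, 500).astype(float)
        c = g + rng.standard_normal(500)
        t = 2.0 * c - 1.0  # noiseless function of the cis transcript
        trip = CausalTriplet(G=g, C=c, T=t)
        assert trans_assoc_variance_explained(trip) == 1.0

    def test_independent_trans_effect_is_unexplained(self):
        trip = planted_triplet("INDEP", 11, n=2000)
        assert trans_assoc_variance_explained(trip) < 0.1

    def test_monotone_in_mediation_strength(self):
        vals = []
        for strength in (0.05, 0.2, 0.6):
            out = []
            for seed in range(5):
                trip = planted_triplet("SCT", 600 + seed, n=2000,
                                       strength=strength)
                out.append(trans_assoc_variance_explained(trip))
            vals.append(np.mean(out))
        assert vals[0] < vals[1] < vals[2] or vals[2] > 0.9

    def test_no_trans_association_is_an_error(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.3, 500).astype(float)
        gc = g - g.mean()
        noise = rng.standard_normal(500)
        t = noise - (noise @ gc) / (gc @ gc) * gc  # exactly orthogonal
        trip = CausalTriplet(G=g, C=rng.standard_normal(500), T=t)
        with pytest.raises(ValueError, match="no trans association"):
            trans_assoc_variance_explained(trip)
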