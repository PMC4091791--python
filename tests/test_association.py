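"""Spearman engine, scan geometry, and the CNV trans artifact filter."""

import itertools

import numpy as np
import pandas as pd
import pytest

from transmed_eqtl.association import (
    cis_scan,
    cnv_trans_filter,
    neglog10_p_from_rho,
    p_from_rho,
    rank_standardize_rows,
    spearman_test,
    trans_scan,
)
from transmed_eqtl.datatypes import ExpressionMatrix, GenotypeTable, ProbeAnnotation
from transmed_eqtl.simulate import make_scenario, simulate_cohort


class TestSpearmanTest:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p, n = spearman_test(x, np.exp(x))
        assert rho == 1.0 and n == 10
        assert p == np.finfo(float).tiny  # reported as smallest normal float

    def test_perfect_antimonotone_with_ties(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([5, 5, 3, 3, 1, 1], dtype=float)
        rho, _, _ = spearman_test(x, y)
        assert rho == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r1, p1, _ = spearman_test(x, y)
        r2, p2, _ = spearman_test(np.tanh(x), y**3)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)

    def test_agrees_with_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=40).astype(float)
        y = rng.normal(size=40)
        rho, p, _ = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("x, y, match", [
        (np.ones(10), np.arange(10.0), "constant"),
        (np.arange(10.0), np.arange(9.0), "equal length"),
        (np.arange(3.0), np.arange(3.0), "n >= 4"),
    ])
    def test_input_validation(self, x, y, match):
        with pytest.raises(ValueError, match=match):
            spearman_test(x, y)

    def test_agrees_with_exact_permutation_null(self):
        """t-approximation vs the exhaustive n=7 permutation distribution."""
        rng = np.random.default_rng(2)
        perms = np.array(list(itertools.permutations(range(7))))
        checked = 0
        for _ in range(12):
            x, y = rng.normal(size=7), rng.normal(size=7)
            rho, p, _ = spearman_test(x, y)
            ry = rank_standardize_rows(y)[0]
            rx = rank_standardize_rows(x)[0]
            absr = np.abs(rx[perms] @ ry)
            # mid-p: the continuous t approximation targets the midpoint
            # of the discrete permutation null's atoms
            p_exact = 0.5 * (np.mean(absr >= abs(rho) - 1e-12)
                             + np.mean(absr > abs(rho) + 1e-12))
            if p_exact > 0.01:
                assert p == pytest.approx(p_exact, rel=0.10)
                checked += 1
        assert checked >= 8  # most random draws are non-extreme


class TestNeglog10P:
    def test_strong_trans_association_arithmetic(self):
        # printed rho of a CNV trans-eQTL at n=869 implies -log10 p ~42.35
        assert neglog10_p_from_rho(0.443, 869) == pytest.approx(42.3473, rel=1e-3)
        assert neglog10_p_from_rho(0.435, 869) == pytest.approx(40.6971, rel=1e-3)

    def test_zero_rho_means_p_one(self):
        assert neglog10_p_from_rho(0.0, 100) == 0.0

    def test_no_underflow_deep_in_the_tail(self):
        val = neglog10_p_from_rho(0.9, 869)  # |t| ~ 60, p ~ 1e-300s
        assert np.isfinite(val) and val > 250

    def test_rejects_degenerate_rho(self):
        with pytest.raises(ValueError):
            neglog10_p_from_rho(1.0, 100)

    def test_matches_linear_space_where_representable(self):
        from scipy import stats
        rho, n = 0.2, 400
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        direct = -np.log10(2 * stats.t.sf(t, n - 2))
        assert neglog10_p_from_rho(rho, n) == pytest.approx(direct, rel=1e-12)


def geometry_fixture(positions, tss=10_000_000, n=12, probe_kwargs=None):
    """One probe at ``tss`` on chr1, variants at given (chrom, pos)."""
    rng = np.random.default_rng(3)
    variants = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(len(positions))],
        "chromosome": [c for c, _ in positions],
        "position": [p for _, p in positions],
        "variant_type": "SNP",
    })
    dosages = rng.integers(0, 3, size=(len(positions), n)).astype(float)
    geno = GenotypeTable(variants=variants, dosages=dosages,
                         sample_ids=[f"s{i}" for i in range(n)])
    geno.variants["maf"] = geno.computed_maf()
    expr = ExpressionMatrix(values=pd.DataFrame(
        rng.normal(size=(1, n)), index=pd.Index(["pA"], name="probe_id"),
        columns=geno.sample_ids))
    kw = {"contains_common_snp": [False], "multi_mapped": [False]}
    kw.update(probe_kwargs or {})
    annot = ProbeAnnotation(table=pd.DataFrame({
        "probe_id": ["pA"], "gene_id": ["GA"], "chromosome": ["1"],
        "tss": [tss], **kw}))
    return geno, expr, annot


class TestScanGeometry:
    def test_cis_window_boundary_is_closed(self):
        geno, expr, annot = geometry_fixture(
            [("1", 9_000_000), ("1", 11_000_000), ("1", 11_000_001),
             ("1", 8_999_999)])
        tested = set(cis_scan(geno, expr, annot).records["variant_id"])
        assert tested == {"v0", "v1"}  # exactly +-1 Mb included

    def test_trans_exclusion_boundary_is_open(self):
        geno, expr, annot = geometry_fixture(
            [("1", 15_000_000), ("1", 15_000_001), ("2", 100),
             ("1", 4_999_999)])
        tested = set(trans_scan(geno, expr, annot).records["variant_id"])
        # same chromosome: strictly farther than 5 Mb from the TSS at
        # 10 Mb (v0 sits exactly at the boundary and is excluded);
        # another chromosome is always tested
        assert tested == {"v1", "v2", "v3"}

    def test_probe_flags_gate_the_scans(self):
        geno, expr, annot = geometry_fixture(
            [("1", 10_000_000), ("2", 100)],
            probe_kwargs={"contains_common_snp": [True], "multi_mapped": [True]})
        assert cis_scan(geno, expr, annot).records.empty
        assert trans_scan(geno, expr, annot).records.empty

    def test_cis_and_trans_never_share_a_pair(self):
        geno, expr, annot = geometry_fixture(
            [("1", p) for p in range(6_000_000, 18_000_001, 1_000_000)]
            + [("2", 1_000_000)])
        cis_pairs = set(map(tuple, cis_scan(geno, expr, annot)
                            .records[["variant_id", "probe_id"]].to_numpy()))
        trans_pairs = set(map(tuple, trans_scan(geno, expr, annot)
                              .records[["variant_id", "probe_id"]].to_numpy()))
        assert not cis_pairs & trans_pairs
        # the 1-5 Mb band is tested by neither scan
        all_tested = {v for v, _ in cis_pairs | trans_pairs}
        band = {f"v{i}" for i, (_, p) in enumerate(
            [("1", p) for p in range(6_000_000, 18_000_001, 1_000_000)])
            if 1_000_000 < abs(p - 10_000_000) <= 5_000_000}
        assert not band & all_tested

    def test_scan_is_order_invariant(self, cis_only_cohort):
        co = cis_only_cohort
        sub_ids = list(co.genotypes.variant_ids[:50])
        geno = co.genotypes.subset_variants(sub_ids)
        shuffled = co.genotypes.subset_variants(sub_ids[::-1])
        a = cis_scan(geno, co.expression, co.annotation).records
        b = cis_scan(shuffled, co.expression, co.annotation).records
        key = lambda df: df.sort_values(["variant_id", "probe_id"]).reset_index(drop=True)  # noqa: E731
        pd.testing.assert_frame_equal(key(a), key(b))

    def test_best_per_probe_is_the_minimum(self, cis_only_cohort):
        co = cis_only_cohort
        result = cis_scan(co.genotypes, co.expression, co.annotation)
        best = result.best_per_probe
        for probe, rec in list(best.items())[:20]:
            sub = result.records[result.records["probe_id"] == probe]
            assert rec.p == sub["p"].min()


class TestCnvTransFilter:
    def test_same_chromosome_removed(self):
        co = simulate_cohort(make_scenario("sex_cnv_confound"))
        # force a probe onto a CNV chromosome by scanning everything
        result = trans_scan(co.genotypes, co.expression, co.annotation)
        filtered, log = cnv_trans_filter(result, co.genotypes, co.annotation,
                                         sex=None, sex_alpha=None)
        same = log[log["reason"] == "same_chrom"]
        cnv_chrom = co.genotypes.variants.set_index("variant_id")["chromosome"]
        probe_chrom = co.annotation.table.set_index("probe_id")["chromosome"]
        for _, row in same.iterrows():
            assert cnv_chrom[row["variant_id"]] == probe_chrom[row["probe_id"]]

    def test_sex_imbalanced_cnvs_flagged_and_only_those(self):
        co = simulate_cohort(make_scenario("sex_cnv_confound"))
        result = trans_scan(co.genotypes, co.expression, co.annotation)
        _, log = cnv_trans_filter(result, co.genotypes, co.annotation,
                                  sex=co.sex)
        flagged = set(log.loc[log["reason"] == "sex_imbalance", "variant_id"])
        assert flagged == set(co.truth.sex_imbalanced_cnvs)

    def test_relaxed_ld_leaves_only_same_chromosome_removals(self):
        co = simulate_cohort(make_scenario("sex_cnv_confound"))
        result = trans_scan(co.genotypes, co.expression, co.annotation)
        _, log = cnv_trans_filter(result, co.genotypes, co.annotation,
                                  sex=None, ld_r2=1.0)
        assert set(log["reason"]) <= {"same_chrom"}

    def test_snp_records_pass_through(self, cis_only_cohort):
        co = cis_only_cohort
        result = trans_scan(
            co.genotypes.subset_variants(list(co.genotypes.variant_ids[:20])),
            co.expression, co.annotation)
        filtered, log = cnv_trans_filter(result, co.genotypes, co.annotation)
        assert log.empty and len(filtered.records) == len(result.records)


def test_p_from_rho_saturates_at_unit_correlation():
    assert p_from_rho(1.0, 50) == np.finfo(float).tiny
    assert p_from_rho(0.0, 50) == pytest.approx(1.0)
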