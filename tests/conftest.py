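"""Shared fixtures: small hand-built tables and synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from transmed_eqtl.datatypes import ExpressionMatrix, GenotypeTable, ProbeAnnotation
from transmed_eqtl.simulate import make_scenario, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(make_scenario("null"))


@pytest.fixture(scope="session")
def cis_only_cohort():
    return simulate_cohort(make_scenario("cis_only"))


@pytest.fixture(scope="session")
def mediation_cohort():
    return simulate_cohort(make_scenario("mediation"))


@pytest.fixture
def tiny_geno():
    """Two chromosomes, hand-placed variants, 8 samples."""
    variants = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4"],
        "chromosome": ["1", "1", "1", "2"],
        "position": [1_000_000, 2_000_000, 6_000_001, 500_000],
        "variant_type": ["SNP", "SNP", "SNP", "SNP"],
    })
    rng = np.random.default_rng(0)
    dosages = rng.integers(0, 3, size=(4, 8)).astype(float)
    dosages[0] = [0, 1, 1, 2, 0, 1, 2, 1]  # non-constant, known MAF
    geno = GenotypeTable(variants=variants, dosages=dosages,
                         sample_ids=[f"s{i}" for i in range(8)])
    geno.variants["maf"] = geno.computed_maf()
    return geno


@pytest.fixture
def tiny_expr(tiny_geno):
    rng = np.random.default_rng(1)
    values = pd.DataFrame(
        rng.normal(size=(3, 8)),
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=tiny_geno.sample_ids,
    )
    return ExpressionMatrix(values=values,
                            probe_to_gene={"p1": "G1", "p2": "G2", "p3": "G3"})


@pytest.fixture
def tiny_annot():
    return ProbeAnnotation(table=pd.DataFrame({
        "probe_id": ["p1", "p2", "p3"],
        "gene_id": ["G1", "G2", "G3"],
        "chromosome": ["1", "1", "2"],
        "tss": [1_000_000, 1_000_000, 700_000],
        "contains_common_snp": [False, True, False],
        "multi_mapped": [False, False, True],
    }))
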