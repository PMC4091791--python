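"""Matched-variant resampling test for eQTL enrichment of a target set.

Whether trait-associated variants are eQTLs more often than chance
cannot be judged against random variants: allele frequency and proximity
to genes both drive eQTL discovery.  The null here therefore draws, for
each target, a random variant matched on minor allele frequency (+-1%)
and distance to the closest gene (+-2 kb), and compares the observed
overlap with a significant-variant set against the matched overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable


@dataclass
class EnrichmentResult:
    observed_overlap: int
    null_overlaps: np.ndarray
    null_median: float
    empirical_p: float
    n_unmatchable: int
    n_targets_matched: int


def match_variants(
    targets: pd.DataFrame,  # columns: variant_id, maf, distance_to_closest_gene
    pool: pd.DataFrame,     # same columns; should exclude the targets
    maf_tol: float = 0.01,
    dist_tol: int = 2000,
    seed: int = 0,
) -> tuple[list[str], int]:
    """One matched pool variant per target (MAF +-maf_tol, distance +-dist_tol).

    Sampling is uniform over eligible pool variants, without replacement
    within the matched set.  Targets with no eligible match are skipped
    and counted.  Returns (matched variant ids, n_unmatchable).
    """
    rng = np.random.default_rng(seed)
    pool_maf = pool["maf"].to_numpy(dtype=float)
    pool_dist = pool["distance_to_closest_gene"].to_numpy(dtype=float)
    pool_ids = pool["variant_id"].to_numpy()
    matched: list[str] = []
    used: set[int] = set()
    n_unmatchable = 0
    for _, row in targets.iterrows():
        ok = (
            (np.abs(pool_maf - float(row["maf"])) <= maf_tol)
            & (np.abs(pool_dist - float(row["distance_to_closest_gene"])) <= dist_tol)
        )
        candidates = [i for i in np.flatnonzero(ok) if i not in used]
        if not candidates:
            n_unmatchable += 1
            continue
        pick = int(rng.choice(candidates))
        used.add(pick)
        matched.append(str(pool_ids[pick]))
    return matched, n_unmatchable


def enrichment_test(
    targets: pd.DataFrame,
    significant_set: set[str],
    pool: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    maf_tol: float = 0.01,
    dist_tol: int = 2000,
) -> EnrichmentResult:
    """Observed vs matched-null overlap of targets with significant eQTLs.

    Each permutation draws a fresh matched set (independent across
    rounds); the empirical p-value is (1 + #{null >= observed}) /
    (n_perm + 1), so it can never be smaller than 1/(n_perm + 1).
    """
    observed = int(targets["variant_id"].isin(significant_set).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    any_matchable = False
    for b in range(n_perm):
        matched, n_unmatch = match_variants(
            targets, pool, maf_tol=maf_tol, dist_tol=dist_tol,
            seed=int(rng.integers(2**31 - 1)),
        )
        if matched:
            any_matchable = True
        null[b] = sum(1 for v in matched if v in significant_set)
    if not any_matchable:
        raise ValueError("no target could be matched in the pool")
    empirical_p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(
        observed_overlap=observed,
        null_overlaps=null,
        null_median=float(np.median(null)),
        empirical_p=float(empirical_p),
        n_unmatchable=n_unmatch,
        n_targets_matched=len(targets) - n_unmatch,
    )


def variant_metadata_table(
    geno: GenotypeTable, distances: np.ndarray
) -> pd.DataFrame:
    """Per-variant (maf, distance-to-closest-gene) frame for matching."""
    return pd.DataFrame({
        "variant_id": geno.variants["variant_id"],
        "maf": geno.variants["maf"],
        "distance_to_closest_gene": distances,
    })
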