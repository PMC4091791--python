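"""Expression normalization and sample QC.

The normalization pipeline mirrors standard array-expression practice:
log2 transform, quantile normalization of each individual's technical
replicates followed by quantile normalization across individuals, PCA
based exclusion of outlying samples, and a per-probe rank-based inverse
normal ("standard") transform used by every downstream linear model.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix


def quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of ``mat`` to their common mean distribution.

    Tied values within a column receive the mean of the reference
    quantiles they span (average-rank convention).
    """
    mat = np.asarray(mat, dtype=float)
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    n = mat.shape[0]
    for j in range(mat.shape[1]):
        ranks = stats.rankdata(mat[:, j], method="average")  # 1..n, ties averaged
        # interpolate the reference distribution at (possibly fractional) ranks
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return out


def log2_quantile_normalize(
    raw: ExpressionMatrix, replicate_map: Mapping[str, Sequence[str]]
) -> ExpressionMatrix:
    """Two-stage normalization of replicated raw intensities.

    Stage 1: log2-transform, then quantile-normalize each individual's
    replicate columns and average them into one column per individual.
    Stage 2: quantile-normalize the per-individual columns, so that every
    individual ends with identical sorted values.

    ``replicate_map`` maps each individual id to the raw column names of
    its technical replicates (>= 1 each).
    """
    mat = raw.matrix()
    if (mat <= 0).any():
        raise ValueError("raw intensities must be strictly positive for log2")
    logged = pd.DataFrame(np.log2(mat), index=raw.probe_ids, columns=raw.sample_ids)

    individuals = list(replicate_map)
    stage1 = np.empty((logged.shape[0], len(individuals)))
    for k, ind in enumerate(individuals):
        reps = list(replicate_map[ind])
        if not reps:
            raise ValueError(f"individual {ind!r} has no replicates")
        missing = [r for r in reps if r not in logged.columns]
        if missing:
            raise ValueError(f"replicate columns not found: {missing}")
        block = logged[reps].to_numpy()
        stage1[:, k] = quantile_normalize(block).mean(axis=1)

    stage2 = quantile_normalize(stage1)
    values = pd.DataFrame(stage2, index=raw.probe_ids, columns=individuals)
    return ExpressionMatrix(values=values, probe_to_gene=dict(raw.probe_to_gene))


def pca_outlier_filter(
    expr: ExpressionMatrix, n_pcs: int = 2, sd_mult: float = 1.0
) -> list[str]:
    """Sample ids kept after excluding PCA outliers.

    Samples are scored on the leading principal components of the
    probe-centered expression matrix; sample ``i`` is excluded when
    ``|PC_k(i) - mean(PC_k)| > sd_mult * sd(PC_k)`` for any ``k <= n_pcs``.
    Zero-variance components exclude nobody.

    Note: under approximate Gaussianity a literal one-standard-deviation
    rule excludes a substantial fraction of samples; ``sd_mult`` is
    exposed so stricter cutoffs can be chosen.
    """
    n_samples = len(expr.sample_ids)
    if n_samples < 3:
        raise ValueError("need at least 3 samples for PCA outlier filtering")
    if n_pcs > n_samples - 1:
        raise ValueError(f"n_pcs={n_pcs} exceeds samples-1={n_samples - 1}")
    if sd_mult <= 1.0:
        warnings.warn(
            "sd_mult <= 1 excludes a large fraction of samples under "
            "approximate Gaussianity of PC scores",
            stacklevel=2,
        )
    mat = expr.matrix()  # probes x samples
    centered = (mat - mat.mean(axis=1, keepdims=True)).T  # samples x probes
    # sample-space PCs via SVD; scores = U * S
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    keep = np.ones(n_samples, dtype=bool)
    for k in range(n_pcs):
        pc = scores[:, k]
        sd = pc.std()
        if sd == 0 or not np.isfinite(sd):
            continue
        keep &= np.abs(pc - pc.mean()) <= sd_mult * sd
    return [s_id for s_id, k in zip(expr.sample_ids, keep) if k]


def standard_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform of one probe's expression.

    value_i -> Phi^{-1}((rank_i - 0.5) / n) with average ranks for ties;
    the output is invariant to any strictly increasing transform of the
    input and has mean ~0, sd ~1.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(values) == 0:
        raise ValueError("cannot standard-normalize a constant vector")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def standard_normalize_matrix(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply :func:`standard_normalize` to every probe (row)."""
    mat = expr.matrix()
    out = np.vstack([standard_normalize(row) for row in mat])
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=expr.probe_ids, columns=expr.sample_ids),
        probe_to_gene=dict(expr.probe_to_gene),
    )
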