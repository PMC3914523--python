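"""Normalization, presence calling and transcriptome divergence.

The three analysis states of the progression model (control progenitors,
short-term oncogene-induced progenitors, overt leukemia) are compared at
the whole-transcriptome level: counts are library-size normalized to
counts per million (CPM), each gene is called expressed or absent per
condition from its mean normalized abundance, pairwise divergence is the
squared Pearson correlation of the per-condition log2 summaries, and the
three expressed sets are partitioned into the seven disjoint regions of
a three-way Venn diagram.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import (NORMALIZED, RAW_COUNTS, ConditionProfile,
                     ExpressionMatrix, MatrixError)


def normalize_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to counts per million.

    Every value becomes ``count / sample_total * 1e6``; within-sample
    proportions are conserved.  A sample whose total count is zero has
    no defined scaling and is rejected by name.
    """
    if matrix.flavor != RAW_COUNTS:
        raise MatrixError("normalize_cpm expects a raw_counts matrix")
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise MatrixError(f"cannot normalize zero-total sample(s): {zero}")
    vals = matrix.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(vals, dict(matrix.condition_of), flavor=NORMALIZED)


def summarize_conditions(matrix: ExpressionMatrix, pseudocount: float = 1.0,
                         presence_threshold: float = 1.0) -> ConditionProfile:
    """Collapse replicates into per-condition summaries and presence calls.

    For each gene and condition the summary is
    ``log2(mean normalized abundance + pseudocount)`` and the gene is
    called present when the mean abundance is at or above
    ``presence_threshold`` (default 1 CPM, inclusive at the boundary).
    """
    if matrix.flavor != NORMALIZED:
        raise MatrixError("summarize_conditions expects a normalized matrix")
    if pseudocount <= 0:
        raise MatrixError("pseudocount must be positive")
    conds = matrix.conditions
    if not conds:
        raise MatrixError("matrix has no conditions")
    means = {}
    for c in conds:
        samples = matrix.samples_for(c)
        if not samples:
            raise MatrixError(f"condition {c!r} has no samples")
        means[c] = matrix.values[samples].mean(axis=1)
    mean_df = pd.DataFrame(means, index=matrix.values.index)[conds]
    log2 = np.log2(mean_df + pseudocount)
    presence = mean_df >= presence_threshold
    return ConditionProfile(mean_df, log2, presence, pseudocount,
                            presence_threshold)


def pairwise_r2(profile: ConditionProfile, cond_a: str, cond_b: str) -> float:
    """Squared Pearson correlation of two conditions' log2 summaries.

    The gene universe is the union of the two conditions' expressed
    sets: genes absent from both would contribute coincident points
    near the origin and inflate the correlation.
    """
    for c in (cond_a, cond_b):
        if c not in profile.conditions:
            raise MatrixError(f"unknown condition {c!r}")
    universe = profile.presence[cond_a] | profile.presence[cond_b]
    if int(universe.sum()) < 3:
        raise MatrixError("fewer than 3 genes expressed in either condition")
    x = profile.log2_summary.loc[universe, cond_a].to_numpy()
    y = profile.log2_summary.loc[universe, cond_b].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise MatrixError("zero variance in a summary vector")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def r2_matrix(profile: ConditionProfile) -> pd.DataFrame:
    """All pairwise R-squared values as a symmetric condition matrix."""
    conds = profile.conditions
    out = pd.DataFrame(np.ones((len(conds), len(conds))), index=conds,
                       columns=conds)
    for a, b in combinations(conds, 2):
        r2 = pairwise_r2(profile, a, b)
        out.loc[a, b] = out.loc[b, a] = r2
    return out


def venn_partition(profile: ConditionProfile) -> dict[tuple[str, ...], set[str]]:
    """Partition the union of three expressed sets into 7 disjoint regions.

    Keys are tuples of the condition names a region belongs to, in the
    profile's condition order; e.g. ``("control",)`` is the set of genes
    expressed only in control, and the three-condition key is the common
    core.  Region sets are pairwise disjoint and cover the union.
    """
    conds = profile.conditions
    if len(conds) != 3:
        raise MatrixError(f"venn_partition requires exactly 3 conditions, "
                          f"got {len(conds)}")
    expressed = {c: profile.expressed_set(c) for c in conds}
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, 4):
        for combo in combinations(conds, r):
            inside = set.intersection(*(expressed[c] for c in combo))
            outside = set.union(*(expressed[c] for c in conds
                                  if c not in combo), set())
            regions[combo] = inside - outside
    return regions


def venn_sizes(regions: dict[tuple[str, ...], set[str]]) -> dict[tuple[str, ...], int]:
    return {k: len(v) for k, v in regions.items()}
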