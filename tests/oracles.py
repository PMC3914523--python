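"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (scalar loops, exhaustive
enumeration) and shares no code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def classify_oracle(c: float, s: float, l: float, pc: bool, ps: bool,
                    pl: bool, fold_min: float = 1.0,
                    flat_max: float = 1.0) -> str:
    """Rule-table classifier, evaluated one condition at a time."""
    up_st = (s - c) >= fold_min
    down_st = (s - c) <= -fold_min
    flat_st = abs(s - c) < flat_max
    up_l = (l - s) >= fold_min
    down_l = (l - s) <= -fold_min
    flat_l = abs(l - s) < flat_max
    flat_lc = abs(l - c) < flat_max
    if (not pc) and (not ps) and pl:
        return "UNIQUE_L"
    if pc and ps and (not pl):
        return "SHUTDOWN_L"
    if up_st and up_l:
        return "PROGRESSIVE_UP"
    if down_st and down_l:
        return "PROGRESSIVE_DOWN"
    if flat_st and up_l:
        return "SPECIFIC_UP"
    if flat_st and down_l:
        return "SPECIFIC_DOWN"
    if (not pc) and (not ps) and (not pl):
        return "ABSENT"
    if flat_st and flat_l and flat_lc:
        return "STABLE"
    return "OTHER"


def running_sum_oracle(scores: np.ndarray, member: np.ndarray,
                       weight_exponent: float) -> tuple[float, list[float]]:
    """Step the weighted running sum one position at a time."""
    n = len(scores)
    n_hits = int(member.sum())
    denom = sum(abs(scores[i]) ** weight_exponent
                for i in range(n) if member[i])
    path, total = [], 0.0
    for i in range(n):
        if member[i]:
            if denom > 0:
                total += abs(scores[i]) ** weight_exponent / denom
            else:
                total += 1.0 / n_hits
        else:
            total -= 1.0 / (n - n_hits)
        path.append(total)
    es = 0.0
    for v in path:
        if abs(v) > abs(es):
            es = v
    return es, path


def assert_es_matches_path(es: float, path: list[float]) -> None:
    """Check an ES against an independently stepped running sum.

    When the positive maximum and negative minimum of the path tie in
    magnitude (to rounding), either sign is a valid extremum and only
    the magnitude is compared.
    """
    maxpos, minneg = max(path), min(path)
    if abs(abs(maxpos) - abs(minneg)) < 1e-9:
        assert abs(abs(es) - abs(maxpos)) < 1e-9
    else:
        expected = maxpos if abs(maxpos) > abs(minneg) else minneg
        assert abs(es - expected) < 1e-9


def presence_oracle(values: pd.DataFrame, condition_of: dict[str, str],
                    threshold: float) -> dict[tuple[str, str], bool]:
    """Per-gene, per-condition mean-and-compare presence calls."""
    out = {}
    conditions = sorted(set(condition_of.values()))
    for gene in values.index:
        for cond in conditions:
            samples = [s for s in values.columns if condition_of[s] == cond]
            mean = sum(values.loc[gene, s] for s in samples) / len(samples)
            out[(gene, cond)] = mean >= threshold
    return out


def venn_oracle(expressed: dict[str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """Exhaustive per-gene membership enumeration over three sets."""
    conds = list(expressed)
    assert len(conds) == 3
    universe = set().union(*expressed.values())
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in (1, 2, 3):
        for combo in combinations(conds, r):
            regions[combo] = set()
    for gene in universe:
        membership = tuple(c for c in conds if gene in expressed[c])
        regions[membership].add(gene)
    return regions


def hypergeom_enumeration_p(universe: list[str], query_size: int,
                            annotation: set[str], min_overlap: int) -> float:
    """P(overlap >= min_overlap) by enumerating every possible query draw."""
    total = comb(len(universe), query_size)
    hits = 0
    for draw in combinations(universe, query_size):
        if len(set(draw) & annotation) >= min_overlap:
            hits += 1
    return hits / total


def cascade_oracle(labels: pd.Series, omap_table: pd.DataFrame,
                   cohort_values: pd.DataFrame,
                   cohort_condition_of: dict[str, str],
                   baseline_values: pd.DataFrame,
                   baseline_condition_of: dict[str, str],
                   min_fold: float, epsilon: float,
                   max_level: float) -> set[str]:
    """Single-pass conjunction filter: evaluate every criterion per gene."""
    mouse_counts = omap_table["mouse_id"].value_counts()
    human_counts = omap_table["human_id"].value_counts()
    survivors = set()
    for gene, label in labels.items():
        if label not in ("UNIQUE_L", "SPECIFIC_UP"):
            continue
        rows = omap_table[omap_table["mouse_id"] == gene]
        if len(rows) != 1:
            continue
        human = rows["human_id"].iloc[0]
        if mouse_counts[gene] != 1 or human_counts[human] != 1:
            continue
        if human not in cohort_values.index:
            continue
        case = [s for s in cohort_values.columns
                if cohort_condition_of[s] == "case"]
        ctrl = [s for s in cohort_values.columns
                if cohort_condition_of[s] == "control"]
        ratio = ((cohort_values.loc[human, case].mean() + epsilon)
                 / (cohort_values.loc[human, ctrl].mean() + epsilon))
        if ratio < min_fold:
            continue
        if human in baseline_values.index:
            groups = sorted(set(baseline_condition_of.values()))
            peak = max(
                baseline_values.loc[
                    human, [s for s in baseline_values.columns
                            if baseline_condition_of[s] == g]].mean()
                for g in groups)
            if peak > max_level:
                continue
        survivors.add(gene)
    return survivors
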