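"""Gene-set enrichment: weighted running-sum statistic with a
permutation null, plus a hypergeometric over-representation test.

The enrichment statistic follows the classical weighted
Kolmogorov-Smirnov-like running sum: genes are ranked by a case/control
metric (signal-to-noise by default), the sum increases by
``|metric|^p / sum_hits |metric|^p`` at gene-set members and decreases
by ``1 / (N - N_hits)`` elsewhere, and the enrichment score (ES) is the
extremum of largest absolute value.  Significance comes from a seeded
permutation null (random member sets by default, or sample-label
shuffling for cohorts with enough samples); the nominal p-value uses
the standard add-one permutation estimator and is therefore floored at
``1 / (n_permutations + 1)``.

The over-representation test is the generic hypergeometric tail with
Benjamini-Hochberg adjustment across annotation sets; it stands in for
proprietary pathway knowledge bases and works against any user-supplied
collection of sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, MatrixError


class EnrichmentError(ValueError):
    """Raised for invalid enrichment inputs."""


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene ids (unique, non-empty)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise EnrichmentError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_list(cls, name: str, genes: list[str],
                  description: str = "") -> "GeneSet":
        if len(genes) != len(set(genes)):
            raise EnrichmentError(f"gene set {name!r} has duplicate members")
        return cls(name, frozenset(genes), description)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members, tab-separated)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(f"malformed GMT line: {line[:80]!r}")
            sets.append(GeneSet.from_list(fields[0], fields[2:], fields[1]))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            members = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.description}\t{members}\n")


# ---------------------------------------------------------------- ranking

def rank_genes(cohort: ExpressionMatrix, case_label: str = "case",
               control_label: str = "control", sd_floor_frac: float = 0.2,
               sd_floor_abs: float = 0.2) -> pd.Series:
    """Rank genes by descending signal-to-noise ratio.

    The metric is ``(mean_case - mean_control) / (sd_case + sd_control)``
    with each group standard deviation floored at
    ``max(sd_floor_frac * |mean|, sd_floor_abs)`` so that near-constant
    genes on small groups do not explode the ratio.  Ties are broken
    lexicographically by gene id, so the ranking is fully deterministic.
    """
    for lbl in (case_label, control_label):
        if lbl not in cohort.conditions:
            raise EnrichmentError(f"cohort has no condition {lbl!r}")
        if len(cohort.samples_for(lbl)) < 2:
            raise EnrichmentError(f"group {lbl!r} has fewer than 2 samples")
    case = cohort.values[cohort.samples_for(case_label)]
    ctrl = cohort.values[cohort.samples_for(control_label)]

    def _floored_sd(df: pd.DataFrame) -> pd.Series:
        sd = df.std(axis=1, ddof=1)
        floor = np.maximum(sd_floor_frac * df.mean(axis=1).abs(), sd_floor_abs)
        return np.maximum(sd, floor)

    metric = (case.mean(axis=1) - ctrl.mean(axis=1)) / \
        (_floored_sd(case) + _floored_sd(ctrl))
    order = pd.DataFrame({"score": metric, "gene": metric.index})
    order = order.sort_values(["score", "gene"], ascending=[False, True])
    return pd.Series(order["score"].to_numpy(), index=order["gene"].to_numpy(),
                     name="score")


# ------------------------------------------------------------ running sum

def _running_sum(scores: np.ndarray, hit: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    n = len(scores)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise EnrichmentError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise EnrichmentError("gene set covers the whole ranked list")
    w = np.abs(scores[hit]) ** weight_exponent
    denom = w.sum()
    if denom == 0:  # all hit metrics zero: fall back to equal weights
        w = np.ones(n_hits)
        denom = float(n_hits)
    steps = np.full(n, -1.0 / (n - n_hits))
    steps[hit] = w / denom
    return np.cumsum(steps)


def enrichment_score(ranked: pd.Series, gene_set: GeneSet,
                     weight_exponent: float = 1.0,
                     ) -> tuple[float, np.ndarray, list[str]]:
    """Running-sum enrichment score of one gene set in a ranked list.

    Returns ``(ES, running_sum, leading_edge)``.  ES is the running-sum
    value of largest absolute magnitude (earliest position on ties); the
    leading edge contains the members at or before a positive extremum,
    or at and after a negative one.
    """
    if weight_exponent < 0:
        raise EnrichmentError("weight_exponent must be >= 0")
    genes = ranked.index.to_numpy()
    hit = np.isin(genes, list(gene_set.genes))
    running = _running_sum(ranked.to_numpy(dtype=float), hit, weight_exponent)
    i_star = int(np.argmax(np.abs(running)))
    es = float(running[i_star])
    if es >= 0:
        edge = genes[: i_star + 1][hit[: i_star + 1]]
    else:
        edge = genes[i_star:][hit[i_star:]]
    return es, running, list(edge)


@dataclass
class EnrichmentResult:
    """One gene set against one ranked contrast."""

    set_name: str
    es: float
    nes: float
    p_nominal: float
    n_permutations: int
    leading_edge: list[str]
    mode: str
    seed: int
    note: str = ""

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mode={self.mode} seed={self.seed} "
                     f"n_permutations={self.n_permutations}\n")
            if self.note:
                fh.write(f"# note={self.note}\n")
            fh.write("set\tES\tNES\tp_nominal\tleading_edge\n")
            fh.write(f"{self.set_name}\t{self.es:.6g}\t{self.nes:.6g}\t"
                     f"{self.p_nominal:.6g}\t{','.join(self.leading_edge)}\n")


def _null_es_gene_label(ranked: pd.Series, set_size: int, n_permutations: int,
                        weight_exponent: float,
                        rng: np.random.Generator) -> np.ndarray:
    scores = ranked.to_numpy(dtype=float)
    n = len(scores)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        hit = np.zeros(n, dtype=bool)
        hit[rng.choice(n, size=set_size, replace=False)] = True
        running = _running_sum(scores, hit, weight_exponent)
        out[i] = running[np.argmax(np.abs(running))]
    return out


def permutation_p(source: pd.Series | ExpressionMatrix, gene_set: GeneSet,
                  n_permutations: int = 1000, seed: int = 0,
                  mode: str = "gene_label", weight_exponent: float = 1.0,
                  case_label: str = "case", control_label: str = "control",
                  ) -> EnrichmentResult:
    """Permutation significance of an enrichment score.

    ``mode="gene_label"`` (default) draws random member sets of the same
    size from the ranked list; ``mode="sample_label"`` reshuffles the
    case/control labels and re-ranks (requires an
    :class:`~leukotraj.matrix.ExpressionMatrix` source).  Cohorts with
    fewer than 7 samples cannot support enough label permutations, so
    the exhaustive set of label assignments is used instead and the
    degradation is recorded in the result's ``note``.

    ``p = (1 + #{same-sign null |ES*| >= |ES|}) / (1 + #{same-sign null})``
    and ``NES = ES / mean(|ES*| over same-sign nulls)``.
    """
    if n_permutations < 100:
        raise EnrichmentError("n_permutations must be >= 100")
    if mode not in ("gene_label", "sample_label"):
        raise EnrichmentError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    note = ""

    if mode == "gene_label":
        if isinstance(source, ExpressionMatrix):
            ranked = rank_genes(source, case_label, control_label)
        else:
            ranked = source
        set_size = int(np.isin(ranked.index.to_numpy(),
                               list(gene_set.genes)).sum())
        es, _run, edge = enrichment_score(ranked, gene_set, weight_exponent)
        null = _null_es_gene_label(ranked, set_size, n_permutations,
                                   weight_exponent, rng)
        n_used = n_permutations
    else:
        if not isinstance(source, ExpressionMatrix):
            raise EnrichmentError(
                "sample_label mode needs an ExpressionMatrix source")
        ranked = rank_genes(source, case_label, control_label)
        es, _run, edge = enrichment_score(ranked, gene_set, weight_exponent)
        samples = source.sample_ids
        case_n = len(source.samples_for(case_label))
        n_total = len(samples)
        values = source.values

        def _es_for(case_idx: tuple[int, ...]) -> float:
            cond = {s: (case_label if i in case_idx else control_label)
                    for i, s in enumerate(samples)}
            perm = ExpressionMatrix(values, cond, flavor=source.flavor)
            r = rank_genes(perm, case_label, control_label)
            e, _r, _le = enrichment_score(r, gene_set, weight_exponent)
            return e

        if n_total < 7:
            combos = list(combinations(range(n_total), case_n))
            null = np.array([_es_for(c) for c in combos])
            n_used = len(combos)
            note = (f"only {n_total} samples: exhaustive label assignments "
                    f"({n_used}) used instead of {n_permutations} random "
                    f"permutations")
        else:
            null = np.empty(n_permutations)
            idx = np.arange(n_total)
            for i in range(n_permutations):
                perm_idx = rng.permutation(idx)[:case_n]
                null[i] = _es_for(tuple(perm_idx))
            n_used = n_permutations

    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
    p = (1 + n_extreme) / (1 + n_same)
    mean_abs = float(np.abs(null[same_sign]).mean()) if n_same else np.nan
    nes = es / mean_abs if n_same and mean_abs > 0 else float("nan")
    return EnrichmentResult(gene_set.name, es, float(nes), float(p), n_used,
                            edge, mode, seed, note)


# ------------------------------------------------- over-representation

def overrepresentation(query_set: set[str], universe: set[str],
                       annotation_sets: list[GeneSet]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query set.

    For each annotation set the tail probability of observing at least
    the seen overlap is computed under sampling without replacement from
    the universe; Benjamini-Hochberg adjustment is applied across sets.
    """
    if not universe:
        raise EnrichmentError("empty universe")
    if not query_set:
        raise EnrichmentError("empty query set")
    if not query_set <= universe:
        raise EnrichmentError("query set is not contained in the universe")
    if not annotation_sets:
        raise EnrichmentError("no annotation sets supplied")
    m = len(universe)
    nq = len(query_set)
    rows = []
    for s in annotation_sets:
        members = s.genes & universe
        overlap = len(query_set & members)
        # P(X >= overlap), X ~ Hypergeom(M=m, n=|members|, N=nq)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), nq))
        rows.append((s.name, len(members), overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "set"]).reset_index(drop=True)
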