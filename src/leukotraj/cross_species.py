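"""Cross-species candidate prioritization cascade.

Leukemia-specific mouse transcripts (uniquely expressed or specifically
upregulated in the leukemic state) are carried through a conjunction of
filters meant to isolate plausible therapeutic targets:

1. map each mouse gene to a human ortholog (strict 1:1 by default);
2. require at least ``min_fold`` mean upregulation in a human
   case/control cohort;
3. require absence or weak expression in a normal hematopoietic
   baseline panel (hard filter);
4. survey a normal-tissue panel (annotation only by default).

Every gene's fate at every stage is recorded, so survivors + dropped
always account exactly for the entrants of each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .trajectory import SPECIFIC_UP, UNIQUE_L, TrajectoryTable

ONE_TO_ONE = "one_to_one"
ONE_TO_MANY = "one_to_many"
MANY_TO_ONE = "many_to_one"
MANY_TO_MANY = "many_to_many"

#: mouse evidence classes admitted into the cascade
CANDIDATE_CLASSES = (UNIQUE_L, SPECIFIC_UP)


class CascadeError(ValueError):
    """Raised on schema violations in cascade inputs."""


def _infer_classes(table: pd.DataFrame) -> pd.Series:
    mouse_mult = table.groupby("mouse_id")["human_id"].transform("size")
    human_mult = table.groupby("human_id")["mouse_id"].transform("size")
    cls = np.where(
        (mouse_mult == 1) & (human_mult == 1), ONE_TO_ONE,
        np.where((mouse_mult > 1) & (human_mult > 1), MANY_TO_MANY,
                 np.where(mouse_mult > 1, ONE_TO_MANY, MANY_TO_ONE)))
    return pd.Series(cls, index=table.index)


@dataclass
class OrthologMap:
    """Mouse-to-human ortholog pairs with mapping-multiplicity classes."""

    table: pd.DataFrame  # columns: mouse_id, human_id, mapping_class

    def __post_init__(self) -> None:
        t = self.table
        required = {"mouse_id", "human_id"}
        if not required.issubset(t.columns):
            raise CascadeError("ortholog map needs mouse_id and human_id columns")
        if t.duplicated(["mouse_id", "human_id"]).any():
            raise CascadeError("duplicate (mouse, human) pairs in ortholog map")
        # the class column is derived from the table's actual multiplicities,
        # which keeps it consistent by construction
        self.table = t.assign(mapping_class=_infer_classes(t)).reset_index(drop=True)

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "OrthologMap":
        return cls(pd.DataFrame(pairs, columns=["mouse_id", "human_id"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        return cls(df[["mouse_id", "human_id"]])


def map_orthologs(genes: list[str], omap: OrthologMap,
                  policy: str = "one_to_one_only",
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve mouse genes to human orthologs under a mapping policy.

    Under ``one_to_one_only`` (default) only strict 1:1 pairs pass;
    ``best_effort`` keeps the lexicographically first human partner of
    ambiguous genes.  Returns ``(pairs, dropped)`` where ``pairs`` has
    columns mouse_id/human_id and ``dropped`` records every rejected
    gene with a reason (``unmapped`` or ``ambiguous``).
    """
    if policy not in ("one_to_one_only", "best_effort"):
        raise CascadeError(f"unknown ortholog policy {policy!r}")
    if omap.table.empty:
        raise CascadeError("empty ortholog map")
    mapped, dropped = [], []
    by_mouse = {m: g.sort_values("human_id")
                for m, g in omap.table.groupby("mouse_id")}
    for gene in genes:
        sub = by_mouse.get(gene)
        if sub is None:
            dropped.append((gene, "unmapped"))
        elif (sub["mapping_class"] == ONE_TO_ONE).all() and len(sub) == 1:
            mapped.append((gene, sub["human_id"].iloc[0]))
        elif policy == "best_effort":
            mapped.append((gene, sub["human_id"].iloc[0]))
        else:
            dropped.append((gene, "ambiguous"))
    pairs = pd.DataFrame(mapped, columns=["mouse_id", "human_id"])
    drop = pd.DataFrame(dropped, columns=["mouse_id", "reason"])
    return pairs, drop


def cohort_fold_filter(pairs: pd.DataFrame, cohort: ExpressionMatrix,
                       min_fold: float = 2.0, epsilon: float = 0.5,
                       case_label: str = "case", control_label: str = "control",
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep genes at least ``min_fold`` upregulated in the case group.

    The fold ratio is ``(mean_case + eps) / (mean_control + eps)`` with a
    small stabilizer ``eps`` so that genes silent in controls do not
    divide by zero; the boundary is inclusive (ratio == min_fold passes).
    """
    for lbl in (case_label, control_label):
        if lbl not in cohort.conditions:
            raise CascadeError(f"cohort has no condition {lbl!r}")
    case_mean = cohort.values[cohort.samples_for(case_label)].mean(axis=1)
    ctrl_mean = cohort.values[cohort.samples_for(control_label)].mean(axis=1)
    kept, dropped = [], []
    for mouse, human in pairs[["mouse_id", "human_id"]].itertuples(index=False):
        if human not in case_mean.index:
            dropped.append((mouse, human, np.nan, "absent_from_cohort"))
            continue
        ratio = (case_mean[human] + epsilon) / (ctrl_mean[human] + epsilon)
        if ratio >= min_fold:
            kept.append((mouse, human, ratio))
        else:
            dropped.append((mouse, human, ratio, "below_fold"))
    surv = pd.DataFrame(kept, columns=["mouse_id", "human_id", "cohort_fold"])
    drop = pd.DataFrame(dropped,
                        columns=["mouse_id", "human_id", "cohort_fold", "reason"])
    return surv, drop


def baseline_group_means(baseline: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean abundance in each sample group of a baseline panel."""
    return pd.DataFrame(
        {g: baseline.values[baseline.samples_for(g)].mean(axis=1)
         for g in baseline.conditions})


def default_max_level(baseline: ExpressionMatrix) -> float:
    """Rank-based default cut-off: the 25th percentile of all per-gene,
    per-group mean abundances of the baseline panel itself.  Absolute
    thresholds do not transfer across platforms; a within-panel quantile
    does."""
    gm = baseline_group_means(baseline)
    return float(np.percentile(gm.to_numpy().ravel(), 25.0))


def normal_expression_filter(pairs: pd.DataFrame, baseline: ExpressionMatrix,
                             max_level: float | None = None,
                             mode: str = "hard",
                             missing_policy: str = "pass_flag",
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter (or annotate) genes by their normal-baseline expression.

    In ``hard`` mode a gene is dropped when its maximum per-group mean
    exceeds ``max_level`` (default: the panel's own 25th percentile of
    group means); in ``annotation`` mode levels are recorded and nothing
    is dropped.  Genes missing from the panel pass with a flag under the
    default missing policy, or are dropped under ``drop``.
    """
    if mode not in ("hard", "annotation"):
        raise CascadeError(f"unknown filter mode {mode!r}")
    if missing_policy not in ("pass_flag", "drop"):
        raise CascadeError(f"unknown missing policy {missing_policy!r}")
    if max_level is None:
        max_level = default_max_level(baseline)
    gm = baseline_group_means(baseline)
    kept, dropped = [], []
    for mouse, human in pairs[["mouse_id", "human_id"]].itertuples(index=False):
        if human not in gm.index:
            if missing_policy == "pass_flag":
                kept.append((mouse, human, np.nan, "", True))
            else:
                dropped.append((mouse, human, np.nan, "absent_from_baseline"))
            continue
        levels = gm.loc[human]
        peak_group = str(levels.idxmax())
        peak = float(levels.max())
        if mode == "hard" and peak > max_level:
            dropped.append((mouse, human, peak,
                            f"expressed_in_baseline:{peak_group}"))
        else:
            kept.append((mouse, human, peak, peak_group, False))
    surv = pd.DataFrame(kept, columns=["mouse_id", "human_id", "baseline_level",
                                       "baseline_peak_group", "baseline_missing"])
    drop = pd.DataFrame(dropped, columns=["mouse_id", "human_id",
                                          "baseline_level", "reason"])
    return surv, drop


@dataclass
class CandidateTable:
    """Outcome of the cascade: one row per entrant with per-stage flags."""

    records: pd.DataFrame
    stage_counts: pd.DataFrame  # stage, entered, survived, dropped

    @property
    def candidates(self) -> list[str]:
        mask = self.records["verdict"]
        return list(self.records.index[mask])

    def to_tsv(self, records_path: str | Path,
               summary_path: str | Path | None = None) -> None:
        out = self.records.copy()
        out.index.name = "mouse_id"
        for col in out.columns:
            if out[col].dtype == bool:
                out[col] = out[col].astype(int)
        out.to_csv(records_path, sep="\t", float_format="%.6g")
        if summary_path is not None:
            self.stage_counts.to_csv(summary_path, sep="\t", index=False)


@dataclass
class CascadeConfig:
    ortholog_policy: str = "one_to_one_only"
    min_fold: float = 2.0
    epsilon: float = 0.5
    max_level: float | None = None
    tissue_mode: str = "annotation"
    missing_policy: str = "pass_flag"
    case_label: str = "case"
    control_label: str = "control"


def run_cascade(trajectory: TrajectoryTable, omap: OrthologMap,
                cohort: ExpressionMatrix,
                baselines: dict[str, ExpressionMatrix],
                config: CascadeConfig = CascadeConfig()) -> CandidateTable:
    """Run the full prioritization cascade and account for every gene.

    ``baselines`` maps scope names to panels; ``"hematopoietic"`` is the
    hard filter, ``"tissue"`` (optional) is surveyed in the configured
    mode.  The final verdict is the conjunction of all hard criteria.
    """
    if "hematopoietic" not in baselines:
        raise CascadeError("cascade requires a 'hematopoietic' baseline panel")

    entrants = trajectory.genes_with(*CANDIDATE_CLASSES)
    rec = pd.DataFrame(index=pd.Index(entrants, name="mouse_id"))
    rec["evidence_class"] = trajectory.labels.loc[entrants]
    rec["human_id"] = ""
    rec["pass_ortholog"] = False
    rec["cohort_fold"] = np.nan
    rec["pass_cohort"] = False
    rec["baseline_level"] = np.nan
    rec["pass_baseline"] = False
    rec["drop_reason"] = ""

    stages = [("select_evidence_class", len(trajectory.table), len(entrants))]

    pairs, drop_map = map_orthologs(entrants, omap, config.ortholog_policy)
    rec.loc[pairs["mouse_id"].to_numpy(), "human_id"] = pairs["human_id"].to_numpy()
    rec.loc[pairs["mouse_id"].to_numpy(), "pass_ortholog"] = True
    for m, reason in drop_map.itertuples(index=False):
        rec.loc[m, "drop_reason"] = f"ortholog:{reason}"
    stages.append(("map_orthologs", len(entrants), len(pairs)))

    surv_cohort, drop_cohort = cohort_fold_filter(
        pairs, cohort, config.min_fold, config.epsilon,
        config.case_label, config.control_label)
    if len(surv_cohort):
        rec.loc[surv_cohort["mouse_id"].to_numpy(), "cohort_fold"] = \
            surv_cohort["cohort_fold"].to_numpy()
        rec.loc[surv_cohort["mouse_id"].to_numpy(), "pass_cohort"] = True
    for m, _h, ratio, reason in drop_cohort.itertuples(index=False):
        rec.loc[m, "cohort_fold"] = ratio
        rec.loc[m, "drop_reason"] = f"cohort:{reason}"
    stages.append(("cohort_fold_filter", len(pairs), len(surv_cohort)))

    surv_base, drop_base = normal_expression_filter(
        surv_cohort, baselines["hematopoietic"], config.max_level,
        mode="hard", missing_policy=config.missing_policy)
    if len(surv_base):
        rec.loc[surv_base["mouse_id"].to_numpy(), "baseline_level"] = \
            surv_base["baseline_level"].to_numpy()
        rec.loc[surv_base["mouse_id"].to_numpy(), "pass_baseline"] = True
    for m, _h, level, reason in drop_base.itertuples(index=False):
        rec.loc[m, "baseline_level"] = level
        rec.loc[m, "drop_reason"] = f"baseline:{reason}"
    stages.append(("normal_expression_filter", len(surv_cohort), len(surv_base)))

    if "tissue" in baselines:
        tissue_surv, tissue_drop = normal_expression_filter(
            surv_base, baselines["tissue"], config.max_level,
            mode=config.tissue_mode, missing_policy=config.missing_policy)
        rec["tissue_level"] = np.nan
        rec["tissue_peak_group"] = ""
        if len(tissue_surv):
            rec.loc[tissue_surv["mouse_id"].to_numpy(), "tissue_level"] = \
                tissue_surv["baseline_level"].to_numpy()
            rec.loc[tissue_surv["mouse_id"].to_numpy(), "tissue_peak_group"] = \
                tissue_surv["baseline_peak_group"].to_numpy()
        for m, _h, level, reason in tissue_drop.itertuples(index=False):
            rec.loc[m, "tissue_level"] = level
            rec.loc[m, "drop_reason"] = f"tissue:{reason}"
        n_tissue_surv = len(tissue_surv)
        stages.append(("tissue_survey", len(surv_base), n_tissue_surv))
        final_survivors = set(tissue_surv["mouse_id"])
    else:
        final_survivors = set(surv_base["mouse_id"])

    rec["verdict"] = (rec["pass_ortholog"] & rec["pass_cohort"]
                      & rec["pass_baseline"]
                      & rec.index.to_series().isin(final_survivors))

    counts = pd.DataFrame(stages, columns=["stage", "entered", "survived"])
    counts["dropped"] = counts["entered"] - counts["survived"]
    return CandidateTable(rec, counts)
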