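import numpy as np
import pandas as pd
import pytest

import leukotraj as lt
from leukotraj.cross_species import (CANDIDATE_CLASSES, CascadeConfig,
                                     CascadeError, OrthologMap,
                                     default_max_level)
from leukotraj.matrix import ExpressionMatrix
from leukotraj.trajectory import (SPECIFIC_UP, STABLE, UNIQUE_L,
                                  TrajectoryTable)
from oracles import cascade_oracle


def _traj(labels: dict[str, str]) -> TrajectoryTable:
    df = pd.DataFrame({"label": pd.Series(labels),
                       "lfc_l_vs_ctrl": 0.0, "lfc_st_vs_ctrl": 0.0,
                       "lfc_l_vs_st": 0.0})
    return TrajectoryTable(df)


def _matrix(rows: dict[str, list[float]], condition_of: dict[str, str],
            columns: list[str]) -> ExpressionMatrix:
    values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return ExpressionMatrix(values, condition_of, flavor="normalized")


# ------------------------------------------------------------- orthologs

def test_one_to_one_map_passes_everything():
    omap = OrthologMap.from_pairs([("m1", "h1"), ("m2", "h2")])
    pairs, dropped = lt.map_orthologs(["m1", "m2"], omap)
    assert len(pairs) == 2 and dropped.empty


def test_unmapped_gene_reported():
    omap = OrthologMap.from_pairs([("m1", "h1")])
    pairs, dropped = lt.map_orthologs(["m1", "mX"], omap)
    assert dropped.set_index("mouse_id").loc["mX", "reason"] == "unmapped"


def test_ambiguous_genes_dropped_under_strict_policy():
    omap = OrthologMap.from_pairs(
        [("m1", "h1"), ("m2", "h2a"), ("m2", "h2b"), ("m3", "h3"),
         ("m4", "h3")])
    pairs, dropped = lt.map_orthologs(["m1", "m2", "m3", "m4"], omap)
    assert set(pairs["mouse_id"]) == {"m1"}
    assert set(dropped["mouse_id"]) == {"m2", "m3", "m4"}
    assert (dropped["reason"] == "ambiguous").all()


def test_best_effort_keeps_lexicographic_first_partner():
    omap = OrthologMap.from_pairs([("m2", "h2b"), ("m2", "h2a")])
    pairs, dropped = lt.map_orthologs(["m2"], omap, policy="best_effort")
    assert pairs.loc[0, "human_id"] == "h2a"
    assert dropped.empty


def test_mixed_map_accounting_matches_recomputed_sets(small_cfg):
    genes = [f"mg{i:04d}" for i in range(1, 201)]
    cfg = lt.SimulationConfig(ambiguous_ortholog_fraction=0.2, seed=6)
    omap = lt.simulate_ortholog_map(cfg, genes)
    pairs, dropped = lt.map_orthologs(genes, omap)
    assert len(pairs) + len(dropped) == len(genes)
    ambiguous = set(omap.table.loc[omap.table["mapping_class"] != "one_to_one",
                                   "mouse_id"])
    assert set(dropped["mouse_id"]) == ambiguous  # no unmapped planted here


def test_empty_map_is_an_error():
    with pytest.raises(CascadeError):
        lt.map_orthologs(["m1"], OrthologMap(pd.DataFrame(
            columns=["mouse_id", "human_id"])))


# ----------------------------------------------------------- fold filter

def test_fold_boundary_is_inclusive_with_negligible_epsilon():
    pairs = pd.DataFrame({"mouse_id": ["m1"], "human_id": ["h1"]})
    cohort = _matrix({"h1": [10.0, 10.0, 5.0, 5.0]},
                     {"c1": "case", "c2": "case", "k1": "control",
                      "k2": "control"}, ["c1", "c2", "k1", "k2"])
    surv, dropped = lt.cohort_fold_filter(pairs, cohort, min_fold=2.0,
                                          epsilon=0.0)
    assert list(surv["mouse_id"]) == ["m1"]
    assert surv.loc[0, "cohort_fold"] == pytest.approx(2.0)


def test_flat_gene_dropped_and_missing_gene_reported():
    pairs = pd.DataFrame({"mouse_id": ["m1", "m2"],
                          "human_id": ["h1", "h_missing"]})
    cohort = _matrix({"h1": [5.0, 5.0, 5.0, 5.0]},
                     {"c1": "case", "c2": "case", "k1": "control",
                      "k2": "control"}, ["c1", "c2", "k1", "k2"])
    surv, dropped = lt.cohort_fold_filter(pairs, cohort)
    assert surv.empty
    reasons = dict(zip(dropped["mouse_id"], dropped["reason"]))
    assert reasons == {"m1": "below_fold", "m2": "absent_from_cohort"}


def test_fold_filter_matches_bruteforce_recomputation(small_study):
    from leukotraj.simulate import human_ortholog_id
    cfg, _m, truth = small_study
    cohort = lt.simulate_cohort(cfg, truth)
    genes = list(truth.trajectory.index[:100])
    pairs = pd.DataFrame({"mouse_id": genes,
                          "human_id": [human_ortholog_id(g) for g in genes]})
    surv, dropped = lt.cohort_fold_filter(pairs, cohort, min_fold=2.0,
                                          epsilon=0.5)
    case = cohort.values[cohort.samples_for("case")].mean(axis=1)
    ctrl = cohort.values[cohort.samples_for("control")].mean(axis=1)
    expected = {m for m, h in zip(pairs["mouse_id"], pairs["human_id"])
                if (case[h] + 0.5) / (ctrl[h] + 0.5) >= 2.0}
    assert set(surv["mouse_id"]) == expected
    assert len(surv) + len(dropped) == len(pairs)


# ------------------------------------------------------- baseline filter

def _baseline():
    cond = {"b1": "HSC", "b2": "HSC", "b3": "blood", "b4": "blood"}
    rows = {"h_silent": [0.0, 0.0, 0.0, 0.0],
            "h_low": [0.5, 0.7, 0.2, 0.1],
            "h_high": [0.1, 0.2, 40.0, 50.0]}
    return _matrix(rows, cond, ["b1", "b2", "b3", "b4"])


def test_silent_gene_survives_with_zero_level():
    pairs = pd.DataFrame({"mouse_id": ["m1"], "human_id": ["h_silent"]})
    surv, dropped = lt.normal_expression_filter(pairs, _baseline(),
                                                max_level=1.0)
    assert surv.loc[0, "baseline_level"] == 0.0
    assert dropped.empty


def test_expressed_gene_dropped_with_group_named():
    pairs = pd.DataFrame({"mouse_id": ["m1"], "human_id": ["h_high"]})
    surv, dropped = lt.normal_expression_filter(pairs, _baseline(),
                                                max_level=1.0)
    assert surv.empty
    assert dropped.loc[0, "reason"] == "expressed_in_baseline:blood"


def test_annotation_mode_drops_nothing():
    pairs = pd.DataFrame({"mouse_id": ["m1", "m2"],
                          "human_id": ["h_high", "h_silent"]})
    surv, dropped = lt.normal_expression_filter(pairs, _baseline(),
                                                max_level=1.0,
                                                mode="annotation")
    assert dropped.empty and len(surv) == 2


def test_missing_gene_passes_with_flag_by_default():
    pairs = pd.DataFrame({"mouse_id": ["m1"], "human_id": ["h_unknown"]})
    surv, _ = lt.normal_expression_filter(pairs, _baseline(), max_level=1.0)
    assert bool(surv.loc[0, "baseline_missing"])
    surv2, dropped2 = lt.normal_expression_filter(
        pairs, _baseline(), max_level=1.0, missing_policy="drop")
    assert surv2.empty and len(dropped2) == 1


def test_planted_silent_set_recovered_from_simulated_baseline(small_study):
    from leukotraj.simulate import BASELINE_SILENT, human_ortholog_id
    cfg, _m, truth = small_study
    base = lt.simulate_baseline(cfg, truth, "hematopoietic")
    genes = list(truth.trajectory.index)
    pairs = pd.DataFrame({"mouse_id": genes,
                          "human_id": [human_ortholog_id(g) for g in genes]})
    surv, _ = lt.normal_expression_filter(pairs, base, max_level=0.0)
    planted = {g for g, s in truth.baseline_status["hematopoietic"].items()
               if s == BASELINE_SILENT}
    assert set(surv.loc[~surv["baseline_missing"], "mouse_id"]) == planted


# ---------------------------------------------------------------- cascade

def _hand_built_inputs():
    """Five pass-all genes plus one failure per criterion."""
    labels = {"c1": UNIQUE_L, "c2": UNIQUE_L, "c3": SPECIFIC_UP,
              "c4": SPECIFIC_UP, "c5": SPECIFIC_UP,
              "f_ambig": UNIQUE_L, "f_unmapped": SPECIFIC_UP,
              "f_flat": UNIQUE_L, "f_base": SPECIFIC_UP,
              "f_label": STABLE}
    traj = _traj(labels)
    pairs = [(g, f"h_{g}") for g in labels if g != "f_unmapped"]
    pairs.append(("f_ambig", "h_f_ambig_2"))
    omap = OrthologMap.from_pairs(pairs)
    cohort_cond = {"p1": "case", "p2": "case", "n1": "control",
                   "n2": "control"}
    rows = {}
    for g in labels:
        h = f"h_{g}"
        if g == "f_flat":
            rows[h] = [5.0, 5.0, 5.0, 5.0]
        else:
            rows[h] = [50.0, 50.0, 5.0, 5.0]
    cohort = _matrix(rows, cohort_cond, ["p1", "p2", "n1", "n2"])
    base_cond = {"b1": "HSC", "b2": "blood"}
    base_rows = {f"h_{g}": ([30.0, 30.0] if g == "f_base" else [0.0, 0.0])
                 for g in labels}
    baseline = _matrix(base_rows, base_cond, ["b1", "b2"])
    return traj, omap, cohort, baseline


def test_cascade_recovers_planted_pass_all_genes():
    traj, omap, cohort, baseline = _hand_built_inputs()
    table = lt.run_cascade(traj, omap, cohort, {"hematopoietic": baseline},
                           CascadeConfig(max_level=1.0))
    assert set(table.candidates) == {"c1", "c2", "c3", "c4", "c5"}
    rec = table.records
    assert rec.loc["f_ambig", "drop_reason"] == "ortholog:ambiguous"
    assert rec.loc["f_unmapped", "drop_reason"] == "ortholog:unmapped"
    assert rec.loc["f_flat", "drop_reason"] == "cohort:below_fold"
    assert rec.loc["f_base", "drop_reason"].startswith("baseline:")
    assert "f_label" not in rec.index


def test_cascade_accounting_is_exact():
    traj, omap, cohort, baseline = _hand_built_inputs()
    table = lt.run_cascade(traj, omap, cohort, {"hematopoietic": baseline},
                           CascadeConfig(max_level=1.0))
    counts = table.stage_counts.set_index("stage")
    assert (counts["entered"] - counts["survived"] == counts["dropped"]).all()
    # each stage's entrants are the previous stage's survivors
    assert counts.loc["map_orthologs", "entered"] == \
        counts.loc["select_evidence_class", "survived"]
    assert counts.loc["cohort_fold_filter", "entered"] == \
        counts.loc["map_orthologs", "survived"]
    assert counts.loc["normal_expression_filter", "entered"] == \
        counts.loc["cohort_fold_filter", "survived"]


def test_cascade_empty_evidence_classes_succeed():
    traj = _traj({"g1": STABLE, "g2": "ABSENT"})
    _t, omap, cohort, baseline = _hand_built_inputs()
    table = lt.run_cascade(traj, omap, cohort, {"hematopoietic": baseline})
    assert table.records.empty
    assert table.candidates == []


def test_cascade_monotone_in_min_fold(small_study):
    from leukotraj.simulate import human_ortholog_id
    cfg, matrix, truth = small_study
    prof = lt.summarize_conditions(lt.normalize_cpm(matrix))
    traj = lt.classify_all(prof)
    omap = lt.simulate_ortholog_map(cfg, list(truth.trajectory.index))
    cohort = lt.simulate_cohort(cfg, truth)
    base = lt.simulate_baseline(cfg, truth, "hematopoietic")
    previous = None
    for min_fold in (1.5, 2.0, 3.0, 4.5):
        table = lt.run_cascade(traj, omap, cohort, {"hematopoietic": base},
                               CascadeConfig(min_fold=min_fold))
        got = set(table.candidates)
        if previous is not None:
            assert got <= previous
        previous = got


def test_cascade_matches_single_pass_conjunction(small_study):
    cfg, matrix, truth = small_study
    prof = lt.summarize_conditions(lt.normalize_cpm(matrix))
    traj = lt.classify_all(prof)
    omap = lt.simulate_ortholog_map(cfg, list(truth.trajectory.index))
    cohort = lt.simulate_cohort(cfg, truth)
    base = lt.simulate_baseline(cfg, truth, "hematopoietic")
    max_level = default_max_level(base)
    table = lt.run_cascade(traj, omap, cohort, {"hematopoietic": base},
                           CascadeConfig(max_level=max_level))
    expected = cascade_oracle(traj.labels, omap.table, cohort.values,
                              cohort.condition_of, base.values,
                              base.condition_of, 2.0, 0.5, max_level)
    assert set(table.candidates) == expected
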