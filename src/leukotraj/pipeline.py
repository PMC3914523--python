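"""End-to-end pipeline orchestration with a declarative config.

``run_pipeline`` executes normalize -> summarize -> divergence (R^2)
-> Venn partition -> trajectory classification, then optionally the
enrichment stage (when a cohort and gene sets are configured) and the
cross-species prioritization cascade (when a cohort, ortholog map and
baseline panels are configured).  Every intermediate is written as
tab-separated text and listed in a manifest with a SHA-256 checksum,
so a run is fully reproducible and diffable from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import cross_species, enrichment, expression
from .matrix import ExpressionMatrix
from .trajectory import ClassifierThresholds, ROLES, classify_all

log = logging.getLogger("leukotraj")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All inputs, thresholds and policies of one pipeline run."""

    counts: str = ""
    conditions: str = ""
    out_dir: str = ""
    condition_map: dict[str, str] = field(
        default_factory=lambda: {r: r for r in ROLES})
    pseudocount: float = 1.0
    presence_threshold: float = 1.0
    fold_min: float = 1.0
    flat_max: float = 1.0
    # enrichment stage (optional)
    cohort: str | None = None
    cohort_conditions: str | None = None
    gene_sets: str | None = None
    case_label: str = "case"
    control_label: str = "control"
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    permutation_mode: str = "gene_label"
    # cascade stage (optional)
    ortholog_map: str | None = None
    baseline_hematopoietic: str | None = None
    baseline_hematopoietic_conditions: str | None = None
    baseline_tissue: str | None = None
    baseline_tissue_conditions: str | None = None
    ortholog_policy: str = "one_to_one_only"
    min_fold: float = 2.0
    epsilon: float = 0.5
    max_level: float | None = None
    seed: int = 0

    REQUIRED = ("counts", "conditions", "out_dir")

    def validation_errors(self) -> list[str]:
        """Every violation, not just the first."""
        errs = []
        for name in self.REQUIRED:
            if not getattr(self, name):
                errs.append(f"missing required path: {name}")
        for name in ("counts", "conditions", "cohort", "cohort_conditions",
                     "gene_sets", "ortholog_map", "baseline_hematopoietic",
                     "baseline_hematopoietic_conditions", "baseline_tissue",
                     "baseline_tissue_conditions"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                errs.append(f"{name}: path does not exist: {p}")
        for name in ("pseudocount", "fold_min", "flat_max"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        if self.presence_threshold < 0:
            errs.append("presence_threshold must be >= 0")
        if self.n_permutations < 100:
            errs.append("n_permutations must be >= 100")
        if self.min_fold < 1:
            errs.append("min_fold must be >= 1")
        if self.epsilon <= 0:
            errs.append("epsilon must be positive")
        if self.ortholog_policy not in ("one_to_one_only", "best_effort"):
            errs.append(f"unknown ortholog_policy {self.ortholog_policy!r}")
        if self.permutation_mode not in ("gene_label", "sample_label"):
            errs.append(f"unknown permutation_mode {self.permutation_mode!r}")
        missing_roles = [r for r in ROLES if r not in self.condition_map]
        if missing_roles:
            errs.append(f"condition_map missing roles: {missing_roles}")
        return errs

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(path: str | Path) -> tuple[PipelineConfig, list[str]]:
    """Parse and validate a YAML config file.

    Returns the fully defaulted config plus the complete list of
    violations (empty when valid).  An unparseable file yields a single
    parse error.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return PipelineConfig(), [f"cannot parse config: {exc}"]
    if not isinstance(raw, dict):
        return PipelineConfig(), ["config must be a key/value mapping"]
    known = {f.name for f in fields(PipelineConfig)}
    errs = [f"unknown config key: {k}" for k in raw if k not in known]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    errs.extend(cfg.validation_errors())
    return cfg, errs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, dict[str, str]]:
    """Run all configured stages; return the artifact manifest.

    The manifest maps artifact names to ``{"path", "sha256"}``.  Stage
    failures raise :class:`PipelineError` naming the stage; artifacts
    written before the failure remain on disk.
    """
    errs = config.validation_errors()
    if errs:
        raise PipelineError("config: " + "; ".join(errs))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}

    def emit(name: str, path: Path) -> None:
        manifest[name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        matrix = ExpressionMatrix.from_tsv(config.counts, config.conditions)
        log.info("load: %d genes x %d samples", len(matrix.gene_ids),
                 len(matrix.sample_ids))

        stage = "normalize"
        norm = expression.normalize_cpm(matrix)
        p = out / "normalized.tsv"
        norm.to_tsv(p, out / "normalized_conditions.tsv")
        emit("normalized", p)
        emit("normalized_conditions", out / "normalized_conditions.tsv")

        stage = "summarize"
        profile = expression.summarize_conditions(
            norm, config.pseudocount, config.presence_threshold)
        p = out / "profile.tsv"
        profile.to_tsv(p)
        emit("profile", p)
        log.info("summarize: %d genes, conditions %s",
                 len(profile.gene_ids), profile.conditions)

        stage = "divergence"
        r2 = expression.r2_matrix(profile)
        p = out / "r2.tsv"
        r2.to_csv(p, sep="\t", float_format="%.6g")
        emit("r2", p)

        stage = "venn"
        regions = expression.venn_partition(profile)
        rows = [("+".join(k), len(v), ",".join(sorted(v))) for k, v in
                sorted(regions.items(), key=lambda kv: (len(kv[0]), kv[0]))]
        p = out / "venn.tsv"
        pd.DataFrame(rows, columns=["region", "size", "genes"]).to_csv(
            p, sep="\t", index=False)
        emit("venn", p)

        stage = "classify"
        thresholds = ClassifierThresholds(config.fold_min, config.flat_max)
        traj = classify_all(profile, thresholds, config.condition_map)
        p = out / "trajectory.tsv"
        traj.to_tsv(p)
        emit("trajectory", p)
        counts = traj.label_counts()
        p = out / "trajectory_counts.tsv"
        counts.rename_axis("label").rename("n_genes").to_csv(p, sep="\t")
        emit("trajectory_counts", p)
        log.info("classify: %s", counts.to_dict())

        if config.cohort and config.gene_sets:
            stage = "enrichment"
            cohort = ExpressionMatrix.from_tsv(
                config.cohort, config.cohort_conditions, flavor="normalized")
            sets = enrichment.read_gmt(config.gene_sets)
            lines = []
            for s in sets:
                res = enrichment.permutation_p(
                    rank_or_matrix(cohort, config), s,
                    n_permutations=config.n_permutations, seed=config.seed,
                    mode=config.permutation_mode,
                    weight_exponent=config.weight_exponent,
                    case_label=config.case_label,
                    control_label=config.control_label)
                lines.append((s.name, res.es, res.nes, res.p_nominal,
                              res.n_permutations,
                              ",".join(res.leading_edge)))
            p = out / "enrichment.tsv"
            with open(p, "w") as fh:
                fh.write(f"# seed={config.seed} mode={config.permutation_mode} "
                         f"n_permutations={config.n_permutations}\n")
                pd.DataFrame(lines, columns=["set", "ES", "NES", "p_nominal",
                                             "n_perm", "leading_edge"]).to_csv(
                    fh, sep="\t", index=False, float_format="%.6g")
            emit("enrichment", p)

        if config.cohort and config.ortholog_map and config.baseline_hematopoietic:
            stage = "cascade"
            cohort = ExpressionMatrix.from_tsv(
                config.cohort, config.cohort_conditions, flavor="normalized")
            omap = cross_species.OrthologMap.from_tsv(config.ortholog_map)
            baselines = {"hematopoietic": ExpressionMatrix.from_tsv(
                config.baseline_hematopoietic,
                config.baseline_hematopoietic_conditions, flavor="normalized")}
            if config.baseline_tissue:
                baselines["tissue"] = ExpressionMatrix.from_tsv(
                    config.baseline_tissue, config.baseline_tissue_conditions,
                    flavor="normalized")
            ccfg = cross_species.CascadeConfig(
                ortholog_policy=config.ortholog_policy,
                min_fold=config.min_fold, epsilon=config.epsilon,
                max_level=config.max_level, case_label=config.case_label,
                control_label=config.control_label)
            table = cross_species.run_cascade(traj, omap, cohort, baselines,
                                              ccfg)
            table.to_tsv(out / "candidates.tsv", out / "cascade_summary.tsv")
            emit("candidates", out / "candidates.tsv")
            emit("cascade_summary", out / "cascade_summary.tsv")
            log.info("cascade: %d candidates", len(table.candidates))

        stage = "manifest"
        config.to_yaml(out / "config_resolved.yaml")
        emit("config", out / "config_resolved.yaml")
        mpath = out / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump({"config_hash": config.config_hash(),
                       "artifacts": manifest}, fh, indent=2, sort_keys=True)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return manifest


def rank_or_matrix(cohort: ExpressionMatrix,
                   config: PipelineConfig):
    """Gene-label permutations rank once; sample-label needs the matrix."""
    if config.permutation_mode == "sample_label":
        return cohort
    return enrichment.rank_genes(cohort, config.case_label,
                                 config.control_label)
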