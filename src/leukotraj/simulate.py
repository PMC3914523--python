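"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the study design end to end: a three-condition
bulk RNA-seq count matrix (control, short-term oncogene induction,
overt leukemia) containing genes planted from every trajectory
subclass plus stable background; a two-group human cohort with a
planted upregulated subset; normal hematopoietic and tissue baseline
panels with planted silent genes; and a mouse-to-human ortholog map
with a configurable fraction of ambiguous mappings.

Counts are drawn from a negative binomial with mean/dispersion
parameterization (variance = mu + dispersion * mu**2), the standard
overdispersion model for bulk RNA-seq; baseline abundances are
log-normal, matching the heavy-tailed abundance distribution of real
transcriptomes.  "Absent" states are structural zeros (mean 0), which
makes the uniquely-expressed and shut-down ground truth unambiguous.
Per-sample library-size scaling is applied to the means before
sampling, so integer counts are preserved while the normalization
stage is still exercised.

All randomness flows through :func:`numpy.random.default_rng` seeded
from ``config.seed``; identical config and seed give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cross_species import OrthologMap
from .matrix import NORMALIZED, RAW_COUNTS, ExpressionMatrix
from .trajectory import (ABSENT, ALL_LABELS, OTHER, PROGRESSIVE_DOWN,
                         PROGRESSIVE_UP, ROLES, SHUTDOWN_L, SPECIFIC_DOWN,
                         SPECIFIC_UP, STABLE, SUBCLASSES, UNIQUE_L)

COHORT_UP = "cohort_up"
COHORT_FLAT = "cohort_flat"
BASELINE_SILENT = "silent"
BASELINE_EXPRESSED = "expressed"

HEMATOPOIETIC_GROUPS = ("HSC", "MPP", "CMP", "GMP", "lymphoid")
TISSUE_GROUPS = ("brain", "liver", "lung", "kidney", "heart", "muscle")


class ConfigError(ValueError):
    """Raised for out-of-domain simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    n_genes_per_class
        Genes planted per trajectory subclass (six subclasses).
    n_background, n_absent, n_other
        Stable, all-silent and non-monotone background genes.
    n_replicates
        Samples per condition.
    baseline_mean_log
        (location, scale) of the log-normal baseline mean on the
        natural-log scale; the default centres typical expressed genes
        near 250 expected counts.
    dispersion
        Negative-binomial dispersion; 0 gives the Poisson limit.
    effect_fold
        Linear fold change applied per planted transition (> 1).
    library_size
        Expected total counts per sample; ``None`` disables scaling.
    ambiguous_ortholog_fraction
        Fraction of genes given non-1:1 ortholog mappings.
    cohort_fold
        Planted case/control mean ratio for cohort-up genes (>= 2).
    cohort_up_fraction / cohort_background_up_fraction
        Probability that a leukemia-evidence gene / any other gene is
        planted cohort-up.
    baseline_silent_fraction / baseline_background_silent_fraction
        Probability that a leukemia-evidence gene / any other gene is
        silent in a baseline panel.
    """

    n_genes_per_class: int = 200
    n_background: int = 12000
    n_absent: int = 300
    n_other: int = 100
    n_replicates: int = 3
    baseline_mean_log: tuple[float, float] = (5.5, 0.5)
    dispersion: float = 0.05
    effect_fold: float = 4.0
    library_size: float | None = 2e7
    seed: int = 0
    ambiguous_ortholog_fraction: float = 0.2
    cohort_n_cases: int = 15
    cohort_n_controls: int = 15
    cohort_fold: float = 4.0
    cohort_up_fraction: float = 0.8
    cohort_background_up_fraction: float = 0.1
    cohort_noise_sd: float = 0.5
    baseline_silent_fraction: float = 0.5
    baseline_background_silent_fraction: float = 0.1
    baseline_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.effect_fold <= 1:
            raise ConfigError("effect_fold must be > 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        for name in ("n_genes_per_class", "n_background", "n_absent", "n_other"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("ambiguous_ortholog_fraction", "cohort_up_fraction",
                     "cohort_background_up_fraction", "baseline_silent_fraction",
                     "baseline_background_silent_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.cohort_fold < 2:
            raise ConfigError("cohort_fold must be >= 2")
        if self.library_size is not None and self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if self.cohort_n_cases < 1 or self.cohort_n_controls < 1:
            raise ConfigError("cohort group sizes must be >= 1")


@dataclass
class GroundTruth:
    """Planted per-gene labels for every downstream stage."""

    trajectory: pd.Series          # gene -> trajectory label
    cohort_status: pd.Series       # gene -> cohort_up / cohort_flat
    baseline_status: dict[str, pd.Series]  # scope -> gene -> silent / expressed

    def genes_with_label(self, *labels: str) -> list[str]:
        return list(self.trajectory.index[self.trajectory.isin(labels)])

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame({"label": self.trajectory})
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def human_ortholog_id(mouse_id: str) -> str:
    """Canonical synthetic human ortholog id of a mouse gene id."""
    return "hs_" + mouse_id


def class_condition_means(label: str, b: float, effect_fold: float,
                          ) -> tuple[float, float, float]:
    """Planted (control, short_term, leukemia) means for one gene.

    ``b`` is the baseline mean; ``effect_fold`` the per-transition fold.
    Uniquely-expressed and shut-down states have structural-zero means.
    """
    f = effect_fold
    means = {
        SPECIFIC_UP: (b, b, b * f),
        SPECIFIC_DOWN: (b, b, b / f),
        PROGRESSIVE_UP: (b, b * f, b * f * f),
        PROGRESSIVE_DOWN: (b, b / f, b / (f * f)),
        UNIQUE_L: (0.0, 0.0, b),
        SHUTDOWN_L: (b, b, 0.0),
        STABLE: (b, b, b),
        ABSENT: (0.0, 0.0, 0.0),
        # up at induction, back down in leukemia: matches no subclass
        OTHER: (b, b * f, b),
    }
    try:
        return means[label]
    except KeyError:
        raise ConfigError(f"unknown trajectory label {label!r}") from None


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance = mu + dispersion * mu**2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _stream(config: SimulationConfig, channel: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([channel, config.seed])


def planted_gene_table(config: SimulationConfig) -> pd.Series:
    """Gene ids and their planted trajectory labels, in generation order."""
    labels: list[str] = []
    for lab in SUBCLASSES:
        labels += [lab] * config.n_genes_per_class
    labels += [STABLE] * config.n_background
    labels += [ABSENT] * config.n_absent
    labels += [OTHER] * config.n_other
    if not labels:
        raise ConfigError("configuration plants no genes")
    width = max(4, len(str(len(labels))))
    ids = [f"mg{i:0{width}d}" for i in range(1, len(labels) + 1)]
    return pd.Series(labels, index=pd.Index(ids, name="gene_id"))


def simulate_trajectory_counts(config: SimulationConfig,
                               ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the three-condition count matrix and its ground truth.

    Per planted class the condition means follow the class definition
    (see :func:`class_condition_means`), baseline means are drawn
    log-normally, means are rescaled per sample to ``library_size``,
    and integer counts are drawn negative-binomially.
    """
    traj = planted_gene_table(config)
    n = len(traj)
    loc, scale = config.baseline_mean_log

    rng = _stream(config, 0)
    b = rng.lognormal(mean=loc, sigma=scale, size=n)
    mu3 = np.array([class_condition_means(lab, bi, config.effect_fold)
                    for lab, bi in zip(traj, b)])

    reps = config.n_replicates
    sample_ids, condition_of = [], {}
    for role in ROLES:
        for i in range(1, reps + 1):
            sid = f"{role}_{i}"
            sample_ids.append(sid)
            condition_of[sid] = role
    mu = np.repeat(mu3, reps, axis=1)
    if config.library_size is not None:
        totals = mu.sum(axis=0)
        scale_per_sample = np.where(totals > 0,
                                    config.library_size / totals, 1.0)
        mu = mu * scale_per_sample
    counts = _nb_draw(rng, mu, config.dispersion)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=traj.index, columns=sample_ids),
        condition_of, flavor=RAW_COUNTS)

    truth_rng = _stream(config, 1)
    is_candidate = traj.isin([UNIQUE_L, SPECIFIC_UP]).to_numpy()
    p_up = np.where(is_candidate, config.cohort_up_fraction,
                    config.cohort_background_up_fraction)
    cohort = np.where(truth_rng.random(n) < p_up, COHORT_UP, COHORT_FLAT)
    baseline_status = {}
    for scope in ("hematopoietic", "tissue"):
        p_silent = np.where(is_candidate, config.baseline_silent_fraction,
                            config.baseline_background_silent_fraction)
        status = np.where(truth_rng.random(n) < p_silent,
                          BASELINE_SILENT, BASELINE_EXPRESSED)
        baseline_status[scope] = pd.Series(status, index=traj.index)
    truth = GroundTruth(traj, pd.Series(cohort, index=traj.index),
                        baseline_status)
    return matrix, truth


def simulate_cohort(config: SimulationConfig, truth: GroundTruth,
                    ) -> ExpressionMatrix:
    """Two-group human cohort over the orthologs of the simulated genes.

    Cohort-up genes have case mean = ``cohort_fold`` times the control
    mean; multiplicative log-normal noise of scale ``cohort_noise_sd``
    is applied per sample (0 disables noise, making the planted ratio
    exact).  The matrix is keyed by canonical human ortholog ids and
    carries ``case`` / ``control`` condition labels.
    """
    genes = truth.trajectory.index
    if not truth.cohort_status.index.equals(genes):
        raise ConfigError("cohort status does not cover the simulated genes")
    rng = _stream(config, 2)
    loc, scale = config.baseline_mean_log
    ctrl_mean = rng.lognormal(mean=loc, sigma=scale, size=len(genes))
    up = (truth.cohort_status == COHORT_UP).to_numpy()
    case_mean = np.where(up, ctrl_mean * config.cohort_fold, ctrl_mean)

    n_case, n_ctrl = config.cohort_n_cases, config.cohort_n_controls
    sample_ids = [f"case_{i}" for i in range(1, n_case + 1)] + \
                 [f"control_{i}" for i in range(1, n_ctrl + 1)]
    condition_of = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    means = np.column_stack([np.repeat(case_mean[:, None], n_case, axis=1),
                             np.repeat(ctrl_mean[:, None], n_ctrl, axis=1)])
    if config.cohort_noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=config.cohort_noise_sd,
                              size=means.shape)
        values = means * noise
    else:
        values = means
    human_ids = [human_ortholog_id(g) for g in genes]
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(human_ids, name="gene_id"),
                     columns=sample_ids),
        condition_of, flavor=NORMALIZED)


def simulate_baseline(config: SimulationConfig, truth: GroundTruth,
                      scope: str = "hematopoietic") -> ExpressionMatrix:
    """Normal-cell or normal-tissue baseline panel over human orthologs.

    Planted silent genes are structural zeros in every group; expressed
    genes get a log-normal base level with per-group and per-sample
    multiplicative variation.
    """
    if scope not in truth.baseline_status:
        raise ConfigError(f"unknown baseline scope {scope!r}")
    groups = HEMATOPOIETIC_GROUPS if scope == "hematopoietic" else TISSUE_GROUPS
    status = truth.baseline_status[scope]
    rng = _stream(config, 3 if scope == "hematopoietic" else 4)
    loc, scale = config.baseline_mean_log
    n = len(status)
    base = rng.lognormal(mean=loc, sigma=scale, size=n)
    base[(status == BASELINE_SILENT).to_numpy()] = 0.0

    reps = config.baseline_replicates
    cols, condition_of, blocks = [], {}, []
    for g in groups:
        group_factor = rng.lognormal(0.0, 0.25, size=n)
        noise = rng.lognormal(0.0, 0.25, size=(n, reps))
        blocks.append(base[:, None] * group_factor[:, None] * noise)
        for i in range(1, reps + 1):
            sid = f"{g}_{i}"
            cols.append(sid)
            condition_of[sid] = g
    values = np.concatenate(blocks, axis=1)
    human_ids = [human_ortholog_id(g) for g in status.index]
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(human_ids, name="gene_id"),
                     columns=cols),
        condition_of, flavor=NORMALIZED)


def simulate_ortholog_map(config: SimulationConfig,
                          gene_ids: list[str]) -> OrthologMap:
    """Mouse-to-human map with a planted fraction of ambiguous mappings.

    ``round(fraction * n)`` genes are made ambiguous: half get a second
    human partner (one-to-many), the rest are paired so that two mouse
    genes share one human gene (many-to-one); everything else maps 1:1.
    """
    if not gene_ids:
        raise ConfigError("simulate_ortholog_map needs a non-empty gene list")
    rng = _stream(config, 5)
    n = len(gene_ids)
    n_amb = int(round(config.ambiguous_ortholog_fraction * n))
    order = rng.permutation(n)
    ambiguous = [gene_ids[i] for i in sorted(order[:n_amb])]
    plain = [gene_ids[i] for i in sorted(order[n_amb:])]

    pairs: list[tuple[str, str]] = []
    for g in plain:
        pairs.append((g, human_ortholog_id(g)))
    n_o2m = (n_amb + 1) // 2
    for g in ambiguous[:n_o2m]:
        pairs.append((g, human_ortholog_id(g)))
        pairs.append((g, human_ortholog_id(g) + "_alt"))
    shared = ambiguous[n_o2m:]
    for g1, g2 in zip(shared[::2], shared[1::2]):
        pairs.append((g1, human_ortholog_id(g1)))
        pairs.append((g2, human_ortholog_id(g1)))
    if len(shared) % 2 == 1:  # unpaired leftover becomes one-to-many
        g = shared[-1]
        pairs.append((g, human_ortholog_id(g)))
        pairs.append((g, human_ortholog_id(g) + "_alt"))
    return OrthologMap.from_pairs(sorted(pairs))


def simulate_drift_counts(config: SimulationConfig, n_genes: int = 4000,
                          drift_sd_short: float = 0.9,
                          drift_sd_leukemia: float = 0.65) -> ExpressionMatrix:
    """Cumulative-drift counts for divergence-ordering studies.

    Per gene, the short-term log2 mean is the control mean plus
    N(0, drift_sd_short) and the leukemia mean adds a further
    independent N(0, drift_sd_leukemia).  With the induction drift
    larger than the leukemic drift, the squared correlations reproduce
    the characteristic ordering R2(ST, L) > R2(Ctrl, ST) > R2(Ctrl, L):
    the transcriptome moves farthest from control overall, with the
    larger single step at induction.
    """
    if n_genes < 3:
        raise ConfigError("need at least 3 genes")
    rng = _stream(config, 6)
    loc, scale = config.baseline_mean_log
    mu_ctrl = rng.lognormal(mean=loc, sigma=scale, size=n_genes)
    mu_st = mu_ctrl * 2.0 ** rng.normal(0.0, drift_sd_short, size=n_genes)
    mu_l = mu_st * 2.0 ** rng.normal(0.0, drift_sd_leukemia, size=n_genes)
    mu3 = np.column_stack([mu_ctrl, mu_st, mu_l])

    reps = config.n_replicates
    sample_ids, condition_of = [], {}
    for role in ROLES:
        for i in range(1, reps + 1):
            sid = f"{role}_{i}"
            sample_ids.append(sid)
            condition_of[sid] = role
    mu = np.repeat(mu3, reps, axis=1)
    if config.library_size is not None:
        mu = mu * (config.library_size / mu.sum(axis=0))
    counts = _nb_draw(rng, mu, config.dispersion)
    width = max(4, len(str(n_genes)))
    ids = [f"mg{i:0{width}d}" for i in range(1, n_genes + 1)]
    return ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"),
                     columns=sample_ids),
        condition_of, flavor=RAW_COUNTS)


def expected_candidates(truth: GroundTruth, omap: OrthologMap) -> set[str]:
    """Genes that should survive the full cascade, from ground truth alone:
    leukemia-evidence class, 1:1 ortholog, planted cohort-up and silent in
    the hematopoietic baseline."""
    from .cross_species import ONE_TO_ONE
    t = omap.table
    one_to_one = set(t.loc[t["mapping_class"] == ONE_TO_ONE, "mouse_id"])
    out = set()
    for g in truth.genes_with_label(UNIQUE_L, SPECIFIC_UP):
        if (g in one_to_one
                and truth.cohort_status[g] == COHORT_UP
                and truth.baseline_status["hematopoietic"][g] == BASELINE_SILENT):
            out.add(g)
    return out
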