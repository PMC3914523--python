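# Methods

This note documents the models, defaults and design choices behind
`leukotraj`, and what the synthetic-data experiments do and do not
demonstrate.

## Expression model and normalization

The pipeline starts from a gene-by-sample integer count matrix with a
condition label per sample (three conditions: `control`, `short_term`,
`leukemia`; names configurable).  Normalization is counts per million
(CPM): value = count / sample total × 10⁶.  CPM is deliberately
minimal — it conserves within-sample proportions, is assumption-free,
and keeps every stage auditable; it does not correct for composition
shifts between conditions (no TMM/median-ratio step, by scope).  The
practical consequence is that strongly asymmetric differential
programs bleed a global scale shift into all genes; the pipeline is
intended for transcriptomes in which differentially behaving genes are
a minority of the library (see the generator defaults below).

Per condition, a gene's summary is log2(mean CPM across replicates +
pseudocount), pseudocount 1.  Presence is mean CPM ≥ 1 (inclusive
boundary), the standard expressed-gene convention; both the threshold
and pseudocount are configurable.  With one sample per condition the
mean reduces to the single profile.

## Divergence and the Venn partition

Pairwise divergence is the squared Pearson correlation of two
conditions' log2 summaries over the **union** of their expressed sets.
The union (not all genes, not the intersection) avoids inflating the
correlation with genes that sit at the pseudocount floor in both
conditions, while still penalizing presence differences.  Fewer than 3
universe genes or a zero-variance summary vector is an error rather
than a NaN.  The three expressed sets are partitioned into the 7
disjoint Venn regions by exhaustive membership; regions always sum to
the union.

## Trajectory classification

Genes are assigned one of nine labels from their two transition fold
changes Δ₁ (short-term vs control) and Δ₂ (leukemia vs short-term) on
the log2 summary scale, plus presence flags.  Rules are evaluated in a
fixed priority order: presence-defined classes first (`UNIQUE_L`,
`SHUTDOWN_L`), then progressive, then leukemia-specific, then the
background categories (`ABSENT`, `STABLE`, `OTHER`).  Presence rules
come first because fold changes are pseudocount-dominated when a state
is silent; the fixed order makes the classes mutually exclusive by
construction.  Defaults are twofold for a change (Δ ≥ 1 log2) and
under twofold for flatness (|Δ| < 1), mirroring the twofold convention
used in the cohort filter; both are configurable.  A gene expressed in
control only (absent later) matches no six-class definition and falls
to `OTHER`; "shut down" deliberately requires presence in both of the
first two states.

## Synthetic-data generator

The generator is the pipeline's ground-truth instrument.  Counts are
negative binomial with variance μ + φμ² (φ = `dispersion`, default
0.05; φ = 0 is the Poisson limit), the standard bulk RNA-seq noise
model.  Baseline means are log-normal (natural-log location 5.5, scale
0.5).  The scale models the abundance spread of the *classifiable*
stratum — genes robustly expressed in at least one state — rather than
the full transcriptome's multi-decade dynamic range; a wider spread
would push the bottom tail of 16-fold-down trajectories below the
detection threshold, where a presence-based classifier genuinely
cannot distinguish "progressively down" from "shut down".

Per planted class, condition means follow the class definition with a
single fold parameter f (default 4): leukemia-specific (b, b, b·f) and
(b, b, b/f); progressive (b, b·f, b·f²) and (b, b/f, b/f²); uniquely
expressed (0, 0, b); shut down (b, b, 0).  Absent states are
structural zeros, which makes presence ground truth unambiguous.
Defaults plant 200 genes per subclass over a background of 12 000
stable, 300 silent and 100 non-monotone genes, i.e. differential
classes are ~9% of the library.  This matters because CPM transfers
any net imbalance of up- vs down-regulation into a global scale shift;
with the default composition the shift is ≈0.3 log2 in the leukemic
state, well inside the 1-log2 margin between planted folds and the
classifier cut-offs.  Per-sample means are rescaled to an expected
library size (default 2×10⁷) before sampling, so integer counts are
preserved and the normalization stage is genuinely exercised.
Replicates default to 3 per condition, a typical bulk design.

The human cohort plants case/control means with ratio `cohort_fold`
(default 4, ≥ 2 required) for cohort-up genes and multiplicative
log-normal noise (σ = 0.5; σ = 0 makes planted ratios exact).
Leukemia-evidence genes are planted cohort-up with probability 0.8,
others 0.1.  Baseline panels plant silent genes as structural zeros
(probability 0.5 for evidence genes, 0.1 otherwise).  The ortholog map
makes a configurable fraction of genes ambiguous, split between
one-to-many and many-to-one mappings; classes are always re-derived
from the table's actual multiplicities.

A separate cumulative-drift mode generates control means, then
multiplies by 2^N(0, s₁) for the short-term state and further by
2^N(0, s₂) for leukemia (defaults s₁ = 0.9, s₂ = 0.65 log2).  With the
larger step at induction, the squared correlations reproduce the
characteristic ordering R²(ST,L) > R²(Ctrl,ST) > R²(Ctrl,L).  Default
4 000 genes keep replicate-to-replicate ordering stable.

What the generator does **not** emulate: batch effects, isoforms,
read-level noise, correlated genes, cohort platform effects, or
partial (non-structural) silencing.  Passing tests therefore show the
pipeline's logic is correct under its stated noise model, not that the
thresholds are optimal for any particular real dataset.

## Enrichment statistic

Ranking metric: signal-to-noise (mean_case − mean_control)/(s_case +
s_control) with each group sd floored at max(0.2·|mean|, 0.2) — robust
on small groups; ties break lexicographically by gene id so rankings
are fully deterministic.  The running sum gains |r|^p/Σ_hits|r|^p at
members and loses 1/(N−N_hits) elsewhere; p defaults to 1 (weighted
statistic), p = 0 is retained because it is analytically checkable.
ES is the running-sum value of largest magnitude (earliest position on
exact ties; when the positive and negative extrema tie in magnitude to
rounding, the reported sign is the earlier extremum).  If all member
metrics are zero at p > 0, weights fall back to equal.

The default null permutes gene labels (random member sets of the same
size), appropriate for external cohorts of unknown sample structure;
sample-label permutation re-ranks under shuffled group labels and is
available for cohorts with enough samples.  Below 7 total samples the
sample-label null degrades to the exhaustive set of label assignments
and records that in the result.  p = (1 + #{same-sign |ES*| ≥
|ES|})/(1 + #{same-sign}), floored at 1/(n_permutations+1) — a valid
permutation p that never reports zero.  NES divides ES by the mean
|ES*| of same-sign nulls.  Over-representation is the one-sided
hypergeometric tail with Benjamini–Hochberg adjustment across sets;
single-set enrichment reports nominal p only (no cross-set FDR
pooling, by scope).

## Prioritization cascade

Stages: evidence-class selection (`UNIQUE_L` ∪ `SPECIFIC_UP`) →
ortholog mapping → cohort fold filter → normal-expression hard filter
→ tissue survey.  Ortholog policy defaults to strict 1:1 with full
drop accounting; `best_effort` keeps the lexicographically first
partner.  The cohort ratio is (mean_case + ε)/(mean_control + ε) with
ε = 0.5 on the normalized scale — enough to keep control-silent genes
finite without eroding twofold calls at moderate expression; the
boundary is inclusive.  "Absent or poorly expressed" in a baseline
panel is a rank-based default: a gene is dropped when its maximum
per-group mean exceeds the panel's own 25th percentile of group means,
since absolute cut-offs do not transfer across platforms; an explicit
`max_level` overrides it.  The tissue panel is annotation-only by
default because tissue-wide expression is a context for interpretation
rather than an exclusion criterion; it can be switched to a hard
filter.  Genes missing from a panel pass with a flag by default
(configurable to drop).  The final verdict is the conjunction of all
hard criteria, and survivors + dropped equal entrants at every stage.

## Reproducibility and numerics

All generator randomness flows through independent
`numpy.random.default_rng` streams keyed by (channel, seed); identical
config + seed is bit-identical.  Pipeline outputs are plain
tab-separated text with fixed `%.6g` float formatting, and the
manifest lists a SHA-256 checksum per artifact, so reruns of the same
config are byte-identical.  Config validation collects every violation
rather than failing at the first.

## Problem sizes

The test suite and the acceptance script run the default study
(13 600 genes × 9 samples), 100 drift replicates of 4 000 genes for
the divergence ordering, 500 random sets of 12 genes against a
200-gene ranked list (100 permutations each) for null calibration, and
50 compact studies for cascade cross-checks — sizes chosen so a full
verification pass completes in well under a minute while keeping every
per-class estimate at n = 200.

## Known limitations

CPM-only normalization (composition shifts uncorrected); no
statistical testing of differential expression — the classifier is
set-algebraic by design, and replicate-aware testing would be a
different method; the enrichment p-value is nominal per set; candidate
identity depends on user-supplied ortholog maps and baselines and
inherits their quality; microarray probe-to-gene resolution must
happen upstream.
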