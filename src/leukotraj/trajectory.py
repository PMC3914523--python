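"""Six-subclass trajectory classification across the three disease states.

Each gene's behaviour over control -> short-term induction -> leukemia is
reduced to one of six progression subclasses or three background
categories, from its per-condition log2 summaries and presence calls:

* ``UNIQUE_L``       -- absent in control and short-term, expressed in leukemia
* ``SHUTDOWN_L``     -- expressed in control and short-term, absent in leukemia
* ``PROGRESSIVE_UP`` -- up at induction and further up in leukemia
* ``PROGRESSIVE_DOWN`` -- down at induction and further down in leukemia
* ``SPECIFIC_UP``    -- flat at induction, up only in leukemia
* ``SPECIFIC_DOWN``  -- flat at induction, down only in leukemia
* ``ABSENT``         -- not expressed in any state
* ``STABLE``         -- expressed, all fold changes below the flat bound
* ``OTHER``          -- any remaining pattern (e.g. up then back down)

Presence-based rules take priority over fold-based rules because fold
changes are pseudocount-dominated when a state is silent; evaluating
the rules in a fixed order makes the subclasses mutually exclusive by
construction.  Fold thresholds default to twofold (1 on the log2 scale)
and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ConditionProfile, MatrixError

SPECIFIC_UP = "SPECIFIC_UP"
SPECIFIC_DOWN = "SPECIFIC_DOWN"
PROGRESSIVE_UP = "PROGRESSIVE_UP"
PROGRESSIVE_DOWN = "PROGRESSIVE_DOWN"
UNIQUE_L = "UNIQUE_L"
SHUTDOWN_L = "SHUTDOWN_L"
STABLE = "STABLE"
OTHER = "OTHER"
ABSENT = "ABSENT"

SUBCLASSES = (SPECIFIC_UP, SPECIFIC_DOWN, PROGRESSIVE_UP, PROGRESSIVE_DOWN,
              UNIQUE_L, SHUTDOWN_L)
ALL_LABELS = SUBCLASSES + (STABLE, OTHER, ABSENT)

#: canonical condition roles, in trajectory order
ROLES = ("control", "short_term", "leukemia")


class ClassifierError(ValueError):
    """Raised on invalid thresholds or missing conditions."""


@dataclass(frozen=True)
class ClassifierThresholds:
    """Fold-change cut-offs on the log2 scale.

    ``fold_min`` is the minimum |log2 fold| counted as a change (default
    1, i.e. twofold); ``flat_max`` is the bound below which a fold change
    counts as "unchanged" (default 1).
    """

    fold_min: float = 1.0
    flat_max: float = 1.0

    def __post_init__(self) -> None:
        if self.fold_min <= 0:
            raise ClassifierError("fold_min must be positive")
        if self.flat_max <= 0:
            raise ClassifierError("flat_max must be positive")


def classify_gene(summaries: tuple[float, float, float],
                  present: tuple[bool, bool, bool],
                  thresholds: ClassifierThresholds = ClassifierThresholds(),
                  ) -> tuple[str, tuple[float, float, float]]:
    """Classify one gene from its (control, short_term, leukemia) profile.

    Returns the label and the three log2 fold changes
    (leukemia vs control, short_term vs control, leukemia vs short_term)
    used for the call.
    """
    if len(summaries) != 3 or len(present) != 3:
        raise ClassifierError("need exactly three condition summaries")
    c, s, l = (float(v) for v in summaries)
    pc, ps, pl = (bool(v) for v in present)
    st_c = s - c
    l_st = l - s
    l_c = l - c
    fm, fl = thresholds.fold_min, thresholds.flat_max

    if not pc and not ps and pl:
        label = UNIQUE_L
    elif pc and ps and not pl:
        label = SHUTDOWN_L
    elif st_c >= fm and l_st >= fm:
        label = PROGRESSIVE_UP
    elif st_c <= -fm and l_st <= -fm:
        label = PROGRESSIVE_DOWN
    elif abs(st_c) < fl and l_st >= fm:
        label = SPECIFIC_UP
    elif abs(st_c) < fl and l_st <= -fm:
        label = SPECIFIC_DOWN
    elif not (pc or ps or pl):
        label = ABSENT
    elif abs(st_c) < fl and abs(l_st) < fl and abs(l_c) < fl:
        label = STABLE
    else:
        label = OTHER
    return label, (l_c, st_c, l_st)


@dataclass
class TrajectoryTable:
    """Per-gene label assignments plus the fold changes behind each call."""

    table: pd.DataFrame  # columns: label, lfc_l_vs_ctrl, lfc_st_vs_ctrl, lfc_l_vs_st

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def label_counts(self) -> pd.Series:
        counts = self.labels.value_counts()
        return counts.reindex(ALL_LABELS, fill_value=0)

    def genes_with(self, *labels: str) -> list[str]:
        mask = self.labels.isin(labels)
        return list(self.table.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrajectoryTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        return cls(df)


def classify_all(profile: ConditionProfile,
                 thresholds: ClassifierThresholds = ClassifierThresholds(),
                 condition_map: dict[str, str] | None = None) -> TrajectoryTable:
    """Classify every gene in a three-condition profile.

    ``condition_map`` maps the roles ``control`` / ``short_term`` /
    ``leukemia`` to the profile's actual condition labels; by default the
    roles themselves are used as labels.
    """
    cmap = dict(condition_map or {r: r for r in ROLES})
    for role in ROLES:
        if role not in cmap:
            raise ClassifierError(f"condition_map is missing role {role!r}")
        if cmap[role] not in profile.conditions:
            raise ClassifierError(
                f"profile has no condition {cmap[role]!r} (role {role!r})")

    cols = [cmap[r] for r in ROLES]
    summ = profile.log2_summary[cols].to_numpy(dtype=float)
    pres = profile.presence[cols].to_numpy(dtype=bool)
    c, s, l = summ.T
    pc, ps, pl = pres.T
    st_c, l_st, l_c = s - c, l - s, l - c
    fm, fl = thresholds.fold_min, thresholds.flat_max

    conditions = [
        ~pc & ~ps & pl,
        pc & ps & ~pl,
        (st_c >= fm) & (l_st >= fm),
        (st_c <= -fm) & (l_st <= -fm),
        (np.abs(st_c) < fl) & (l_st >= fm),
        (np.abs(st_c) < fl) & (l_st <= -fm),
        ~(pc | ps | pl),
        (np.abs(st_c) < fl) & (np.abs(l_st) < fl) & (np.abs(l_c) < fl),
    ]
    choices = [UNIQUE_L, SHUTDOWN_L, PROGRESSIVE_UP, PROGRESSIVE_DOWN,
               SPECIFIC_UP, SPECIFIC_DOWN, ABSENT, STABLE]
    labels = np.select(conditions, choices, default=OTHER)

    table = pd.DataFrame({
        "label": labels,
        "lfc_l_vs_ctrl": l_c,
        "lfc_st_vs_ctrl": st_c,
        "lfc_l_vs_st": l_st,
    }, index=profile.log2_summary.index)
    return TrajectoryTable(table)
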