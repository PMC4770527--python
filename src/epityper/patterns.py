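"""Epitype-specific hyper- and hypomethylation pattern sets.

Each pattern is a conjunction of strict per-epitype mean-beta constraints
applied to one of the two tumor-specific universes (cancer-methylated or
cancer-unmethylated CpGs).  The biological roles of the clusters (basal-like,
hypermethylated luminal, globally hypomethylated luminal) are declared
explicitly rather than inferred, since ordinal cluster labels carry no
biology on new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .site_selection import TumorSpecificSets


@dataclass(frozen=True)
class SetConstraint:
    """One strict mean-beta bound: mean beta of ``epitype`` {>,<} ``threshold``."""

    epitype: str
    op: str  # ">" or "<"
    threshold: float

    def __post_init__(self):
        if self.op not in (">", "<"):
            raise ValueError(f"op must be '>' or '<', got {self.op!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")


def epitype_means(beta_values: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-probe mean beta per epitype over non-missing members."""
    labels = labels.reindex(beta_values.columns)
    if labels.isna().any():
        raise ValueError("labels do not cover all samples")
    return beta_values.T.groupby(labels).mean().T


def select_constrained_set(
    beta_values: pd.DataFrame,
    labels: pd.Series,
    universe: pd.Index,
    constraints: list[SetConstraint],
) -> pd.Index:
    """Probes in ``universe`` satisfying every constraint (strict inequalities).

    A probe with no observed value in a constrained epitype fails that
    constraint (conservative).  An empty constraint list returns the universe.
    """
    universe = pd.Index(universe)
    if not constraints:
        return universe
    means = epitype_means(beta_values.loc[universe], labels)
    keep = np.ones(len(universe), dtype=bool)
    for c in constraints:
        if c.epitype not in means.columns:
            raise ValueError(f"constraint references absent epitype {c.epitype!r}")
        m = means[c.epitype].to_numpy(float)
        ok = (m > c.threshold) if c.op == ">" else (m < c.threshold)
        keep &= np.nan_to_num(ok.astype(float), nan=0.0).astype(bool)
    return universe[keep]


#: default role labels under the normal-similarity ordering convention:
#: ET7-like basal, ET5-like hypermethylated luminal, ET4-like globally
#: hypomethylated luminal (for a seven-epitype model).
DEFAULT_ROLES = {"basal": "ET7", "hyper_luminal": "ET5", "hypo_luminal": "ET4"}


@dataclass
class EpitypePatternSets:
    """The five pattern sets with the per-epitype mean-beta table.

    - ``basal_methylated``: cancer-methylated CpGs with mean beta > 0.5 in the
      basal-like epitype (constitutive methylation shared with hypermethylated
      luminal tumors).
    - ``luminal_methylated``: mean beta > 0.5 in the hypermethylated luminal
      epitype and < 0.1 in the basal-like epitype (luminal-specific).
    - ``global_hypo``: cancer-unmethylated CpGs with mean beta < 0.5 in the
      globally hypomethylated epitype and > 0.7 in both the hypermethylated
      luminal and basal-like epitypes.
    - ``luminal_hypo``: mean beta < 0.5 in the hypermethylated luminal epitype
      and > 0.7 in the basal-like epitype.
    - ``basal_hypo``: mean beta < 0.5 in the basal-like epitype and > 0.7 in
      the globally hypomethylated epitype.
    """

    basal_methylated: pd.Index
    luminal_methylated: pd.Index
    global_hypo: pd.Index
    luminal_hypo: pd.Index
    basal_hypo: pd.Index
    means: pd.DataFrame
    roles: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, pd.Index]:
        return {
            "basal_methylated": self.basal_methylated,
            "luminal_methylated": self.luminal_methylated,
            "global_hypo": self.global_hypo,
            "luminal_hypo": self.luminal_hypo,
            "basal_hypo": self.basal_hypo,
        }

    def sizes(self) -> dict[str, int]:
        return {name: len(ix) for name, ix in self.as_dict().items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, ix in self.as_dict().items():
            for probe in ix:
                rows.append((probe, name))
        out = pd.DataFrame(rows, columns=["probe_id", "pattern"])
        return out.join(self.means, on="probe_id")


def pattern_constraints(roles: dict[str, str]) -> dict[str, tuple[str, list[SetConstraint]]]:
    """The five rule definitions, keyed by pattern name.

    Each value is ``(universe_name, constraints)`` with universe_name in
    {"cancer_methylated", "cancer_unmethylated"}.
    """
    basal = roles["basal"]
    hyper = roles["hyper_luminal"]
    hypo = roles["hypo_luminal"]
    return {
        "basal_methylated": (
            "cancer_methylated",
            [SetConstraint(basal, ">", 0.5)],
        ),
        "luminal_methylated": (
            "cancer_methylated",
            [SetConstraint(hyper, ">", 0.5), SetConstraint(basal, "<", 0.1)],
        ),
        "global_hypo": (
            "cancer_unmethylated",
            [
                SetConstraint(hypo, "<", 0.5),
                SetConstraint(hyper, ">", 0.7),
                SetConstraint(basal, ">", 0.7),
            ],
        ),
        "luminal_hypo": (
            "cancer_unmethylated",
            [SetConstraint(hyper, "<", 0.5), SetConstraint(basal, ">", 0.7)],
        ),
        "basal_hypo": (
            "cancer_unmethylated",
            [SetConstraint(basal, "<", 0.5), SetConstraint(hypo, ">", 0.7)],
        ),
    }


def extract_epitype_patterns(
    beta_values: pd.DataFrame,
    labels: pd.Series,
    sets: TumorSpecificSets,
    roles: dict[str, str] | None = None,
) -> EpitypePatternSets:
    """Apply the five mean-beta pattern rules to the tumor-specific universes."""
    roles = dict(DEFAULT_ROLES if roles is None else roles)
    missing = {r for r in ("basal", "hyper_luminal", "hypo_luminal") if r not in roles}
    if missing:
        raise ValueError(f"incomplete role mapping; missing {sorted(missing)}")
    present = set(labels.unique())
    absent = {v for v in roles.values() if v not in present}
    if absent:
        raise ValueError(f"role epitypes absent from labels: {sorted(absent)}")

    universes = {
        "cancer_methylated": sets.cancer_methylated,
        "cancer_unmethylated": sets.cancer_unmethylated,
    }
    selected = {}
    for name, (universe_name, constraints) in pattern_constraints(roles).items():
        selected[name] = select_constrained_set(
            beta_values, labels, universes[universe_name], constraints
        )
    means = epitype_means(beta_values.loc[sets.all_selected], labels)
    return EpitypePatternSets(means=means, roles=roles, **selected)
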