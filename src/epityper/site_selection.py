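"""Constitutive methylation calls in normals and tumor-specific CpG selection.

A CpG is constitutively methylated in the normal cohort when every non-missing
normal beta is strictly above 0.7 (symmetrically, unmethylated below 0.3),
allowing a small number of missing values.  Among constitutive sites, a CpG is
cancer-methylated when it is unmethylated in normals but crosses beta > 0.7 in
at least a minimum fraction of tumors (5% by default), and vice versa for
cancer-unmethylated sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BetaMatrix

STATUS_METHYLATED = "methylated"
STATUS_UNMETHYLATED = "unmethylated"
STATUS_EXCLUDED = "excluded"


def _values(beta) -> pd.DataFrame:
    return beta.values if isinstance(beta, BetaMatrix) else beta


def call_normal_status(
    normal_beta,
    meth_min: float = 0.7,
    unmeth_max: float = 0.3,
    max_missing: int = 2,
) -> pd.DataFrame:
    """Call per-probe constitutive status across the normal cohort.

    Inequalities are strict: a probe is methylated only if *all* non-missing
    normal values satisfy ``beta > meth_min`` (unmethylated: ``beta <
    unmeth_max``).  Any non-missing value in ``[unmeth_max, meth_min]`` or more
    than ``max_missing`` missing values excludes the probe.

    Returns a DataFrame indexed by probe with columns ``status``,
    ``n_missing`` and ``n_violations`` (non-missing values on the wrong side
    of the best-fitting threshold).
    """
    vals = _values(normal_beta)
    if vals.shape[1] == 0:
        raise ValueError("empty normal cohort")
    arr = vals.to_numpy(float)
    missing = np.isnan(arr)
    n_missing = missing.sum(axis=1)
    above = (arr > meth_min) | missing
    below = (arr < unmeth_max) | missing
    n_not_above = (~above).sum(axis=1)
    n_not_below = (~below).sum(axis=1)
    allowed = n_missing <= max_missing
    status = np.where(
        allowed & above.all(axis=1),
        STATUS_METHYLATED,
        np.where(allowed & below.all(axis=1), STATUS_UNMETHYLATED, STATUS_EXCLUDED),
    )
    return pd.DataFrame(
        {
            "status": status,
            "n_missing": n_missing,
            "n_violations": np.minimum(n_not_above, n_not_below),
        },
        index=vals.index,
    )


@dataclass
class TumorSpecificSets:
    """Probe sets with tumor-specific methylation status.

    ``cancer_methylated``: unmethylated in normals, beta > 0.7 in at least the
    minimum fraction of tumors.  ``cancer_unmethylated``: the mirror image.
    ``switched_fraction`` gives, for every probe with a constitutive normal
    status, the fraction of tumors with switched status.
    """

    cancer_methylated: pd.Index
    cancer_unmethylated: pd.Index
    switched_fraction: pd.Series
    min_count: int

    @property
    def all_selected(self) -> pd.Index:
        return self.cancer_methylated.union(self.cancer_unmethylated, sort=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for probe in self.cancer_methylated:
            rows.append((probe, "cancer_methylated", self.switched_fraction[probe]))
        for probe in self.cancer_unmethylated:
            rows.append((probe, "cancer_unmethylated", self.switched_fraction[probe]))
        return pd.DataFrame(rows, columns=["probe_id", "direction", "switched_fraction"])


def select_tumor_specific(
    tumor_beta,
    normal_status: pd.DataFrame,
    min_fraction: float = 0.05,
    meth_min: float = 0.7,
    unmeth_max: float = 0.3,
) -> TumorSpecificSets:
    """Select CpG sites that switch methylation status in tumors.

    The count threshold is ``ceil(min_fraction * n_tumors)`` (5% of 188 tumors
    gives n = 10).  Missing tumor values never count as switched, and the
    denominator stays the full tumor count.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    vals = _values(tumor_beta)
    vals = vals.loc[normal_status.index.intersection(vals.index)]
    n_tumors = vals.shape[1]
    min_count = math.ceil(min_fraction * n_tumors)
    arr = vals.to_numpy(float)
    status = normal_status.loc[vals.index, "status"].to_numpy()

    n_meth = np.nansum(arr > meth_min, axis=1)
    n_unmeth = np.nansum(arr < unmeth_max, axis=1)
    is_normal_unmeth = status == STATUS_UNMETHYLATED
    is_normal_meth = status == STATUS_METHYLATED

    switched = np.where(is_normal_unmeth, n_meth, np.where(is_normal_meth, n_unmeth, 0))
    frac = pd.Series(switched / max(n_tumors, 1), index=vals.index, name="switched_fraction")
    cancer_methylated = vals.index[is_normal_unmeth & (n_meth >= min_count)]
    cancer_unmethylated = vals.index[is_normal_meth & (n_unmeth >= min_count)]
    return TumorSpecificSets(
        cancer_methylated=cancer_methylated,
        cancer_unmethylated=cancer_unmethylated,
        switched_fraction=frac[is_normal_unmeth | is_normal_meth],
        min_count=min_count,
    )
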