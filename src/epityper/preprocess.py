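"""Signal-to-beta conversion, QC masking, and Infinium I/II peak normalization.

The 450K array reports, for every CpG and sample, a methylated (M) and an
unmethylated (U) fluorescence intensity.  The methylation level is summarized
as the beta value ``beta = M / (M + U)`` in [0, 1].  Two probe chemistries
(Infinium type I and type II) coexist on the platform; type II probes show a
compressed dynamic range, so the two assay types are rescaled separately by
moving the unmethylated density peak to 0 and the methylated peak to 1
(linear stretch, then clamping to [0, 1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ASSAY_TYPES = ("I", "II")

#: columns a long-format signal table must provide.  ``n_beads`` is optional
#: (the TCGA level-2 dialect does not report bead counts).
SIGNAL_COLUMNS = ("probe_id", "sample_id", "M", "U", "detection_p")


class PeakSeparationError(ValueError):
    """Raised when a sample/assay stratum has no resolvable bimodal density."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with a per-probe assay type.

    Attributes
    ----------
    values
        DataFrame indexed by probe, columns are samples; ``NaN`` marks missing
        (masked) measurements.  All non-missing entries lie in [0, 1].
    assay_type
        Series mapping probe -> "I" or "II".
    normalized
        Provenance flag: True once peak normalization has been applied.
    """

    values: pd.DataFrame
    assay_type: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        self.assay_type = self.assay_type.reindex(self.values.index)

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def missing_per_sample(self) -> pd.Series:
        return self.values.isna().sum(axis=0)

    def restrict(self, probes) -> "BetaMatrix":
        """Return a view on a subset of probes (order follows ``probes``)."""
        probes = pd.Index(probes)
        return BetaMatrix(
            self.values.loc[probes], self.assay_type.loc[probes], self.normalized
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy(), self.assay_type.copy(), self.normalized)


def compute_beta_and_mask(
    signals: pd.DataFrame,
    assay_type: pd.Series,
    p_max: float = 0.05,
    min_beads: int = 3,
) -> BetaMatrix:
    """Convert a long signal table to a masked :class:`BetaMatrix`.

    ``beta = M / (M + U)``.  A measurement is set missing when its detection
    p value is strictly greater than ``p_max`` or the bead count is strictly
    fewer than ``min_beads``.  When the table carries no ``n_beads`` column
    (TCGA dialect) only the p-value rule applies.  ``M + U == 0`` yields a
    missing value rather than an error; negative intensities are rejected.
    """
    missing_cols = set(SIGNAL_COLUMNS) - set(signals.columns)
    if missing_cols:
        raise ValueError(f"signal table lacks columns: {sorted(missing_cols)}")
    m = signals["M"].to_numpy(float)
    u = signals["U"].to_numpy(float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("negative signal intensities")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    mask = signals["detection_p"].to_numpy(float) > p_max
    if "n_beads" in signals.columns and signals["n_beads"].notna().any():
        beads = signals["n_beads"].to_numpy(float)
        mask |= np.nan_to_num(beads, nan=np.inf) < min_beads
    beta = np.where(mask, np.nan, beta)

    wide = (
        pd.DataFrame(
            {"probe_id": signals["probe_id"], "sample_id": signals["sample_id"], "beta": beta}
        )
        .pivot(index="probe_id", columns="sample_id", values="beta")
        .rename_axis(index=None, columns=None)
    )
    return BetaMatrix(wide, assay_type.reindex(wide.index), normalized=False)


def epanechnikov_density(
    values: np.ndarray, grid: np.ndarray, bandwidth: float, reflect: bool = True
) -> np.ndarray:
    """Kernel density estimate with the Epanechnikov kernel on ``grid``.

    With ``reflect=True`` the estimate is boundary-corrected by reflection at
    0 and 1, so mass piled at the ends of the beta scale (e.g. after clamping)
    keeps its mode on the boundary instead of drifting inward.
    """
    values = np.asarray(values, float)
    copies = (values, -values, 2.0 - values) if reflect else (values,)
    dens = np.zeros_like(grid)
    for copy in copies:
        u = (grid[:, None] - copy[None, :]) / bandwidth
        dens += (0.75 * np.clip(1.0 - u * u, 0.0, None)).sum(axis=1)
    return dens / (values.size * bandwidth)


def density_modes(
    values: np.ndarray,
    bandwidth: float = 0.04,
    grid_size: int = 1001,
    midpoint: float = 0.5,
) -> tuple[float, float]:
    """Locate the unmethylated (< midpoint) and methylated (>= midpoint) density peaks."""
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = epanechnikov_density(values, grid, bandwidth)
    lo = grid < midpoint
    peak_u = grid[lo][np.argmax(dens[lo])]
    peak_m = grid[~lo][np.argmax(dens[~lo])]
    return float(peak_u), float(peak_m)


def peak_normalize(
    beta: BetaMatrix,
    bandwidth: float = 0.04,
    grid_size: int = 1001,
    midpoint: float = 0.5,
    min_separation: float = 0.2,
    min_values: int = 25,
) -> BetaMatrix:
    """Peak-based correction of Infinium I/II assay bias.

    For each sample and each assay type independently, the beta density is
    smoothed (Epanechnikov kernel on a fixed grid over [0, 1]); the
    unmethylated peak (density argmax below ``midpoint``) is moved to 0 and
    the methylated peak (argmax above) to 1 by the linear map
    ``x -> (x - p_u) / (p_m - p_u)``.  Values below 0 are set to 0 and values
    above 1 are set to 1.  Missing entries stay missing.

    Raises
    ------
    PeakSeparationError
        If ``p_m - p_u < min_separation`` in any sample/assay stratum, or a
        stratum has fewer than ``min_values`` non-missing values.
    """
    out = beta.values.to_numpy(float).copy()
    assay = beta.assay_type.to_numpy()
    for atype in ASSAY_TYPES:
        rows = assay == atype
        if not rows.any():
            continue
        block = out[rows]
        for j, sample in enumerate(beta.samples):
            col = block[:, j]
            obs = col[~np.isnan(col)]
            if obs.size < min_values:
                raise PeakSeparationError(
                    f"sample {sample!r}, assay type {atype}: only {obs.size} "
                    f"non-missing values (need >= {min_values})"
                )
            peak_u, peak_m = density_modes(obs, bandwidth, grid_size, midpoint)
            if peak_m - peak_u < min_separation:
                raise PeakSeparationError(
                    f"sample {sample!r}, assay type {atype}: peaks {peak_u:.3f} and "
                    f"{peak_m:.3f} closer than {min_separation}"
                )
            block[:, j] = np.clip((col - peak_u) / (peak_m - peak_u), 0.0, 1.0)
        out[rows] = block
    values = pd.DataFrame(out, index=beta.probes, columns=beta.samples)
    return BetaMatrix(values, beta.assay_type, normalized=True)


@dataclass
class HypermethylationScore:
    """Per-sample mean-beta summaries over two CpG universes."""

    global_score: pd.Series
    promoter_island_score: pd.Series
    n_global: pd.Series
    n_promoter_island: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "global_score": self.global_score,
                "promoter_island_score": self.promoter_island_score,
                "n_global": self.n_global,
                "n_promoter_island": self.n_promoter_island,
            }
        )


def promoter_island_probes(annotation: pd.DataFrame) -> pd.Index:
    """Probes annotated to TSS1500/TSS200 AND located in a CpG island."""
    region = annotation["region"].fillna("")
    in_promoter = region.str.split(";").map(
        lambda parts: any(p in ("TSS1500", "TSS200") for p in parts)
    )
    in_island = annotation["island_relation"].fillna("") == "Island"
    return annotation.index[in_promoter & in_island]


def hypermethylation_score(
    beta: BetaMatrix, annotation: pd.DataFrame
) -> HypermethylationScore:
    """Global and promoter-CpG-island hypermethylation scores.

    Both scores are the per-sample mean beta over the contributing probe set,
    excluding missing values.  The global score uses every probe on the
    platform; the promoter-island score uses probes whose region annotation
    includes TSS1500 or TSS200 and whose island relation is "Island".
    """
    promo = promoter_island_probes(annotation.loc[annotation.index.intersection(beta.probes)])
    if len(beta.probes) == 0:
        raise ValueError("empty beta matrix")
    if len(promo) == 0:
        raise ValueError("no promoter CpG-island probes in annotation")
    vals = beta.values
    return HypermethylationScore(
        global_score=vals.mean(axis=0),
        promoter_island_score=vals.loc[promo].mean(axis=0),
        n_global=vals.notna().sum(axis=0),
        n_promoter_island=vals.loc[promo].notna().sum(axis=0),
    )


def qc_report(beta: BetaMatrix, max_missing: int = 10_000) -> pd.DataFrame:
    """Per-sample missing-value counts with a warn flag above ``max_missing``."""
    miss = beta.missing_per_sample()
    return pd.DataFrame({"n_missing": miss, "warn": miss > max_missing})
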