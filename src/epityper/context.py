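"""Genomic-context annotation of CpG sites and enrichment summaries.

CpGs are mapped by position (0-based) into interval tracks: chromatin-state
segmentations per cell type, peak calls (e.g. DNase accessibility, EZH2
binding), and repeat annotations with a repeat class.  All intervals are
0-based half-open; a probe at an interval's end coordinate is not covered.
Strand is ignored (CpG methylation is strand-symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

BED_COLUMNS = ("chrom", "start", "end")


def _build_trees(intervals: pd.DataFrame, data_col: str | None = None) -> dict:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            if row.end > row.start:
                tree.addi(row.start, row.end, getattr(row, data_col) if data_col else True)
        trees[chrom] = tree
    return trees


@dataclass
class GenomeTracks:
    """Interval tracks over a genome.

    ``chromatin_states`` maps cell type -> BED-like DataFrame with a ``state``
    column; ``peaks`` maps track name -> BED-like DataFrame; ``repeats`` is a
    BED-like DataFrame with a ``repeat_class`` column; ``chrom_lengths`` maps
    chromosome -> length in bp.
    """

    chromatin_states: dict[str, pd.DataFrame] = field(default_factory=dict)
    peaks: dict[str, pd.DataFrame] = field(default_factory=dict)
    repeats: pd.DataFrame | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for name, df in list(self.chromatin_states.items()) + list(self.peaks.items()):
            bad = df[(df["start"] < 0) | (df["end"] < df["start"])]
            if len(bad):
                raise ValueError(f"track {name!r} has invalid intervals")
        self._state_trees = {
            ct: _build_trees(df, "state") for ct, df in self.chromatin_states.items()
        }
        self._peak_trees = {name: _build_trees(df) for name, df in self.peaks.items()}
        self._repeat_trees = (
            _build_trees(self.repeats, "repeat_class") if self.repeats is not None else {}
        )

    def state_at(self, cell_type: str, chrom: str, pos: int) -> str | None:
        tree = self._state_trees.get(cell_type, {}).get(chrom)
        if tree is None:
            return None
        hits = tree[pos]
        return next(iter(hits)).data if hits else None

    def in_peak(self, track: str, chrom: str, pos: int) -> bool:
        tree = self._peak_trees.get(track, {}).get(chrom)
        return bool(tree[pos]) if tree is not None else False

    def repeat_classes_at(self, chrom: str, pos: int) -> set:
        tree = self._repeat_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree[pos]}


@dataclass
class ContextProfile:
    per_probe: pd.DataFrame
    state_fractions: dict[str, pd.Series]
    island_fractions: pd.Series
    peak_fractions: pd.Series
    n_unassigned: dict[str, int]


def annotate_context(
    probes,
    tracks: GenomeTracks,
    annotation: pd.DataFrame,
) -> ContextProfile:
    """Assign each probe its chromatin state per cell type, island relation,
    peak overlap flags, and distance to the nearest chromosome end.

    State fractions are computed over assigned probes only; probes on
    chromosomes absent from a track are counted as unassigned.
    """
    probes = pd.Index(probes)
    ann = annotation.loc[probes]
    per_probe = pd.DataFrame(index=probes)
    per_probe["chrom"] = ann["chrom"]
    per_probe["pos"] = ann["pos"]
    if "island_relation" in ann.columns:
        per_probe["island_relation"] = ann["island_relation"]

    state_fractions = {}
    n_unassigned = {}
    for ct in tracks.chromatin_states:
        states = [
            tracks.state_at(ct, c, p) for c, p in zip(ann["chrom"], ann["pos"])
        ]
        col = f"state_{ct}"
        per_probe[col] = states
        assigned = per_probe[col].dropna()
        n_unassigned[ct] = int(per_probe[col].isna().sum())
        if len(assigned):
            state_fractions[ct] = assigned.value_counts(normalize=True).sort_index()
        else:
            state_fractions[ct] = pd.Series(dtype=float)

    peak_fractions = {}
    for name in tracks.peaks:
        flags = [tracks.in_peak(name, c, p) for c, p in zip(ann["chrom"], ann["pos"])]
        per_probe[f"peak_{name}"] = flags
        peak_fractions[name] = float(np.mean(flags)) if len(flags) else np.nan

    if tracks.chrom_lengths:
        per_probe["dist_to_end"] = [
            distance_to_chromosome_end(c, p, tracks.chrom_lengths)
            if c in tracks.chrom_lengths
            else np.nan
            for c, p in zip(ann["chrom"], ann["pos"])
        ]

    island_fractions = (
        per_probe["island_relation"].value_counts(normalize=True).sort_index()
        if "island_relation" in per_probe.columns
        else pd.Series(dtype=float)
    )
    return ContextProfile(
        per_probe=per_probe,
        state_fractions=state_fractions,
        island_fractions=island_fractions,
        peak_fractions=pd.Series(peak_fractions, dtype=float),
        n_unassigned=n_unassigned,
    )


def distance_to_chromosome_end(chrom: str, pos: int, chrom_lengths: dict) -> int:
    length = chrom_lengths[chrom]
    if pos > length:
        raise ValueError(f"position {pos} beyond {chrom} length {length}")
    return min(pos, length - pos)


@dataclass
class RepeatEnrichment:
    table: np.ndarray  # rows: (target, background); cols: (in class, not in class)
    odds_ratio: float
    p_value: float
    classes: tuple


def repeat_enrichment(
    target_probes,
    background_probes,
    tracks: GenomeTracks,
    annotation: pd.DataFrame,
    classes=("LINE", "LTR"),
) -> RepeatEnrichment:
    """2x2 Fisher's exact test for repeat-class overlap, target vs background.

    A probe overlapping any interval of any listed class counts once.
    """
    classes = tuple(classes)

    def _in_class(probes) -> int:
        ann = annotation.loc[pd.Index(probes)]
        hits = 0
        for c, p in zip(ann["chrom"], ann["pos"]):
            if tracks.repeat_classes_at(c, p) & set(classes):
                hits += 1
        return hits

    target_probes = pd.Index(target_probes)
    background_probes = pd.Index(background_probes)
    a = _in_class(target_probes)
    b = len(target_probes) - a
    c = _in_class(background_probes)
    d = len(background_probes) - c
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
        raise ValueError("empty margin in the repeat-enrichment table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return RepeatEnrichment(table=table, odds_ratio=float(odds), p_value=float(p), classes=classes)


@dataclass
class SubtelomereStats:
    fraction_target: float
    fraction_background: float
    t_statistic: float
    p_value: float
    window: float
    distances_target: pd.Series
    distances_background: pd.Series


def subtelomere_stats(
    target_probes,
    platform_probes,
    tracks: GenomeTracks,
    annotation: pd.DataFrame,
    window: float = 5e6,
) -> SubtelomereStats:
    """Chromosome-end proximity of a target set versus the rest of the platform.

    Per-probe distance to the nearest end is ``min(pos, length - pos)``.
    Reports the fraction of probes within ``window`` of an end for the target
    and for the non-target platform probes, plus a two-sided Welch t test on
    the distances.
    """
    target_probes = pd.Index(target_probes)
    background = pd.Index(platform_probes).difference(target_probes)

    def _dist(probes) -> pd.Series:
        ann = annotation.loc[probes]
        return pd.Series(
            [
                distance_to_chromosome_end(c, p, tracks.chrom_lengths)
                for c, p in zip(ann["chrom"], ann["pos"])
            ],
            index=probes,
            dtype=float,
        )

    dt = _dist(target_probes)
    db = _dist(background)
    t, p = stats.ttest_ind(dt, db, equal_var=False)
    return SubtelomereStats(
        fraction_target=float((dt <= window).mean()),
        fraction_background=float((db <= window).mean()),
        t_statistic=float(t),
        p_value=float(p),
        window=window,
        distances_target=dt,
        distances_background=db,
    )
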