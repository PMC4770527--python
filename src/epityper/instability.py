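"""Copy-number summaries (FGA, amplification calls) and mutation-table merging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Variant_Classification values NOT counted as nonsilent mutations.
SILENT_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "IGR", "5'Flank", "3'Flank", "RNA"}
)

CALL_GAIN = "gain"
CALL_LOSS = "loss"
CALL_NEUTRAL = "neutral"


def call_gain_loss(
    estimates: pd.DataFrame, gain_threshold: float = 0.2, loss_threshold: float = -0.2
) -> pd.DataFrame:
    """Threshold probe-level copy-number estimates into gain/loss/neutral calls."""
    arr = estimates.to_numpy(float)
    calls = np.where(
        arr > gain_threshold, CALL_GAIN, np.where(arr < loss_threshold, CALL_LOSS, CALL_NEUTRAL)
    )
    return pd.DataFrame(calls, index=estimates.index, columns=estimates.columns)


def compute_fga(calls: pd.DataFrame) -> pd.Series:
    """Fraction of the genome altered per sample.

    FGA = (number of probes called gain or loss) / (total probes on the
    platform), per sample.
    """
    if calls.shape[0] == 0:
        raise ValueError("empty copy-number profile")
    altered = calls.isin([CALL_GAIN, CALL_LOSS])
    return altered.sum(axis=0) / calls.shape[0]


@dataclass
class AmplificationCalls:
    calls: pd.DataFrame  # regions x samples boolean
    region_means: pd.DataFrame
    uncallable: list
    per_sample_count: pd.Series


def call_amplifications(
    estimates: pd.DataFrame,
    probe_positions: pd.DataFrame,
    regions: pd.DataFrame,
    threshold: float = 0.8,
) -> AmplificationCalls:
    """Call a region amplified when the mean probe estimate is strictly > threshold.

    ``probe_positions`` must carry ``chrom`` and ``pos`` for each probe of
    ``estimates``; ``regions`` is a named BED-like table (``name``, ``chrom``,
    ``start``, ``end``, half-open).  Regions containing no probe are reported
    uncallable rather than called.
    """
    means = {}
    uncallable = []
    pos = probe_positions.loc[estimates.index]
    for row in regions.itertuples(index=False):
        inside = (
            (pos["chrom"] == row.chrom) & (pos["pos"] >= row.start) & (pos["pos"] < row.end)
        )
        if not inside.any():
            uncallable.append(row.name)
            continue
        means[row.name] = estimates.loc[inside.to_numpy()].mean(axis=0)
    region_means = pd.DataFrame(means).T
    calls = region_means > threshold
    return AmplificationCalls(
        calls=calls,
        region_means=region_means,
        uncallable=uncallable,
        per_sample_count=calls.sum(axis=0) if len(calls) else pd.Series(dtype=int),
    )


@dataclass
class MutationCatalog:
    """Per-tumor nonsilent mutated genes and merged substitution counts.

    ``mutated`` is a boolean genes x tumors frame (a gene is mutated when it
    is nonsilently mutated in at least one experiment for the tumor);
    ``substitutions`` is the per-tumor substitution count averaged over the
    tumor's experiments.
    """

    mutated: pd.DataFrame
    substitutions: pd.Series
    n_experiments: pd.Series

    def genes_for(self, tumor: str) -> set:
        if tumor not in self.mutated.columns:
            return set()
        col = self.mutated[tumor]
        return set(col.index[col])


def merge_mutation_experiments(
    maf: pd.DataFrame,
    silent_classes=SILENT_CLASSES,
    experiment_col: str = "experiment",
) -> MutationCatalog:
    """Merge a MAF-minimal table with possibly several experiments per tumor.

    Requires columns ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
    ``Variant_Classification``; an optional experiment column distinguishes
    repeated sequencing experiments of the same tumor.  A gene is called
    mutated when it is nonsilently mutated in at least one experiment, and the
    substitution count per tumor is the mean count over its experiments
    (``Variant_Type == "SNP"`` rows when that column is present, otherwise all
    rows).
    """
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(maf.columns)
    if missing:
        raise ValueError(f"MAF table lacks columns: {sorted(missing)}")
    maf = maf.copy()
    if experiment_col not in maf.columns:
        maf[experiment_col] = "exp1"

    nonsilent = maf[~maf["Variant_Classification"].isin(silent_classes)]
    mutated = (
        nonsilent.groupby(["Hugo_Symbol", "Tumor_Sample_Barcode"]).size().unstack(fill_value=0)
        > 0
    )
    mutated = mutated.reindex(columns=sorted(maf["Tumor_Sample_Barcode"].unique()), fill_value=False)

    subs = maf
    if "Variant_Type" in maf.columns:
        subs = maf[maf["Variant_Type"] == "SNP"]
    per_exp = subs.groupby(["Tumor_Sample_Barcode", experiment_col]).size()
    n_exp = maf.groupby("Tumor_Sample_Barcode")[experiment_col].nunique()
    # experiments with zero substitutions still count in the mean
    counts = per_exp.unstack(fill_value=np.nan)
    all_exp = maf.groupby(["Tumor_Sample_Barcode", experiment_col]).size().unstack()
    counts = counts.reindex_like(all_exp).where(all_exp.isna(), counts.fillna(0.0))
    substitutions = counts.mean(axis=1)
    substitutions = substitutions.reindex(mutated.columns).fillna(0.0)
    return MutationCatalog(
        mutated=mutated,
        substitutions=substitutions,
        n_experiments=n_exp.reindex(mutated.columns).fillna(0).astype(int),
    )


def merge_catalogs(a: MutationCatalog, b: MutationCatalog) -> MutationCatalog:
    """Combine two catalogs: union of mutated genes, mean substitution counts.

    Idempotent: merging a catalog with itself changes nothing.
    """
    genes = a.mutated.index.union(b.mutated.index)
    tumors = a.mutated.columns.union(b.mutated.columns)
    ma = a.mutated.reindex(index=genes, columns=tumors, fill_value=False)
    mb = b.mutated.reindex(index=genes, columns=tumors, fill_value=False)
    sa = a.substitutions.reindex(tumors)
    sb = b.substitutions.reindex(tumors)
    subs = pd.concat([sa, sb], axis=1).mean(axis=1)
    n_exp = pd.concat(
        [a.n_experiments.reindex(tumors), b.n_experiments.reindex(tumors)], axis=1
    ).max(axis=1).fillna(0).astype(int)
    return MutationCatalog(mutated=ma | mb, substitutions=subs, n_experiments=n_exp)
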