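"""Epitype discovery by bootstrap consensus clustering and centroid classification.

Tumors are clustered on their beta profiles over the tumor-specific CpG sites.
Each bootstrap iteration resamples samples with replacement; the unique
resampled samples are clustered by Ward agglomeration on Pearson-correlation
distance (the inner clustering).  Co-clustering frequencies, normalized by how
often a pair was co-present in a resample, are accumulated into a consensus
matrix, whose rows are then clustered the same way (the outer clustering) to
give the epitype labels.  New samples are classified by Pearson correlation to
per-epitype centroid profiles (mean beta per CpG).

Dialect notes: R's ``hclust(method="ward.D")`` applied to a dissimilarity d is
reproduced by scipy's ``linkage(method="ward")`` applied to sqrt(d), because
scipy treats its input as Euclidean distances and works internally with their
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def pearson_distance_matrix(values: pd.DataFrame, min_overlap: int = 100) -> np.ndarray:
    """1 - pairwise Pearson correlation between columns (pairwise-complete).

    Raises if any pair overlaps in fewer than ``min_overlap`` non-missing rows.
    """
    arr = values.to_numpy(float)
    if np.isnan(arr).any():
        mask = (~np.isnan(arr)).astype(float)
        overlap = mask.T @ mask
        if (overlap < min_overlap).any():
            i, j = np.unravel_index(np.argmin(overlap), overlap.shape)
            raise ValueError(
                f"columns {values.columns[i]!r} and {values.columns[j]!r} share only "
                f"{int(overlap[i, j])} non-missing sites (need >= {min_overlap})"
            )
        corr = values.corr(method="pearson", min_periods=min_overlap).to_numpy()
    else:
        if arr.shape[0] < min_overlap:
            raise ValueError(f"only {arr.shape[0]} sites available (need >= {min_overlap})")
        corr = np.corrcoef(arr.T)
    return 1.0 - corr


def ward_labels(dist: np.ndarray, k: int) -> np.ndarray:
    """Ward.D labels (1..k) for a square dissimilarity matrix."""
    cond = squareform(np.clip(dist, 0.0, None), checks=False)
    link = linkage(np.sqrt(cond), method="ward")
    return fcluster(link, t=k, criterion="maxclust")


@dataclass
class ConsensusResult:
    """Bootstrap consensus-clustering output.

    ``cocluster_freq`` maps k to a samples x samples matrix of co-clustering
    frequencies (co-assignments / co-presences); ``copresence_count`` counts
    how often each pair appeared together in a bootstrap resample.
    """

    samples: pd.Index
    cocluster_freq: dict[int, np.ndarray]
    copresence_count: np.ndarray
    labels_by_k: dict[int, pd.Series]
    stability_by_k: dict[int, pd.DataFrame]
    n_boot: int
    seed: int

    def frequencies(self, k: int) -> pd.DataFrame:
        return pd.DataFrame(self.cocluster_freq[k], index=self.samples, columns=self.samples)


def _cluster_stability(freq: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster consensus summaries: size, mean within-pair consensus, and
    the largest mean consensus to any other cluster."""
    rows = []
    ids = np.unique(labels)
    for cid in ids:
        members = labels == cid
        size = int(members.sum())
        sub = freq[np.ix_(members, members)]
        if size > 1:
            within = float(sub[np.triu_indices(size, k=1)].mean())
        else:
            within = 1.0
        between = 0.0
        for other in ids:
            if other == cid:
                continue
            others = labels == other
            between = max(between, float(freq[np.ix_(members, others)].mean()))
        rows.append((int(cid), size, within, between, within - between))
    return pd.DataFrame(
        rows, columns=["cluster", "size", "within", "max_between", "margin"]
    ).set_index("cluster")


def bootstrap_consensus(
    beta_values: pd.DataFrame,
    k_range=range(3, 11),
    n_boot: int = 2000,
    seed: int = 0,
    min_overlap: int = 100,
    outer_distance: str = "pearson",
    on_uncovered: str = "error",
) -> ConsensusResult:
    """Bootstrap consensus clustering of samples (columns of ``beta_values``).

    Each of ``n_boot`` iterations resamples the n samples with replacement;
    the unique resampled samples are Ward-clustered on 1 - Pearson distance
    and cut at every k in ``k_range``.  The outer clustering applies the same
    Ward procedure to 1 - Pearson correlation between rows of the consensus
    matrix (``outer_distance="pearson"``), or directly to 1 - consensus
    frequency (``outer_distance="frequency"``).

    A sample never drawn in any resample is an error by default
    (``on_uncovered="error"``); with ``on_uncovered="ignore"`` its consensus
    row stays zero off-diagonal (useful for single-iteration diagnostics).
    """
    if beta_values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    k_range = [int(k) for k in k_range]
    samples = beta_values.columns
    n = len(samples)
    dist = pearson_distance_matrix(beta_values, min_overlap=min_overlap)

    rng = np.random.default_rng(seed)
    co = {k: np.zeros((n, n)) for k in k_range}
    copresent = np.zeros((n, n))
    for _ in range(n_boot):
        idx = np.unique(rng.integers(0, n, size=n))
        sub = dist[np.ix_(idx, idx)]
        cond = squareform(np.clip(sub, 0.0, None), checks=False)
        link = linkage(np.sqrt(cond), method="ward")
        ix = np.ix_(idx, idx)
        copresent[ix] += 1.0
        for k in k_range:
            labels = fcluster(link, t=min(k, len(idx)), criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co[k][ix] += same

    never = np.diag(copresent) == 0
    if never.any() and on_uncovered == "error":
        missing = list(samples[never])
        raise ValueError(
            f"samples never drawn in any bootstrap resample: {missing}; "
            "increase n_boot"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = {
            k: np.where(copresent > 0, co[k] / np.where(copresent > 0, copresent, 1), 0.0)
            for k in k_range
        }
    for k in k_range:
        np.fill_diagonal(freq[k], 1.0)

    labels_by_k: dict[int, pd.Series] = {}
    stability_by_k: dict[int, pd.DataFrame] = {}
    for k in k_range:
        if outer_distance == "pearson":
            outer = 1.0 - np.corrcoef(freq[k])
        elif outer_distance == "frequency":
            outer = 1.0 - freq[k]
        else:
            raise ValueError(f"unknown outer_distance {outer_distance!r}")
        labels = ward_labels(outer, k)
        labels_by_k[k] = pd.Series(labels, index=samples, name=f"k{k}")
        stability_by_k[k] = _cluster_stability(freq[k], labels)

    return ConsensusResult(
        samples=samples,
        cocluster_freq=freq,
        copresence_count=copresent,
        labels_by_k=labels_by_k,
        stability_by_k=stability_by_k,
        n_boot=n_boot,
        seed=seed,
    )


@dataclass
class KChoice:
    k: int
    diagnostics: pd.DataFrame


def choose_k(
    result: ConsensusResult,
    min_cluster_size: int = 5,
    stability_threshold: float = 0.6,
) -> KChoice:
    """Pick the largest admissible k.

    A k is inadmissible when any of its outer clusters has fewer than
    ``min_cluster_size`` samples or a consensus margin (mean within-cluster
    consensus minus the largest mean consensus to another cluster) below
    ``stability_threshold``.  Among admissible k, the largest is returned
    (the solution with the largest number of robust clusters).
    """
    rows = []
    for k, stab in sorted(result.stability_by_k.items()):
        too_small = int((stab["size"] < min_cluster_size).sum())
        min_margin = float(stab["margin"].min())
        admissible = too_small == 0 and min_margin >= stability_threshold
        rows.append((k, too_small, float(stab["within"].min()), min_margin, admissible))
    diag = pd.DataFrame(
        rows, columns=["k", "n_small_clusters", "min_within", "min_margin", "admissible"]
    ).set_index("k")
    admissible = diag.index[diag["admissible"]]
    if len(admissible) == 0:
        raise ValueError(f"no admissible k; diagnostics:\n{diag}")
    return KChoice(k=int(admissible.max()), diagnostics=diag)


@dataclass
class EpitypeModel:
    """Trained centroid classifier: per-epitype mean beta profiles."""

    centroids: pd.DataFrame  # probes x epitypes
    epitype_order: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def probes(self) -> pd.Index:
        return self.centroids.index

    def sizes(self) -> dict:
        return self.metadata.get("sizes", {})


def build_centroids(
    beta_values: pd.DataFrame,
    labels: pd.Series,
    reference_profile: pd.Series | None = None,
    name_prefix: str = "ET",
) -> EpitypeModel:
    """Average beta per CpG across the tumors of each cluster.

    Missing values are excluded from the mean.  When ``reference_profile``
    (typically the normal-cohort mean profile) is given, epitypes are ordered
    by descending correlation of their centroid to it, so the most normal-like
    cluster becomes ET1; otherwise clusters keep their label order.
    """
    labels = labels.reindex(beta_values.columns)
    if labels.isna().any():
        raise ValueError("labels do not cover all samples")
    groups = sorted(labels.unique())
    cents = {}
    sizes = {}
    for g in groups:
        cols = labels.index[labels == g]
        if len(cols) == 0:
            raise ValueError(f"empty epitype {g!r}")
        cents[g] = beta_values[cols].mean(axis=1)
        sizes[g] = int(len(cols))
    cent = pd.DataFrame(cents)
    if reference_profile is not None:
        ref = reference_profile.reindex(cent.index)
        order = (
            cent.corrwith(ref).sort_values(ascending=False).index.tolist()
        )
    else:
        order = groups
    names = [f"{name_prefix}{i + 1}" for i in range(len(order))]
    cent = cent[order]
    cent.columns = names
    mapping = dict(zip(order, names))
    return EpitypeModel(
        centroids=cent,
        epitype_order=names,
        metadata={
            "sizes": {mapping[g]: sizes[g] for g in order},
            "source_labels": {str(g): mapping[g] for g in order},
            "n_training_samples": int(beta_values.shape[1]),
            "n_sites": int(beta_values.shape[0]),
        },
    )


def relabel(labels: pd.Series, model: EpitypeModel) -> pd.Series:
    """Map raw cluster labels to the model's ordered epitype names."""
    mapping = {k: v for k, v in model.metadata["source_labels"].items()}
    return labels.map(lambda g: mapping[str(g)])


@dataclass
class EpitypeAssignment:
    labels: pd.Series
    correlations: pd.DataFrame  # samples x epitypes
    margin: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.correlations.copy()
        out["label"] = self.labels
        out["margin"] = self.margin
        return out


def classify_by_centroid(
    beta_values: pd.DataFrame,
    model: EpitypeModel,
    min_overlap: int = 100,
) -> EpitypeAssignment:
    """Assign each sample to the centroid with the largest Pearson correlation.

    Correlations use sites non-missing in both the sample and the centroid.
    Exact ties are broken by ``epitype_order``.  Zero-variance samples (over
    the overlapping model sites) are an error.
    """
    common = model.probes.intersection(beta_values.index)
    x = beta_values.loc[common].to_numpy(float)
    c = model.centroids.loc[common].to_numpy(float)
    n_samples = x.shape[1]
    n_ep = c.shape[1]
    corrs = np.empty((n_samples, n_ep))
    for j in range(n_samples):
        col = x[:, j]
        obs = ~np.isnan(col)
        for e in range(n_ep):
            both = obs & ~np.isnan(c[:, e])
            if both.sum() < min_overlap:
                raise ValueError(
                    f"sample {beta_values.columns[j]!r}: only {int(both.sum())} sites "
                    f"overlap centroid {model.epitype_order[e]} (need >= {min_overlap})"
                )
            a = col[both]
            b = c[both, e]
            if a.std() == 0 or b.std() == 0:
                raise ValueError(
                    f"zero-variance profile for sample {beta_values.columns[j]!r} "
                    "over model sites; correlation undefined"
                )
            corrs[j, e] = np.corrcoef(a, b)[0, 1]
    corr_df = pd.DataFrame(corrs, index=beta_values.columns, columns=model.epitype_order)
    best = corr_df.to_numpy().argmax(axis=1)  # argmax takes the first maximum
    labels = pd.Series(
        [model.epitype_order[i] for i in best], index=corr_df.index, name="epitype"
    )
    sorted_corr = np.sort(corr_df.to_numpy(), axis=1)
    margin = pd.Series(
        sorted_corr[:, -1] - (sorted_corr[:, -2] if n_ep > 1 else 0.0),
        index=corr_df.index,
        name="margin",
    )
    return EpitypeAssignment(labels=labels, correlations=corr_df, margin=margin)
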