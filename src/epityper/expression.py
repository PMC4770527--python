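"""Expression transforms, methylation-expression correlation, module scores,
and promoter methylation calling for candidate driver genes.

Expression enters in one of two modes: *relative* levels (log2(x+1) per-gene
mean-centered across samples; suitable for comparing one gene across tumors)
or *absolute* levels (log2(TPM+1); suitable for comparing genes).  CpG sites
mapping to a unique gene are screened for correlation between methylation and
expression, with Pearson r thresholds of 0.2 / -0.2 for the positive and
negative classes.  Promoter methylation for a candidate driver is called from
the "informative" CpGs: sites within the gene's transcripts or 1 kb upstream
whose methylation is negatively correlated (r < -0.2) with the gene's
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import BetaMatrix


def collapse_probes(expr: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Keep, for each gene, the probe with the largest variance across samples."""
    genes = probe_to_gene.reindex(expr.index)
    variances = expr.var(axis=1, ddof=1)
    order = variances.sort_values(ascending=False).index
    keep = pd.Series(genes.loc[order]).drop_duplicates(keep="first")
    keep = keep[keep.notna()]
    out = expr.loc[keep.index]
    out.index = keep.to_numpy()
    return out.sort_index()


def transform_expression(
    raw: pd.DataFrame,
    mode: str = "relative",
    probe_to_gene: pd.Series | None = None,
) -> pd.DataFrame:
    """Transform non-negative expression estimates.

    relative
        ``log2(x + 1)`` then per-gene mean-centering across samples.
    absolute
        Scaled estimates are converted to transcripts per million by column
        normalization, then ``log2(TPM + 1)``.

    When ``probe_to_gene`` is given, multiple probes per gene are collapsed
    first, keeping the probe with the largest variance.
    """
    if (raw.to_numpy(float) < 0).any():
        raise ValueError("negative expression input")
    if probe_to_gene is not None:
        raw = collapse_probes(raw, probe_to_gene)
    if mode == "relative":
        logged = np.log2(raw + 1.0)
        return logged.sub(logged.mean(axis=1), axis=0)
    if mode == "absolute":
        tpm = raw.div(raw.sum(axis=0), axis=1) * 1e6
        return np.log2(tpm + 1.0)
    raise ValueError(f"unknown mode {mode!r}")


CLASS_POSITIVE = "positive"
CLASS_NEGATIVE = "negative"
CLASS_LOW = "low"
CLASS_UNMAPPED = "unmapped"


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    both = ~np.isnan(x) & ~np.isnan(y)
    n = int(both.sum())
    if n < 2:
        return np.nan, n
    a, b = x[both], y[both]
    if a.std() == 0 or b.std() == 0:
        return np.nan, n
    return float(np.corrcoef(a, b)[0, 1]), n


def correlate_meth_expr(
    beta,
    expr: pd.DataFrame,
    cpg_to_gene: pd.Series,
    pos_threshold: float = 0.2,
    neg_threshold: float = -0.2,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-CpG Pearson correlation between methylation and gene expression.

    Only CpGs mapped to a unique gene present in ``expr`` are correlated,
    over the shared samples, pairwise-complete.  Thresholds are strict.
    CpGs without a usable correlation (no gene, gene absent, fewer than
    ``min_pairs`` complete pairs, or zero variance on either side) fall into
    the "unmapped" class with a reason.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    shared = values.columns.intersection(expr.columns)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples (need >= 3)")
    bv = values[shared]
    ev = expr[shared]
    rows = []
    for probe in bv.index:
        gene = cpg_to_gene.get(probe)
        if gene is None or (isinstance(gene, float) and np.isnan(gene)) or gene == "":
            rows.append((probe, None, np.nan, 0, CLASS_UNMAPPED, "no unique gene"))
            continue
        if gene not in ev.index:
            rows.append((probe, gene, np.nan, 0, CLASS_UNMAPPED, "gene not in expression"))
            continue
        r, n = _pairwise_pearson(bv.loc[probe].to_numpy(float), ev.loc[gene].to_numpy(float))
        if n < min_pairs:
            rows.append((probe, gene, np.nan, n, CLASS_UNMAPPED, "too few pairs"))
            continue
        if np.isnan(r):
            rows.append((probe, gene, np.nan, n, CLASS_UNMAPPED, "zero variance"))
            continue
        if r > pos_threshold:
            cls = CLASS_POSITIVE
        elif r < neg_threshold:
            cls = CLASS_NEGATIVE
        else:
            cls = CLASS_LOW
        rows.append((probe, gene, r, n, cls, ""))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene", "r", "n_pairs", "class", "reason"]
    ).set_index("probe_id")


def module_score(expr: pd.DataFrame, module_genes) -> tuple[pd.Series, int]:
    """Average relative expression of the module genes present in the matrix.

    Returns the per-sample score and the number of module genes matched.
    """
    found = expr.index.intersection(pd.Index(module_genes))
    if len(found) == 0:
        raise ValueError("no module genes found in the expression matrix")
    return expr.loc[found].mean(axis=0), int(len(found))


@dataclass(frozen=True)
class PromoterCallConfig:
    """How to call promoter methylation status for one gene.

    ``direction="methylated"`` calls a sample methylated when the mean beta
    over informative CpGs is strictly greater than ``threshold`` (the BRCA1
    preset: > 0.2).  ``direction="unmethylated"`` calls a sample unmethylated
    when the mean is strictly less than ``threshold`` (the HORMAD1 preset:
    < 0.8).  Informative CpGs are the window CpGs (within transcripts or
    ``upstream`` bp upstream of the transcription start, strand-aware) with
    Pearson r < ``r_max`` against the gene's expression in the screening
    cohort.
    """

    gene: str
    direction: str  # "methylated" | "unmethylated"
    threshold: float
    r_max: float = -0.2
    upstream: int = 1000

    def __post_init__(self):
        if self.direction not in ("methylated", "unmethylated"):
            raise ValueError(f"direction must be methylated/unmethylated, got {self.direction!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")


def brca1_preset(gene: str = "BRCA1") -> PromoterCallConfig:
    return PromoterCallConfig(gene=gene, direction="methylated", threshold=0.2)


def hormad1_preset(gene: str = "HORMAD1") -> PromoterCallConfig:
    return PromoterCallConfig(gene=gene, direction="unmethylated", threshold=0.8)


def promoter_window_probes(
    probe_annotation: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    gene: str,
    upstream: int = 1000,
) -> pd.Index:
    """CpGs within any of a gene's transcripts or ``upstream`` bp upstream.

    Transcript intervals are 0-based half-open; upstream is measured from the
    annotated transcription start on the coding strand (before ``start`` for
    plus-strand transcripts, after ``end`` for minus-strand ones).  Windows of
    multiple transcripts are unioned.
    """
    tx = gene_annotation[gene_annotation["gene"] == gene]
    if tx.empty:
        raise ValueError(f"gene {gene!r} absent from gene annotation")
    hits = []
    for _, row in tx.iterrows():
        if row.get("strand", "+") == "-":
            lo, hi = row["start"], row["end"] + upstream
        else:
            lo, hi = row["start"] - upstream, row["end"]
        on_chrom = probe_annotation["chrom"] == row["chrom"]
        inside = (probe_annotation["pos"] >= lo) & (probe_annotation["pos"] < hi)
        hits.append(probe_annotation.index[on_chrom & inside])
    out = hits[0]
    for h in hits[1:]:
        out = out.union(h, sort=False)
    return out


@dataclass
class PromoterCallResult:
    gene: str
    status: pd.Series  # per sample: "methylated"/"unmethylated"/"uncallable"
    called: pd.Series  # boolean: meets the configured call rule
    mean_beta: pd.Series
    informative_probes: pd.Index
    window_probes: pd.Index
    median_r: float
    correlations: pd.Series


def call_promoter_status(
    beta,
    expr: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    config: PromoterCallConfig,
    screen_samples=None,
) -> PromoterCallResult:
    """Screen the promoter window for informative CpGs and call samples.

    ``screen_samples`` declares the cohort used for the correlation screen
    (defaults to the samples shared between beta and expression); the call is
    applied to every sample in ``beta``.  Zero informative CpGs yields status
    "uncallable" for every sample rather than a default call.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    window = promoter_window_probes(
        probe_annotation, gene_annotation, config.gene, config.upstream
    )
    window = window.intersection(values.index)
    if len(window) == 0:
        raise ValueError(f"no CpGs in the promoter window of {config.gene!r}")

    if screen_samples is None:
        screen_samples = values.columns.intersection(expr.columns)
    screen_samples = pd.Index(screen_samples)
    if config.gene not in expr.index:
        raise ValueError(f"gene {config.gene!r} absent from expression matrix")
    gene_expr = expr.loc[config.gene, screen_samples].to_numpy(float)

    rs = {}
    for probe in window:
        r, n = _pairwise_pearson(
            values.loc[probe, screen_samples].to_numpy(float), gene_expr
        )
        rs[probe] = r
    corr = pd.Series(rs, name="r")
    informative = corr.index[corr < config.r_max]

    if len(informative) == 0:
        status = pd.Series("uncallable", index=values.columns, name="status")
        called = pd.Series(False, index=values.columns, name="called")
        mean_beta = pd.Series(np.nan, index=values.columns, name="mean_beta")
        median_r = float("nan")
    else:
        mean_beta = values.loc[informative].mean(axis=0)
        if config.direction == "methylated":
            hit = mean_beta > config.threshold
            status = pd.Series(
                np.where(hit, "methylated", "unmethylated"), index=values.columns
            )
        else:
            hit = mean_beta < config.threshold
            status = pd.Series(
                np.where(hit, "unmethylated", "methylated"), index=values.columns
            )
        status[mean_beta.isna()] = "uncallable"
        called = hit & mean_beta.notna()
        median_r = float(corr.loc[informative].median())

    return PromoterCallResult(
        gene=config.gene,
        status=status,
        called=called,
        mean_beta=mean_beta,
        informative_probes=pd.Index(informative),
        window_probes=window,
        median_r=median_r,
        correlations=corr,
    )
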