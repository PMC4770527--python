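"""Synthetic breast-tumor methylation cohorts with planted structure.

The generator emulates the statistical structure the epityping analysis
assumes, so every downstream stage can be exercised without any external
download: bimodal beta distributions with assay-type-II peak compression, a
normal cohort with near-constitutive site states, seven planted tumor
epitypes with graded promoter hypermethylation and global hypomethylation,
methylation-expression coupling of both signs, detection-p censoring,
copy-number gain/loss tracks, mutation tables with repeated experiments, and
survival times differing by epitype.

Beta noise is drawn on the logit scale and mapped back through the logistic
function, which keeps values inside [0, 1] and concentrates noise away from
the peaks (mirroring the heteroscedasticity of real beta values) without
clipping.  Type-II assay bias is modeled as linear peak shrinkage toward 0.5,
exactly the dialect the peak normalizer corrects.

Planted site classes
--------------------
constitutive_unmeth / constitutive_meth
    At the unmethylated / methylated peak in every sample.
variable
    Intermediate mean per probe; excluded by the normal-status caller.
cancer_meth_graded / cancer_unmeth_graded
    Tumor-specific switching whose per-epitype *rate* follows a gradient but
    whose per-epitype mean beta stays strictly below / above the pattern-rule
    cutoffs: members of the tumor-specific universes, not of any pattern set.
basal_meth
    Methylated (mean > 0.5) in the basal-like epitype and in the
    hypermethylated luminal epitype (constitutive tumor methylation).
luminal_meth
    Graded hypermethylation across luminal epitypes, high in the
    hypermethylated luminal epitype and absent in the basal-like one.
et4_hypo / luminal_hypo / basal_hypo
    The three hypomethylation patterns (specific to the globally
    hypomethylated epitype, shared across luminal epitypes, and specific to
    the basal-like epitype).  et4_hypo probes are placed subtelomerically;
    luminal_hypo probes inside LINE/LTR repeats.
driver promoter probes
    A BRCA1-like gene (silenced subset: promoter beta ~0.6, suppressed
    expression) and a HORMAD1-like gene (demethylated subset: promoter beta
    ~0.25, elevated expression), each with informative and non-informative
    window CpGs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .preprocess import BetaMatrix, compute_beta_and_mask
from .context import GenomeTracks

CHROM_LENGTHS = {"chr1": 80_000_000, "chr2": 60_000_000, "chr3": 40_000_000}

CHROMATIN_STATES = (
    "Active_promoter",
    "Weak_promoter",
    "Poised_promoter",
    "Strong_enhancer",
    "Weak_enhancer",
    "Insulator",
    "Transcription_elongation",
    "Weak_transcribed",
    "Polycomb_repressed",
    "Heterochromatin_low",
)
_STATE_PROBS = (0.05, 0.05, 0.05, 0.05, 0.06, 0.04, 0.08, 0.10, 0.08, 0.44)

REPEAT_CLASSES = ("LINE", "LTR", "SINE", "Simple_repeat")
_REPEAT_PROBS = (0.45, 0.20, 0.25, 0.10)

#: default per-epitype mean-beta targets / switch rates for the planted
#: classes of a seven-epitype cohort (ET1 normal-like; ET2-ET5 luminal with
#: graded promoter hypermethylation; ET4 globally hypomethylated; ET6
#: amplifier-rich; ET7 basal-like).
DEFAULT_GRADIENT_SPEC = {
    "basal_meth": (0.05, 0.10, 0.15, 0.25, 0.85, 0.70, 0.85),
    "luminal_meth": (0.05, 0.30, 0.50, 0.65, 0.85, 0.15, 0.05),
    "et4_hypo": (0.95, 0.92, 0.90, 0.22, 0.90, 0.90, 0.88),
    "luminal_hypo": (0.95, 0.65, 0.45, 0.25, 0.22, 0.60, 0.92),
    "basal_hypo": (0.95, 0.92, 0.90, 0.90, 0.85, 0.90, 0.22),
    "cancer_meth_graded": (0.00, 0.05, 0.08, 0.08, 0.15, 0.08, 0.06),
    "cancer_unmeth_graded": (0.00, 0.04, 0.06, 0.10, 0.15, 0.08, 0.10),
}

#: split of the tumor-specific probe budget over planted classes; most
#: selected sites follow coherent epitype gradients, a minority switch
#: idiosyncratically per tumor.
_METH_SPLIT = {"basal_meth": 0.12, "luminal_meth": 0.58, "cancer_meth_graded": 0.30}
_UNMETH_SPLIT = {
    "et4_hypo": 0.22,
    "luminal_hypo": 0.55,
    "basal_hypo": 0.03,
    "cancer_unmeth_graded": 0.20,
}

DEFAULT_ROLES = {"basal": "ET7", "hyper_luminal": "ET5", "hypo_luminal": "ET4"}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_tumors: int = 120
    n_normals: int = 96
    n_probes: int = 5000
    n_epitypes: int = 7
    epitype_proportions: tuple = (0.20, 0.08, 0.14, 0.12, 0.10, 0.08, 0.28)
    unmeth_peak: float = 0.05
    meth_peak: float = 0.95
    noise_sd: float = 0.05
    typeII_compression: tuple = (0.05, 0.10)
    frac_cancer_meth_sites: float = 0.10
    frac_cancer_unmeth_sites: float = 0.10
    frac_variable_sites: float = 0.06
    frac_assay_type_II: float = 0.7
    gradient_spec: dict | None = None
    expr_coupling: dict | None = None
    expr_noise_sd: float = 0.1
    n_background_genes: int = 100
    missing_rate: float = 0.005
    n_cn_probes: int = 1500
    seed: int = 0

    def __post_init__(self):
        if self.n_epitypes < 2:
            raise ValueError("n_epitypes must be >= 2")
        if abs(sum(self.epitype_proportions) - 1.0) > 1e-9:
            raise ValueError("epitype_proportions must sum to 1")
        if len(self.epitype_proportions) != self.n_epitypes:
            raise ValueError("epitype_proportions length must equal n_epitypes")
        for peak in (self.unmeth_peak, self.meth_peak):
            if not 0.0 <= peak <= 1.0:
                raise ValueError("beta peak locations must lie in [0, 1]")
        if self.meth_peak <= self.unmeth_peak:
            raise ValueError("meth_peak must exceed unmeth_peak")
        if self.gradient_spec is None:
            if self.n_epitypes != 7:
                raise ValueError(
                    "the default gradient_spec is defined for 7 epitypes; "
                    "pass gradient_spec explicitly for other counts"
                )
            self.gradient_spec = {k: tuple(v) for k, v in DEFAULT_GRADIENT_SPEC.items()}
        if self.expr_coupling is None:
            self.expr_coupling = {
                "luminal_meth": -3.0,
                "et4_hypo": 3.0,
                "luminal_hypo": 3.0,
                "basal_meth": 0.0,
            }

    @property
    def epitype_names(self) -> list[str]:
        return [f"ET{i + 1}" for i in range(self.n_epitypes)]


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    epitype_labels: pd.Series  # per tumor
    site_class: pd.Series  # per probe
    planted_sets: dict[str, list]  # exact sets each selection rule recovers
    expr_truth: dict[str, int]  # gene -> coupling sign (-1, 0, +1)
    roles: dict[str, str]
    brca1_silenced: list
    hormad1_demethylated: list

    def to_json_dict(self) -> dict:
        return {
            "epitype_labels": self.epitype_labels.to_dict(),
            "site_class": self.site_class.to_dict(),
            "planted_sets": {k: list(v) for k, v in self.planted_sets.items()},
            "expr_truth": self.expr_truth,
            "roles": self.roles,
            "brca1_silenced": list(self.brca1_silenced),
            "hormad1_demethylated": list(self.hormad1_demethylated),
        }


@dataclass
class Cohort:
    """All tables of one synthetic cohort."""

    signals: pd.DataFrame
    beta: BetaMatrix
    annotation: pd.DataFrame
    gene_annotation: pd.DataFrame
    expression: pd.DataFrame
    cn_estimates: pd.DataFrame
    cn_positions: pd.DataFrame
    cn_regions: pd.DataFrame
    maf: pd.DataFrame
    clinical: pd.DataFrame
    truth: SyntheticTruth
    tracks: GenomeTracks
    config: GeneratorConfig

    @property
    def tumor_samples(self) -> pd.Index:
        return pd.Index(self.truth.epitype_labels.index)

    @property
    def normal_samples(self) -> pd.Index:
        return self.beta.samples.difference(self.tumor_samples, sort=False)


def _allocate_counts(total: int, proportions) -> np.ndarray:
    """Largest-remainder allocation of ``total`` over ``proportions``."""
    raw = np.asarray(proportions, float) * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _tile_segments(rng, length: int, mean_len: float, labels, probs) -> pd.DataFrame:
    rows = []
    pos = 0
    while pos < length:
        seg = int(max(10_000, rng.exponential(mean_len)))
        end = min(pos + seg, length)
        rows.append((pos, end, rng.choice(labels, p=probs)))
        pos = end
    return pd.DataFrame(rows, columns=["start", "end", "state"])


def generate_tracks(rng) -> GenomeTracks:
    """Random chromatin-state segmentations, peaks and repeats for the toy genome."""
    states = {}
    for cell_type in ("HMEC", "H1hESC"):
        frames = []
        for chrom, length in CHROM_LENGTHS.items():
            df = _tile_segments(rng, length, 200_000, CHROMATIN_STATES, _STATE_PROBS)
            df.insert(0, "chrom", chrom)
            frames.append(df)
        states[cell_type] = pd.concat(frames, ignore_index=True)

    def _peaks_from(state_df: pd.DataFrame, state: str, keep: float) -> pd.DataFrame:
        segs = state_df[state_df["state"] == state]
        take = segs.sample(frac=keep, random_state=np.random.RandomState(rng.integers(2**31)))
        mid = ((take["start"] + take["end"]) // 2).to_numpy()
        return pd.DataFrame(
            {"chrom": take["chrom"].to_numpy(), "start": mid - 500, "end": mid + 500}
        ).reset_index(drop=True)

    peaks = {
        "DNase": _peaks_from(states["HMEC"], "Active_promoter", 0.8),
        "EZH2": _peaks_from(states["HMEC"], "Polycomb_repressed", 0.6),
    }

    rep_rows = []
    for chrom, length in CHROM_LENGTHS.items():
        pos = int(rng.exponential(20_000))
        while pos < length:
            seg = int(max(500, rng.exponential(3_000)))
            end = min(pos + seg, length)
            rep_rows.append((chrom, pos, end, rng.choice(REPEAT_CLASSES, p=_REPEAT_PROBS)))
            pos = end + int(rng.exponential(12_000))
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "repeat_class"])
    return GenomeTracks(
        chromatin_states=states,
        peaks=peaks,
        repeats=repeats,
        chrom_lengths=dict(CHROM_LENGTHS),
    )


def _positions_in_intervals(rng, intervals: pd.DataFrame, n: int) -> pd.DataFrame:
    lengths = (intervals["end"] - intervals["start"]).to_numpy(float)
    pick = rng.choice(len(intervals), size=n, p=lengths / lengths.sum())
    rows = intervals.iloc[pick]
    offset = (rng.random(n) * lengths[pick]).astype(int)
    return pd.DataFrame(
        {"chrom": rows["chrom"].to_numpy(), "pos": rows["start"].to_numpy() + offset}
    )


def _uniform_positions(rng, n: int) -> pd.DataFrame:
    chroms = list(CHROM_LENGTHS)
    lengths = np.array([CHROM_LENGTHS[c] for c in chroms], float)
    pick = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[pick]).astype(int)
    return pd.DataFrame({"chrom": [chroms[i] for i in pick], "pos": pos})


def _subtelomeric_positions(rng, n: int, window: int = 5_000_000) -> pd.DataFrame:
    rows = []
    for chrom, length in CHROM_LENGTHS.items():
        rows.append((chrom, 0, window))
        rows.append((chrom, length - window, length))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return _positions_in_intervals(rng, windows, n)


# --- driver-gene layout (fixed coordinates on the toy genome) ---------------
_BRCA1_LIKE = {
    "gene": "BRCA1L",
    "chrom": "chr1",
    "start": 10_000_000,
    "end": 10_080_000,
    "strand": "+",
    "n_informative": 8,
    "n_noninformative": 4,
}
_HORMAD1_LIKE = {
    "gene": "HORMAD1L",
    "chrom": "chr2",
    "start": 20_000_000,
    "end": 20_020_000,
    "strand": "-",
    "n_informative": 7,
    "n_noninformative": 2,
}


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort.  Deterministic given ``config.seed``
    (PCG64 generator via :func:`numpy.random.default_rng`)."""
    rng = np.random.default_rng(config.seed)
    ets = config.epitype_names
    n_et = config.n_epitypes

    tumors = pd.Index([f"T{i + 1:03d}" for i in range(config.n_tumors)])
    normals = pd.Index([f"N{i + 1:03d}" for i in range(config.n_normals)])
    samples = tumors.append(normals)

    et_counts = _allocate_counts(config.n_tumors, config.epitype_proportions)
    epitype_labels = pd.Series(
        np.repeat(ets, et_counts), index=tumors, name="epitype", dtype=object
    )
    et_members = {et: np.flatnonzero(epitype_labels.to_numpy() == et) for et in ets}

    tracks = generate_tracks(rng)

    # --- probe budget ------------------------------------------------------
    with_drivers = config.n_probes >= 1000
    n_driver = (
        _BRCA1_LIKE["n_informative"]
        + _BRCA1_LIKE["n_noninformative"]
        + _HORMAD1_LIKE["n_informative"]
        + _HORMAD1_LIKE["n_noninformative"]
    ) if with_drivers else 0
    n_free = config.n_probes - n_driver
    n_meth = int(round(config.frac_cancer_meth_sites * config.n_probes))
    n_unmeth = int(round(config.frac_cancer_unmeth_sites * config.n_probes))
    n_var = int(round(config.frac_variable_sites * config.n_probes))
    n_const = n_free - n_meth - n_unmeth - n_var
    if n_const < 2:
        raise ValueError("n_probes too small for the configured class fractions")

    class_counts: dict[str, int] = {}
    for cls, frac in _METH_SPLIT.items():
        class_counts[cls] = int(round(frac * n_meth))
    class_counts["cancer_meth_graded"] += n_meth - sum(
        class_counts[c] for c in _METH_SPLIT
    )
    for cls, frac in _UNMETH_SPLIT.items():
        class_counts[cls] = int(round(frac * n_unmeth))
    class_counts["cancer_unmeth_graded"] += n_unmeth - sum(
        class_counts[c] for c in _UNMETH_SPLIT
    )
    class_counts["variable"] = n_var
    class_counts["constitutive_unmeth"] = n_const // 2
    class_counts["constitutive_meth"] = n_const - n_const // 2
    if with_drivers:
        class_counts["brca1_informative"] = _BRCA1_LIKE["n_informative"]
        class_counts["brca1_noninformative"] = _BRCA1_LIKE["n_noninformative"]
        class_counts["hormad1_informative"] = _HORMAD1_LIKE["n_informative"]
        class_counts["hormad1_noninformative"] = _HORMAD1_LIKE["n_noninformative"]

    site_class = pd.Series(
        np.repeat(list(class_counts), list(class_counts.values())), dtype=object
    )
    probes = pd.Index([f"cg{i + 1:08d}" for i in range(len(site_class))])
    site_class.index = probes
    members = {cls: np.flatnonzero(site_class.to_numpy() == cls) for cls in class_counts}

    # --- probe positions respecting class placement constraints ------------
    positions = _uniform_positions(rng, len(probes))
    hmec = tracks.chromatin_states["HMEC"]

    def _place(cls: str, pos_df: pd.DataFrame) -> None:
        ix = members.get(cls, np.array([], int))
        positions.iloc[ix, 0] = pos_df["chrom"].to_numpy()[: len(ix)]
        positions.iloc[ix, 1] = pos_df["pos"].to_numpy()[: len(ix)]

    polycomb = hmec[hmec["state"] == "Polycomb_repressed"]
    promoter = hmec[hmec["state"].isin(["Active_promoter", "Weak_promoter"])]
    line_ltr = tracks.repeats[tracks.repeats["repeat_class"].isin(["LINE", "LTR"])]
    _place("basal_meth", _positions_in_intervals(rng, polycomb, class_counts["basal_meth"]))
    _place("luminal_meth", _positions_in_intervals(rng, promoter, class_counts["luminal_meth"]))
    _place("et4_hypo", _subtelomeric_positions(rng, class_counts["et4_hypo"]))
    _place("luminal_hypo", _positions_in_intervals(rng, line_ltr, class_counts["luminal_hypo"]))

    if with_drivers:
        for spec, inf_cls, noninf_cls in (
            (_BRCA1_LIKE, "brca1_informative", "brca1_noninformative"),
            (_HORMAD1_LIKE, "hormad1_informative", "hormad1_noninformative"),
        ):
            tss = spec["start"] if spec["strand"] == "+" else spec["end"]
            n_inf = spec["n_informative"]
            inf_pos = tss - 400 + (800 * np.arange(n_inf) / max(n_inf - 1, 1)).astype(int)
            _place(inf_cls, pd.DataFrame({"chrom": spec["chrom"], "pos": inf_pos}))
            body = spec["start"] + (
                (spec["end"] - spec["start"])
                * (0.3 + 0.5 * np.arange(spec["n_noninformative"]) / max(spec["n_noninformative"], 1))
            ).astype(int)
            _place(noninf_cls, pd.DataFrame({"chrom": spec["chrom"], "pos": body}))

    # --- per-probe x per-sample target means -------------------------------
    u, m = config.unmeth_peak, config.meth_peak
    mu = np.empty((len(probes), len(samples)))
    n_t = config.n_tumors

    def _fill(cls: str, tumor_mu, normal_mu) -> None:
        ix = members.get(cls)
        if ix is None or len(ix) == 0:
            return
        mu[np.ix_(ix, np.arange(n_t))] = tumor_mu
        mu[np.ix_(ix, np.arange(n_t, len(samples)))] = normal_mu

    _fill("constitutive_unmeth", u, u)
    _fill("constitutive_meth", m, m)
    if class_counts.get("variable", 0):
        v = rng.uniform(0.35, 0.65, size=class_counts["variable"])[:, None]
        ix = members["variable"]
        mu[ix, :] = v

    for cls in ("basal_meth", "luminal_meth", "et4_hypo", "luminal_hypo", "basal_hypo"):
        ix = members.get(cls, np.array([], int))
        if len(ix) == 0:
            continue
        targets = np.asarray(config.gradient_spec[cls], float)
        normal_mu = u if cls in ("basal_meth", "luminal_meth") else m
        mu[np.ix_(ix, np.arange(n_t, len(samples)))] = normal_mu
        for e, et in enumerate(ets):
            cols = et_members[et]
            if len(cols):
                mu[np.ix_(ix, cols)] = targets[e]

    for cls, baseline, switched_to in (
        ("cancer_meth_graded", u, m),
        ("cancer_unmeth_graded", m, u),
    ):
        ix = members.get(cls, np.array([], int))
        if len(ix) == 0:
            continue
        rates = np.asarray(config.gradient_spec[cls], float)
        mu[np.ix_(ix, np.arange(n_t, len(samples)))] = baseline
        mu[np.ix_(ix, np.arange(n_t))] = baseline
        for e, et in enumerate(ets):
            cols = et_members[et]
            n_switch = int(round(rates[e] * len(cols)))
            if n_switch == 0:
                continue
            for row in ix:  # deterministic switch count per probe and epitype
                chosen = rng.choice(cols, size=n_switch, replace=False)
                mu[row, chosen] = switched_to

    brca1_silenced: list = []
    hormad1_demethylated: list = []
    if with_drivers:
        basal_cols = et_members[DEFAULT_ROLES["basal"]] if n_et >= 7 else np.arange(n_t)
        n_sil = int(round(0.25 * len(basal_cols)))
        n_dem = int(round(0.30 * len(basal_cols)))
        sil = rng.choice(basal_cols, size=n_sil, replace=False) if n_sil else np.array([], int)
        dem = rng.choice(basal_cols, size=n_dem, replace=False) if n_dem else np.array([], int)
        brca1_silenced = list(tumors[np.sort(sil)])
        hormad1_demethylated = list(tumors[np.sort(dem)])

        _fill("brca1_informative", 0.02, 0.02)
        if len(sil):
            mu[np.ix_(members["brca1_informative"], sil)] = 0.60
        _fill("brca1_noninformative", 0.5, 0.5)
        _fill("hormad1_informative", 0.95, 0.95)
        if len(dem):
            mu[np.ix_(members["hormad1_informative"], dem)] = 0.25
        _fill("hormad1_noninformative", 0.5, 0.5)

    # --- beta values: logit-scale noise, then type-II peak compression -----
    sigma_logit = 4.0 * config.noise_sd  # d(expit)/dz = 1/4 at z = 0
    z = logit(np.clip(mu, 1e-6, 1 - 1e-6))
    if sigma_logit > 0:
        z = z + rng.normal(0.0, sigma_logit, size=mu.shape)
    beta_true = expit(z)

    assay_type = pd.Series(
        np.where(rng.random(len(probes)) < config.frac_assay_type_II, "II", "I"),
        index=probes,
        name="assay_type",
    )
    c0, c1 = config.typeII_compression
    u2, m2 = u + c0, m - c1
    type2 = (assay_type == "II").to_numpy()
    beta_obs = beta_true.copy()
    beta_obs[type2] = u2 + (beta_true[type2] - u) * (m2 - u2) / (m - u)

    # --- signal table with detection-p / bead-count censoring --------------
    n_cells = len(probes) * len(samples)
    total = rng.gamma(8.0, 500.0, size=n_cells)
    flat_beta = beta_obs.ravel()
    detection_p = rng.uniform(0.0, 0.01, size=n_cells)
    n_beads = rng.poisson(14, size=n_cells) + 4
    censored = rng.random(n_cells) < config.missing_rate
    by_p = censored & (rng.random(n_cells) < 0.5)
    by_beads = censored & ~by_p
    detection_p[by_p] = rng.uniform(0.06, 0.5, size=by_p.sum())
    n_beads[by_beads] = rng.integers(0, 3, size=by_beads.sum())
    signals = pd.DataFrame(
        {
            "probe_id": np.repeat(probes.to_numpy(), len(samples)),
            "sample_id": np.tile(samples.to_numpy(), len(probes)),
            "M": np.round(flat_beta * total, 1),
            "U": np.round((1.0 - flat_beta) * total, 1),
            "detection_p": detection_p,
            "n_beads": n_beads,
        }
    )
    beta = compute_beta_and_mask(signals, assay_type)
    beta = BetaMatrix(beta.values[samples], beta.assay_type, normalized=False)

    # --- probe annotation ---------------------------------------------------
    annotation = pd.DataFrame(index=probes)
    annotation["chrom"] = positions["chrom"].to_numpy()
    annotation["pos"] = positions["pos"].to_numpy()
    annotation["assay_type"] = assay_type

    region = np.array([""] * len(probes), dtype=object)
    island = np.array([""] * len(probes), dtype=object)

    def _annotate(cls, regions, region_p, islands, island_p):
        ix = members.get(cls, np.array([], int))
        if len(ix) == 0:
            return
        region[ix] = rng.choice(regions, size=len(ix), p=region_p)
        island[ix] = rng.choice(islands, size=len(ix), p=island_p)

    shore_shelf = ("Island", "N_Shore", "S_Shelf", "OpenSea")
    _annotate("constitutive_unmeth", ("TSS200", "TSS1500", "5'UTR"), (0.5, 0.3, 0.2),
              shore_shelf, (0.70, 0.15, 0.05, 0.10))
    _annotate("constitutive_meth", ("Body", "3'UTR", ""), (0.6, 0.1, 0.3),
              shore_shelf, (0.05, 0.10, 0.15, 0.70))
    _annotate("variable", ("Body", "TSS1500", ""), (0.4, 0.2, 0.4),
              shore_shelf, (0.2, 0.2, 0.2, 0.4))
    _annotate("cancer_meth_graded", ("TSS200", "TSS1500", "Body"), (0.35, 0.30, 0.35),
              shore_shelf, (0.55, 0.25, 0.05, 0.15))
    _annotate("basal_meth", ("TSS200", "TSS1500"), (0.5, 0.5),
              shore_shelf, (0.44, 0.49, 0.02, 0.05))
    _annotate("luminal_meth", ("TSS200", "TSS1500"), (0.6, 0.4),
              shore_shelf, (0.68, 0.23, 0.02, 0.07))
    _annotate("cancer_unmeth_graded", ("Body", "", "3'UTR"), (0.4, 0.4, 0.2),
              shore_shelf, (0.05, 0.15, 0.15, 0.65))
    _annotate("et4_hypo", ("Body", ""), (0.4, 0.6),
              shore_shelf, (0.24, 0.18, 0.11, 0.47))
    _annotate("luminal_hypo", ("Body", ""), (0.3, 0.7),
              shore_shelf, (0.004, 0.10, 0.126, 0.77))
    _annotate("basal_hypo", ("Body", ""), (0.5, 0.5),
              shore_shelf, (0.03, 0.47, 0.03, 0.47))
    if with_drivers:
        for cls, gene in (
            ("brca1_informative", "BRCA1L"),
            ("brca1_noninformative", "BRCA1L"),
            ("hormad1_informative", "HORMAD1L"),
            ("hormad1_noninformative", "HORMAD1L"),
        ):
            ix = members[cls]
            region[ix] = "TSS200" if cls.endswith("informative") and "non" not in cls else "Body"
            island[ix] = "Island" if "non" not in cls else "OpenSea"
    annotation["region"] = region
    annotation["island_relation"] = island

    # --- gene annotation and cpg-to-gene mapping ----------------------------
    gene_rows = []
    if with_drivers:
        for spec in (_BRCA1_LIKE, _HORMAD1_LIKE):
            gene_rows.append(
                (spec["gene"], spec["chrom"], spec["start"], spec["end"], spec["strand"])
            )
    gene_annotation = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "strand"]
    )

    gene_col = np.array([""] * len(probes), dtype=object)
    coupled_classes = [c for c in ("luminal_meth", "et4_hypo", "luminal_hypo", "basal_meth")
                       if c in members]
    for cls in coupled_classes:
        for row in members[cls]:
            gene_col[row] = f"G_{probes[row]}"
    if with_drivers:
        for cls in ("brca1_informative", "brca1_noninformative"):
            gene_col[members[cls]] = "BRCA1L"
        for cls in ("hormad1_informative", "hormad1_noninformative"):
            gene_col[members[cls]] = "HORMAD1L"
    annotation["gene"] = gene_col

    # --- expression (tumors only) -------------------------------------------
    expr_rows = {}
    expr_truth: dict[str, int] = {}
    beta_tumor_true = pd.DataFrame(beta_true[:, :n_t], index=probes, columns=tumors)
    for cls in coupled_classes:
        slope = float(config.expr_coupling.get(cls, 0.0))
        for row in members[cls]:
            gene = gene_col[row]
            b = beta_tumor_true.iloc[row].to_numpy()
            if slope == 0.0:
                vals = 1.0 + rng.normal(0.0, config.expr_noise_sd, size=n_t)
            else:
                b0 = 8.0 if slope < 0 else 2.0
                vals = b0 + slope * b + rng.normal(0.0, config.expr_noise_sd, size=n_t)
            expr_rows[gene] = np.clip(vals, 0.0, None)
            expr_truth[gene] = int(np.sign(slope))
    if with_drivers and n_t:
        b_inf = beta_tumor_true.iloc[members["brca1_informative"]].mean(axis=0).to_numpy()
        expr_rows["BRCA1L"] = np.clip(
            8.0 - 6.0 * b_inf + rng.normal(0.0, 0.3, size=n_t), 0.0, None
        )
        expr_truth["BRCA1L"] = -1
        h_inf = beta_tumor_true.iloc[members["hormad1_informative"]].mean(axis=0).to_numpy()
        expr_rows["HORMAD1L"] = np.clip(
            2.0 + 5.0 * (1.0 - h_inf) + rng.normal(0.0, 0.3, size=n_t), 0.0, None
        )
        expr_truth["HORMAD1L"] = -1
    for i in range(config.n_background_genes):
        expr_rows[f"BG_{i + 1:04d}"] = np.clip(rng.normal(8.0, 1.0, size=n_t), 0.0, None)
        expr_truth[f"BG_{i + 1:04d}"] = 0
    expression = pd.DataFrame(expr_rows, index=tumors).T.sort_index()

    # --- copy number ---------------------------------------------------------
    cn_positions = _uniform_positions(rng, config.n_cn_probes)
    cn_positions = cn_positions.sort_values(["chrom", "pos"]).reset_index(drop=True)
    cn_positions.index = pd.Index([f"cn{i + 1:06d}" for i in range(len(cn_positions))])
    fga_by_et = np.linspace(0.05, 0.40, n_et)
    est = rng.normal(0.0, 0.05, size=(config.n_cn_probes, n_t))
    for e, et in enumerate(ets):
        for col in et_members[et]:
            n_alt = int(round(fga_by_et[e] * config.n_cn_probes))
            altered = 0
            while altered < n_alt:
                start = int(rng.integers(0, config.n_cn_probes))
                seg = int(min(max(20, rng.exponential(80)), n_alt - altered))
                end = min(start + seg, config.n_cn_probes)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                est[start:end, col] = sign * 0.6 + rng.normal(0.0, 0.1, size=end - start)
                altered += end - start
    # named amplicon regions; the ERBB2-like one is enriched in ET6
    region_rows = []
    n_regions = 5
    chroms = list(CHROM_LENGTHS)
    for r in range(n_regions):
        chrom = chroms[r % len(chroms)]
        start = int((r + 1) * CHROM_LENGTHS[chrom] / (n_regions + 2))
        region_rows.append((f"region_{r + 1}", chrom, start, start + 2_000_000))
    cn_regions = pd.DataFrame(region_rows, columns=["name", "chrom", "start", "end"])
    amp_prob = np.tile(np.linspace(0.02, 0.15, n_et), (n_regions, 1))
    if n_et >= 6:
        amp_prob[0, :] = 0.05
        amp_prob[0, 5] = 0.8  # ERBB2-like amplicon in the HER2-enriched epitype
    for r, row in enumerate(cn_regions.itertuples(index=False)):
        inside = (
            (cn_positions["chrom"] == row.chrom)
            & (cn_positions["pos"] >= row.start)
            & (cn_positions["pos"] < row.end)
        ).to_numpy()
        for e, et in enumerate(ets):
            for col in et_members[et]:
                if rng.random() < amp_prob[r, e]:
                    est[inside, col] = rng.uniform(1.2, 1.8) + rng.normal(
                        0.0, 0.05, size=inside.sum()
                    )
    cn_estimates = pd.DataFrame(est, index=cn_positions.index, columns=tumors)

    # --- mutations -----------------------------------------------------------
    driver_rates = {
        "PIK3CAL": (0.10, 0.35, 0.35, 0.30, 0.30, 0.20, 0.10),
        "TP53L": (0.10, 0.10, 0.15, 0.30, 0.40, 0.70, 0.80),
        "CDH1L": (0.05, 0.20, 0.20, 0.15, 0.15, 0.05, 0.02),
    }
    subs_rate = np.linspace(15, 70, n_et)
    maf_rows = []
    for e, et in enumerate(ets):
        for col in et_members[et]:
            tumor = tumors[col]
            if n_et == 7:
                for gene, rates in driver_rates.items():
                    if rng.random() < rates[e]:
                        maf_rows.append((gene, tumor, "Missense_Mutation", "SNP", "exp1"))
            for _ in range(rng.poisson(subs_rate[e])):
                gene = f"MG_{rng.integers(1, 400):04d}"
                cls = "Missense_Mutation" if rng.random() < 0.7 else "Silent"
                maf_rows.append((gene, tumor, cls, "SNP", "exp1"))
    maf = pd.DataFrame(
        maf_rows,
        columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
                 "Variant_Type", "experiment"],
    )
    # a handful of tumors carry a second sequencing experiment
    if n_t >= 10:
        dup_tumors = tumors[:: max(n_t // 5, 1)][:5]
        extra = maf[maf["Tumor_Sample_Barcode"].isin(dup_tumors)].copy()
        extra = extra.sample(frac=0.8, random_state=np.random.RandomState(rng.integers(2**31)))
        extra["experiment"] = "exp2"
        maf = pd.concat([maf, extra], ignore_index=True)

    # --- clinical ------------------------------------------------------------
    death_rate = np.linspace(0.02, 0.08, n_et)
    if n_et == 7:
        death_rate = np.array([0.03, 0.015, 0.025, 0.05, 0.07, 0.08, 0.06])
    age_offset = np.zeros(n_et)
    if n_et == 7:
        age_offset = np.array([0.0, 2.0, 4.0, 6.0, 16.0, 2.0, -4.0])
    clin_rows = []
    for e, et in enumerate(ets):
        for col in et_members[et]:
            tumor = tumors[col]
            t_death = rng.exponential(1.0 / death_rate[e])
            t_cens = rng.uniform(4.0, 15.0)
            time = min(t_death, t_cens)
            event = int(t_death <= t_cens)
            age = float(np.round(rng.normal(50.0 + age_offset[e], 8.0), 1))
            clin_rows.append((tumor, f"P{col + 1:03d}", age, round(time, 3), event))
    clinical = pd.DataFrame(
        clin_rows, columns=["sample_id", "patient_id", "age", "time", "event"]
    ).sort_values("sample_id").reset_index(drop=True)
    # a few patients contribute a second (recurrent) sample
    if n_t >= 6:
        for k in range(3):
            clinical.loc[clinical.index[-(k + 1)], "patient_id"] = f"P{k + 1:03d}"

    # --- planted truth -------------------------------------------------------
    def _cls_probes(*classes) -> list:
        out = []
        for cls in classes:
            out.extend(probes[members[cls]] if cls in members else [])
        return out

    planted_sets = {
        "cancer_methylated": _cls_probes(
            "basal_meth", "luminal_meth", "cancer_meth_graded"
        ),
        "cancer_unmethylated": _cls_probes(
            "et4_hypo", "luminal_hypo", "basal_hypo", "cancer_unmeth_graded",
            "hormad1_informative",
        ),
        "basal_methylated": _cls_probes("basal_meth"),
        "luminal_methylated": _cls_probes("luminal_meth"),
        "global_hypo": _cls_probes("et4_hypo"),
        "luminal_hypo": _cls_probes("luminal_hypo"),
        "basal_hypo": _cls_probes("basal_hypo"),
    }
    truth = SyntheticTruth(
        epitype_labels=epitype_labels,
        site_class=site_class,
        planted_sets=planted_sets,
        expr_truth=expr_truth,
        roles=dict(DEFAULT_ROLES) if n_et == 7 else {},
        brca1_silenced=brca1_silenced,
        hormad1_demethylated=hormad1_demethylated,
    )
    return Cohort(
        signals=signals,
        beta=beta,
        annotation=annotation,
        gene_annotation=gene_annotation,
        expression=expression,
        cn_estimates=cn_estimates,
        cn_positions=cn_positions,
        cn_regions=cn_regions,
        maf=maf,
        clinical=clinical,
        truth=truth,
        tracks=tracks,
        config=config,
    )


# --- fixture I/O -------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index_label is not None,
              index_label=index_label, float_format=_FLOAT_FMT)


def write_fixture(cohort: Cohort, directory) -> dict:
    """Write every cohort table as TSV/BED/JSON and return a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_tsv(cohort.signals, directory / "signals.tsv")
    _write_tsv(cohort.beta.values, directory / "beta.tsv", index_label="probe_id")
    _write_tsv(cohort.annotation, directory / "probe_annotation.tsv", index_label="probe_id")
    _write_tsv(cohort.gene_annotation, directory / "gene_annotation.tsv")
    _write_tsv(cohort.expression, directory / "expression.tsv", index_label="gene")
    _write_tsv(cohort.cn_estimates, directory / "copy_number.tsv", index_label="probe_id")
    _write_tsv(cohort.cn_positions, directory / "cn_probe_annotation.tsv", index_label="probe_id")
    _write_tsv(cohort.cn_regions, directory / "cn_regions.tsv")
    _write_tsv(cohort.maf, directory / "mutations.maf.tsv")
    _write_tsv(cohort.clinical, directory / "clinical.tsv")
    for ct, df in cohort.tracks.chromatin_states.items():
        df.to_csv(directory / f"states_{ct}.bed", sep="\t", header=False, index=False)
    for name, df in cohort.tracks.peaks.items():
        df.to_csv(directory / f"peaks_{name}.bed", sep="\t", header=False, index=False)
    cohort.tracks.repeats.to_csv(directory / "repeats.bed", sep="\t", header=False, index=False)
    pd.Series(cohort.tracks.chrom_lengths).rename("length").to_csv(
        directory / "chrom_lengths.tsv", sep="\t", header=False
    )
    (directory / "truth.json").write_text(
        json.dumps(cohort.truth.to_json_dict(), indent=1, sort_keys=True)
    )
    (directory / "config.json").write_text(
        json.dumps(asdict(cohort.config), indent=1, sort_keys=True, default=list)
    )

    manifest = {}
    for path in sorted(directory.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_beta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def read_fixture(directory) -> dict:
    """Read a written fixture back into DataFrames (keyed like the files)."""
    directory = Path(directory)
    out = {
        "signals": pd.read_csv(directory / "signals.tsv", sep="\t"),
        "beta": read_beta_tsv(directory / "beta.tsv"),
        "annotation": pd.read_csv(directory / "probe_annotation.tsv", sep="\t", index_col=0,
                                  keep_default_na=False, na_values=[]),
        "gene_annotation": pd.read_csv(directory / "gene_annotation.tsv", sep="\t"),
        "expression": pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0),
        "cn_estimates": pd.read_csv(directory / "copy_number.tsv", sep="\t", index_col=0),
        "cn_positions": pd.read_csv(directory / "cn_probe_annotation.tsv", sep="\t", index_col=0),
        "cn_regions": pd.read_csv(directory / "cn_regions.tsv", sep="\t"),
        "maf": pd.read_csv(directory / "mutations.maf.tsv", sep="\t"),
        "clinical": pd.read_csv(directory / "clinical.tsv", sep="\t"),
        "truth": json.loads((directory / "truth.json").read_text()),
    }
    return out
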