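"""Shared fixtures: synthetic cohorts at the study's default and low-noise
conditions, processed once per session through the analysis chain."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from epityper.synthetic import GeneratorConfig, generate_cohort
from epityper.preprocess import peak_normalize
from epityper.site_selection import call_normal_status, select_tumor_specific
from epityper.epityping import (
    bootstrap_consensus,
    choose_k,
    build_centroids,
    relabel,
)


def _process(cohort, n_boot=200, consensus_seed=29, cluster=True):
    norm = peak_normalize(cohort.beta)
    tumors = list(cohort.tumor_samples)
    normals = list(cohort.normal_samples)
    tumor_beta = norm.values[tumors]
    normal_beta = norm.values[normals]
    status = call_normal_status(normal_beta)
    sets = select_tumor_specific(tumor_beta, status)
    bundle = SimpleNamespace(
        cohort=cohort,
        norm=norm,
        tumor_beta=tumor_beta,
        normal_beta=normal_beta,
        status=status,
        sets=sets,
        truth=cohort.truth,
    )
    if cluster:
        bundle.consensus = bootstrap_consensus(
            tumor_beta.loc[sets.all_selected],
            range(3, 11),
            n_boot=n_boot,
            seed=consensus_seed,
        )
        bundle.choice = choose_k(bundle.consensus)
        raw = bundle.consensus.labels_by_k[bundle.choice.k]
        bundle.model = build_centroids(
            tumor_beta.loc[sets.all_selected],
            raw,
            reference_profile=normal_beta.loc[sets.all_selected].mean(axis=1),
        )
        bundle.labels = relabel(raw, bundle.model)
        # majority-vote map from discovered epitype names to planted labels
        bundle.to_planted = pd.crosstab(
            bundle.labels, cohort.truth.epitype_labels
        ).idxmax(axis=1)
    return bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 120 tumors, 5000 probes, noise_sd 0.05."""
    return _process(generate_cohort(GeneratorConfig(seed=11)))


@pytest.fixture(scope="session")
def lownoise_bundle():
    """Low-noise fixture for exact selection-rule recovery."""
    cohort = generate_cohort(GeneratorConfig(seed=7, noise_sd=0.01, missing_rate=0.0))
    return _process(cohort, cluster=False)


@pytest.fixture(scope="session")
def heldout_bundle(default_bundle):
    """A second cohort from the same conditions, for held-out classification."""
    cohort = generate_cohort(GeneratorConfig(seed=211))
    norm = peak_normalize(cohort.beta)
    return SimpleNamespace(
        cohort=cohort,
        norm=norm,
        tumor_beta=norm.values[list(cohort.tumor_samples)],
        truth=cohort.truth,
    )


# ---------------------------------------------------------------------------
# independent oracles used by several test modules


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    from math import comb

    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(top-left cell = x) under the hypergeometric null
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def bh_stepup_oracle(p_values):
    """Benjamini-Hochberg adjusted p values by the literal step-up recipe."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj
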