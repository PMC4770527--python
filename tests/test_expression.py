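"""Expression transforms, methylation-expression screens, module scores, and
promoter methylation calling."""

import numpy as np
import pandas as pd
import pytest

from epityper.expression import (
    transform_expression,
    collapse_probes,
    correlate_meth_expr,
    module_score,
    call_promoter_status,
    promoter_window_probes,
    brca1_preset,
    hormad1_preset,
    PromoterCallConfig,
)


class TestTransform:
    def test_log2_pseudocount_then_centering(self):
        raw = pd.DataFrame({"s1": [0.0], "s2": [1.0], "s3": [3.0]}, index=["g"])
        out = transform_expression(raw, mode="relative")
        # log2(x+1) = (0, 1, 2), centered at 1
        np.testing.assert_allclose(out.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_gene_centers_to_zero(self):
        raw = pd.DataFrame(np.full((1, 4), 7.0), index=["g"], columns=list("abcd"))
        out = transform_expression(raw, mode="relative")
        np.testing.assert_allclose(out.loc["g"], 0.0, atol=1e-12)

    def test_absolute_mode_is_log2_tpm_plus_one(self):
        raw = pd.DataFrame({"s1": [10.0, 30.0], "s2": [5.0, 15.0]}, index=["g1", "g2"])
        out = transform_expression(raw, mode="absolute")
        tpm = 2.0 ** out - 1.0
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6)
        np.testing.assert_allclose(tpm.loc["g1", "s1"], 0.25 * 1e6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            transform_expression(pd.DataFrame({"s": [-1.0]}, index=["g"]))

    def test_highest_variance_probe_kept_per_gene(self):
        raw = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [1.2, 3.0], "s3": [0.9, 5.0]},
            index=["probeA", "probeB"],
        )
        mapping = pd.Series({"probeA": "G", "probeB": "G"})
        out = collapse_probes(raw, mapping)
        assert list(out.index) == ["G"]
        np.testing.assert_allclose(out.loc["G"], raw.loc["probeB"])


class TestCorrelation:
    def _inputs(self):
        samples = [f"s{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(
            {
                "cg_neg": np.linspace(0.1, 0.9, 20),
                "cg_pos": np.linspace(0.9, 0.1, 20),
                "cg_flat": np.full(20, 0.5),
                "cg_lost": rng.random(20),
            },
            index=samples,
        ).T
        expr = pd.DataFrame(
            {
                "G1": 5.0 - 4.0 * np.linspace(0.1, 0.9, 20),
                "G2": 1.0 + 4.0 * np.linspace(0.1, 0.9, 20),
                "G3": rng.normal(3, 1, 20),
            },
            index=samples,
        ).T
        mapping = pd.Series(
            {"cg_neg": "G1", "cg_pos": "G2", "cg_flat": "G3", "cg_lost": "ABSENT"}
        )
        return beta, expr, mapping

    def test_classes_and_exclusions(self):
        beta, expr, mapping = self._inputs()
        out = correlate_meth_expr(beta, expr, mapping)
        assert out.loc["cg_neg", "class"] == "negative"
        assert out.loc["cg_neg", "r"] == pytest.approx(-1.0)
        assert out.loc["cg_pos", "class"] == "negative"  # G2 rises as beta falls
        assert out.loc["cg_flat", "class"] == "unmapped"  # constant methylation
        assert out.loc["cg_flat", "reason"] == "zero variance"
        assert out.loc["cg_lost", "class"] == "unmapped"

    def test_classes_partition_mapped_variable_cpgs(self, lownoise_bundle):
        b = lownoise_bundle
        cohort = b.cohort
        mapping = cohort.annotation["gene"].replace("", np.nan)
        probes = mapping.dropna().index[:500]
        out = correlate_meth_expr(
            b.tumor_beta.loc[probes], cohort.expression, mapping
        )
        mapped = out[out["class"] != "unmapped"]
        counts = mapped["class"].value_counts()
        assert counts.sum() == len(mapped)
        assert set(counts.index) <= {"positive", "negative", "low"}

    def test_planted_couplings_recovered(self, lownoise_bundle):
        b = lownoise_bundle
        cohort = b.cohort
        site_class = b.truth.site_class
        mapping = cohort.annotation["gene"].replace("", np.nan)
        neg_probes = site_class.index[site_class == "luminal_meth"]
        pos_probes = site_class.index[site_class == "et4_hypo"]
        out = correlate_meth_expr(
            b.tumor_beta.loc[neg_probes.union(pos_probes)], cohort.expression, mapping
        )
        assert (out.loc[neg_probes, "class"] == "negative").all()
        assert (out.loc[pos_probes, "class"] == "positive").all()

    def test_too_few_shared_samples_rejected(self):
        beta, expr, mapping = self._inputs()
        with pytest.raises(ValueError, match="shared"):
            correlate_meth_expr(beta[["s0", "s1"]], expr, mapping)


class TestModuleScore:
    EXPR = pd.DataFrame(
        {"s1": [1.0, 3.0, 10.0], "s2": [2.0, 4.0, 20.0]},
        index=["g1", "g2", "g3"],
    )

    def test_single_gene_module_equals_that_row(self):
        score, n = module_score(self.EXPR, ["g3"])
        assert n == 1
        np.testing.assert_allclose(score, self.EXPR.loc["g3"])

    def test_mean_over_module_genes(self):
        score, n = module_score(self.EXPR, ["g1", "g2"])
        assert n == 2
        assert score["s1"] == pytest.approx(2.0)

    def test_absent_genes_ignored(self):
        score, n = module_score(self.EXPR, ["g1", "g2", "nope", "alsonope"])
        assert n == 2
        assert score["s1"] == pytest.approx(2.0)

    def test_no_genes_matched_rejected(self):
        with pytest.raises(ValueError, match="module"):
            module_score(self.EXPR, ["nope"])

    def test_disjoint_union_is_size_weighted_mean(self):
        a, na = module_score(self.EXPR, ["g1"])
        b, nb = module_score(self.EXPR, ["g2", "g3"])
        union, nu = module_score(self.EXPR, ["g1", "g2", "g3"])
        np.testing.assert_allclose(union, (na * a + nb * b) / nu)


class TestPromoterCaller:
    def _toy(self):
        samples = [f"s{i}" for i in range(12)]
        meth = np.array([0.7, 0.6, 0.05, 0.02, 0.03, 0.04, 0.05, 0.02, 0.6, 0.01, 0.02, 0.03])
        beta = pd.DataFrame(
            {
                "cgA": meth,  # informative: tracks silencing
                "cgB": meth * 0.9 + 0.02,  # informative
                "cgC": np.full(12, 0.5) + np.linspace(0, 0.01, 12),  # uninformative
            },
            index=samples,
        ).T
        expr = pd.DataFrame({"GENE": 8.0 - 7.0 * meth}, index=samples).T
        probe_ann = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [1000, 1400, 2500],
                "gene": ["GENE"] * 3,
            },
            index=["cgA", "cgB", "cgC"],
        )
        gene_ann = pd.DataFrame(
            [["GENE", "chr1", 1200, 3000, "+"]],
            columns=["gene", "chrom", "start", "end", "strand"],
        )
        return beta, expr, probe_ann, gene_ann

    def test_window_is_strand_aware_half_open(self):
        _, _, probe_ann, gene_ann = self._toy()
        window = promoter_window_probes(probe_ann, gene_ann, "GENE", upstream=1000)
        assert set(window) == {"cgA", "cgB", "cgC"}  # cgA is 200 bp upstream
        minus = gene_ann.copy()
        minus.loc[0, "strand"] = "-"
        window = promoter_window_probes(probe_ann, minus, "GENE", upstream=1000)
        assert set(window) == {"cgB", "cgC"}  # upstream now beyond end

    def test_informative_screen_and_calls(self):
        beta, expr, probe_ann, gene_ann = self._toy()
        result = call_promoter_status(
            beta, expr, probe_ann, gene_ann, brca1_preset("GENE")
        )
        assert set(result.informative_probes) == {"cgA", "cgB"}
        assert result.median_r < -0.9
        called = set(result.status.index[result.status == "methylated"])
        assert called == {"s0", "s1", "s8"}

    def test_boundary_mean_is_not_called(self):
        samples = [f"s{i}" for i in range(8)]
        track = np.array([0.6, 0.5, 0.05, 0.02, 0.3, 0.02, 0.05, 0.01])
        beta = pd.DataFrame({"cgA": track, "cgB": 0.4 - track / 3}, index=samples).T
        # sample s4: mean of (0.3, 0.3) = 0.3 > 0.2 called; craft exact 0.2
        beta.loc["cgB"] = track  # identical informative probes
        beta.loc[:, "s4"] = 0.2  # informative mean exactly 0.2
        expr = pd.DataFrame({"G": 5.0 - 4.0 * beta.loc["cgA"]}, index=samples).T
        probe_ann = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [100, 200], "gene": ["G", "G"]},
            index=["cgA", "cgB"],
        )
        gene_ann = pd.DataFrame(
            [["G", "chr1", 0, 1000, "+"]], columns=["gene", "chrom", "start", "end", "strand"]
        )
        result = call_promoter_status(beta, expr, probe_ann, gene_ann, brca1_preset("G"))
        assert result.mean_beta["s4"] == pytest.approx(0.2)
        assert result.status["s4"] == "unmethylated"  # strict ">"

    def test_no_informative_cpgs_is_uncallable(self):
        beta, expr, probe_ann, gene_ann = self._toy()
        flat = beta.copy()
        for probe in flat.index:
            flat.loc[probe] = 0.5  # constant: correlation undefined, never informative
        result = call_promoter_status(flat, expr, probe_ann, gene_ann, brca1_preset("GENE"))
        assert (result.status == "uncallable").all()
        assert not result.called.any()

    def test_planted_silenced_tumors_recovered_exactly(self, lownoise_bundle):
        b = lownoise_bundle
        cohort = b.cohort
        result = call_promoter_status(
            b.norm.values,  # tumors and normals; screen defaults to tumors
            cohort.expression,
            cohort.annotation,
            cohort.gene_annotation,
            brca1_preset("BRCA1L"),
        )
        tumors = cohort.tumor_samples
        called = set(tumors[result.called[tumors]])
        assert called == set(b.truth.brca1_silenced)  # sensitivity and specificity 1
        normals = cohort.normal_samples
        assert not result.called[normals].any()  # no methylated normal

    def test_planted_demethylated_tumors_recovered(self, lownoise_bundle):
        b = lownoise_bundle
        cohort = b.cohort
        result = call_promoter_status(
            b.norm.values, cohort.expression, cohort.annotation,
            cohort.gene_annotation, hormad1_preset("HORMAD1L"),
        )
        tumors = cohort.tumor_samples
        called = set(tumors[result.called[tumors]])
        assert called == set(b.truth.hormad1_demethylated)
        assert not result.called[cohort.normal_samples].any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PromoterCallConfig(gene="G", direction="sideways", threshold=0.2)
        with pytest.raises(ValueError):
            PromoterCallConfig(gene="G", direction="methylated", threshold=1.2)
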