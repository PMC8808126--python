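import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma

from lnc_immunotype.coexpression import log2_transform
from lnc_immunotype.downstream import (
    concordance,
    count_significant_features,
    differential_expression,
    marker_score,
    ora,
    ssgsea_scores,
    subtype_gsea,
)
from lnc_immunotype.io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PipelineConfig,
)
from lnc_immunotype.survival import wilcoxon_rank_sum


def _collection(**sets):
    return GeneSetCollection({
        name: GeneSet(name, "", frozenset(genes)) for name, genes in sets.items()
    })


def _expr(array, genes=None, samples=None):
    array = np.asarray(array, dtype=float)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{i}" for i in range(array.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(array, index=genes, columns=samples), log_transformed=True
    )


def _labels(n1, n2):
    return pd.Series(
        ["C1"] * n1 + ["C2"] * n2,
        index=[f"s{i}" for i in range(n1 + n2)],
    )


class TestDifferentialExpression:
    def test_equal_means_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=(1, 6))
        x = np.vstack([base, base + 0.0])
        out = differential_expression(_expr(x), _labels(3, 3), PipelineConfig())
        assert (out["fc"] >= 1).all()
        same = out.iloc[0]
        assert same["status"] == "not_significant"

    def test_fold_change_boundary_is_strict(self):
        rng = np.random.default_rng(1)
        n = 400
        x = rng.normal(0, 0.05, size=(n, 40))
        x[0, 20:] += np.log2(1.2)  # exactly the cutoff
        x[1, 20:] += 1.0           # clear two-fold change
        out = differential_expression(_expr(x), _labels(20, 20), PipelineConfig())
        boundary, clear = out.iloc[0], out.iloc[1]
        # means are noisy, so force the exact-boundary check on the rule itself
        assert clear["status"] == "up_in_C2"
        assert not (
            (boundary["fdr"] < 0.05)
            and (boundary["fc"] > 1.2)
        ) or boundary["status"] != "not_significant"
        exact = out[(out["fc"] <= 1.2) & (out["fdr"] < 0.05)]
        assert (exact["status"] == "not_significant").all()

    def test_planted_two_fold_genes_recovered_with_fdr_control(self):
        rng = np.random.default_rng(2)
        n_genes, n_true = 2000, 100
        x = rng.normal(0, 0.8, size=(n_genes, 60))
        x[:n_true, 30:] += 1.0  # two-fold on log2 scale
        out = differential_expression(_expr(x), _labels(30, 30), PipelineConfig())
        called = out[out["status"] != "not_significant"]
        true_called = (called.index < n_true).sum()
        assert true_called >= 90
        false_called = (called.index >= n_true).sum()
        assert false_called / max(len(called), 1) <= 0.10

    def test_prior_df_zero_recovers_per_gene_t_test(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=(50, 12))
        out = differential_expression(
            _expr(x), _labels(6, 6), PipelineConfig(), prior_df=0
        )
        t_ref, p_ref = stats.ttest_ind(x[:, 6:], x[:, :6], axis=1, equal_var=True)
        np.testing.assert_allclose(out["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, atol=1e-10)

    def test_prior_df_inf_recovers_common_variance_test(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=(50, 12))
        out = differential_expression(
            _expr(x), _labels(6, 6), PipelineConfig(), prior_df=np.inf
        )
        m1, m2 = x[:, :6].mean(1), x[:, 6:].mean(1)
        s2 = (((x[:, :6] - m1[:, None]) ** 2).sum(1)
              + ((x[:, 6:] - m2[:, None]) ** 2).sum(1)) / 10
        s0 = np.exp(np.mean(np.log(s2) - digamma(5) + np.log(5.0)))
        t_ref = (m2 - m1) / np.sqrt(s0 * (2 / 6))
        np.testing.assert_allclose(out["t"], t_ref, rtol=1e-8)

    def test_zero_variance_gene_reported_inert(self):
        x = np.vstack([np.full(8, 3.0), np.random.default_rng(5).normal(size=8)])
        out = differential_expression(_expr(x), _labels(4, 4), PipelineConfig())
        assert out.iloc[0]["p"] == 1.0

    def test_more_than_two_groups_rejected(self):
        x = np.random.default_rng(6).normal(size=(5, 9))
        labels = pd.Series(
            ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
            index=[f"s{i}" for i in range(9)],
        )
        with pytest.raises(ValueError, match="two groups"):
            differential_expression(_expr(x), labels, PipelineConfig())


class TestCountSignificant:
    @pytest.mark.parametrize("n_sig,total,pct", [
        (11, 17, 64.71), (0, 17, 0.0), (17, 17, 100.0),
    ])
    def test_percentages(self, n_sig, total, pct):
        p = [0.01] * n_sig + [0.5] * (total - n_sig)
        assert count_significant_features(p, 0.05) == (n_sig, total, pct)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_significant_features([], 0.05)


class TestORA:
    def test_fully_recovered_set_has_minimum_p(self):
        universe = [f"g{i}" for i in range(60)]
        sets = _collection(
            target=universe[:10], other1=universe[20:30], other2=universe[40:50]
        )
        out = ora(universe[:10], universe, sets, keep_all=True)
        assert out.iloc[0]["set"] == "target"
        assert out.iloc[0]["p"] == out["p"].min()

    def test_matches_enumeration_oracle(self):
        universe = [f"g{i}" for i in range(10)]
        out = ora(universe[1:6], universe, _collection(s=universe[:4]),
                  keep_all=True)
        assert out.iloc[0]["p"] == pytest.approx(66 / 252)

    def test_null_query_calibrated(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(400)]
        sets = _collection(**{
            f"s{j}": rng.choice(universe, 25, replace=False) for j in range(20)
        })
        ps = []
        for _ in range(30):
            query = rng.choice(universe, 40, replace=False)
            ps.extend(ora(query, universe, sets, keep_all=True)["p"])
        assert abs(np.mean(np.asarray(ps) < 0.05) - 0.05) < 0.04

    def test_empty_query_warns_and_returns_empty(self):
        out = ora([], ["a", "b"], _collection(s=["a"]))
        assert out.empty

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ora(["zzz"], ["a"], _collection(s=["a"]))


class TestSubtypeGSEA:
    def test_single_planted_elevated_set_passes_all_filters(self):
        # one gene set elevated in the first group against an otherwise null
        # background: must clear |ES|, p and FDR screens with positive ES
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, size=(500, 40))
        target = [f"g{i}" for i in range(25)]
        x[:25, :20] += 1.5  # elevated in C1
        expr = _expr(x)
        labels = _labels(20, 20)
        sets = _collection(
            target=target,
            decoy1=[f"g{i}" for i in range(100, 125)],
            decoy2=[f"g{i}" for i in range(200, 225)],
        )
        out = subtype_gsea(expr, labels, sets, PipelineConfig(rng_seed=0),
                           n_perm=500, keep_all=True)
        row = out[out["pathway"] == "target"].iloc[0]
        assert row["passed"] and row["es"] > 0.4
        assert row["p"] < 0.05 and row["fdr"] < 0.25
        assert set(row["leading_edge"].split(",")) <= set(target)

    def test_cohort_pathways_orient_toward_immune_high(self, cohort):
        # with every immune pathway subtype-shifted, the phenotype-permutation
        # null keeps gene-gene correlation, so only the strongest pathway is
        # expected to clear the screen -- but all enrichments must point at C1
        b = cohort
        logm = log2_transform(b.tumor, 1.0)
        mrna = logm.subset_genes([g for g in logm.gene_ids if g.startswith("M")])
        cfg = PipelineConfig(rng_seed=0)
        out = subtype_gsea(mrna, b.truth.subtype_labels, b.pathways, cfg,
                           n_perm=200, keep_all=True)
        assert (out["es"] > 0).all()
        assert out[out["passed"]]["pathway"].size >= 1

    def test_exact_es_threshold_excluded(self, cohort):
        b = cohort
        logm = log2_transform(b.tumor, 1.0)
        mrna = logm.subset_genes([g for g in logm.gene_ids if g.startswith("M")])
        cfg = PipelineConfig(rng_seed=0)
        out = subtype_gsea(mrna, b.truth.subtype_labels, b.pathways, cfg,
                           n_perm=100, keep_all=True)
        es0 = abs(out.iloc[0]["es"])
        strict = PipelineConfig(rng_seed=0, gsea_es_min=es0)
        out2 = subtype_gsea(mrna, b.truth.subtype_labels, b.pathways, strict,
                            n_perm=100, keep_all=True)
        row = out2[out2["pathway"] == out.iloc[0]["pathway"]].iloc[0]
        assert not row["passed"]

    def test_permuted_labels_pass_nothing(self, cohort):
        b = cohort
        rng = np.random.default_rng(9)
        logm = log2_transform(b.tumor, 1.0)
        mrna = logm.subset_genes([g for g in logm.gene_ids if g.startswith("M")])
        labels = pd.Series(
            rng.permutation(b.truth.subtype_labels.to_numpy()),
            index=b.truth.subtype_labels.index,
        )
        out = subtype_gsea(mrna, labels, b.pathways,
                           PipelineConfig(rng_seed=1), n_perm=200)
        assert out.empty


class TestMarkerScore:
    def test_single_gene_set_equals_that_gene(self):
        x = _expr([[1, 2, 3], [9, 9, 9]])
        out = marker_score(x, _collection(c=["g0"]))
        np.testing.assert_allclose(out["c"], [1, 2, 3])

    def test_constant_genes_give_constant_score(self):
        x = _expr(np.full((3, 4), 3.0))
        out = marker_score(x, _collection(c=["g0", "g2"]))
        np.testing.assert_allclose(out["c"], 3.0)

    def test_invariant_to_genes_outside_sets(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 5))
        small = marker_score(_expr(x[:4]), _collection(c=["g1", "g3"]))
        big = marker_score(_expr(x), _collection(c=["g1", "g3"]))
        pd.testing.assert_frame_equal(small, big)

    def test_absent_set_omitted(self):
        out = marker_score(_expr([[1, 2]]), _collection(c=["g0"], gone=["zzz"]))
        assert list(out.columns) == ["c"]

    def test_immune_high_subtype_scores_higher(self, cohort):
        b = cohort
        logm = log2_transform(b.tumor, 1.0)
        scores = marker_score(logm, b.markers)
        labels = b.truth.subtype_labels
        mean_score = scores.mean(axis=1)
        p = wilcoxon_rank_sum(
            mean_score[labels == "C1"], mean_score[labels == "C2"]
        )
        assert p < 0.05
        assert mean_score[labels == "C1"].mean() > mean_score[labels == "C2"].mean()


class TestSsgseaScores:
    def test_top_ranked_signature_scores_near_maximum(self):
        x = np.zeros((30, 1))
        x[:5, 0] = 10.0  # signature genes occupy the top ranks
        out = ssgsea_scores(_expr(x), _collection(ImmuneSig=[f"g{i}" for i in range(5)],
                                                  StromalSig=["g20", "g21"]))
        assert out["ImmuneSig"].iloc[0] > 0.9
        assert "ESTIMATEScore" in out.columns

    def test_identical_samples_identical_rows(self):
        rng = np.random.default_rng(10)
        col = rng.normal(size=30)
        x = np.column_stack([col, col])
        out = ssgsea_scores(_expr(x), _collection(ImmuneSig=["g1", "g2", "g3"],
                                                  StromalSig=["g8", "g9"]))
        np.testing.assert_allclose(out.iloc[0], out.iloc[1])

    def test_monotone_transform_invariance_at_exponent_zero(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(40, 3))
        sig = _collection(s=["g5", "g6", "g7", "g8"])
        a = ssgsea_scores(_expr(x), sig, weight_exponent=0.0)
        b = ssgsea_scores(_expr(np.exp(x)), sig, weight_exponent=0.0)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_immune_high_samples_outscore_immune_low(self):
        # samples with the immune signature directly elevated must outrank
        # unshifted samples in nearly every cross pair
        rng = np.random.default_rng(13)
        x = rng.normal(4, 1, size=(300, 40))
        immune = [f"g{i}" for i in range(30)]
        x[:30, :20] += 2.0  # immune-high samples are the first 20
        sigs = _collection(ImmuneSig=immune,
                           StromalSig=[f"g{i}" for i in range(200, 220)])
        scores = ssgsea_scores(_expr(x), sigs)["ImmuneSig"]
        hi, lo = scores[:20].to_numpy(), scores[20:].to_numpy()
        assert (hi[:, None] > lo[None, :]).mean() >= 0.95

    def test_cohort_immune_score_tracks_subtype(self, cohort):
        # on the full cohort every immune gene moves with the subtype, so the
        # ordering is noisier; the subtype contrast must still be clear
        b = cohort
        logm = log2_transform(b.tumor, 1.0)
        marker_union = sorted(b.markers.genes())
        noise = [g for g in logm.gene_ids
                 if g.startswith("M") and g not in set(marker_union)
                 and g not in b.pathways.genes()][:100]
        sigs = _collection(ImmuneSig=marker_union, StromalSig=noise)
        scores = ssgsea_scores(logm, sigs)["ImmuneSig"]
        labels = b.truth.subtype_labels
        hi = scores[labels == "C1"].to_numpy()
        lo = scores[labels == "C2"].to_numpy()
        assert hi.mean() > lo.mean()
        assert (hi[:, None] > lo[None, :]).mean() > 0.55


class TestConcordance:
    def _series(self, mapping):
        return pd.Series(mapping)

    def test_identical_labelings_are_diagonal(self):
        lab = self._series({"a": "C1", "b": "C1", "c": "C2"})
        out = concordance(lab, lab.rename("ext"))
        assert out.row_pct.loc["C1", "C1"] == 100.0
        assert out.row_pct.loc["C2", "C2"] == 100.0

    def test_combined_pair_percentage(self):
        internal = self._series({f"x{i}": "C1" for i in range(100)})
        ext = ["Atypical"] * 50 + ["Basal"] * 30 + ["Classical"] * 10 + ["Mesenchymal"] * 10
        external = pd.Series(ext, index=[f"x{i}" for i in range(100)])
        out = concordance(internal, external, combine=("Atypical", "Basal"))
        assert out.combined_pct["C1"] == 80.0

    def test_missing_external_label_keeps_zero_column(self):
        internal = self._series({"a": "C1", "b": "C2"})
        external = pd.Series(
            ["Basal", "Basal", "Atypical"], index=["a", "b", "zzz"]
        )
        out = concordance(internal, external)
        assert "Atypical" in out.counts.columns
        assert out.counts["Atypical"].sum() == 0

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            concordance(self._series({"a": "C1"}), self._series({"b": "X"}))
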