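import numpy as np
import pandas as pd
import pytest

from lnc_immunotype.immune_lncrna import (
    cell_enrichment,
    compute_lncres,
    overlap_stats,
    select_dysregulated,
    significant_pairs,
    tumor_specific_lncrnas,
)
from lnc_immunotype.io_formats import GeneSet, GeneSetCollection, PipelineConfig
from lnc_immunotype.synthetic import pairs_from_counts


def _collection(**sets):
    return GeneSetCollection({
        name: GeneSet(name, "", frozenset(genes)) for name, genes in sets.items()
    })


def _cor_table(lnc_id, scores, strong=()):
    """Correlation table for one lncRNA: mrna -> score, strong ids pass the
    significance filter."""
    rows = []
    for mrna, score in scores.items():
        strong_hit = mrna in strong
        rows.append({
            "lnc_id": lnc_id, "mrna_id": mrna,
            "R": 0.9 if strong_hit else 0.1,
            "P": 1e-6 if strong_hit else 0.5,
            "score": score,
        })
    return pd.DataFrame(rows)


class TestComputeLncres:
    def test_segregated_pathway_reaches_extreme_lncres(self):
        # pathway members own the 12 largest scores -> |lncRES| ~ 1
        members = [f"m{i}" for i in range(12)]
        others = [f"x{i}" for i in range(48)]
        scores = {m: 20.0 + i for i, m in enumerate(members)}
        scores.update({x: np.sin(i) for i, x in enumerate(others)})
        table = compute_lncres(
            _cor_table("l1", scores, strong=members),
            _collection(PW=members),
            PipelineConfig(rng_seed=0, n_permutations=200),
            cohort="tumor",
        )
        assert len(table) == 1
        rec = table.iloc[0]
        assert abs(rec["lncres"]) > 0.99
        assert rec["p"] == pytest.approx(1 / 201)

    def test_pathway_without_overlap_yields_no_record(self):
        scores = {f"m{i}": float(i) for i in range(20)}
        strong = list(scores)[:12]
        table = compute_lncres(
            _cor_table("l1", scores, strong=strong),
            _collection(PW=["absent1", "absent2"]),
            PipelineConfig(rng_seed=0, n_permutations=100),
        )
        assert table.empty

    def test_lncrnas_below_partner_gate_skipped(self):
        scores = {f"m{i}": float(i) for i in range(20)}
        table = compute_lncres(
            _cor_table("l1", scores, strong=list(scores)[:3]),  # only 3 partners
            _collection(PW=list(scores)[:5]),
            PipelineConfig(rng_seed=0, n_permutations=100),
        )
        assert table.empty

    def test_shuffled_scores_rarely_reach_fdr(self):
        # a null configuration: scores carry no set structure
        rng = np.random.default_rng(42)
        frames, pathways = [], {}
        mrnas = [f"m{i}" for i in range(150)]
        for i in range(10):
            pathways[f"PW{i}"] = rng.choice(mrnas, size=15, replace=False)
        for j in range(12):
            scores = dict(zip(mrnas, rng.normal(size=len(mrnas))))
            frames.append(_cor_table(f"l{j}", scores, strong=mrnas[:12]))
        cfg = PipelineConfig(rng_seed=7, n_permutations=1000)
        table = compute_lncres(pd.concat(frames), _collection(**pathways), cfg)
        assert (table["fdr"] < 0.05).mean() <= 0.05

    def test_same_seed_reproduces_table(self):
        scores = {f"m{i}": float(np.cos(i)) for i in range(40)}
        cor = _cor_table("l1", scores, strong=list(scores)[:15])
        coll = _collection(PW=list(scores)[5:20])
        cfg = PipelineConfig(rng_seed=3, n_permutations=200)
        a = compute_lncres(cor, coll, cfg)
        b = compute_lncres(cor, coll, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestSignificantPairs:
    def _table(self, lncres, fdr):
        return pd.DataFrame({
            "lnc_id": ["l"], "pathway": ["p"], "lncres": [lncres],
            "n_hits": [5], "p": [fdr], "fdr": [fdr], "cohort": ["tumor"],
        })

    @pytest.mark.parametrize("lncres,fdr,kept", [
        (0.996, 0.01, True),
        (0.995, 0.001, False),   # |lncRES| exactly at threshold
        (-0.999, 0.04, True),    # absolute value
        (0.999, 0.05, False),    # FDR exactly at threshold
    ])
    def test_strict_thresholds(self, lncres, fdr, kept):
        cfg = PipelineConfig()
        out = significant_pairs(self._table(lncres, fdr), cfg)
        assert (len(out) == 1) is kept


class TestOverlapStats:
    def test_reproduces_published_overlap_percentages(self):
        tumor, normal = pairs_from_counts(5564, 12626, 1637, 2078, 4746, 1046)
        stats = overlap_stats(tumor, normal)
        assert stats["shared_pair_pct_of_normal"] == 12.97
        assert stats["shared_pair_pct_of_tumor"] == 29.42
        assert stats["shared_lnc_pct_of_normal"] == 22.04
        assert stats["shared_lnc_pct_of_tumor"] == 50.34
        assert stats["tumor_specific_lncrnas"] == 1032
        assert stats["tumor_specific_lnc_pct"] == 49.66

    def test_disjoint_sets_give_zero_percentages(self):
        stats = overlap_stats({("a", "p1")}, {("b", "p1")})
        assert stats["shared_pair_pct_of_normal"] == 0.0
        assert stats["shared_lnc_pct_of_tumor"] == 0.0
        assert stats["tumor_specific_lnc_pct"] == 100.0

    def test_counts_are_internally_consistent(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            t = {(f"l{rng.integers(30)}", f"p{rng.integers(6)}") for _ in range(40)}
            n = {(f"l{rng.integers(30)}", f"p{rng.integers(6)}") for _ in range(40)}
            s = overlap_stats(t, n)
            assert s["shared_pairs"] <= min(s["tumor_pairs"], s["normal_pairs"])
            assert s["tumor_specific_lncrnas"] + s["shared_lncrnas"] == s["tumor_lncrnas"]


class TestTumorSpecific:
    def test_membership_rules(self):
        tumor = {("a", "p1"), ("b", "p2")}
        normal = {("b", "p3")}
        assert tumor_specific_lncrnas(tumor, normal) == {"a"}


class TestCellEnrichment:
    def _run(self, correlated, marker_genes, universe, min_k=3):
        cfg = PipelineConfig(min_marker_overlap_k=min_k)
        sig = pd.DataFrame({
            "lnc_id": "l1", "mrna_id": sorted(correlated),
            "R": 0.9, "P": 1e-8, "score": 8.0,
        })
        table = cell_enrichment(
            ["l1"], sig, _collection(CELL=marker_genes), universe, cfg
        )
        return table.iloc[0]

    def test_small_overlap_forced_nonsignificant(self):
        universe = [f"m{i}" for i in range(30)]
        rec = self._run(universe[:10], universe[8:20], universe)  # k = 2
        assert rec["k"] == 2 and rec["p"] == 1.0 and not rec["significant"]

    def test_matches_enumeration_oracle(self):
        universe = [f"m{i}" for i in range(10)]
        marker = universe[:4]
        correlated = universe[1:6]          # overlap with marker = 3
        rec = self._run(correlated, marker, universe)
        assert (rec["N"], rec["M"], rec["n"], rec["k"]) == (10, 4, 5, 3)
        assert rec["p"] == pytest.approx(66 / 252)

    def test_lncrna_without_correlates_is_inert(self):
        universe = [f"m{i}" for i in range(10)]
        cfg = PipelineConfig()
        sig = pd.DataFrame(columns=["lnc_id", "mrna_id", "R", "P", "score"])
        table = cell_enrichment(["l1"], sig, _collection(CELL=universe[:4]),
                                universe, cfg)
        assert (table["n"] == 0).all() and not table["significant"].any()

    def test_empty_universe_rejected(self):
        cfg = PipelineConfig()
        sig = pd.DataFrame(columns=["lnc_id", "mrna_id", "R", "P", "score"])
        with pytest.raises(ValueError, match="universe"):
            cell_enrichment(["l1"], sig, _collection(CELL=["a"]), [], cfg)

    def test_pvalues_superuniform_under_random_markers(self):
        rng = np.random.default_rng(12)
        universe = [f"m{i}" for i in range(300)]
        cfg = PipelineConfig()
        ps = []
        for rep in range(40):
            correlated = rng.choice(universe, size=40, replace=False)
            sig = pd.DataFrame({
                "lnc_id": "l1", "mrna_id": correlated, "R": 0.9, "P": 1e-8,
                "score": 8.0,
            })
            markers = _collection(**{
                f"c{j}": rng.choice(universe, size=20, replace=False)
                for j in range(10)
            })
            table = cell_enrichment(["l1"], sig, markers, universe, cfg)
            ps.extend(table["p"].tolist())
        assert np.mean(np.asarray(ps) < 0.05) <= 0.05 + 0.02


class TestSelectDysregulated:
    def _table(self, counts):
        rows = []
        for lnc, c in counts.items():
            for j in range(24):
                rows.append({
                    "lnc_id": lnc, "cell_type": f"cell{j}",
                    "N": 100, "M": 10, "n": 20, "k": 5,
                    "p": 0.01 if j < c else 0.9, "significant": j < c,
                })
        return pd.DataFrame(rows)

    def test_inclusive_boundary_at_minimum(self):
        cfg = PipelineConfig(min_enriched_cells=10)
        out = select_dysregulated(self._table({"a": 10, "b": 9}), cfg)
        assert out.lnc_ids == ["a"]
        assert out.enriched_cell_counts["a"] == 10

    def test_empty_table_empty_selection(self):
        out = select_dysregulated(pd.DataFrame(), PipelineConfig())
        assert out.lnc_ids == []

    def test_monotone_in_min_enriched_cells(self):
        table = self._table({"a": 24, "b": 15, "c": 10, "d": 5})
        prev = None
        for thr in (5, 10, 15, 24):
            sel = set(select_dysregulated(
                table, PipelineConfig(min_enriched_cells=thr)
            ).lnc_ids)
            if prev is not None:
                assert sel <= prev
            prev = sel
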