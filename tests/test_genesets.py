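"""Gene-set IO, enrichment statistics and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lactopath import genesets
from lactopath.containers import LABEL_HIGH, LABEL_LOW, LABEL_MID, GeneSet
from lactopath.errors import ParseError

from oracles import es_bruteforce, ssgsea_bruteforce


class TestGmt:
    def test_roundtrip_identity(self, tmp_path):
        sets = [
            GeneSet("LAC", ["LDHA", "SLC16A1"], description="desc"),
            GeneSet("OTHER", ["A", "B", "C"], description="x"),
        ]
        path = tmp_path / "sets.gmt"
        genesets.write_gmt(sets, path)
        back = genesets.read_gmt(path)
        assert [s.name for s in back] == ["LAC", "OTHER"]
        assert [s.genes for s in back] == [["LDHA", "SLC16A1"], ["A", "B", "C"]]

    def test_single_line_parse(self, tmp_path):
        path = tmp_path / "one.gmt"
        path.write_text("LAC\tdesc\tLDHA\tSLC16A1\n")
        (gs,) = genesets.read_gmt(path)
        assert gs.name == "LAC" and gs.genes == ["LDHA", "SLC16A1"]

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        assert genesets.read_gmt(path) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("GOOD\td\tG1\nBADLINE\tonly-two-fields\n")
        with pytest.raises(ParseError, match="line 2"):
            genesets.read_gmt(path)

    def test_duplicate_genes_deduplicated_with_warning(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S\td\tG2\tG1\tG2\tG3\n")
        with pytest.warns(UserWarning, match="duplicate"):
            (gs,) = genesets.read_gmt(path)
        assert gs.genes == ["G2", "G1", "G3"]  # order preserved


class TestSsgsea:
    def test_matches_bruteforce_on_toy_instance(self):
        # 6 genes, 2 samples, set of 2 genes
        genes = ["a", "b", "c", "d", "e", "f"]
        values = np.array(
            [[5.0, 1.0], [4.0, 2.0], [3.0, 6.0], [2.0, 5.0], [1.0, 4.0], [0.0, 3.0]]
        )
        expr = pd.DataFrame(values, index=genes, columns=["s1", "s2"])
        gs = GeneSet("S", ["a", "d"])
        scores = genesets.ssgsea_scores(expr, gs, alpha=0.25)
        for j, sample in enumerate(["s1", "s2"]):
            expected = ssgsea_bruteforce(
                dict(zip(genes, values[:, j])), {"a", "d"}, alpha=0.25
            )
            assert scores.loc[sample, "S"] == pytest.approx(expected, rel=1e-12)

    def test_matches_gseapy_es(self, small_expression):
        gseapy = pytest.importorskip("gseapy")
        gs = GeneSet("SETA", list(small_expression.index[:8]))
        mine = genesets.ssgsea_scores(small_expression, gs)
        res = gseapy.ssgsea(
            data=small_expression,
            gene_sets={"SETA": gs.genes},
            outdir=None,
            sample_norm_method="rank",
            weight=0.25,
            min_size=2,
            seed=0,
        )
        theirs = (
            res.res2d.set_index("Name")["ES"].astype(float).reindex(mine.index)
        )
        np.testing.assert_allclose(mine["SETA"], theirs, rtol=1e-4)

    def test_top_ranked_scores_higher_than_bottom_ranked(self):
        genes = ["g1", "g2", "g3", "g4"]
        expr = pd.DataFrame(
            {"top": [9.0, 3.0, 2.0, 1.0], "bottom": [0.5, 3.0, 2.0, 1.0]},
            index=genes,
        )
        scores = genesets.ssgsea_scores(expr, GeneSet("S", ["g1"]))
        assert scores.loc["top", "S"] > scores.loc["bottom", "S"]

    def test_invariant_to_monotone_transform(self, small_expression):
        gs = GeneSet("S", list(small_expression.index[:5]))
        base = genesets.ssgsea_scores(small_expression, gs)
        affine = genesets.ssgsea_scores(2.0 * small_expression + 7.0, gs)
        curved = genesets.ssgsea_scores(np.exp(small_expression / 3.0), gs)
        pd.testing.assert_frame_equal(base, affine)
        pd.testing.assert_frame_equal(base, curved)

    def test_zero_overlap_skipped_full_coverage_errors(self, small_expression):
        with pytest.warns(UserWarning, match="skipped"):
            out = genesets.ssgsea_scores(
                small_expression, GeneSet("NONE", ["absent1", "absent2"])
            )
        assert out.empty or "NONE" not in out.columns
        with pytest.raises(ValueError, match="every measured gene"):
            genesets.ssgsea_scores(
                small_expression, GeneSet("ALL", list(small_expression.index))
            )


class TestPrerankedGsea:
    def test_all_inset_at_top_gives_unit_es(self):
        stats = pd.Series(
            np.linspace(3, -3, 20), index=[f"g{i}" for i in range(20)]
        )
        gs = GeneSet("TOP", [f"g{i}" for i in range(4)])
        es, _, _ = genesets.preranked_gsea(stats, gs, n_perm=50, seed=0)
        assert es == pytest.approx(1.0, abs=1e-9)

    def test_es_matches_bruteforce_on_toy_ranking(self, rng):
        genes = [f"g{i}" for i in range(8)]
        values = rng.normal(size=8)
        stats = pd.Series(values, index=genes)
        gs = GeneSet("S", ["g1", "g4", "g6"])
        es, _, _ = genesets.preranked_gsea(stats, gs, n_perm=50, seed=0)
        expected = es_bruteforce(dict(zip(genes, values)), {"g1", "g4", "g6"})
        assert es == pytest.approx(expected, rel=1e-12)

    def test_too_few_permutations_rejected(self, rng):
        stats = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError, match="n_perm"):
            genesets.preranked_gsea(stats, GeneSet("S", ["g0", "g1"]), n_perm=5)

    def test_null_pvalues_roughly_uniform(self, rng):
        # small-scale calibration check; the full one runs in acceptance
        from scipy import stats as sps

        pvals = []
        genes = [f"g{i}" for i in range(30)]
        gs = GeneSet("S", genes[:6])
        for rep in range(100):
            ranking = pd.Series(rng.normal(size=30), index=genes)
            _, _, p = genesets.preranked_gsea(ranking, gs, n_perm=99, seed=rep)
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestStratify:
    def test_fraction_033_of_500_gives_165_per_group(self):
        scores = pd.Series(
            np.arange(500, dtype=float), index=[f"s{i:03d}" for i in range(500)]
        )
        out = genesets.stratify_tertiles(scores, fraction=0.33)
        counts = out["group"].value_counts()
        assert counts[LABEL_HIGH] == 165 and counts[LABEL_LOW] == 165

    def test_three_samples_give_one_per_extreme(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        out = genesets.stratify_tertiles(scores, fraction=0.33)
        assert out.loc["a", "group"] == LABEL_LOW
        assert out.loc["c", "group"] == LABEL_HIGH
        assert out.loc["b", "group"] == LABEL_MID

    def test_all_tied_scores_split_by_sample_id(self):
        scores = pd.Series(np.zeros(10), index=[f"s{i}" for i in range(10)])
        out = genesets.stratify_tertiles(scores, fraction=0.33)
        counts = out["group"].value_counts()
        assert counts[LABEL_HIGH] == 3 and counts[LABEL_LOW] == 3
        # deterministic: earliest ids low, latest ids high
        assert set(out.index[out["group"] == LABEL_LOW]) == {"s0", "s1", "s2"}

    def test_groups_disjoint_and_sized_floor(self, rng):
        for n in (7, 20, 101):
            scores = pd.Series(rng.normal(size=n), index=[f"s{i:03d}" for i in range(n)])
            out = genesets.stratify_tertiles(scores, fraction=0.33)
            k = max(1, int(np.floor(0.33 * n)))
            assert (out["group"] == LABEL_HIGH).sum() == k
            assert (out["group"] == LABEL_LOW).sum() == k

    def test_invalid_fraction_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            genesets.stratify_tertiles(scores, fraction=0.6)


class TestSignatureDelta:
    def test_simple_means(self):
        scores = pd.Series([2.0, 3.0, 0.0, 1.0], index=list("abcd"), name="sig")
        groups = pd.Series(
            [LABEL_HIGH, LABEL_HIGH, LABEL_LOW, LABEL_LOW], index=list("abcd")
        )
        out = genesets.signature_delta(scores, groups)
        assert out.loc["sig", "delta"] == pytest.approx(2.0)
        flipped = genesets.signature_delta(scores, groups, high_minus_low=False)
        assert flipped.loc["sig", "delta"] == pytest.approx(-2.0)

    def test_identical_groups_delta_zero_p_near_one(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 2
        scores = pd.Series(vals, index=[f"s{i}" for i in range(8)], name="sig")
        groups = pd.Series(
            [LABEL_HIGH] * 4 + [LABEL_LOW] * 4, index=scores.index
        )
        out = genesets.signature_delta(scores, groups)
        assert out.loc["sig", "delta"] == pytest.approx(0.0)
        assert out.loc["sig", "p_value"] > 0.9  # 1 up to continuity correction

    def test_p_close_to_exact_enumeration(self, rng):
        from scipy import stats as sps

        hi = rng.normal(0.8, 1.0, size=8)
        lo = rng.normal(0.0, 1.0, size=8)
        scores = pd.Series(
            np.concatenate([hi, lo]), index=[f"s{i}" for i in range(16)], name="sig"
        )
        groups = pd.Series([LABEL_HIGH] * 8 + [LABEL_LOW] * 8, index=scores.index)
        out = genesets.signature_delta(scores, groups)
        exact = sps.mannwhitneyu(hi, lo, alternative="two-sided", method="exact")
        assert out.loc["sig", "p_value"] == pytest.approx(exact.pvalue, abs=0.02)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-50, max_value=50, allow_nan=False),
        min_size=6,
        max_size=30,
    )
)
def test_stratify_extreme_groups_never_overlap(values):
    scores = pd.Series(values, index=[f"s{i:03d}" for i in range(len(values))])
    out = genesets.stratify_tertiles(scores, fraction=0.33)
    hi = set(out.index[out["group"] == LABEL_HIGH])
    lo = set(out.index[out["group"] == LABEL_LOW])
    assert not hi & lo
    assert len(hi) == len(lo) == max(1, int(np.floor(0.33 * len(values))))
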