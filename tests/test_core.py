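"""Gene Scores, ranks, Enrichment Scores/Ratios, paired t, BH, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gocrispr.core import (
    Contrast,
    TracsParams,
    bh_adjust,
    enrichment_ratio,
    filter_essential,
    library_cutoff,
    paired_t_test,
    run_tracs,
)
from gocrispr.screen_io import CountMatrix


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_average_ranks(values):
    """Sort-and-index ranking with average ties, O(n^2) but obviously right."""
    values = list(values)
    out = []
    for v in values:
        below = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        # average of ranks below+1 .. below+equal
        out.append(below + (equal + 1) / 2)
    return np.array(out)


def oracle_bh(p):
    """Step-up BH from the definition: p_adj_i = min_{p_j >= p_i} m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for k in range(m - 1, -1, -1):
        i = order[k]
        running_min = min(running_min, m * p[i] / (k + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def oracle_quantile(values, q):
    """Linear interpolation between order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


# ---------------------------------------------------------------------------
# unit behaviour
# ---------------------------------------------------------------------------

class TestEnrichmentRatio:
    @pytest.mark.parametrize("initial,final,expected", [
        (1384.00, 16.61, -6.38),
        (2216.28, 37.33, -5.89),
    ])
    def test_worked_examples(self, initial, final, expected):
        assert round(enrichment_ratio(initial, final), 2) == expected

    def test_equal_scores_give_zero(self):
        assert enrichment_ratio(123.4, 123.4) == 0.0

    def test_antisymmetry(self):
        a, b = 17.0, 423.5
        assert enrichment_ratio(a, b) == pytest.approx(-enrichment_ratio(b, a))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(0.0, 1.0)


class TestPairedT:
    def test_identical_pairs_give_p_one(self):
        t, p, const = paired_t_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0 and const

    def test_constant_difference_flagged(self):
        t, p, const = paired_t_test([10, 12, 14], [4, 6, 8])
        assert p == 1.0 and const

    def test_matches_closed_form(self):
        # diffs (initial - final): 6, 5, 8 -> mean 6.333, sd 1.5275, t = 7.18
        t, p, const = paired_t_test([10, 12, 14], [4, 7, 6])
        assert not const
        diffs = np.array([10 - 4, 12 - 7, 14 - 6])
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        assert abs(t) == pytest.approx(t_hand)
        assert abs(t) == pytest.approx(7.18, abs=0.01)
        p_hand = 2 * stats.t.sf(t_hand, df=2)
        assert p == pytest.approx(p_hand)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


class TestBH:
    def test_step_up_by_hand(self):
        p_adj, sig = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.04])
        assert sig.all()

    def test_single_p_unchanged(self):
        p_adj, _ = bh_adjust(np.array([0.2]))
        assert p_adj[0] == pytest.approx(0.2)

    def test_pointwise_geq_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        p_adj, _ = bh_adjust(p)
        assert (p_adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestLibraryCutoff:
    def test_linear_interpolation(self):
        assert library_cutoff(np.arange(1, 101), 0.25) == pytest.approx(25.75)

    def test_median_of_three(self):
        assert library_cutoff(np.array([1.0, 2.0, 3.0]), 0.5) == 2.0

    def test_identical_values(self):
        assert library_cutoff(np.full(10, 7.0), 0.25) == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            library_cutoff(np.array([]))


# ---------------------------------------------------------------------------
# oracle equivalence (property-based)
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=100)
@given(st.lists(st.integers(min_value=-50, max_value=50),
                min_size=1, max_size=200))
def test_ranking_matches_oracle(values):
    got = stats.rankdata(np.array(values, dtype=float), method="average")
    np.testing.assert_allclose(got, oracle_average_ranks(values))
    # rank conservation
    x = len(values)
    assert got.sum() == pytest.approx(x * (x + 1) / 2)


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=1, max_size=200))
def test_bh_matches_oracle(p):
    p_adj, _ = bh_adjust(np.array(p))
    np.testing.assert_allclose(p_adj, oracle_bh(p), rtol=1e-12, atol=1e-12)


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
                min_size=4, max_size=200),
       st.floats(min_value=0.05, max_value=0.95))
def test_quantile_matches_oracle(values, q):
    got = library_cutoff(np.array(values), q)
    assert got == pytest.approx(oracle_quantile(values, q), rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# full pipeline behaviour
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scored(small_screen):
    matrix, design, library, truth = small_screen
    return run_tracs(matrix, design)


class TestRunTracs:
    def test_er_identity_rowwise(self, scored):
        t = scored.table
        ok = t[~t["excluded"].astype(bool)]
        np.testing.assert_array_equal(
            ok["er"].to_numpy(),
            np.log2(ok["final_es"].to_numpy() / ok["initial_es"].to_numpy()))

    def test_deterministic(self, small_screen):
        matrix, design, *_ = small_screen
        a = run_tracs(matrix, design).table
        b = run_tracs(matrix, design).table
        pd.testing.assert_frame_equal(a, b)

    def test_padj_dominates_p(self, scored):
        t = scored.table
        ok = t[~t["excluded"].astype(bool)]
        assert (ok["p_adj"] >= ok["p"] - 1e-12).all()

    def test_scale_invariance_of_scores(self, small_screen):
        """Multiplying one sample's counts by an integer changes no ES/ER/p.

        Size factors absorb per-sample depth.  The additive pseudocount on
        zero counts breaks exactness, so the check uses a zero-free matrix
        with a negligible pseudocount.
        """
        _, design, library, _ = small_screen
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            rng.integers(1, 400, size=(len(library), len(design.samples))),
            index=library.sgrna_ids, columns=design.sample_ids)
        matrix = CountMatrix(counts, library, design)
        scaled = counts.copy()
        scaled.iloc[:, 3] = scaled.iloc[:, 3] * 7
        m2 = CountMatrix(scaled, library, design)
        params = TracsParams(pseudocount=1e-9)
        r1 = run_tracs(matrix, design, params).table
        r2 = run_tracs(m2, design, params).table
        for col in ("library_es", "initial_es", "final_es", "er", "p"):
            np.testing.assert_allclose(r1[col].to_numpy(dtype=float),
                                       r2[col].to_numpy(dtype=float),
                                       rtol=1e-6, equal_nan=True)

    def test_monotone_in_final_counts(self, small_screen):
        """Inflating a gene's Cas9-positive Tf counts never lowers its ER."""
        matrix, design, library, _ = small_screen
        result0 = run_tracs(matrix, design)
        gene = result0.table.loc[~result0.table["excluded"].astype(bool),
                                 "gene"].iloc[10]
        bumped = matrix.counts.copy()
        tf = design.group("cas9_pos", "Tf")
        rows = library.sgrnas_of(gene)
        bumped.loc[rows, tf] = bumped.loc[rows, tf] * 5
        result1 = run_tracs(CountMatrix(bumped, library, design), design)
        r0 = result0.table.set_index("gene").loc[gene]
        r1 = result1.table.set_index("gene").loc[gene]
        assert r1["final_es"] >= r0["final_es"]
        assert r1["er"] >= r0["er"]

    def test_excluded_gene_flagged_not_scored(self, small_screen):
        matrix, design, library, _ = small_screen
        counts = matrix.counts.copy()
        gene = library.genes[0]
        counts.loc[library.sgrnas_of(gene), :] = 0
        result = run_tracs(CountMatrix(counts, library, design), design)
        row = result.table.set_index("gene").loc[gene]
        assert bool(row["excluded"])
        assert np.isnan(row["er"])

    def test_rank_sums_conserved(self, small_screen):
        from gocrispr.core import Contrast, gene_scores, rank_scores
        from gocrispr.preprocess import add_pseudocount, median_ratio_normalize
        matrix, design, library, _ = small_screen
        norm = median_ratio_normalize(add_pseudocount(matrix))
        genes = matrix.genes
        c = Contrast.final(design)
        mask = (matrix.counts[c.all_samples] >= 1).any(axis=1)
        det = mask.groupby(genes).sum().astype(int)
        tbl = rank_scores(gene_scores(norm, c, det[det > 0], genes, mask))
        x = len(tbl.ranks)
        np.testing.assert_allclose(tbl.ranks.sum(axis=0), x * (x + 1) / 2)


class TestGeneScoresArithmetic:
    def test_hand_computed_example(self, design):
        """2 guides with numerator abundances (8,8) vs reference means (2,4):
        GS = log2(8/2) + log2(8/4) = 3."""
        from gocrispr.core import Contrast, gene_scores
        from gocrispr.preprocess import NormalizedMatrix
        from gocrispr.screen_io import LibraryReference

        lib = LibraryReference((
            ("a_s1", "A", "ACGT" * 5), ("a_s2", "A", "TTTT" * 5),
        ))
        c = Contrast.initial(design)
        cols = {s: [1.0, 1.0] for s in design.sample_ids}
        for s in c.numerator_samples:
            cols[s] = [8.0, 8.0]
        for s in c.denominator_samples:
            cols[s] = [2.0, 4.0]
        abundance = pd.DataFrame(cols, index=["a_s1", "a_s2"])
        norm = NormalizedMatrix(abundance,
                                pd.Series(1.0, index=abundance.columns), 1.0)
        genes = pd.Series(["A", "A"], index=abundance.index)
        mask = pd.Series([True, True], index=abundance.index)
        det = pd.Series({"A": 2})
        tbl = gene_scores(norm, c, det, genes, mask)
        # reference mean per guide = mean(2,2,2)=2 and mean(4,4,4)=4
        np.testing.assert_allclose(tbl.gs.loc["A"], 3.0)

    def test_gs_zero_when_numerator_equals_reference(self, design):
        from gocrispr.core import Contrast, gene_scores
        from gocrispr.preprocess import NormalizedMatrix
        c = Contrast.final(design)
        abundance = pd.DataFrame(5.0, index=["a_s1", "a_s2"],
                                 columns=design.sample_ids)
        norm = NormalizedMatrix(abundance,
                                pd.Series(1.0, index=abundance.columns), 1.0)
        genes = pd.Series(["A", "A"], index=abundance.index)
        mask = pd.Series(True, index=abundance.index)
        tbl = gene_scores(norm, c, pd.Series({"A": 2}), genes, mask)
        np.testing.assert_allclose(tbl.gs.loc["A"], 0.0)

    def test_halving_numerator_drops_gs_by_s(self, design):
        from gocrispr.core import Contrast, gene_scores
        from gocrispr.preprocess import NormalizedMatrix
        c = Contrast.final(design)
        base = pd.DataFrame(4.0, index=["a_s1", "a_s2", "a_s3"],
                            columns=design.sample_ids)
        halved = base.copy()
        halved.loc[:, list(c.numerator_samples)] = 2.0
        genes = pd.Series("A", index=base.index)
        mask = pd.Series(True, index=base.index)
        det = pd.Series({"A": 3})
        sf = pd.Series(1.0, index=base.columns)
        g0 = gene_scores(NormalizedMatrix(base, sf, 1.0), c, det, genes, mask)
        g1 = gene_scores(NormalizedMatrix(halved, sf, 1.0), c, det, genes, mask)
        np.testing.assert_allclose(g0.gs.loc["A"] - g1.gs.loc["A"], 3.0)


class TestEnrichmentScoreFormula:
    def test_mean_rank_over_s(self):
        from gocrispr.core import GeneScoreTable, enrichment_scores
        ranks = pd.DataFrame({"r1": [100.0], "r2": [110.0], "r3": [120.0]},
                             index=["A"])
        tbl = GeneScoreTable(None, ranks.copy(), pd.Series({"A": 6}), ranks)
        es = enrichment_scores(tbl)
        assert es["A"] == pytest.approx(110 / 6)

    def test_single_gene_single_guide(self):
        from gocrispr.core import GeneScoreTable, enrichment_scores
        ranks = pd.DataFrame({"r1": [1.0], "r2": [1.0]}, index=["A"])
        tbl = GeneScoreTable(None, ranks.copy(), pd.Series({"A": 1}), ranks)
        assert enrichment_scores(tbl)["A"] == 1.0

    def test_brute_force_recomputation(self, small_screen):
        from gocrispr.core import (Contrast, enrichment_scores, gene_scores,
                                   rank_scores)
        from gocrispr.preprocess import add_pseudocount, median_ratio_normalize
        matrix, design, library, _ = small_screen
        norm = median_ratio_normalize(add_pseudocount(matrix))
        genes = matrix.genes
        c = Contrast.initial(design)
        mask = (matrix.counts[c.all_samples] >= 1).any(axis=1)
        det = mask.groupby(genes).sum().astype(int)
        tbl = rank_scores(gene_scores(norm, c, det[det > 0], genes, mask))
        es = enrichment_scores(tbl)
        for gene in es.index[:50]:
            expect = tbl.ranks.loc[gene].mean() / tbl.s[gene]
            assert es[gene] == pytest.approx(expect)


class TestFilterEssential:
    def _result(self, rows):
        from gocrispr.core import TracsResult, RESULT_COLUMNS
        df = pd.DataFrame(rows)
        for col in RESULT_COLUMNS:
            if col not in df.columns:
                df[col] = False if col in ("low_library_es", "significant",
                                           "excluded", "constant_difference") \
                    else np.nan
        return TracsResult(df[RESULT_COLUMNS], TracsParams(), cutoff := 100.0), cutoff

    def test_strict_boundaries_and_sorting(self):
        rows = [
            dict(gene="AT_CUTOFF", library_es=100.0, er=-1.0, p_adj=0.01),
            dict(gene="DEEP", library_es=200.0, er=-3.0, p_adj=0.01),
            dict(gene="MILD", library_es=200.0, er=-0.5, p_adj=0.01),
            dict(gene="NOT_SIG", library_es=200.0, er=-2.0, p_adj=0.2),
            dict(gene="ER_ZERO", library_es=200.0, er=0.0, p_adj=0.01),
            dict(gene="ENRICHED", library_es=200.0, er=1.0, p_adj=0.01),
        ]
        result, cutoff = self._result(rows)
        got = filter_essential(result, cutoff=cutoff)
        # brute force: strict >cutoff, <0, <0.05
        expect = sorted(
            (r for r in rows
             if r["library_es"] > cutoff and r["er"] < 0 and r["p_adj"] < 0.05),
            key=lambda r: r["er"])
        assert got["gene"].tolist() == [r["gene"] for r in expect]
        assert got["gene"].tolist() == ["DEEP", "MILD"]
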