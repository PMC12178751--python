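"""Rank tests, FDR correction and MAG classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
import nichedecay as nd
from nichedecay.differential_abundance import default_pseudocount


class TestKwTest:
    def test_identical_interleaved_distributions(self):
        values = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        groups = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        h, p = nd.kw_test(values, groups)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_tie_case_matches_rank_formula(self):
        values = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        groups = np.array([1, 1, 1, 2, 2, 2])
        h, _ = nd.kw_test(values, groups)
        assert h == pytest.approx(oracles.kruskal_wallis_h([[1, 2, 3], [10, 11, 12]]))

    def test_heavy_ties_match_corrected_oracle(self):
        h, _ = nd.kw_test(np.array([1, 1, 1, 1, 1, 2.0]),
                          np.array([1, 1, 1, 2, 2, 2]))
        assert h == pytest.approx(oracles.kruskal_wallis_h([[1, 1, 1], [1, 1, 2]]))

    def test_exhaustive_small_integer_samples(self):
        """All 2-group samples with sizes (2,2) and (3,2) over {1,2,3} must
        match the from-scratch rank oracle, including tie correction."""
        for n1, n2 in ((2, 2), (3, 2)):
            groups = np.array([1] * n1 + [2] * n2)
            for combo in itertools.product((1, 2, 3), repeat=n1 + n2):
                values = np.array(combo, dtype=float)
                if np.all(values == values[0]):
                    continue  # degenerate by convention: H=0, p=1
                h, _ = nd.kw_test(values, groups)
                ref = oracles.kruskal_wallis_h([list(combo[:n1]), list(combo[n1:])])
                assert h == pytest.approx(ref, abs=1e-10), combo

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            nd.kw_test(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_exact_permutation_p_on_separated_groups(self):
        # perfectly separated 3-vs-3: only the 2 of the 20 group splits
        # achieve the maximal H, so the exact tail probability is 0.1
        values = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        groups = np.array([1, 1, 1, 2, 2, 2])
        h_exact, p_exact = nd.kw_test(values, groups, exact=True)
        h_chi2, _ = nd.kw_test(values, groups)
        assert h_exact == h_chi2
        assert p_exact == pytest.approx(0.1)

    def test_exact_permutation_limited_to_small_n(self):
        values = np.arange(12, dtype=float)
        groups = np.array([1, 2] * 6)
        with pytest.raises(ValueError, match="n <= 10"):
            nd.kw_test(values, groups, exact=True)


class TestBhFdr:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(nd.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(nd.bh_fdr([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nd.bh_fdr([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_bruteforce_stepup_and_is_monotone(self, pvals):
        q = nd.bh_fdr(pvals)
        np.testing.assert_allclose(q, oracles.bh_stepup(pvals), atol=1e-12)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(pvals) - 1e-12).all()


class TestLog2Ratio:
    @staticmethod
    def _matrix(col1, col2):
        values = np.column_stack([col1, col2])
        values = np.column_stack([values, 1 - values.sum(axis=1)])
        return nd.AbundanceMatrix([f"s{i}" for i in range(len(col1))],
                                  ["mA", "mB", "rest"], values)

    def test_equal_means_zero(self):
        m = self._matrix([0.2, 0.2, 0.2, 0.2], [0.1, 0.1, 0.1, 0.1])
        labels = np.array([1, 1, 2, 2])
        assert nd.log2_ratio(m, labels, "mA") == pytest.approx(0.0, abs=1e-9)

    def test_fourfold_difference_near_two(self):
        m = self._matrix([0.1, 0.1, 0.4, 0.4], [0.1, 0.1, 0.1, 0.1])
        labels = np.array([1, 1, 2, 2])
        assert nd.log2_ratio(m, labels, "mA",
                             pseudocount=1e-9) == pytest.approx(2.0, abs=1e-6)

    def test_zero_mean_with_pseudocount_closed_form(self):
        eps = 0.001
        m = self._matrix([0.0, 0.0, 10 * eps, 10 * eps], [0.2, 0.2, 0.2, 0.2])
        labels = np.array([1, 1, 2, 2])
        expected = np.log2(11 * eps / eps)  # ~3.459
        assert nd.log2_ratio(m, labels, "mA", pseudocount=eps) == pytest.approx(expected)

    def test_default_pseudocount_is_min_nonzero_over_ten(self):
        m = self._matrix([0.0, 0.25, 0.5, 0.25], [0.001, 0.25, 0.2, 0.2])
        assert default_pseudocount(m) == pytest.approx(0.0001)


class TestClassifyMag:
    @pytest.mark.parametrize("log2r,q,expected", [
        (-1.5, 0.01, nd.CLUSTER1),
        (1.0, 0.049, nd.CLUSTER2),   # fold boundary inclusive, q strict
        (1.0, 0.05, nd.UNASSIGNED),  # q boundary exclusive
        (0.99, 0.01, nd.UNASSIGNED),
        (3.0, 0.2, nd.UNASSIGNED),
    ])
    def test_classification_rule(self, log2r, q, expected):
        assert nd.classify_mag(log2r, q) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=-8, max_value=8), st.floats(min_value=0, max_value=1))
    def test_antisymmetry_under_ratio_flip(self, log2r, q):
        swap = {nd.CLUSTER1: nd.CLUSTER2, nd.CLUSTER2: nd.CLUSTER1,
                nd.UNASSIGNED: nd.UNASSIGNED}
        assert nd.classify_mag(-log2r, q) == swap[nd.classify_mag(log2r, q)]


class TestVolcanoTable:
    def test_identical_columns_all_unassigned(self):
        values = np.full((6, 4), 0.25)
        m = nd.AbundanceMatrix([f"s{i}" for i in range(6)],
                               [f"m{j}" for j in range(4)], values)
        df, counts = nd.volcano_table(m, np.array([1, 1, 1, 2, 2, 2]))
        assert counts[nd.UNASSIGNED] == 4

    def test_class_counts_conserve_mag_total(self, default_run):
        counts = default_run["class_counts"]
        assert sum(counts.values()) == default_run["matrix"].n_mags

    def test_planted_classes_recovered(self, default_run):
        """With strong planted selection most central MAGs must classify
        into their own state's cluster."""
        stats, truth = default_run["stats"], default_run["truth"]
        merged = stats.merge(truth.mag_classes.rename_axis("mag_id").reset_index(),
                             on="mag_id")
        rec1 = (merged.loc[merged.true_class == nd.CENTRAL_1, "assoc_class"]
                == nd.CLUSTER1).mean()
        rec2 = (merged.loc[merged.true_class == nd.CENTRAL_2, "assoc_class"]
                == nd.CLUSTER2).mean()
        assert rec1 >= 0.9 and rec2 >= 0.9


class TestPhylumVolcano:
    @staticmethod
    def _records(phyla):
        return [nd.MagRecord(f"m{j}",
                             nd.parse_gtdb_lineage(f"d__Bacteria;p__{p}" if p else "d__Bacteria"),
                             90.0, 5.0) for j, p in enumerate(phyla)]

    def test_single_phylum_matches_whole_matrix_aggregate(self, rng):
        values = rng.dirichlet(np.ones(4), size=8)
        m = nd.AbundanceMatrix([f"s{i}" for i in range(8)],
                               [f"m{j}" for j in range(4)], values)
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        df = nd.phylum_volcano(m, self._records(["A"] * 4), labels)
        assert len(df) == 1
        # phylum abundance sums each row to 1 -> degenerate KW convention
        assert df.p.iloc[0] == pytest.approx(1.0)
        assert df.mag_count.iloc[0] == 4

    def test_opposite_enrichment_opposite_signs(self):
        labels = np.array([1, 1, 1, 2, 2, 2])
        col_a = np.array([0.8, 0.7, 0.75, 0.1, 0.2, 0.15])
        values = np.column_stack([col_a, 1 - col_a])
        m = nd.AbundanceMatrix([f"s{i}" for i in range(6)], ["m0", "m1"], values)
        df = nd.phylum_volcano(m, self._records(["A", "B"]), labels)
        signs = dict(zip(df.phylum, np.sign(df.log2_ratio)))
        assert signs["A"] == -1 and signs["B"] == 1

    def test_mag_counts_match_taxonomic_summary(self, default_run):
        matrix, bundle = default_run["matrix"], default_run["bundle"]
        df = nd.phylum_volcano(matrix, bundle["mag_records"],
                               default_run["assignment"].binary_labels)
        summary = nd.taxonomic_summary(matrix, bundle["mag_records"], "phylum")
        expected = dict(zip(summary.taxon, summary.mag_count))
        for phylum, count in zip(df.phylum, df.mag_count):
            if phylum != "Unclassified":
                assert expected[phylum] == count


class TestContaminationCorrelation:
    @staticmethod
    def _records(contaminations):
        return [nd.MagRecord(f"m{j}", nd.parse_gtdb_lineage("d__Bacteria"),
                             90.0, float(c)) for j, c in enumerate(contaminations)]

    def test_perfect_monotone_relation(self):
        stats = pd.DataFrame({"mag_id": [f"m{j}" for j in range(5)],
                              "log2_ratio": [1.0, 2.0, 3.0, 4.0, 5.0]})
        rho, _ = nd.contamination_correlation(stats, self._records([1, 2, 3, 4, 5]))
        assert rho == pytest.approx(1.0)

    def test_constant_contamination_flagged(self):
        stats = pd.DataFrame({"mag_id": ["m0", "m1"], "log2_ratio": [1.0, 2.0]})
        with pytest.raises(ValueError, match="undefined"):
            nd.contamination_correlation(stats, self._records([5, 5]))

    def test_mismatched_ids_rejected(self):
        stats = pd.DataFrame({"mag_id": ["mX"], "log2_ratio": [1.0]})
        with pytest.raises(ValueError, match="mX"):
            nd.contamination_correlation(stats, self._records([5]))

    def test_independent_contamination_stays_null(self):
        """Simulator contamination is drawn independently of class, so the
        correlation should be weak and non-significant in nearly all runs."""
        ok = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            log2r = rng.normal(0, 2, size=200)
            records = self._records(rng.uniform(0, 25, size=200))
            stats = pd.DataFrame({"mag_id": [r.mag_id for r in records],
                                  "log2_ratio": log2r})
            rho, p = nd.contamination_correlation(stats, records)
            ok += (abs(rho) < 0.2) and (p > 0.01)
        assert ok >= 0.95 * n_rep
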