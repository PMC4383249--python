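"""Tag-count stages: TPM, filters, quantile normalization, patterns,
DIANA clustering and the longest-branch tree cut."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import torporna as tp
from torporna.errors import ConfigurationError
from torporna.tags import replicate_concordance_filter


def toy_matrix(values, groups=None, columns=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    columns = columns or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, columns=columns,
                      index=[f"t{i}" for i in range(values.shape[0])])
    if groups is None:
        return df
    return df, pd.Series(groups, index=columns)


class TestCountsToTpm:
    def test_single_tag_owns_the_library(self):
        df = toy_matrix([[10.0]])
        assert tp.counts_to_tpm(df).iloc[0, 0] == 1e6

    def test_hand_worked_two_tag_column(self):
        df = toy_matrix([[3.0], [1.0]])
        out = tp.counts_to_tpm(df)
        assert list(out.iloc[:, 0]) == [750000.0, 250000.0]

    def test_columns_sum_to_one_million(self, rng):
        df = pd.DataFrame(rng.integers(0, 100, (30, 8)).astype(float))
        out = tp.counts_to_tpm(df)
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_column_dropped_with_warning(self):
        df = toy_matrix([[1.0, 0.0], [2.0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            out = tp.counts_to_tpm(df)
        assert list(out.columns) == ["s0"]


def brute_force_expression_filter(tpm, groups, min_tpm):
    """Literal re-evaluation of the n-1 rule, tag by tag."""
    retained = []
    for tag in tpm.index:
        ok = False
        for g in groups.unique():
            cols = groups[groups == g].index
            n = len(cols)
            hits = sum(tpm.loc[tag, c] >= min_tpm for c in cols)
            if hits >= n - 1:
                ok = True
        if ok:
            retained.append(tag)
    return retained


def brute_force_replicate_filter(values, pairs, fold_limit):
    retained = []
    for tag in values.index:
        a = np.mean([values.loc[tag, p[0]] for p in pairs])
        b = np.mean([values.loc[tag, p[1]] for p in pairs])
        if a == 0 and b == 0:
            retained.append(tag)
        elif a == 0 or b == 0:
            continue
        elif max(a / b, b / a) < fold_limit:
            retained.append(tag)
    return retained


class TestExpressionFilter:
    def test_null_tag_removed(self):
        df, groups = toy_matrix([[0, 0, 0, 0]], groups=["A", "A", "B", "B"])
        assert len(tp.expression_filter(df, groups)) == 0

    def test_three_of_four_at_floor_retained(self):
        df, groups = toy_matrix(
            [[2, 2, 2, 0, 0, 0, 0, 0]], groups=["A"] * 4 + ["B"] * 4
        )
        assert list(tp.expression_filter(df, groups)) == ["t0"]

    def test_two_of_four_at_floor_removed(self):
        df, groups = toy_matrix(
            [[2, 2, 0, 0, 0, 0, 0, 0]], groups=["A"] * 4 + ["B"] * 4
        )
        assert len(tp.expression_filter(df, groups)) == 0

    def test_singleton_group_rejected(self):
        df, groups = toy_matrix([[1, 2, 3]], groups=["A", "A", "B"])
        with pytest.raises(ConfigurationError):
            tp.expression_filter(df, groups)

    def test_matches_brute_force_on_random_matrices(self, rng):
        groups = pd.Series(
            ["A"] * 5 + ["B"] * 4 + ["C"] * 6 + ["D"] * 5,
            index=[f"s{j}" for j in range(20)],
        )
        for _ in range(40):
            df = pd.DataFrame(
                rng.integers(0, 6, (50, 20)).astype(float),
                index=[f"t{i}" for i in range(50)],
                columns=groups.index,
            )
            got = list(tp.expression_filter(df, groups, min_tpm=2.0))
            assert got == brute_force_expression_filter(df, groups, 2.0)

    def test_idempotent(self, rng):
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=[f"s{j}" for j in range(8)])
        df = pd.DataFrame(
            rng.integers(0, 5, (30, 8)).astype(float), columns=groups.index
        )
        first = tp.expression_filter(df, groups)
        second = tp.expression_filter(df.loc[first], groups)
        assert list(first) == list(second)


class TestReplicateFilter:
    pairs = [("s0", "s1")]

    def test_identical_replicates_all_retained(self):
        df = toy_matrix([[5, 5], [9, 9]])
        assert len(replicate_concordance_filter(df, self.pairs)) == 2

    def test_exact_threefold_removed_boundary_inclusive(self):
        df = toy_matrix([[30, 10]])
        assert len(replicate_concordance_filter(df, self.pairs)) == 0

    def test_twofold_retained(self):
        df = toy_matrix([[20, 10]])
        assert len(replicate_concordance_filter(df, self.pairs)) == 1

    def test_zero_versus_nonzero_removed(self):
        df = toy_matrix([[0, 10], [0, 0]])
        kept = replicate_concordance_filter(df, self.pairs)
        assert list(kept) == ["t1"]  # double zero is concordant

    def test_no_pairs_is_noop_with_warning(self):
        df = toy_matrix([[1, 2]])
        with pytest.warns(UserWarning, match="no technical-replicate"):
            kept = replicate_concordance_filter(df, [])
        assert list(kept) == ["t0"]

    def test_matches_brute_force_on_random_matrices(self, rng):
        pairs = [("s0", "s1"), ("s2", "s3")]
        for _ in range(40):
            df = pd.DataFrame(
                rng.integers(0, 20, (50, 4)).astype(float),
                index=[f"t{i}" for i in range(50)],
                columns=["s0", "s1", "s2", "s3"],
            )
            got = list(replicate_concordance_filter(df, pairs))
            assert got == brute_force_replicate_filter(df, pairs, 3.0)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = toy_matrix([[1, 1], [5, 5], [3, 3]])
        out = tp.full_quantile_normalize(df)
        assert np.allclose(out, df)

    def test_worked_two_by_two_example(self):
        df = toy_matrix([[1, 3], [5, 7]])
        out = tp.full_quantile_normalize(df)
        assert np.allclose(out.to_numpy(), [[2.0, 2.0], [6.0, 6.0]])

    def test_columns_share_sorted_multiset(self, rng):
        df = pd.DataFrame(rng.uniform(0, 100, (40, 6)))
        out = tp.full_quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 6):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.uniform(0, 100, (40, 6)))
        once = tp.full_quantile_normalize(df)
        twice = tp.full_quantile_normalize(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_ties_share_mean_of_tied_quantiles(self):
        # column 0 has a tie at ranks 1-2; they share the mean of the
        # first two reference quantiles
        df = toy_matrix([[1, 10], [1, 20], [9, 30]])
        out = tp.full_quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out.iloc[0, 0] == out.iloc[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_single_column_rejected(self):
        with pytest.raises(ConfigurationError):
            tp.full_quantile_normalize(toy_matrix([[1.0]]))

    def test_preserves_row_order_mapping(self, rng):
        df = pd.DataFrame(rng.uniform(0, 10, (20, 3)))
        out = tp.full_quantile_normalize(df)
        for j in range(3):
            assert np.array_equal(
                np.argsort(df.iloc[:, j].to_numpy(), kind="stable"),
                np.argsort(out.iloc[:, j].to_numpy(), kind="stable"),
            )


class TestMeanScalePatterns:
    def test_constant_tag_gives_flat_pattern(self):
        df, groups = toy_matrix([[4, 4, 4, 4]], groups=["A", "A", "B", "B"])
        pat = tp.mean_scale_patterns(df, groups)
        assert np.allclose(pat.to_numpy(), 1.0)

    def test_hand_worked_group_means(self):
        df, groups = toy_matrix([[2, 2, 4, 4]], groups=["A", "A", "B", "B"])
        pat = tp.mean_scale_patterns(df, groups, ("A", "B"))
        assert np.allclose(pat.to_numpy(), [[2 / 3, 4 / 3]])

    def test_rows_average_to_one(self, rng):
        groups = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 2,
                           index=[f"s{j}" for j in range(8)])
        df = pd.DataFrame(rng.uniform(1, 50, (25, 8)), columns=groups.index)
        pat = tp.mean_scale_patterns(df, groups)
        assert np.allclose(pat.mean(axis=1), 1.0)

    def test_zero_grand_mean_dropped_with_warning(self):
        df, groups = toy_matrix([[0, 0, 0, 0], [1, 1, 2, 2]],
                                groups=["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="zero grand mean"):
            pat = tp.mean_scale_patterns(df, groups)
        assert list(pat.index) == ["t1"]


def first_split_oracle(patterns):
    """Exhaustive 2-partition search: among all non-trivial bipartitions
    minimize the larger within-part diameter (1 - Pearson)."""
    x = patterns.to_numpy()
    D = 1 - np.corrcoef(x)
    np.fill_diagonal(D, 0)
    n = len(x)
    best, best_score = None, np.inf

    def diam(idx):
        if len(idx) < 2:
            return 0.0
        return D[np.ix_(idx, idx)].max()

    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), r):
            rest = [i for i in range(n) if i not in combo]
            score = max(diam(list(combo)), diam(rest))
            if score < best_score:
                best_score = score
                best = frozenset(combo)
    return best


class TestDiana:
    def two_archetype_patterns(self, rng, n_per=3):
        a = np.array([2.0, 2.0, 0.5, 0.2, 0.2, 0.2, 0.4, 0.5])
        b = np.array([0.2, 0.3, 0.3, 0.5, 0.6, 2.2, 2.0, 1.9])
        rows = []
        for base in (a, b):
            for _ in range(n_per):
                rows.append(base * (1 + rng.normal(0, 0.02, len(base))))
        df = pd.DataFrame(rows, index=[f"t{i}" for i in range(2 * n_per)])
        return df.div(df.mean(axis=1), axis=0)

    def test_first_split_matches_exhaustive_partition_oracle(self, rng):
        pat = self.two_archetype_patterns(rng)
        tree = tp.diana_cluster(pat)
        got = frozenset(tree.root.left.members)
        want = first_split_oracle(pat)
        assert got == want or frozenset(tree.root.right.members) == want

    def test_two_archetypes_cut_to_two_clusters(self, rng):
        pat = self.two_archetype_patterns(rng)
        assign = tp.cut_tree_longest_branch(tp.diana_cluster(pat))
        assert assign.nunique() == 2
        assert assign.iloc[:3].nunique() == 1 and assign.iloc[3:].nunique() == 1

    def test_identical_patterns_single_zero_diameter_cluster(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]] * 4)
        tree = tp.diana_cluster(df)
        assert tree.root.is_terminal and tree.root.height == 0.0
        assign = tp.cut_tree_longest_branch(tree)
        assert assign.nunique() == 1

    def test_heights_monotone_root_to_leaves(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (20, 8)))
        tree = tp.diana_cluster(df)

        def walk(node):
            if node.is_terminal:
                return
            for child in (node.left, node.right):
                assert child.height <= node.height + 1e-12
                walk(child)

        walk(tree.root)

    def test_constant_pattern_excluded_with_warning(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (5, 6)))
        df.iloc[2] = 3.0
        with pytest.warns(UserWarning, match="constant-pattern"):
            tree = tp.diana_cluster(df)
        assert len(tree.labels) == 4

    def test_planted_six_archetypes_recovered(self):
        matrix, truth = tp.generate_tag_counts(tp.TagSimConfig(seed=17, n_tags=240, n_de=240, n_null=0, biased_tag_fraction=0.0))
        tpm = tp.counts_to_tpm(matrix)
        reps = [b for _, b in matrix.replicate_pairs()]
        pat = tp.mean_scale_patterns(
            tpm.drop(columns=reps), matrix.groups().drop(reps), tp.DEFAULT_GROUP_ORDER
        )
        assign = tp.cut_tree_longest_branch(tp.diana_cluster(pat))
        score = tp.score_cluster_recovery(truth.archetype, assign)
        assert score["n_clusters"] == 6
        assert score["ari"] > 0.9

    def test_single_tag_rejected(self):
        with pytest.raises(ConfigurationError):
            tp.diana_cluster(pd.DataFrame([[1.0, 2.0]]))


class TestTagCountMatrix:
    def test_asymmetric_replicates_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2]}, index=["t0"])
        meta = pd.DataFrame(
            {"group": ["A", "A"], "platform": ["A", "B"],
             "replicate_partner": ["b", None]},
            index=["a", "b"],
        )
        with pytest.raises(ConfigurationError):
            tp.TagCountMatrix(counts, meta)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"a": [-1], "b": [2]}, index=["t0"])
        meta = pd.DataFrame({"group": ["A", "A"], "platform": ["A", "A"],
                             "replicate_partner": [None, None]}, index=["a", "b"])
        with pytest.raises(ConfigurationError):
            tp.TagCountMatrix(counts, meta)

    def test_round_trip_through_tsv(self, tmp_path):
        matrix, _ = tp.generate_tag_counts(tp.TagSimConfig(seed=5, n_tags=20, n_de=12, n_null=2))
        matrix.to_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = tp.TagCountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert back.counts.equals(matrix.counts)
        assert back.replicate_pairs() == matrix.replicate_pairs()


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_quantile_normalization_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.uniform(0, 50, (15, 4)))
    once = tp.full_quantile_normalize(df)
    assert np.allclose(once, tp.full_quantile_normalize(once), atol=1e-10)
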