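"""Paired pre/post comparison: turnover, fold changes, deltas, rank-sum test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tcrrep import (
    Clonotype,
    ClonotypeTable,
    ComparisonError,
    compare_repertoires,
    diversity_delta,
    fold_changes,
    overlap_partition,
    preset_config,
    rank_sum_test,
    simulate_repertoire,
    summarize,
)


def table_from_counts(counts: dict, sample_id="s"):
    """Counts keyed by (v, j, junction) -> productive-flagged-off table."""
    clones = [
        Clonotype(v, j, junction, None, False, n)
        for (v, j, junction), n in counts.items()
    ]
    total = sum(counts.values())
    return ClonotypeTable(sample_id, clones, total, total, 0)


K = lambda name: ("TRBV18", "TRBJ2-7", name)  # noqa: E731


class TestOverlapPartition:
    def test_identical_tables(self):
        t = table_from_counts({K("TGCGCATTC"): 5, K("TGCAAATTC"): 2})
        shared, gained, lost = overlap_partition(t, t)
        assert gained == lost == set()
        assert shared == {K("TGCGCATTC"), K("TGCAAATTC")}

    def test_disjoint_tables(self):
        a = table_from_counts({K("TGCGCATTC"): 5})
        b = table_from_counts({K("TGCAAATTC"): 5})
        shared, gained, lost = overlap_partition(a, b)
        assert shared == set()
        assert gained == {K("TGCAAATTC")} and lost == {K("TGCGCATTC")}

    def test_set_algebra(self):
        pre = table_from_counts({K("A" * 6): 1, K("C" * 6): 1, K("G" * 6): 1})
        post = table_from_counts({K("C" * 6): 1, K("G" * 6): 1, K("T" * 6): 1})
        shared, gained, lost = overlap_partition(pre, post)
        assert shared == {K("C" * 6), K("G" * 6)}
        assert lost == {K("A" * 6)} and gained == {K("T" * 6)}
        assert len(shared) + len(gained) + len(lost) == 4  # |pre U post|

    def test_amino_acid_keys_rejected(self):
        bad = table_from_counts({("TRBV18", "TRBJ2-7", "CASSF"): 1})
        good = table_from_counts({K("TGCGCATTC"): 1})
        with pytest.raises(ComparisonError, match="nucleotide"):
            overlap_partition(bad, good)


class TestFoldChanges:
    def test_highest_expansion_clone_fold(self):
        # published pre/post frequencies of a top post-treatment clonotype
        pre = table_from_counts({K("TGCGCATTC"): 8_880_571, K("TGCAAATTC"): 991_119_429})
        post = table_from_counts({K("TGCGCATTC"): 61_386_633, K("TGCAAATTC"): 938_613_367})
        df = fold_changes(pre, post, productive_only=False)
        row = df[df.junction == "TGCGCATTC"].iloc[0]
        assert row.pre_freq == pytest.approx(0.008880571, abs=1e-12)
        assert row.post_freq == pytest.approx(0.061386633, abs=1e-12)
        assert row.fold == pytest.approx(0.061386633 / 0.008880571, rel=1e-12)
        assert row.fold == pytest.approx(6.912, abs=1e-3)
        assert not row.censored

    def test_equal_frequencies_fold_one(self):
        t = table_from_counts({K("TGCGCATTC"): 3, K("TGCAAATTC"): 7})
        df = fold_changes(t, t, productive_only=False)
        assert np.allclose(df.fold, 1.0)

    def test_gained_clone_censored_at_pseudo_floor(self):
        pre = table_from_counts({K("TGCAAATTC"): 100})
        post = table_from_counts(
            {K("TGCAAATTC"): 992_810_333, K("TGCGCATTC"): 7_189_667}
        )
        df = fold_changes(pre, post, pseudo=1e-6, productive_only=False)
        row = df[df.junction == "TGCGCATTC"].iloc[0]
        assert row.censored and row.status == "gained"
        assert row.post_freq == pytest.approx(0.007189667, abs=1e-12)
        assert row.fold == pytest.approx(7.189667e3, rel=1e-9)

    def test_default_pseudo_is_one_read(self):
        pre = table_from_counts({K("TGCAAATTC"): 500})
        post = table_from_counts({K("TGCAAATTC"): 400, K("TGCGCATTC"): 100})
        df = fold_changes(pre, post, productive_only=False)
        row = df[df.junction == "TGCGCATTC"].iloc[0]
        assert row.pre_freq == pytest.approx(1 / 500)

    def test_nonpositive_pseudo_rejected(self):
        t = table_from_counts({K("TGCAAATTC"): 5})
        with pytest.raises(ComparisonError):
            fold_changes(t, t, pseudo=0.0)


class TestDiversityDelta:
    def test_identical_summaries_zero_delta(self):
        t = table_from_counts({K("TGCGCATTC"): 3, K("TGCAAATTC"): 7})
        s = summarize(t, productive_only=False)
        d = diversity_delta(s, s)
        assert d.d_inverse_simpson == 0 and d.d_shannon == 0
        assert d.inverse_simpson_ratio == 1 and d.shannon_ratio == 1

    def test_uniform_expansion_delta(self):
        pre = table_from_counts({K(f"{'GCA' * i}TGCTTC"): 10 for i in range(10)})
        post = table_from_counts({K(f"{'GCA' * i}TGCTTC"): 10 for i in range(100)})
        d = diversity_delta(
            summarize(pre, productive_only=False), summarize(post, productive_only=False)
        )
        assert d.d_inverse_simpson == pytest.approx(90.0, abs=1e-9)

    def test_preset_truths_increase_diversity(self):
        pre = simulate_repertoire(preset_config("pre_like", seed=3, n_clonotypes=400))
        post = simulate_repertoire(preset_config("post_like", seed=3, n_clonotypes=400))
        s_pre = summarize(pre.to_clonotype_table("pre"))
        s_post = summarize(post.to_clonotype_table("post"))
        assert diversity_delta(s_pre, s_post).d_inverse_simpson > 0


class TestRankSumTest:
    def test_small_exact_example(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_degenerate_identical_groups(self):
        res = rank_sum_test([5, 5, 5], [5, 5])
        assert res.degenerate and res.p_value == 1.0

    def test_exact_vs_normal_agreement(self):
        a, b = list(range(1, 7)), list(range(7, 13))
        exact = rank_sum_test(a, b)
        assert exact.method == "exact"
        approx = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert abs(exact.p_value - approx.pvalue) < 0.02

    def test_normal_branch_above_limit(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        res = rank_sum_test(a, b)
        assert res.method == "normal"
        assert 0 <= res.p_value <= 1

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_a = int(rng.integers(1, 6))
            n_b = int(rng.integers(1, 13 - n_a - 1)) if n_a < 11 else 1
            pool = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pool[:n_a], pool[n_a:]
            mine = rank_sum_test(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @given(
        st.lists(st.integers(0, 4), min_size=1, max_size=5),
        st.lists(st.integers(0, 4), min_size=1, max_size=5),
    )
    def test_exact_matches_permutation_oracle(self, a, b):
        # independent oracle: U counted pairwise over all relabelings
        pooled = a + b
        n, n_a = len(pooled), len(a)

        def u_of(group_a, group_b):
            return sum(
                1.0 if x > y else (0.5 if x == y else 0.0)
                for x in group_a
                for y in group_b
            )

        mu = n_a * (n - n_a) / 2.0
        dev = abs(u_of(a, b) - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n), n_a):
            grp_a = [pooled[i] for i in idx]
            grp_b = [pooled[i] for i in range(n) if i not in idx]
            total += 1
            if abs(u_of(grp_a, grp_b) - mu) >= dev - 1e-12:
                hits += 1
        res = rank_sum_test(a, b)
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ComparisonError):
            rank_sum_test([], [1.0])


class TestComparePipelines:
    def _paired_tables(self, seed):
        pre_t = simulate_repertoire(preset_config("pre_like", seed=seed, n_clonotypes=500))
        post_t = simulate_repertoire(preset_config("post_like", seed=seed + 1, n_clonotypes=500))
        rng = np.random.default_rng([seed, 7])
        pre = pre_t.to_clonotype_table("pre", pre_t.sample_counts(30_000, rng))
        post = post_t.to_clonotype_table("post", post_t.sample_counts(30_000, rng))
        return pre, post

    def test_partition_conservation(self):
        pre, post = self._paired_tables(31)
        comp = compare_repertoires(pre, post)
        union = {c.key for c in pre.clonotypes} | {c.key for c in post.clonotypes}
        assert len(comp.shared) + len(comp.gained) + len(comp.lost) == len(union)

    def test_antisymmetry(self):
        pre, post = self._paired_tables(37)
        fwd = compare_repertoires(pre, post)
        rev = compare_repertoires(post, pre)
        assert rev.diversity.d_inverse_simpson == pytest.approx(
            -fwd.diversity.d_inverse_simpson, abs=1e-9
        )
        assert rev.diversity.d_shannon == pytest.approx(-fwd.diversity.d_shannon, abs=1e-9)
        assert rev.gained == fwd.lost and rev.lost == fwd.gained
        # fold changes invert on the shared set
        fwd_shared = fwd.fold_table[fwd.fold_table.status == "shared"]
        rev_map = {
            (r.v_call, r.j_call, r.junction): r.fold
            for r in rev.fold_table.itertuples()
            if r.status == "shared"
        }
        for r in fwd_shared.itertuples():
            assert rev_map[(r.v_call, r.j_call, r.junction)] == pytest.approx(
                1.0 / r.fold, rel=1e-9
            )

    def test_headline_direction_on_presets(self):
        pre, post = self._paired_tables(41)
        comp = compare_repertoires(pre, post)
        assert comp.diversity.d_inverse_simpson > 0
        assert comp.post_summary.max_clone_freq < comp.pre_summary.max_clone_freq
        pre_above = comp.pre_summary.above_threshold[0.01][0]
        post_above = comp.post_summary.above_threshold[0.01][0]
        assert post_above < pre_above

    def test_highest_expansion_from_shared_clones(self):
        pre = table_from_counts({K("TGCGCATTC"): 10, K("TGCAAATTC"): 90})
        post = table_from_counts(
            {K("TGCGCATTC"): 60, K("TGCAAATTC"): 30, K("TGCCCCTTC"): 10}
        )
        comp = compare_repertoires(pre, post, productive_only=False)
        assert comp.highest_expansion["junction"] == "TGCGCATTC"
        assert comp.highest_expansion["fold"] == pytest.approx(6.0)
        assert comp.highest_expansion_censored["junction"] == "TGCCCCTTC"
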