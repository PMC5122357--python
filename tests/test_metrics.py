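"""Diversity indices, clonality summaries, spectratypes and V-J usage."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tcrrep import (
    Clonotype,
    ClonotypeTable,
    MetricsError,
    SimulationConfig,
    clones_above_threshold,
    clonotype_frequencies,
    inverse_simpson,
    inverse_simpson_unbiased,
    marker_bias,
    shannon,
    simulate_repertoire,
    spectratype,
    summarize,
    top_n_cumulative,
    usage_matrix,
)


simplex = st.lists(st.floats(0.01, 1.0), min_size=1, max_size=30).map(
    lambda xs: np.array(xs) / np.sum(xs)
)


class TestDiversityIndices:
    def test_uniform_identities(self):
        for k in (1, 2, 7, 100):
            p = np.full(k, 1.0 / k)
            assert inverse_simpson(p) == pytest.approx(k, abs=1e-12)
            assert shannon(p) == pytest.approx(math.log(k), abs=1e-12)

    def test_single_clone_bounds(self):
        assert inverse_simpson([1.0]) == 1.0
        assert shannon([1.0]) == 0.0

    def test_direct_evaluation(self):
        p = [0.5, 0.25, 0.25]
        assert inverse_simpson(p) == pytest.approx(1 / 0.375, abs=1e-12)
        assert shannon(p) == pytest.approx(
            -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25)), abs=1e-12
        )
        assert shannon(p) == pytest.approx(1.0397, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(MetricsError):
            inverse_simpson([])
        with pytest.raises(MetricsError):
            shannon([])

    def test_unbiased_simpson_matches_plugin_at_scale(self):
        counts = np.array([5000, 2500, 2500])
        plug = inverse_simpson(counts / counts.sum())
        unbiased = inverse_simpson_unbiased(counts)
        assert abs(plug - unbiased) / plug < 1e-3

    @given(simplex)
    def test_oracle_equivalence(self, p):
        # naive direct-summation oracles
        simpson_oracle = 1.0 / sum(x * x for x in p)
        shannon_oracle = -sum(x * math.log(x) for x in p if x > 0)
        assert inverse_simpson(p) == pytest.approx(simpson_oracle, abs=1e-12)
        assert shannon(p) == pytest.approx(shannon_oracle, abs=1e-12)

    @given(simplex)
    def test_bounds(self, p):
        k = len(p)
        assert 1.0 - 1e-9 <= inverse_simpson(p) <= k + 1e-9
        assert -1e-12 <= shannon(p) <= math.log(k) + 1e-9

    @given(simplex)
    def test_uniform_maximizes_both(self, p):
        k = len(p)
        uniform = np.full(k, 1.0 / k)
        assert inverse_simpson(uniform) >= inverse_simpson(p) - 1e-9
        assert shannon(uniform) >= shannon(p) - 1e-9

    @given(simplex)
    def test_label_invariance(self, p):
        rng = np.random.default_rng(0)
        q = rng.permutation(p)
        assert inverse_simpson(q) == pytest.approx(inverse_simpson(p), abs=1e-12)
        assert shannon(q) == pytest.approx(shannon(p), abs=1e-12)


class TestClonalitySummaries:
    def test_top_n(self):
        p = [0.5, 0.25, 0.15, 0.10]
        assert top_n_cumulative(p, 2) == pytest.approx(0.75)
        assert top_n_cumulative(p, 10) == pytest.approx(1.0)

    def test_clones_above_threshold(self):
        p = [0.5, 0.25, 0.15, 0.10]
        count, cum = clones_above_threshold(p, 0.2)
        assert (count, cum) == (2, pytest.approx(0.75))
        assert clones_above_threshold(p, 0.99) == (0, 0.0)

    def test_threshold_is_strict(self):
        count, _ = clones_above_threshold([0.5, 0.3, 0.2], 0.2)
        assert count == 2  # the clone at exactly 0.2 is excluded


def _sim_table(seed, n=300, depth=20_000, **kw):
    cfg = SimulationConfig(n_clonotypes=n, seed=seed, **kw)
    truth = simulate_repertoire(cfg)
    rng = np.random.default_rng([seed, 99])
    return truth, truth.to_clonotype_table("s", truth.sample_counts(depth, rng))


class TestTableMetrics:
    def test_frequencies_from_counts(self, toy_set):
        _, table = _sim_table(101, segment_set=toy_set)
        f, clones = clonotype_frequencies(table, productive_only=False)
        assert abs(f.sum() - 1) < 1e-12
        assert np.all(np.diff(f) <= 0)
        assert len(f) == len(clones) == len(table)

    def test_merge_invariance(self, toy_set):
        # doubling every count leaves all frequency-based metrics unchanged
        _, table = _sim_table(103, segment_set=toy_set)
        doubled = ClonotypeTable(
            sample_id="s2",
            clonotypes=[
                Clonotype(c.v_call, c.j_call, c.junction_nt, c.junction_aa,
                          c.productive, 2 * c.read_count)
                for c in table.clonotypes
            ],
            total_reads=2 * table.total_reads,
            assigned_reads=2 * table.assigned_reads,
            unassigned_reads=2 * table.unassigned_reads,
        )
        s1 = summarize(table, productive_only=False)
        s2 = summarize(doubled, productive_only=False)
        assert s2.inverse_simpson == pytest.approx(s1.inverse_simpson, abs=1e-12)
        assert s2.shannon == pytest.approx(s1.shannon, abs=1e-12)
        assert s2.max_clone_freq == pytest.approx(s1.max_clone_freq, abs=1e-15)

    def test_spectratype_read_weighted(self, toy_set):
        v, j = "TRBV18", "TRBJ2-7"
        clones = [
            Clonotype(v, j, "TGCGCAGCAGCAGCATTC" + "GCAGCAGCAGCAGCAGCAGCA", None, False, 1),  # 39
            Clonotype(v, j, "TGCACAGCAGCAGCATTC" + "GCAGCAGCAGCAGCAGCAGCA", None, False, 1),  # 39
            Clonotype(v, j, "TGCGCAGCAGCAGCATTC" + "GCAGCAGCAGCAGCAGCAGCAGCA", None, False, 1),  # 42
        ]
        table = ClonotypeTable("s", clones, 3, 3, 0)
        prof = spectratype(table, productive_only=False)
        assert prof.fractions == pytest.approx({39: 2 / 3, 42: 1 / 3})
        assert prof.modal_length == 39

    def test_productive_spectratype_in_frame(self, toy_set):
        _, table = _sim_table(107, segment_set=toy_set)
        prof = spectratype(table, productive_only=True)
        assert all(length % 3 == 0 for length in prof.fractions)
        assert sum(prof.fractions.values()) == pytest.approx(1.0)

    def test_usage_matrix_single_clone(self):
        table = ClonotypeTable(
            "s", [Clonotype("TRBV18", "TRBJ2-7", "TGCGCATTC", None, False, 10)], 10, 10, 0
        )
        usage = usage_matrix(table, productive_only=False)
        assert usage.matrix.loc["TRBV18", "TRBJ2-7"] == 1.0
        assert usage.v_usage.sum() == pytest.approx(1.0)
        assert usage.j_usage.sum() == pytest.approx(1.0)

    def test_usage_marginals_sum_to_one(self, toy_set):
        _, table = _sim_table(109, segment_set=toy_set)
        usage = usage_matrix(table, productive_only=False, segment_set=toy_set)
        assert usage.matrix.values.sum() == pytest.approx(1.0)
        assert usage.v_usage.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(usage.matrix.sum(axis=1).values, usage.v_usage.values)

    def test_uniform_segment_usage(self, toy_set):
        # uniform V/J choice with an even abundance model: every V-J cell
        # close to 1/(nV*nJ) at depth
        truth, table = _sim_table(
            113, n=2000, depth=100_000, segment_set=toy_set,
            abundance_model="even", require_productive=True,
        )
        usage = usage_matrix(table, productive_only=True, segment_set=toy_set)
        n_cells = usage.matrix.size
        se = np.sqrt((1 / n_cells) * (1 - 1 / n_cells) / 2000)
        assert np.all(np.abs(usage.matrix.values - 1 / n_cells) < 4 * se)


class TestMarkerBias:
    def _usage_from_marginals(self, marginals):
        clones = [
            Clonotype(v, "TRBJ2-7", "TGC" + "GCA" * i + "TTC", None, False, n)
            for i, (v, n) in enumerate(marginals.items())
        ]
        total = sum(marginals.values())
        table = ClonotypeTable("s", clones, total, total, 0)
        return usage_matrix(table, productive_only=False)

    def test_arithmetic(self):
        usage = self._usage_from_marginals(
            {"TRBV5-4": 2, "TRBV7-2": 3, "TRBV18": 1, "TRBV7-9": 3, "TRBV28": 91}
        )
        bias = marker_bias(usage)
        assert bias.defined
        assert bias.value == pytest.approx(2.0)

    def test_equal_markers_give_three(self):
        usage = self._usage_from_marginals(
            {"TRBV5-4": 5, "TRBV7-2": 5, "TRBV18": 5, "TRBV7-9": 5}
        )
        assert marker_bias(usage).value == pytest.approx(3.0)

    def test_zero_cd8_marker_flagged_not_raised(self, toy_set):
        usage = self._usage_from_marginals(
            {"TRBV5-4": 2, "TRBV7-2": 3, "TRBV18": 1}
        )
        # include TRBV7-9 in the gene space with zero usage
        usage.matrix.loc["TRBV7-9"] = 0.0
        usage.v_usage = usage.matrix.sum(axis=1)
        bias = marker_bias(usage)
        assert not bias.defined
        assert math.isnan(bias.value)

    def test_missing_marker_named(self):
        usage = self._usage_from_marginals({"TRBV5-4": 1, "TRBV7-2": 1, "TRBV18": 1})
        with pytest.raises(MetricsError, match="TRBV7-9"):
            marker_bias(usage)
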