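"""Abundance, richness, core virome, shared vOTUs, study clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster

from rvkit.ecology import (ReadAlignment, classify_core, cluster_studies,
                           filter_read_alignments, richness_per_gbp,
                           shared_votus, trimmed_mean_coverage)
from _oracles import average_linkage_merges


class TestReadFilter:
    @pytest.mark.parametrize("pid,frac,kept", [
        (96.0, 0.80, True),
        (94.9, 0.99, False),
        (99.0, 0.74, False),
        (95.0, 0.75, True),  # both boundaries inclusive
    ])
    def test_identity_and_aligned_fraction_thresholds(self, pid, frac, kept):
        aln = ReadAlignment("r1", "v1", pid, frac)
        assert (filter_read_alignments([aln]) == [aln]) is kept


class TestTrimmedMean:
    def test_constant_vector_is_its_own_mean(self):
        assert trimmed_mean_coverage(np.full(100, 7)) == pytest.approx(7.0)

    def test_worked_twenty_position_example(self):
        """18 positions at depth 5, one spike of 100, one zero: the single
        highest and lowest positions are trimmed, leaving a mean of 5."""
        depth = np.array([5] * 18 + [100, 0])
        assert trimmed_mean_coverage(depth) == pytest.approx(5.0)

    def test_covered_fraction_gate(self):
        depth = np.array([0] * 60 + [10] * 40)
        assert trimmed_mean_coverage(depth) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean_coverage(np.array([]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(1, 500), min_size=20, max_size=200),
           st.integers(1, 50))
    def test_translation_equivariance_and_permutation_invariance(self, depths, c):
        depth = np.array(depths)
        base = trimmed_mean_coverage(depth)
        assert trimmed_mean_coverage(depth + c) == pytest.approx(base + c)
        rng = np.random.default_rng(0)
        assert trimmed_mean_coverage(rng.permutation(depth)) == pytest.approx(base)


class TestRichness:
    def test_per_gbp_normalization(self):
        assert richness_per_gbp(500, 2_000_000_000) == pytest.approx(250.0)

    def test_zero_detected(self):
        assert richness_per_gbp(0, 10**9) == 0.0

    def test_doubling_bases_halves_richness(self):
        assert richness_per_gbp(100, 2 * 10**9) == \
            pytest.approx(richness_per_gbp(100, 10**9) / 2)

    def test_zero_bases_rejected(self):
        with pytest.raises(ValueError):
            richness_per_gbp(5, 0)


def _matrix(rows, samples):
    return pd.DataFrame(rows, index=[f"v{i}" for i in range(len(rows))],
                        columns=samples)


class TestClassifyCore:
    SAMPLES = [f"{g}{i}" for g in "ABC" for i in range(4)]
    GROUPS = {s: s[0] for s in SAMPLES}

    def test_single_occurrence_is_individualized(self):
        m = _matrix([[1] + [0] * 11], self.SAMPLES)
        res = classify_core(m, self.GROUPS)
        assert res.table.loc["v0", "class"] == "individualized"

    def test_exactly_half_is_not_core_under_strict_rule(self):
        m = _matrix([[1, 1, 0, 0] + [0] * 8], self.SAMPLES)
        res = classify_core(m, self.GROUPS)
        assert not res.table.loc["v0", "core_A"]
        relaxed = classify_core(m, self.GROUPS, strict=False)
        assert relaxed.table.loc["v0", "core_A"]

    def test_global_core_in_triple_intersection(self):
        m = _matrix([[1] * 12, [1, 1, 1, 0] + [0] * 8], self.SAMPLES)
        res = classify_core(m, self.GROUPS)
        assert res.table.loc["v0", "global_core"]
        assert res.table.loc["v0", "class"] == "three_levels"
        assert res.venn_counts["A+B+C"] == 1
        assert res.table.loc["v1", "class"] == "one_level"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(12)
        m = _matrix(rng.integers(0, 2, size=(30, 12)), self.SAMPLES)
        sets = [classify_core(m, self.GROUPS, core_threshold=t).core_sets
                for t in (0.7, 0.5, 0.3)]
        for low, high in zip(sets[1:], sets):
            for g in low:
                assert high[g] <= low[g]  # lowering the threshold only grows

    def test_unlabeled_sample_rejected(self):
        m = _matrix([[1, 0]], ["s1", "s2"])
        with pytest.raises(ValueError):
            classify_core(m, {"s1": "A"})


class TestSharedVotus:
    def test_identical_and_disjoint_rows(self):
        m = pd.DataFrame({"s1": [1, 1, 1, 0], "s2": [1, 1, 1, 0],
                          "s3": [0, 0, 0, 1]})
        out = shared_votus(m, [("s1", "s2"), ("s1", "s3")], ["same", "diff"])
        assert list(out.shared_votus) == [3, 0]

    def test_matches_brute_force_intersections(self):
        rng = np.random.default_rng(21)
        m = pd.DataFrame(rng.integers(0, 2, (10, 10)),
                         columns=[f"s{i}" for i in range(10)])
        pairs = [(f"s{i}", f"s{j}") for i in range(10) for j in range(i + 1, 10)]
        out = shared_votus(m, pairs, ["x"] * len(pairs))
        for (a, b), count in zip(pairs, out.shared_votus):
            expected = sum(1 for k in range(10)
                           if m.loc[k, a] == 1 and m.loc[k, b] == 1)
            assert count == expected

    def test_symmetric_in_pair_order(self):
        rng = np.random.default_rng(22)
        m = pd.DataFrame(rng.integers(0, 2, (8, 4)),
                         columns=list("wxyz"))
        ab = shared_votus(m, [("w", "x")], ["l"]).shared_votus[0]
        ba = shared_votus(m, [("x", "w")], ["l"]).shared_votus[0]
        assert ab == ba


class TestClusterStudies:
    def _matrix(self, presence_by_study, per_study=13):
        cols, data, labels = [], [], {}
        for study, row in presence_by_study.items():
            for k in range(per_study):
                name = f"{study}_{k}"
                cols.append(name)
                data.append(row)
                labels[name] = study
        m = pd.DataFrame(np.array(data).T, columns=cols)
        return m, labels

    def test_study_with_twelve_samples_excluded(self):
        m, labels = self._matrix({"s1": [1, 0], "s2": [0, 1], "s3": [1, 1]})
        small = [c for c in m.columns if labels[c] == "s3"][0]
        m = m.drop(columns=[c for c in m.columns
                            if labels[c] == "s3" and c != small])
        labels = {c: labels[c] for c in m.columns}
        result = cluster_studies(m, labels)
        assert result.studies == ["s1", "s2"]  # s3 has 1 <= 12 samples

    def test_identical_studies_merge_first(self):
        m, labels = self._matrix({
            "a": [1, 1, 0, 0], "b": [1, 1, 0, 0], "c": [0, 0, 1, 1]})
        result = cluster_studies(m, labels)
        first = result.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # a and b
        assert first[2] == pytest.approx(0.0)

    def test_matches_average_linkage_oracle(self):
        m, labels = self._matrix({
            "a": [1, 1, 1, 0, 0, 0], "b": [1, 1, 0, 0, 0, 1],
            "c": [0, 0, 0, 1, 1, 1], "d": [0, 0, 1, 1, 1, 0]})
        result = cluster_studies(m, labels)
        oracle = average_linkage_merges(result.dissimilarity.to_numpy())
        for row, (left, right, height) in zip(result.linkage, oracle):
            assert row[2] == pytest.approx(height)
        # identical partitions at the 2-cluster cut
        cut = fcluster(result.linkage, 2, criterion="maxclust")
        partition = {frozenset(np.where(cut == c)[0]) for c in set(cut)}
        oracle_partition = {oracle[-1][0], oracle[-1][1]}
        assert partition == oracle_partition

    def test_fewer_than_two_studies_is_an_error(self):
        m, labels = self._matrix({"a": [1, 0]}, per_study=13)
        with pytest.raises(ValueError):
            cluster_studies(m, labels)
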