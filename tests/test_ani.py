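"""ANI computation and greedy vOTU clustering."""

import random

import numpy as np
import pytest

from rvkit.ani import (AlignmentBlock, Contig, PairwiseANI, VOtu, admit_contigs,
                       cluster_votus, compute_pairwise_ani, local_align,
                       reverse_complement, select_representative)
from rvkit.synth import mutate_sequence, random_sequence
from _oracles import brute_force_greedy_clusters, make_random_ani_instance, \
    nw_identity


def _block(q="q", s="s", pid=100.0, length=100, qs=1, qe=None, ss=1, se=None):
    qe = qe if qe is not None else qs + length - 1
    se = se if se is not None else ss + length - 1
    return AlignmentBlock(query_id=q, subject_id=s, percent_identity=pid,
                          alignment_length=length, query_start=qs, query_end=qe,
                          subject_start=ss, subject_end=se)


class TestLocalAlign:
    def test_self_alignment_full_identity(self):
        seq = random_sequence(800, np.random.default_rng(0))
        a = Contig(id="a", sequence=seq)
        blocks = local_align(a, a)
        top = max(blocks, key=lambda b: b.alignment_length)
        assert top.percent_identity == 100.0
        assert top.alignment_length == 800
        assert (top.query_start, top.query_end) == (1, 800)
        assert (top.subject_start, top.subject_end) == (1, 800)

    def test_reverse_complement_minus_strand(self):
        seq = random_sequence(600, np.random.default_rng(1))
        a = Contig(id="a", sequence=seq)
        b = Contig(id="b", sequence=reverse_complement(seq))
        blocks = local_align(a, b)
        top = max(blocks, key=lambda bl: bl.alignment_length)
        assert top.alignment_length == 600
        assert top.percent_identity == 100.0
        assert top.is_minus
        assert (top.subject_start, top.subject_end) == (600, 1)

    @pytest.mark.parametrize("divergence", [0.01, 0.03])
    def test_identity_matches_global_aligner(self, divergence):
        """Length-weighted block identity tracks an independent NW aligner."""
        rng = np.random.default_rng(7)
        seq = random_sequence(1500, rng)
        mut = mutate_sequence(seq, divergence, rng)
        blocks = local_align(Contig(id="a", sequence=seq),
                             Contig(id="b", sequence=mut))
        total = sum(b.alignment_length for b in blocks)
        weighted = sum(b.percent_identity * b.alignment_length for b in blocks) / total
        assert weighted == pytest.approx(nw_identity(seq, mut), abs=1.0)

    def test_small_seed_rejected(self):
        a = Contig(id="a", sequence="ACGT" * 50)
        with pytest.raises(ValueError):
            local_align(a, a, k=10)


class TestComputePairwiseANI:
    def test_single_block(self):
        p = compute_pairwise_ani([_block(pid=96.0, length=8000)], 10000, 10000)
        assert p.ani == pytest.approx(96.0)
        assert p.af_query == pytest.approx(80.0)
        assert p.af_subject == pytest.approx(80.0)

    def test_weighted_mean_over_disjoint_blocks(self):
        blocks = [_block(pid=100.0, length=4000, qs=1, ss=1),
                  _block(pid=90.0, length=1000, qs=5001, ss=5001)]
        p = compute_pairwise_ani(blocks, 10000, 10000)
        assert p.ani == pytest.approx(98.0)  # (100*4000 + 90*1000) / 5000
        assert p.af_query == pytest.approx(50.0)

    def test_overlapping_blocks_use_interval_union(self):
        blocks = [_block(pid=95.0, length=1000, qs=1, ss=1),
                  _block(pid=95.0, length=1000, qs=501, ss=2001)]
        p = compute_pairwise_ani(blocks, 10000, 10000)
        assert p.af_query == pytest.approx(15.0)  # union 1,500 of 10,000

    def test_out_of_range_block_rejected(self):
        with pytest.raises(ValueError):
            compute_pairwise_ani([_block(length=2000)], 1000, 10000)

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            compute_pairwise_ani([_block(q="a"), _block(q="b")], 1000, 1000)


def _pair(a, b, ani, af=100.0):
    return PairwiseANI(query_id=a, subject_id=b, ani=ani,
                       af_query=af, af_subject=af)


class TestClusterVotus:
    def test_forced_partition(self):
        contigs = [Contig(id="A", _length=20000), Contig(id="B", _length=10000),
                   Contig(id="C", _length=8000)]
        votus = cluster_votus(contigs, [_pair("A", "B", 100.0)])
        clusters = {frozenset(v.member_ids) for v in votus}
        assert clusters == {frozenset({"A", "B"}), frozenset({"C"})}
        rep = {v.representative_id for v in votus if "A" in v.member_ids}
        assert rep == {"A"}  # longer member is representative

    def test_membership_tested_only_against_centroids(self):
        """A transitively linked contig founds its own vOTU when it fails the
        centroid (even while matching a non-centroid member)."""
        contigs = [Contig(id="A", _length=30000), Contig(id="B", _length=20000),
                   Contig(id="C", _length=10000)]
        table = [_pair("A", "B", 96.0, 90.0), _pair("B", "C", 96.0, 90.0),
                 _pair("A", "C", 80.0, 90.0)]
        votus = cluster_votus(contigs, table)
        clusters = {frozenset(v.member_ids) for v in votus}
        assert clusters == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_duplicate_ids_rejected(self):
        contigs = [Contig(id="A", _length=6000), Contig(id="A", _length=7000)]
        with pytest.raises(ValueError):
            cluster_votus(contigs, [])

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            contigs, table = make_random_ani_instance(rng)
            got = {frozenset(v.member_ids)
                   for v in cluster_votus(contigs, table)}
            assert got == brute_force_greedy_clusters(contigs, table)

    def test_permutation_stability(self):
        rng = np.random.default_rng(99)
        contigs, table = make_random_ani_instance(rng, max_n=8)
        expected = {frozenset(v.member_ids) for v in cluster_votus(contigs, table)}
        shuffler = random.Random(5)
        for _ in range(10):
            shuffled = list(contigs)
            shuffler.shuffle(shuffled)
            got = {frozenset(v.member_ids) for v in cluster_votus(shuffled, table)}
            assert got == expected

    def test_centroid_separation_and_partition(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            contigs, table = make_random_ani_instance(rng)
            votus = cluster_votus(contigs, table)
            members = [m for v in votus for m in v.member_ids]
            assert sorted(members) == sorted(c.id for c in contigs)  # partition
            lengths = {c.id: c.length for c in contigs}
            pairs = {tuple(sorted((p.query_id, p.subject_id))): p for p in table}
            reps = [v.representative_id for v in votus]
            for i, a in enumerate(reps):
                for b in reps[i + 1:]:
                    p = pairs.get(tuple(sorted((a, b))))
                    if p is None:
                        continue
                    af = (p.af_query if lengths[p.query_id] < lengths[p.subject_id]
                          else p.af_subject
                          if lengths[p.subject_id] < lengths[p.query_id]
                          else max(p.af_query, p.af_subject))
                    assert not (p.ani >= 95.0 and af >= 85.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            contigs, table = make_random_ani_instance(rng)
            base = len(cluster_votus(contigs, table, 90.0, 70.0))
            for ani_min, af_min in ((95.0, 70.0), (90.0, 85.0), (99.0, 99.0)):
                assert len(cluster_votus(contigs, table, ani_min, af_min)) >= base


class TestRepresentativeSelection:
    def test_length_ranks_before_completeness(self):
        contigs = [Contig(id="long", _length=12000, completeness=50.0),
                   Contig(id="complete", _length=10000, completeness=100.0)]
        votu = VOtu(representative_id="long", member_ids={"long", "complete"})
        assert select_representative(votu, contigs) == "long"

    def test_singleton(self):
        contigs = [Contig(id="only", _length=8000)]
        votu = VOtu(representative_id="only", member_ids={"only"})
        assert select_representative(votu, contigs) == "only"

    def test_full_tie_breaks_lexicographically(self):
        contigs = [Contig(id="b", _length=8000, completeness=90.0),
                   Contig(id="a", _length=8000, completeness=90.0)]
        votu = VOtu(representative_id="b", member_ids={"a", "b"})
        assert select_representative(votu, contigs) == "a"


def test_admission_floor_is_strict():
    contigs = [Contig(id="at", _length=5000), Contig(id="above", _length=5001)]
    assert [c.id for c in admit_contigs(contigs)] == ["above"]
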