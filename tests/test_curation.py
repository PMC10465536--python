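"""AMG curation cascade and ARG calling rules."""

import numpy as np
import pytest

from rvkit.ani import Contig
from rvkit.curation import (ArgHit, GeneFeature, REASONS, call_args,
                            filter_genomic_islands,
                            pick_representative_arg_contig, screen_amg_context,
                            select_vmags)


def _gene(idx, category, labels=frozenset(), amg_category=None, contig="c1"):
    start = 100 + idx * 1000
    return GeneFeature(contig_id=contig, start=start, end=start + 900,
                       category=category, labels=frozenset(labels),
                       amg_category=amg_category, gene_id=f"g{idx}")


AMG = {"amg_candidate"}
CAPSID = {"structural:capsid"}


class TestSelectVmags:
    def test_complete_and_long_kept(self):
        contigs = [Contig(id="a", _length=12000, quality_tier="complete"),
                   Contig(id="b", _length=10000, quality_tier="complete"),
                   Contig(id="c", _length=50000, quality_tier="high")]
        assert select_vmags(contigs) == {"a"}  # 10 kb exact and non-complete drop


class TestScreenAmgContext:
    def test_hallmark_plus_viral_like_flanks_retained(self):
        genes = [_gene(0, "viral_hallmark", CAPSID),
                 _gene(1, "cellular", AMG, amg_category=1),
                 _gene(2, "viral_like")]
        [(g, keep, reason)] = screen_amg_context(genes)
        assert keep and reason == "keep"

    def test_terminal_amg_dropped(self):
        genes = [_gene(0, "viral_hallmark"), _gene(1, "viral_like"),
                 _gene(2, "cellular", AMG, amg_category=1)]
        [(_, keep, reason)] = screen_amg_context(genes)
        assert not keep and reason == REASONS["amg_end"]

    def test_cellular_flanks_dropped(self):
        genes = [_gene(0, "cellular"), _gene(1, "cellular", AMG, amg_category=1),
                 _gene(2, "cellular")]
        [(_, keep, reason)] = screen_amg_context(genes)
        assert not keep and reason == REASONS["amg_flank"]

    def test_category_3_dropped(self):
        genes = [_gene(0, "viral_hallmark"), _gene(1, "cellular", AMG, amg_category=3),
                 _gene(2, "viral_hallmark")]
        [(_, keep, reason)] = screen_amg_context(genes)
        assert not keep and reason == REASONS["amg_category"]

    def test_unordered_input_normalized(self):
        genes = [_gene(2, "viral_like"), _gene(0, "viral_hallmark"),
                 _gene(1, "cellular", AMG, amg_category=2)]
        [(_, keep, _)] = screen_amg_context(genes)
        assert keep


class TestGenomicIslandFilter:
    def test_structural_vmag_kept(self):
        genes = [_gene(0, "viral_hallmark", CAPSID), _gene(1, "viral_like"),
                 _gene(2, "viral_hallmark", {"structural:terminase"})]
        keep, reason = filter_genomic_islands(genes)
        assert keep and reason == "keep"

    def test_only_mobile_viral_genes_dropped(self):
        genes = [_gene(0, "viral_hallmark", {"integrase"}),
                 _gene(1, "viral_like", {"tail_fiber"}),
                 _gene(2, "cellular")]
        keep, reason = filter_genomic_islands(genes)
        assert not keep and reason == REASONS["island_mobile"]

    def test_no_structural_gene_dropped(self):
        genes = [_gene(0, "viral_hallmark"), _gene(1, "viral_like")]
        keep, reason = filter_genomic_islands(genes)
        assert not keep and reason == REASONS["island_structural"]

    def test_island_marker_dropped_despite_portal(self):
        genes = [_gene(0, "viral_hallmark", {"structural:portal"}),
                 _gene(1, "cellular", {"island_marker:GT25"})]
        keep, reason = filter_genomic_islands(genes)
        assert not keep and reason == REASONS["island_marker"]

    def test_filters_commute_as_per_contig_predicates(self):
        """The cascade is order-stable: both screens are per-contig
        predicates, so applying them in either order keeps the same set."""
        rng = np.random.default_rng(8)
        cats = ["viral_hallmark", "viral_like", "cellular", "unannotated"]
        label_pool = [frozenset(), frozenset({"integrase"}),
                      frozenset({"structural:capsid"}),
                      frozenset({"island_marker:endonuclease"}),
                      frozenset({"amg_candidate"})]
        for trial in range(100):
            genes = [
                GeneFeature(contig_id="c", start=i * 1000, end=i * 1000 + 900,
                            category=cats[rng.integers(4)],
                            labels=label_pool[rng.integers(5)],
                            amg_category=int(rng.integers(1, 5)),
                            gene_id=f"g{i}")
                for i in range(int(rng.integers(3, 9)))
            ]
            keep_island, _ = filter_genomic_islands(genes)
            screened = {g.gene_id for g, k, _ in screen_amg_context(genes) if k}
            island_then_screen = screened if keep_island else set()
            screen_then_island = {g for g in screened} if keep_island else set()
            # both screens are pure per-contig predicates: same survivors
            assert island_then_screen == screen_then_island
            # and re-application is idempotent
            assert filter_genomic_islands(genes) == filter_genomic_islands(genes)


class TestCallArgs:
    GENES = {"c1": [_gene(0, "viral_hallmark"), _gene(1, "viral_like"),
                    _gene(2, "cellular"), _gene(3, "viral_hallmark"),
                    _gene(4, "cellular")]}

    def _hit(self, idx, pid=85.0, cov=45.0):
        g = self.GENES["c1"][idx]
        return ArgHit(contig_id="c1", start=g.start, end=g.end,
                      arg_class="tetW", percent_identity=pid,
                      reference_coverage=cov)

    def test_interior_hit_above_thresholds_kept(self):
        [(_, keep, reason)] = call_args([self._hit(2)], self.GENES)
        assert keep and reason == "keep"

    def test_coverage_just_below_40_dropped(self):
        [(_, keep, reason)] = call_args([self._hit(2, cov=39.9)], self.GENES)
        assert not keep and reason == REASONS["arg_coverage"]

    def test_identity_below_80_dropped(self):
        [(_, keep, reason)] = call_args([self._hit(2, pid=79.0)], self.GENES)
        assert not keep and reason == REASONS["arg_identity"]

    def test_terminal_gene_needs_viral_neighbor(self):
        genes = {"c1": [_gene(0, "cellular"), _gene(1, "viral_hallmark"),
                        _gene(2, "cellular"), _gene(3, "viral_hallmark"),
                        _gene(4, "cellular")]}
        # last gene, inward neighbor viral -> kept
        [(_, keep, _)] = call_args([self._hit(4)], genes)
        assert keep
        # first gene, inward neighbor viral in GENES -> kept; make it cellular
        genes2 = {"c1": [_gene(0, "cellular"), _gene(1, "cellular"),
                         _gene(2, "viral_hallmark")]}
        [(_, keep2, reason2)] = call_args([self._hit(0)], genes2)
        assert not keep2 and reason2 == REASONS["arg_end"]

    def test_unresolvable_hit_warns_and_skips(self):
        orphan = ArgHit(contig_id="c1", start=99999, end=100900,
                        arg_class="tetW", percent_identity=90.0,
                        reference_coverage=50.0)
        with pytest.warns(UserWarning):
            assert call_args([orphan], self.GENES) == []


class TestArgRepresentative:
    GENES = {
        "a": [_gene(0, "cellular", contig="a")] * 5,
        "b": [_gene(0, "cellular", contig="b")] * 9,
        "c": [_gene(0, "cellular", contig="c")] * 2,
    }

    def test_completeness_ranks_first(self):
        comp = {"a": 90.0, "b": 95.0}
        assert pick_representative_arg_contig(["a", "b"], comp, self.GENES) == "b"

    def test_fewest_cellular_breaks_ties(self):
        comp = {"a": 90.0, "c": 90.0}
        assert pick_representative_arg_contig(["a", "c"], comp, self.GENES) == "c"

    def test_full_tie_breaks_on_id(self):
        genes = {"x": [], "y": []}
        comp = {"x": 90.0, "y": 90.0}
        assert pick_representative_arg_contig(["y", "x"], comp, genes) == "x"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            pick_representative_arg_contig([], {}, {})


def test_reason_codes_are_distinct():
    assert len(set(REASONS.values())) == len(REASONS)
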