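"""Axis scaling, stem heights, collision-free label placement, full layout."""

import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lollipop.domain_source import DomainFeature, ProteinRecord
from lollipop.layout import (
    LayoutParams,
    build_layout,
    place_labels,
    scale_position,
    stem_heights,
)
from lollipop.mutation_io import read_mutation_table
from lollipop.recurrence import HighlightSet, aggregate, select_highlights

from .conftest import overlapping_pairs

P = LayoutParams()


def profile_from(*rows, gene="TP53"):
    header = "Hugo_Symbol\tSample_ID\tProtein_Change\tMutation_Type"
    table = read_mutation_table(io.StringIO("\n".join([header, *rows]) + "\n"))
    return aggregate(table, gene)


class TestScalePosition:
    def test_endpoints(self):
        assert scale_position(1, 393, P) == pytest.approx(P.axis_x0)
        assert scale_position(393, 393, P) == pytest.approx(P.axis_x1)

    def test_midpoint_odd_length(self):
        mid = scale_position(51, 101, P)
        assert mid == pytest.approx((P.axis_x0 + P.axis_x1) / 2)

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            scale_position(0, 100, P)
        with pytest.raises(ValueError):
            scale_position(101, 100, P)

    @given(st.sets(st.integers(1, 5000), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_monotone(self, positions):
        length = max(positions)
        xs = [scale_position(p, length, P) for p in sorted(positions)]
        assert all(a < b for a, b in zip(xs, xs[1:]))


class TestStemHeights:
    def test_proportionality_exact(self):
        h = stem_heights({175: 4, 273: 2}, P)
        assert h[175] == pytest.approx(2 * h[273], abs=1e-9)
        assert h[175] == pytest.approx(P.stem_max_height, abs=1e-9)

    def test_single_position_full_height(self):
        assert stem_heights({10: 7}, P)[10] == pytest.approx(P.stem_max_height)

    def test_equal_counts_equal_heights(self):
        h = stem_heights({1: 3, 50: 3, 99: 3}, P)
        assert len(set(h.values())) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stem_heights({}, P)


class TestPlaceLabels:
    def test_single_label_centered_above(self):
        [lab] = place_labels([(500.0, 200.0)], [(60.0, 14.0)], P, texts=["A1B (1)"])
        x, y, w, h = lab.box
        assert x + w / 2 == pytest.approx(500.0)
        assert y + h < 200.0  # above the anchor
        assert len(lab.leader) == 2  # straight leader, zero bends
        assert not lab.flagged

    def test_identical_anchors_do_not_overlap(self):
        anchors = [(500.0, 200.0)] * 2
        labels = place_labels(anchors, [(60.0, 14.0)] * 2, P, texts=["A", "B"])
        assert overlapping_pairs([l.box for l in labels]) == []

    def test_twenty_clustered_labels_no_overlap_inside_canvas(self):
        # adversarial: 20 labels anchored within a 40-unit x-span
        anchors = [(480.0 + 2.0 * i, 180.0) for i in range(20)]
        boxes = [(58.0, 14.0)] * 20
        labels = place_labels(anchors, boxes, P, texts=[f"L{i:02d}" for i in range(20)])
        assert overlapping_pairs([l.box for l in labels]) == []
        for x, y, w, h in (l.box for l in labels):
            assert 0 <= x and x + w <= P.canvas_width
            assert 0 <= y and y + h <= P.canvas_height
        assert not any(l.flagged for l in labels)

    def test_deterministic(self):
        anchors = [(100.0 + 7 * i, 150.0) for i in range(12)]
        boxes = [(50.0, 14.0)] * 12
        a = place_labels(anchors, boxes, P, texts=[str(i) for i in range(12)])
        b = place_labels(anchors, boxes, P, texts=[str(i) for i in range(12)])
        assert a == b

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            place_labels([(0.0, 0.0)], [], P)


class TestBuildLayout:
    def test_tp53_like_counts(self, tp53_record):
        profile = profile_from(*[f"TP53\tS{i}\tp.R175H\tMissense_Mutation"
                                 for i in (1, 2, 3)])
        layout = build_layout(profile, tp53_record, select_highlights(profile, 1))
        assert len(layout.domain_rects) == 3
        assert len(layout.lollipops) == 1
        assert len(layout.labels) == 1
        assert layout.labels[0].text == "R175H (3)"

    def test_threshold_above_max_no_labels(self, tp53_record):
        profile = profile_from("TP53\tS1\tp.R175H\tMissense_Mutation")
        layout = build_layout(profile, tp53_record, select_highlights(profile, 5))
        assert len(layout.lollipops) == 1 and len(layout.labels) == 0

    def test_shared_position_one_lollipop_two_labels(self, tp53_record):
        profile = profile_from(
            "TP53\tS1\tp.R273C\tMissense_Mutation",
            "TP53\tS2\tp.R273H\tMissense_Mutation",
        )
        layout = build_layout(profile, tp53_record, select_highlights(profile, 1))
        assert len(layout.lollipops) == 1
        assert len(layout.labels) == 2
        assert overlapping_pairs([l.box for l in layout.labels]) == []

    def test_out_of_range_variant_flagged_not_fatal(self, tp53_record):
        profile = profile_from(
            "TP53\tS1\tp.R175H\tMissense_Mutation",
            "TP53\tS2\tp.Q999H\tMissense_Mutation",  # beyond length 393
        )
        layout = build_layout(profile, tp53_record, select_highlights(profile, 1))
        assert layout.out_of_range == ("Q999H",)
        assert len(layout.lollipops) == 1
        assert any("excluded" in w for w in layout.warnings)

    def test_empty_profile_domain_track_only(self, tp53_record):
        with pytest.warns(UserWarning):
            profile = profile_from("EGFR\tS1\tp.L858R\tMissense_Mutation", gene="TP53")
        layout = build_layout(profile, tp53_record, HighlightSet(1, frozenset()))
        assert len(layout.domain_rects) == 3
        assert layout.lollipops == () and layout.labels == ()
        assert any("empty profile" in w for w in layout.warnings)

    def test_serialization_deterministic(self, tp53_record):
        profile = profile_from(
            "TP53\tS1\tp.R175H\tMissense_Mutation",
            "TP53\tS2\tp.R273C\tMissense_Mutation",
        )
        hl = select_highlights(profile, 1)
        assert build_layout(profile, tp53_record, hl).to_text() == \
            build_layout(profile, tp53_record, hl).to_text()

    def test_domain_rects_within_axis(self, tp53_record):
        profile = profile_from("TP53\tS1\tp.R175H\tMissense_Mutation")
        layout = build_layout(profile, tp53_record, select_highlights(profile, 1))
        for d in layout.domain_rects:
            assert d.x >= P.axis_x0 - 1e-9
            assert d.x + d.width <= P.axis_x1 + 1e-9

    def test_overlapping_domains_stack_in_lanes(self):
        record = ProteinRecord("X1", "G", 9606, 200, (
            DomainFeature(10, 120, "A"), DomainFeature(100, 180, "B"),
        ))
        profile = profile_from("G\tS1\tp.R50H\tMissense_Mutation", gene="G")
        layout = build_layout(profile, record, select_highlights(profile, 1))
        lanes = {d.name: d.lane for d in layout.domain_rects}
        assert lanes["A"] != lanes["B"]

    def test_legend_has_full_domain_names(self, tp53_record):
        profile = profile_from("TP53\tS1\tp.R175H\tMissense_Mutation")
        layout = build_layout(profile, tp53_record, select_highlights(profile, 1))
        domain_labels = [e.label for e in layout.legend if e.kind == "domain"]
        assert any(l.startswith("P53_tetramer") for l in domain_labels)

    def test_random_dense_layouts_zero_overlap(self, tp53_record):
        rng = random.Random(5)
        for _ in range(10):
            rows = [
                f"TP53\tS{rng.randint(1, 9)}\tp.R{rng.randint(150, 200)}H\tMissense_Mutation"
                for _ in range(40)
            ]
            profile = profile_from(*rows)
            layout = build_layout(profile, tp53_record, select_highlights(profile, 1))
            assert overlapping_pairs([l.box for l in layout.labels]) == []
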