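"""Geometry resolution: axis scaling, domain lanes, stems and label placement.

All coordinates are abstract drawing units with the SVG convention (origin
top-left, y increasing downward).  The protein axis runs along the bottom
of the canvas; residue positions are mapped affinely onto it, stems rise
from the axis baseline with height proportional to per-position recurrence,
and highlighted alterations get text labels placed by a deterministic
greedy collision-avoidance pass.

Label placement is deliberately *not* force-based: candidate slots are
tried in a fixed order (directly above the anchor, then left/right shifts,
then higher tiers) and the first slot that is inside the canvas and at
least ``label_gap`` away from every already-placed box wins.  Identical
inputs therefore always give identical layouts, which makes the rendered
SVG byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .domain_source import DomainFeature, ProteinRecord
from .recurrence import AlterationCount, HighlightSet, RecurrenceProfile

__all__ = [
    "LayoutParams",
    "Lollipop",
    "PlacedLabel",
    "DomainRect",
    "LegendEntry",
    "LollipopLayout",
    "scale_position",
    "stem_heights",
    "place_labels",
    "build_layout",
    "boxes_overlap",
    "overlap_area",
]


@dataclass(frozen=True)
class LayoutParams:
    """Tunable geometry of the drawing, in abstract drawing units."""

    canvas_width: float = 1000.0
    canvas_height: float = 420.0
    margin_left: float = 60.0
    margin_right: float = 40.0
    margin_top: float = 30.0
    margin_bottom: float = 70.0
    stem_max_height: float = 160.0
    head_radius: float = 5.0
    domain_lane_height: float = 16.0
    label_gap: float = 3.0
    label_char_width: float = 6.6   # approximate glyph advance at font size 11
    label_height: float = 14.0
    max_repel_iterations: int = 400

    def __post_init__(self) -> None:
        for name in (
            "canvas_width", "canvas_height", "stem_max_height", "head_radius",
            "domain_lane_height", "label_gap", "label_char_width", "label_height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_repel_iterations < 1:
            raise ValueError("max_repel_iterations must be >= 1")
        if self.margin_left + self.margin_right >= self.canvas_width:
            raise ValueError("horizontal margins exceed canvas width")
        if self.margin_top + self.margin_bottom >= self.canvas_height:
            raise ValueError("vertical margins exceed canvas height")

    @property
    def axis_x0(self) -> float:
        return self.margin_left

    @property
    def axis_x1(self) -> float:
        return self.canvas_width - self.margin_right

    @property
    def baseline_y(self) -> float:
        return self.canvas_height - self.margin_bottom


Box = tuple[float, float, float, float]  # (x, y, width, height)


@dataclass(frozen=True)
class Lollipop:
    position: int
    x: float
    stem_height: float
    head_y: float
    color_key: str
    alterations: tuple[str, ...]


@dataclass(frozen=True)
class PlacedLabel:
    text: str
    anchor: tuple[float, float]
    box: Box
    leader: tuple[tuple[float, float], ...]
    flagged: bool = False  # True when no fully collision-free slot was found


@dataclass(frozen=True)
class DomainRect:
    name: str
    start: int
    end: int
    x: float
    y: float
    width: float
    height: float
    lane: int


@dataclass(frozen=True)
class LegendEntry:
    kind: str  # "mutation_type" | "domain"
    label: str  # full, never truncated


@dataclass(frozen=True)
class LollipopLayout:
    gene_symbol: str
    protein_length: int
    params: LayoutParams
    domain_rects: tuple[DomainRect, ...]
    lollipops: tuple[Lollipop, ...]
    labels: tuple[PlacedLabel, ...]
    legend: tuple[LegendEntry, ...]
    out_of_range: tuple[str, ...] = ()  # alteration labels beyond the protein
    warnings: tuple[str, ...] = ()

    def to_text(self) -> str:
        """Stable structured-text serialization (golden-test artifact)."""
        lines = [f"layout\t{self.gene_symbol}\t{self.protein_length}"]
        for d in self.domain_rects:
            lines.append(
                f"domain\t{d.name}\t{d.start}\t{d.end}\t{d.x:.4f}\t{d.y:.4f}"
                f"\t{d.width:.4f}\t{d.height:.4f}\t{d.lane}"
            )
        for l in self.lollipops:
            lines.append(
                f"lollipop\t{l.position}\t{l.x:.4f}\t{l.stem_height:.4f}"
                f"\t{l.head_y:.4f}\t{l.color_key}\t{','.join(l.alterations)}"
            )
        for lab in self.labels:
            x, y, w, h = lab.box
            leader = ";".join(f"{px:.4f},{py:.4f}" for px, py in lab.leader)
            lines.append(
                f"label\t{lab.text}\t{lab.anchor[0]:.4f}\t{lab.anchor[1]:.4f}"
                f"\t{x:.4f}\t{y:.4f}\t{w:.4f}\t{h:.4f}\t{leader}\t{int(lab.flagged)}"
            )
        for e in self.legend:
            lines.append(f"legend\t{e.kind}\t{e.label}")
        for o in self.out_of_range:
            lines.append(f"out_of_range\t{o}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# primitives


def scale_position(position: int, length: int, params: LayoutParams) -> float:
    """Affine map of residue index ``[1, length]`` onto the axis span."""
    if not (1 <= position <= length):
        raise ValueError(f"position {position} outside [1, {length}]")
    if length == 1:
        return params.axis_x0
    frac = (position - 1) / (length - 1)
    return params.axis_x0 + frac * (params.axis_x1 - params.axis_x0)


def stem_heights(
    per_position: dict[int, int], params: LayoutParams
) -> dict[int, float]:
    """Heights proportional to counts; the maximum count gets full height."""
    if not per_position:
        raise ValueError("per_position counts must be non-empty")
    max_count = max(per_position.values())
    return {
        pos: params.stem_max_height * count / max_count
        for pos, count in per_position.items()
    }


def overlap_area(a: Box, b: Box) -> float:
    """Area of the intersection of two (x, y, w, h) rectangles."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    dx = min(ax + aw, bx + bw) - max(ax, bx)
    dy = min(ay + ah, by + bh) - max(ay, by)
    return max(0.0, dx) * max(0.0, dy)


def boxes_overlap(a: Box, b: Box, gap: float = 0.0) -> bool:
    """True when the rectangles come closer than ``gap`` (touching counts)."""
    ax, ay, aw, ah = a
    return overlap_area((ax - gap, ay - gap, aw + 2 * gap, ah + 2 * gap), b) > 0.0


def _clamp_x(x: float, width: float, params: LayoutParams) -> float:
    return min(max(x, 0.0), params.canvas_width - width)


def _candidate_slots(
    anchor: tuple[float, float], box_w: float, box_h: float, params: LayoutParams
) -> Iterable[Box]:
    """Deterministic candidate boxes: above the anchor, then sideways shifts,
    then higher tiers, scanning left-to-right alternately outward."""
    ax, ay = anchor
    step = box_w / 2.0 + params.label_gap
    base_y = ay - box_h - 2.0  # sit just above the head
    tier = 0
    while True:
        y = base_y - tier * (box_h + params.label_gap)
        if y < 0:
            return
        for k in range(0, 7):
            # 0, -1, +1, -2, +2, ... in units of half-box steps
            offset = (k + 1) // 2 * (-1 if k % 2 else 1) * step
            x = _clamp_x(ax - box_w / 2.0 + offset, box_w, params)
            if y >= params.margin_top / 4:  # keep a sliver of headroom
                yield (x, y, box_w, box_h)
        tier += 1


def _leader_for(box: Box, anchor: tuple[float, float]) -> tuple[tuple[float, float], ...]:
    x, y, w, h = box
    return ((x + w / 2.0, y + h), anchor)


def place_labels(
    anchors: Sequence[tuple[float, float]],
    boxes: Sequence[tuple[float, float]],
    params: LayoutParams,
    texts: Optional[Sequence[str]] = None,
) -> list[PlacedLabel]:
    """Place one label box per anchor with zero pairwise overlap.

    ``boxes`` gives (width, height) extents.  Labels are processed in a
    fixed order (anchor x, then text) and each greedily takes the first
    candidate slot that keeps ``label_gap`` clearance from all previously
    placed boxes and stays inside the canvas.  If ``max_repel_iterations``
    candidates are exhausted, the least-overlapping candidate is used and
    the label is flagged rather than dropped.
    """
    if len(anchors) != len(boxes):
        raise ValueError("anchors and boxes must have equal length")
    texts = list(texts) if texts is not None else [""] * len(anchors)
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i][0], texts[i], i))

    placed: list[tuple[int, PlacedLabel]] = []
    occupied: list[Box] = []
    for i in order:
        w, h = boxes[i]
        best: Optional[Box] = None
        best_overlap = float("inf")
        chosen: Optional[Box] = None
        for n_tried, cand in enumerate(_candidate_slots(anchors[i], w, h, params)):
            total = sum(
                overlap_area(
                    (cand[0] - params.label_gap, cand[1] - params.label_gap,
                     cand[2] + 2 * params.label_gap, cand[3] + 2 * params.label_gap),
                    other,
                )
                for other in occupied
            )
            if total == 0.0:
                chosen = cand
                break
            if total < best_overlap:
                best_overlap, best = total, cand
            if n_tried + 1 >= params.max_repel_iterations:
                break
        flagged = chosen is None
        box = chosen if chosen is not None else best
        if box is None:  # no candidate fit on the canvas at all
            box = (_clamp_x(anchors[i][0] - w / 2.0, w, params), 0.0, w, h)
            flagged = True
        occupied.append(box)
        placed.append(
            (i, PlacedLabel(
                text=texts[i],
                anchor=tuple(anchors[i]),
                box=box,
                leader=_leader_for(box, tuple(anchors[i])),
                flagged=flagged,
            ))
        )
    placed.sort(key=lambda pair: pair[0])
    return [p for _, p in placed]


# ---------------------------------------------------------------------------
# full layout


def _assign_domain_lanes(domains: Sequence[DomainFeature]) -> list[int]:
    """Greedy interval coloring: overlapping domains go to separate lanes."""
    lanes: list[int] = []
    lane_end: list[int] = []  # rightmost residue occupied per lane
    for d in sorted(domains):
        for li, end in enumerate(lane_end):
            if d.start > end:
                lanes.append(li)
                lane_end[li] = d.end
                break
        else:
            lanes.append(len(lane_end))
            lane_end.append(d.end)
    # restore input (sorted) order mapping
    return lanes


def build_layout(
    profile: RecurrenceProfile,
    record: ProteinRecord,
    highlights: HighlightSet,
    params: LayoutParams = LayoutParams(),
) -> LollipopLayout:
    """Resolve the full plot geometry for one gene.

    Domain rectangles sit on the axis baseline (overlapping domains stack
    into separate lanes); one lollipop is emitted per distinct mutated
    position, colored by the position's dominant mutation type; one label
    per highlighted alteration, text ``"<change> (<count>)"``.  Alterations
    annotated beyond the protein length are excluded and reported in
    ``out_of_range`` with a warning instead of failing the plot.
    """
    warnings_: list[str] = []
    if profile.gene_symbol.upper() != record.gene_symbol.upper():
        warnings_.append(
            f"profile gene {profile.gene_symbol!r} != record gene {record.gene_symbol!r}"
        )

    in_range = [a for a in profile.per_alteration if a.position <= record.length]
    out_of_range = tuple(
        a.protein_change for a in profile.per_alteration if a.position > record.length
    )
    if out_of_range:
        warnings_.append(
            f"{len(out_of_range)} alteration(s) beyond protein length "
            f"{record.length} excluded: {', '.join(out_of_range)}"
        )
    if not in_range:
        warnings_.append("empty profile: domain track only")

    sorted_domains = tuple(sorted(record.domains))
    lanes = _assign_domain_lanes(sorted_domains)
    domain_rects = []
    for d, lane in zip(sorted_domains, lanes):
        x0 = scale_position(d.start, record.length, params)
        x1 = scale_position(d.end, record.length, params)
        domain_rects.append(
            DomainRect(
                name=d.name, start=d.start, end=d.end,
                x=x0,
                y=params.baseline_y + lane * (params.domain_lane_height + 2.0),
                width=max(x1 - x0, 1.0),
                height=params.domain_lane_height,
                lane=lane,
            )
        )

    per_position = {p: c for p, c in profile.per_position.items() if p <= record.length}
    lollipops: list[Lollipop] = []
    if per_position:
        heights = stem_heights(per_position, params)
        alts_at: dict[int, list[AlterationCount]] = {}
        for a in in_range:
            alts_at.setdefault(a.position, []).append(a)
        for pos in sorted(per_position):
            alts = sorted(alts_at.get(pos, []), key=lambda a: a.protein_change)
            # dominant mutation type at the position: most samples, tie lexical
            color_key = min(
                alts, key=lambda a: (-a.n_samples, a.mutation_type)
            ).mutation_type if alts else "other"
            h = heights[pos]
            lollipops.append(
                Lollipop(
                    position=pos,
                    x=scale_position(pos, record.length, params),
                    stem_height=h,
                    head_y=params.baseline_y - h,
                    color_key=color_key,
                    alterations=tuple(a.protein_change for a in alts),
                )
            )

    # labels for highlighted alterations only
    lolli_by_pos = {l.position: l for l in lollipops}
    to_label = [a for a in in_range if a.protein_change in highlights.members]
    anchors = [(lolli_by_pos[a.position].x, lolli_by_pos[a.position].head_y) for a in to_label]
    texts = [f"{a.protein_change} ({a.n_samples})" for a in to_label]
    extents = [
        (len(t) * params.label_char_width + 6.0, params.label_height) for t in texts
    ]
    labels = tuple(place_labels(anchors, extents, params, texts=texts))

    mutation_types = sorted({a.mutation_type for a in in_range})
    legend = tuple(
        [LegendEntry("mutation_type", t) for t in mutation_types]
        + [LegendEntry("domain", f"{d.name} ({d.start}-{d.end})") for d in sorted_domains]
    )
    return LollipopLayout(
        gene_symbol=profile.gene_symbol,
        protein_length=record.length,
        params=params,
        domain_rects=tuple(domain_rects),
        lollipops=tuple(lollipops),
        labels=labels,
        legend=legend,
        out_of_range=out_of_range,
        warnings=tuple(warnings_),
    )
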