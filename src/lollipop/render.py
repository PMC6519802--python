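"""SVG emission, raster export, deterministic colors and table export.

SVG is the canonical artifact: :func:`render_svg` writes a plain SVG 1.1
document by direct string construction, with no timestamps, random ids or
dict-order dependence, so equal layouts give byte-identical files.  PNG,
JPEG and PDF are produced by rasterizing that SVG with a small built-in
renderer for the element subset this package emits (rect, line, circle,
polyline, text), drawn via Pillow.  Raster output is validated by format
signature and non-emptiness only; the SVG is the bit-exact reference.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Mapping, Sequence
from xml.sax.saxutils import escape, quoteattr

from PIL import Image, ImageDraw

from .domain_source import ProteinRecord
from .layout import LollipopLayout
from .recurrence import HighlightSet, RecurrenceProfile

__all__ = [
    "StyleConfig",
    "FigureBundle",
    "assign_colors",
    "render_svg",
    "export_image",
    "export_tables",
    "make_figure_bundle",
    "SUPPORTED_FORMATS",
]

SUPPORTED_FORMATS = ("SVG", "PNG", "PDF", "JPEG")

#: Okabe-Ito qualitative palette (colorblind-safe).
_OKABE_ITO = (
    "#E69F00", "#56B4E9", "#009E73", "#F0E442",
    "#0072B2", "#D55E00", "#CC79A7", "#999999",
)
_DOMAIN_PALETTE = (
    "#8DA0CB", "#66C2A5", "#FC8D62", "#E78AC3", "#A6D854", "#FFD92F",
)

_HEX_COLOR = re.compile(r"^#[0-9A-Fa-f]{6}$")


@dataclass(frozen=True)
class StyleConfig:
    mutation_type_palette: tuple[str, ...] = _OKABE_ITO
    domain_palette: tuple[str, ...] = _DOMAIN_PALETTE
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 11.0
    highlight_emphasis: float = 1.0  # extra stroke width for labeled lollipops

    def __post_init__(self) -> None:
        for pal_name in ("mutation_type_palette", "domain_palette"):
            pal = getattr(self, pal_name)
            if not pal:
                raise ValueError(f"{pal_name} must be non-empty")
            for c in pal:
                if not _HEX_COLOR.match(c):
                    raise ValueError(f"{pal_name}: invalid hex color {c!r}")


@dataclass(frozen=True)
class FigureBundle:
    svg_text: str
    raster_exports: Mapping[str, bytes]
    data_table: str
    domain_table: str


def assign_colors(
    categories: Sequence[str], palette: Sequence[str]
) -> dict[str, str]:
    """Map labels to palette colors: lexicographic order, cyclic reuse.

    The sort makes the assignment independent of input order, so the same
    category set always gets the same colors.
    """
    if len(set(categories)) != len(categories):
        raise ValueError("categories must be distinct")
    return {
        label: palette[i % len(palette)]
        for i, label in enumerate(sorted(categories))
    }


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def render_svg(layout: LollipopLayout, style: StyleConfig = StyleConfig()) -> str:
    """Emit the layout as a deterministic, well-formed SVG 1.1 document."""
    p = layout.params
    type_labels = [e.label for e in layout.legend if e.kind == "mutation_type"]
    domain_names = [d.name for d in layout.domain_rects]
    type_colors = assign_colors(type_labels, style.mutation_type_palette)
    domain_colors = assign_colors(sorted(set(domain_names)), style.domain_palette)
    labeled_x = {lab.anchor[0] for lab in layout.labels}

    out: list[str] = []
    w, h = _fmt(p.canvas_width), _fmt(p.canvas_height)
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w}" height="{h}" viewBox="0 0 {w} {h}" '
        f'font-family={quoteattr(style.font_family)} font-size="{_fmt(style.font_size)}">'
    )
    out.append(f'<rect class="background" x="0" y="0" width="{w}" height="{h}" fill="#FFFFFF"/>')

    # protein axis with terminal residue ticks
    y0 = _fmt(p.baseline_y)
    out.append(
        f'<g class="axis"><line x1="{_fmt(p.axis_x0)}" y1="{y0}" '
        f'x2="{_fmt(p.axis_x1)}" y2="{y0}" stroke="#333333" stroke-width="1.5"/>'
        f'<text x="{_fmt(p.axis_x0)}" y="{_fmt(p.baseline_y + p.domain_lane_height + 16)}" '
        f'fill="#333333" text-anchor="middle">1</text>'
        f'<text x="{_fmt(p.axis_x1)}" y="{_fmt(p.baseline_y + p.domain_lane_height + 16)}" '
        f'fill="#333333" text-anchor="middle">{layout.protein_length}</text></g>'
    )

    out.append('<g class="domains">')
    for d in layout.domain_rects:
        out.append(
            f'<rect class="domain" x="{_fmt(d.x)}" y="{_fmt(d.y)}" '
            f'width="{_fmt(d.width)}" height="{_fmt(d.height)}" '
            f'fill="{domain_colors[d.name]}" stroke="#444444" stroke-width="0.5">'
            f'<title>{escape(d.name)} ({d.start}-{d.end})</title></rect>'
        )
    out.append("</g>")

    for l in layout.lollipops:
        color = type_colors.get(l.color_key, "#999999")
        width = 1.5 + (style.highlight_emphasis if l.x in labeled_x else 0.0)
        out.append(
            f'<g class="lollipop">'
            f'<line x1="{_fmt(l.x)}" y1="{y0}" x2="{_fmt(l.x)}" y2="{_fmt(l.head_y)}" '
            f'stroke="{color}" stroke-width="{_fmt(width)}"/>'
            f'<circle cx="{_fmt(l.x)}" cy="{_fmt(l.head_y)}" r="{_fmt(p.head_radius)}" '
            f'fill="{color}" stroke="#333333" stroke-width="0.75"/></g>'
        )

    for lab in layout.labels:
        x, y, bw, bh = lab.box
        points = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in lab.leader)
        out.append(
            f'<g class="label">'
            f'<polyline points="{points}" fill="none" stroke="#777777" stroke-width="0.75"/>'
            f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(bw)}" height="{_fmt(bh)}" '
            f'fill="#FFFFFF" stroke="#AAAAAA" stroke-width="0.5"/>'
            f'<text x="{_fmt(x + bw / 2)}" y="{_fmt(y + bh - 3.5)}" fill="#111111" '
            f'text-anchor="middle">{escape(lab.text)}</text></g>'
        )

    # legend: mutation types then domains, full names, never truncated
    out.append('<g class="legend">')
    lx = p.axis_x0
    ly = p.canvas_height - 18.0
    for label in type_labels:
        out.append(
            f'<rect x="{_fmt(lx)}" y="{_fmt(ly - 9)}" width="10" height="10" '
            f'fill="{type_colors[label]}"/>'
            f'<text x="{_fmt(lx + 14)}" y="{_fmt(ly)}" fill="#333333">{escape(label)}</text>'
        )
        lx += 14 + len(label) * 6.6 + 18
    for e in layout.legend:
        if e.kind != "domain":
            continue
        name = e.label.split(" (")[0]
        out.append(
            f'<rect x="{_fmt(lx)}" y="{_fmt(ly - 9)}" width="10" height="10" '
            f'fill="{domain_colors.get(name, "#CCCCCC")}"/>'
            f'<text x="{_fmt(lx + 14)}" y="{_fmt(ly)}" fill="#333333">{escape(e.label)}</text>'
        )
        lx += 14 + len(e.label) * 6.6 + 18
    out.append("</g>")

    out.append(
        f'<text class="title" x="{_fmt(p.canvas_width / 2)}" y="{_fmt(p.margin_top * 0.6)}" '
        f'text-anchor="middle" fill="#111111" font-size="{_fmt(style.font_size + 3)}">'
        f'{escape(layout.gene_symbol)}</text>'
    )
    out.append("</svg>")
    svg = "\n".join(out) + "\n"
    ET.fromstring(svg)  # guarantee well-formedness before returning
    return svg


# ---------------------------------------------------------------------------
# rasterization of our own SVG subset


def _color(value: str | None, default=(0, 0, 0, 255)):
    if value is None:
        return default
    value = value.strip()
    if value == "none":
        return None
    if _HEX_COLOR.match(value):
        return tuple(int(value[i : i + 2], 16) for i in (1, 3, 5)) + (255,)
    named = {"white": (255, 255, 255, 255), "black": (0, 0, 0, 255)}
    return named.get(value.lower(), default)


def _rasterize(svg_text: str, scale: float = 2.0) -> Image.Image:
    root = ET.fromstring(svg_text)
    width = int(round(float(root.get("width", "800")) * scale))
    height = int(round(float(root.get("height", "400")) * scale))
    img = Image.new("RGBA", (width, height), (255, 255, 255, 255))
    draw = ImageDraw.Draw(img)

    def s(v: str | None, default: float = 0.0) -> float:
        return float(v) * scale if v is not None else default * scale

    def walk(el: ET.Element) -> None:
        tag = el.tag.split("}")[-1]
        if tag == "rect":
            x, y = s(el.get("x")), s(el.get("y"))
            w, h = s(el.get("width")), s(el.get("height"))
            fill = _color(el.get("fill"), (0, 0, 0, 255))
            stroke = _color(el.get("stroke"), None) if el.get("stroke") else None
            draw.rectangle(
                [x, y, x + w, y + h], fill=fill, outline=stroke,
                width=max(1, int(round(s(el.get("stroke-width"), 1) / scale * scale))),
            )
        elif tag == "line":
            stroke = _color(el.get("stroke"))
            lw = max(1, int(round(float(el.get("stroke-width", "1")) * scale)))
            draw.line(
                [s(el.get("x1")), s(el.get("y1")), s(el.get("x2")), s(el.get("y2"))],
                fill=stroke, width=lw,
            )
        elif tag == "circle":
            cx, cy, r = s(el.get("cx")), s(el.get("cy")), s(el.get("r"))
            fill = _color(el.get("fill"))
            stroke = _color(el.get("stroke"), None) if el.get("stroke") else None
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=fill, outline=stroke)
        elif tag == "polyline":
            pts = [
                tuple(float(c) * scale for c in pair.split(","))
                for pair in el.get("points", "").split()
            ]
            if len(pts) >= 2:
                draw.line(pts, fill=_color(el.get("stroke")), width=1)
        elif tag == "text":
            content = "".join(el.itertext())
            fill = _color(el.get("fill"))
            x, y = s(el.get("x")), s(el.get("y"))
            anchor = {"middle": "ms", "end": "rs"}.get(el.get("text-anchor", ""), "ls")
            draw.text((x, y), content, fill=fill, anchor=anchor)
            return  # skip <title> etc. children
        for child in el:
            if child.tag.split("}")[-1] != "title":
                walk(child)

    for child in root:
        walk(child)
    return img


def export_image(svg_text: str, format: str) -> bytes:
    """Encode the figure in one of the supported formats.

    SVG is a byte-identical passthrough; PNG/JPEG/PDF are rasterized.
    """
    fmt = format.upper().replace("JPG", "JPEG")
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported format {format!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    if fmt == "SVG":
        return svg_text.encode("utf-8")
    img = _rasterize(svg_text)
    buf = io.BytesIO()
    if fmt == "PNG":
        img.save(buf, format="PNG")
    elif fmt == "JPEG":
        img.convert("RGB").save(buf, format="JPEG", quality=95)
    else:  # PDF: single-page raster-backed document
        img.convert("RGB").save(buf, format="PDF", resolution=144)
    return buf.getvalue()


def export_tables(
    profile: RecurrenceProfile,
    record: ProteinRecord,
    highlights: HighlightSet,
) -> tuple[str, str]:
    """Return (data_table, domain_table) as TSV strings.

    The data table is the figure's source data: one row per alteration with
    its position, type, distinct-sample count and highlight flag.  The
    domain table lists every domain feature with its accession.
    """
    data_lines = ["gene\tprotein_change\tposition\tmutation_type\tn_samples\thighlighted"]
    for a in profile.per_alteration:
        data_lines.append(
            f"{profile.gene_symbol}\t{a.protein_change}\t{a.position}"
            f"\t{a.mutation_type}\t{a.n_samples}"
            f"\t{str(a.protein_change in highlights.members).lower()}"
        )
    domain_lines = ["name\tstart\tend\taccession"]
    for d in record.domains:
        domain_lines.append(f"{d.name}\t{d.start}\t{d.end}\t{record.accession}")
    return "\n".join(data_lines) + "\n", "\n".join(domain_lines) + "\n"


def make_figure_bundle(
    layout: LollipopLayout,
    profile: RecurrenceProfile,
    record: ProteinRecord,
    highlights: HighlightSet,
    formats: Sequence[str] = ("SVG",),
    style: StyleConfig = StyleConfig(),
) -> FigureBundle:
    """Render the layout and package every requested export format."""
    svg = render_svg(layout, style)
    rasters = {
        f.upper(): export_image(svg, f)
        for f in formats
        if f.upper() != "SVG"
    }
    data_table, domain_table = export_tables(profile, record, highlights)
    return FigureBundle(
        svg_text=svg,
        raster_exports=rasters,
        data_table=data_table,
        domain_table=domain_table,
    )
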