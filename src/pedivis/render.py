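"""Layer-based figure construction: static matplotlib and interactive HTML.

Both backends consume one shared draw list (symbols + segments) derived from
the layout and connection stages, so static and interactive output always
agree on geometry.  Standard human-pedigree nomenclature is used: squares
are male, circles female, diamonds unknown sex; filled symbols are affected;
placeholder parents are semi-transparent; duplicate appearances are dashed
and carry a repetition mark.

The static backend returns a live ``matplotlib.figure.Figure`` the caller
can keep customising; the interactive backend returns an
:class:`HTMLWidget` wrapping a self-contained SVG + JavaScript document with
hover tooltips, wheel zoom and drag panning.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.lines import Line2D
from matplotlib.patches import Circle, PathPatch, Polygon, Rectangle
from matplotlib.path import Path as MplPath

from .config import PlotConfig
from .connections import ConnectionSet, Segment, build_all
from .layout import LayoutResult, compute_layout
from .ped_model import PedigreeTable, Sex, assign_families, pad_founders, validate
from . import relatedness as rel


class PedigreeError(ValueError):
    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


@dataclass
class DrawSymbol:
    nodeID: str
    personID: str
    x: float
    y: float
    shape: str  # square | circle | diamond
    fill: str
    stroke: str
    strokeStyle: str
    alpha: float
    label: str
    tooltip: Dict[str, str]
    duplicate: bool = False
    placeholder: bool = False
    highlighted: bool = False


@dataclass
class DrawList:
    symbols: List[DrawSymbol]
    segments: List[Segment]
    layout: LayoutResult
    connections: ConnectionSet
    ped: PedigreeTable
    cfg: PlotConfig = field(default_factory=PlotConfig)


_LINESTYLES = {"solid": "-", "dashed": "--", "dotted": ":", "dashdot": "-."}


def _prepare(ped: PedigreeTable, cfg: Optional[PlotConfig]) -> PlotConfig:
    if cfg is None:
        cfg = PlotConfig()
    if len(ped) == 0:
        raise PedigreeError("EMPTY_PEDIGREE", "cannot draw an empty pedigree")
    report = validate(ped)
    if not report.isValid:
        raise PedigreeError("INVALID_PEDIGREE", str(report))
    return cfg


def build_draw_list(ped: PedigreeTable, cfg: Optional[PlotConfig] = None,
                    highlight_matrix: Optional[rel.RelatednessMatrix] = None
                    ) -> DrawList:
    """Validate, lay out, route, and style one pedigree into a draw list."""
    cfg = _prepare(ped, cfg)
    if cfg.get("layoutParams.padFounders"):
        ped = pad_founders(ped)
    if any(ind.famID is None for ind in ped):
        ped = assign_families(ped)
    layout = compute_layout(ped, gutter=cfg.get("layoutParams.gutter"))
    conn = build_all(layout, ped, cfg)

    highlighted: set = set()
    if cfg.get("highlight.enabled") and cfg.get("highlight.focalIDs"):
        mat = highlight_matrix
        if mat is None:
            kind = cfg.get("highlight.matrixKind")
            if kind == "mitochondrial":
                mat = rel.mitochondrial_matrix(ped)
            else:
                mat = rel.additive_matrix(ped)
        for focal in cfg.get("highlight.focalIDs"):
            highlighted |= rel.highlight_set(mat, focal,
                                             cfg.get("highlight.threshold"))

    tooltip_fields = cfg.get("interactive.tooltipFields")
    label_field = cfg.get("labels.field")
    symbols: List[DrawSymbol] = []
    shape_by_sex = {Sex.MALE: "male", Sex.FEMALE: "female", Sex.UNKNOWN: "unknown"}
    for node in layout.nodes:
        ind = ped.get(node.personID)
        sex_key = shape_by_sex[ind.sex]
        shape = cfg.get(f"symbols.{sex_key}.shape")
        fill = cfg.get(f"symbols.{sex_key}.fill")
        stroke = cfg.get(f"symbols.{sex_key}.stroke")
        style = "solid"
        alpha = 1.0
        if ind.affected is True:
            fill = cfg.get("symbols.affectedFill")
        if node.personID in highlighted and not cfg.get("highlight.outlineOnly"):
            fill = cfg.get("highlight.fill")
        if node.personID in highlighted and cfg.get("highlight.outlineOnly"):
            stroke = cfg.get("highlight.outlineColor")
        if ind.placeholder:
            alpha = cfg.get("symbols.placeholderAlpha")
            fill = cfg.get("symbols.placeholderFill")
            style = cfg.get("symbols.placeholderStrokeStyle")
        if node.duplicateIndex > 0:
            style = cfg.get("symbols.duplicateStrokeStyle")

        tip = {}
        for f in tooltip_fields:
            if f == "personID":
                tip[f] = ind.personID
            elif f == "sex":
                tip[f] = ind.sex.value
            elif f == "famID":
                tip[f] = ind.famID or ""
            elif f in ind.phenotypes:
                tip[f] = f"{ind.phenotypes[f]:.3g}"
        label = ""
        if cfg.get("labels.show"):
            if label_field == "personID":
                label = ind.personID
            elif label_field in ind.phenotypes:
                label = f"{ind.phenotypes[label_field]:.3g}"
        if node.duplicateIndex > 0 and cfg.get("symbols.duplicateMark"):
            label = f"{label}*{node.duplicateIndex}" if label else f"*{node.duplicateIndex}"
        symbols.append(DrawSymbol(
            nodeID=node.nodeID, personID=node.personID, x=node.x, y=node.y,
            shape=shape, fill=fill, stroke=stroke, strokeStyle=style,
            alpha=alpha, label=label, tooltip=tip,
            duplicate=node.duplicateIndex > 0, placeholder=ind.placeholder,
            highlighted=node.personID in highlighted))
    return DrawList(symbols=symbols, segments=list(conn.segments),
                    layout=layout, connections=conn, ped=ped, cfg=cfg)


# -- static backend ----------------------------------------------------------

def _symbol_patch(sym: DrawSymbol, half: float):
    if sym.shape == "square":
        return Rectangle((sym.x - half, sym.y - half), 2 * half, 2 * half)
    if sym.shape == "circle":
        return Circle((sym.x, sym.y), half)
    return Polygon([(sym.x, sym.y - half), (sym.x + half, sym.y),
                    (sym.x, sym.y + half), (sym.x - half, sym.y)])


def plot_static(ped: PedigreeTable, cfg: Optional[PlotConfig] = None,
                path: Optional[str] = None,
                highlight_matrix: Optional[rel.RelatednessMatrix] = None,
                draw_list: Optional[DrawList] = None):
    """Static pedigree figure; returns the matplotlib Figure.

    Segments are drawn beneath symbols beneath labels.  When ``path`` is
    given the figure is also written (PNG/SVG/PDF by extension).
    """
    dl = draw_list if draw_list is not None else build_draw_list(
        ped, cfg, highlight_matrix)
    cfg = dl.cfg
    fig, ax = plt.subplots(
        figsize=(cfg.get("canvas.width"), cfg.get("canvas.height")),
        dpi=cfg.get("canvas.dpi"))
    fig.patch.set_facecolor(cfg.get("canvas.background"))
    ax.set_facecolor(cfg.get("canvas.background"))

    for seg in dl.segments:
        kind = seg.replaced or seg.kind
        kind_key = kind if kind in ("spouse", "drop", "sibbar", "stub",
                                    "twin_tie") else "arc"
        color = cfg.get(f"lines.{kind_key}.color")
        width = cfg.get(f"lines.{kind_key}.width")
        style = _LINESTYLES.get(cfg.get(f"lines.{kind_key}.style"), "-")
        alpha = cfg.get(f"lines.{kind_key}.alpha")
        if seg.kind == "arc" and seg.control is not None:
            p = MplPath([seg.frm, seg.control, seg.to],
                        [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3])
            ax.add_patch(PathPatch(p, fill=False, edgecolor=color,
                                   linewidth=width, linestyle=style,
                                   alpha=alpha,
                                   zorder=cfg.get("lines.zOrder")))
        else:
            ax.add_line(Line2D([seg.frm[0], seg.to[0]],
                               [seg.frm[1], seg.to[1]],
                               color=color, linewidth=width, linestyle=style,
                               alpha=alpha, zorder=cfg.get("lines.zOrder")))

    half = cfg.get("symbols.size")
    for sym in dl.symbols:
        patch = _symbol_patch(sym, half)
        patch.set_facecolor(sym.fill)
        patch.set_edgecolor(sym.stroke)
        patch.set_linewidth(cfg.get("symbols.strokeWidth"))
        patch.set_linestyle(_LINESTYLES.get(sym.strokeStyle, "-"))
        patch.set_alpha(sym.alpha)
        patch.set_zorder(cfg.get("symbols.zOrder"))
        ax.add_patch(patch)
        if sym.label:
            ax.text(sym.x + cfg.get("labels.offsetX"),
                    sym.y + cfg.get("labels.offsetY"), sym.label,
                    ha=cfg.get("labels.align"), va="top",
                    fontsize=cfg.get("labels.fontSize"),
                    color=cfg.get("labels.color"),
                    family=cfg.get("labels.fontFamily"),
                    zorder=cfg.get("symbols.zOrder") + 1)

    xs = [s.x for s in dl.symbols]
    ys = [s.y for s in dl.symbols]
    px, py = cfg.get("canvas.xPadding"), cfg.get("canvas.yPadding")
    ax.set_xlim(min(xs) - px - half, max(xs) + px + half)
    ax.set_ylim(min(ys) - py - half, max(ys) + py + half + 0.5)
    if cfg.get("canvas.invertY"):
        ax.invert_yaxis()
    ax.set_aspect("equal")
    if not cfg.get("canvas.frameOn"):
        ax.set_axis_off()
    if cfg.get("canvas.title"):
        ax.set_title(cfg.get("canvas.title"),
                     fontsize=cfg.get("canvas.titleFontSize"),
                     color=cfg.get("canvas.titleColor"))
    if cfg.get("canvas.legendShow"):
        handles = [
            Line2D([], [], marker="s", linestyle="none", markersize=8,
                   markerfacecolor="white", markeredgecolor="#222", label="male"),
            Line2D([], [], marker="o", linestyle="none", markersize=8,
                   markerfacecolor="white", markeredgecolor="#222", label="female"),
            Line2D([], [], marker="D", linestyle="none", markersize=7,
                   markerfacecolor="white", markeredgecolor="#222", label="unknown"),
        ]
        if any(s.highlighted for s in dl.symbols):
            handles.append(Line2D([], [], marker="o", linestyle="none",
                                  markersize=8,
                                  markerfacecolor=cfg.get("highlight.fill"),
                                  markeredgecolor="#222",
                                  label=cfg.get("highlight.legendLabel")))
        ax.legend(handles=handles, loc=cfg.get("canvas.legendPosition"),
                  fontsize=cfg.get("canvas.legendFontSize"),
                  frameon=cfg.get("canvas.legendFrame"))
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig


# -- interactive backend -----------------------------------------------------

class HTMLWidget:
    """Self-contained interactive pedigree document."""

    def __init__(self, html: str, draw_list: DrawList):
        self.html = html
        self.draw_list = draw_list

    def save(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(self.html)

    def _repr_html_(self) -> str:  # pragma: no cover - notebook hook
        return self.html


_JS = """
(function(){
  var svg = document.getElementById('pv-svg');
  var tip = document.getElementById('pv-tip');
  var vb = svg.viewBox.baseVal;
  var vb0 = {x: vb.x, y: vb.y, w: vb.width, h: vb.height};
  svg.addEventListener('wheel', function(e){
    if (!PV.zoom) return;
    e.preventDefault();
    var k = e.deltaY < 0 ? 1/PV.zf : PV.zf;
    var pt = svg.createSVGPoint(); pt.x = e.clientX; pt.y = e.clientY;
    var p = pt.matrixTransform(svg.getScreenCTM().inverse());
    vb.x = p.x - (p.x - vb.x) * k; vb.y = p.y - (p.y - vb.y) * k;
    vb.width *= k; vb.height *= k;
  });
  var drag = null;
  svg.addEventListener('mousedown', function(e){
    if (!PV.pan) return; drag = {x: e.clientX, y: e.clientY};
  });
  window.addEventListener('mouseup', function(){ drag = null; });
  svg.addEventListener('mousemove', function(e){
    if (drag && PV.pan){
      var s = vb.width / svg.clientWidth;
      vb.x -= (e.clientX - drag.x) * s; vb.y -= (e.clientY - drag.y) * s;
      drag = {x: e.clientX, y: e.clientY};
    }
  });
  svg.addEventListener('dblclick', function(){
    if (!PV.reset) return;
    vb.x = vb0.x; vb.y = vb0.y; vb.width = vb0.w; vb.height = vb0.h;
  });
  Array.prototype.forEach.call(document.getElementsByClassName('pv-node'),
    function(el){
      el.addEventListener('mousemove', function(e){
        tip.style.display = 'block';
        tip.style.left = (e.pageX + 12) + 'px';
        tip.style.top = (e.pageY + 12) + 'px';
        tip.innerHTML = el.getAttribute('data-tip');
      });
      el.addEventListener('mouseleave', function(){
        tip.style.display = 'none';
      });
    });
})();
"""


def plot_interactive(ped: PedigreeTable, cfg: Optional[PlotConfig] = None,
                     path: Optional[str] = None,
                     highlight_matrix: Optional[rel.RelatednessMatrix] = None,
                     draw_list: Optional[DrawList] = None) -> HTMLWidget:
    """Interactive pedigree with hover tooltips, zoom and pan.

    Geometry is identical to :func:`plot_static` — both consume the same
    draw list.  Writes a self-contained HTML document when ``path`` given.
    """
    dl = draw_list if draw_list is not None else build_draw_list(
        ped, cfg, highlight_matrix)
    cfg = dl.cfg
    scale = 60.0
    half = cfg.get("symbols.size") * scale
    xs = [s.x for s in dl.symbols]
    ys = [s.y for s in dl.symbols]
    pad = 1.0
    x0, y0 = (min(xs) - pad) * scale, (min(ys) - pad) * scale
    w = (max(xs) - min(xs) + 2 * pad) * scale
    h = (max(ys) - min(ys) + 2 * pad) * scale

    def sx(x): return x * scale
    def sy(y): return y * scale

    parts: List[str] = []
    for seg in dl.segments:
        kind = seg.replaced or seg.kind
        key = kind if kind in ("spouse", "drop", "sibbar", "stub", "twin_tie") else "arc"
        color = cfg.get(f"lines.{key}.color")
        width = cfg.get(f"lines.{key}.width")
        dash = {"solid": "", "dashed": "6,4", "dotted": "2,3"}.get(
            cfg.get(f"lines.{key}.style"), "")
        dash_attr = f' stroke-dasharray="{dash}"' if dash else ""
        if seg.kind == "arc" and seg.control is not None:
            d = (f"M {sx(seg.frm[0]):.2f} {sy(seg.frm[1]):.2f} "
                 f"Q {sx(seg.control[0]):.2f} {sy(seg.control[1]):.2f} "
                 f"{sx(seg.to[0]):.2f} {sy(seg.to[1]):.2f}")
            parts.append(f'<path d="{d}" fill="none" stroke="{color}" '
                         f'stroke-width="{width}"{dash_attr}/>')
        else:
            parts.append(
                f'<line x1="{sx(seg.frm[0]):.2f}" y1="{sy(seg.frm[1]):.2f}" '
                f'x2="{sx(seg.to[0]):.2f}" y2="{sy(seg.to[1]):.2f}" '
                f'stroke="{color}" stroke-width="{width}"{dash_attr}/>')

    for sym in dl.symbols:
        tip = "<br/>".join(f"<b>{_html.escape(k)}</b>: {_html.escape(v)}"
                           for k, v in sym.tooltip.items())
        dash = ' stroke-dasharray="5,3"' if sym.strokeStyle == "dashed" else (
            ' stroke-dasharray="2,2"' if sym.strokeStyle == "dotted" else "")
        common = (f'class="pv-node" data-tip="{_html.escape(tip, quote=True)}" '
                  f'fill="{sym.fill}" stroke="{sym.stroke}" '
                  f'stroke-width="{cfg.get("symbols.strokeWidth")}" '
                  f'opacity="{sym.alpha}"{dash}')
        cx, cy = sx(sym.x), sy(sym.y)
        if sym.shape == "square":
            parts.append(f'<rect x="{cx - half:.2f}" y="{cy - half:.2f}" '
                         f'width="{2 * half:.2f}" height="{2 * half:.2f}" {common}/>')
        elif sym.shape == "circle":
            parts.append(f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="{half:.2f}" {common}/>')
        else:
            pts = (f"{cx:.2f},{cy - half:.2f} {cx + half:.2f},{cy:.2f} "
                   f"{cx:.2f},{cy + half:.2f} {cx - half:.2f},{cy:.2f}")
            parts.append(f'<polygon points="{pts}" {common}/>')
        if sym.label:
            parts.append(
                f'<text x="{cx:.2f}" y="{cy + half + 12:.2f}" '
                f'text-anchor="middle" font-size="{cfg.get("labels.fontSize") + 2}" '
                f'fill="{cfg.get("labels.color")}">{_html.escape(sym.label)}</text>')

    opts = json.dumps({
        "zoom": cfg.get("interactive.zoomEnabled"),
        "pan": cfg.get("interactive.panEnabled"),
        "reset": cfg.get("interactive.doubleClickReset"),
        "zf": cfg.get("interactive.wheelZoomFactor"),
    })
    title = _html.escape(cfg.get("canvas.title") or "pedigree")
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ margin: 0; font-family: {cfg.get("interactive.fontFamily")};
       background: {cfg.get("interactive.background")}; }}
#pv-tip {{ display: none; position: absolute; pointer-events: none;
  background: {cfg.get("interactive.tooltipBackground")};
  color: {cfg.get("interactive.tooltipColor")};
  border: {cfg.get("interactive.tooltipBorderWidth")}px solid
          {cfg.get("interactive.tooltipBorderColor")};
  padding: {cfg.get("interactive.tooltipPadding")}px;
  font-size: {cfg.get("interactive.tooltipFontSize")}px; border-radius: 4px; }}
svg {{ display: block; margin: auto; }}
</style></head><body>
<div id="pv-tip"></div>
<svg id="pv-svg" width="{cfg.get("interactive.width")}"
     height="{cfg.get("interactive.height")}"
     viewBox="{x0:.2f} {y0:.2f} {w:.2f} {h:.2f}">
{chr(10).join(parts)}
</svg>
<script>var PV = {opts};{_JS}</script>
</body></html>
"""
    widget = HTMLWidget(doc, dl)
    if path is not None:
        widget.save(path)
    return widget
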