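"""Hierarchical plot configuration.

Every aesthetic and layout knob lives in one schema of documented leaf
parameters, grouped as ``symbols``, ``lines``, ``labels``, ``highlight``,
``layoutParams``, ``interactive``, ``canvas``, ``heatmap`` and ``pbd``.
Each leaf has a typed default; unknown keys are rejected with a
nearest-name suggestion, and a config round-trips losslessly through YAML.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Any, Dict, List, Optional

import yaml


@dataclass(frozen=True)
class Param:
    default: Any
    type: type
    doc: str


def _build_schema() -> Dict[str, Param]:
    s: Dict[str, Param] = {}

    def add(path: str, default, typ, doc: str) -> None:
        s[path] = Param(default, typ, doc)

    # -- symbols -------------------------------------------------------------
    add("symbols.size", 0.30, float, "symbol half-width in layout units")
    add("symbols.strokeWidth", 1.2, float, "outline width (pt)")
    add("symbols.strokeColor", "#222222", str, "outline colour")
    add("symbols.interiorFill", "#ffffff", str, "fill for unaffected symbols")
    add("symbols.affectedFill", "#444444", str, "fill for affected symbols")
    add("symbols.affectedAlpha", 1.0, float, "fill opacity for affected")
    add("symbols.affectedUseFill", True, bool, "fill (vs hatch) marks affected")
    add("symbols.unknownAffectedHatch", "..", str, "hatch for unknown status")
    add("symbols.deceasedSlash", False, bool, "draw slash over deceased")
    add("symbols.deceasedSlashWidth", 1.0, float, "slash line width (pt)")
    add("symbols.probandArrow", False, bool, "draw proband arrow")
    add("symbols.probandArrowSize", 0.2, float, "proband arrow size (units)")
    add("symbols.placeholderAlpha", 0.35, float, "opacity of padded parents")
    add("symbols.placeholderStrokeStyle", "dotted", str, "outline style of padded parents")
    add("symbols.placeholderFill", "#f2f2f2", str, "fill of padded parents")
    add("symbols.duplicateStrokeStyle", "dashed", str, "outline style of duplicate appearances")
    add("symbols.duplicateStrokeWidth", 1.2, float, "duplicate outline width (pt)")
    add("symbols.duplicateMark", True, bool, "superscript repetition mark on duplicates")
    add("symbols.duplicateMarkSize", 7.0, float, "repetition mark font size (pt)")
    add("symbols.zOrder", 3, int, "draw order of the symbol layer")
    shapes = {"male": "square", "female": "circle", "unknown": "diamond"}
    for sex, shape in shapes.items():
        add(f"symbols.{sex}.shape", shape, str, f"marker for {sex} individuals")
        add(f"symbols.{sex}.fill", "#ffffff", str, f"fill for {sex} individuals")
        add(f"symbols.{sex}.stroke", "#222222", str, f"outline colour for {sex}")
        add(f"symbols.{sex}.strokeWidth", 1.2, float, f"outline width for {sex} (pt)")
        add(f"symbols.{sex}.size", 0.30, float, f"symbol half-width for {sex}")

    # -- lines ---------------------------------------------------------------
    add("lines.width", 1.0, float, "default connection line width (pt)")
    add("lines.color", "#333333", str, "default connection colour")
    add("lines.alpha", 1.0, float, "default connection opacity")
    add("lines.capStyle", "round", str, "line cap style")
    add("lines.joinStyle", "round", str, "line join style")
    add("lines.barOffset", 0.35, float, "sibship bar height above the child row (units)")
    add("lines.curveOffset", 0.30, float, "lateral control-point offset for arcs (units)")
    add("lines.nodeClearance", 0.25, float, "min distance a segment may pass a foreign symbol")
    add("lines.twinTieHeightFrac", 0.5, float, "tie position along twin diagonals")
    add("lines.zOrder", 1, int, "draw order of the line layer")
    for kind in ("spouse", "drop", "sibbar", "stub", "twin_tie", "arc"):
        add(f"lines.{kind}.color", "#333333", str, f"{kind} segment colour")
        add(f"lines.{kind}.width", 1.0, float, f"{kind} segment width (pt)")
        add(f"lines.{kind}.style", "solid", str, f"{kind} segment dash style")
        add(f"lines.{kind}.alpha", 1.0, float, f"{kind} segment opacity")

    # -- labels --------------------------------------------------------------
    add("labels.show", True, bool, "draw text labels")
    add("labels.field", "personID", str, "field shown as the main label")
    add("labels.fontSize", 8.0, float, "label font size (pt)")
    add("labels.fontFamily", "sans-serif", str, "label font family")
    add("labels.fontStyle", "normal", str, "label font style")
    add("labels.fontWeight", "normal", str, "label font weight")
    add("labels.color", "#111111", str, "label colour")
    add("labels.offsetX", 0.0, float, "horizontal label offset (units)")
    add("labels.offsetY", 0.45, float, "vertical label offset below symbol (units)")
    add("labels.align", "center", str, "horizontal alignment")
    add("labels.wrapWidth", 12, int, "wrap labels longer than this many characters")
    add("labels.maxLines", 2, int, "max wrapped lines")
    add("labels.secondField", "", str, "optional second label field")
    add("labels.secondFontSize", 7.0, float, "second label font size (pt)")
    add("labels.secondColor", "#555555", str, "second label colour")
    add("labels.background", False, bool, "draw label background box")
    add("labels.backgroundColor", "#ffffff", str, "label background colour")
    add("labels.backgroundAlpha", 0.6, float, "label background opacity")
    add("labels.rotation", 0.0, float, "label rotation (degrees)")
    add("labels.outlineWidth", 0.0, float, "label halo width (pt)")

    # -- highlight -----------------------------------------------------------
    add("highlight.enabled", False, bool, "recolour a focal person's relatives")
    add("highlight.matrixKind", "additive", str, "additive | mitochondrial | custom")
    add("highlight.focalIDs", [], list, "focal person ids")
    add("highlight.threshold", 0.25, float, "min coefficient for inclusion")
    add("highlight.fill", "#e6a817", str, "highlight fill colour")
    add("highlight.alpha", 1.0, float, "highlight opacity")
    add("highlight.outlineOnly", False, bool, "recolour outline instead of fill")
    add("highlight.outlineColor", "#e6a817", str, "highlight outline colour")
    add("highlight.outlineWidth", 2.0, float, "highlight outline width (pt)")
    add("highlight.legendLabel", "highlighted", str, "legend entry for highlights")
    add("highlight.cmap", "", str, "optional colormap for graded highlighting")
    add("highlight.showLegend", True, bool, "add highlight entry to legend")

    # -- layoutParams --------------------------------------------------------
    add("layoutParams.gutter", 2.0, float, "horizontal gap between families (units)")
    add("layoutParams.sweepCap", 4, int, "max barycenter sweeps")
    add("layoutParams.slotWidth", 1.0, float, "width of one symbol slot (units)")
    add("layoutParams.rowHeight", 1.0, float, "height of one generation row (units)")
    add("layoutParams.centerSibships", True, bool, "center mating pairs over sibships")
    add("layoutParams.tileFamilies", True, bool, "tile families horizontally")
    add("layoutParams.padFounders", True, bool, "insert placeholder co-parents")
    add("layoutParams.normalizeOrigin", True, bool, "shift family min x to 0")
    add("layoutParams.maxIterations", 1000, int, "leveling iteration cap")
    add("layoutParams.dedupPolicy", "oldest-child", str, "which mating keeps the primary symbol")

    # -- interactive ---------------------------------------------------------
    add("interactive.tooltipFields", ["personID", "sex"], list, "fields shown on hover")
    add("interactive.hoverMode", "closest", str, "hover behaviour")
    add("interactive.zoomEnabled", True, bool, "mouse-wheel zoom")
    add("interactive.panEnabled", True, bool, "drag to pan")
    add("interactive.wheelZoomFactor", 1.1, float, "zoom step per wheel notch")
    add("interactive.width", 900, int, "widget width (px)")
    add("interactive.height", 600, int, "widget height (px)")
    add("interactive.background", "#ffffff", str, "widget background colour")
    add("interactive.fontFamily", "sans-serif", str, "widget font family")
    add("interactive.fontSize", 12.0, float, "widget base font size (px)")
    add("interactive.tooltipBackground", "#222222", str, "tooltip background colour")
    add("interactive.tooltipColor", "#ffffff", str, "tooltip text colour")
    add("interactive.tooltipFontSize", 11.0, float, "tooltip font size (px)")
    add("interactive.tooltipBorderColor", "#888888", str, "tooltip border colour")
    add("interactive.tooltipBorderWidth", 1.0, float, "tooltip border width (px)")
    add("interactive.tooltipPadding", 6.0, float, "tooltip padding (px)")
    add("interactive.doubleClickReset", True, bool, "double-click resets the view")
    add("interactive.showControls", True, bool, "show zoom reset control")

    # -- canvas --------------------------------------------------------------
    add("canvas.title", "", str, "figure title")
    add("canvas.subtitle", "", str, "figure subtitle")
    add("canvas.titleFontSize", 14.0, float, "title font size (pt)")
    add("canvas.subtitleFontSize", 11.0, float, "subtitle font size (pt)")
    add("canvas.titleColor", "#111111", str, "title colour")
    add("canvas.background", "#ffffff", str, "figure background colour")
    add("canvas.frameOn", False, bool, "draw axes frame")
    add("canvas.gridShow", False, bool, "draw grid")
    add("canvas.gridColor", "#dddddd", str, "grid colour")
    add("canvas.gridAlpha", 0.5, float, "grid opacity")
    add("canvas.marginLeft", 0.5, float, "left margin (units)")
    add("canvas.marginRight", 0.5, float, "right margin (units)")
    add("canvas.marginTop", 0.5, float, "top margin (units)")
    add("canvas.marginBottom", 0.8, float, "bottom margin (units)")
    add("canvas.width", 10.0, float, "figure width (inches)")
    add("canvas.height", 7.0, float, "figure height (inches)")
    add("canvas.dpi", 150, int, "raster resolution")
    add("canvas.xPadding", 0.5, float, "horizontal data padding (units)")
    add("canvas.yPadding", 0.5, float, "vertical data padding (units)")
    add("canvas.invertY", True, bool, "generation 0 at the top")
    add("canvas.legendShow", True, bool, "draw legend")
    add("canvas.legendPosition", "upper right", str, "legend position")
    add("canvas.legendFontSize", 9.0, float, "legend font size (pt)")
    add("canvas.legendTitle", "", str, "legend title")
    add("canvas.legendFrame", False, bool, "draw legend frame")

    # -- heatmap -------------------------------------------------------------
    add("heatmap.cmap", "viridis", str, "heatmap colormap")
    add("heatmap.clusterMethod", "average", str, "linkage method for clustering")
    add("heatmap.showDendrogram", False, bool, "draw the dendrogram margin")
    add("heatmap.cellBorderColor", "", str, "cell border colour (empty = none)")
    add("heatmap.cellBorderWidth", 0.0, float, "cell border width (pt)")
    add("heatmap.showColorbar", True, bool, "draw the colourbar")
    add("heatmap.colorbarLabel", "relatedness", str, "colourbar label")
    add("heatmap.tickFontSize", 7.0, float, "id tick font size (pt)")
    add("heatmap.showTicks", True, bool, "label rows/columns with ids")
    add("heatmap.vmin", 0.0, float, "colour scale minimum")
    add("heatmap.vmax", -1.0, float, "colour scale maximum (-1 = data max)")
    add("heatmap.square", True, bool, "force square cells")

    # -- phenotype-by-degree -------------------------------------------------
    add("pbd.ribbonColor", "#4477aa", str, "CI ribbon colour")
    add("pbd.ribbonAlpha", 0.25, float, "CI ribbon opacity")
    add("pbd.lineColor", "#4477aa", str, "correlation line colour")
    add("pbd.pointSize", 30.0, float, "marker area (pt^2)")
    add("pbd.minPairs", 4, int, "min unique pairs for a CI")
    add("pbd.ciLevel", 0.95, float, "confidence level")
    add("pbd.xLabel", "additive relatedness", str, "x axis label")
    add("pbd.yLabel", "phenotypic correlation", str, "y axis label")
    add("pbd.showCounts", True, bool, "annotate bins with pair counts")
    add("pbd.dyadicTolerance", 1e-6, float, "snap tolerance for dyadic binning")

    return s


SCHEMA: Dict[str, Param] = _build_schema()


def count_config_parameters() -> int:
    """Number of documented leaf parameters in the schema."""
    return len(SCHEMA)


class _Group:
    """Attribute proxy over one schema subtree (``cfg.symbols.size``)."""

    def __init__(self, cfg: "PlotConfig", prefix: str):
        object.__setattr__(self, "_cfg", cfg)
        object.__setattr__(self, "_prefix", prefix)

    def __getattr__(self, name: str):
        path = f"{self._prefix}.{name}" if self._prefix else name
        if path in SCHEMA:
            return self._cfg.get(path)
        if any(k.startswith(path + ".") for k in SCHEMA):
            return _Group(self._cfg, path)
        raise AttributeError(_unknown_key_message(path))

    def __setattr__(self, name: str, value) -> None:
        path = f"{self._prefix}.{name}" if self._prefix else name
        self._cfg.set(path, value)


def _unknown_key_message(path: str) -> str:
    close = difflib.get_close_matches(path, SCHEMA.keys(), n=1)
    hint = f"; did you mean {close[0]!r}?" if close else ""
    return f"unknown config parameter {path!r}{hint}"


class PlotConfig:
    """Flat store of leaf values over the documented schema."""

    def __init__(self, overrides: Optional[Dict[str, Any]] = None):
        self._values: Dict[str, Any] = {}
        for path, value in (overrides or {}).items():
            self.set(path, value)

    def get(self, path: str):
        if path not in SCHEMA:
            raise KeyError(_unknown_key_message(path))
        if path in self._values:
            return self._values[path]
        d = SCHEMA[path].default
        return list(d) if isinstance(d, list) else d

    def set(self, path: str, value) -> None:
        if path not in SCHEMA:
            raise KeyError(_unknown_key_message(path))
        want = SCHEMA[path].type
        if want is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if want is bool and isinstance(value, str):
            value = value.strip().lower() in ("1", "true", "yes", "on")
        if want in (int, float) and isinstance(value, str):
            value = want(value)
        if not isinstance(value, want):
            raise TypeError(
                f"config parameter {path!r} expects {want.__name__}, "
                f"got {type(value).__name__}: {value!r}")
        self._values[path] = value

    def __getattr__(self, name: str):
        if name.startswith("_"):
            raise AttributeError(name)
        return _Group(self, "").__getattr__(name)

    def overrides(self) -> Dict[str, Any]:
        return dict(self._values)

    def as_dict(self) -> Dict[str, Any]:
        return {path: self.get(path) for path in SCHEMA}

    def copy(self) -> "PlotConfig":
        return PlotConfig(self.overrides())

    def __eq__(self, other) -> bool:
        return isinstance(other, PlotConfig) and self.as_dict() == other.as_dict()

    # -- YAML round trip -----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self._values, sort_keys=True, default_flow_style=False)
        if path is not None:
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _flatten(d: Dict[str, Any], prefix: str = "") -> Dict[str, Any]:
    out: Dict[str, Any] = {}
    for k, v in d.items():
        path = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict) and path not in SCHEMA:
            out.update(_flatten(v, path))
        else:
            out[path] = v
    return out


def load_config(source) -> PlotConfig:
    """Read a YAML config (nested or dotted keys) merged over the defaults.

    Unknown keys raise ``KeyError`` with a nearest-name suggestion; type
    mismatches raise ``TypeError``.  An empty file yields pure defaults.
    """
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise TypeError("config file must contain a mapping")
    return PlotConfig(_flatten(data))
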