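"""Layered, coordinate-aligned locus figures.

Panels are described declaratively (:class:`PanelSpec`) and realised by a
matplotlib backend; the same spec drives static (PDF/SVG/PNG) and
interactive (self-contained HTML with per-variant hover) output. The core
guarantee is alignment: every panel in an assembled figure gets bit-identical
x-limits, and loci with mismatched windows are rejected rather than silently
rescaled. SVG output is deterministic (fixed hash salt, no timestamp) so
figures can be snapshot-tested.
"""

from __future__ import annotations

import io
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib import ticker
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.patches import Rectangle

import numpy as np

from .annotation import TrackLayout, default_label_width, layout_gene_track
from .core import Locus, neglog10
from .overlays import (
    LD_BIN_LABELS,
    LD_INDEX_LABEL,
    ld_category,
    recomb_step_points,
)

# deterministic SVG ids for snapshot-stable output
plt.rcParams["svg.hashsalt"] = "locusplot"


class AlignmentError(ValueError):
    """Panels with mismatched loci cannot share an x-axis."""


#: Default aesthetic: index variant purple diamond, LD bins red -> navy
#: descending, NA grey; all overridable via a style mapping.
DEFAULT_STYLE = {
    "ld_colors": {
        LD_INDEX_LABEL: "#9632b8",
        "0.8-1.0": "#d43f3a",
        "0.6-0.8": "#eea236",
        "0.4-0.6": "#5cb85c",
        "0.2-0.4": "#46b8da",
        "0.0-0.2": "#357ebd",
        "na": "#b8b8b8",
    },
    "point_color": "#357ebd",
    "point_size": 18.0,
    "index_marker": "D",
    "symbol_by": None,            # None | "typed" | "direction"
    "recomb_color": "#6baed6",
    "recomb_ylim": (0.0, 100.0),  # fixed right axis in cM/Mb
    "gene_color": "#2c3e50",
    "gene_highlight_color": "#d62728",
    "label_fontsize": 7,
    "gene_fontsize": 7,
    "max_gene_rows": None,
}

_DIRECTION_MARKERS = {1: "^", -1: "v", 0: "o"}


def _style(overrides: Optional[dict]) -> dict:
    s = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_STYLE.items()}
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(s.get(k), dict):
            s[k].update(v)
        else:
            s[k] = v
    return s


@dataclass
class PanelSpec:
    """One panel of a figure: what to draw (kind + locus), how (style), which
    variants to label, and its relative height in the stack."""

    kind: str                       # scatter | eqtl | genetrack
    locus: Locus
    style: dict = field(default_factory=dict)
    labels: list = field(default_factory=list)
    height_share: float = 1.0
    highlight: tuple = ()           # gene symbols (genetrack)
    show_recomb: bool = True
    layout: Optional[TrackLayout] = None
    ylabel: Optional[str] = None


@dataclass
class FigureSpec:
    """Ordered top-to-bottom panel stack sharing one x-axis."""

    panels: list
    title: str = ""
    figsize: tuple = (7.0, 6.0)


def scatter_panel(locus, style=None, labels=(), height_share=3.0,
                  show_recomb=True) -> PanelSpec:
    return PanelSpec("scatter", locus, dict(style or {}), list(labels),
                     height_share, show_recomb=show_recomb)


def eqtl_panel(locus, style=None, labels=(), height_share=2.0) -> PanelSpec:
    return PanelSpec("eqtl", locus, dict(style or {}), list(labels),
                     height_share, show_recomb=False)


def genetrack_panel(locus, style=None, highlight=(), height_share=1.5,
                    layout=None, max_rows=None) -> PanelSpec:
    """Gene-track panel; the row layout is computed here (first-fit packing
    with label-aware extents) unless one is supplied."""
    st = _style(style)
    if layout is None:
        window = (locus.start, locus.end)
        layout = layout_gene_track(
            locus.genes, window,
            label_width_fn=default_label_width(window),
            max_rows=max_rows if max_rows is not None else st["max_gene_rows"],
        )
    return PanelSpec("genetrack", locus, dict(style or {}), [],
                     height_share, highlight=tuple(highlight), layout=layout)


def figure_spec(locus, *, style=None, labels=(), highlight=(), eqtl=False,
                title="") -> FigureSpec:
    """The standard layered layout: GWAS scatter on top, optional eQTL panel,
    gene track at the bottom."""
    panels = [scatter_panel(locus, style, labels)]
    if eqtl and locus.eqtl is not None:
        panels.append(eqtl_panel(locus, style))
    panels.append(genetrack_panel(locus, style, highlight))
    return FigureSpec(panels, title=title)


# ---------------------------------------------------------------------------
# Label placement
# ---------------------------------------------------------------------------

def place_labels(points: Sequence[tuple], texts: Sequence[str],
                 xrange: tuple, yrange: tuple,
                 char_width_frac: float = 0.012,
                 box_height_frac: float = 0.055) -> list:
    """Greedy non-overlapping label placement.

    Each label starts just above its anchor point and is nudged upward in
    box-height steps until its box is disjoint from every previously placed
    box. Returns (x0, y0, x1, y1) boxes in data coordinates, one per point,
    in input order. Pure geometry — drawing happens elsewhere.
    """
    xspan = xrange[1] - xrange[0]
    yspan = max(yrange[1] - yrange[0], 1e-12)
    h = box_height_frac * yspan
    placed = []
    order = sorted(range(len(points)), key=lambda i: (points[i][0], points[i][1]))
    boxes = [None] * len(points)
    for i in order:
        x, y = points[i]
        w = max(len(texts[i]), 1) * char_width_frac * xspan
        x0 = min(max(x - w / 2, xrange[0]), xrange[1] - w)
        y0 = y + 0.4 * h
        box = (x0, y0, x0 + w, y0 + h)
        while any(_boxes_overlap(box, b) for b in placed):
            y0 += h * 1.15
            box = (x0, y0, x0 + w, y0 + h)
        placed.append(box)
        boxes[i] = box
    return boxes


def _boxes_overlap(a, b) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def label_points(panel: PanelSpec, ids: Sequence[str],
                 placement: str = "auto") -> PanelSpec:
    """Return a panel spec with the given variant ids marked for labelling.

    Unknown ids are skipped with a warning. With an empty list, the index
    variant is labelled by default.
    """
    df = panel.locus.stats.df
    known = set(df["id"].astype(str)) if "id" in df.columns else set()
    ids = list(ids)
    if not ids and panel.locus.index_variant is not None:
        ids = [panel.locus.index_variant.id or str(panel.locus.index_variant.pos)]
    kept = []
    for i in ids:
        if i in known:
            kept.append(i)
        else:
            warnings.warn(f"label id {i!r} not in locus; skipped", stacklevel=2)
    return replace(panel, labels=list(panel.labels) + kept)


# ---------------------------------------------------------------------------
# Backend: drawing panels onto axes
# ---------------------------------------------------------------------------

def _variant_gid(vid, pos) -> str:
    base = vid if vid not in (None, "", "nan") else f"pos{pos}"
    return f"variant-{base}"


def _draw_scatter(ax, panel: PanelSpec, source: str = "gwas") -> dict:
    """Draw a scatter panel; returns per-variant drawn info (colour, marker,
    coordinates, hover text) keyed by gid."""
    st = _style(panel.style)
    locus = panel.locus
    if source == "eqtl":
        df = locus.eqtl
        ylab = panel.ylabel or "eQTL  -log10(p)"
    else:
        df = locus.stats.df
        ylab = panel.ylabel or "-log10(p)"
    if df is None or len(df) == 0:
        warnings.warn("empty panel: no variants to draw", stacklevel=2)
        ax.set_ylabel(ylab)
        return {}

    idx = locus.index_variant
    idx_id = idx.id if idx is not None else None
    info = {}
    rows = list(df.itertuples(index=False))
    # index variant drawn last (topmost)
    rows.sort(key=lambda r: (
        source == "gwas" and idx is not None
        and getattr(r, "id", None) == idx_id and r.pos == (idx.pos if idx else -1),
    ))
    ymax = 0.0
    for r in rows:
        vid = str(getattr(r, "id", "") or "")
        y = neglog10(float(r.p))
        ymax = max(ymax, y)
        is_index = (
            source == "gwas" and idx is not None
            and vid == (idx_id or "") and int(r.pos) == idx.pos
        )
        if source == "eqtl":
            marker = _DIRECTION_MARKERS.get(int(getattr(r, "direction", 0) or 0), "o")
            color = st["point_color"]
        else:
            if locus.ld is not None:
                cat = ld_category(locus.ld.get(vid), is_index=is_index)
                color = st["ld_colors"][cat]
            else:
                color = st["ld_colors"][LD_INDEX_LABEL] if is_index else st["point_color"]
            if is_index:
                marker = st["index_marker"]
            elif st["symbol_by"] == "typed":
                typed = getattr(r, "typed", None)
                marker = "o" if (typed is None or bool(typed)) else "s"
            elif st["symbol_by"] == "direction":
                marker = _DIRECTION_MARKERS.get(int(getattr(r, "direction", 0) or 0), "o")
            else:
                marker = "o"
        gid = ("eqtl-" if source == "eqtl" else "") + _variant_gid(vid, int(r.pos))
        ax.plot(
            [int(r.pos)], [y], linestyle="none", marker=marker,
            markersize=np.sqrt(st["point_size"]) * (1.4 if is_index else 1.0),
            markerfacecolor=color, markeredgecolor="#333333",
            markeredgewidth=0.4, gid=gid, zorder=5 if is_index else 3,
        )
        info[gid] = {
            "id": vid or str(int(r.pos)), "x": int(r.pos), "y": y,
            "color": color, "marker": marker, "is_index": is_index,
            "hover": f"{vid or int(r.pos)}  p={float(r.p):.3g}",
        }
    ax.set_ylabel(ylab)
    ax.set_ylim(0, max(ymax * 1.12, 1.0))

    if panel.show_recomb and locus.recomb:
        ax2 = ax.twinx()
        xs, ys = recomb_step_points(locus.recomb)
        ax2.plot(xs, ys, color=st["recomb_color"], linewidth=1.0,
                 drawstyle="steps-post", zorder=1, gid="recomb-track")
        ax2.set_ylim(*st["recomb_ylim"])
        ax2.set_ylabel("recombination rate (cM/Mb)", fontsize=8)
        ax2.set_xlim(locus.start, locus.end)

    if panel.labels:
        sub = df[df["id"].astype(str).isin([str(i) for i in panel.labels])]
        pts = [(int(r.pos), neglog10(float(r.p))) for r in sub.itertuples(index=False)]
        texts = [str(r.id) for r in sub.itertuples(index=False)]
        ylim = ax.get_ylim()
        boxes = place_labels(pts, texts, (locus.start, locus.end), ylim)
        for (x, y), t, box in zip(pts, texts, boxes):
            ax.annotate(
                t, xy=(x, y), xytext=((box[0] + box[2]) / 2, box[1]),
                fontsize=st["label_fontsize"], ha="center", va="bottom",
                arrowprops=dict(arrowstyle="-", linewidth=0.5, color="#555555"),
                gid=f"label-{t}",
            )
        ax.set_ylim(ylim[0], max(ylim[1], max(b[3] for b in boxes) * 1.05))
    return info


def _draw_genetrack(ax, panel: PanelSpec) -> dict:
    """Draw the gene track from the panel's TrackLayout; returns per-gene
    drawn info (row, y-band) keyed by symbol."""
    st = _style(panel.style)
    layout = panel.layout
    info = {}
    n = max(layout.n_rows, 1)
    wstart, wend = layout.window
    for pl in layout.placements:
        g = pl.gene
        y = n - pl.row + 1  # row 1 at the top
        color = (st["gene_highlight_color"] if g.symbol in panel.highlight
                 else st["gene_color"])
        cs, ce = max(g.start, wstart), min(g.end, wend)
        ax.plot([cs, ce], [y, y], color=color, linewidth=0.9, zorder=2,
                gid=f"gene-{g.symbol}")
        for (ea, eb) in g.exons:
            ea, eb = max(ea, wstart), min(eb, wend)
            if ea > eb:
                continue
            ax.add_patch(Rectangle((ea, y - 0.18), max(eb - ea, 1), 0.36,
                                   facecolor=color, edgecolor="none", zorder=3))
        # strand arrowheads along the intron line
        if g.strand in "+-":
            marker = ">" if g.strand == "+" else "<"
            xs = np.linspace(cs, ce, 4)[1:-1]
            ax.plot(xs, [y] * len(xs), linestyle="none", marker=marker,
                    markersize=2.5, color=color, zorder=2)
        # truncation markers where the gene runs past the window
        if pl.clipped_left:
            ax.plot([wstart], [y], marker="<", markersize=4, color=color, zorder=4)
        if pl.clipped_right:
            ax.plot([wend], [y], marker=">", markersize=4, color=color, zorder=4)
        tx = cs - 0.004 * (wend - wstart) if pl.label_side == "left" else ce + 0.004 * (wend - wstart)
        ax.text(tx, y, g.symbol, fontsize=st["gene_fontsize"],
                ha="right" if pl.label_side == "left" else "left", va="center",
                style="italic", color=color, gid=f"genelabel-{g.symbol}")
        info[g.symbol] = {"row": pl.row, "y": y, "band": (y - 0.18, y + 0.18),
                          "color": color}
    if layout.clipped:
        ax.text(wend, 0.25, f"+{len(layout.clipped)} more", fontsize=6,
                ha="right", va="bottom", color="#666666", gid="genetrack-clipped")
    ax.set_ylim(0, n + 1)
    ax.set_yticks([])
    return info


# ---------------------------------------------------------------------------
# Figure assembly
# ---------------------------------------------------------------------------

def assemble_figure(spec: FigureSpec, target=None):
    """Realise a FigureSpec as a matplotlib Figure.

    Panels are stacked top to bottom with heights proportional to their
    height shares and one shared x-axis; x-limits are set to exactly the
    locus window on every panel (bit-identical across panels). Panels whose
    loci differ in chromosome or window raise :class:`AlignmentError`.
    """
    if not spec.panels:
        raise ValueError("figure needs at least one panel")
    first = spec.panels[0].locus
    for p in spec.panels[1:]:
        if (p.locus.chrom, p.locus.start, p.locus.end) != (first.chrom, first.start, first.end):
            raise AlignmentError(
                f"panel locus {p.locus.chrom}:{p.locus.start}-{p.locus.end} does not "
                f"match {first.chrom}:{first.start}-{first.end}; refusing to rescale"
            )

    fig = target if target is not None else plt.figure(figsize=spec.figsize)
    shares = [p.height_share for p in spec.panels]
    gs = fig.add_gridspec(len(spec.panels), 1, height_ratios=shares, hspace=0.12)
    axes, info = [], {}
    for i, panel in enumerate(spec.panels):
        ax = fig.add_subplot(gs[i, 0])
        if panel.kind == "scatter":
            info[i] = _draw_scatter(ax, panel, source="gwas")
        elif panel.kind == "eqtl":
            info[i] = _draw_scatter(ax, panel, source="eqtl")
        elif panel.kind == "genetrack":
            info[i] = _draw_genetrack(ax, panel)
        else:
            raise ValueError(f"unknown panel kind {panel.kind!r}")
        ax.set_xlim(first.start, first.end)
        ax.xaxis.set_major_formatter(ticker.FuncFormatter(lambda x, _: f"{x / 1e6:.2f}"))
        if i < len(spec.panels) - 1:
            ax.tick_params(labelbottom=False)
        axes.append(ax)
    axes[-1].set_xlabel(f"chromosome {first.chrom} position (Mb)")
    if spec.title:
        fig.suptitle(spec.title, fontsize=10)
    fig._locusplot_axes = axes
    fig._locusplot_info = info
    return fig


def multi_locus_page(specs: Sequence[FigureSpec], grid: tuple):
    """Place several locus figures on one page in row-major order.

    Each figure keeps its own x-axis (the loci differ); the grid must be
    large enough for all figures.
    """
    rows, cols = grid
    if len(specs) > rows * cols:
        raise ValueError(f"{len(specs)} figures do not fit a {rows}x{cols} grid")
    fig = plt.figure(figsize=(cols * 5.0, rows * 4.0))
    subfigs = np.atleast_2d(fig.subfigures(rows, cols, squeeze=False))
    for i, s in enumerate(specs):
        assemble_figure(s, target=subfigs[i // cols][i % cols])
    return fig


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_SVG_NS = "http://www.w3.org/2000/svg"


def _figure_svg_bytes(fig) -> bytes:
    buf = io.BytesIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    return buf.getvalue()


def figure_to_html(fig) -> str:
    """Self-contained interactive HTML: the figure's SVG with one hover
    ``<title>`` entry injected per drawn variant."""
    hover = {}
    for panel_info in getattr(fig, "_locusplot_info", {}).values():
        for gid, d in panel_info.items():
            if isinstance(d, dict) and "hover" in d:
                hover[gid] = d["hover"]
    ET.register_namespace("", _SVG_NS)
    ET.register_namespace("xlink", "http://www.w3.org/1999/xlink")
    root = ET.fromstring(_figure_svg_bytes(fig))
    for el in root.iter():
        gid = el.attrib.get("id", "")
        if gid in hover:
            t = ET.Element(f"{{{_SVG_NS}}}title")
            t.text = hover[gid]
            el.insert(0, t)
    svg = ET.tostring(root, encoding="unicode")
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<style>g[id^='variant-']:hover,g[id^='eqtl-']:hover{opacity:0.5;}</style>"
        "</head><body>\n" + svg + "\n</body></html>\n"
    )


def export(figures, path, format: Optional[str] = None, dpi: int = 150,
           close: bool = False) -> None:
    """Write one figure (pdf/svg/png/html) or a sequence of figures (pdf:
    one page each). Figures may be given lazily as callables returning a
    Figure so 100+ locus batches stream one figure at a time."""
    path = str(path)
    if format is None:
        format = path.rsplit(".", 1)[-1].lower()
    single = not isinstance(figures, (list, tuple))
    figs = [figures] if single else list(figures)

    def _realise(f):
        return f() if callable(f) else f

    if format == "pdf":
        with PdfPages(path) as pdf:
            for f in figs:
                f = _realise(f)
                pdf.savefig(f)
                if close or callable(figures) or not single:
                    plt.close(f)
        return
    if len(figs) != 1:
        raise ValueError(f"{format} export takes exactly one figure")
    fig = _realise(figs[0])
    if format == "svg":
        with open(path, "wb") as fh:
            fh.write(_figure_svg_bytes(fig))
    elif format == "png":
        fig.savefig(path, format="png", dpi=dpi)
    elif format == "html":
        with open(path, "w") as fh:
            fh.write(figure_to_html(fig))
    else:
        raise ValueError(f"unknown export format {format!r}")
    if close:
        plt.close(fig)
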