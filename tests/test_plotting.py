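"""Figure assembly: panel alignment, LD colouring, gene-track rendering,
label collision handling, and export formats."""

import io
import xml.etree.ElementTree as ET

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pytest

import locusplot as lp
from oracles import pdf_page_count
from locusplot.plotting import (
    DEFAULT_STYLE,
    _draw_scatter,
    place_labels,
)


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")


def small_locus(n=3, with_ld=False):
    df = pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "pos": np.linspace(1000, 9000, n).astype(int),
            "p": np.logspace(-8, -2, n),
            "id": [f"rs{i}" for i in range(n)],
        }
    )
    locus = lp.make_locus(lp.from_dataframe(df), region=("1", 500, 10_000))
    if with_ld:
        ld = lp.LDTable(index_id="rs0",
                        values={f"rs{i}": max(0.0, 1.0 - 0.3 * i) for i in range(n)})
        lp.attach_overlays(locus, ld=ld)
    return locus


class TestScatterPanel:
    def test_every_variant_drawn_once_default_colour(self):
        locus = small_locus(3)
        fig = lp.assemble_figure(lp.FigureSpec([lp.scatter_panel(locus)]))
        info = fig._locusplot_info[0]
        assert len(info) == 3
        non_index = [d for d in info.values() if not d["is_index"]]
        assert {d["color"] for d in non_index} == {DEFAULT_STYLE["point_color"]}

    def test_ld_attached_colours_match_category_table(self, demo_locus):
        fig = lp.assemble_figure(lp.FigureSpec([lp.scatter_panel(demo_locus)]))
        info = fig._locusplot_info[0]
        assert len(info) == len(demo_locus.stats)
        for d in info.values():
            cat = lp.ld_category(demo_locus.ld.get(d["id"]), is_index=d["is_index"])
            assert d["color"] == DEFAULT_STYLE["ld_colors"][cat]

    def test_index_variant_topmost_distinct_symbol(self, demo_locus):
        fig = lp.assemble_figure(lp.FigureSpec([lp.scatter_panel(demo_locus)]))
        info = fig._locusplot_info[0]
        idx = [d for d in info.values() if d["is_index"]]
        assert len(idx) == 1
        assert idx[0]["marker"] == DEFAULT_STYLE["index_marker"]

    def test_recomb_secondary_axis_in_cm_per_mb(self, demo_locus):
        fig = lp.assemble_figure(lp.FigureSpec([lp.scatter_panel(demo_locus)]))
        labels = [ax.get_ylabel() for ax in fig.axes]
        assert any("cM/Mb" in l for l in labels)

    def test_direction_symbols_in_eqtl_panel(self, demo_locus):
        fig = lp.assemble_figure(lp.FigureSpec([lp.eqtl_panel(demo_locus)]))
        info = fig._locusplot_info[0]
        by_id = {d["id"]: d["marker"] for d in info.values()}
        for r in demo_locus.eqtl.itertuples(index=False):
            assert by_id[str(r.id)] == {1: "^", -1: "v", 0: "o"}[int(r.direction)]

    def test_empty_stats_warns(self):
        df = pd.DataFrame({"chrom": ["1"], "pos": [50], "p": [0.5], "id": ["r"]})
        with pytest.warns(UserWarning, match="no variants"):
            locus = lp.make_locus(lp.from_dataframe(df), region=("1", 1000, 2000))
        fig = plt.figure()
        ax = fig.add_subplot()
        with pytest.warns(UserWarning, match="empty panel"):
            assert _draw_scatter(ax, lp.scatter_panel(locus)) == {}


class TestGenetrackPanel:
    def test_exon_rectangles_and_line(self):
        g = lp.GeneModel("G1", "ABC", "1", 1000, 9000, "+", "protein_coding",
                         ((1000, 2000), (7000, 9000)))
        locus = small_locus()
        locus.genes = [g]
        fig = lp.assemble_figure(lp.FigureSpec([lp.genetrack_panel(locus)]))
        ax = fig._locusplot_axes[0]
        assert len(ax.patches) == 2  # one rectangle per exon
        assert any(line.get_gid() == "gene-ABC" for line in ax.lines)

    def test_highlighted_gene_uses_highlight_colour(self, demo_locus):
        sym = demo_locus.genes[0].symbol
        fig = lp.assemble_figure(
            lp.FigureSpec([lp.genetrack_panel(demo_locus, highlight=(sym,))])
        )
        info = fig._locusplot_info[0]
        assert info[sym]["color"] == DEFAULT_STYLE["gene_highlight_color"]
        others = [d for s, d in info.items() if s != sym]
        assert all(d["color"] == DEFAULT_STYLE["gene_color"] for d in others)

    def test_drawn_rows_match_track_layout(self, demo_locus):
        panel = lp.genetrack_panel(demo_locus)
        fig = lp.assemble_figure(lp.FigureSpec([panel]))
        info = fig._locusplot_info[0]
        for pl in panel.layout.placements:
            d = info[pl.gene.symbol]
            assert d["row"] == pl.row
            assert d["band"][0] < d["y"] < d["band"][1]
            assert d["y"] == panel.layout.n_rows - pl.row + 1

    def test_clipped_caption_present_when_rows_capped(self, demo_locus):
        panel = lp.genetrack_panel(demo_locus, max_rows=1)
        assert panel.layout.clipped  # 12 genes in 1 Mb cannot fit one row
        fig = lp.assemble_figure(lp.FigureSpec([panel]))
        texts = [t.get_text() for t in fig._locusplot_axes[0].texts]
        assert f"+{len(panel.layout.clipped)} more" in texts


class TestAssembleFigure:
    def test_three_panel_layered_layout_shares_xrange(self, demo_locus):
        spec = lp.figure_spec(demo_locus, eqtl=True)
        assert [p.kind for p in spec.panels] == ["scatter", "eqtl", "genetrack"]
        fig = lp.assemble_figure(spec)
        xlims = {ax.get_xlim() for ax in fig.axes}
        assert xlims == {(float(demo_locus.start), float(demo_locus.end))}

    def test_single_panel_figure(self):
        locus = small_locus()
        fig = lp.assemble_figure(lp.FigureSpec([lp.scatter_panel(locus)]))
        assert len(fig._locusplot_axes) == 1

    def test_mismatched_windows_rejected(self, sim_stats):
        stats, _ = sim_stats
        a = lp.make_locus(stats, region=("1", 9_500_001, 10_500_000))
        b = lp.make_locus(stats, region=("1", 9_500_001, 10_400_000))
        with pytest.raises(lp.AlignmentError):
            lp.assemble_figure(
                lp.FigureSpec([lp.scatter_panel(a), lp.scatter_panel(b)])
            )

    def test_height_shares_respected(self, demo_locus):
        spec = lp.FigureSpec(
            [lp.scatter_panel(demo_locus, height_share=3.0),
             lp.genetrack_panel(demo_locus, height_share=1.0)]
        )
        fig = lp.assemble_figure(spec)
        h = [ax.get_position().height for ax in fig._locusplot_axes]
        assert h[0] / h[1] == pytest.approx(3.0, rel=0.05)


class TestLabels:
    def test_single_label_anchored(self):
        locus = small_locus(3)
        panel = lp.label_points(lp.scatter_panel(locus), ["rs1"])
        fig = lp.assemble_figure(lp.FigureSpec([panel]))
        ann = [t for t in fig._locusplot_axes[0].texts if t.get_text() == "rs1"]
        assert len(ann) == 1

    def test_unknown_id_warns_and_skips(self):
        locus = small_locus(3)
        with pytest.warns(UserWarning, match="rs99"):
            panel = lp.label_points(lp.scatter_panel(locus), ["rs99", "rs1"])
        assert panel.labels == ["rs1"]

    def test_empty_ids_default_to_index_variant(self):
        locus = small_locus(3)
        panel = lp.label_points(lp.scatter_panel(locus), [])
        assert panel.labels == [locus.index_variant.id]

    def test_near_coincident_points_get_disjoint_boxes(self):
        pts = [(100.0, 5.0), (101.0, 5.0), (100.5, 5.01)]
        boxes = place_labels(pts, ["aaa", "bbb", "ccc"], (0, 1000), (0, 10))
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                disjoint = a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]
                assert disjoint, (a, b)


class TestExport:
    def test_multipage_pdf_page_count(self, tmp_path, demo_locus):
        figs = [lp.assemble_figure(lp.figure_spec(demo_locus)) for _ in range(3)]
        out = tmp_path / "batch.pdf"
        lp.export(figs, out)
        data = out.read_bytes()
        assert pdf_page_count(data) == 3

    def test_svg_is_valid_xml(self, tmp_path, demo_locus):
        out = tmp_path / "fig.svg"
        lp.export(lp.assemble_figure(lp.figure_spec(demo_locus)), out)
        root = ET.parse(out).getroot()
        assert root.tag.endswith("svg")

    def test_svg_snapshot_stable_across_runs(self, tmp_path, demo_locus):
        outs = []
        for name in ("a.svg", "b.svg"):
            fig = lp.assemble_figure(lp.figure_spec(demo_locus, title="snap"))
            lp.export(fig, tmp_path / name)
            outs.append((tmp_path / name).read_bytes())
            plt.close(fig)
        assert outs[0] == outs[1]

    def test_html_has_one_hover_entry_per_variant(self, tmp_path, demo_locus):
        fig = lp.assemble_figure(lp.FigureSpec([lp.scatter_panel(demo_locus)]))
        out = tmp_path / "fig.html"
        lp.export(fig, out)
        html = out.read_text()
        assert html.count("<title>") == len(demo_locus.stats)
        for vid in demo_locus.stats.df["id"].astype(str).head(10):
            assert f"variant-{vid}" in html

    def test_png_written(self, tmp_path):
        fig = lp.assemble_figure(lp.FigureSpec([lp.scatter_panel(small_locus())]))
        out = tmp_path / "fig.png"
        lp.export(fig, out, dpi=60)
        assert out.stat().st_size > 0


class TestMultiLocusPage:
    def _specs(self, stats, windows):
        return [
            lp.FigureSpec([lp.scatter_panel(
                lp.make_locus(stats, region=("1", a, b)))])
            for a, b in windows
        ]

    def test_three_figures_in_two_by_two(self, sim_stats):
        stats, _ = sim_stats
        specs = self._specs(
            stats, [(1, 2_000_000), (9_500_001, 10_500_000), (29_000_000, 31_000_000)]
        )
        fig = lp.multi_locus_page(specs, grid=(2, 2))
        assert len(fig.subfigs) == 4

    def test_each_keeps_its_own_xrange(self, sim_stats):
        stats, _ = sim_stats
        windows = [(1, 2_000_000), (9_500_001, 10_500_000)]
        specs = self._specs(stats, windows)
        fig = lp.multi_locus_page(specs, grid=(1, 2))
        got = sorted(ax.get_xlim() for sf in fig.subfigs for ax in sf.axes)
        assert got == sorted((float(a), float(b)) for a, b in windows)

    def test_overflow_rejected(self, sim_stats):
        stats, _ = sim_stats
        specs = self._specs(stats, [(1, 2_000_000)] * 3)
        with pytest.raises(ValueError, match="grid"):
            lp.multi_locus_page(specs, grid=(1, 2))
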