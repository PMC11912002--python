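"""Gene models from GFF3/GTF, region queries, and the gene-track layout.

Gene structure is collapsed to one drawn model per gene: the union of all
exons across transcripts (overlapping exons merged). Region queries run on
per-chromosome interval trees. The track layout is a greedy first-fit
interval packing: genes sorted by start are placed on the lowest display
row where their extent — the gene span clipped to the window, widened by
the label — does not collide with anything already placed. With zero label
widths this is the classic first-fit interval colouring, which uses exactly
max-overlap-depth rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

from .core import normalize_chrom

logger = logging.getLogger("locusplot")


class FormatError(ValueError):
    """An annotation file could not be parsed in the named format."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: stable id, display symbol, 1-based inclusive span, strand
    (+/-/. for unknown), biotype, and merged exon intervals."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = ""
    exons: tuple = ()

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for (a, b) in self.exons:
            if not (self.start <= a <= b <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({a},{b}) outside span")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class GeneAnnotation:
    """Indexed collection of GeneModels supporting by-symbol/id lookup and
    region overlap queries (each overlapping gene returned exactly once)."""

    def __init__(self, genes: Iterable[GeneModel], source: str = ""):
        self.genes = list(genes)
        self.source = source
        self._by_id = {}
        self._by_symbol = {}
        self._trees = {}
        for g in self.genes:
            self._by_id[g.gene_id] = g
            self._by_symbol.setdefault(g.symbol, g)
            # interval trees are half-open; +1 converts the inclusive end
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)

    def __len__(self) -> int:
        return len(self.genes)

    def get_gene(self, key: str) -> Optional[GeneModel]:
        return self._by_symbol.get(key) or self._by_id.get(key)

    def query(self, chrom, start: int, end: int, biotypes: Optional[set] = None):
        return query_genes(self, chrom, start, end, biotypes)


def query_genes(
    ann: GeneAnnotation, chrom, start: int, end: int, biotypes: Optional[set] = None
) -> list:
    """Genes whose span overlaps [start, end] (1-based inclusive), ordered by
    start; optionally restricted to the given biotypes."""
    if start > end:
        raise ValueError(f"query start {start} > end {end}")
    tree = ann._trees.get(normalize_chrom(chrom))
    if tree is None:
        return []
    hits = {iv.data.gene_id: iv.data for iv in tree.overlap(start, end + 1)}
    out = sorted(hits.values(), key=lambda g: (g.start, g.end, g.gene_id))
    if biotypes is not None:
        out = [g for g in out if g.biotype in biotypes]
    return out


#: Named biotype presets; "protein_coding" restricts the track to coding genes.
BIOTYPE_PRESETS = {"protein_coding": {"protein_coding"}}


def _merge_intervals(ivs: Sequence[tuple]) -> tuple:
    """Union of 1-based inclusive intervals; strictly overlapping intervals
    merge, abutting ones stay separate."""
    ivs = sorted(ivs)
    out = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return tuple(out)


def _attr(feature, *names, default=""):
    for n in names:
        if n in feature.attributes:
            v = feature.attributes[n]
            return v[0] if isinstance(v, list) else v
    return default


def load_gene_models(path, format: Optional[str] = None) -> GeneAnnotation:
    """Load gene models from a GFF3 or GTF file.

    The format is inferred from the extension when not given. Transcript-level
    detail is collapsed to the union of exons per gene. A parse failure raises
    :class:`FormatError`; a file with zero gene features returns an empty
    annotation with a warning.
    """
    path = str(path)
    if format is None:
        low = path.lower()
        format = "gtf" if low.endswith((".gtf", ".gtf.gz")) else "gff3"
    if format not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation format {format!r}")

    try:
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        if "No lines parsed" in str(exc):
            warnings.warn(f"{path} contains no gene features", stacklevel=2)
            return GeneAnnotation([], source=f"{path} ({format})")
        raise FormatError(f"could not parse {path} as {format}: {exc}") from exc

    genes = _genes_from_gtf(db) if format == "gtf" else _genes_from_gff3(db)
    if not genes:
        warnings.warn(f"{path} contains no gene features", stacklevel=2)
    return GeneAnnotation(genes, source=f"{path} ({format})")


def _genes_from_gff3(db) -> list:
    genes = []
    for feat in db.features_of_type("gene"):
        exons = [(e.start, e.end) for e in db.children(feat, featuretype="exon")]
        if not exons:
            exons = [(feat.start, feat.end)]
        gene_id = _attr(feat, "gene_id", "ID", default=feat.id)
        if gene_id.startswith("gene:"):
            gene_id = gene_id[5:]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=_attr(feat, "gene_name", "Name", "gene_id", default=gene_id),
                chrom=normalize_chrom(feat.seqid),
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else ".",
                biotype=_attr(feat, "gene_biotype", "biotype", "gene_type"),
                exons=_merge_intervals(exons),
            )
        )
    return genes


def _genes_from_gtf(db) -> list:
    """GTF carries gene identity in attributes, not feature hierarchy; group
    all features by gene_id. Gene span comes from an explicit gene/transcript
    feature when present, else the exon union."""
    groups: dict = {}
    for feat in db.all_features():
        gid = _attr(feat, "gene_id", default="")
        if not gid:
            continue
        g = groups.setdefault(
            gid, {"exons": [], "spans": [], "chrom": normalize_chrom(feat.seqid),
                  "strand": feat.strand, "symbol": "", "biotype": ""}
        )
        if feat.featuretype == "exon":
            g["exons"].append((feat.start, feat.end))
        elif feat.featuretype in ("gene", "transcript", "mRNA"):
            g["spans"].append((feat.start, feat.end))
        g["symbol"] = g["symbol"] or _attr(feat, "gene_name")
        g["biotype"] = g["biotype"] or _attr(feat, "gene_biotype", "gene_type")
    genes = []
    for gid, g in groups.items():
        all_iv = g["spans"] + g["exons"]
        if not all_iv:
            continue
        start = min(a for a, _ in all_iv)
        end = max(b for _, b in all_iv)
        exons = _merge_intervals(g["exons"]) if g["exons"] else ((start, end),)
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=g["symbol"] or gid,
                chrom=g["chrom"],
                start=start,
                end=end,
                strand=g["strand"] if g["strand"] in "+-" else ".",
                biotype=g["biotype"],
                exons=exons,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Track layout
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    gene: GeneModel
    row: int                      # 1-based display row
    extent: tuple                 # (start, end) genomic units: span U label
    clipped_left: bool = False    # gene truncated at the window edge
    clipped_right: bool = False
    label_side: str = "left"


@dataclass
class TrackLayout:
    """Genes assigned to non-overlapping display rows.

    Within a row no two extents (gene span clipped to the window, unioned
    with the label box) overlap; genes that would need more than ``max_rows``
    rows are listed in ``clipped``.
    """

    placements: list = field(default_factory=list)
    n_rows: int = 0
    clipped: list = field(default_factory=list)
    window: tuple = (0, 0)


def default_label_width(window: tuple, per_char_frac: float = 0.009) -> Callable:
    """Label width estimator: character count x a per-character width expressed
    as a fraction of the window span (default 0.9% per character)."""
    span = window[1] - window[0] + 1

    def width(gene: GeneModel) -> float:
        return len(gene.symbol) * per_char_frac * span

    return width


def layout_gene_track(
    genes: Sequence[GeneModel],
    window: tuple,
    label_width_fn: Optional[Callable] = None,
    max_rows: Optional[int] = None,
) -> TrackLayout:
    """Greedy first-fit interval packing of genes into display rows.

    Genes are clipped to the window, sorted by (clipped) start, and each is
    placed on the lowest row where its extent does not overlap an existing
    placement. Labels sit left of the gene span by default and flip to the
    right when the left extent would exit the window. Input order does not
    matter; genes wholly outside the window are ignored.
    """
    wstart, wend = window
    if label_width_fn is None:
        label_width_fn = lambda g: 0.0

    items = []
    for g in genes:
        if g.end < wstart or g.start > wend:
            continue
        cs, ce = max(g.start, wstart), min(g.end, wend)
        w = float(label_width_fn(g))
        side = "left"
        ext = (cs - w, float(ce))
        if ext[0] < wstart:
            side = "right"
            ext = (float(cs), ce + w)
        items.append(
            Placement(
                gene=g,
                row=0,
                extent=ext,
                clipped_left=g.start < wstart,
                clipped_right=g.end > wend,
                label_side=side,
            )
        )
    items.sort(key=lambda p: (p.extent[0], p.extent[1], p.gene.gene_id))

    rows: list = []  # per row: list of extents
    placements, clipped = [], []
    for it in items:
        placed = False
        for r, extents in enumerate(rows):
            if all(it.extent[0] > e[1] or it.extent[1] < e[0] for e in extents):
                it.row = r + 1
                extents.append(it.extent)
                placements.append(it)
                placed = True
                break
        if not placed:
            if max_rows is not None and len(rows) >= max_rows:
                clipped.append(it.gene)
                continue
            rows.append([it.extent])
            it.row = len(rows)
            placements.append(it)
    return TrackLayout(placements=placements, n_rows=len(rows), clipped=clipped,
                       window=(wstart, wend))
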