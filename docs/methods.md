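# Methods

## Coordinate conventions

All positions are 1-based and all windows inclusive on both ends, the
frame used by GFF/GTF and by GWAS summary statistics. BED/bedGraph/bigWig
inputs (0-based, half-open) are converted once, at the reader boundary;
nothing downstream ever mixes frames. Chromosome labels are normalised on
load (strip `chr`, uppercase X/Y/MT, `M` → `MT`) so UCSC- and
Ensembl-style sources join correctly. Sorting uses the natural genome
order 1–22, X, Y, MT, then other contigs lexicographically.

## Summary statistics

`read_summary_stats` streams delimited text in chunks (default 10⁶ rows)
so multi-million-row files load in bounded memory. Rows with an
unparseable position, a missing chromosome, or a *p*-value outside [0, 1]
are dropped and counted rather than raising: real summary-statistics files
routinely contain artefact rows and a hard failure would abort batch runs.
A missing *mandatory* column (chromosome, position, *p*) is a
configuration error, because silently guessing columns is worse than
failing.

−log10 *p* is the display scale throughout. *p* = 0 (which occurs in
published files when the true value underflows double precision) maps to a
configurable cap, default 300 ≈ −log10 of the smallest positive double,
with a warning: the axis stays finite and the point stays visible.

The index variant of a window is the minimum-*p* record; ties break by
smallest position, then lexicographic variant id. The rule is arbitrary
but total, which is what matters — every downstream artefact (LD
colouring, labels, peak lists) is then deterministic.

## Peak scanning

`quickpeak` implements greedy select-and-exclude: take the unmasked
variant with the smallest *p* below the cutoff, emit it, mask every
variant on the same chromosome within ± span/2, repeat. Defaults:
`p_cutoff = 5e-8` (the conventional genome-wide significance level) and
`span = 1 Mb`, matching the 1 Mb plotting window so that one parameter
governs both the exclusion geometry and the figure extent. The masking
boundary is inclusive: a variant exactly span/2 away is masked, so
surviving peaks are pairwise strictly farther apart than span/2.

Implementation: candidates below the cutoff are sorted once by
(*p*, genome order, id); each emitted peak masks an interval found by two
binary searches in the per-chromosome position array. Runtime is
sort-dominated (near-linear in record count); the tests assert exact
record-level equality with a literal O(n·k) re-scan oracle rather than any
wall-clock figure, since speed claims are hardware-bound.

Peaks are distance-pruned only; LD-aware clumping and conditional analysis
are out of scope.

## Gene models and track layout

GFF3/GTF parsing is delegated to `gffutils`. Transcript detail is
collapsed to one drawn model per gene — the union of all exons across
transcripts, with strictly overlapping exons merged (abutting exons are
kept distinct so serialisation round-trips exactly). GTF carries gene
identity in attributes rather than feature hierarchy, so GTF features are
grouped by `gene_id`, taking the span from explicit gene/transcript
features when present and the exon union otherwise.

The gene track uses greedy first-fit interval packing: genes clipped to
the window and widened by their label box are sorted by start and each
placed on the lowest row whose existing extents it does not intersect.
With zero-width labels this is first-fit colouring of an interval graph,
which is optimal — it uses exactly the maximum overlap depth — and the
test suite asserts that equality against a sweep-line oracle. Labels sit
left of the gene span and flip right when they would exit the window;
label width is estimated as character count × 0.9 % of the window span per
character, a deliberately crude but deterministic stand-in for font
metrics. Genes that would exceed an optional `max_rows` cap are dropped
from the drawing and reported in a "+N more" caption.

## Overlays

**LD.** r² against the index variant is binned into the classic five
0.2-wide bins (left-closed, top bin closed at 1), plus an NA bin for
variants without LD data and a distinct category for the index variant
itself. Default colours run red (r² ≥ 0.8) → navy with grey NA and a
purple diamond index; everything is overridable through a style mapping.

**Recombination rate.** The track is piecewise-constant (bedGraph
semantics), stored 1-based inclusive. Overlapping source intervals are
resolved last-row-wins by an elementary-segment sweep, with a warning;
abutting intervals are never merged. Attaching a track to a locus clips
segments to the window; this resampling conserves the track exactly — the
integral (rate × bp) of the clipped segments equals the integral of the
overlapping source intervals, which the tests check to 1e-9 relative. The
plot draws the segments as a stepped line on a right-hand secondary axis
fixed at 0–100 cM/Mb by default (configurable), with NaN breaks across
coverage gaps.

**eQTL.** Rows are filtered to the locus window and drawn with direction
glyphs: up-triangle for positive effect on expression, down-triangle for
negative, circle for unknown.

**Providers and caching.** Remote sources sit behind a two-method
contract (`fetch(key) → payload`); tests and batch runs use a file-backed
double. `cached_fetch` writes each JSON-serialisable payload to one file
per key (SHA-256 of the canonical key) in a cache directory, so an
identical query is fetched at most once — including across process
restarts. A corrupted cache entry is bypassed with a warning. Live
network clients are intentionally out of scope; local files are the
recommended batch path anyway.

## Figures

Panels are declarative (`PanelSpec`) and realised by a matplotlib
backend; the same description drives PDF/SVG/PNG and the interactive HTML
export, which injects one SVG `<title>` hover entry per drawn variant into
the variant's SVG group. Assembly validates that every panel shares one
chromosome and identical window bounds and then sets the same x-limits on
every axes; mismatches raise instead of rescaling. Heights follow the
panels' relative shares (defaults 3 : 2 : 1.5 for scatter : eQTL : gene
track).

Label collision is handled by greedy vertical nudging: each label box
starts above its anchor and moves up in box-height steps until disjoint
from all placed boxes; a leader line connects box to point. The placement
routine is pure geometry and unit-tested directly.

SVG output is deterministic — a fixed `svg.hashsalt` and no embedded
timestamp — so figures snapshot-compare byte-for-byte across runs.
Multi-page PDF export accepts lazily constructed figures and closes each
page after writing, bounding memory on 100+ locus batches. Multi-locus
pages place independent figures (each keeping its own x-range) on a
row-major grid of subfigures.

## Synthetic data

The generators exist so every pipeline stage is testable with no
downloads; all are pure functions of (parameters, seed).

* `simulate_gwas`: background −log10 *p* ~ Exponential(mean 1/ln 10),
  i.e. *p* ~ Uniform(0, 1); each planted peak contributes
  height · exp(−d/τ) + N(0, 0.25²) within 5τ of the causal position,
  floored at 0 and combined with the background by max. One variant is
  emitted exactly at each causal position — the causal variant is treated
  as genotyped — which makes parameter-recovery outcomes sharp. Default
  study conditions used in tests and the acceptance script: 12,000–20,000
  SNPs, τ = 50 kb, heights 8–12, peaks ≥ 2 Mb apart.
* `simulate_genes`: uniform starts, spans 5–200 kb, 1–10 non-overlapping
  exons from paired sorted coordinates, random strand and biotype;
  round-trips exactly through the GFF3/GTF writers and loader.
* `simulate_ld`: r² = clip(exp(−d/τ) + N(0, 0.05²), 0, 1), index = 1.
* `simulate_recomb`: contiguous intervals covering the chromosome with
  lognormal(0, 1) rates (median 1 cM/Mb, the right order for genome-wide
  averages).

What the model deliberately omits: LD-driven correlation between nearby
*p*-values, allele frequencies, winner's-curse effects, and any
population-genetic structure. Passing tests therefore demonstrate the
*mechanics* — scanning, windowing, layout, alignment, conservation — not
statistical performance on real GWAS, where neighbouring variants are
strongly correlated and peak shapes are raggeder.

## Problem sizes

The default suite and acceptance script run at deliberately modest sizes —
hundreds of oracle-checked scanner instances up to 10,000 records, 100
recovery replicates of 12,000 SNPs per k, 500 layout instances, 100
tracks — chosen so the whole battery completes in a few minutes while
still exercising every code path at scales where the oracles are
exhaustive. The scanner itself is routinely used on multi-million-row
files; the full-scale reproduction test documents where to place the
published SLE/RA summary statistics to run it.

## Known limitations

* No allele/effect harmonisation and no genome-build liftover; inputs are
  assumed to be on one build.
* Per-transcript isoform drawing is not supported (one collapsed model
  per gene).
* Label-width estimation is character-count based, not font-metric based;
  extremely long labels can look loose or tight at unusual figure widths.
* The HTML export is a static SVG with native hover tooltips, not a
  zoomable widget.
* Live LD/recombination/eQTL web clients are not bundled; the provider
  contract and persistent cache are the integration point.
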