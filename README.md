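# locusplot

Publication-ready **regional association ("locus") plots** from GWAS summary
statistics, plus a very fast scanner that extracts every independent
association peak from genome-wide results.

Regional plots put per-variant association strength, −log10 *p*, against
genomic position over a gene-exon track, optionally coloured by linkage
disequilibrium (r²) with the index variant and overlaid with the local
recombination rate (cM/Mb) and eQTL signals. They are the standard way to
inspect and publish individual GWAS loci. The perennial pain points are
(a) getting the scatter panel, eQTL panel and gene track *exactly*
coordinate-aligned, and (b) doing this for dozens of loci in one batch.
locusplot addresses both:

* **Alignment by construction.** Figures are described declaratively
  (panel specs sharing one locus window) and every panel receives
  bit-identical x-limits; loci with mismatched windows are rejected rather
  than silently rescaled.
* **Fast peak scanning.** `quickpeak` applies the greedy
  select-and-exclude rule — repeatedly take the unmasked variant with the
  smallest *p* below a cutoff and mask everything on the same chromosome
  within ± span/2 of it — implemented as one sort plus binary-searched
  interval masks, so multi-million-row summary statistics scan in seconds.

The library reads GWAS summary statistics as delimited text (with a
configurable column map), gene models from GFF3/GTF, recombination rate
from bedGraph or bigWig, and LD / eQTL tables as TSV. A synthetic-data
module generates all of these (with planted peaks of known position and
height), so the whole pipeline is testable offline.

## Worked example

```python
import locusplot as lp

# a synthetic genome: 20,000 SNPs on two chromosomes, three planted peaks
peaks = [
    lp.PeakSpec("1", 10_000_000, height=10),
    lp.PeakSpec("1", 30_000_000, height=9),
    lp.PeakSpec("2", 15_000_000, height=12),
]
stats = lp.simulate_gwas(20_000, {"1": 40_000_000, "2": 30_000_000}, peaks, seed=11)

# scan for independent peaks: p < 1e-6, 1 Mb exclusion span
for pk in lp.quickpeak(stats, p_cutoff=1e-6, span=1_000_000):
    v = pk.variant
    print(f"rank {pk.rank}: {v.id}  chr{v.chrom}:{v.pos}  p = {v.p:.3g}")

# build a 1 Mb locus around the first peak and plot it
ann = lp.simulate_genes("1", (9_500_001, 10_500_000), 8, seed=5)
locus = lp.make_locus(stats, region=("1", 9_500_001, 10_500_000), annotation=ann)
lp.attach_overlays(locus,
                   ld=lp.simulate_ld(locus, seed=6),
                   recomb=lp.simulate_recomb("1", 40_000_000, 200, seed=7))
fig = lp.assemble_figure(lp.figure_spec(locus, highlight=("GENE1",), title="chr1 locus"))
lp.export(fig, "locus.pdf")
```

This prints:

```
rank 1: rs0020003  chr2:15000000  p = 7.09e-13
rank 2: rs0011019  chr1:10000290  p = 7.11e-11
rank 3: rs0020002  chr1:30000000  p = 5.67e-10
```

The three planted peaks are recovered, ranked by ascending *p*-value; the
rank-2 variant sits 290 bp from the planted causal position at
chr1:10,000,000 because the decaying signal plus noise can promote an
immediate neighbour. `locus.pdf` shows the scatter panel (points coloured
by r² bin against the purple-diamond index variant, recombination rate as
a stepped line on the right-hand 0–100 cM/Mb axis) above the gene track
with GENE1 highlighted in red. `lp.export(fig, "locus.html")` writes a
self-contained interactive version with a hover tooltip per variant.

The same workflow is available from the shell:

```sh
locusplot peaks --stats gwas.tsv --p-cutoff 5e-8 --span 1000000 --out peaks.tsv
locusplot plot  --stats gwas.tsv --genes genes.gff3 \
                --region 7:128000000-129000000 --ld ld.tsv \
                --recomb recomb.bedgraph --highlight IRF5 --out fig.pdf
locusplot batch --stats gwas.tsv --genes genes.gff3 --out all_loci.pdf
```

`batch` finds all peaks and writes one figure per peak, in rank order, to a
single multi-page PDF.

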