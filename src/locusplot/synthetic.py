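"""Self-contained synthetic fixtures: GWAS summary statistics with planted
association peaks, gene models, LD tables, recombination tracks and eQTL
tables, all pure functions of (parameters, seed).

The GWAS noise model is deliberately simple: background p-values are
Uniform(0, 1) (equivalently -log10 p ~ Exponential with mean 1/ln 10 ~
0.4343); each planted peak adds an exponentially decaying -log10 p signal
``height * exp(-d / tau)`` with Gaussian jitter (sd 0.25) for variants
within 5 tau of the causal position, floored at zero and combined with the
background by max. One variant is emitted exactly at each causal position
(the causal variant is genotyped). This produces realistic-looking loci
without modelling LD-driven p-value correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, GeneModel
from .core import Locus, SummaryStats, from_dataframe
from .overlays import LDTable, RecombTrack, _resolve_overlaps

LN10 = np.log(10.0)

#: Gaussian jitter (sd) on the -log10 p signal of planted peaks.
PEAK_NOISE_SD = 0.25
#: Signal is planted only within this many decay scales of the causal variant.
PEAK_REACH = 5.0


@dataclass(frozen=True)
class PeakSpec:
    """A planted association peak: causal position, target -log10 p at the
    causal variant, and the genomic decay scale tau of the signal."""

    chrom: str
    causal_pos: int
    height: float
    decay_scale: int = 50_000

    def __post_init__(self):
        if self.height <= 0 or self.decay_scale <= 0:
            raise ValueError("peak height and decay scale must be positive")


def simulate_gwas(
    n_snps: int,
    chrom_lengths: Mapping[str, int],
    peaks: Sequence[PeakSpec] = (),
    seed: int = 42,
    typed_fraction: float = 0.7,
) -> SummaryStats:
    """Simulate GWAS summary statistics with planted peaks.

    ``n_snps`` background variants are placed uniformly across chromosomes
    (proportionally to length) with Uniform(0,1) p-values; one extra variant
    is placed exactly at each planted causal position. Variants within
    5 tau of a causal position get -log10 p = max(background,
    height * exp(-d/tau) + N(0, 0.25)), floored at 0. Deterministic under
    ``seed``; ids, random effect directions and typed flags are included.
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    assign = rng.choice(len(chroms), size=n_snps, p=lengths / lengths.sum())

    chrom_col, pos_col = [], []
    for ci, c in enumerate(chroms):
        k = int((assign == ci).sum())
        chrom_col.extend([c] * k)
        pos_col.extend(rng.integers(1, chrom_lengths[c] + 1, size=k).tolist())
    for pk in peaks:
        chrom_col.append(pk.chrom)
        pos_col.append(int(pk.causal_pos))

    pos = np.asarray(pos_col, dtype=np.int64)
    chrom_arr = np.asarray(chrom_col)
    nlp = rng.exponential(scale=1.0 / LN10, size=len(pos))  # p ~ U(0,1)

    for pk in peaks:
        d = np.abs(pos - pk.causal_pos).astype(float)
        near = (chrom_arr == pk.chrom) & (d <= PEAK_REACH * pk.decay_scale)
        if near.any():
            signal = pk.height * np.exp(-d[near] / pk.decay_scale)
            signal = signal + rng.normal(0.0, PEAK_NOISE_SD, size=int(near.sum()))
            nlp[near] = np.maximum(nlp[near], np.maximum(signal, 0.0))

    df = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos,
            "p": np.power(10.0, -nlp),
            "id": [f"rs{i + 1:07d}" for i in range(len(pos))],
            "direction": rng.choice([-1, 1], size=len(pos)),
            "typed": rng.random(len(pos)) < typed_fraction,
        }
    )
    return from_dataframe(df, source=f"synthetic(seed={seed})")


def simulate_genes(
    chrom: str,
    window: tuple,
    n_genes: int,
    seed: int = 42,
    biotypes: Sequence[str] = ("protein_coding", "lincRNA", "pseudogene"),
) -> GeneAnnotation:
    """Random gene models in a window: non-degenerate spans, 1-10
    non-overlapping exons inside each span, random strand and biotype.
    Round-trips exactly through GFF3 write/load."""
    rng = np.random.default_rng(seed)
    wstart, wend = window
    genes = []
    for i in range(n_genes):
        span = int(rng.integers(5_000, 200_000))
        start = int(rng.integers(wstart, max(wstart + 1, wend - span)))
        end = min(start + span, wend)
        n_exons = int(rng.integers(1, 11))
        # 2*n distinct sorted coordinates pair into non-overlapping exons
        coords = np.sort(rng.choice(np.arange(start, end + 1),
                                    size=min(2 * n_exons, end - start + 1),
                                    replace=False))
        exons = tuple(
            (int(coords[j]), int(coords[j + 1])) for j in range(0, len(coords) - 1, 2)
        )
        if not exons:
            exons = ((start, end),)
        genes.append(
            GeneModel(
                gene_id=f"SYNG{i:04d}",
                symbol=f"GENE{i + 1}",
                chrom=str(chrom),
                start=start,
                end=end,
                strand=str(rng.choice(["+", "-"])),
                biotype=str(rng.choice(list(biotypes))),
                exons=exons,
            )
        )
    return GeneAnnotation(genes, source=f"synthetic(seed={seed})")


def write_gff3(ann: GeneAnnotation, path) -> None:
    """Serialise gene models as GFF3 (genes + exon children), consumable by
    the annotation loader."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            attrs = (
                f"ID={g.gene_id};Name={g.symbol};gene_id={g.gene_id};"
                f"biotype={g.biotype}"
            )
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for j, (a, b) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{j + 1};Parent={g.gene_id}\n"
                )


def write_gtf(ann: GeneAnnotation, path) -> None:
    """Serialise the same models as GTF (transcript + exon features)."""
    with open(path, "w") as fh:
        for g in ann.genes:
            base = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_name "{g.symbol}"; gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tsynthetic\ttranscript\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{base}\n"
            )
            for (a, b) in g.exons:
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{a}\t{b}\t.\t{g.strand}\t.\t{base}\n"
                )


def simulate_ld(
    locus: Locus, index_id: Optional[str] = None, decay_scale: int = 50_000,
    seed: int = 42
) -> LDTable:
    """Distance-decaying LD against the index variant:
    r^2 = clip(exp(-d/tau) + N(0, 0.05), 0, 1); the index itself gets 1.0."""
    rng = np.random.default_rng(seed)
    df = locus.stats.df
    if index_id is None:
        if locus.index_variant is None:
            raise ValueError("locus has no index variant")
        index_id = locus.index_variant.id
    ids = df["id"].astype(str).to_numpy()
    if index_id not in ids:
        raise KeyError(f"index id {index_id!r} not in locus")
    ipos = int(df.loc[df["id"] == index_id, "pos"].iloc[0])
    d = np.abs(df["pos"].to_numpy() - ipos).astype(float)
    r2 = np.clip(np.exp(-d / decay_scale) + rng.normal(0, 0.05, size=len(d)), 0.0, 1.0)
    values = dict(zip(ids, r2.astype(float)))
    values[str(index_id)] = 1.0
    return LDTable(index_id=str(index_id), values=values)


def write_ld_tsv(ld: LDTable, path) -> None:
    pd.DataFrame({"id": list(ld.values), "r2": list(ld.values.values())}).to_csv(
        path, sep="\t", index=False
    )


def simulate_recomb(
    chrom: str, length: int, n_intervals: int, seed: int = 42
) -> RecombTrack:
    """Contiguous recombination-rate intervals covering [1, length] with
    lognormal rates (median 1 cM/Mb, typical of genome-wide averages)."""
    rng = np.random.default_rng(seed)
    if n_intervals < 1 or length < n_intervals:
        raise ValueError("need 1 <= n_intervals <= length")
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_intervals - 1, replace=False)) \
        if n_intervals > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [length]])
    rates = rng.lognormal(mean=0.0, sigma=1.0, size=n_intervals)
    intervals = [
        (str(chrom), int(bounds[i]) + 1, int(bounds[i + 1]), float(rates[i]))
        for i in range(n_intervals)
    ]
    return RecombTrack(intervals=_resolve_overlaps(intervals),
                       source=f"synthetic(seed={seed})")


def write_bedgraph(track: RecombTrack, path) -> None:
    """Write the track as bedGraph (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for c, s, e, r in track.intervals:
            fh.write(f"{c}\t{s - 1}\t{e}\t{r:.6g}\n")


def simulate_eqtl(
    locus: Locus, gene: str = "GENE1", tissue: str = "whole_blood",
    seed: int = 42, signal_fraction: float = 0.3
) -> pd.DataFrame:
    """eQTL rows for the locus variants: a fraction share the GWAS signal
    shape (scaled), the rest are null; directions random in {-1, +1}."""
    rng = np.random.default_rng(seed)
    df = locus.stats.df
    nlp = -np.log10(df["p"].to_numpy())
    keep = rng.random(len(df)) < 1.0
    scale = np.where(rng.random(len(df)) < signal_fraction, 0.6, 0.0)
    e_nlp = np.maximum(nlp * scale + rng.exponential(1 / LN10, size=len(df)), 0.0)
    out = pd.DataFrame(
        {
            "id": df["id"].astype(str),
            "pos": df["pos"],
            "p": np.power(10.0, -e_nlp),
            "direction": rng.choice([-1, 1], size=len(df)),
            "gene": gene,
            "tissue": tissue,
        }
    )
    return out[keep].reset_index(drop=True)


def write_eqtl_tsv(eqtl: pd.DataFrame, path) -> None:
    eqtl.to_csv(path, sep="\t", index=False)


def write_gwas_tsv(stats: SummaryStats, path) -> None:
    stats.df.to_csv(path, sep="\t", index=False)
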