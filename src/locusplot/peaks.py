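"""Genome-wide peak scanning of summary statistics.

``quickpeak`` implements the greedy select-and-exclude rule: repeatedly take
the unmasked variant with the smallest p-value below the cutoff, emit it as
a peak, and mask every variant on the same chromosome within +/- span/2 of
it. The result is a set of distance-pruned "independent" loci (LD-aware
clumping is deliberately out of scope). The implementation is a single sort
of the candidate set by p-value plus one binary-searched interval mask per
emitted peak, so runtime is sort-dominated and near-linear in record count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    Locus,
    SummaryStats,
    VariantRecord,
    chrom_sort_key,
    pick_index_variant,
)

#: Conventional genome-wide significance level.
DEFAULT_P_CUTOFF = 5e-8
#: Default exclusion span, matched to the 1 Mb plotting window.
DEFAULT_SPAN = 1_000_000


@dataclass(frozen=True)
class Peak:
    """An index variant chosen by the scanner, its rank (1 = smallest p) and
    the exclusion window applied around it."""

    variant: VariantRecord
    rank: int
    window: tuple  # (start, end) exclusion interval, clipped at 1


def quickpeak(
    stats: SummaryStats,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    span: int = DEFAULT_SPAN,
    max_peaks: Optional[int] = None,
) -> list:
    """Scan summary statistics for independent association peaks.

    Greedy rule: the unmasked record with smallest p (< ``p_cutoff``) becomes
    the next peak; all records on its chromosome within +/- span/2 are then
    masked. Ties on p break by chromosome order, then position, then variant
    id, so output is deterministic. Returns peaks ordered by rank; an empty
    list when nothing passes the cutoff.
    """
    if not (0 < p_cutoff < 1):
        raise ValueError(f"p_cutoff must lie in (0, 1), got {p_cutoff}")
    if span <= 0:
        raise ValueError(f"span must be positive, got {span}")
    half = span / 2.0

    df = stats.df
    p = df["p"].to_numpy(dtype=float)
    pos = df["pos"].to_numpy(dtype=np.int64)
    chroms = df["chrom"].to_numpy()
    ids = df["id"].astype(str).to_numpy() if "id" in df.columns else np.full(len(df), "")

    cand = np.flatnonzero(p < p_cutoff)
    if cand.size == 0:
        return []

    # deterministic candidate order: p, then genome order, then id
    ckeys = sorted(
        range(cand.size),
        key=lambda i: (p[cand[i]], chrom_sort_key(chroms[cand[i]]), pos[cand[i]], ids[cand[i]]),
    )
    cand = cand[ckeys]

    # per-chromosome position index for fast interval masking (df is sorted,
    # so each chromosome occupies one contiguous, position-sorted block)
    chrom_block = {}
    start = 0
    for i in range(1, len(df) + 1):
        if i == len(df) or chroms[i] != chroms[start]:
            chrom_block[chroms[start]] = (start, i)
            start = i

    masked = np.zeros(len(df), dtype=bool)
    peaks = []
    for idx in cand:
        if masked[idx]:
            continue
        v = VariantRecord.from_row(df.iloc[idx].to_dict())
        lo, hi = v.pos - half, v.pos + half
        peaks.append(
            Peak(variant=v, rank=len(peaks) + 1,
                 window=(max(1, int(np.ceil(lo))), int(np.floor(hi))))
        )
        b0, b1 = chrom_block[chroms[idx]]
        i0 = b0 + np.searchsorted(pos[b0:b1], lo, side="left")
        i1 = b0 + np.searchsorted(pos[b0:b1], hi, side="right")
        masked[i0:i1] = True
        if max_peaks is not None and len(peaks) >= max_peaks:
            break
    return peaks


def peaks_to_loci(
    peaks: list,
    stats: SummaryStats,
    annotation=None,
    window_width: int = DEFAULT_SPAN,
    biotypes: Optional[set] = None,
) -> list:
    """One Locus per peak, centred on the peak variant with total width
    ``window_width``; windows running past the chromosome start are shifted
    right so the width is preserved where possible."""
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    loci = []
    for pk in peaks:
        start = pk.variant.pos - window_width // 2 + 1
        end = start + window_width - 1
        if start < 1:
            start, end = 1, window_width
        locus = Locus(
            chrom=pk.variant.chrom,
            start=start,
            end=end,
            stats=stats.slice(pk.variant.chrom, start, end),
            index_variant=pk.variant,
            genes=annotation.query(pk.variant.chrom, start, end, biotypes=biotypes)
            if annotation is not None
            else [],
        )
        loci.append(locus)
    return loci
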