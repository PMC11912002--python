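"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package internals beyond the
public tie-break definition: the peak oracle is a literal O(n * k) rescan
of the greedy select-and-exclude rule, the layout oracles are exhaustive
pairwise/sweep checks, and the recombination integral sums source
intervals directly.
"""

from __future__ import annotations


def _chrom_key(c):
    try:
        return (0, int(c), "")
    except ValueError:
        return (0, {"X": 23, "Y": 24, "MT": 25}.get(c, 99), c)


def greedy_peak_oracle(df, p_cutoff, span, max_peaks=None):
    """Literal greedy select-and-exclude on a summary-stats frame.

    Returns [(chrom, pos, p, id), ...] in rank order. Each round scans every
    surviving record for the minimum p (ties: chromosome order, position,
    id), then removes all same-chromosome records within span/2.
    """
    recs = [
        (str(r.chrom), int(r.pos), float(r.p), str(getattr(r, "id", "") or ""))
        for r in df.itertuples(index=False)
    ]
    alive = [r[2] < p_cutoff for r in recs]
    out = []
    while True:
        best_i = None
        for i, r in enumerate(recs):
            if not alive[i]:
                continue
            key = (r[2], _chrom_key(r[0]), r[1], r[3])
            if best_i is None or key < best_key:
                best_i, best_key = i, key
        if best_i is None:
            break
        c, pos, p, vid = recs[best_i]
        out.append((c, pos, p, vid))
        for j, q in enumerate(recs):
            if q[0] == c and abs(q[1] - pos) <= span / 2:
                alive[j] = False
        if max_peaks is not None and len(out) >= max_peaks:
            break
    return out


def overlap_depth(intervals):
    """Maximum number of simultaneously overlapping closed intervals."""
    events = []
    for a, b in intervals:
        events.append((a, 1))
        events.append((b + 1, -1))  # closed interval ends after b
    events.sort()
    depth = best = 0
    for _, d in events:
        depth += d
        best = max(best, depth)
    return best


def genes_overlapping(genes, start, end):
    """Exhaustive interval-overlap scan over gene models (1-based incl.)."""
    return sorted(
        (g for g in genes if g.start <= end and g.end >= start),
        key=lambda g: (g.start, g.end, g.gene_id),
    )


def recomb_window_integral(intervals, chrom, start, end):
    """Integral (rate x bp) of source track intervals clipped to a window."""
    total = 0.0
    for c, s, e, r in intervals:
        if c != chrom or e < start or s > end:
            continue
        total += r * (min(e, end) - max(s, start) + 1)
    return total


def pdf_page_count(data: bytes) -> int:
    """Count page objects in a PDF byte stream (excludes the /Pages tree node)."""
    import re

    return len(re.findall(rb"/Type\s*/Page\b", data))


def ld_bin_histogram(values):
    """Brute-force histogram of r^2 values over the five 0.2-wide bins
    (left-closed, last bin closed at 1)."""
    counts = [0] * 5
    for v in values:
        if v >= 1.0:
            counts[4] += 1
        else:
            counts[int(v / 0.2)] += 1
    return counts
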