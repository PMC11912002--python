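"""LD, recombination-rate and eQTL overlays, and cached data providers.

LD is colour-binned against the index variant using the classic LocusZoom
five-bin scheme (0.2 steps) plus an NA bin and a distinct index category.
Recombination rate is a piecewise-constant track (bedGraph semantics, read
from bedGraph or bigWig) resampled into the locus window; resampling
conserves the track exactly — the integral of the clipped segments equals
the integral of the overlapping source intervals.

Remote services (LDlink, UCSC) sit behind the small :class:`Provider`
contract with a persistent on-disk cache, so identical queries hit the
network at most once, including across process restarts. Tests and batch
runs use file-backed providers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, DomainError, Locus, normalize_chrom

logger = logging.getLogger("locusplot")


class ChromosomeMismatchError(ValueError):
    """An overlay refers to a different chromosome than the locus."""


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

#: Ordered r^2 bin labels, least to most correlated; "na" for missing,
#: "index" reserved for the index variant itself.
LD_BIN_LABELS = ("na", "0.0-0.2", "0.2-0.4", "0.4-0.6", "0.6-0.8", "0.8-1.0")
LD_INDEX_LABEL = "index"
_LD_BREAKS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class LDTable:
    """r^2 values of locus variants against one index variant."""

    index_id: str
    values: dict = field(default_factory=dict)  # variant id -> r^2 in [0, 1]

    def r2(self, variant_id) -> Optional[float]:
        if variant_id == self.index_id:
            return self.values.get(variant_id, 1.0)
        return self.values.get(variant_id)


def ld_category(r2: Optional[float], is_index: bool = False) -> str:
    """Map an r^2 value (or None for missing) to its ordered bin label.

    Bins are left-closed: [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1].
    The index variant gets the distinct "index" category regardless of r^2.
    """
    if is_index:
        return LD_INDEX_LABEL
    if r2 is None or (isinstance(r2, float) and np.isnan(r2)):
        return LD_BIN_LABELS[0]
    if not (0 <= r2 <= 1):
        raise DomainError(f"r^2 {r2} outside [0, 1]")
    for i, brk in enumerate(_LD_BREAKS):
        if r2 < brk:
            return LD_BIN_LABELS[i + 1]
    return LD_BIN_LABELS[5]


def load_ld(
    path,
    index_id: str,
    id_col: str = "id",
    r2_col: str = "r2",
    delimiter: str = "\t",
) -> LDTable:
    """Read an LD table (variant id, r^2 against ``index_id``) from delimited
    text. Rows with r^2 outside [0, 1] are dropped with a warning; a file
    omitting the index variant itself implies r^2 = 1 for it."""
    df = pd.read_csv(path, sep=delimiter)
    for col in (id_col, r2_col):
        if col not in df.columns:
            raise ConfigurationError(f"LD file {path} is missing the '{col}' column")
    r2 = pd.to_numeric(df[r2_col], errors="coerce")
    bad = r2.isna() | (r2 < 0) | (r2 > 1)
    if bad.any():
        warnings.warn(f"dropped {int(bad.sum())} LD rows with r^2 outside [0, 1]",
                      stacklevel=2)
    keep = df[~bad]
    values = dict(zip(keep[id_col].astype(str), r2[~bad].astype(float)))
    values.setdefault(str(index_id), 1.0)
    return LDTable(index_id=str(index_id), values=values)


# ---------------------------------------------------------------------------
# Recombination rate
# ---------------------------------------------------------------------------

@dataclass
class RecombTrack:
    """Sorted, non-overlapping (chrom, start, end, rate cM/Mb) intervals,
    1-based inclusive internally."""

    intervals: list = field(default_factory=list)
    source: str = ""

    def chrom_intervals(self, chrom: str) -> list:
        chrom = normalize_chrom(chrom)
        return [iv for iv in self.intervals if iv[0] == chrom]

    def rate_at(self, chrom: str, pos: int) -> float:
        """Point query of the step function; NaN outside coverage."""
        for c, s, e, r in self.chrom_intervals(chrom):
            if s <= pos <= e:
                return r
        return float("nan")


def _resolve_overlaps(rows: Sequence[tuple]) -> list:
    """Turn possibly-overlapping (chrom,start,end,rate) rows (file order) into
    sorted non-overlapping intervals; where rows overlap, the later row wins."""
    by_chrom: dict = {}
    for i, (c, s, e, r) in enumerate(rows):
        by_chrom.setdefault(c, []).append((s, e, r, i))
    out = []
    overlapped = False
    for c, ivs in by_chrom.items():
        srt = sorted(ivs)
        clean = all(srt[i][1] < srt[i + 1][0] for i in range(len(srt) - 1))
        if clean:
            out.extend((c, s, e, r) for s, e, r, _ in srt)
            continue
        overlapped = True
        # elementary-segment sweep, last file row wins on each segment
        bounds = sorted({b for s, e, _, _ in ivs for b in (s, e + 1)})
        for a, b in zip(bounds[:-1], bounds[1:]):
            cover = [iv for iv in ivs if iv[0] <= a and b - 1 <= iv[1]]
            if cover:
                winner = max(cover, key=lambda iv: iv[3])
                out.append((c, a, b - 1, winner[2]))
    if overlapped:
        warnings.warn("overlapping recombination intervals resolved last-wins",
                      stacklevel=3)
    return sorted(out, key=lambda iv: (iv[0], iv[1]))


def load_recomb(path, format: Optional[str] = None) -> RecombTrack:
    """Load a recombination-rate track from bedGraph or bigWig.

    bedGraph/bigWig coordinates (0-based half-open) are converted to the
    internal 1-based inclusive frame at this boundary. Overlapping source
    intervals are resolved last-wins with a warning.
    """
    path = str(path)
    if format is None:
        format = "bigwig" if path.lower().endswith((".bw", ".bigwig")) else "bedgraph"
    rows = []
    if format == "bedgraph":
        try:
            with open(path) as fh:
                for ln, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split()
                    if len(parts) < 4:
                        raise FormatErrorAt(path, ln, "expected 4 columns")
                    c = normalize_chrom(parts[0])
                    try:
                        s, e, r = int(parts[1]), int(parts[2]), float(parts[3])
                    except ValueError as exc:
                        raise FormatErrorAt(path, ln, str(exc)) from exc
                    rows.append((c, s + 1, e, r))  # 0-based half-open -> 1-based incl.
        except OSError as exc:
            raise FormatErrorAt(path, 0, str(exc)) from exc
    elif format == "bigwig":
        import pyBigWig

        bw = pyBigWig.open(path)
        try:
            for bw_chrom in bw.chroms():
                for s, e, r in bw.intervals(bw_chrom) or []:
                    rows.append((normalize_chrom(bw_chrom), s + 1, e, float(r)))
        finally:
            bw.close()
    else:
        raise ValueError(f"unknown recombination track format {format!r}")

    bad = [iv for iv in rows if iv[3] < 0 or iv[1] > iv[2]]
    if bad:
        warnings.warn(f"dropped {len(bad)} invalid recombination intervals", stacklevel=2)
        rows = [iv for iv in rows if iv not in bad]
    return RecombTrack(intervals=_resolve_overlaps(rows), source=path)


class FormatErrorAt(ValueError):
    """Unparseable track file, carrying the offending line number."""

    def __init__(self, path, line, msg):
        super().__init__(f"{path}:{line}: {msg}")
        self.path, self.line = path, line


def resample_recomb(track: RecombTrack, chrom: str, start: int, end: int) -> list:
    """Clip the track's piecewise-constant segments to [start, end].

    Returns (start, end, rate) segments in order. The integral (rate x
    base-pair length) over the returned segments equals the integral of the
    source intervals restricted to the window — resampling conserves the
    track.
    """
    out = []
    for c, s, e, r in track.chrom_intervals(chrom):
        if e < start or s > end:
            continue
        out.append((max(s, start), min(e, end), r))
    return out


def recomb_step_points(segments: Sequence[tuple]) -> tuple:
    """Turn clipped segments into step-plot arrays (x, y) with 'post' steps;
    gaps in coverage become NaN so the line breaks there."""
    xs, ys = [], []
    prev_end = None
    for s, e, r in segments:
        if prev_end is not None and s > prev_end + 1:
            xs.append(prev_end + 1)
            ys.append(np.nan)
        xs.extend([s, e])
        ys.extend([r, r])
        prev_end = e
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


# ---------------------------------------------------------------------------
# eQTL
# ---------------------------------------------------------------------------

EQTL_COLUMNS = ("id", "pos", "p", "direction", "gene", "tissue")


def load_eqtl(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read an eQTL table (variant id, pos, p, direction, target gene, tissue)
    from delimited text; rows with p outside [0, 1] are dropped."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in ("id", "pos", "p") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"eQTL file {path} is missing columns: {missing}")
    df["p"] = pd.to_numeric(df["p"], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df = df.dropna(subset=["pos", "p"])
    df = df[(df["p"] >= 0) & (df["p"] <= 1)].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    if "direction" in df.columns:
        df["direction"] = np.sign(pd.to_numeric(df["direction"], errors="coerce").fillna(0)).astype(int)
    else:
        df["direction"] = 0
    return df


# ---------------------------------------------------------------------------
# Attachment
# ---------------------------------------------------------------------------

def attach_overlays(
    locus: Locus,
    ld: Optional[LDTable] = None,
    recomb: Optional[RecombTrack] = None,
    eqtl: Optional[pd.DataFrame] = None,
    recomb_chrom: Optional[str] = None,
) -> Locus:
    """Attach overlays to a locus (additive — stats records are untouched).

    LD joins by variant id (variants absent from the table get the NA
    category at plot time); the recombination track is resampled into the
    window; the eQTL table is filtered to the window. A recombination track
    or eQTL table with no data for the locus chromosome raises
    :class:`ChromosomeMismatchError`.
    """
    if ld is not None:
        ids = (
            locus.stats.df["id"].astype(str).tolist()
            if "id" in locus.stats.df.columns
            else []
        )
        locus.ld = {i: ld.r2(i) for i in ids if ld.r2(i) is not None}
        if locus.index_variant is not None and locus.index_variant.id == ld.index_id:
            locus.ld.setdefault(ld.index_id, 1.0)
    if recomb is not None:
        if not recomb.chrom_intervals(recomb_chrom or locus.chrom):
            raise ChromosomeMismatchError(
                f"recombination track has no data for chromosome {locus.chrom}"
            )
        locus.recomb = resample_recomb(recomb, recomb_chrom or locus.chrom,
                                       locus.start, locus.end)
    if eqtl is not None:
        sub = eqtl[(eqtl["pos"] >= locus.start) & (eqtl["pos"] <= locus.end)]
        if "chrom" in eqtl.columns:
            chrom_match = eqtl["chrom"].map(normalize_chrom) == locus.chrom
            if not chrom_match.any():
                raise ChromosomeMismatchError(
                    f"eQTL table has no rows on chromosome {locus.chrom}"
                )
            sub = sub[chrom_match.loc[sub.index]]
        locus.eqtl = sub.reset_index(drop=True)
    return locus


# ---------------------------------------------------------------------------
# Providers and the persistent cache
# ---------------------------------------------------------------------------

class Provider:
    """Contract for remote data sources: ``fetch(key) -> payload`` where the
    key is any JSON-serialisable query description and the payload is
    JSON-serialisable. Concrete live clients (LDlink, UCSC) plug in here;
    tests and batch runs use file-backed providers."""

    def fetch(self, key):
        raise NotImplementedError


class FileProvider(Provider):
    """Test/batch double: serves payloads from a prebuilt mapping."""

    def __init__(self, payloads: Mapping):
        self._payloads = dict(payloads)
        self.calls = 0

    def fetch(self, key):
        self.calls += 1
        k = json.dumps(key, sort_keys=True)
        if k not in self._payloads:
            raise KeyError(f"no payload for key {key!r}")
        return self._payloads[k]

    @staticmethod
    def key(key) -> str:
        return json.dumps(key, sort_keys=True)


class FileCache:
    """Persistent key -> payload cache: one JSON file per key under a
    directory, so cached responses survive process restarts. A corrupted
    entry is bypassed with a warning, never fatal."""

    def __init__(self, directory):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, key) -> Path:
        digest = hashlib.sha256(json.dumps(key, sort_keys=True).encode()).hexdigest()
        return self.directory / f"{digest}.json"

    def get(self, key):
        path = self._path(key)
        if not path.exists():
            return None
        try:
            return json.loads(path.read_text())
        except (json.JSONDecodeError, OSError) as exc:
            warnings.warn(f"cache entry {path.name} unreadable ({exc}); bypassing",
                          stacklevel=2)
            return None

    def set(self, key, payload) -> None:
        self._path(key).write_text(json.dumps(payload))

    def clear(self) -> None:
        for f in self.directory.glob("*.json"):
            f.unlink()


def cached_fetch(provider: Provider, key, cache: FileCache):
    """Fetch through the cache: the first call for a key delegates to the
    provider and stores the payload; identical keys afterwards — including in
    later processes sharing the cache directory — are served from disk."""
    hit = cache.get(key)
    if hit is not None:
        return hit
    try:
        payload = provider.fetch(key)
    except Exception as exc:
        raise RuntimeError(f"provider fetch failed for key {key!r}: {exc}") from exc
    cache.set(key, payload)
    return payload
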