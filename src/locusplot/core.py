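"""Summary statistics I/O and the locus window abstraction.

Coordinate conventions used throughout the package:

* positions are 1-based and windows are inclusive on both ends, matching
  GFF/GTF and the way GWAS summary statistics report positions;
* BED/bedGraph inputs (0-based, half-open) are converted at the reader
  boundary, never downstream;
* chromosome labels are normalised on load: the ``chr`` prefix is stripped
  and X/Y/MT are upper-cased, so UCSC- and Ensembl-style inputs compare
  equal.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("locusplot")

#: -log10(p) value reported for p == 0 (keeps axes finite).
DEFAULT_P0_CAP = 300.0

#: Canonical column order of the internal summary-statistics table.
CANONICAL_COLUMNS = ("chrom", "pos", "p", "id", "direction", "typed")

MANDATORY_FIELDS = ("chrom", "pos", "p")


class ConfigurationError(ValueError):
    """A column map, style or run configuration is invalid."""


class EmptyInputError(ValueError):
    """An input file contained no usable records."""


class UnknownFeatureError(KeyError):
    """A gene symbol or variant id referenced by a region spec does not exist."""


class DomainError(ValueError):
    """A numeric argument is outside its mathematical domain."""


def normalize_chrom(label: object) -> str:
    """Normalise a chromosome label: strip ``chr`` prefix, uppercase X/Y/MT.

    ``chr7`` and ``7`` become ``7``; ``chrx`` becomes ``X``; the common
    mitochondrial aliases ``M``/``chrM`` become ``MT``.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("X", "Y", "MT"):
        s = s.upper()
    elif s.upper() == "M":
        s = "MT"
    return s


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key giving the natural genome order: 1..22, X, Y, MT, then others."""
    try:
        return (0, int(chrom), "")
    except ValueError:
        order = {"X": 23, "Y": 24, "MT": 25}
        if chrom in order:
            return (0, order[chrom], "")
        return (1, 0, chrom)


def neglog10(p, cap: float = DEFAULT_P0_CAP):
    """Return -log10(p) for a scalar or array of p-values in [0, 1].

    p == 0 maps to ``cap`` (default 300) with a warning rather than inf,
    so axis limits stay finite.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise DomainError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.log10(arr)
    zeros = arr == 0
    if np.any(zeros):
        warnings.warn(
            f"p = 0 encountered; capping -log10(p) at {cap}", stacklevel=2
        )
        out = np.where(zeros, cap, out)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Records and tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One variant: normalised chromosome, 1-based position, p-value, and
    optional id, effect direction (-1/0/+1) and typed-vs-imputed flag."""

    chrom: str
    pos: int
    p: float
    id: Optional[str] = None
    direction: Optional[int] = None
    typed: Optional[bool] = None

    def __post_init__(self):
        if not (0 <= self.p <= 1):
            raise DomainError(f"p-value {self.p} outside [0, 1]")
        if self.pos < 1:
            raise DomainError(f"position {self.pos} < 1")
        if not self.chrom:
            raise DomainError("empty chromosome label")

    @classmethod
    def from_row(cls, row: Mapping) -> "VariantRecord":
        def _opt(key, cast):
            v = row.get(key) if hasattr(row, "get") else getattr(row, key, None)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA:
                return None
            return cast(v)

        return cls(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            p=float(row["p"]),
            id=_opt("id", str),
            direction=_opt("direction", int),
            typed=_opt("typed", bool),
        )


@dataclass
class SummaryStats:
    """A validated, position-sorted table of variant records.

    ``df`` holds the canonical columns (chrom, pos, p, and whichever of
    id/direction/typed the source provided); ``column_map`` records how the
    source columns mapped onto them, and ``n_dropped`` how many malformed
    rows were discarded on load.
    """

    df: pd.DataFrame
    column_map: Mapping[str, str] = field(default_factory=dict)
    source: str = ""
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list:
        return [VariantRecord.from_row(r) for r in self.df.to_dict("records")]

    def slice(self, chrom: str, start: int, end: int) -> "SummaryStats":
        chrom = normalize_chrom(chrom)
        m = (self.df["chrom"] == chrom) & (self.df["pos"] >= start) & (self.df["pos"] <= end)
        return SummaryStats(self.df[m].reset_index(drop=True), dict(self.column_map), self.source, 0)


def _sort_stats_frame(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iat[i], df["pos"].iat[i]))
    return df.iloc[order].reset_index(drop=True)


def from_dataframe(
    df: pd.DataFrame,
    column_map: Optional[Mapping[str, str]] = None,
    source: str = "<dataframe>",
) -> SummaryStats:
    """Build a SummaryStats from an in-memory table with canonical or mapped
    column names, applying the same validation and sorting as the file reader."""
    column_map = dict(column_map or {c: c for c in CANONICAL_COLUMNS if c in df.columns})
    for f in MANDATORY_FIELDS:
        if f not in column_map:
            raise ConfigurationError(f"column map does not name the mandatory '{f}' column")
    frame, dropped = _clean_chunk(df, column_map)
    return SummaryStats(_sort_stats_frame(frame), column_map, source, dropped)


def _clean_chunk(chunk: pd.DataFrame, column_map: Mapping[str, str]):
    """Select, rename, coerce and validate one chunk. Returns (frame, n_dropped)."""
    for canon, src in column_map.items():
        if src not in chunk.columns:
            raise ConfigurationError(f"input is missing the '{src}' column (mapped to '{canon}')")
    sub = chunk[[column_map[c] for c in CANONICAL_COLUMNS if c in column_map]].copy()
    sub.columns = [c for c in CANONICAL_COLUMNS if c in column_map]

    n0 = len(sub)
    sub = sub.dropna(subset=["chrom", "pos"])
    sub["pos"] = pd.to_numeric(sub["pos"], errors="coerce")
    sub["p"] = pd.to_numeric(sub["p"], errors="coerce")
    sub = sub.dropna(subset=["pos", "p"])
    sub = sub[(sub["p"] >= 0) & (sub["p"] <= 1) & (sub["pos"] >= 1)]
    sub["pos"] = sub["pos"].astype(np.int64)
    sub["chrom"] = sub["chrom"].map(normalize_chrom)
    sub = sub[sub["chrom"] != ""]
    if "id" in sub.columns:
        sub["id"] = sub["id"].astype("string")
    if "direction" in sub.columns:
        sub["direction"] = pd.to_numeric(sub["direction"], errors="coerce").clip(-1, 1)
        sub["direction"] = np.sign(sub["direction"]).astype("Int64")
    if "typed" in sub.columns:
        truthy = {"1", "true", "t", "yes", "typed", "genotyped"}
        sub["typed"] = (
            sub["typed"].astype(str).str.strip().str.lower().isin(truthy)
        )
    return sub.reset_index(drop=True), n0 - len(sub)


def read_summary_stats(
    path,
    column_map: Mapping[str, str],
    delimiter: Optional[str] = None,
    chunksize: int = 1_000_000,
) -> SummaryStats:
    """Read GWAS summary statistics from delimited text.

    ``column_map`` maps canonical field names (chrom, pos, p, and optionally
    id, direction, typed) to the source file's column names. The delimiter is
    auto-detected (tab vs comma) when not given. The file is streamed in
    chunks so multi-million-row inputs load in bounded memory; rows with an
    unparseable position or a p-value outside [0, 1] are dropped and counted
    (``n_dropped``), not fatal.
    """
    column_map = dict(column_map)
    for f in MANDATORY_FIELDS:
        if f not in column_map:
            raise ConfigurationError(f"column map does not name the mandatory '{f}' column")

    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise EmptyInputError(f"{path} is empty")
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","

    frames = []
    dropped = 0
    try:
        reader = pd.read_csv(path, sep=delimiter, chunksize=chunksize, dtype=str)
        for chunk in reader:
            frame, d = _clean_chunk(chunk, column_map)
            frames.append(frame)
            dropped += d
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None

    if not frames:
        raise EmptyInputError(f"{path} contains no data rows")
    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        raise EmptyInputError(f"{path} contains no valid records")
    df = _sort_stats_frame(df)
    if dropped:
        logger.info("read_summary_stats: dropped %d malformed rows from %s", dropped, path)
    return SummaryStats(df, column_map, str(path), dropped)


def write_summary_stats(stats: SummaryStats, path, delimiter: str = "\t") -> None:
    """Write the canonical table back out as delimited text (round-trips
    through :func:`read_summary_stats` with an identity column map)."""
    stats.df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Locus
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    """A genomic window bundling everything drawn in one coordinate frame:
    a SummaryStats slice, the index variant, gene models, and optional
    LD / recombination / eQTL overlays."""

    chrom: str
    start: int
    end: int
    stats: SummaryStats
    index_variant: Optional[VariantRecord] = None
    genes: list = field(default_factory=list)
    ld: Optional[dict] = None            # variant id -> r^2 against index
    recomb: Optional[list] = None        # clipped (start, end, rate cM/Mb) segments
    eqtl: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.start > self.end:
            raise DomainError(f"locus window start {self.start} > end {self.end}")
        if len(self.stats):
            pos = self.stats.df["pos"]
            if pos.min() < self.start or pos.max() > self.end:
                raise DomainError("stats records outside the locus window")
        if self.index_variant is not None and not (
            self.index_variant.chrom == self.chrom
            and self.start <= self.index_variant.pos <= self.end
        ):
            raise DomainError("index variant outside the locus window")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def pick_index_variant(stats: SummaryStats) -> Optional[VariantRecord]:
    """The min-p record; ties broken by smallest position then lexicographic id,
    so output is deterministic."""
    if not len(stats):
        return None
    df = stats.df
    pmin = df["p"].min()
    cand = df[df["p"] == pmin]
    cand = cand.sort_values(
        ["pos"] + (["id"] if "id" in cand.columns else []),
        kind="mergesort",
        na_position="last",
    )
    return VariantRecord.from_row(cand.iloc[0].to_dict())


def make_locus(
    stats: SummaryStats,
    region: Optional[tuple] = None,
    gene: Optional[str] = None,
    variant: Optional[str] = None,
    flank: int = 100_000,
    annotation=None,
    index_variant: Optional[VariantRecord] = None,
    biotypes: Optional[set] = None,
) -> Locus:
    """Resolve a region spec to an explicit window and build a Locus.

    Exactly one of ``region`` (chrom, start, end), ``gene`` (symbol, widened
    by ``flank`` on each side; requires ``annotation``) or ``variant`` (id,
    +/- ``flank``) must be given. Stats are filtered to the window, genes
    populated from the annotation, and the index variant defaults to the
    min-p record in the window.
    """
    given = [x is not None for x in (region, gene, variant)]
    if sum(given) != 1:
        raise ConfigurationError("specify exactly one of region, gene or variant")

    if region is not None:
        chrom, start, end = region
        chrom = normalize_chrom(chrom)
        start, end = int(start), int(end)
    elif gene is not None:
        if annotation is None:
            raise ConfigurationError("a gene-centred region spec requires an annotation")
        g = annotation.get_gene(gene)
        if g is None:
            raise UnknownFeatureError(f"gene symbol {gene!r} not found in annotation")
        chrom, start, end = g.chrom, g.start - flank, g.end + flank
    else:
        m = stats.df["id"] == variant if "id" in stats.df.columns else pd.Series(False, index=stats.df.index)
        if not m.any():
            raise UnknownFeatureError(f"variant id {variant!r} not found in summary statistics")
        row = stats.df[m].iloc[0]
        chrom = row["chrom"]
        start, end = int(row["pos"]) - flank, int(row["pos"]) + flank
    start = max(1, start)
    if start > end:
        raise DomainError(f"resolved window start {start} > end {end}")

    window_stats = stats.slice(chrom, start, end)
    if not len(window_stats):
        warnings.warn(f"locus {chrom}:{start}-{end} contains no variants", stacklevel=2)
    genes = []
    if annotation is not None:
        genes = annotation.query(chrom, start, end, biotypes=biotypes)
    idx = index_variant if index_variant is not None else pick_index_variant(window_stats)
    return Locus(chrom=chrom, start=start, end=end, stats=window_stats,
                 index_variant=idx, genes=genes)


def write_locus_tsv(locus: Locus, path) -> None:
    """Write the locus's stats slice as TSV."""
    write_summary_stats(locus.stats, path)
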