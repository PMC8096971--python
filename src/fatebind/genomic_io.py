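"""Genomic interval containers and standard-format I/O.

All coordinates are 0-based, half-open (BED convention). A narrowPeak
summit is an offset from the interval start, per the ENCODE dialect.
The "center" of a peak is ``start + summit`` when a summit is known and
the integer midpoint otherwise, matching common summit-centric practice
for ChIP-seq peak callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: promoter/distal boundary: a site whose center lies more than this many
#: base pairs from the nearest TSS is called distal.
DISTAL_BP = 2000

PEAK_COLUMNS = ["chrom", "start", "end", "site_id", "score", "strand", "summit"]


class PeakParseError(ValueError):
    """Raised when a peak file line cannot be parsed; names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A single 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    site_id: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class PeakSet:
    """An ordered collection of peaks backed by a DataFrame.

    Columns: chrom, start, end, site_id, score (-log10 q, NaN when
    absent), strand, summit (offset from start, NaN when absent).
    Rows are sorted by (chrom, start) and site_ids are unique.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))

    def __post_init__(self):
        df = self.df.copy()
        for col in PEAK_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("score", "summit") else "."
        df = df[list(dict.fromkeys(PEAK_COLUMNS + [c for c in df.columns]))]
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            df["chrom"] = df["chrom"].astype(str)
            df["site_id"] = df["site_id"].astype(str)
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
            if (df["end"] <= df["start"]).any():
                bad = df.index[df["end"] <= df["start"]][0]
                raise ValueError(f"end <= start for site {df.loc[bad, 'site_id']!r}")
            if df["site_id"].duplicated().any():
                dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
                raise ValueError(f"duplicate site_id {dup!r}")
            widths = df["end"] - df["start"]
            s = df["summit"]
            bad = s.notna() & ((s < 0) | (s >= widths))
            if bad.any():
                raise ValueError("summit offset outside interval")
            df = df.sort_values(["chrom", "start", "end", "site_id"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def centers(self) -> np.ndarray:
        """Per-peak center: start + summit when known, else midpoint."""
        start = self.df["start"].to_numpy()
        end = self.df["end"].to_numpy()
        mid = (start + end) // 2
        summit = self.df["summit"].to_numpy(dtype=float)
        has = ~np.isnan(summit)
        out = mid.copy()
        out[has] = start[has] + summit[has].astype(np.int64)
        return out

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.site_id)
            for r in self.df.itertuples()
        ]


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: identifier, chromosome, TSS and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


def _autoname(i: int) -> str:
    return f"peak_{i + 1}"


def read_peaks(path, format: str = "narrowPeak") -> PeakSet:
    """Read a BED (3-6 column) or 10-column narrowPeak file.

    narrowPeak column 9 (-log10 q-value) becomes ``score``; column 10
    becomes the summit offset (-1 meaning absent). Malformed lines raise
    :class:`PeakParseError` naming the 1-based line number.
    """
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown format {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if format == "narrowPeak":
                    if len(f) != 10:
                        raise ValueError(f"expected 10 columns, got {len(f)}")
                    chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                    strand = f[5] if f[5] in {"+", "-", "."} else "."
                    score = float(f[8])
                    summit = int(f[9])
                    summit = np.nan if summit < 0 else float(summit)
                else:
                    if len(f) < 3:
                        raise ValueError(f"expected >= 3 columns, got {len(f)}")
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else ""
                    score = float(f[4]) if len(f) > 4 and f[4] != "." else np.nan
                    strand = f[5] if len(f) > 5 and f[5] in {"+", "-", "."} else "."
                    summit = np.nan
                if end <= start:
                    raise ValueError(f"end <= start ({start}, {end})")
            except ValueError as exc:
                raise PeakParseError(f"{path}: line {lineno}: {exc}") from exc
            rows.append((chrom, start, end, name, score, strand, summit))
    if not rows:
        return PeakSet()
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    unnamed = df["site_id"].isin(["", "."])
    if unnamed.any():
        df.loc[unnamed, "site_id"] = [_autoname(i) for i in df.index[unnamed]]
    return PeakSet(df)


def write_peaks(peaks: PeakSet, path, format: str = "narrowPeak") -> None:
    """Write a PeakSet; ``read_peaks(write_peaks(p))`` round-trips coordinates,
    ids, scores and (narrowPeak only) summits bit-exactly."""
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown format {format!r}")
    df = peaks.df
    if format == "bed" and df["summit"].notna().any():
        logger.warning("BED output drops %d summit offsets", int(df["summit"].notna().sum()))
    with open(path, "w") as fh:
        for r in df.itertuples():
            score = "." if np.isnan(r.score) else repr(float(r.score))
            if format == "bed":
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.site_id}\t{score}\t{r.strand}\n")
            else:
                summit = -1 if np.isnan(r.summit) else int(r.summit)
                qv = 0.0 if np.isnan(r.score) else float(r.score)
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.site_id}\t0\t{r.strand}"
                    f"\t0\t-1\t{qv!r}\t{summit}\n"
                )


def recenter_fixed_width(peaks: PeakSet, width: int) -> PeakSet:
    """Replace every interval by a fixed-width window around its center.

    The window is [c - width//2, c - width//2 + width). Windows running
    off the left chromosome edge are clipped at 0 (right edge kept) and
    flagged in a ``clipped`` column.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    df = peaks.df.copy()
    if not len(df):
        df["clipped"] = pd.Series(dtype=bool)
        return PeakSet(df)
    c = peaks.centers
    start = c - width // 2
    end = start + width
    clipped = start < 0
    start = np.maximum(start, 0)
    df["start"], df["end"] = start, end
    df["summit"] = (c - start).astype(float)
    df["clipped"] = clipped
    return PeakSet(df)


def _merged_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (non-overlapping, sorted) intervals."""
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        ms, me = [], []
        for i in range(len(s)):
            if ms and s[i] < me[-1]:
                me[-1] = max(me[-1], e[i])
            else:
                ms.append(s[i])
                me.append(e[i])
        out[chrom] = (np.asarray(ms), np.asarray(me))
    return out


def _overlaps_any(df: pd.DataFrame, merged) -> np.ndarray:
    """Boolean mask: does each interval overlap >=1 bp of the merged set."""
    mask = np.zeros(len(df), dtype=bool)
    pos = {c: np.flatnonzero(df["chrom"].to_numpy() == c) for c in df["chrom"].unique()}
    for chrom, idx in pos.items():
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        s = df["start"].to_numpy()[idx]
        e = df["end"].to_numpy()[idx]
        # first merged interval ending strictly after s; overlap iff it starts before e
        j = np.searchsorted(me, s, side="right")
        ok = j < len(ms)
        hit = np.zeros(len(idx), dtype=bool)
        hit[ok] = ms[j[ok]] < e[ok]
        mask[idx] = hit
    return mask


def subtract_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop peaks overlapping (>=1 bp, half-open) any blacklist interval."""
    if not len(peaks) or not len(blacklist):
        return PeakSet(peaks.df.copy())
    mask = _overlaps_any(peaks.df, _merged_intervals(blacklist.df))
    logger.info("subtract_blacklist removed %d of %d peaks", int(mask.sum()), len(peaks))
    return PeakSet(peaks.df.loc[~mask].reset_index(drop=True))


class OverlapCounts(NamedTuple):
    shared_a: int
    shared_b: int
    a_only: int
    b_only: int


def overlap_sets(a: PeakSet, b: PeakSet) -> OverlapCounts:
    """Count sites shared (>=1 bp overlap with the other set) from each side."""
    if not len(a) or not len(b):
        return OverlapCounts(0, 0, len(a), len(b))
    in_b = _overlaps_any(a.df, _merged_intervals(b.df))
    in_a = _overlaps_any(b.df, _merged_intervals(a.df))
    return OverlapCounts(
        int(in_b.sum()), int(in_a.sum()), int((~in_b).sum()), int((~in_a).sum())
    )


def nearest_tss(peaks: PeakSet, genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Annotate each peak with its nearest-TSS gene and signed distance.

    distance = peak center - TSS, minimized in |distance| over genes on the
    same chromosome; ties broken by lexicographically smaller gene_id.
    Returns a DataFrame (site_id, gene_id, distance, locale) where locale is
    promoter_proximal (|distance| <= 2 kb), distal, or unannotated for peaks
    on chromosomes without genes (gene_id None, distance NaN).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene collection is empty")
    gdf = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "chrom": [g.chrom for g in genes],
         "tss": [g.tss for g in genes]}
    )
    if gdf["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids")
    by_chrom = {}
    for chrom, sub in gdf.groupby("chrom"):
        sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
        by_chrom[chrom] = (sub["tss"].to_numpy(), sub["gene_id"].to_numpy())
    centers = peaks.centers
    out = []
    for i, r in enumerate(peaks.df.itertuples()):
        if r.chrom not in by_chrom:
            out.append((r.site_id, None, np.nan, "unannotated"))
            continue
        tss, gids = by_chrom[r.chrom]
        c = centers[i]
        d = np.abs(tss - c)
        best = d.min()
        cand = np.flatnonzero(d == best)
        gid = min(gids[cand])  # lexicographic tie-break
        signed = int(c - tss[cand[np.argmax(gids[cand] == gid)]])
        locale = "promoter_proximal" if abs(signed) <= DISTAL_BP else "distal"
        out.append((r.site_id, gid, signed, locale))
    return pd.DataFrame(out, columns=["site_id", "gene_id", "distance", "locale"])


def read_genes(path) -> list[GeneModel]:
    """Read a GTF-lite gene table: tab-delimited gene_id, chrom, tss, strand."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            f = line.split("\t")
            try:
                if len(f) < 4:
                    raise ValueError(f"expected 4 columns, got {len(f)}")
                genes.append(GeneModel(f[0], f[1], int(f[2]), f[3]))
            except ValueError as exc:
                raise PeakParseError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")
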