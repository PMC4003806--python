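"""Marker-site allele-count tables: data model, TSV/BED IO, and marker filters.

The observed data of a bulk-segregant experiment is, per polymorphic marker
site, the number of pooled reads supporting the superior-parent variant and
the total read count.  Tables are tab-separated text with a header line
(columns CHROM, POS, SUPERIOR_COUNT, TOTAL_COUNT, optional QUAL); ``#``
prefixed lines are comments.  Coordinates are 1-based (VCF convention);
region output is 5-column BED (0-based, half-open).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

__all__ = [
    "MarkerSite",
    "MarkerTrack",
    "MarkerTableError",
    "read_marker_table",
    "write_marker_table",
    "filter_by_coverage",
    "filter_by_spacing",
    "filter_by_quality",
    "write_posterior_table",
    "write_regions_bed",
]


class MarkerTableError(ValueError):
    """Malformed marker table (carries the offending line number when known)."""


@dataclass(frozen=True)
class MarkerSite:
    """A single polymorphic site with pooled allele counts.

    ``superior_count`` is the number of reads supporting the variant of the
    superior parent; ``total_count`` the total reads covering the site.
    """

    chrom: str
    pos: int
    superior_count: int
    total_count: int
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0 <= self.superior_count <= self.total_count):
            raise ValueError(
                f"need 0 <= superior_count <= total_count, got "
                f"{self.superior_count}/{self.total_count} at {self.chrom}:{self.pos}"
            )
        if self.quality is not None and self.quality < 0:
            raise ValueError(f"quality must be non-negative, got {self.quality}")


@dataclass
class MarkerTrack:
    """Ordered series of marker sites on one chromosome.

    Positions are strictly increasing; the track may be empty.  Array views
    (``positions``, ``superior``, ``total``) are provided for vectorised code.
    """

    chrom: str
    sites: list[MarkerSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sites:
            if s.chrom != self.chrom:
                raise ValueError(f"site chrom {s.chrom!r} != track chrom {self.chrom!r}")
        pos = [s.pos for s in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"positions on {self.chrom} must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def superior(self) -> np.ndarray:
        return np.array([s.superior_count for s in self.sites], dtype=np.int64)

    @property
    def total(self) -> np.ndarray:
        return np.array([s.total_count for s in self.sites], dtype=np.int64)

    @property
    def qualities(self) -> np.ndarray | None:
        if any(s.quality is None for s in self.sites):
            return None
        return np.array([s.quality for s in self.sites], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        chrom: str,
        positions: Sequence[int],
        superior: Sequence[int],
        total: Sequence[int],
        qualities: Sequence[float] | None = None,
    ) -> "MarkerTrack":
        sites = [
            MarkerSite(
                chrom,
                int(p),
                int(k),
                int(n),
                None if qualities is None else float(qualities[i]),
            )
            for i, (p, k, n) in enumerate(zip(positions, superior, total))
        ]
        return cls(chrom, sites)


_REQUIRED = ("CHROM", "POS", "SUPERIOR_COUNT", "TOTAL_COUNT")


def read_marker_table(source: str | Path | IO[str]) -> list[MarkerTrack]:
    """Read a marker TSV into one :class:`MarkerTrack` per chromosome.

    The header must contain CHROM, POS, SUPERIOR_COUNT, TOTAL_COUNT and may
    contain QUAL.  Rows are grouped by chromosome and sorted by position;
    duplicate (CHROM, POS) pairs are rejected.  Errors name the 1-based line
    number of the offending row.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8", newline="") as fh:
            return read_marker_table(fh)

    header: list[str] | None = None
    cols: dict[str, int] = {}
    rows: dict[str, list[tuple[int, int, int, float | None, int]]] = {}
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            cols = {name: i for i, name in enumerate(header)}
            missing = [c for c in _REQUIRED if c not in cols]
            if missing:
                raise MarkerTableError(
                    f"line {lineno}: header missing required column(s) {missing}"
                )
            continue
        try:
            chrom = fields[cols["CHROM"]]
            pos = int(fields[cols["POS"]])
            sup = int(fields[cols["SUPERIOR_COUNT"]])
            tot = int(fields[cols["TOTAL_COUNT"]])
            qual = None
            if "QUAL" in cols:
                raw = fields[cols["QUAL"]]
                qual = None if raw in ("", ".") else float(raw)
        except (IndexError, ValueError) as exc:
            raise MarkerTableError(f"line {lineno}: malformed row: {exc}") from exc
        if pos < 1:
            raise MarkerTableError(f"line {lineno}: non-positive POS {pos}")
        if sup < 0 or tot < 0 or sup > tot:
            raise MarkerTableError(
                f"line {lineno}: need 0 <= SUPERIOR_COUNT <= TOTAL_COUNT, got {sup}/{tot}"
            )
        rows.setdefault(chrom, []).append((pos, sup, tot, qual, lineno))
    if header is None:
        raise MarkerTableError("empty input: no header line found")

    tracks: list[MarkerTrack] = []
    for chrom, recs in rows.items():
        recs.sort(key=lambda r: r[0])
        for (p1, *_, l1), (p2, *_, l2) in zip(recs, recs[1:]):
            if p1 == p2:
                raise MarkerTableError(
                    f"line {l2}: duplicate marker {chrom}:{p2} (first seen line {l1})"
                )
        tracks.append(
            MarkerTrack(
                chrom,
                [MarkerSite(chrom, p, s, t, q) for p, s, t, q, _ in recs],
            )
        )
    return tracks


def write_marker_table(tracks: Iterable[MarkerTrack], sink: str | Path | IO[str]) -> None:
    """Write tracks back to the canonical TSV (QUAL column only if all sites carry it)."""
    if isinstance(sink, (str, Path)):
        with open(sink, "wt", encoding="utf-8", newline="") as fh:
            write_marker_table(tracks, fh)
        return
    tracks = list(tracks)
    with_qual = all(s.quality is not None for t in tracks for s in t)
    w = csv.writer(sink, delimiter="\t", lineterminator="\n")
    hdr = list(_REQUIRED) + (["QUAL"] if with_qual else [])
    w.writerow(hdr)
    for t in tracks:
        for s in t:
            row = [s.chrom, s.pos, s.superior_count, s.total_count]
            if with_qual:
                row.append(f"{s.quality:g}")
            w.writerow(row)


def filter_by_coverage(
    track: MarkerTrack, min_cov: int = 20, max_cov: int = 100
) -> MarkerTrack:
    """Keep sites with min_cov <= total_count <= max_cov (bounds inclusive)."""
    if min_cov > max_cov:
        raise ValueError(f"min_cov {min_cov} > max_cov {max_cov}")
    kept = [s for s in track if min_cov <= s.total_count <= max_cov]
    return MarkerTrack(track.chrom, kept)


def filter_by_spacing(track: MarkerTrack, min_spacing_bp: int = 30) -> MarkerTrack:
    """Drop BOTH members of every pair of input sites closer than ``min_spacing_bp``.

    Distances are measured on the original input in a single pass, so a site
    survives iff its distance to each original neighbour is >= the threshold;
    this makes the filter order-independent and idempotent.
    """
    n = len(track)
    if n <= 1:
        return MarkerTrack(track.chrom, list(track.sites))
    pos = track.positions
    gaps = np.diff(pos)
    close_prev = np.concatenate([[False], gaps < min_spacing_bp])
    close_next = np.concatenate([gaps < min_spacing_bp, [False]])
    keep = ~(close_prev | close_next)
    return MarkerTrack(track.chrom, [s for s, k in zip(track.sites, keep) if k])


def filter_by_quality(track: MarkerTrack, min_quality: float = 40) -> MarkerTrack:
    """Keep sites whose upstream genotype quality is >= ``min_quality``."""
    for s in track:
        if s.quality is None:
            raise ValueError(
                f"quality filter requested but {s.chrom}:{s.pos} has no quality value"
            )
    kept = [s for s in track if s.quality >= min_quality]
    return MarkerTrack(track.chrom, kept)


def write_posterior_table(
    tracks: Iterable[MarkerTrack],
    posteriors: Iterable[np.ndarray],
    sink: str | Path | IO[str],
) -> None:
    """Write per-site linkage posteriors as TSV (POSTERIOR with 6 decimals)."""
    if isinstance(sink, (str, Path)):
        with open(sink, "wt", encoding="utf-8", newline="") as fh:
            write_posterior_table(tracks, posteriors, fh)
        return
    sink.write("CHROM\tPOS\tSUPERIOR_COUNT\tTOTAL_COUNT\tPOSTERIOR\n")
    for track, post in zip(tracks, posteriors):
        post = np.asarray(post, dtype=float)
        if len(post) != len(track):
            raise ValueError(
                f"{track.chrom}: {len(post)} posteriors for {len(track)} sites"
            )
        for s, p in zip(track, post):
            sink.write(
                f"{s.chrom}\t{s.pos}\t{s.superior_count}\t{s.total_count}\t{p:.6f}\n"
            )


def write_regions_bed(regions: Iterable, sink: str | Path | IO[str]) -> None:
    """Write called regions as 5-column BED.

    chromStart = first marker pos - 1, chromEnd = last marker pos (0-based,
    half-open); score = round(1000 * max posterior in the region).
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "wt", encoding="utf-8", newline="") as fh:
            write_regions_bed(regions, fh)
        return
    for i, r in enumerate(regions, start=1):
        score = int(round(1000 * r.max_posterior))
        sink.write(f"{r.chrom}\t{r.start_pos - 1}\t{r.end_pos}\tregion_{i}\t{score}\n")


def tracks_to_dataframe(tracks: Iterable[MarkerTrack]):
    """Flatten tracks into a pandas DataFrame (CHROM, POS, SUPERIOR_COUNT, TOTAL_COUNT[, QUAL])."""
    import pandas as pd

    recs = []
    for t in tracks:
        for s in t:
            recs.append((s.chrom, s.pos, s.superior_count, s.total_count, s.quality))
    df = pd.DataFrame(
        recs, columns=["CHROM", "POS", "SUPERIOR_COUNT", "TOTAL_COUNT", "QUAL"]
    )
    if df["QUAL"].isna().all():
        df = df.drop(columns=["QUAL"])
    return df


def tracks_from_dataframe(df) -> list[MarkerTrack]:
    """Build tracks from a DataFrame with the canonical column names."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_marker_table(buf)
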