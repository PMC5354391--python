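"""Interval formats, the genome coordinate model, and the sample sheet.

All coordinates are 0-based, half-open (BED convention). Every grid,
track and interval in the package refers back to a :class:`Genome`, whose
chromosome order is fixed and shared by all downstream arrays.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "Genome",
    "DomainSet",
    "FeatureTrack",
    "SampleRecord",
    "SampleSheet",
    "read_scored_bed",
    "read_interval_bed",
    "read_sample_sheet",
    "subtract_intervals",
    "intervals_by_chrom",
    "merge_intervals",
    "write_bed",
    "write_bedgraph",
]

SEX_CHROM_SUFFIXES = ("X", "Y")

#: Sample categories recognised by the pipeline.
CATEGORIES = ("granulocyte", "cd34", "aml", "k562_control", "k562_unc0638")


class Interval(NamedTuple):
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class BedFormatError(ValueError):
    """Raised on malformed or invalid BED-dialect input."""


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths; the coordinate frame for all grids."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {n} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def is_sex_chrom(self, chrom: str) -> bool:
        return chrom.upper().rstrip() .endswith(SEX_CHROM_SUFFIXES)

    def is_y(self, chrom: str) -> bool:
        return chrom.upper().endswith("Y")

    def autosomes(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if not self.is_sex_chrom(n))

    def validate_interval(self, iv: Interval) -> None:
        if iv.chrom not in self.lengths:
            raise BedFormatError(f"unknown chromosome {iv.chrom!r}")
        if not (0 <= iv.start < iv.end <= self.length(iv.chrom)):
            raise BedFormatError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome "
                f"bounds [0, {self.length(iv.chrom)})"
            )

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "Genome":
        """Read a two-column chrom\\tlength TSV."""
        chroms = []
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise BedFormatError(f"{path}:{ln}: expected chrom\\tlength")
                chroms.append((parts[0], int(parts[1])))
        return cls(tuple(chroms))

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for n, l in self.chromosomes:
                fh.write(f"{n}\t{l}\n")


@dataclass
class DomainSet:
    """One sample's scored, non-overlapping enriched domains.

    ``mean_depth`` is the domain's average read count per nucleotide as
    reported by the domain caller; it is the quantity each domain
    contributes per bp when mapped onto windows.
    """

    sample_id: str
    domains: list[tuple[Interval, float]]

    def __post_init__(self) -> None:
        self.domains.sort(key=lambda d: (d[0].chrom, d[0].start))
        prev: Interval | None = None
        for iv, depth in self.domains:
            if depth < 0:
                raise BedFormatError(
                    f"{self.sample_id}: negative score {depth} at "
                    f"{iv.chrom}:{iv.start}-{iv.end}"
                )
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise BedFormatError(
                    f"{self.sample_id}: overlapping domains "
                    f"{prev.chrom}:{prev.start}-{prev.end} and "
                    f"{iv.chrom}:{iv.start}-{iv.end}"
                )
            prev = iv

    def intervals(self) -> list[Interval]:
        return [iv for iv, _ in self.domains]

    def total_bp(self) -> int:
        return sum(iv.length for iv, _ in self.domains)


@dataclass
class FeatureTrack:
    """A genomic feature annotation: intervals (possibly overlapping) or points.

    Points are stored as length-1 intervals. ``names``, when present, is
    aligned with ``intervals`` and carries e.g. gene symbols.
    """

    feature_id: str
    intervals: list[Interval]
    kind: str = "interval"  # "interval" | "point"
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("interval", "point"):
            raise ValueError(f"bad feature kind {self.kind!r}")
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start),
        )
        self.intervals = [self.intervals[i] for i in order]
        if self.names is not None:
            if len(self.names) != len(self.intervals):
                raise ValueError("names not aligned with intervals")
            self.names = [self.names[i] for i in order]

    def __len__(self) -> int:
        return len(self.intervals)


class SampleRecord(NamedTuple):
    sample_id: str
    category: str
    aml_cluster: str  # "A" | "B" | "none"
    sex: str  # "M" | "F"
    platform: str
    replicate_group: str
    path: str


@dataclass
class SampleSheet:
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in sample sheet")
        for s in self.samples:
            if s.category not in CATEGORIES:
                raise ValueError(f"{s.sample_id}: unknown category {s.category!r}")
            if (s.aml_cluster != "none") != (s.category == "aml"):
                raise ValueError(
                    f"{s.sample_id}: aml_cluster must be A/B iff category is aml"
                )
            if s.sex not in ("M", "F"):
                raise ValueError(f"{s.sample_id}: sex must be M or F")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def by_id(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def group(self, key: str) -> list[SampleRecord]:
        """Samples of a comparison group: a category name, or aml_a / aml_b."""
        if key in ("aml_a", "aml_b"):
            cluster = key[-1].upper()
            return [s for s in self.samples if s.category == "aml" and s.aml_cluster == cluster]
        return [s for s in self.samples if s.category == key]

    def replicate_groups(self) -> dict[str, list[SampleRecord]]:
        out: dict[str, list[SampleRecord]] = {}
        for s in self.samples:
            out.setdefault(s.replicate_group, []).append(s)
        return out

    def to_file(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.samples, columns=SampleRecord._fields)
        df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | os.PathLike, check_paths: bool = True) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("none")
    missing = set(SampleRecord._fields) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    base = Path(path).parent
    records = []
    for row in df.itertuples(index=False):
        p = str(getattr(row, "path"))
        if not os.path.isabs(p):
            p = str(base / p)
        rec = SampleRecord(
            sample_id=str(row.sample_id),
            category=str(row.category),
            aml_cluster=str(row.aml_cluster),
            sex=str(row.sex),
            platform=str(row.platform),
            replicate_group=str(row.replicate_group),
            path=p,
        )
        if check_paths and not os.path.exists(rec.path):
            raise FileNotFoundError(f"{rec.sample_id}: missing file {rec.path}")
        records.append(rec)
    return SampleSheet(records)


def _open_text(path: str | os.PathLike) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_bed_line(line: str, ln: int, path: str) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise BedFormatError(f"{path}:{ln}: fewer than 3 columns")
    try:
        int(parts[1]), int(parts[2])
    except ValueError:
        raise BedFormatError(f"{path}:{ln}: non-integer coordinates") from None
    return parts


def read_scored_bed(
    path: str | os.PathLike,
    genome: Genome,
    score_column: int = 5,
    sample_id: str | None = None,
) -> DomainSet:
    """Read a domain-caller output BED into a validated :class:`DomainSet`.

    ``score_column`` is the 1-based column holding the per-domain average
    read count (default 5, i.e. the BED score slot). Gzip is handled
    transparently.
    """
    if sample_id is None:
        name = Path(path).name
        for suf in (".gz", ".bed", ".rsegout"):
            if name.endswith(suf):
                name = name[: -len(suf)]
        sample_id = name
    domains: list[tuple[Interval, float]] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _parse_bed_line(line, ln, str(path))
            if len(parts) < score_column:
                raise BedFormatError(
                    f"{path}:{ln}: score column {score_column} absent "
                    f"({len(parts)} columns)"
                )
            try:
                depth = float(parts[score_column - 1])
            except ValueError:
                raise BedFormatError(
                    f"{path}:{ln}: score {parts[score_column - 1]!r} is not a number"
                ) from None
            iv = Interval(parts[0], int(parts[1]), int(parts[2]))
            genome.validate_interval(iv)
            domains.append((iv, depth))
    return DomainSet(sample_id, domains)


def read_interval_bed(
    path: str | os.PathLike,
    genome: Genome,
    kind: str = "interval",
    feature_id: str | None = None,
) -> FeatureTrack:
    """Read a plain BED into a :class:`FeatureTrack`; column 4 becomes names."""
    if feature_id is None:
        feature_id = Path(path).stem.removesuffix(".bed")
    intervals: list[Interval] = []
    names: list[str] = []
    have_names = True
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _parse_bed_line(line, ln, str(path))
            iv = Interval(parts[0], int(parts[1]), int(parts[2]))
            genome.validate_interval(iv)
            intervals.append(iv)
            if len(parts) >= 4:
                names.append(parts[3])
            else:
                have_names = False
    return FeatureTrack(
        feature_id, intervals, kind=kind, names=names if (have_names and names) else None
    )


def intervals_by_chrom(intervals: Iterable[Interval]) -> dict[str, np.ndarray]:
    """Group intervals into per-chromosome (n, 2) start/end arrays, sorted."""
    grouped: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(rows), dtype=np.int64).reshape(-1, 2)
        for c, rows in grouped.items()
    }


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of a set of intervals: sorted, non-overlapping, adjacent merged."""
    out: list[Interval] = []
    for chrom, arr in sorted(intervals_by_chrom(intervals).items()):
        cur_s, cur_e = None, None
        for s, e in arr:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(Interval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append(Interval(chrom, int(cur_s), int(cur_e)))
    return out


def subtract_intervals(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[Interval]:
    """Exact base-pair set difference a \\ b.

    Both inputs may be unsorted and b may overlap itself; the result is
    sorted and non-overlapping provided a is non-overlapping.
    """
    b_merged = intervals_by_chrom(merge_intervals(list(b)))
    out: list[Interval] = []
    for iv in sorted(a, key=lambda x: (x.chrom, x.start)):
        cuts = b_merged.get(iv.chrom)
        if cuts is None or len(cuts) == 0:
            out.append(iv)
            continue
        pos = iv.start
        # only cuts overlapping [start, end) matter
        lo = int(np.searchsorted(cuts[:, 1], iv.start, side="right"))
        for s, e in cuts[lo:]:
            if s >= iv.end:
                break
            if s > pos:
                out.append(Interval(iv.chrom, pos, int(s)))
            pos = max(pos, int(e))
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(Interval(iv.chrom, pos, iv.end))
    return out


def write_bed(
    records: Iterable[tuple[Interval, str] | tuple[Interval, str, float]],
    path: str | os.PathLike,
) -> None:
    """Write (interval, label[, score]) records as BED lines."""
    with open(path, "w") as fh:
        for rec in records:
            iv, label = rec[0], rec[1]
            cols = [iv.chrom, str(iv.start), str(iv.end), label]
            if len(rec) > 2:
                cols.append(f"{rec[2]:.6g}")
            fh.write("\t".join(cols) + "\n")


def write_bedgraph(track, path: str | os.PathLike) -> None:
    """Write a window track as bedGraph, omitting masked windows.

    Values are printed with 6 significant digits so a read/write/read
    cycle reproduces scores to 1e-6 relative.
    """
    grid = track.grid
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={track.sample_id}\n")
        for chrom in grid.genome.names:
            off = grid.offsets[chrom]
            n = grid.n_windows[chrom]
            L = grid.genome.length(chrom)
            r = grid.resolution
            for k in range(n):
                i = off + k
                if track.mask[i]:
                    continue
                fh.write(
                    f"{chrom}\t{k * r}\t{min((k + 1) * r, L)}\t{track.scores[i]:.6g}\n"
                )


def read_bedgraph(path: str | os.PathLike, grid) -> "np.ndarray":
    """Read a bedGraph written by :func:`write_bedgraph` back onto ``grid``.

    Returns a scores array with NaN at windows absent from the file.
    """
    scores = np.full(grid.n_total, np.nan)
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, s, _e, v = line.split("\t")
            scores[grid.offsets[chrom] + int(s) // grid.resolution] = float(v)
    return scores
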