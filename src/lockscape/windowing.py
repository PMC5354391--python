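"""Fixed-resolution window grids and domain-to-window score tracks.

A window's raw score is the sum over domains of ``mean_depth * overlap_bp``
after deadzone (low-alignability) nucleotides are removed — i.e. each
domain contributes its average read count for every non-deadzone
nucleotide that falls in the window. Raw scores are additive, so a 10 kb
track can be coarsened to any multiple resolution exactly. Tracks are
normalized by the mean over unmasked windows, and technical replicates
are averaged after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genomic_io import DomainSet, FeatureTrack, Genome, Interval, intervals_by_chrom, merge_intervals

__all__ = ["WindowGrid", "WindowTrack", "score_windows", "normalize_track",
           "average_replicates", "coarsen", "RESOLUTIONS"]

#: The five analysis resolutions, bp.
RESOLUTIONS = (10_000, 50_000, 100_000, 500_000, 1_000_000)


def _coverage_per_window(
    arr: np.ndarray, r: int, n_win: int, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted bp of the given (n,2) intervals falling in each window."""
    out = np.zeros(n_win)
    if len(arr) == 0:
        return out
    for idx in range(len(arr)):
        s, e = int(arr[idx, 0]), int(arr[idx, 1])
        w = 1.0 if weights is None else float(weights[idx])
        w0, w1 = s // r, (e - 1) // r
        if w0 == w1:
            out[w0] += w * (e - s)
        else:
            ks = np.arange(w0, w1 + 1)
            left = np.maximum(s, ks * r)
            right = np.minimum(e, (ks + 1) * r)
            out[w0 : w1 + 1] += w * (right - left)
    return out


class WindowGrid:
    """Consecutive tiles of size ``resolution`` over every chromosome.

    Windows are stored flat in chromosome order; ``offsets[chrom]`` gives
    the index of a chromosome's first window. ``effective_length`` is the
    non-deadzone bp per window and a window is masked iff it is 0.
    """

    def __init__(
        self,
        genome: Genome,
        resolution: int,
        deadzones: Sequence[Interval] | None = None,
        _effective_length: np.ndarray | None = None,
    ):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.genome = genome
        self.resolution = int(resolution)
        self.n_windows: dict[str, int] = {}
        self.offsets: dict[str, int] = {}
        off = 0
        for chrom, L in genome.chromosomes:
            n = -(-L // resolution)  # ceil
            self.n_windows[chrom] = n
            self.offsets[chrom] = off
            off += n
        self.n_total = off

        self.window_length = np.empty(self.n_total, dtype=np.int64)
        self.chrom_index = np.empty(self.n_total, dtype=np.int32)
        for ci, (chrom, L) in enumerate(genome.chromosomes):
            o, n = self.offsets[chrom], self.n_windows[chrom]
            self.window_length[o : o + n] = resolution
            self.window_length[o + n - 1] = L - (n - 1) * resolution
            self.chrom_index[o : o + n] = ci

        if _effective_length is not None:
            self.effective_length = _effective_length.astype(np.int64)
        else:
            self.effective_length = self.window_length.copy()
            if deadzones:
                dz = intervals_by_chrom(merge_intervals(list(deadzones)))
                for chrom, arr in dz.items():
                    if chrom not in self.offsets:
                        continue
                    o, n = self.offsets[chrom], self.n_windows[chrom]
                    covered = _coverage_per_window(arr, resolution, n)
                    self.effective_length[o : o + n] -= covered.astype(np.int64)
        if (self.effective_length < 0).any():
            raise ValueError("deadzones exceed window lengths (overlapping input?)")
        self.mask = self.effective_length == 0

    def window_interval(self, i: int) -> Interval:
        chrom = self.genome.names[self.chrom_index[i]]
        k = i - self.offsets[chrom]
        r = self.resolution
        return Interval(chrom, k * r, k * r + int(self.window_length[i]))

    def window_ids(self) -> list[str]:
        return [
            f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in (self.window_interval(i) for i in range(self.n_total))
        ]

    def chrom_slice(self, chrom: str) -> slice:
        o = self.offsets[chrom]
        return slice(o, o + self.n_windows[chrom])

    def is_y_window(self) -> np.ndarray:
        y = np.array([self.genome.is_y(n) for n in self.genome.names])
        return y[self.chrom_index]

    def is_sex_window(self) -> np.ndarray:
        s = np.array([self.genome.is_sex_chrom(n) for n in self.genome.names])
        return s[self.chrom_index]

    def autosome_selector(self) -> np.ndarray:
        return ~self.is_sex_window()

    def compatible(self, other: "WindowGrid") -> bool:
        return (
            self.genome.chromosomes == other.genome.chromosomes
            and self.resolution == other.resolution
            and np.array_equal(self.effective_length, other.effective_length)
        )


@dataclass
class WindowTrack:
    """Per-window scores of one sample (or one averaged replicate group)."""

    sample_id: str
    grid: WindowGrid
    scores: np.ndarray  # float, undefined (0) on masked windows
    mask: np.ndarray  # bool, True = excluded; superset of grid.mask
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.scores.shape != (self.grid.n_total,):
            raise ValueError("scores shape does not match grid")
        if self.mask.shape != (self.grid.n_total,):
            raise ValueError("mask shape does not match grid")

    def unmasked_scores(self) -> np.ndarray:
        return self.scores[~self.mask]


def score_windows(
    domains: DomainSet,
    grid: WindowGrid,
    deadzones: Sequence[Interval] | None = None,
    double_xy: bool = False,
) -> WindowTrack:
    """Map scored domains onto a grid (raw scores, read-count·bp units).

    ``deadzones`` must be the same set used to build ``grid`` so masking
    and score subtraction agree. With ``double_xy`` the raw X/Y scores of
    a male sample are doubled to compensate haploid sex chromosomes.
    """
    from .genomic_io import subtract_intervals

    scores = np.zeros(grid.n_total)
    ivs = [iv for iv, _ in domains.domains]
    depths = [d for _, d in domains.domains]
    if deadzones:
        # carry each domain's depth through the subtraction
        pieces: list[tuple[Interval, float]] = []
        for iv, depth in zip(ivs, depths):
            for piece in subtract_intervals([iv], deadzones):
                pieces.append((piece, depth))
    else:
        pieces = list(zip(ivs, depths))

    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for iv, depth in pieces:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, depth))
    for chrom, rows in by_chrom.items():
        if chrom not in grid.offsets:
            raise ValueError(f"domain chromosome {chrom!r} absent from grid genome")
        arr = np.array([(s, e) for s, e, _ in rows], dtype=np.int64)
        w = np.array([d for _, _, d in rows])
        o, n = grid.offsets[chrom], grid.n_windows[chrom]
        scores[o : o + n] += _coverage_per_window(arr, grid.resolution, n, weights=w)

    if double_xy:
        sexw = grid.is_sex_window()
        scores[sexw] *= 2.0

    scores[grid.mask] = 0.0
    return WindowTrack(domains.sample_id, grid, scores, grid.mask.copy(), normalized=False)


def normalize_track(track: WindowTrack) -> WindowTrack:
    """Divide by the mean over unmasked windows; idempotent up to rounding."""
    vals = track.unmasked_scores()
    if vals.size == 0 or not np.any(vals > 0):
        raise ValueError(f"degenerate sample {track.sample_id}: all-zero track")
    mean = vals.mean()
    scores = track.scores / mean
    scores[track.mask] = 0.0
    return WindowTrack(track.sample_id, track.grid, scores, track.mask.copy(), normalized=True)


def average_replicates(tracks: Sequence[WindowTrack], sample_id: str | None = None) -> WindowTrack:
    """Element-wise mean of normalized technical replicates; masks union."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if not t.grid.compatible(first.grid):
            raise ValueError("replicates on different grids")
    if not all(t.normalized for t in tracks):
        raise ValueError("replicates must be normalized before averaging")
    mask = np.logical_or.reduce([t.mask for t in tracks])
    scores = np.mean([t.scores for t in tracks], axis=0)
    scores[mask] = 0.0
    return WindowTrack(
        sample_id or first.sample_id, first.grid, scores, mask,
        normalized=True,
    )


def coarsen(track: WindowTrack, resolution: int) -> WindowTrack:
    """Re-bin a raw fine track to a coarser resolution (exact: raw sums add).

    The coarse grid's effective lengths are the sums of the member fine
    windows', so masking matches a direct build from the same deadzones.
    """
    if track.normalized:
        raise ValueError("coarsen requires a raw (unnormalized) track")
    fine = track.grid
    if resolution % fine.resolution != 0:
        raise ValueError("target resolution must be a multiple of the fine one")
    factor = resolution // fine.resolution

    coarse = WindowGrid(fine.genome, resolution, _effective_length=np.zeros(1))
    # rebuild flat arrays by group-summing per chromosome
    eff = np.zeros(coarse.n_total, dtype=np.int64)
    scores = np.zeros(coarse.n_total)
    for chrom in fine.genome.names:
        fo, fn = fine.offsets[chrom], fine.n_windows[chrom]
        co, cn = coarse.offsets[chrom], coarse.n_windows[chrom]
        groups = np.arange(fn) // factor
        eff[co : co + cn] = np.bincount(groups, weights=fine.effective_length[fo : fo + fn], minlength=cn).astype(np.int64)
        scores[co : co + cn] = np.bincount(groups, weights=track.scores[fo : fo + fn], minlength=cn)
    coarse.effective_length = eff
    coarse.mask = eff == 0
    scores[coarse.mask] = 0.0
    return WindowTrack(track.sample_id, coarse, scores, coarse.mask.copy(), normalized=False)
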