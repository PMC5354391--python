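"""Pearson correlation of window tracks, sample clustering, boundary profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy

from .genomic_io import DomainSet, FeatureTrack, Interval, intervals_by_chrom, merge_intervals
from .windowing import WindowGrid, WindowTrack, _coverage_per_window

__all__ = [
    "CorrelationMatrix",
    "BoundaryProfile",
    "feature_density_track",
    "pearson_pairwise",
    "hcluster_samples",
    "linkage_to_newick",
    "boundary_metaprofile",
]


@dataclass
class CorrelationMatrix:
    ids: list[str]
    resolution: int
    r: np.ndarray  # (k, k), NaN where undefined (zero-variance track)
    n_windows: np.ndarray  # (k, k) int, jointly unmasked windows used


@dataclass
class BoundaryProfile:
    """Mean feature bp-density around domain boundaries.

    Offsets are bin centers relative to a boundary; positive offsets lie
    inside the domain (5' and 3' boundaries are pooled after mirroring
    the 3' side so the inward direction is consistent).
    """

    offsets: np.ndarray  # bp, signed
    density: np.ndarray  # mean covered fraction per bin
    n_boundaries: int


def feature_density_track(
    feature: FeatureTrack,
    grid: WindowGrid,
    deadzones: Sequence[Interval] | None = None,
) -> WindowTrack:
    """Per-window feature density: non-deadzone covered bp, or point counts.

    Interval features are merged first (overlaps count once) and deadzone
    nucleotides are subtracted, mirroring the handling of sample tracks.
    Point features are counted per window; points inside deadzones are
    dropped.
    """
    from .genomic_io import subtract_intervals

    scores = np.zeros(grid.n_total)
    if feature.kind == "interval":
        ivs = merge_intervals(feature.intervals)
        if deadzones:
            ivs = subtract_intervals(ivs, deadzones)
        for chrom, arr in intervals_by_chrom(ivs).items():
            if chrom not in grid.offsets:
                continue
            o, n = grid.offsets[chrom], grid.n_windows[chrom]
            scores[o : o + n] += _coverage_per_window(arr, grid.resolution, n)
    else:
        dz = intervals_by_chrom(merge_intervals(list(deadzones))) if deadzones else {}
        for iv in feature.intervals:
            if iv.chrom not in grid.offsets:
                continue
            cuts = dz.get(iv.chrom)
            if cuts is not None and len(cuts):
                j = int(np.searchsorted(cuts[:, 0], iv.start, side="right")) - 1
                if j >= 0 and cuts[j, 1] > iv.start:
                    continue
            scores[grid.offsets[iv.chrom] + iv.start // grid.resolution] += 1.0
    scores[grid.mask] = 0.0
    return WindowTrack(feature.feature_id, grid, scores, grid.mask.copy(), normalized=False)


def _select_windows(
    tracks: Sequence[WindowTrack], autosomes_only: bool, region: Interval | None
) -> np.ndarray:
    grid = tracks[0].grid
    sel = np.ones(grid.n_total, dtype=bool)
    if autosomes_only:
        sel &= grid.autosome_selector()
    if region is not None:
        rsel = np.zeros(grid.n_total, dtype=bool)
        o = grid.offsets[region.chrom]
        r = grid.resolution
        first = region.start // r
        last = (region.end - 1) // r
        rsel[o + first : o + last + 1] = True
        sel &= rsel
    return sel


def pearson_pairwise(
    tracks: Sequence[WindowTrack],
    autosomes_only: bool = True,
    region: Interval | None = None,
) -> CorrelationMatrix:
    """Pairwise Pearson r over windows unmasked in both tracks.

    Undefined correlations (a zero-variance track) are reported as NaN.
    Fewer than 3 jointly unmasked windows is an error.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    grid = tracks[0].grid
    for t in tracks[1:]:
        if not t.grid.compatible(grid):
            raise ValueError("tracks on different grids")
    sel = _select_windows(tracks, autosomes_only, region)
    k = len(tracks)
    r = np.eye(k)
    n = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        n[i, i] = int((sel & ~tracks[i].mask).sum())
    for i in range(k):
        for j in range(i + 1, k):
            ok = sel & ~tracks[i].mask & ~tracks[j].mask
            m = int(ok.sum())
            if m < 3:
                raise ValueError(
                    f"fewer than 3 jointly unmasked windows for "
                    f"{tracks[i].sample_id} vs {tracks[j].sample_id}"
                )
            x, y = tracks[i].scores[ok], tracks[j].scores[ok]
            sx, sy = x.std(), y.std()
            rij = np.nan if sx == 0 or sy == 0 else float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = rij
            n[i, j] = n[j, i] = m
    return CorrelationMatrix([t.sample_id for t in tracks], grid.resolution, r, n)


def hcluster_samples(
    tracks: Sequence[WindowTrack],
    region: Interval | None = None,
    autosomes_only: bool = True,
    centered: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage clustering on distance 1 - Pearson r.

    Inputs are ordered by sample_id before linkage so tied merges are
    deterministic. With ``centered=False`` the uncentered correlation
    (cosine of raw scores) is used instead. Returns the scipy linkage
    matrix and the leaf order as sample ids.
    """
    tracks = sorted(tracks, key=lambda t: t.sample_id)
    cm = pearson_pairwise(tracks, autosomes_only=autosomes_only, region=region)
    if centered:
        sim = cm.r
    else:
        sel = _select_windows(tracks, autosomes_only, region)
        k = len(tracks)
        sim = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                ok = sel & ~tracks[i].mask & ~tracks[j].mask
                x, y = tracks[i].scores[ok], tracks[j].scores[ok]
                denom = np.sqrt((x * x).sum() * (y * y).sum())
                sim[i, j] = sim[j, i] = (x * y).sum() / denom if denom > 0 else np.nan
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    condensed = d[np.triu_indices(len(tracks), k=1)]
    Z = hierarchy.linkage(condensed, method="complete")
    order = [tracks[i].sample_id for i in hierarchy.leaves_list(Z)]
    return Z, order


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def _coverage_fn(feature: FeatureTrack):
    """Return covered(chrom, a, b): merged-feature bp inside [a, b)."""
    merged = intervals_by_chrom(merge_intervals(feature.intervals))
    prefix = {
        c: np.concatenate([[0], np.cumsum(arr[:, 1] - arr[:, 0])])
        for c, arr in merged.items()
    }

    def covered(chrom: str, a: int, b: int) -> float:
        arr = merged.get(chrom)
        if arr is None or len(arr) == 0 or b <= a:
            return 0.0
        starts, ends = arr[:, 0], arr[:, 1]
        i = int(np.searchsorted(ends, a, side="right"))
        j = int(np.searchsorted(starts, b, side="left"))
        if i >= j:
            return 0.0
        total = prefix[chrom][j] - prefix[chrom][i]
        total -= max(0, a - starts[i])
        total -= max(0, ends[j - 1] - b)
        return float(total)

    return covered


def boundary_metaprofile(
    domains: DomainSet,
    feature: FeatureTrack,
    flank: int,
    bin: int,
    genome=None,
) -> BoundaryProfile:
    """Average feature density in fixed bins around every domain boundary.

    Each domain contributes its 5' boundary as-is and its 3' boundary
    mirrored, so positive offsets always point into the domain. When a
    ``genome`` is given, bins falling outside the chromosome are excluded
    from that boundary's average (per-bin counts are tracked).
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    if not domains.domains:
        raise ValueError("no domain boundaries")
    covered = _coverage_fn(feature)
    lengths = genome.lengths if genome is not None else {}
    nb = 2 * (flank // bin)
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=np.int64)
    edges = np.arange(-flank, flank + 1, bin)

    def add_boundary(chrom: str, pos: int, inward: int, chrom_len: int) -> None:
        for k in range(nb):
            lo_off, hi_off = edges[k], edges[k + 1]
            if inward > 0:
                a, b = pos + lo_off, pos + hi_off
            else:
                a, b = pos - hi_off, pos - lo_off
            if a < 0 or b > chrom_len:
                continue
            sums[k] += covered(chrom, a, b) / bin
            counts[k] += 1

    for iv, _ in domains.domains:
        chrom_len = lengths.get(iv.chrom, 2**62)
        add_boundary(iv.chrom, iv.start, +1, chrom_len)
        add_boundary(iv.chrom, iv.end, -1, chrom_len)

    density = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2
    return BoundaryProfile(centers, density, n_boundaries=2 * len(domains.domains))
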