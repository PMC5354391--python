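"""Conserved-high / variable / conserved-low classification of 10 kb windows.

Every unmasked window is classified across the granulocyte, CD34+ and AML
panel. The per-window threshold is one standard deviation of the samples'
normalized scores at that window (sample standard deviation, n-1
denominator); a sample is 'high' when its score exceeds the threshold and
'low' otherwise. A window is conserved-low (GREEN) when at most 2 samples
are high with at most one high per category, conserved-high (RED)
symmetrically for 'low' calls, and variable (YELLOW) otherwise. On the Y
chromosome only male samples enter the threshold and the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import Interval
from .windowing import WindowGrid, WindowTrack

__all__ = ["ZoneMap", "classify_zones", "zone_fractions", "zones_to_bed",
           "RED", "YELLOW", "GREEN", "MASKED", "ZONE_NAMES"]

RED, YELLOW, GREEN, MASKED = 0, 1, 2, 3
ZONE_NAMES = ("RED", "YELLOW", "GREEN", "MASKED")

#: zone categories entering the classifier (K562 lines are excluded)
ZONE_CATEGORIES = ("granulocyte", "cd34", "aml")


@dataclass
class ZoneMap:
    grid: WindowGrid
    labels: np.ndarray  # int8 per window, one of RED/YELLOW/GREEN/MASKED
    sigma: np.ndarray  # per-window threshold actually used
    high: np.ndarray  # (n_samples, n_windows) bool high/low calls
    sample_ids: list[str]


def classify_zones(
    tracks: Sequence[WindowTrack],
    categories: Sequence[str],
    sexes: Sequence[str],
    sigma_rule: str = "per-window",
    max_outliers: int = 2,
    max_per_category: int = 1,
) -> ZoneMap:
    """Classify each window as RED / YELLOW / GREEN across the panel.

    ``categories`` and ``sexes`` align with ``tracks``. All tracks must be
    normalized and share one grid. ``sigma_rule`` selects the per-window
    sample standard deviation (default) or a single pooled "global" value
    computed over all samples' unmasked scores.
    """
    if not tracks:
        raise ValueError("no tracks")
    grid = tracks[0].grid
    for t in tracks:
        if not t.normalized:
            raise ValueError(f"track {t.sample_id} is not normalized")
        if not t.grid.compatible(grid):
            raise ValueError("tracks on different grids")
    categories = list(categories)
    sexes = list(sexes)
    present = set(categories)
    for cat in ZONE_CATEGORIES:
        if cat not in present:
            raise ValueError(f"category {cat!r} has zero samples")
    if sigma_rule not in ("per-window", "global"):
        raise ValueError(f"unknown sigma_rule {sigma_rule!r}")

    S = np.vstack([t.scores for t in tracks])  # (k, W)
    masks = np.vstack([t.mask for t in tracks])
    masked_any = masks.any(axis=0)

    male = np.array([s == "M" for s in sexes])
    y_win = grid.is_y_window()
    include = np.ones_like(S, dtype=bool)  # sample enters window's stats
    if male.any():
        include[:, y_win] = male[:, None]
    # if no male samples exist, Y windows fall back to the full panel

    k_eff = include.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(include, S, 0.0).sum(axis=0) / k_eff
        ss = (np.where(include, S - mean, 0.0) ** 2).sum(axis=0)
        sigma_w = np.sqrt(ss / np.maximum(k_eff - 1, 1))
    if sigma_rule == "global":
        pooled = np.concatenate([t.unmasked_scores() for t in tracks])
        sigma_w = np.full(grid.n_total, pooled.std(ddof=1))

    high = S > sigma_w  # strict: score > sigma; low iff score <= sigma
    low = ~high
    high &= include
    low &= include

    n_high = high.sum(axis=0)
    n_low = low.sum(axis=0)
    cat_arr = np.array(categories)
    per_cat_high_ok = np.ones(grid.n_total, dtype=bool)
    per_cat_low_ok = np.ones(grid.n_total, dtype=bool)
    for cat in ZONE_CATEGORIES:
        rows = cat_arr == cat
        per_cat_high_ok &= high[rows].sum(axis=0) <= max_per_category
        per_cat_low_ok &= low[rows].sum(axis=0) <= max_per_category

    green = (n_high <= max_outliers) & per_cat_high_ok
    red = (n_low <= max_outliers) & per_cat_low_ok

    labels = np.full(grid.n_total, YELLOW, dtype=np.int8)
    labels[green] = GREEN
    labels[red] = RED  # disjoint from GREEN whenever >=2 samples per category
    labels[masked_any] = MASKED
    sigma_w = np.where(masked_any, np.nan, sigma_w)
    return ZoneMap(grid, labels, sigma_w, high, [t.sample_id for t in tracks])


def zone_fractions(zonemap: ZoneMap) -> tuple[float, float, float]:
    """(RED, YELLOW, GREEN) percentages of unmasked (non-deadzone) bp."""
    eff = zonemap.grid.effective_length
    total = eff[zonemap.labels != MASKED].sum()
    if total == 0:
        raise ValueError("no unmasked windows")
    out = []
    for lab in (RED, YELLOW, GREEN):
        out.append(100.0 * eff[zonemap.labels == lab].sum() / total)
    return tuple(out)


def zones_to_bed(zonemap: ZoneMap) -> list[tuple[Interval, str]]:
    """Merge runs of equally-labeled adjacent windows into labeled intervals."""
    out: list[tuple[Interval, str]] = []
    grid = zonemap.grid
    r = grid.resolution
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        labs = zonemap.labels[sl]
        L = grid.genome.length(chrom)
        start_k = 0
        for k in range(1, len(labs) + 1):
            if k == len(labs) or labs[k] != labs[start_k]:
                if labs[start_k] != MASKED:
                    out.append(
                        (
                            Interval(chrom, start_k * r, min(k * r, L)),
                            ZONE_NAMES[labs[start_k]],
                        )
                    )
                start_k = k
    return out
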