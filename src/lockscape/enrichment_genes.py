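"""Fold enrichment of feature tracks inside window sets; gene extraction.

Enrichment is a plain density ratio: feature density (bp of coverage for
interval features, counts for point features) per non-deadzone bp inside
the window set, divided by the same density genome-wide over all unmasked
windows. No significance model is attached; ratios are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import FeatureTrack, Interval, intervals_by_chrom, merge_intervals
from .windowing import WindowTrack

__all__ = [
    "EnrichmentResult",
    "GeneSet",
    "fold_enrichment",
    "genes_in_dlocks",
    "gene_intersection_pct",
]


@dataclass
class EnrichmentResult:
    feature_id: str
    set_id: str
    fold: float
    set_bp: int
    genome_bp: int
    density_in_set: float
    density_genome: float


@dataclass
class GeneSet:
    set_id: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def fold_enrichment(
    window_set: np.ndarray,
    feature_density: WindowTrack,
    set_id: str = "set",
) -> EnrichmentResult:
    """Density ratio of a feature inside a boolean window set vs genome-wide.

    ``window_set`` is a boolean selector over the grid; masked windows are
    ignored on both sides, and bp are counted on non-deadzone lengths so
    the all-windows set has fold exactly 1.
    """
    grid = feature_density.grid
    unmasked = ~feature_density.mask
    sel = np.asarray(window_set, dtype=bool) & unmasked
    if not sel.any():
        raise ValueError("window set is empty (or fully masked)")
    eff = grid.effective_length
    set_bp = int(eff[sel].sum())
    genome_bp = int(eff[unmasked].sum())
    dens_genome = feature_density.scores[unmasked].sum() / genome_bp
    if dens_genome == 0:
        raise ValueError(f"feature absent: {feature_density.sample_id}")
    dens_set = feature_density.scores[sel].sum() / set_bp
    return EnrichmentResult(
        feature_id=feature_density.sample_id,
        set_id=set_id,
        fold=float(dens_set / dens_genome),
        set_bp=set_bp,
        genome_bp=genome_bp,
        density_in_set=float(dens_set),
        density_genome=float(dens_genome),
    )


def genes_in_dlocks(dlocks: Sequence, genes: FeatureTrack, set_id: str = "genes") -> GeneSet:
    """Genes whose body overlaps >= 1 bp of any of the given blocks.

    Half-open convention: a gene exactly abutting a block end has zero
    overlap and is excluded. A gene spanning several blocks counts once.
    """
    if genes.names is None:
        raise ValueError("gene track has no names")
    merged = intervals_by_chrom(
        merge_intervals([d.interval if hasattr(d, "interval") else d for d in dlocks])
    )
    hit: set[str] = set()
    for iv, name in zip(genes.intervals, genes.names):
        arr = merged.get(iv.chrom)
        if arr is None or len(arr) == 0:
            continue
        # rightmost merged block starting before the gene end
        j = int(np.searchsorted(arr[:, 0], iv.end, side="left")) - 1
        if j >= 0 and arr[j, 1] > iv.start:
            hit.add(name)
    return GeneSet(set_id, frozenset(hit))


def gene_intersection_pct(a: GeneSet, b: GeneSet) -> float:
    """Percentage of genes of ``a`` that also occur in ``b``."""
    if not a.genes:
        raise ValueError("first gene set is empty")
    return 100.0 * len(a.genes & b.genes) / len(a.genes)
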