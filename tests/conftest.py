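import math

import numpy as np
import pytest

from lockscape.genomic_io import DomainSet, Genome, Interval
from lockscape.windowing import WindowGrid, WindowTrack


@pytest.fixture
def toy_genome():
    return Genome((("chr1", 100_000), ("chr2", 55_000)))


def make_grid(n_windows: int, resolution: int = 10_000, chrom: str = "chr1") -> WindowGrid:
    """A single-chromosome grid of exactly n full windows."""
    genome = Genome(((chrom, n_windows * resolution),))
    return WindowGrid(genome, resolution)


def make_track(scores, sample_id="s", grid=None, normalized=True, mask=None):
    scores = np.asarray(scores, dtype=float)
    if grid is None:
        grid = make_grid(len(scores))
    if mask is None:
        mask = grid.mask.copy()
    return WindowTrack(sample_id, grid, scores, mask, normalized=normalized)


def nt_oracle(domains: DomainSet, genome: Genome, resolution: int, deadzones=()):
    """Per-nucleotide accumulation oracle for window scoring.

    Builds an explicit depth-per-nucleotide array, zeroes deadzone
    nucleotides, and sums each window — the literal definition against
    which the interval-arithmetic implementation is checked.
    """
    scores, eff = [], []
    for chrom, L in genome.chromosomes:
        cov = np.zeros(L)
        for iv, depth in domains.domains:
            if iv.chrom == chrom:
                cov[iv.start : iv.end] += depth
        alive = np.ones(L, dtype=bool)
        for dz in deadzones:
            if dz.chrom == chrom:
                alive[dz.start : dz.end] = False
        cov = cov * alive
        n = math.ceil(L / resolution)
        for k in range(n):
            sl = slice(k * resolution, min((k + 1) * resolution, L))
            scores.append(cov[sl].sum())
            eff.append(int(alive[sl].sum()))
    return np.array(scores), np.array(eff)


def random_domains(rng, genome: Genome, max_domains=30, sample_id="r") -> DomainSet:
    """Random non-overlapping scored domains over a genome."""
    doms = []
    for chrom, L in genome.chromosomes:
        pos = 0
        for _ in range(rng.integers(0, max_domains)):
            gap = int(rng.integers(0, max(2, L // 20)))
            length = int(rng.integers(1, max(2, L // 10)))
            if pos + gap + length > L:
                break
            start = pos + gap
            doms.append((Interval(chrom, start, start + length), float(rng.uniform(0, 5))))
            pos = start + length
    return DomainSet(sample_id, doms)


def random_intervals(rng, genome: Genome, n=10):
    out = []
    for _ in range(n):
        chrom, L = genome.chromosomes[rng.integers(len(genome.chromosomes))]
        s = int(rng.integers(0, L - 1))
        e = int(rng.integers(s + 1, min(L, s + max(2, L // 10)) + 1))
        out.append(Interval(chrom, s, e))
    return out
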