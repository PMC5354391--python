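"""Differential LOCK (dLOCK) calling between two sample categories.

The method works on normalized 10 kb window tracks:

1. *LOCK bases*: within the first-listed category, maximal contiguous runs
   of unmasked windows where at least one sample is positive, kept when
   every sample of the category is positive in at least 50% of the run.
2. *Sum Log Ratio* (SLR): per window inside a base, the mean over all
   (c1, c2) sample pairs of ``-log(s_i / s_j)`` with a small floor epsilon
   guarding zeros. On the X and Y chromosomes only same-sex pairs enter
   the mean.
3. *Segmentation*: each base is split into maximal runs of strictly
   same-sign SLR; zero-SLR windows terminate runs and join no block. A
   run's total score is the sum of its window SLRs and its sign is the
   sign of that total.
4. *Significance*: empirical quantile thresholds (linear-interpolation
   "type 7" sample quantiles) of all non-chrY total scores; a positive
   block is significant at level p when its score strictly exceeds Q(p), a
   negative one at level 1-p when its score falls strictly below Q(1-p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genomic_io import FeatureTrack, Genome, Interval, SampleSheet
from .windowing import WindowGrid, WindowTrack

__all__ = [
    "LockBase",
    "DLockScoreTrack",
    "DLock",
    "DLockSummary",
    "find_lock_bases",
    "slr_window_scores",
    "segment_dlocks",
    "rank_dlocks",
    "summarize_dlocks",
    "run_comparisons",
    "COMPARISONS",
    "DEFAULT_EPSILON",
    "DEFAULT_ALPHAS",
]

DEFAULT_EPSILON = 1e-6
DEFAULT_ALPHAS = (0.90, 0.95, 0.99)

#: The ten ordered comparison pairs (first-listed category supplies the bases).
COMPARISONS: tuple[tuple[str, str], ...] = (
    ("cd34", "granulocyte"),
    ("granulocyte", "cd34"),
    ("cd34", "aml_a"),
    ("aml_a", "cd34"),
    ("granulocyte", "aml_a"),
    ("aml_a", "granulocyte"),
    ("cd34", "aml_b"),
    ("aml_b", "cd34"),
    ("k562_unc0638", "k562_control"),
    ("k562_control", "k562_unc0638"),
)


@dataclass(frozen=True)
class LockBase:
    """A contiguous run of 10 kb windows [start_win, end_win) on one chromosome."""

    chrom: str
    start_win: int  # flat grid index, inclusive
    end_win: int  # flat grid index, exclusive

    @property
    def n_windows(self) -> int:
        return self.end_win - self.start_win


@dataclass
class DLockScoreTrack:
    pair: tuple[str, str]
    grid: WindowGrid
    bases: list[LockBase]
    slr: np.ndarray  # per window; NaN outside bases or where undefined
    n_pairs: np.ndarray  # int per window, pairwise terms used


@dataclass
class DLock:
    interval: Interval
    start_win: int
    end_win: int
    total_score: float
    n_windows: int
    pair: tuple[str, str]
    flags: dict[float, bool] = field(default_factory=dict)

    @property
    def sign(self) -> int:
        return 1 if self.total_score > 0 else -1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def name(self) -> str:
        return f"{self.pair[0]}_gt_{self.pair[1]}"


@dataclass
class DLockSummary:
    alpha: float
    pct_genome: float
    avg_size_bp: float
    n_dlocks: int
    n_genes: int
    gene_density_ratio: float


def find_lock_bases(tracks: Sequence[WindowTrack]) -> list[LockBase]:
    """LOCK bases of one category.

    Candidate runs are maximal stretches of unmasked windows where at
    least one sample has a positive score; a candidate is kept iff every
    sample is positive in >= 50% of the run's windows.
    """
    if not tracks:
        raise ValueError("no tracks")
    grid = tracks[0].grid
    S = np.vstack([t.scores for t in tracks])
    mask_any = np.logical_or.reduce([t.mask for t in tracks])
    pos = S > 0
    candidate = ~mask_any & pos.any(axis=0)

    bases: list[LockBase] = []
    for chrom in grid.genome.names:
        sl = grid.chrom_slice(chrom)
        c = candidate[sl]
        o = sl.start
        i = 0
        n = len(c)
        while i < n:
            if not c[i]:
                i += 1
                continue
            j = i
            while j < n and c[j]:
                j += 1
            run = slice(o + i, o + j)
            frac = pos[:, run].mean(axis=1)
            if (frac >= 0.5).all():
                bases.append(LockBase(chrom, o + i, o + j))
            i = j
    return bases


def slr_window_scores(
    c1_tracks: Sequence[WindowTrack],
    c2_tracks: Sequence[WindowTrack],
    bases: Sequence[LockBase],
    epsilon: float = DEFAULT_EPSILON,
    c1_sexes: Sequence[str] | None = None,
    c2_sexes: Sequence[str] | None = None,
) -> DLockScoreTrack:
    """Mean pairwise negative log ratio per window over the given bases.

    ``SLR(w) = (1/N) sum_{i in c1, j in c2} -log(max(s_i, eps)/max(s_j, eps))``
    with the natural log. On X/Y windows only same-sex (i, j) pairs are
    used; if none exists those windows are NaN (with a warning) and are
    skipped by segmentation.
    """
    if not c1_tracks or not c2_tracks:
        raise ValueError("both categories must be non-empty")
    grid = c1_tracks[0].grid
    L1 = np.log(np.maximum(np.vstack([t.scores for t in c1_tracks]), epsilon))
    L2 = np.log(np.maximum(np.vstack([t.scores for t in c2_tracks]), epsilon))
    n1, n2 = len(c1_tracks), len(c2_tracks)

    # autosomal SLR: mean_j log s_j - mean_i log s_i
    slr_all = L2.mean(axis=0) - L1.mean(axis=0)
    n_pairs = np.full(grid.n_total, n1 * n2, dtype=np.int64)

    sex_win = grid.is_sex_window()
    if sex_win.any() and (c1_sexes is not None or c2_sexes is not None):
        if c1_sexes is None or c2_sexes is None:
            raise ValueError("sexes must be given for both categories or neither")
        s1 = np.array(list(c1_sexes))
        s2 = np.array(list(c2_sexes))
        num = np.zeros(grid.n_total)
        N = 0
        for sex in ("M", "F"):
            r1, r2 = s1 == sex, s2 == sex
            m1, m2 = int(r1.sum()), int(r2.sum())
            if m1 == 0 or m2 == 0:
                continue
            # sum over same-sex pairs of (L2_j - L1_i)
            num += m1 * L2[r2].sum(axis=0) - m2 * L1[r1].sum(axis=0)
            N += m1 * m2
        if N == 0:
            warnings.warn(
                f"no same-sex sample pair for {len(c1_tracks)}x{len(c2_tracks)} "
                "comparison; X/Y windows undefined",
                stacklevel=2,
            )
            slr_all = np.where(sex_win, np.nan, slr_all)
            n_pairs[sex_win] = 0
        else:
            slr_all = np.where(sex_win, num / N, slr_all)
            n_pairs[sex_win] = N

    slr = np.full(grid.n_total, np.nan)
    for b in bases:
        slr[b.start_win : b.end_win] = slr_all[b.start_win : b.end_win]
    return DLockScoreTrack((_cat_of(c1_tracks), _cat_of(c2_tracks)), grid, list(bases), slr, n_pairs)


def _cat_of(tracks: Sequence[WindowTrack]) -> str:
    # comparison labels are attached by run_comparisons; fall back to ids
    return getattr(tracks[0], "category", tracks[0].sample_id)


def segment_dlocks(score_track: DLockScoreTrack) -> list[DLock]:
    """Split each base into maximal strictly-same-sign SLR runs.

    Windows with SLR exactly 0 (or undefined) terminate runs and belong
    to no block.
    """
    grid = score_track.grid
    r = grid.resolution
    out: list[DLock] = []
    for base in score_track.bases:
        vals = score_track.slr[base.start_win : base.end_win]
        signs = np.zeros(len(vals), dtype=np.int8)
        signs[vals > 0] = 1
        signs[vals < 0] = -1  # NaN compares False on both: stays 0
        i = 0
        while i < len(signs):
            if signs[i] == 0:
                i += 1
                continue
            j = i
            while j < len(signs) and signs[j] == signs[i]:
                j += 1
            w0, w1 = base.start_win + i, base.start_win + j
            iv0 = grid.window_interval(w0)
            iv1 = grid.window_interval(w1 - 1)
            out.append(
                DLock(
                    interval=Interval(base.chrom, iv0.start, iv1.end),
                    start_win=w0,
                    end_win=w1,
                    total_score=float(vals[i:j].sum()),
                    n_windows=j - i,
                    pair=score_track.pair,
                )
            )
            i = j
    return out


def rank_dlocks(
    dlocks: Sequence[DLock],
    alpha_levels: Sequence[float] = DEFAULT_ALPHAS,
    grid: WindowGrid | None = None,
    genome: Genome | None = None,
) -> list[DLock]:
    """Attach empirical-quantile significance flags to each block.

    Thresholds are type-7 sample quantiles of the total scores of all
    non-chrY blocks of this comparison; chrY blocks inherit them. A
    positive block passes level p iff score > Q(p); a negative block
    passes iff score < Q(1-p). Flags are stored under the upper level
    (0.90 means "top/bottom 10%").
    """
    dlocks = list(dlocks)
    if not dlocks:
        raise ValueError("no dLOCKs to rank")
    gen = genome or (grid.genome if grid is not None else None)

    def on_y(d: DLock) -> bool:
        if gen is not None:
            return gen.is_y(d.chrom)
        return d.chrom.upper().endswith("Y")

    ref = np.array([d.total_score for d in dlocks if not on_y(d)])
    if ref.size < 2:
        raise ValueError("need at least two non-chrY dLOCKs for quantiles")
    for d in dlocks:
        d.flags = {}
        for p in alpha_levels:
            q_hi = float(np.quantile(ref, p))  # numpy default = type 7
            q_lo = float(np.quantile(ref, 1.0 - p))
            if d.sign > 0:
                d.flags[p] = d.total_score > q_hi
            else:
                d.flags[p] = d.total_score < q_lo
    return dlocks


def summarize_dlocks(
    dlocks: Sequence[DLock],
    genes: FeatureTrack,
    genome: Genome,
    alpha: float = float("nan"),
) -> DLockSummary:
    """Table-style summary of a set of (already filtered) blocks."""
    from .enrichment_genes import genes_in_dlocks

    total_bp = sum(d.length for d in dlocks)
    genome_bp = genome.total_bp
    if not dlocks:
        return DLockSummary(alpha, 0.0, 0.0, 0, 0, 0.0)
    gene_set = genes_in_dlocks(dlocks, genes) if genes.names else None
    n_genes = len(gene_set.genes) if gene_set else 0
    dens_in = n_genes / total_bp if total_bp else 0.0
    dens_gen = len(genes) / genome_bp
    return DLockSummary(
        alpha=alpha,
        pct_genome=100.0 * total_bp / genome_bp,
        avg_size_bp=total_bp / len(dlocks),
        n_dlocks=len(dlocks),
        n_genes=n_genes,
        gene_density_ratio=dens_in / dens_gen if dens_gen > 0 else float("nan"),
    )


@dataclass
class ComparisonResult:
    pair: tuple[str, str]
    bases: list[LockBase]
    score_track: DLockScoreTrack
    dlocks: list[DLock]


def run_comparisons(
    tracks_by_group: dict[str, list[WindowTrack]],
    sexes_by_group: dict[str, list[str]] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    alpha_levels: Sequence[float] = DEFAULT_ALPHAS,
    comparisons: Sequence[tuple[str, str]] = COMPARISONS,
) -> dict[str, ComparisonResult]:
    """Run every ordered category comparison that has samples on both sides.

    ``tracks_by_group`` keys are comparison-group names (category names,
    with AML split into ``aml_a`` / ``aml_b``). Missing groups cause their
    comparisons to be skipped with a warning. Output order follows the
    canonical comparison list.
    """
    out: dict[str, ComparisonResult] = {}
    for c1, c2 in comparisons:
        if not tracks_by_group.get(c1) or not tracks_by_group.get(c2):
            warnings.warn(f"skipping comparison {c1} vs {c2}: missing samples", stacklevel=2)
            continue
        t1, t2 = tracks_by_group[c1], tracks_by_group[c2]
        bases = find_lock_bases(t1)
        kw = {}
        if sexes_by_group is not None:
            kw = dict(c1_sexes=sexes_by_group[c1], c2_sexes=sexes_by_group[c2])
        st = slr_window_scores(t1, t2, bases, epsilon=epsilon, **kw)
        st.pair = (c1, c2)
        dl = segment_dlocks(st)
        for d in dl:
            d.pair = (c1, c2)
        if dl:
            try:
                dl = rank_dlocks(dl, alpha_levels, grid=t1[0].grid)
            except ValueError:
                warnings.warn(f"{c1} vs {c2}: too few blocks for quantiles", stacklevel=2)
        out[f"{c1}_gt_{c2}"] = ComparisonResult((c1, c2), bases, st, dl)
    return out
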