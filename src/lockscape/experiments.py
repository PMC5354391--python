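"""Seeded end-to-end simulation experiments on the synthetic generator.

Each trial runs the actual pipeline — simulate domain files, score 10 kb
windows, normalize, call LOCK bases, score and segment differential
blocks, rank by empirical quantiles — and measures recovery of the
planted structure. These drive the calibration and power checks and the
summary numbers reported by the acceptance script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .correlation_clustering import feature_density_track
from .dlocks import (
    DEFAULT_EPSILON,
    find_lock_bases,
    rank_dlocks,
    segment_dlocks,
    slr_window_scores,
)
from .enrichment_genes import fold_enrichment
from .genomic_io import Interval
from .synthetic_data import FeatureSpec, PlantedBlock, SimConfig, simulate_domains, simulate_features
from .windowing import WindowGrid, normalize_track, score_windows
from .zones import RED, classify_zones, zone_fractions

__all__ = [
    "BlockTrial",
    "planted_block_trial",
    "recovery_rate",
    "enrichment_trial",
    "zone_recovery_trial",
]


@dataclass
class BlockTrial:
    recovered: bool
    mean_slr: float
    n_dlocks: int
    flagged_fraction: float  # fraction of blocks significant at `alpha`
    block: Interval


def planted_block_trial(
    seed: int,
    delta: float = 1.0,
    sigma: float = 0.25,
    n_per_cat: int = 3,
    block_len: int = 500_000,
    chrom_len: int = 200_000_000,
    alpha: float = 0.99,
    null: bool = False,
    epsilon: float = DEFAULT_EPSILON,
) -> BlockTrial:
    """One seeded differential-block experiment on a two-category panel.

    A single block is planted with log-fold ``delta`` in the ``aml_a``
    category against a ``cd34`` baseline of equal size. Recovery means an
    alpha-significant positive block overlapping at least half of the
    planted region. Under ``null`` the planted block gets delta = 0 and
    its length is drawn from the background LOCK length distribution, so
    it is exchangeable with every other LOCK and significance at level p
    should fire at the nominal 1 - p tail rate.
    """
    rng = np.random.default_rng([seed, 11])
    cfg0 = SimConfig()  # defaults carry the LOCK geometry
    if null:
        delta = 0.0
        block_len = int(
            round(
                math.exp(rng.uniform(math.log(cfg0.lock_min), math.log(cfg0.lock_max)))
            )
        )
    start = int(rng.integers(int(0.5 * chrom_len), int(0.8 * chrom_len)))
    block = PlantedBlock("planted", "chr1", start, start + block_len, "aml_a", delta)

    samples = tuple(
        (f"{grp}{i + 1}", grp, "MF"[i % 2], f"{grp}{i + 1}")
        for grp in ("cd34", "aml_a")
        for i in range(n_per_cat)
    )
    config = SimConfig(
        chrom_lengths=(chrom_len,),
        samples=samples,
        sigma=sigma,
        diff_blocks=(block,),
        deadzone_fraction=0.0,
        seed=seed,
    )
    domain_sets, _truth = simulate_domains(config)
    genome = config.genome()
    grid = WindowGrid(genome, 10_000)
    tracks = {
        sid: normalize_track(score_windows(ds, grid)) for sid, ds in domain_sets.items()
    }
    c1 = [tracks[s[0]] for s in samples if s[1] == "cd34"]
    c2 = [tracks[s[0]] for s in samples if s[1] == "aml_a"]

    bases = find_lock_bases(c1)
    st = slr_window_scores(c1, c2, bases, epsilon=epsilon)
    dlocks = segment_dlocks(st)
    dlocks = rank_dlocks(dlocks, (alpha,), grid=grid)

    recovered = False
    for d in dlocks:
        if d.sign > 0 and d.flags.get(alpha):
            ov = min(d.interval.end, block.end) - max(d.interval.start, block.start)
            if ov >= 0.5 * block_len:
                recovered = True
                break
    # mean SLR over windows fully inside the planted block
    r = grid.resolution
    w0 = -(-block.start // r)  # first window fully inside
    w1 = block.end // r
    inside = st.slr[w0:w1]
    inside = inside[~np.isnan(inside)]
    mean_slr = float(inside.mean()) if inside.size else float("nan")
    flagged = sum(1 for d in dlocks if d.flags.get(alpha)) / max(len(dlocks), 1)
    return BlockTrial(recovered, mean_slr, len(dlocks), flagged, block.interval)


def recovery_rate(n_seeds: int, seed0: int = 0, **kwargs) -> tuple[float, np.ndarray]:
    """Fraction of seeds recovering the planted block, plus per-seed mean SLR."""
    hits = 0
    slrs = np.empty(n_seeds)
    for k in range(n_seeds):
        t = planted_block_trial(seed0 + k, **kwargs)
        hits += t.recovered
        slrs[k] = t.mean_slr
    return hits / n_seeds, slrs


def enrichment_trial(
    seed: int,
    k: float = 3.0,
    chrom_len: int = 50_000_000,
    block_len: int = 500_000,
    intensity: float = 5e-5,
) -> tuple[float, float]:
    """Estimate fold enrichment of a planted point feature.

    Returns (estimated fold, expected fold). The expectation accounts for
    the enriched block inflating the genome-wide average density:
    ``k / (1 + f_b (k - 1))`` with f_b the block's genome fraction.
    """
    start = chrom_len // 2
    block = PlantedBlock("fb", "chr1", start, start + block_len, None, 0.0)
    config = SimConfig(
        chrom_lengths=(chrom_len,),
        samples=(("s1", "cd34", "F", "s1"),),
        diff_blocks=(block,),
        deadzone_fraction=0.0,
        features=(
            FeatureSpec("snv", "point", intensity=intensity, enrichment=k, block_id="fb"),
        ),
        seed=seed,
    )
    _ds, truth = simulate_domains(config)
    feats, truth = simulate_features(config, truth)
    genome = config.genome()
    grid = WindowGrid(genome, 10_000)
    dens = feature_density_track(feats["snv"], grid)
    sel = np.zeros(grid.n_total, dtype=bool)
    sel[block.start // grid.resolution : block.end // grid.resolution] = True
    res = fold_enrichment(sel, dens, set_id="planted")
    fb = block_len / chrom_len
    expected = k / (1.0 + fb * (k - 1.0))
    return res.fold, expected


def zone_recovery_trial(seed: int, sigma: float = 0.25) -> tuple[float, tuple[float, float, float]]:
    """Classify zones on a simulated three-category panel.

    Returns (fraction of planted conserved-high bp labeled RED, overall
    zone fractions).
    """
    from .synthetic_data import small_config

    config = small_config(seed)
    config = SimConfig(**{**config.__dict__, "sigma": sigma})
    domain_sets, truth = simulate_domains(config)
    genome = config.genome()
    grid = WindowGrid(genome, 10_000, deadzones=truth.deadzones)
    sheet = {s[0]: s for s in config.samples}
    tracks, cats, sexes = [], [], []
    for sid, ds in domain_sets.items():
        tracks.append(normalize_track(score_windows(ds, grid, deadzones=truth.deadzones)))
        grp = sheet[sid][1]
        cats.append("aml" if grp.startswith("aml") else grp)
        sexes.append(sheet[sid][2])
    zm = classify_zones(tracks, cats, sexes)

    red_bp = labeled_bp = 0
    r = grid.resolution
    for b in truth.red_blocks:
        o = grid.offsets[b.chrom]
        w0 = -(-b.start // r)
        w1 = b.end // r
        for w in range(o + w0, o + w1):
            if zm.labels[w] == 3:  # MASKED windows don't count either way
                continue
            labeled_bp += grid.effective_length[w]
            if zm.labels[w] == RED:
                red_bp += grid.effective_length[w]
    frac = red_bp / labeled_bp if labeled_bp else float("nan")
    return frac, zone_fractions(zm)
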