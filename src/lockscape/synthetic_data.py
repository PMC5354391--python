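"""Synthetic domain-level data with planted, recoverable structure.

The generator emulates the statistical structure the downstream methods
assume, at the level of the pipeline's actual input (scored domain
intervals), not reads:

* a LOCK skeleton shared by all samples — domains drawn with log-uniform
  lengths and exponential gaps to hit a target genome fraction;
* multiplicative lognormal depth noise, one draw per (sample, domain),
  matching the log-ratio statistic used by differential calling;
* planted conserved-high blocks (every sample elevated), conserved-low
  gaps (no domains), and differential blocks where one category's depth
  is multiplied by exp(delta);
* deadzones and feature tracks placed by a Poisson process with a k-fold
  intensity step inside a named planted block.

Everything is reproducible from the config seed, and the emitted
``SimTruth`` records the planted structure for recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomic_io import (
    DomainSet,
    FeatureTrack,
    Genome,
    Interval,
    SampleRecord,
    SampleSheet,
    merge_intervals,
    subtract_intervals,
)

__all__ = [
    "FeatureSpec",
    "PlantedBlock",
    "SimConfig",
    "SimTruth",
    "simulate_domains",
    "simulate_features",
    "make_fixture",
    "tiny_config",
    "small_config",
]


@dataclass(frozen=True)
class FeatureSpec:
    feature_id: str
    kind: str = "interval"  # "interval" | "point"
    intensity: float = 2e-5  # expected features per bp outside the enriched block
    enrichment: float = 1.0  # k: intensity multiplier inside block_id
    block_id: str | None = None
    length: int = 5_000  # interval length (ignored for points)

    def __post_init__(self) -> None:
        if self.enrichment < 0:
            raise ValueError("enrichment factor must be >= 0")


@dataclass(frozen=True)
class PlantedBlock:
    block_id: str
    chrom: str
    start: int
    end: int
    category: str | None = None  # comparison group whose depth is scaled
    delta: float = 0.0  # log-fold applied to that category

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class SimConfig:
    chrom_lengths: tuple[int, ...] = (20_000_000,)
    #: (sample_id, group, sex, replicate_group); group is a comparison
    #: group name: granulocyte, cd34, aml_a, aml_b, k562_control, k562_unc0638
    samples: tuple[tuple[str, str, str, str], ...] = ()
    chrom_names: tuple[str, ...] | None = None
    lock_fraction: float = 0.4
    lock_min: int = 50_000
    lock_max: int = 500_000
    mu: float = 2.0  # base read-count/nt of a background LOCK
    mu_high: float = 6.0  # depth of planted conserved-high blocks
    sigma: float = 0.25  # lognormal depth noise, per (sample, domain)
    red_blocks: tuple[PlantedBlock, ...] = ()
    green_gaps: tuple[Interval, ...] = ()
    diff_blocks: tuple[PlantedBlock, ...] = ()
    deadzone_fraction: float = 0.02
    deadzone_length: int = 2_000
    features: tuple[FeatureSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.lock_fraction <= 1):
            raise ValueError("lock_fraction must be in [0, 1]")
        if not (0 <= self.deadzone_fraction <= 1):
            raise ValueError("deadzone_fraction must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def genome(self) -> Genome:
        names = self.chrom_names or tuple(
            f"chr{i + 1}" for i in range(len(self.chrom_lengths))
        )
        return Genome(tuple(zip(names, self.chrom_lengths)))

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, grp, _sex, _rg in self.samples:
            out.setdefault(grp, []).append(sid)
        return out


@dataclass
class SimTruth:
    """Planted structure emitted alongside the simulated data."""

    locks: list[Interval]
    lock_tag: list[str]  # "background" | "red:<id>" | "diff:<id>"
    red_blocks: list[PlantedBlock]
    green_gaps: list[Interval]
    diff_blocks: list[PlantedBlock]
    deadzones: list[Interval]
    expected_depth: dict[str, list[float]]  # per sample, per lock, noise-free
    feature_enrichments: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        def iv(x: Interval) -> list:
            return [x.chrom, int(x.start), int(x.end)]

        def pb(b: PlantedBlock) -> dict:
            return {
                "block_id": b.block_id,
                "chrom": b.chrom,
                "start": int(b.start),
                "end": int(b.end),
                "category": b.category,
                "delta": float(b.delta),
            }

        payload = {
            "locks": [iv(x) for x in self.locks],
            "lock_tag": self.lock_tag,
            "red_blocks": [pb(b) for b in self.red_blocks],
            "green_gaps": [iv(x) for x in self.green_gaps],
            "diff_blocks": [pb(b) for b in self.diff_blocks],
            "deadzones": [iv(x) for x in self.deadzones],
            "expected_depth": {
                k: [float(v) for v in vs] for k, vs in self.expected_depth.items()
            },
            "feature_enrichments": self.feature_enrichments,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            locks=[Interval(*x) for x in d["locks"]],
            lock_tag=list(d["lock_tag"]),
            red_blocks=[PlantedBlock(**b) for b in d["red_blocks"]],
            green_gaps=[Interval(*x) for x in d["green_gaps"]],
            diff_blocks=[PlantedBlock(**b) for b in d["diff_blocks"]],
            deadzones=[Interval(*x) for x in d["deadzones"]],
            expected_depth=d["expected_depth"],
            feature_enrichments=dict(d["feature_enrichments"]),
        )


def _mean_loguniform(lo: float, hi: float) -> float:
    if hi == lo:
        return float(lo)
    return (hi - lo) / math.log(hi / lo)


def _build_skeleton(config: SimConfig, rng: np.random.Generator):
    """Draw the shared LOCK intervals: planted blocks first, then fill."""
    genome = config.genome()
    planted: list[tuple[Interval, str]] = []
    for b in config.red_blocks:
        planted.append((b.interval, f"red:{b.block_id}"))
    for b in config.diff_blocks:
        planted.append((b.interval, f"diff:{b.block_id}"))
    for iv, _ in planted:
        genome.validate_interval(iv)
    for iv in config.green_gaps:
        genome.validate_interval(iv)
    forbidden = [iv for iv, _ in planted] + list(config.green_gaps)
    if sum(iv.length for iv in forbidden) != sum(
        iv.length for iv in merge_intervals(forbidden)
    ):
        raise ValueError("planted intervals must be disjoint")

    locks: list[tuple[Interval, str]] = list(planted)
    mean_lock = _mean_loguniform(config.lock_min, config.lock_max)
    f = config.lock_fraction
    mean_gap = mean_lock * (1.0 / f - 1.0) if f > 0 else None
    if mean_gap is not None:
        whole = [Interval(c, 0, L) for c, L in genome.chromosomes]
        for seg in subtract_intervals(whole, forbidden):
            pos = seg.start
            while True:
                pos += max(1, int(round(rng.exponential(mean_gap))))
                L = int(
                    round(
                        math.exp(
                            rng.uniform(
                                math.log(config.lock_min), math.log(config.lock_max)
                            )
                        )
                    )
                )
                if pos + L > seg.end:
                    break
                locks.append((Interval(seg.chrom, pos, pos + L), "background"))
                pos += L
    locks.sort(key=lambda t: (t[0].chrom, t[0].start))
    return locks


def _draw_deadzones(config: SimConfig, rng: np.random.Generator) -> list[Interval]:
    out: list[Interval] = []
    genome = config.genome()
    for chrom, L in genome.chromosomes:
        n = int(round(L * config.deadzone_fraction / config.deadzone_length))
        if n == 0:
            continue
        starts = np.sort(rng.integers(0, max(1, L - config.deadzone_length), size=n))
        out.extend(
            Interval(chrom, int(s), int(s) + config.deadzone_length) for s in starts
        )
    return merge_intervals(out)


def simulate_domains(
    config: SimConfig,
) -> tuple[dict[str, DomainSet], SimTruth]:
    """Generate one DomainSet per sample plus the planted ground truth.

    The LOCK skeleton and deadzones are drawn once; each sample then gets
    an independent lognormal depth per skeleton domain. Outside LOCKs no
    domain is emitted (depth 0).
    """
    if not config.samples:
        raise ValueError("config has no samples")
    rng = np.random.default_rng(config.seed)
    locks = _build_skeleton(config, rng)
    deadzones = _draw_deadzones(config, rng)

    diff_by_tag = {f"diff:{b.block_id}": b for b in config.diff_blocks}
    n_locks = len(locks)
    sample_ids = [s[0] for s in config.samples]
    groups = [s[1] for s in config.samples]
    Z = rng.standard_normal((len(sample_ids), n_locks))

    base_mu = np.array(
        [config.mu_high if tag.startswith("red:") else config.mu for _, tag in locks]
    )
    expected: dict[str, list[float]] = {}
    domain_sets: dict[str, DomainSet] = {}
    for si, (sid, grp) in enumerate(zip(sample_ids, groups)):
        mu_s = base_mu.copy()
        for li, (_, tag) in enumerate(locks):
            b = diff_by_tag.get(tag)
            if b is not None and b.category == grp:
                mu_s[li] *= math.exp(b.delta)
        depths = mu_s * np.exp(config.sigma * Z[si])
        expected[sid] = [float(v) for v in mu_s]
        domain_sets[sid] = DomainSet(
            sid, [(iv, float(d)) for (iv, _), d in zip(locks, depths)]
        )

    truth = SimTruth(
        locks=[iv for iv, _ in locks],
        lock_tag=[tag for _, tag in locks],
        red_blocks=list(config.red_blocks),
        green_gaps=list(config.green_gaps),
        diff_blocks=list(config.diff_blocks),
        deadzones=deadzones,
        expected_depth=expected,
    )
    return domain_sets, truth


def simulate_features(
    config: SimConfig, truth: SimTruth
) -> tuple[dict[str, FeatureTrack], SimTruth]:
    """Place feature tracks by a Poisson process, k-fold denser in a block."""
    rng = np.random.default_rng([config.seed, 7])
    genome = config.genome()
    blocks = {b.block_id: b.interval for b in truth.red_blocks + truth.diff_blocks}
    out: dict[str, FeatureTrack] = {}
    for spec in config.features:
        if spec.enrichment < 0:
            raise ValueError("enrichment factor must be >= 0")
        intervals: list[Interval] = []
        names: list[str] = []
        counter = 0
        block = blocks.get(spec.block_id) if spec.block_id else None
        for chrom, L in genome.chromosomes:
            regions: list[tuple[int, int, float]] = []
            if block is not None and block.chrom == chrom:
                regions.append((block.start, block.end, spec.intensity * spec.enrichment))
                if block.start > 0:
                    regions.append((0, block.start, spec.intensity))
                if block.end < L:
                    regions.append((block.end, L, spec.intensity))
            else:
                regions.append((0, L, spec.intensity))
            for a, b, lam in sorted(regions):
                n = rng.poisson(lam * (b - a))
                if n == 0:
                    continue
                starts = np.sort(rng.integers(a, b, size=n))
                width = 1 if spec.kind == "point" else spec.length
                for s in starts:
                    e = min(int(s) + width, L)
                    intervals.append(Interval(chrom, int(s), e))
                    names.append(f"{spec.feature_id}_{counter}")
                    counter += 1
        out[spec.feature_id] = FeatureTrack(
            spec.feature_id, intervals, kind=spec.kind, names=names
        )
        truth.feature_enrichments[spec.feature_id] = spec.enrichment
    return out, truth


# ---------------------------------------------------------------------------
# canned configurations / on-disk fixtures


def _panel(groups: dict[str, int], sexes: str = "MF") -> tuple[tuple[str, str, str, str], ...]:
    out = []
    for grp, n in groups.items():
        for i in range(n):
            sid = f"{grp}{i + 1}"
            out.append((sid, grp, sexes[i % len(sexes)], sid))
    return tuple(out)


def tiny_config(seed: int = 0) -> SimConfig:
    """1 chromosome x 2 Mb, 2 samples in each of three categories."""
    return SimConfig(
        chrom_lengths=(2_000_000,),
        samples=_panel({"granulocyte": 2, "cd34": 2, "aml_a": 2}),
        lock_fraction=0.4,
        lock_min=20_000,
        lock_max=100_000,
        red_blocks=(PlantedBlock("red1", "chr1", 100_000, 200_000),),
        green_gaps=(Interval("chr1", 300_000, 400_000),),
        diff_blocks=(
            PlantedBlock("dblock1", "chr1", 1_000_000, 1_250_000, "aml_a", 1.0),
        ),
        deadzone_fraction=0.01,
        deadzone_length=1_000,
        features=(
            FeatureSpec("genes", "interval", intensity=2e-5, length=5_000),
            FeatureSpec("snv", "point", intensity=5e-5, enrichment=3.0, block_id="dblock1"),
        ),
        seed=seed,
    )


def small_config(seed: int = 0) -> SimConfig:
    """3 chromosomes x 20 Mb, 3 samples per category."""
    return SimConfig(
        chrom_lengths=(20_000_000, 20_000_000, 20_000_000),
        samples=_panel({"granulocyte": 3, "cd34": 3, "aml_a": 3}),
        red_blocks=(PlantedBlock("red1", "chr1", 2_000_000, 2_500_000),),
        green_gaps=(Interval("chr2", 5_000_000, 6_000_000),),
        diff_blocks=(
            PlantedBlock("dblock1", "chr3", 10_000_000, 10_500_000, "aml_a", 1.0),
        ),
        features=(
            FeatureSpec("genes", "interval", intensity=2e-5, length=20_000),
            FeatureSpec("snv", "point", intensity=2e-5, enrichment=3.0, block_id="dblock1"),
        ),
        seed=seed,
    )


GROUP_TO_CATEGORY = {
    "granulocyte": ("granulocyte", "none"),
    "cd34": ("cd34", "none"),
    "aml_a": ("aml", "A"),
    "aml_b": ("aml", "B"),
    "k562_control": ("k562_control", "none"),
    "k562_unc0638": ("k562_unc0638", "none"),
}


def make_fixture(
    outdir: str | os.PathLike, size: str = "tiny", seed: int = 0
) -> Path:
    """Write a complete on-disk bundle: domain BEDs, sheet, deadzones,
    features, truth and a pipeline config. Returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = {"tiny": tiny_config, "small": small_config}[size](seed)
    genome = config.genome()
    domain_sets, truth = simulate_domains(config)
    features, truth = simulate_features(config, truth)

    genome.to_file(out / "chrom.sizes")
    with open(out / "deadzones.bed", "w") as fh:
        for iv in truth.deadzones:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    records = []
    for sid, grp, sex, rg in config.samples:
        fname = f"{sid}.rsegout.bed"
        with open(out / fname, "w") as fh:
            for k, (iv, depth) in enumerate(domain_sets[sid].domains):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tdomain{k}\t{depth:.6f}\n")
        category, cluster = GROUP_TO_CATEGORY[grp]
        records.append(
            SampleRecord(sid, category, cluster, sex, "synthetic", rg, fname)
        )
    SampleSheet(records).to_file(out / "samples.tsv")

    fdir = out / "features"
    fdir.mkdir(exist_ok=True)
    for fid, track in features.items():
        with open(fdir / f"{fid}.bed", "w") as fh:
            for iv, name in zip(track.intervals, track.names or [""] * len(track)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")

    truth.to_json(out / "truth.json")

    cfg_lines = [
        f"genome: chrom.sizes",
        f"deadzones: deadzones.bed",
        f"sample_sheet: samples.tsv",
        f"features_dir: features",
        f"out_dir: results",
        f"resolutions: [10000, 50000]",
        f"alphas: [0.9, 0.95, 0.99]",
        f"epsilon: 1.0e-6",
        f"sigma_rule: per-window",
        f"score_column: 5",
        f"autosomes_only_correlations: false",
        f"double_male_xy: false",
        f"seed: {seed}",
    ]
    (out / "config.yaml").write_text("\n".join(cfg_lines) + "\n")
    return out
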