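"""Stage logic behind the command-line interface.

Stages hand data to each other through window-matrix TSVs (one per
resolution) in the output directory, so any stage can be re-run in
isolation and every intermediate is inspectable. A manifest records
input hashes, the config and row counts; outputs contain no timestamps,
so re-running a stage with unchanged inputs reproduces files byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation_clustering import (
    feature_density_track,
    hcluster_samples,
    linkage_to_newick,
    pearson_pairwise,
)
from .dlocks import ComparisonResult, run_comparisons, summarize_dlocks
from .enrichment_genes import fold_enrichment
from .genomic_io import (
    Genome,
    Interval,
    SampleSheet,
    read_interval_bed,
    read_sample_sheet,
    read_scored_bed,
    write_bed,
    write_bedgraph,
)
from .windowing import WindowGrid, WindowTrack, average_replicates, coarsen, normalize_track, score_windows
from .zones import MASKED, RED, YELLOW, GREEN, classify_zones, zone_fractions, zones_to_bed

log = logging.getLogger("lockscape")

_CONFIG_KEYS = {
    "genome", "deadzones", "sample_sheet", "features_dir", "out_dir",
    "resolutions", "alphas", "epsilon", "sigma_rule", "score_column",
    "autosomes_only_correlations", "double_male_xy", "seed",
}


class UserError(Exception):
    """A problem with inputs or configuration (exit code 1)."""


@dataclass
class PipelineConfig:
    base: Path
    genome: Path
    deadzones: Path | None
    sample_sheet: Path
    features_dir: Path | None
    out_dir: Path
    resolutions: list[int] = field(default_factory=lambda: [10_000])
    alphas: list[float] = field(default_factory=lambda: [0.90, 0.95, 0.99])
    epsilon: float = 1e-6
    sigma_rule: str = "per-window"
    score_column: int = 5
    autosomes_only_correlations: bool = True
    double_male_xy: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        p = Path(path)
        try:
            raw = yaml.safe_load(p.read_text())
        except FileNotFoundError:
            raise UserError(f"config file not found: {p}") from None
        if not isinstance(raw, dict):
            raise UserError(f"config {p} is not a key-value mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise UserError(f"unknown config keys: {sorted(unknown)}")
        base = p.parent

        def path_of(key, required=True):
            v = raw.get(key)
            if v is None:
                if required:
                    raise UserError(f"config missing required key {key!r}")
                return None
            q = Path(v)
            return q if q.is_absolute() else base / q

        cfg = cls(
            base=base,
            genome=path_of("genome"),
            deadzones=path_of("deadzones", required=False),
            sample_sheet=path_of("sample_sheet"),
            features_dir=path_of("features_dir", required=False),
            out_dir=path_of("out_dir") if raw.get("out_dir") else base / "results",
            resolutions=[int(r) for r in raw.get("resolutions", [10_000])],
            alphas=[float(a) for a in raw.get("alphas", [0.90, 0.95, 0.99])],
            epsilon=float(raw.get("epsilon", 1e-6)),
            sigma_rule=str(raw.get("sigma_rule", "per-window")),
            score_column=int(raw.get("score_column", 5)),
            autosomes_only_correlations=bool(raw.get("autosomes_only_correlations", True)),
            double_male_xy=bool(raw.get("double_male_xy", False)),
            seed=int(raw.get("seed", 0)),
        )
        if 10_000 not in cfg.resolutions:
            cfg.resolutions = [10_000] + cfg.resolutions
        for r in cfg.resolutions:
            if r % 10_000 != 0:
                raise UserError(f"resolution {r} is not a multiple of 10000")
        if cfg.sigma_rule not in ("per-window", "global"):
            raise UserError(f"bad sigma_rule {cfg.sigma_rule!r}")
        for f in (cfg.genome, cfg.sample_sheet):
            if not f.exists():
                raise UserError(f"input file not found: {f}")
        return cfg

    def matrix_path(self, resolution: int) -> Path:
        return self.out_dir / f"matrix_{resolution}.tsv"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    genome = Genome.from_file(cfg.genome)
    deadzones = []
    if cfg.deadzones and cfg.deadzones.exists():
        deadzones = read_interval_bed(cfg.deadzones, genome).intervals
    sheet = read_sample_sheet(cfg.sample_sheet)
    return genome, deadzones, sheet


def _group_key(rec) -> str:
    if rec.category == "aml":
        return f"aml_{rec.aml_cluster.lower()}"
    return rec.category


def stage_windows(cfg: PipelineConfig) -> dict[int, Path]:
    """Score, normalize and replicate-average every sample at each resolution."""
    t0 = time.monotonic()
    genome, deadzones, sheet = _load_inputs(cfg)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    grid10 = WindowGrid(genome, 10_000, deadzones=deadzones)

    raw10: dict[str, WindowTrack] = {}
    for rec in sheet:
        ds = read_scored_bed(rec.path, genome, score_column=cfg.score_column, sample_id=rec.sample_id)
        raw10[rec.sample_id] = score_windows(
            ds, grid10, deadzones=deadzones,
            double_xy=cfg.double_male_xy and rec.sex == "M",
        )

    outputs: dict[int, Path] = {}
    for res in sorted(set(cfg.resolutions)):
        tracks: dict[str, WindowTrack] = {}
        for rg, members in sheet.replicate_groups().items():
            reps = []
            for rec in members:
                raw = raw10[rec.sample_id] if res == 10_000 else coarsen(raw10[rec.sample_id], res)
                reps.append(normalize_track(raw))
            tracks[rg] = average_replicates(reps, sample_id=rg)
        grid = next(iter(tracks.values())).grid
        path = _write_matrix(cfg, grid, tracks, res)
        outputs[res] = path
        for rg, tr in tracks.items():
            write_bedgraph(tr, cfg.out_dir / f"{rg}_{res}.bedgraph")
        log.info("windows: resolution=%d groups=%d windows=%d", res, len(tracks), grid.n_total)
    log.info("stage windows done in %.2fs", time.monotonic() - t0)
    return outputs


def _write_matrix(cfg, grid: WindowGrid, tracks: dict[str, WindowTrack], res: int) -> Path:
    df = pd.DataFrame({"window": grid.window_ids(), "eff_length": grid.effective_length})
    for rg in sorted(tracks):
        t = tracks[rg]
        col = t.scores.astype(float).copy()
        col[t.mask] = np.nan
        df[rg] = col
    path = cfg.matrix_path(res)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def load_matrix(cfg: PipelineConfig, resolution: int = 10_000):
    """Reload the window matrix of a resolution as normalized tracks."""
    path = cfg.matrix_path(resolution)
    if not path.exists():
        raise UserError(
            f"missing window matrix {path}; run the windows stage first"
        )
    genome, deadzones, sheet = _load_inputs(cfg)
    df = pd.read_csv(path, sep="\t")
    grid = WindowGrid(genome, resolution, _effective_length=df["eff_length"].to_numpy())
    grid.mask = grid.effective_length == 0
    tracks: dict[str, WindowTrack] = {}
    for rg in df.columns[2:]:
        col = df[rg].to_numpy(dtype=float)
        mask = np.isnan(col) | grid.mask
        col = np.where(mask, 0.0, col)
        tracks[rg] = WindowTrack(rg, grid, col, mask, normalized=True)
    return grid, tracks, sheet


def _group_meta(sheet: SampleSheet):
    """Per replicate group: comparison group key, zone category, sex."""
    meta = {}
    for rg, members in sheet.replicate_groups().items():
        keys = {_group_key(m) for m in members}
        sexes = {m.sex for m in members}
        if len(keys) != 1 or len(sexes) != 1:
            raise UserError(f"replicate group {rg} mixes categories or sexes")
        meta[rg] = (keys.pop(), sexes.pop())
    return meta


def stage_correlate(cfg: PipelineConfig) -> list[Path]:
    out = []
    for res in sorted(set(cfg.resolutions)):
        grid, tracks, _ = load_matrix(cfg, res)
        ids = sorted(tracks)
        cm = pearson_pairwise([tracks[i] for i in ids], autosomes_only=cfg.autosomes_only_correlations)
        df = pd.DataFrame(cm.r, index=ids, columns=ids)
        path = cfg.out_dir / f"correlation_{res}.tsv"
        df.to_csv(path, sep="\t", float_format="%.6g")
        out.append(path)
        log.info("correlate: resolution=%d samples=%d", res, len(ids))
    return out


def stage_cluster(cfg: PipelineConfig) -> Path:
    _, tracks, _ = load_matrix(cfg, 10_000)
    Z, order = hcluster_samples(
        list(tracks.values()), autosomes_only=cfg.autosomes_only_correlations
    )
    newick = linkage_to_newick(Z, sorted(tracks))
    path = cfg.out_dir / "dendrogram.nwk"
    path.write_text(newick + "\n")
    (cfg.out_dir / "leaf_order.txt").write_text("\n".join(order) + "\n")
    log.info("cluster: leaves=%d", len(order))
    return path


def stage_zones(cfg: PipelineConfig) -> Path:
    grid, tracks, sheet = load_matrix(cfg, 10_000)
    meta = _group_meta(sheet)
    zs, cats, sexes = [], [], []
    for rg in sorted(tracks):
        key, sex = meta[rg]
        if key.startswith("aml"):
            cat = "aml"
        elif key in ("granulocyte", "cd34"):
            cat = key
        else:
            continue  # K562 lines are excluded from zone classification
        zs.append(tracks[rg]); cats.append(cat); sexes.append(sex)
    zm = classify_zones(zs, cats, sexes, sigma_rule=cfg.sigma_rule)
    bed = zones_to_bed(zm)
    path = cfg.out_dir / "zones.bed"
    write_bed(bed, path)
    fr = zone_fractions(zm)
    pd.DataFrame(
        {"zone": ["RED", "YELLOW", "GREEN"], "pct_of_unmasked_bp": fr}
    ).to_csv(cfg.out_dir / "zone_fractions.tsv", sep="\t", index=False, float_format="%.6g")
    log.info("zones: windows=%d red=%.2f%% yellow=%.2f%% green=%.2f%%", grid.n_total, *fr)
    return path


def stage_dlocks(cfg: PipelineConfig) -> dict[str, ComparisonResult]:
    grid, tracks, sheet = load_matrix(cfg, 10_000)
    meta = _group_meta(sheet)
    by_group: dict[str, list[WindowTrack]] = {}
    sexes_by_group: dict[str, list[str]] = {}
    for rg in sorted(tracks):
        key, sex = meta[rg]
        by_group.setdefault(key, []).append(tracks[rg])
        sexes_by_group.setdefault(key, []).append(sex)
    results = run_comparisons(
        by_group, sexes_by_group, epsilon=cfg.epsilon, alpha_levels=cfg.alphas
    )
    genome = grid.genome
    genes = _load_gene_track(cfg, genome)
    summary_rows = []
    for name, res in results.items():
        recs = [
            (d.interval, name, d.total_score) for d in res.dlocks
        ]
        write_bed(recs, cfg.out_dir / f"dlocks_{name}.bed")
        for alpha in cfg.alphas:
            passing = [d for d in res.dlocks if d.flags.get(alpha)]
            s = summarize_dlocks(passing, genes, genome, alpha=alpha) if genes else None
            summary_rows.append(
                {
                    "comparison": name,
                    "alpha": alpha,
                    "pct_genome": s.pct_genome if s else 100.0 * sum(d.length for d in passing) / genome.total_bp,
                    "avg_size_bp": s.avg_size_bp if s else (np.mean([d.length for d in passing]) if passing else 0.0),
                    "n_dlocks": len(passing),
                    "n_genes": s.n_genes if s else "",
                    "gene_density_ratio": s.gene_density_ratio if s else "",
                }
            )
        log.info("dlocks: %s bases=%d blocks=%d", name, len(res.bases), len(res.dlocks))
    pd.DataFrame(summary_rows).to_csv(
        cfg.out_dir / "dlock_summary.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return results


def _load_gene_track(cfg: PipelineConfig, genome: Genome):
    if not cfg.features_dir:
        return None
    p = cfg.features_dir / "genes.bed"
    if not p.exists():
        return None
    return read_interval_bed(p, genome, feature_id="genes")


def stage_enrich(cfg: PipelineConfig) -> Path:
    if not cfg.features_dir or not cfg.features_dir.exists():
        raise UserError("config has no features_dir; nothing to enrich")
    grid, tracks, sheet = load_matrix(cfg, 10_000)
    genome, deadzones, _ = _load_inputs(cfg)

    # window sets: the three zones plus each comparison's significant blocks
    sets: dict[str, np.ndarray] = {}
    zones_bed = cfg.out_dir / "zones.bed"
    if zones_bed.exists():
        lab = {"RED": RED, "YELLOW": YELLOW, "GREEN": GREEN}
        zone_sel = {k: np.zeros(grid.n_total, dtype=bool) for k in lab}
        with open(zones_bed) as fh:
            for line in fh:
                chrom, s, e, name = line.split("\t")[:4]
                name = name.strip()
                o = grid.offsets[chrom]
                w0 = int(s) // grid.resolution
                w1 = -(-int(e) // grid.resolution)
                zone_sel[name][o + w0 : o + w1] = True
        sets.update({f"zone_{k}": v for k, v in zone_sel.items()})
    for bedpath in sorted(cfg.out_dir.glob("dlocks_*.bed")):
        sel = np.zeros(grid.n_total, dtype=bool)
        with open(bedpath) as fh:
            for line in fh:
                chrom, s, e = line.split("\t")[:3]
                o = grid.offsets[chrom]
                sel[o + int(s) // grid.resolution : o + -(-int(e) // grid.resolution)] = True
        if sel.any():
            sets[bedpath.stem] = sel
    if not sets:
        raise UserError("no window sets found; run zones/dlocks stages first")

    rows = []
    for fpath in sorted(cfg.features_dir.glob("*.bed")):
        kind = "point" if fpath.stem in ("snv", "points") else "interval"
        feat = read_interval_bed(fpath, genome, kind=kind)
        dens = feature_density_track(feat, grid, deadzones=deadzones)
        for set_id, sel in sets.items():
            if not (sel & ~grid.mask).any():
                continue
            r = fold_enrichment(sel, dens, set_id=set_id)
            rows.append(
                {
                    "feature": r.feature_id,
                    "set": r.set_id,
                    "fold": r.fold,
                    "set_bp": r.set_bp,
                    "density_in_set": r.density_in_set,
                    "density_genome": r.density_genome,
                }
            )
    path = cfg.out_dir / "enrichment.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    log.info("enrich: features x sets = %d rows", len(rows))
    return path


def write_manifest(cfg: PipelineConfig) -> Path:
    inputs = {}
    for p in [cfg.genome, cfg.sample_sheet] + (
        [cfg.deadzones] if cfg.deadzones and cfg.deadzones.exists() else []
    ):
        inputs[str(p.name)] = _sha256(p)
    _, _, sheet = _load_inputs(cfg)
    for rec in sheet:
        inputs[Path(rec.path).name] = _sha256(Path(rec.path))
    counts = {}
    for out in sorted(cfg.out_dir.glob("*.tsv")):
        with open(out) as fh:
            counts[out.name] = sum(1 for _ in fh) - 1
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            "resolutions": cfg.resolutions,
            "alphas": cfg.alphas,
            "epsilon": cfg.epsilon,
            "sigma_rule": cfg.sigma_rule,
            "score_column": cfg.score_column,
        },
        "inputs_sha256": inputs,
        "row_counts": counts,
    }
    path = cfg.out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def run_all(cfg: PipelineConfig) -> None:
    stage_windows(cfg)
    stage_correlate(cfg)
    stage_cluster(cfg)
    stage_zones(cfg)
    stage_dlocks(cfg)
    if cfg.features_dir and cfg.features_dir.exists():
        stage_enrich(cfg)
    write_manifest(cfg)
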