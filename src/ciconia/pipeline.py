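"""End-to-end orchestration: simulate -> stats -> scan -> DCMS -> overlap,
tracks -> movement, census -> residency, under one reproducible config.

Every stage draws its randomness from a substream derived from the single
global seed, so stages can be rerun independently and the whole run is a
pure function of (config, seed).  Outputs are diff-able text artifacts
(TSV/BED tables, JSON reports) stamped with the config hash, seed and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, census, movement, popstats, sweepscan, synthgen

log = logging.getLogger("ciconia")

__all__ = ["RunConfig", "run", "load_config"]


@dataclass
class GenomeConfig:
    n_chrom: int = 40
    n_scaffolds: int = 4
    scaffold_length: int = 2_000_000
    window_size: int = 50_000
    min_scaffold: int = 1_000_000
    sites_per_window: int = 60
    n_sweeps: int = 3
    sweep_alpha: float = 2e-5
    n_total: int = 108       # pooled chromosomes before the two-group split
    n_group_a: int = 22
    q: float = 0.01
    flip_h: bool = False
    alpha_grid_points: int = 24
    test_spacing: int = 10_000
    min_segregating: int = 10


@dataclass
class TracksConfig:
    n_juveniles: int = 150
    n_adults: int = 80
    n_years: int = 6
    threshold_lat: float = movement.GIBRALTAR_LAT
    month: int = 10
    n_boot: int = 200


@dataclass
class CensusConfig:
    base_pairs: int = 3302
    pair_growth: float = 320.0
    base_winterers: int = 1187
    winterer_growth: float = 720.0
    start_year: int = 1995
    n_years: int = 26


@dataclass
class RunConfig:
    seed: int = 1
    stages: tuple = ("genomes", "tracks", "census")
    genomes: GenomeConfig = field(default_factory=GenomeConfig)
    tracks: TracksConfig = field(default_factory=TracksConfig)
    census: CensusConfig = field(default_factory=CensusConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("genomes", GenomeConfig), ("tracks", TracksConfig),
                         ("census", CensusConfig)):
            if key in d and isinstance(d[key], dict):
                allowed = {f.name for f in dataclasses.fields(sub)}
                bad = set(d[key]) - allowed
                if bad:
                    raise ValueError(f"unknown config key: {key}.{sorted(bad)[0]}")
                d[key] = sub(**d[key])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - allowed
        if bad:
            raise ValueError(f"unknown config key: {sorted(bad)[0]}")
        return cls(**d)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _substream(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _stamp(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed, "version": __version__}


def run_genomes(cfg: RunConfig, out: Path) -> dict:
    g = cfg.genomes
    rng_seed = _substream(cfg.seed, "genomes")
    lengths = {f"scaf{i + 1}": g.scaffold_length for i in range(g.n_scaffolds)}
    windows = popstats.make_windows(lengths, g.window_size, g.min_scaffold)
    rng = np.random.default_rng(rng_seed)
    sweep_windows = sorted(
        rng.choice(len(windows), size=min(g.n_sweeps, len(windows)), replace=False)
    )
    bg = synthgen.neutral_sfs(g.n_chrom)
    parts = []
    for wi, w in windows.iterrows():
        sub_seed = int(rng.integers(2**31))
        if wi in sweep_windows:
            params = synthgen.SweepModelParams(
                alpha=g.sweep_alpha,
                center_pos=int((w["start"] + w["end"]) // 2),
                n_chrom=g.n_chrom,
                background_sfs=bg.probs,
            )
            part = synthgen.sim_sweep_sites(
                params, g.sites_per_window, g.window_size, sub_seed,
                scaffold=w["scaffold"], offset=int(w["start"]),
            )
        else:
            part = synthgen.sim_neutral_sites(
                g.n_chrom, g.sites_per_window, g.window_size, sub_seed,
                scaffold=w["scaffold"], offset=int(w["start"]),
            )
        parts.append(part)
    sites = pd.concat(parts, ignore_index=True)

    # two-group split of an independently simulated pooled sample (the null
    # of one panmictic population: differentiation is sampling noise only)
    pool = sites.copy()
    pool["n"] = g.n_total
    pool["x"] = np.round(pool["x"] * g.n_total / g.n_chrom).clip(1, g.n_total - 1).astype(int)
    split = synthgen.split_pool(pool, g.n_total, g.n_group_a,
                                _substream(cfg.seed, "split"))
    sites[["x_a", "n_a", "x_b", "n_b"]] = split[["x_a", "n_a", "x_b", "n_b"]]

    wstats = popstats.window_stats_table(sites, windows,
                                         min_segregating=g.min_segregating)
    bg_emp = popstats.global_sfs(sites["x"], g.n_chrom)
    clr = sweepscan.clr_scan(
        sites, windows, bg_emp,
        alpha_grid=sweepscan.default_alpha_grid(g.alpha_grid_points),
        test_spacing=g.test_spacing, min_segregating=g.min_segregating,
    )
    table = sweepscan.scan_table(wstats, clr, flip_h=g.flip_h)

    dcms_idx = sweepscan.top_outliers(table["dcms"].to_numpy(), g.q)
    fst_idx = sweepscan.top_outliers(table["fst"].to_numpy(), g.q)
    k = len(np.intersect1d(dcms_idx, fst_idx))
    m = int(table["dcms"].notna().sum())
    ov = sweepscan.overlap_test(m, (len(dcms_idx), len(fst_idx)), k)
    regions = sweepscan.merge_regions(table.iloc[dcms_idx], score="dcms")

    popstats.write_site_counts(sites, out / "sites.tsv")
    popstats.write_window_stats(table.drop(columns=["partial"]), out / "windows.tsv")
    table.iloc[dcms_idx][["scaffold", "start", "end"]].to_csv(
        out / "dcms_outliers.bed", sep="\t", header=False, index=False
    )
    regions.to_csv(out / "dcms_regions.tsv", sep="\t", index=False)
    report = {
        **_stamp(cfg),
        "n_windows": m,
        "n_dcms_outliers": int(len(dcms_idx)),
        "n_fst_outliers": int(len(fst_idx)),
        "n_regions": int(len(regions)),
        "overlap_k": int(k),
        "overlap_p": ov.p_value,
        "overlap_expected": ov.expected,
        "true_sweep_windows": [int(i) for i in sweep_windows],
        "spearman": np.asarray(table.attrs["spearman"]).tolist(),
    }
    (out / "scan_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_tracks(cfg: RunConfig, out: Path) -> dict:
    t = cfg.tracks
    params = synthgen.TrackSimParams()
    seed = _substream(cfg.seed, "tracks")
    juv = synthgen.sim_tracks(params, t.n_juveniles, t.n_years, seed=seed, start_age=1)
    ad = synthgen.sim_tracks(params, t.n_adults, t.n_years, seed=seed + 1, start_age=4)
    ad["bird_id"] = "ad_" + ad["bird_id"]
    birds = pd.concat([juv, ad], ignore_index=True)
    birds["strategy"] = movement.classify_strategy(
        birds["winter_lat"], threshold=t.threshold_lat
    ).to_numpy()
    birds.to_csv(out / "bird_years.csv", index=False)

    adults = birds[birds["age"] >= 4]
    juveniles = birds[birds["age"] < 4]
    rep_ad = movement.repeatability(
        adults["winter_lat"], adults["bird_id"], n_boot=t.n_boot, seed=seed + 2
    )
    rep_juv = movement.repeatability(
        juveniles["winter_lat"], juveniles["bird_id"], n_boot=t.n_boot, seed=seed + 3
    )
    model = movement.fit_age_model(birds)
    trans = movement.transition_summary(birds)
    report = {
        **_stamp(cfg),
        "n_bird_years": int(len(birds)),
        "adult_repeatability": dataclasses.asdict(rep_ad),
        "juvenile_repeatability": dataclasses.asdict(rep_juv),
        "age_model": dataclasses.asdict(model),
        "adult_transitions": trans,
        "migrant_fraction_by_age": {
            str(a): float((sub["strategy"] == "migrant").mean())
            for a, sub in birds.groupby(np.minimum(birds["age"], 4))
        },
    }
    (out / "movement_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_census(cfg: RunConfig, out: Path) -> dict:
    c = cfg.census
    series = synthgen.sim_census(
        c.base_pairs, c.pair_growth, c.base_winterers, c.winterer_growth,
        list(range(c.start_year, c.start_year + c.n_years)),
    )
    series.to_csv(out / "census.csv", index=False)
    trend = census.residency_trend(series)
    trend.to_csv(out / "residency_trend.tsv", sep="\t", index=False)
    first, last = trend.iloc[0], trend.iloc[-1]
    report = {
        **_stamp(cfg),
        "first_year": {"year": int(first["year"]), "proportion": float(first["proportion"])},
        "last_year": {"year": int(last["year"]), "proportion": float(last["proportion"])},
        "wintering_fold_change": census.fold_change(
            series["wintering_individuals"].iloc[0],
            series["wintering_individuals"].iloc[-1],
        ),
    }
    (out / "census_report.json").write_text(json.dumps(report, indent=2))
    return report


_STAGES = {"genomes": run_genomes, "tracks": run_tracks, "census": run_census}


def run(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in order; returns the merged report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in cfg.stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stage: {unknown[0]}")
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    reports = {}
    for stage in cfg.stages:
        log.info("running stage %s", stage)
        reports[stage] = _STAGES[stage](cfg, out)
    (out / "run_report.json").write_text(json.dumps({**_stamp(cfg), **reports}, indent=2))
    return reports
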