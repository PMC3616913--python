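"""End-to-end orchestration: simulate/load, process, call, compare, classify.

``run_pipeline`` chains the Methods-style stages — decile normalization,
spike denoising, 2 kb smoothing, peak calling — over a pair of tracks
(target IP vs reference DSB map), then builds the between-experiment
overlap report, the high/low-Zip3 site classification and, when tetrad
counts are supplied, the genetic-distance report. Every output carries the
full configuration and seed so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from . import peaks as pk
from . import profiles as prof
from . import sites as st
from . import synthetic as syn
from . import tetrads as tg
from .track import FeatureSet, ProbeTrack

__all__ = ["PipelineConfig", "run_pipeline", "process_track"]

log = logging.getLogger("meiochip")


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end analysis, serializable to YAML."""

    window_bp: float = 2000.0
    spike_factor: float = 3.0
    neighbor_span: int = 5
    peak_threshold: float = 2.0
    min_separation: float = 2000.0
    match_dist: float = 2000.0
    n_top: int = 400
    high_cutoff: int = 50
    low_cutoff: int = 100
    cen_excl: float = 10_000.0
    seed: int = 0
    # synthetic-genome defaults: two ~1 Mb chromosomes keeps a full run fast
    # while leaving room for dozens of well-separated hotspots
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    probe_spacing: int = 300
    noise_sigma: float = 0.1
    n_dsb: int = 50
    n_axis: int = 30
    classify: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def process_track(track: ProbeTrack, cfg: PipelineConfig) -> ProbeTrack:
    """Normalize -> denoise -> smooth, the standard processing chain."""
    out = prof.decile_normalize(track)
    out = prof.denoise(out, spike_factor=cfg.spike_factor, neighbor_span=cfg.neighbor_span)
    return prof.smooth(out, window_bp=cfg.window_bp)


def _simulate_bundle(cfg: PipelineConfig):
    layout = syn.make_genome(
        cfg.n_chrom,
        [cfg.chrom_length] * cfg.n_chrom,
        [0.5] * cfg.n_chrom,
        seed=cfg.seed,
    )
    sim_cfg = syn.SimulationConfig(
        probe_spacing=cfg.probe_spacing,
        noise_sigma=cfg.noise_sigma,
        seed=cfg.seed,
        n_dsb=cfg.n_dsb,
        n_axis=cfg.n_axis,
    )
    features = syn.plant_random_features(layout, sim_cfg)
    target = syn.simulate_track(layout, features, sim_cfg, channel="target")
    reference = syn.simulate_track(layout, features, sim_cfg, channel="reference")
    return layout, features, target, reference


def run_pipeline(
    cfg: PipelineConfig,
    target: ProbeTrack | None = None,
    reference: ProbeTrack | None = None,
    centromeres: FeatureSet | None = None,
    axis_sites: FeatureSet | None = None,
    tetrad_counts: list[tg.TetradCounts] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis; simulate a seeded bundle when no tracks are given.

    Returns a report dict (also written as JSON/TSV files under *out_dir*
    when given) with the overlap/correlation report, the site
    classification table and, on synthetic runs, a self-check section
    scoring the classification against the planted ground truth.
    """
    features = None
    if target is None or reference is None:
        log.info("no input tracks: simulating a seeded synthetic bundle")
        layout, features, target, reference = _simulate_bundle(cfg)
        if centromeres is None:
            centromeres = FeatureSet.from_points(
                [n for n, _ in layout.chromosomes],
                [layout.centromeres[n] for n, _ in layout.chromosomes],
                label="centromeres",
            )
        if axis_sites is None:
            axis_sites = syn.features_to_featureset(features, kind="axis")

    report: dict = {"config": cfg.to_dict(), "stages": []}

    proc_t = process_track(target, cfg)
    proc_r = process_track(reference, cfg)
    peaks_t = pk.call_peaks(proc_t, threshold=cfg.peak_threshold, min_separation=cfg.min_separation)
    peaks_r = pk.call_peaks(proc_r, threshold=cfg.peak_threshold, min_separation=cfg.min_separation)
    for label, track, called in (("target", proc_t, peaks_t), ("reference", proc_r, peaks_r)):
        log.info("%s: %d probes -> %d peaks", label, track.n_probes, len(called))
        report["stages"].append(
            {"track": label, "n_probes": track.n_probes, "n_peaks": len(called)}
        )

    pairs, overlap = pk.match_peaks(peaks_t, peaks_r, match_dist=cfg.match_dist)
    pcorr = pk.profile_correlation(proc_t, proc_r)
    report["overlap"] = {
        "n_target_peaks": overlap.n_a,
        "n_reference_peaks": overlap.n_b,
        "n_common": overlap.n_common,
        "fraction_of_target": overlap.fraction_of_a,
        "pcorr": pcorr,
    }

    if cfg.classify:
        top = st.select_top_dsbs(
            peaks_r, min(cfg.n_top, len(peaks_r)), centromeres, cen_excl=cfg.cen_excl
        )
        annotations = st.classify_dsb_sites(
            top,
            peaks_t,
            match_dist=cfg.match_dist,
            high_cutoff=cfg.high_cutoff,
            low_cutoff=cfg.low_cutoff,
            centromeres=centromeres,
            axis_sites=axis_sites,
        )
        counts = {k: sum(a.klass == k for a in annotations) for k in ("high", "low", "intermediate")}
        report["classification"] = {
            "n_sites": len(annotations),
            "counts": counts,
            "sites": [
                {
                    "chrom": a.dsb_peak.chrom,
                    "summit": a.dsb_peak.summit,
                    "dsb_rank": a.dsb_peak.rank,
                    "zip3_rank": a.zip3_peak.rank if a.zip3_peak else None,
                    "rank_delta": a.rank_delta,
                    "class": a.klass,
                    "cen_dist": None if np.isnan(a.cen_dist) else a.cen_dist,
                    "axis_dist": None if np.isnan(a.axis_dist) else a.axis_dist,
                }
                for a in annotations
            ],
        }
        if features is not None:
            report["self_check"] = _self_check(annotations, features, cfg)

    if tetrad_counts:
        report["tetrads"] = _tetrad_report(tetrad_counts)

    if out_dir is not None:
        _write_bundle(report, peaks_t, peaks_r, Path(out_dir))
    return report


def _self_check(annotations, features, cfg: PipelineConfig) -> dict:
    """Score called classes against planted zip3 propensities (synthetic runs)."""
    planted = [
        (f.chrom, f.position, "high" if f.zip3_propensity >= 1 else "low")
        for f in features
        if f.kind == "dsb"
    ]
    n_scored = n_correct = 0
    for a in annotations:
        best = None
        for chrom, posn, truth in planted:
            if chrom == a.dsb_peak.chrom:
                d = abs(posn - a.dsb_peak.summit)
                if best is None or d < best[0]:
                    best = (d, truth)
        if best is not None and best[0] <= cfg.window_bp:
            n_scored += 1
            n_correct += a.klass == best[1]
    acc = n_correct / n_scored if n_scored else float("nan")
    return {"n_scored": n_scored, "n_correct": n_correct, "accuracy": acc}


def _tetrad_report(tetrads: list[tg.TetradCounts]) -> dict:
    rows = []
    for t in tetrads:
        md = tg.perkins_distance(t)
        rows.append(
            {
                "strain": t.strain,
                "interval": t.interval,
                "PD": t.PD,
                "NPD": t.NPD,
                "T": t.T,
                "cM": md.cM,
                "se": md.se,
            }
        )
    pairwise = []
    for i in range(len(tetrads)):
        for j in range(i + 1, len(tetrads)):
            a, b = tetrads[i], tetrads[j]
            if a.interval == b.interval and a.strain != b.strain:
                g, p, df = tg.g_test(a, b)
                pairwise.append(
                    {"interval": a.interval, "strains": [a.strain, b.strain], "G": g, "p": p, "df": df}
                )
    return {"intervals": rows, "g_tests": pairwise}


def _write_bundle(report: dict, peaks_t, peaks_r, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    mio.write_peaks(peaks_t, out_dir / "peaks_target.tsv")
    mio.write_peaks(peaks_r, out_dir / "peaks_reference.tsv")
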