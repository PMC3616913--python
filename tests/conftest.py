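import numpy as np
import pytest

from meiochip import (
    GenomeLayout,
    PlantedFeature,
    ProbeTrack,
    SimulationConfig,
    make_genome,
    simulate_track,
)


def random_track(rng: np.random.Generator, n_chrom: int = 2, n_probes: int = 60,
                 spacing: int = 300) -> ProbeTrack:
    """A positive-valued track with a regular probe grid, for property tests."""
    data = {}
    for i in range(n_chrom):
        pos = np.arange(1, n_probes * spacing + 1, spacing, dtype=np.int64)
        val = rng.lognormal(mean=0.0, sigma=0.5, size=pos.size)
        data[f"chr{i + 1}"] = (pos, val)
    return ProbeTrack(data=data, name="random")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130415)


@pytest.fixture(scope="session")
def dsb_genome() -> GenomeLayout:
    """Two ~1 Mb chromosomes, centromeres mid-arm (the desk-scale test genome)."""
    return make_genome(2, [1_000_000, 1_000_000], [0.5, 0.5], seed=7)


def plant_dsbs(layout: GenomeLayout, n: int, seed: int,
               propensities=(0.0, 3.0)) -> list[PlantedFeature]:
    """Plant *n* well-separated DSB hotspots with bimodal Zip3 propensities."""
    rng = np.random.default_rng(seed)
    feats = []
    lengths = dict(layout.chromosomes)
    taken = {c: [p] for c, p in layout.centromeres.items()}
    while len(feats) < n:
        chrom = f"chr{rng.integers(len(lengths)) + 1}"
        pos = int(rng.integers(15_000, lengths[chrom] - 15_000))
        if all(abs(pos - q) >= 12_000 for q in taken[chrom]):
            taken[chrom].append(pos)
            feats.append(
                PlantedFeature(
                    chrom, pos, "dsb",
                    strength=float(rng.uniform(4.0, 10.0)),
                    zip3_propensity=float(propensities[rng.integers(len(propensities))]),
                )
            )
    return feats


@pytest.fixture(scope="session")
def dsb_bundle(dsb_genome):
    """50 planted hotspots + simulated target/reference tracks (noise 0.1)."""
    feats = plant_dsbs(dsb_genome, 50, seed=7)
    cfg = SimulationConfig(probe_spacing=300, noise_sigma=0.1, seed=7)
    target = simulate_track(dsb_genome, feats, cfg, channel="target")
    reference = simulate_track(dsb_genome, feats, cfg, channel="reference")
    return dsb_genome, feats, cfg, target, reference
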