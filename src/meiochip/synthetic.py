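"""Synthetic genomes, probe tracks and tetrad draws with known ground truth.

The generator emulates the data a tiling-array ChIP experiment in meiotic
yeast produces: ~300 bp-spaced probes over a multi-chromosome genome, with
planted enrichments of three kinds — centromere-proximal, axis-associated
and DSB hotspots — each a Gaussian bump in log-signal space, plus
multiplicative log-normal noise. Two channels share the same planted
features: the *reference* channel reports each feature at its full
strength (a DSB/ssDNA map), while in the *target* channel (the Zip3 IP)
each DSB feature's strength is modulated by its ``zip3_propensity``, the
ground truth for high/low-Zip3 classification.

The tetrad generator draws per-meiosis crossover counts from a Poisson and
assigns each crossover to a random non-sister chromatid pair (no chromatid
interference), the null model under which the Perkins formula is unbiased;
true mean ``m`` crossovers per meiosis corresponds to ``50 m`` cM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tetrads import TetradCounts
from .track import FeatureSet, ProbeTrack

__all__ = [
    "GenomeLayout",
    "PlantedFeature",
    "SimulationConfig",
    "make_genome",
    "plant_random_features",
    "simulate_track",
    "simulate_tetrads",
    "features_to_featureset",
    "expected_tetrad_frequencies",
    "expected_perkins_cM",
]

_KINDS = ("centromere-enrichment", "axis", "dsb")
_DEFAULT_KERNEL = {"centromere-enrichment": 4000.0, "axis": 1500.0, "dsb": 1500.0}


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths with one centromere position per chromosome."""

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, int]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: length must be positive")
            cen = self.centromeres.get(name)
            if cen is None or not (1 <= cen <= length):
                raise ValueError(f"{name}: centromere must lie in [1, {length}]")

    def length_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]


@dataclass(frozen=True)
class PlantedFeature:
    """One planted enrichment: a log-space Gaussian bump of given strength."""

    chrom: str
    position: int
    kind: str
    strength: float
    kernel_width: float | None = None
    zip3_propensity: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.strength < 1:
            raise ValueError("strength must be >= 1 (enrichment multiplier)")
        if self.kernel_width is None:
            object.__setattr__(self, "kernel_width", _DEFAULT_KERNEL[self.kind])
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if self.kind == "dsb":
            if self.zip3_propensity is None or self.zip3_propensity < 0:
                raise ValueError("dsb features require zip3_propensity >= 0")
        elif self.zip3_propensity is not None:
            raise ValueError("zip3_propensity is defined only for dsb features")


@dataclass(frozen=True)
class SimulationConfig:
    probe_spacing: int = 300
    noise_sigma: float = 0.1
    baseline: float = 1.0
    seed: int = 0
    n_dsb: int = 50
    n_axis: int = 30

    def __post_init__(self) -> None:
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


def make_genome(
    n_chrom: int,
    lengths: list[int],
    cen_fractions: list[float],
    seed: int = 0,
) -> GenomeLayout:
    """Build a genome layout with centromeres at the given fractional positions."""
    if len(lengths) != n_chrom or len(cen_fractions) != n_chrom:
        raise ValueError("lengths and cen_fractions must each have n_chrom entries")
    if any(length <= 0 for length in lengths):
        raise ValueError("chromosome lengths must be positive")
    if any(not (0 < f < 1) for f in cen_fractions):
        raise ValueError("cen_fractions must lie in (0, 1)")
    chroms = [(f"chr{i + 1}", int(L)) for i, L in enumerate(lengths)]
    cens = {
        name: max(1, int(round(f * L))) for (name, L), f in zip(chroms, cen_fractions)
    }
    return GenomeLayout(chromosomes=chroms, centromeres=cens)


def plant_random_features(
    layout: GenomeLayout,
    cfg: SimulationConfig,
    dsb_strength: tuple[float, float] = (4.0, 10.0),
    axis_strength: tuple[float, float] = (2.0, 5.0),
    cen_strength: float = 6.0,
    zip3_propensities: tuple[float, ...] = (0.0, 3.0),
    min_spacing: float = 12_000,
    edge_margin: float = 10_000,
) -> list[PlantedFeature]:
    """Draw a random but reproducible feature mixture over *layout*.

    One centromere-enrichment per centromere, plus ``cfg.n_axis`` axis sites
    and ``cfg.n_dsb`` DSB hotspots placed uniformly with a minimum spacing of
    ``min_spacing`` bp (so planted summits stay resolvable after 2 kb
    smoothing) and ``edge_margin`` bp clear of chromosome ends and
    centromeres. Each DSB's ``zip3_propensity`` is drawn uniformly from
    ``zip3_propensities`` — bimodal by default, giving planted "low" (0) and
    "high" (3) crossover-designation classes.
    """
    rng = np.random.default_rng(cfg.seed)
    feats = [
        PlantedFeature(name, cen, "centromere-enrichment", cen_strength)
        for name, cen in layout.centromeres.items()
    ]
    total_len = sum(L for _, L in layout.chromosomes)
    weights = [L / total_len for _, L in layout.chromosomes]
    taken: dict[str, list[int]] = {
        name: [cen] for name, cen in layout.centromeres.items()
    }

    def place() -> tuple[str, int]:
        for _ in range(10_000):
            ci = rng.choice(len(layout.chromosomes), p=weights)
            name, L = layout.chromosomes[ci]
            if L < 2 * edge_margin + 1:
                continue
            pos = int(rng.integers(edge_margin, L - edge_margin + 1))
            if all(abs(pos - q) >= min_spacing for q in taken[name]):
                taken[name].append(pos)
                return name, pos
        raise RuntimeError("could not place features; genome too crowded")

    for _ in range(cfg.n_axis):
        name, pos = place()
        lo, hi = axis_strength
        feats.append(PlantedFeature(name, pos, "axis", float(rng.uniform(lo, hi))))
    for _ in range(cfg.n_dsb):
        name, pos = place()
        lo, hi = dsb_strength
        prop = float(zip3_propensities[rng.integers(len(zip3_propensities))])
        feats.append(
            PlantedFeature(
                name, pos, "dsb", float(rng.uniform(lo, hi)), zip3_propensity=prop
            )
        )
    return feats


def _effective_strength(f: PlantedFeature, channel: str) -> float:
    if channel == "target" and f.kind == "dsb":
        # Zip3 channel: the hotspot's enrichment is its crossover-designation
        # propensity times its strength, floored at 1 (no depletion modeled).
        return max(f.strength * f.zip3_propensity, 1.0)
    return f.strength


def simulate_track(
    layout: GenomeLayout,
    features: list[PlantedFeature],
    cfg: SimulationConfig,
    channel: str = "target",
) -> ProbeTrack:
    """Simulate one probe track over *layout* with the planted *features*.

    Probes sit at 1, 1+spacing, 1+2*spacing, ... on each chromosome. The
    expected log-signal is ``log(baseline)`` plus, per feature, a Gaussian
    bump ``log(s) * exp(-(x - pos)^2 / (2 sigma^2))`` with
    ``sigma = kernel_width / 2`` and effective strength ``s`` as described
    in the module docstring. Log-normal noise of sd ``noise_sigma`` is then
    applied multiplicatively. Fully reproducible: the RNG stream is derived
    from ``(cfg.seed, channel)``.
    """
    if channel not in ("target", "reference"):
        raise ValueError("channel must be 'target' or 'reference'")
    lengths = dict(layout.chromosomes)
    for f in features:
        if f.chrom not in lengths:
            raise ValueError(f"feature on unknown chromosome {f.chrom!r}")
        if not (1 <= f.position <= lengths[f.chrom]):
            raise ValueError(
                f"feature at {f.chrom}:{f.position} outside chromosome bounds"
            )
    rng = np.random.default_rng([cfg.seed, 0 if channel == "target" else 1])
    data = {}
    for name, L in layout.chromosomes:
        pos = np.arange(1, L + 1, cfg.probe_spacing, dtype=np.int64)
        logmu = np.full(pos.size, math.log(cfg.baseline))
        for f in features:
            if f.chrom != name:
                continue
            s = _effective_strength(f, channel)
            sigma = f.kernel_width / 2.0
            logmu += math.log(s) * np.exp(-((pos - f.position) ** 2) / (2 * sigma**2))
        noise = rng.normal(0.0, cfg.noise_sigma, pos.size) if cfg.noise_sigma else 0.0
        data[name] = (pos, np.exp(logmu + noise))
    return ProbeTrack(data=data, name=f"sim-{channel}", processing=("raw",))


def expected_peak_height(f: PlantedFeature, cfg: SimulationConfig, channel: str) -> float:
    """Noise-free signal at the feature's own position (the planted summit height)."""
    return cfg.baseline * _effective_strength(f, channel)


def features_to_featureset(features: list[PlantedFeature], kind: str | None = None) -> FeatureSet:
    """Ground-truth features (optionally one kind) as a point FeatureSet."""
    sel = [f for f in features if kind is None or f.kind == kind]
    return FeatureSet.from_points(
        [f.chrom for f in sel],
        [f.position for f in sel],
        names=[f"{f.kind}-{i}" for i, f in enumerate(sel)],
        kind=[f.kind for f in sel],
        strength=[f.strength for f in sel],
        label=kind or "planted",
    )


# non-sister chromatid pairs: chromatids 0,1 carry parent-A alleles, 2,3 parent-B
_NONSISTER = ((0, 2), (0, 3), (1, 2), (1, 3))

# One extra crossover moves the tetrad class PD -> T always, T -> {PD, T, NPD}
# with probabilities (1/4, 1/2, 1/4), NPD -> T always (classical ditype/
# tetratype Markov chain under no chromatid interference).
_CLASS_CHAIN = np.array(
    [[0.0, 1.0, 0.0], [0.25, 0.5, 0.25], [0.0, 1.0, 0.0]]
)


def expected_tetrad_frequencies(true_m: float, tol: float = 1e-12) -> np.ndarray:
    """Closed-form (PD, T, NPD) class probabilities at *true_m* mean COs/meiosis.

    Mixes the k-crossover class distribution (k steps of the ditype/
    tetratype Markov chain from the all-parental state) over a Poisson(m)
    crossover count, truncated once the remaining Poisson mass is below
    *tol*. This is the analytic counterpart of :func:`simulate_tetrads`.
    """
    from scipy.stats import poisson

    state = np.array([1.0, 0.0, 0.0])
    out = np.zeros(3)
    k = 0
    cum = 0.0
    while cum < 1.0 - tol:
        pk = poisson.pmf(k, true_m)
        out += pk * state
        cum += pk
        state = state @ _CLASS_CHAIN
        k += 1
        if k > 10_000:
            break
    return out / out.sum()


def expected_perkins_cM(true_m: float) -> float:
    """Expected Perkins map distance under the no-interference model.

    The Perkins formula corrects exactly for double crossovers only, so for
    Poisson crossover counts its expectation falls slightly below the
    nominal ``50 * true_m`` cM as ``true_m`` grows; calibration checks
    should target this value, which is what the estimator converges to.
    """
    p_pd, p_t, p_npd = expected_tetrad_frequencies(true_m)
    return 100.0 * (p_t / 2.0 + 3.0 * p_npd)


def simulate_tetrads(true_m: float, n: int, seed: int = 0) -> TetradCounts:
    """Draw *n* tetrads for one two-marker interval at *true_m* mean COs/meiosis.

    Per meiosis the crossover count is Poisson(``true_m``); each crossover
    exchanges the distal-marker alleles of a uniformly chosen non-sister
    chromatid pair. The four resulting chromatids are scored against the
    parental configurations: 0 recombinant chromatids = PD, 2 = T, 4 = NPD.
    Expected map distance is ``50 * true_m`` cM.
    """
    if true_m < 0:
        raise ValueError("true_m must be non-negative")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    ks = rng.poisson(true_m, n)
    total_co = int(ks.sum())
    pair_idx = rng.integers(0, 4, total_co) if total_co else np.empty(0, int)
    pd = npd = t = 0
    off = 0
    parental = (0, 0, 1, 1)
    for k in ks:
        allele = [0, 0, 1, 1]  # distal-marker allele per chromatid
        for pi in pair_idx[off : off + k]:
            i, j = _NONSISTER[pi]
            allele[i], allele[j] = allele[j], allele[i]
        off += k
        rec = sum(a != p for a, p in zip(allele, parental))
        if rec == 0:
            pd += 1
        elif rec == 4:
            npd += 1
        else:
            t += 1
    return TetradCounts(PD=pd, NPD=npd, T=t)
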