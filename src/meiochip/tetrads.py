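"""Tetrad genetics: Perkins map distances, strain comparisons, CO-per-DSB.

For two linked markers, each dissected tetrad is scored as parental ditype
(PD), non-parental ditype (NPD) or tetratype (T). The Perkins formula

    cM = 100 * (T/2 + 3*NPD) / (PD + NPD + T)

estimates the map distance, correcting for double crossovers under no
chromatid interference. Standard errors come from the multinomial delta
method (closed form), with a seeded bootstrap available as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TetradCounts",
    "MapDistance",
    "perkins_distance",
    "bootstrap_se",
    "g_test",
    "co_per_dsb",
]

# Perkins estimator as a linear functional of the (PD, NPD, T) proportions
_PERKINS_COEF = np.array([0.0, 3.0, 0.5])


@dataclass(frozen=True)
class TetradCounts:
    """PD/NPD/T tallies for one marker interval in one strain."""

    PD: int
    NPD: int
    T: int
    interval: str = ""
    strain: str = ""

    def __post_init__(self) -> None:
        if min(self.PD, self.NPD, self.T) < 0:
            raise ValueError("tetrad counts must be non-negative")
        if self.total == 0:
            raise ValueError("at least one tetrad is required")

    @property
    def total(self) -> int:
        return self.PD + self.NPD + self.T

    def as_array(self) -> np.ndarray:
        return np.array([self.PD, self.NPD, self.T], float)


@dataclass(frozen=True)
class MapDistance:
    cM: float
    se: float

    def __post_init__(self) -> None:
        if self.cM < 0 or self.se < 0:
            raise ValueError("map distance and SE must be non-negative")


def perkins_distance(t: TetradCounts) -> MapDistance:
    """Perkins map-distance estimate with its delta-method standard error.

    The estimator is ``100 * (T/2 + 3 NPD) / n``, a linear functional of the
    multinomial class proportions, so its variance has the closed form
    ``(sum c_i^2 p_i - (sum c_i p_i)^2) / n`` with coefficients
    ``c = (0, 3, 1/2)``. Estimates above 50 cM (NPD-rich data) are reported
    unclamped with a warning: the formula leaves its quasi-linear regime
    there.
    """
    n = t.total
    p = t.as_array() / n
    m = float(_PERKINS_COEF @ p)
    cm = 100.0 * m
    var = (float(_PERKINS_COEF**2 @ p) - m**2) / n
    se = 100.0 * np.sqrt(max(var, 0.0))
    if cm > 50.0:
        warnings.warn(
            f"Perkins estimate {cm:.1f} cM exceeds 50 cM; the estimator is "
            "outside its quasi-linear regime",
            stacklevel=2,
        )
    return MapDistance(cM=cm, se=float(se))


def bootstrap_se(t: TetradCounts, n_boot: int = 10_000, seed: int = 0) -> float:
    """Bootstrap standard error of the Perkins estimate (multinomial resampling)."""
    rng = np.random.default_rng(seed)
    n = t.total
    draws = rng.multinomial(n, t.as_array() / n, size=n_boot)
    ests = 100.0 * (draws @ _PERKINS_COEF) / n
    return float(np.std(ests, ddof=1))


def g_test(a: TetradCounts, b: TetradCounts) -> tuple[float, float, int]:
    """Likelihood-ratio G-test comparing PD/NPD/T patterns of two strains.

    Builds the 2x3 strain-by-class table and computes
    ``G = 2 * sum O * ln(O/E)`` with the convention ``0 * ln(0/E) = 0``,
    referred to chi-square with df = (number of retained classes) - 1.
    A class empty in both strains is dropped (with a warning) and df reduced.
    Returns ``(G, p, df)``.
    """
    table = np.vstack([a.as_array(), b.as_array()])
    keep = table.sum(axis=0) > 0
    if not keep.all():
        warnings.warn(
            "tetrad class(es) empty in both strains dropped from the G-test",
            stacklevel=2,
        )
        table = table[:, keep]
    df = table.shape[1] - 1
    if df == 0:
        return 0.0, 1.0, 0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    g = float(2.0 * terms.sum())
    p = float(stats.chi2.sf(g, df))
    return g, p, df


def co_per_dsb(cM: float, dsb_freq_pct: float) -> float:
    """Crossovers-per-DSB proxy for one interval.

    The percentage of cells receiving a crossover is twice the genetic
    distance (each CO involves 2 of 4 chromatids); the percentage of cells
    receiving a DSB is the measured per-chromatid DSB frequency times 4
    chromatids, assuming at most one chromatid per cell is cut in the
    interval. The ratio of the two is dimensionless.
    """
    if dsb_freq_pct <= 0:
        raise ValueError("DSB frequency must be positive")
    if cM < 0:
        raise ValueError("map distance must be non-negative")
    return (cM * 2.0) / (dsb_freq_pct * 4.0)
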