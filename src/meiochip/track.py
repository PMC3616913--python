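"""Core genomic containers: probe-level signal tracks and point/interval features.

Coordinates are 1-based inclusive throughout (SGD convention); there is no
strand: every feature in this analysis is a strandless chromosomal position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ProbeTrack", "FeatureSet"]


@dataclass(frozen=True)
class ProbeTrack:
    """An ordered collection of tiling-array probes with positive signal ratios.

    Parameters
    ----------
    data
        Mapping ``chromosome -> (positions, values)``. Positions are 1-based
        base-pair coordinates, strictly increasing within a chromosome;
        values are strictly positive IP/whole-cell ratios.
    name
        Free-text label (e.g. ``"zip3-4h"``).
    processing
        Append-only tuple of processing-state flags, e.g.
        ``("raw", "decile-normalized", "denoised", "smoothed:2000")``.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray]]
    name: str = ""
    processing: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, val) in self.data.items():
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=np.float64)
            if pos.shape != val.shape or pos.ndim != 1:
                raise ValueError(f"{chrom}: positions and values must be 1-D and equal length")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: probe positions must be strictly increasing")
            if np.any(val <= 0):
                raise ValueError(f"{chrom}: signal ratios must be strictly positive")
            clean[chrom] = (pos, val)
        object.__setattr__(self, "data", clean)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    @property
    def n_probes(self) -> int:
        return sum(pos.size for pos, _ in self.data.values())

    def values_concat(self) -> np.ndarray:
        """All signal values pooled across chromosomes, chromosome order."""
        if not self.data:
            return np.empty(0)
        return np.concatenate([val for _, val in self.data.values()])

    def with_values(
        self, new_values: dict[str, np.ndarray], flag: str | None = None
    ) -> "ProbeTrack":
        """Return a copy with replaced values (same probe grid), appending *flag*."""
        data = {c: (pos, np.asarray(new_values[c], dtype=float)) for c, (pos, _) in self.data.items()}
        processing = self.processing + (flag,) if flag else self.processing
        return ProbeTrack(data=data, name=self.name, processing=processing)

    def has_flag(self, prefix: str) -> bool:
        return any(f == prefix or f.startswith(prefix + ":") for f in self.processing)

    def same_grid(self, other: "ProbeTrack") -> bool:
        if self.chromosomes != other.chromosomes:
            return False
        return all(
            np.array_equal(self.data[c][0], other.data[c][0]) for c in self.data
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"chrom": c, "position": pos, "value": val})
            for c, (pos, val) in self.data.items()
        ]
        if not rows:
            return pd.DataFrame(columns=["chrom", "position", "value"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, name: str = "", processing: tuple[str, ...] = ("raw",)
    ) -> "ProbeTrack":
        data = {}
        for chrom, grp in frame.groupby("chrom", sort=False):
            grp = grp.sort_values("position")
            data[str(chrom)] = (
                grp["position"].to_numpy(np.int64),
                grp["value"].to_numpy(float),
            )
        return cls(data=data, name=name, processing=processing)


@dataclass(frozen=True)
class FeatureSet:
    """Named genomic point/interval features (centromeres, axis sites, hotspots).

    Backed by a DataFrame with 1-based inclusive ``chrom, start, end, name``
    columns; extra columns (``kind``, ``strength``, ``score``) are preserved.
    Point features have ``start == end``.
    """

    frame: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        fr = self.frame.reset_index(drop=True)
        required = {"chrom", "start", "end"}
        missing = required - set(fr.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        if "name" not in fr.columns:
            fr = fr.assign(name=[f"feat{i}" for i in range(len(fr))])
        if len(fr) and (fr["start"] > fr["end"]).any():
            bad = fr.index[fr["start"] > fr["end"]][0]
            raise ValueError(f"feature row {bad}: start > end")
        object.__setattr__(self, "frame", fr)

    def __len__(self) -> int:
        return len(self.frame)

    def positions(self, chrom: str) -> np.ndarray:
        """Representative point per feature on *chrom*: the interval midpoint."""
        sub = self.frame[self.frame["chrom"] == chrom]
        return ((sub["start"].to_numpy(float) + sub["end"].to_numpy(float)) / 2.0)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    @classmethod
    def from_points(
        cls,
        chroms: list[str],
        positions: list[int] | np.ndarray,
        names: list[str] | None = None,
        label: str = "",
        **extra,
    ) -> "FeatureSet":
        fr = pd.DataFrame({"chrom": chroms, "start": positions, "end": positions})
        if names is not None:
            fr["name"] = names
        for k, v in extra.items():
            fr[k] = v
        return cls(frame=fr, label=label)
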