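"""Text formats: probe tracks, BED-like features, peaks, tetrad tables.

All files are tab-delimited with a header line; lines starting with ``#``
are provenance comments. Genomic coordinates are 1-based inclusive
(stated in every output header); conversion to 0-based half-open formats
is the caller's responsibility at the boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .peaks import Peak
from .tetrads import TetradCounts
from .track import FeatureSet, ProbeTrack

__all__ = [
    "read_track",
    "write_track",
    "read_features",
    "write_features",
    "read_peaks",
    "write_peaks",
    "read_tetrads",
    "write_tetrads",
]

_COORD_COMMENT = "# coordinates: 1-based inclusive\n"


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_track(
    path, value_column: str | None = None, name: str | None = None
) -> ProbeTrack:
    """Read a probe track from tab-delimited text.

    Expected columns: optional probe reference (any name, preserved but
    unused), ``chrom``, ``position`` (1-based bp) and one or more signal
    columns. ``value_column`` selects the signal column (default: the first
    column after ``position`` that is neither ``chrom`` nor a reference).
    Probes are sorted by position on read; duplicate positions on a
    chromosome are an error reported with the offending data line.
    """
    path = Path(path)
    processing: tuple[str, ...] = ("raw",)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# processing:"):
                processing = tuple(line.split(":", 1)[1].strip().split(","))
    fr = _read_table(path)
    for col in ("chrom", "position"):
        if col not in fr.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    pos_numeric = pd.to_numeric(fr["position"], errors="coerce")
    bad = pos_numeric.isna() | (pos_numeric <= 0)
    if bad.any():
        # +2: header line plus 1-based line numbering (comments not counted)
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: non-numeric or non-positive position at data line {line}")
    fr["position"] = pos_numeric.astype(np.int64)
    signal_cols = [c for c in fr.columns if c not in ("chrom", "position")]
    # drop a leading probe-reference column from signal candidates
    signal_cols = [
        c for c in signal_cols if not c.lower().startswith(("ref", "probe", "id"))
    ]
    if value_column is None:
        if not signal_cols:
            raise ValueError(f"{path}: no signal column found")
        value_column = signal_cols[0]
    if value_column not in fr.columns:
        raise ValueError(f"{path}: no column {value_column!r}")
    dup = fr.duplicated(subset=["chrom", "position"], keep=False)
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValueError(f"{path}: duplicate probe position at data line {line}")
    frame = pd.DataFrame(
        {
            "chrom": fr["chrom"],
            "position": fr["position"],
            "value": pd.to_numeric(fr[value_column]),
        }
    )
    return ProbeTrack.from_frame(frame, name=name or value_column,
                                 processing=processing)


def write_track(track: ProbeTrack, path, ref_column: bool = True) -> None:
    """Write a track as tab-delimited text (values to 12 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write(f"# processing: {','.join(track.processing)}\n")
        cols = (["RefNumber"] if ref_column else []) + ["chrom", "position", "value"]
        fh.write("\t".join(cols) + "\n")
        i = 0
        for chrom, (pos, val) in track.data.items():
            for p, v in zip(pos, val):
                ref = [f"probe_{i:06d}"] if ref_column else []
                fh.write("\t".join(ref + [chrom, str(int(p)), f"{v:.12g}"]) + "\n")
                i += 1


def read_features(path, label: str = "") -> FeatureSet:
    """Read a 1-based inclusive BED-like feature table (chrom, start, end, ...)."""
    fr = _read_table(path)
    for col in ("chrom", "start", "end"):
        if col not in fr.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    fr["start"] = pd.to_numeric(fr["start"]).astype(np.int64)
    fr["end"] = pd.to_numeric(fr["end"]).astype(np.int64)
    for col in ("score", "strength"):
        if col in fr.columns:
            fr[col] = pd.to_numeric(fr[col])
    return FeatureSet(frame=fr, label=label or Path(path).stem)


def write_features(features: FeatureSet, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        features.frame.to_csv(fh, sep="\t", index=False)


def write_peaks(peaks: list[Peak], path) -> None:
    """Write called peaks (chrom, summit, height, rank), strongest first."""
    fr = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "summit": [p.summit for p in peaks],
            "height": [p.height for p in peaks],
            "rank": [p.rank for p in peaks],
        }
    ).sort_values("rank")
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fr.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_peaks(path) -> list[Peak]:
    fr = _read_table(path)
    return [
        Peak(
            chrom=row["chrom"],
            summit=int(row["summit"]),
            height=float(row["height"]),
            rank=int(row["rank"]),
        )
        for _, row in fr.sort_values("rank", key=lambda s: s.astype(int)).iterrows()
    ]


def read_tetrads(path) -> list[TetradCounts]:
    """Read a tetrad table: strain, interval, PD, NPD, T (tab-delimited)."""
    fr = _read_table(path)
    for col in ("strain", "interval", "PD", "NPD", "T"):
        if col not in fr.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        TetradCounts(
            PD=int(row["PD"]),
            NPD=int(row["NPD"]),
            T=int(row["T"]),
            interval=row["interval"],
            strain=row["strain"],
        )
        for _, row in fr.iterrows()
    ]


def write_tetrads(tetrads: list[TetradCounts], path) -> None:
    fr = pd.DataFrame(
        {
            "strain": [t.strain for t in tetrads],
            "interval": [t.interval for t in tetrads],
            "PD": [t.PD for t in tetrads],
            "NPD": [t.NPD for t in tetrads],
            "T": [t.T for t in tetrads],
        }
    )
    fr.to_csv(path, sep="\t", index=False)
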