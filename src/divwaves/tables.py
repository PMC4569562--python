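"""Tabular output: TSV traces and histograms, JSON summaries.

All writers emit headers; all readers accept their own writers' output.
TSV is used for anything row-shaped (diff-able, greppable); JSON for
summaries and the reproducibility manifest.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .analysis import SADHistogram, WaveSummary, WaveStats

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_diversity_tsv",
    "read_diversity_tsv",
    "write_sad_tsv",
    "read_sad_tsv",
    "write_waves_tsv",
    "write_jumps_tsv",
    "write_json",
    "read_json",
]

PathLike = Union[str, Path]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def write_json(data: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_events_tsv(events, path: PathLike) -> None:
    """Event log: one row per collapse step."""
    from .analysis import _events_frame

    df = _events_frame(events)
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_diversity_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_diversity_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sad_tsv(hist: SADHistogram, path: PathLike) -> None:
    """Log-binned SAD with its metadata in '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# bins_per_decade={hist.bins_per_decade}\n")
        fh.write(f"# n_snapshots={hist.n_snapshots}\n")
        fh.write(f"# n_species={hist.n_species or 0}\n")
        hist.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_sad_tsv(path: PathLike) -> SADHistogram:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, value = line[1:].strip().split("=")
            meta[key.strip()] = int(value)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    hist = SADHistogram(
        low=float(df["bin_low"].iloc[0]),
        bins_per_decade=meta["bins_per_decade"],
    )
    counts = df["count"].to_numpy(dtype=np.int64)
    if counts.size != hist.n_bins:  # writer's grid is authoritative
        hist.counts = counts
        hist._lo_log = math.log10(float(df["bin_low"].iloc[0]))
    else:
        hist.counts = counts
    hist.n_snapshots = meta["n_snapshots"]
    hist.n_species = meta["n_species"] or None
    return hist


def write_waves_tsv(
    waves: WaveStats, path: PathLike, summary: WaveSummary = None
) -> None:
    """One row per complete wave: start step, duration, decay constant."""
    durations = waves.durations
    decay = (
        summary.decay_constants
        if summary is not None
        else np.full(durations.size, np.nan)
    )
    pd.DataFrame(
        {
            "start": waves.boundaries[:-1],
            "duration": durations,
            "decay_constant": decay,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_jumps_tsv(jumps: pd.DataFrame, path: PathLike) -> None:
    jumps.to_csv(path, sep="\t", index=False, float_format="%.10g")
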