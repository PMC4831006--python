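"""CSV/JSON serialization of droplet tables, traces, fields and tallies."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gradient import GradientField
from .occupancy import OccupancyCount
from .synth import DropletRecord
from .traces import DropletSegment, Trace

__all__ = [
    "droplets_to_frame",
    "write_droplets_csv",
    "read_counts_csv",
    "write_counts_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_field_csv",
    "write_profile_csv",
    "segments_to_frame",
    "write_segments_csv",
    "write_results_json",
    "write_plate_manifest_csv",
]


def droplets_to_frame(droplets: Sequence[DropletRecord], species_names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for d in droplets:
        row = {"droplet_id": d.droplet_id, "volume_nL": d.volume_nl}
        for name, k in zip(species_names, d.founders):
            row[f"founders_{name}"] = k
        row["growth"] = d.growth
        row["fluorescent"] = d.fluorescent
        rows.append(row)
    return pd.DataFrame(rows)


def write_droplets_csv(path, droplets: Sequence[DropletRecord], species_names: Sequence[str]) -> None:
    droplets_to_frame(droplets, species_names).to_csv(path, index=False)


def read_counts_csv(path) -> pd.DataFrame:
    """Read an occupancy-count table (condition, n_total, n_growth[, n_fluor, n_growth_nonfluor])."""
    df = pd.read_csv(path)
    required = {"condition", "n_total", "n_growth"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts CSV must have columns {sorted(required)}")
    return df


def write_counts_csv(path, rows: dict[str, OccupancyCount]) -> None:
    recs = []
    for condition, c in rows.items():
        recs.append(
            {
                "condition": condition,
                "n_total": c.n_total,
                "n_growth": c.n_growth,
                "n_fluor": c.n_fluor if c.n_fluor is not None else "",
                "n_growth_nonfluor": c.n_growth_nonfluor if c.n_growth_nonfluor is not None else "",
            }
        )
    pd.DataFrame(recs).to_csv(path, index=False)


def write_trace_csv(path, bright: Trace, fluor: Trace | None = None) -> None:
    data = {"time_s": np.arange(len(bright.values)) / bright.sample_rate, "bright": bright.values}
    if fluor is not None:
        data["fluor"] = fluor.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_trace_csv(path, sample_rate: float | None = None) -> tuple[Trace, Trace | None]:
    df = pd.read_csv(path)
    if sample_rate is None:
        t = df["time_s"].to_numpy()
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    bright = Trace(df["bright"].to_numpy(), sample_rate)
    fluor = Trace(df["fluor"].to_numpy(), sample_rate) if "fluor" in df else None
    return bright, fluor


def write_field_csv(path, fieldobj: GradientField) -> None:
    """Concentration matrix with x (rows, um) and y (columns, um) headers."""
    df = pd.DataFrame(fieldobj.concentration, index=fieldobj.x, columns=fieldobj.y)
    df.index.name = "x_um"
    df.to_csv(path)


def write_profile_csv(path, y: np.ndarray, profile: np.ndarray) -> None:
    pd.DataFrame({"y_um": y, "concentration": profile}).to_csv(path, index=False)


def segments_to_frame(segments: Sequence[DropletSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_idx": s.start_idx,
                "end_idx": s.end_idx,
                "front_peak_idx": s.front_peak_idx,
                "back_peak_idx": s.back_peak_idx,
                "plateau_amplitude": s.plateau_amplitude,
                "label": s.label,
            }
            for s in segments
        ]
    )


def write_segments_csv(path, segments: Sequence[DropletSegment]) -> None:
    segments_to_frame(segments).to_csv(path, index=False)


def write_results_json(path, results: dict) -> None:
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")


def write_plate_manifest_csv(path, segments: Sequence[DropletSegment]) -> None:
    """Per-droplet label manifest for scale-up streaking onto agar plates.

    Position is the droplet's order in the train, which is the order droplets
    are deposited along the streak.
    """
    df = segments_to_frame(segments)
    df.insert(0, "plate_position", np.arange(1, len(df) + 1))
    df[["plate_position", "label"]].to_csv(path, index=False)
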