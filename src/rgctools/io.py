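"""Spike-train exchange format.

Populations travel as one long-format table (CSV, or HDF5 via pandas
when the filename ends in ``.h5``) with columns::

    cell_id, retina_id, condition, age_months, sex, cell_type, spike_time_s

one row per spike, plus a ``duration_s`` column repeated per cell
(format version 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .receptive_fields import SpikeTrain

FORMAT_VERSION = 1
COLUMNS = [
    "cell_id", "retina_id", "condition", "age_months",
    "sex", "cell_type", "spike_time_s", "duration_s",
]

__all__ = ["write_spike_table", "read_spike_table", "COLUMNS", "FORMAT_VERSION"]


def spike_table(trains: list[SpikeTrain]) -> pd.DataFrame:
    frames = []
    for tr in trains:
        md = tr.metadata
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "retina_id": md.get("retina_id"),
                    "condition": md.get("condition"),
                    "age_months": md.get("age_months"),
                    "sex": md.get("sex"),
                    "cell_type": md.get("cell_type"),
                    "spike_time_s": tr.spike_times_s,
                    "duration_s": tr.duration_s,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COLUMNS)


def write_spike_table(trains: list[SpikeTrain], path: str | Path) -> None:
    path = Path(path)
    df = spike_table(trains)
    if path.suffix == ".h5":
        df.to_hdf(path, key="spikes", mode="w")
    else:
        df.to_csv(path, index=False)


def read_spike_table(path: str | Path) -> list[SpikeTrain]:
    path = Path(path)
    if path.suffix == ".h5":
        df = pd.read_hdf(path, key="spikes")
    else:
        df = pd.read_csv(path)
    trains = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        first = sub.iloc[0]
        trains.append(
            SpikeTrain(
                spike_times_s=np.sort(sub["spike_time_s"].to_numpy(dtype=float)),
                cell_id=str(cell_id),
                duration_s=float(first["duration_s"]),
                metadata={
                    k: first[k]
                    for k in ("retina_id", "condition", "age_months", "sex", "cell_type")
                    if k in sub.columns
                },
            )
        )
    return trains
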