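"""TSV interchange between pipeline stages.

All intermediates are tab-separated text: traces (cell_id, time_s,
intensity), ground-truth events (cell_id, event_time_s, event_type),
detected series (cell_id, t0_s, exclusion_reason), intervals
(cell_id, dt_s).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .event_detection import EventSeries, IntensityTrace
from .synthetic_data import TrueEvents

__all__ = [
    "traces_to_frame", "frame_to_traces", "write_traces", "read_traces",
    "write_truth", "read_truth", "write_series", "read_series",
    "write_intervals", "read_intervals", "write_events",
]


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    rows = [(tr.cell_id, t, v)
            for tr in traces for t, v in zip(tr.times, tr.intensities)]
    return pd.DataFrame(rows, columns=["cell_id", "time_s", "intensity"])


def frame_to_traces(df: pd.DataFrame) -> list[IntensityTrace]:
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_s")
        out.append(IntensityTrace(cell_id=int(cid),
                                  times=grp["time_s"].to_numpy(),
                                  intensities=grp["intensity"].to_numpy()))
    return out


def write_traces(path, traces: list[IntensityTrace]) -> None:
    traces_to_frame(traces).to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")


def read_traces(path) -> list[IntensityTrace]:
    return frame_to_traces(pd.read_csv(path, sep="\t"))


def write_truth(path, events: list[TrueEvents]) -> None:
    rows = []
    for ev in events:
        rows.append((ev.cell_id, ev.intake_completion_time, "intake"))
        for t in ev.production_times:
            rows.append((ev.cell_id, t, "production"))
        for _ in range(ev.initial_rna_count):
            rows.append((ev.cell_id, 0.0, "initial_rna"))
    pd.DataFrame(rows, columns=["cell_id", "event_time_s", "event_type"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_truth(path) -> list[TrueEvents]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        intake = float(grp.loc[grp.event_type == "intake", "event_time_s"].iloc[0])
        prod = np.sort(grp.loc[grp.event_type == "production",
                               "event_time_s"].to_numpy(dtype=float))
        n0 = int((grp.event_type == "initial_rna").sum())
        out.append(TrueEvents(cell_id=int(cid), intake_completion_time=intake,
                              production_times=prod, initial_rna_count=n0))
    return out


def write_series(path, series: list[EventSeries]) -> None:
    rows = [(s.cell_id,
             "NA" if s.t0 is None else f"{s.t0:.6g}",
             s.exclusion_reason or "none") for s in series]
    pd.DataFrame(rows, columns=["cell_id", "t0_s", "exclusion_reason"]
                 ).to_csv(path, sep="\t", index=False)


def read_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["t0_s"] = pd.to_numeric(df["t0_s"], errors="coerce")
    return df


def write_intervals(path, series: list[EventSeries]) -> None:
    rows = [(s.cell_id, dt) for s in series for dt in s.intervals]
    pd.DataFrame(rows, columns=["cell_id", "dt_s"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_intervals(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_events(path, series: list[EventSeries]) -> None:
    rows = [(s.cell_id, t) for s in series for t in s.production_times]
    pd.DataFrame(rows, columns=["cell_id", "event_time_s"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.6g")
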