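"""Tabular I/O for traces, profiles, durations and ground truth.

All files are tidy delimiter-separated tables with hour-suffixed column
names (``time_h`` etc.) so units cannot drift.  Reading validates headers
and per-cell invariants; malformed cells are skipped with a logged warning
rather than failing the whole file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CellTrace, DataError, DurationSet, SwitchPath, TranscriptionProfile

__all__ = [
    "read_traces",
    "write_traces",
    "read_profiles",
    "write_profiles",
    "write_durations",
    "read_durations",
    "write_ground_truth",
    "read_ground_truth",
]

log = logging.getLogger("txcycle")

TRACE_COLUMNS = ["cell_id", "reporter", "time_h", "intensity", "treatment"]
PROFILE_COLUMNS = ["cell_id", "reporter", "time_h", "tau", "alphaM"]
DURATION_COLUMNS = ["cell_id", "kind", "duration_h"]
TRUTH_COLUMNS = [
    "cell_id", "reporter", "switch_times_h", "initial_state", "rate_on", "rate_off",
]


def _check_header(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}; expected {expected}")


def write_traces(traces: list[CellTrace], path) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.cell_id, tr.reporter, t, v, tr.treatment))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_traces(path) -> list[CellTrace]:
    df = pd.read_csv(path)
    _check_header(df, TRACE_COLUMNS, path)
    traces = []
    for (cid, rep), grp in df.groupby(["cell_id", "reporter"], sort=False):
        if grp[["time_h", "intensity"]].isna().any().any():
            log.warning("%s: cell %s/%s has missing values; skipped", path, cid, rep)
            continue
        times = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise DataError(
                f"{path}: cell {cid}/{rep} times not strictly increasing "
                f"(first offending row index {int(grp.index[np.argmin(np.diff(times) > 0) + 1])})"
            )
        traces.append(
            CellTrace(
                cell_id=str(cid),
                reporter=str(rep),
                times=times,
                values=grp["intensity"].to_numpy(dtype=float),
                treatment=str(grp["treatment"].iloc[0]),
            )
        )
    return traces


def write_profiles(profiles: list[TranscriptionProfile], path) -> None:
    rows = []
    for pr in profiles:
        for t, tau, am in zip(pr.grid, pr.tau, pr.mrna):
            rows.append((pr.cell_id, pr.reporter, t, tau, am))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles(path) -> list[TranscriptionProfile]:
    df = pd.read_csv(path)
    _check_header(df, PROFILE_COLUMNS, path)
    out = []
    for (cid, rep), grp in df.groupby(["cell_id", "reporter"], sort=False):
        out.append(
            TranscriptionProfile(
                grid=grp["time_h"].to_numpy(dtype=float),
                tau=grp["tau"].to_numpy(dtype=float),
                mrna=grp["alphaM"].to_numpy(dtype=float),
                cell_id=str(cid),
                reporter=str(rep),
            )
        )
    return out


def write_durations(sets: list[DurationSet], path) -> None:
    rows = []
    for ds in sets:
        for kind, arr in (
            ("on", ds.on_durations),
            ("off", ds.off_durations),
            ("period", ds.periods),
        ):
            for d in arr:
                rows.append((ds.cell_id, kind, d))
    pd.DataFrame(rows, columns=DURATION_COLUMNS).to_csv(path, index=False)


def read_durations(path) -> list[DurationSet]:
    df = pd.read_csv(path)
    _check_header(df, DURATION_COLUMNS, path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        out.append(
            DurationSet(
                on_durations=grp.loc[grp["kind"] == "on", "duration_h"].to_numpy(float),
                off_durations=grp.loc[grp["kind"] == "off", "duration_h"].to_numpy(float),
                periods=grp.loc[grp["kind"] == "period", "duration_h"].to_numpy(float),
                cell_id=str(cid),
            )
        )
    return out


def write_ground_truth(paths: list[tuple[str, str, SwitchPath]], path) -> None:
    """Sidecar file of true switch paths: one row per cell/reporter."""
    rows = []
    for cid, rep, sp in paths:
        rows.append(
            (
                cid,
                rep,
                ";".join(f"{t:.6f}" for t in sp.switch_times),
                sp.initial_state,
                sp.levels[1],
                sp.levels[0],
            )
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_ground_truth(path, duration: float) -> list[tuple[str, str, SwitchPath]]:
    df = pd.read_csv(path)
    _check_header(df, TRUTH_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        s = str(row["switch_times_h"])
        times = np.array([float(x) for x in s.split(";")]) if s and s != "nan" else np.empty(0)
        out.append(
            (
                str(row["cell_id"]),
                str(row["reporter"]),
                SwitchPath(
                    switch_times=times[times < duration],
                    initial_state=str(row["initial_state"]),
                    levels=(float(row["rate_off"]), float(row["rate_on"])),
                    duration=duration,
                ),
            )
        )
    return out
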