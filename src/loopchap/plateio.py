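"""Plate-reader CSV and well-map I/O.

Two plate dialects are accepted: *long* form with columns
``time_s, well, signal`` and *wide* form with a ``time_s`` column followed
by one column per well.  The well map is a TSV mapping each well to its
assay metadata (substrate, chaperone, ratio, replicate).
"""
from __future__ import annotations

from typing import Sequence

import pandas as pd

from .activity import AggregationTrace
from .errors import TraceError


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate CSV in long or wide form; returns long form."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"time_s", "well", "signal"} <= cols:
        return df[["time_s", "well", "signal"]].copy()
    if "time_s" in cols and len(cols) > 1:
        long = df.melt(id_vars="time_s", var_name="well", value_name="signal")
        return long.dropna(subset=["signal"]).reset_index(drop=True)
    raise TraceError(
        "plate CSV must be long (time_s, well, signal) or wide (time_s + wells)"
    )


def read_well_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"well", "substrate", "chaperone", "ratio", "replicate"}
    if not required <= set(df.columns):
        raise TraceError(f"well map needs columns {sorted(required)}")
    df = df.copy()
    df["chaperone"] = df["chaperone"].fillna("").astype(str)
    return df


def traces_from_plate(
    plate: pd.DataFrame,
    well_map: pd.DataFrame,
    temperature: float | None = None,
) -> list[AggregationTrace]:
    """Join a long-form plate table with its well map into traces."""
    merged = plate.merge(well_map, on="well", how="inner")
    if merged.empty:
        raise TraceError("no wells shared between plate data and well map")
    traces = []
    for well, grp in merged.groupby("well", sort=True):
        grp = grp.sort_values("time_s")
        meta = grp.iloc[0]
        chap = str(meta["chaperone"]) or None
        ratio = meta["ratio"]
        traces.append(
            AggregationTrace(
                times=grp["time_s"].to_numpy(dtype=float),
                signal=grp["signal"].to_numpy(dtype=float),
                substrate=str(meta["substrate"]),
                chaperone=chap if chap not in ("", "nan", "none") else None,
                ratio=float(ratio) if pd.notna(ratio) else None,
                replicate=int(meta["replicate"]),
                temperature=temperature,
            )
        )
    return traces


def group_traces(traces: Sequence[AggregationTrace]) -> dict:
    """Group traces by (chaperone, ratio); key (None, None) is the control."""
    groups: dict = {}
    for tr in traces:
        groups.setdefault((tr.chaperone, tr.ratio), []).append(tr)
    return groups


def write_plate_csv(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False)


def write_well_map(well_map: pd.DataFrame, path) -> None:
    well_map.to_csv(path, sep="\t", index=False)
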