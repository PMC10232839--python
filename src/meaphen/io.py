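"""Readers and writers for the pipeline's delimited text formats.

All files are comma-separated UTF-8 with a header row:

* spike list: ``time_s,electrode,well``
* plate map: ``well,plate,genotype,drug,dose_mM,condition``
* feature table: ``plate,well,div,<feature...>`` (missing cells empty); a
  leading ``# normalized: true/false`` comment records normalization state
* burst table: ``well,electrode,start_s,end_s,n_spikes``
* TEVC trace: ``time_s,current_uA``; protocol: ``label,conc_mM,start_s,end_s``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    FeatureTable,
    PlateMap,
    ProtocolSegment,
    RecordingMeta,
    SpikeList,
    TEVCTrace,
)


class ParseError(ValueError):
    """A malformed row in a delimited input file."""


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", encoding="utf-8")


def read_spike_list(
    path, meta: RecordingMeta, known_wells: list[str] | None = None
) -> SpikeList:
    """Read and validate a spike-list CSV.

    Raises :class:`ParseError` naming the first offending line for malformed
    rows, and ``ValueError`` for times beyond ``meta.duration`` or wells not
    in ``known_wells`` (when given).
    """
    df = _read_csv(path)
    required = ["time_s", "electrode", "well"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.isna() & df["time_s"].notna() | df["time_s"].isna()
    if bad.any():
        # +2: 1-based line numbers plus the header row
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"{path}: malformed time value on line {line}")
    df = df.assign(time_s=times.astype(float))
    if known_wells is not None:
        unknown = sorted(set(df["well"].astype(str)) - set(known_wells))
        if unknown:
            raise ValueError(f"{path}: unknown wells {unknown}")
    df["electrode"] = df["electrode"].astype(str)
    df["well"] = df["well"].astype(str)
    return SpikeList(spikes=df, duration=meta.duration)


def write_spike_list(spikes: SpikeList, path) -> None:
    spikes.spikes[["time_s", "electrode", "well"]].to_csv(path, index=False)


def read_plate_map(path) -> PlateMap:
    df = _read_csv(path)
    return PlateMap(table=df)


def write_plate_map(pmap: PlateMap, path) -> None:
    pmap.table.to_csv(path, index=False)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table; missing cells become empty fields."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# normalized: {str(table.normalized).lower()}\n")
        table.data.reset_index().to_csv(fh, index=False)


def read_feature_table(path) -> FeatureTable:
    """Read a feature table; duplicate (plate, well, div) keys are an error."""
    path = Path(path)
    normalized = False
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            normalized = "true" in first.lower()
    df = _read_csv(path)
    for col in FeatureTable.INDEX_NAMES:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["div"] = df["div"].astype(int)
    df = df.set_index(list(FeatureTable.INDEX_NAMES))
    return FeatureTable(data=df, normalized=normalized)


def write_bursts(bursts_df: pd.DataFrame, path) -> None:
    cols = ["well", "electrode", "start_s", "end_s", "n_spikes"]
    bursts_df[cols].to_csv(path, index=False)


def read_bursts(path) -> pd.DataFrame:
    return _read_csv(path)


def write_tevc_trace(trace: TEVCTrace, trace_path, protocol_path) -> None:
    pd.DataFrame({"time_s": trace.time, "current_uA": trace.current}).to_csv(
        trace_path, index=False
    )
    pd.DataFrame(
        [
            {
                "label": s.label,
                "conc_mM": s.conc_mM,
                "start_s": s.start,
                "end_s": s.end,
            }
            for s in trace.protocol
        ]
    ).to_csv(protocol_path, index=False)


def read_tevc_trace(trace_path, protocol_path) -> TEVCTrace:
    tdf = _read_csv(trace_path)
    for col in ("time_s", "current_uA"):
        if col not in tdf.columns:
            raise ParseError(f"{trace_path}: missing column {col!r}")
    pdf = _read_csv(protocol_path)
    segments = [
        ProtocolSegment(
            label=str(r.label),
            conc_mM=float(r.conc_mM) if not pd.isna(r.conc_mM) else float("nan"),
            start=float(r.start_s),
            end=float(r.end_s),
        )
        for r in pdf.itertuples()
    ]
    return TEVCTrace(
        time=tdf["time_s"].to_numpy(float),
        current=tdf["current_uA"].to_numpy(float),
        protocol=segments,
    )


def read_dose_points(path) -> pd.DataFrame:
    """Read a pre-computed ``conc_mM,percent_inhibition`` table."""
    df = _read_csv(path)
    for col in ("conc_mM", "percent_inhibition"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df
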