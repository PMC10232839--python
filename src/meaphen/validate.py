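"""Plate-level consistency checks (report-only, never mutating)."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import MAX_ELECTRODES_PER_WELL, PlateMap, RecordingMeta, SpikeList


@dataclass
class PlateReport:
    """Outcome of :func:`validate_plate`; passes iff every list is empty."""

    unmapped_wells: list[str] = field(default_factory=list)
    overfull_wells: list[str] = field(default_factory=list)
    out_of_range_times: list[tuple[str, float]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unmapped_wells or self.overfull_wells or self.out_of_range_times)


def validate_plate(
    spikes: SpikeList | pd.DataFrame, pmap: PlateMap, meta: RecordingMeta
) -> PlateReport:
    """List unmapped wells, wells with too many electrodes, out-of-range times.

    Accepts either a validated :class:`SpikeList` or a raw spike table
    (``time_s, electrode, well``), so that files a :class:`SpikeList` would
    refuse to construct can still be diagnosed.
    """
    report = PlateReport()
    mapped = set(pmap.wells())
    df = spikes.spikes if isinstance(spikes, SpikeList) else spikes
    for well in sorted(df["well"].unique().tolist()):
        if well not in mapped:
            report.unmapped_wells.append(well)
        sub = df[df["well"] == well]
        if sub["electrode"].nunique() > MAX_ELECTRODES_PER_WELL:
            report.overfull_wells.append(well)
    t = df["time_s"]
    bad = df[(t < 0) | (t > meta.duration)]
    for r in bad.itertuples():
        report.out_of_range_times.append((str(r.well), float(r.time_s)))
    return report
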