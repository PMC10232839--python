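"""Activity QC and per-well feature extraction.

QC mirrors standard MEA practice: an electrode is *active* when it fires at
least ``active_spikes_per_min`` spikes per minute (inclusive threshold); a
well is dropped when the fraction of its recorded days with fewer than
``min_active_electrodes`` active electrodes exceeds one half (strict >).
Features are computed on active electrodes only.

Headline features (units in parentheses):

* ``nAE`` — number of active electrodes;
* ``mfr`` (Hz) — total spikes on active electrodes / (duration x nAE);
* ``bursts_per_min`` — total bursts / minutes / nAE;
* ``mean_burst_duration`` (s), ``mean_ibi`` (s), ``mean_spikes_per_burst``;
* ``intraburst_rate`` (Hz) — sum of spikes in bursts / sum of burst durations;
* ``ibi_cv`` — coefficient of variation of inter-burst intervals, a proxy
  for the periodicity of bursting;
* ``pct_spikes_in_ns`` (%), ``mean_mi`` (bits), ``mean_sttc``.

Burst features are NaN for wells with no bursts; IBI features need at least
one electrode with two bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burst import BurstParams, bursts_by_electrode
from .netsync import SyncParams, detect_network_spikes, well_synchrony
from .types import Burst, FeatureTable, PlateMap, RecordingMeta, SpikeList

BURST_FEATURES = (
    "bursts_per_min",
    "mean_burst_duration",
    "mean_ibi",
    "mean_spikes_per_burst",
    "intraburst_rate",
    "ibi_cv",
)
SYNC_FEATURES = ("pct_spikes_in_ns", "mean_mi", "mean_sttc")
ALL_FEATURES = ("nae", "mfr") + BURST_FEATURES + SYNC_FEATURES


@dataclass(frozen=True)
class QCParams:
    """Activity thresholds for electrode- and well-level QC."""

    active_spikes_per_min: float = 5.0
    min_active_electrodes: int = 4
    max_inactive_div_fraction: float = 0.5  # strict > removes the well

    def __post_init__(self) -> None:
        if not self.active_spikes_per_min >= 0:
            raise ValueError("active_spikes_per_min must be >= 0")
        if self.min_active_electrodes < 1:
            raise ValueError("min_active_electrodes must be >= 1")


def electrode_is_active(
    train: np.ndarray, duration: float, spikes_per_min: float = 5.0
) -> bool:
    """True iff the electrode fires >= ``spikes_per_min`` spikes per minute."""
    if not duration > 0:
        raise ValueError("duration must be > 0")
    return len(train) / (duration / 60.0) >= spikes_per_min


def active_trains(
    trains: dict[str, np.ndarray], duration: float, qc: QCParams | None = None
) -> dict[str, np.ndarray]:
    """Subset of a well's trains passing the electrode activity threshold."""
    if qc is None:
        qc = QCParams()
    return {
        e: t
        for e, t in trains.items()
        if electrode_is_active(t, duration, qc.active_spikes_per_min)
    }


def filter_wells(nae: pd.DataFrame, qc: QCParams | None = None) -> list[str]:
    """Wells kept by the multi-day activity filter.

    ``nae`` is a wells x DIVs table of active-electrode counts (NaN for
    unrecorded days).  A well is removed iff the fraction of its recorded
    days with nAE below ``min_active_electrodes`` exceeds
    ``max_inactive_div_fraction`` (strict >).
    """
    if qc is None:
        qc = QCParams()
    kept: list[str] = []
    for well, row in nae.iterrows():
        vals = row.dropna()
        if len(vals) == 0:
            continue
        frac_low = float((vals < qc.min_active_electrodes).mean())
        if not frac_low > qc.max_inactive_div_fraction:
            kept.append(well)
    return kept


def compute_well_features(
    trains: dict[str, np.ndarray],
    duration: float,
    bursts: dict[str, list[Burst]] | None = None,
    burst_params: BurstParams | None = None,
    sync_params: SyncParams | None = None,
) -> dict[str, float]:
    """Feature dict for one well from its *active* electrode trains.

    ``trains`` should already have passed electrode QC; bursts are detected
    here unless supplied.  Results are invariant to electrode relabelling
    and to the order of spikes within the input.
    """
    if burst_params is None:
        burst_params = BurstParams()
    if sync_params is None:
        sync_params = SyncParams()
    nae = len(trains)
    out: dict[str, float] = {f: float("nan") for f in ALL_FEATURES}
    out["nae"] = float(nae)
    if nae == 0:
        return out

    total_spikes = sum(len(t) for t in trains.values())
    out["mfr"] = total_spikes / (duration * nae)

    if bursts is None:
        bursts = bursts_by_electrode(trains, burst_params)
    flat = [b for bs in bursts.values() for b in bs]
    if flat:
        durations = np.array([b.duration for b in flat])
        counts = np.array([b.n_spikes for b in flat], dtype=float)
        out["bursts_per_min"] = len(flat) / (duration / 60.0) / nae
        out["mean_burst_duration"] = float(durations.mean())
        out["mean_spikes_per_burst"] = float(counts.mean())
        total_dur = float(durations.sum())
        out["intraburst_rate"] = float(counts.sum()) / total_dur if total_dur > 0 else float("nan")
        ibis = np.concatenate(
            [
                np.array([nb.start - pb.end for pb, nb in zip(bs, bs[1:])])
                for bs in bursts.values()
                if len(bs) >= 2
            ]
            or [np.array([])]
        )
        if ibis.size:
            out["mean_ibi"] = float(ibis.mean())
            if ibis.size >= 2 and ibis.mean() > 0:
                out["ibi_cv"] = float(ibis.std(ddof=1) / ibis.mean())

    events = detect_network_spikes(trains, duration, sync_params)
    pct, mean_mi, mean_sttc = well_synchrony(trains, duration, sync_params, events=events)
    out["pct_spikes_in_ns"] = pct
    out["mean_mi"] = mean_mi
    out["mean_sttc"] = mean_sttc
    return out


def build_feature_table(
    spikelists: dict[int, SpikeList],
    pmap: PlateMap,
    metas: dict[int, RecordingMeta],
    qc: QCParams | None = None,
    burst_params: BurstParams | None = None,
    sync_params: SyncParams | None = None,
) -> tuple[FeatureTable, dict]:
    """QC + features for one plate across its recorded DIVs.

    ``spikelists``/``metas`` map DIV -> recording.  Returns the raw feature
    table (kept wells only) and a QC log with the removed wells and the
    per-DIV active-electrode counts.
    """
    if qc is None:
        qc = QCParams()
    divs = sorted(spikelists)
    wells = pmap.wells()
    plate = str(pmap.table["plate"].iloc[0])

    trains_by_div = {d: spikelists[d].trains() for d in divs}
    active_by_div: dict[int, dict[str, dict[str, np.ndarray]]] = {}
    nae = pd.DataFrame(index=wells, columns=divs, dtype=float)
    for d in divs:
        duration = metas[d].duration
        active_by_div[d] = {}
        for well in wells:
            tr = trains_by_div[d].get(well, {})
            act = active_trains(tr, duration, qc)
            active_by_div[d][well] = act
            nae.loc[well, d] = len(act)

    kept = filter_wells(nae, qc)
    removed = sorted(set(wells) - set(kept))

    rows = []
    for d in divs:
        duration = metas[d].duration
        for well in kept:
            feats = compute_well_features(
                active_by_div[d][well], duration, burst_params=burst_params, sync_params=sync_params
            )
            rows.append({"plate": plate, "well": well, "div": d, **feats})
    table = FeatureTable.from_rows(rows)
    log = {"plate": plate, "removed_wells": removed, "nae": nae, "n_kept": len(kept)}
    return table, log
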