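#!/usr/bin/env python
"""Detect bursts, apply activity QC and build the per-well feature table.

Reads the spike lists written by ``01_simulate_mea.py``, runs
Maximum-Interval burst detection and network-spike detection, removes
inactive electrodes and wells, computes the per-well features, and writes
both the raw and the WT-normalized tables under ``results/mea/``.
"""

from pathlib import Path

import pandas as pd

from meaphen import io
from meaphen.config import AnalysisConfig
from meaphen.features import build_feature_table
from meaphen.stats import normalize_to_wt
from meaphen.types import RecordingMeta

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = AnalysisConfig()
    simdir = ROOT / "results" / "mea" / "sim"
    outdir = ROOT / "results" / "mea"
    pmap = io.read_plate_map(simdir / "plate_map.csv")
    meta_df = pd.read_csv(simdir / "meta.csv")

    spikelists, metas = {}, {}
    for row in meta_df.itertuples():
        meta = RecordingMeta(plate_id=str(row.plate), div=int(row.div), duration=float(row.duration_s))
        metas[meta.div] = meta
        spikelists[meta.div] = io.read_spike_list(
            simdir / f"spikes_div{meta.div}.csv", meta, known_wells=pmap.wells()
        )

    table, qc_log = build_feature_table(
        spikelists, pmap, metas, qc=cfg.qc, burst_params=cfg.burst, sync_params=cfg.sync
    )
    norm = normalize_to_wt(table, pmap)
    io.write_feature_table(table, outdir / "features_raw.csv")
    io.write_feature_table(norm, outdir / "features_normalized.csv")

    print(
        f"kept {qc_log['n_kept']} of {len(pmap.wells())} wells "
        f"(removed: {qc_log['removed_wells'] or 'none'})"
    )
    summary = (
        table.data.join(pmap.genotype_series(), on="well")
        .groupby("genotype")[["mfr", "bursts_per_min", "mean_burst_duration", "mean_ibi"]]
        .mean()
        .round(3)
    )
    print("\nper-genotype feature means (raw):")
    print(summary.to_string())
    print(f"\ntables -> {outdir}/features_raw.csv, features_normalized.csv")


if __name__ == "__main__":
    main()
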