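"""End-to-end orchestration: simulate/load -> detect -> features -> stats.

``run_mea_pipeline`` reproduces the genotype-comparison workflow: burst and
network-event detection, QC, the per-well feature table, per-plate WT
normalization, label-permutation Mann-Whitney tests per plate, and Fisher
combination across plates.  ``run_dose_pipeline`` reproduces the oocyte
workflow: protocol segmentation, % inhibition and the three model fits.
Both are deterministic given (config, seed) and log every threshold used.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .dose import fit_all_models, percent_inhibition, segment_steady_state
from .features import build_feature_table
from .stats import fisher_combine, genotype_comparison, normalize_to_wt
from .synth import generate_plate, generate_tevc, standard_etx_protocol
from .types import DoseFitParams, FeatureTable, PlateMap, RecordingMeta, SpikeList, TEVCTrace


@dataclass
class MEAResult:
    """Bundle returned by :func:`run_mea_pipeline`."""

    features_raw: dict[str, FeatureTable]
    features_norm: dict[str, FeatureTable]
    per_plate_stats: pd.DataFrame  # plate, feature, p_raw, p_perm, direction
    combined: pd.DataFrame  # feature, p_fisher, direction
    qc_logs: list[dict]
    run_log: list[str] = field(default_factory=list)


def run_mea_pipeline(
    plates: dict[str, tuple[dict[int, SpikeList], PlateMap, dict[int, RecordingMeta]]],
    config: AnalysisConfig | None = None,
    divs: list[int] | None = None,
    features: list[str] | None = None,
    seed: int = 0,
) -> MEAResult:
    """Full genotype comparison over one or more plates.

    ``plates`` maps plate id -> (spike lists per DIV, plate map, metas).
    Per plate: QC + feature extraction, WT normalization, permuted MWU on
    per-well DIV-combined values; then Fisher combination of the per-plate
    permutation p-values per feature.  The reported direction is the mean
    over plates of (mutant - WT) normalized means.
    """
    if config is None:
        config = AnalysisConfig()
    log = [f"config: {asdict(config.burst)} {asdict(config.sync)} {asdict(config.qc)}"]
    log.append(f"stats: n_perm={config.stats.n_perm} combine={config.stats.div_combine}")
    log.append(f"seed: {seed}")

    features_raw: dict[str, FeatureTable] = {}
    features_norm: dict[str, FeatureTable] = {}
    qc_logs = []
    per_plate_rows = []
    for k, (plate_id, (spikelists, pmap, metas)) in enumerate(sorted(plates.items())):
        table, qc_log = build_feature_table(
            spikelists, pmap, metas,
            qc=config.qc, burst_params=config.burst, sync_params=config.sync,
        )
        norm = normalize_to_wt(table, pmap)
        features_raw[plate_id] = table
        features_norm[plate_id] = norm
        qc_logs.append(qc_log)
        log.append(
            f"plate {plate_id}: kept {qc_log['n_kept']} wells, "
            f"removed {len(qc_log['removed_wells'])}"
        )
        stats = genotype_comparison(
            norm, pmap, divs=divs, features=features,
            params=config.stats, seed=seed + k,
        )
        stats.insert(0, "plate", plate_id)
        per_plate_rows.append(stats)
    per_plate = pd.concat(per_plate_rows, ignore_index=True)

    combined_rows = []
    for feat, sub in per_plate.groupby("feature", sort=False):
        combined_rows.append(
            {
                "feature": feat,
                "n_plates": len(sub),
                "p_fisher": fisher_combine(sub["p_perm"]),
                "direction": float(sub["direction"].mean()),
            }
        )
    combined = pd.DataFrame(combined_rows)
    return MEAResult(
        features_raw=features_raw,
        features_norm=features_norm,
        per_plate_stats=per_plate,
        combined=combined,
        qc_logs=qc_logs,
        run_log=log,
    )


def simulate_and_run(
    config: AnalysisConfig | None = None,
    seed: int = 0,
    n_plates: int = 1,
    divs: list[int] | None = None,
    features: list[str] | None = None,
) -> MEAResult:
    """Simulate plates under the configured presets and analyse them."""
    if config is None:
        config = AnalysisConfig()
    presets = {"WT": config.wt, "K78R": config.k78r}
    plates = {}
    for k in range(n_plates):
        plate_id = f"P{k + 1}"
        plates[plate_id] = generate_plate(
            config.sim.n_wells_per_genotype,
            config.sim.duration,
            list(config.sim.divs),
            seed=seed + 1000 * k,
            presets=presets,
            plate_id=plate_id,
        )
    return run_mea_pipeline(plates, config, divs=divs, features=features, seed=seed)


@dataclass
class DoseResult:
    """Bundle returned by :func:`run_dose_pipeline`."""

    points: pd.DataFrame  # conc_mM, percent_inhibition
    fits: pd.DataFrame  # one row per model, ranked by AICc
    run_log: list[str] = field(default_factory=list)


def run_dose_pipeline(
    traces: list[TEVCTrace] | None = None,
    points: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    truth: DoseFitParams | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> DoseResult:
    """Segment traces, compute % inhibition, fit the three models.

    Give ``traces`` (or ``points`` with columns conc_mM, percent_inhibition)
    to analyse measured data; with neither, one trace is simulated from
    ``truth`` (default: one-site isotherm with Kd_app = 1 mM).  Per-trace
    points are pooled for fitting.
    """
    if config is None:
        config = AnalysisConfig()
    log = [f"steady-state window {config.steady.window} s, guard {config.steady.switch_guard} s"]
    if points is None:
        if traces is None:
            if truth is None:
                truth = DoseFitParams(model="one_site", kd_app=1.0)
            log.append(f"simulated trace from {truth.model} truth, noise {noise_sd} uA")
            traces = [
                generate_tevc(
                    standard_etx_protocol(),
                    girk_max=-4.0,
                    leak=-1.0,
                    inhibition=truth,
                    noise_sd=noise_sd,
                    seed=seed,
                )
            ]
        rows = []
        for trace in traces:
            segs = segment_steady_state(trace, config.steady)
            rows.extend(percent_inhibition(segs))
        points = pd.DataFrame(rows, columns=["conc_mM", "percent_inhibition"])
    fits = fit_all_models(
        points["conc_mM"].to_numpy(float), points["percent_inhibition"].to_numpy(float)
    )
    fit_df = pd.DataFrame([
        {
            "model": f.model,
            "kd_app": f.kd_app,
            "n_h": f.n_h,
            "c": f.c,
            "kd1_app": f.kd1_app,
            "kd2_app": f.kd2_app,
            "rss": f.rss,
            "aicc": f.aicc,
        }
        for f in fits
    ]).sort_values("aicc").reset_index(drop=True)
    log.append(f"fitted {len(fits)} models on {len(points)} points")
    return DoseResult(points=points, fits=fit_df, run_log=log)
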