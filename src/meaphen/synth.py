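"""Synthetic MEA spike trains and TEVC traces with known ground truth.

The MEA generator emulates the statistical structure the downstream
analysis assumes: well-level network bursts recruiting electrodes with a
participation probability and small onset jitter, Poisson spiking inside
bursts, an independent tonic Poisson background per electrode, and genotype
presets that differ along the phenotype axes (burst frequency, burst
duration, inter-burst interval, spikes per burst, within-burst rate) while
keeping synchrony parameters equal.

Burst onsets follow a renewal process: successive onsets are separated by
the burst's own duration plus a dead time (``min_burst_gap``) plus an
exponential waiting time whose mean is chosen so the marginal onset rate
equals ``burst_rate`` exactly.  The dead time keeps distinct generated
bursts distinct under the Maximum-Interval detector's 0.8 s merge rule, so
generator parameters are recoverable by the analysis they feed.

The TEVC generator renders the standard solution-exchange protocol
(ND96 -> HK24 -> increasing ETX steps -> Ba2+) with a chosen inhibition
model, first-order settling at each solution switch, and Gaussian noise.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dose import eval_model
from .types import (
    DoseFitParams,
    PlateMap,
    ProtocolSegment,
    RecordingMeta,
    SpikeList,
    TEVCTrace,
    electrode_ids,
    validate_protocol,
)

#: fields interpolated by :func:`apply_drug`
_INTERP_FIELDS = (
    "tonic_rate",
    "burst_rate",
    "burst_duration_mean",
    "burst_duration_shape",
    "intraburst_rate",
    "participation_prob",
    "onset_jitter_sd",
)
#: rate fields additionally scaled by the overshoot suppression factor
_RATE_FIELDS = ("tonic_rate", "burst_rate", "intraburst_rate")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one well's spike-train generator.

    Rates are per the units in the field names; ``burst_rate`` is bursts per
    minute at the well level, ``intraburst_rate`` is Hz per participating
    electrode, ``tonic_rate`` is Hz per electrode.
    """

    tonic_rate: float = 0.5  # Hz per electrode
    burst_rate: float = 12.0  # bursts/min per well
    burst_duration_mean: float = 0.4  # s
    burst_duration_shape: float = 4.0  # gamma shape
    intraburst_rate: float = 60.0  # Hz per participating electrode
    participation_prob: float = 1.0
    onset_jitter_sd: float = 0.01  # s across electrodes
    n_active_electrodes: int = 16
    min_burst_gap: float = 1.0  # s dead time between burst end and next onset

    def __post_init__(self) -> None:
        for name in ("tonic_rate", "burst_rate", "intraburst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must lie in [0, 1]")
        if not self.burst_duration_mean > 0:
            raise ValueError("burst_duration_mean must be > 0")
        if not self.burst_duration_shape > 0:
            raise ValueError("burst_duration_shape must be > 0")
        if not 1 <= self.n_active_electrodes <= 16:
            raise ValueError("n_active_electrodes must lie in 1..16")
        if self.onset_jitter_sd < 0:
            raise ValueError("onset_jitter_sd must be >= 0")


#: genotype presets: directions follow the mutant phenotype (fewer, longer
#: bursts with longer inter-burst intervals, more spikes per burst at a lower
#: within-burst rate); magnitudes are this package's documented defaults.
_PRESETS = {
    "WT": GeneratorParams(
        tonic_rate=0.5,
        burst_rate=12.0,
        burst_duration_mean=0.4,
        intraburst_rate=60.0,
    ),
    "K78R": GeneratorParams(
        tonic_rate=0.5,
        burst_rate=3.0,
        burst_duration_mean=3.0,
        intraburst_rate=35.0,
    ),
}


def genotype_preset(label: str) -> GeneratorParams:
    """Generator parameters for a genotype label ('WT' or 'K78R')."""
    try:
        return _PRESETS[label]
    except KeyError:
        raise ValueError(f"unknown genotype label {label!r}") from None


@dataclass(frozen=True)
class DrugEffectModel:
    """Concentration-dependent pull of generator parameters toward a target.

    The interpolation weight is a Hill function of dose,
    ``w = dose^n / (dose^n + EC50_eff^n)``; at or above ``overshoot_dose``
    all rates are additionally multiplied by ``suppression`` to emulate the
    high-dose overshoot where activity falls below the rescue target.
    """

    ec50_eff: float = 0.5  # mM
    n_eff: float = 2.0
    overshoot_dose: float = 2.0  # mM
    suppression: float = 0.3

    def __post_init__(self) -> None:
        if not self.ec50_eff > 0:
            raise ValueError("ec50_eff must be > 0")
        if not self.n_eff > 0:
            raise ValueError("n_eff must be > 0")
        if not 0.0 < self.suppression <= 1.0:
            raise ValueError("suppression must lie in (0, 1]")

    def weight(self, dose: float) -> float:
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if dose == 0:
            return 0.0
        xn = dose**self.n_eff
        return xn / (xn + self.ec50_eff**self.n_eff)


def apply_drug(
    params: GeneratorParams,
    dose: float,
    effect: DrugEffectModel,
    target: GeneratorParams,
) -> GeneratorParams:
    """Move ``params`` toward ``target`` by the dose-dependent Hill weight.

    Componentwise ``params + w(dose) * (target - params)`` over the float
    parameters; at ``dose >= overshoot_dose`` every rate is then multiplied
    by the suppression factor.
    """
    w = effect.weight(dose)
    updates = {
        f: getattr(params, f) + w * (getattr(target, f) - getattr(params, f))
        for f in _INTERP_FIELDS
    }
    if dose >= effect.overshoot_dose:
        for f in _RATE_FIELDS:
            updates[f] = updates[f] * effect.suppression
    return replace(params, **updates)


# ---------------------------------------------------------------------------
# MEA spike trains


def _burst_onsets_and_durations(
    params: GeneratorParams, duration: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Renewal-process burst onsets with their gamma-distributed durations."""
    if params.burst_rate <= 0:
        return np.array([]), np.array([])
    mean_interval = 60.0 / params.burst_rate
    theta = mean_interval - params.burst_duration_mean - params.min_burst_gap
    if theta <= 0:
        raise ValueError(
            "burst_rate too high for burst_duration_mean + min_burst_gap: "
            f"mean interval {mean_interval:.3f} s cannot accommodate them"
        )
    shape = params.burst_duration_shape
    scale = params.burst_duration_mean / shape
    onsets, durs = [], []
    t = rng.exponential(theta)
    while t < duration:
        d = rng.gamma(shape, scale)
        onsets.append(t)
        durs.append(d)
        t = t + d + params.min_burst_gap + rng.exponential(theta)
    return np.asarray(onsets), np.asarray(durs)


def generate_well(
    params: GeneratorParams,
    duration: float,
    seed: int | np.random.Generator,
    well: str = "A1",
) -> SpikeList:
    """One well of bursty, partially synchronous spike trains.

    Well-level burst onsets are drawn first; each burst recruits each of the
    ``n_active_electrodes`` electrodes with ``participation_prob``, jitters
    its onset by a Gaussian of sd ``onset_jitter_sd``, and fills the burst
    with a Poisson process at ``intraburst_rate``.  Tonic spikes are an
    independent Poisson process at ``tonic_rate`` per electrode.  Spikes
    falling outside [0, duration] are dropped.  Deterministic given seed.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    electrodes = electrode_ids()[: params.n_active_electrodes]
    n_e = len(electrodes)

    onsets, durs = _burst_onsets_and_durations(params, duration, rng)
    n_b = onsets.size

    parts: list[np.ndarray] = []
    elec_idx_parts: list[np.ndarray] = []
    if n_b:
        jitter = rng.normal(0.0, params.onset_jitter_sd, size=(n_b, n_e))
        counts = rng.poisson(params.intraburst_rate * durs[:, None], size=(n_b, n_e))
        if params.participation_prob < 1.0:
            mask = rng.random((n_b, n_e)) < params.participation_prob
            counts = counts * mask
        total = int(counts.sum())
        u = rng.random(total)
        onset_e = (onsets[:, None] + jitter).ravel()
        dur_e = np.broadcast_to(durs[:, None], counts.shape).ravel()
        eidx = np.broadcast_to(np.arange(n_e)[None, :], counts.shape).ravel()
        reps = counts.ravel()
        parts.append(np.repeat(onset_e, reps) + u * np.repeat(dur_e, reps))
        elec_idx_parts.append(np.repeat(eidx, reps))

    tonic_counts = rng.poisson(params.tonic_rate * duration, size=n_e)
    if tonic_counts.sum():
        parts.append(rng.random(int(tonic_counts.sum())) * duration)
        elec_idx_parts.append(np.repeat(np.arange(n_e), tonic_counts))

    if parts:
        times = np.concatenate(parts)
        eidx = np.concatenate(elec_idx_parts)
        keep = (times >= 0.0) & (times <= duration)
        times, eidx = times[keep], eidx[keep]
        order = np.lexsort((times, eidx))
        times, eidx = times[order], eidx[order]
        trains = {
            electrodes[k]: times[eidx == k] for k in np.unique(eidx)
        }
    else:
        trains = {}
    return SpikeList.from_trains({well: trains}, duration)


def _well_names(n: int) -> list[str]:
    """Row-major 48-well plate labels A1..F8."""
    rows = "ABCDEF"
    names = [f"{r}{c}" for r in rows for c in range(1, 9)]
    if n > len(names):
        raise ValueError("a 48-well plate holds at most 48 wells")
    return names[:n]


def generate_plate(
    n_wells_per_genotype: int,
    duration: float,
    divs: list[int],
    seed: int,
    presets: dict[str, GeneratorParams] | None = None,
    plate_id: str = "P1",
    div_scale: dict[int, float] | None = None,
) -> tuple[dict[int, SpikeList], PlateMap, dict[int, RecordingMeta]]:
    """A full simulated plate: per-DIV spike lists, plate map, metadata.

    The first ``n_wells_per_genotype`` wells are WT, the next are K78R.
    Each (well, DIV) gets its own generator seeded by the deterministic
    sequence ``(seed, well_index, div_index)``.  ``div_scale`` optionally
    multiplies every rate by a per-DIV maturation factor (default: none).
    """
    if n_wells_per_genotype < 1:
        raise ValueError("need at least one well per genotype")
    if presets is None:
        presets = {g: genotype_preset(g) for g in ("WT", "K78R")}
    genotypes = ["WT"] * n_wells_per_genotype + ["K78R"] * n_wells_per_genotype
    wells = _well_names(len(genotypes))

    pmap = PlateMap(
        table=pd.DataFrame(
            {
                "well": wells,
                "plate": plate_id,
                "genotype": genotypes,
                "drug": "none",
                "dose_mM": 0.0,
                "condition": "baseline",
            }
        )
    )
    spikelists: dict[int, SpikeList] = {}
    metas: dict[int, RecordingMeta] = {}
    for d_idx, div in enumerate(divs):
        scale = 1.0 if div_scale is None else div_scale.get(div, 1.0)
        frames = []
        for w_idx, (well, geno) in enumerate(zip(wells, genotypes)):
            p = presets[geno]
            if scale != 1.0:
                p = replace(
                    p,
                    tonic_rate=p.tonic_rate * scale,
                    burst_rate=p.burst_rate * scale,
                    intraburst_rate=p.intraburst_rate * scale,
                )
            rng = np.random.default_rng([seed, w_idx, d_idx])
            sl = generate_well(p, duration, rng, well=well)
            frames.append(sl.spikes)
        spikelists[div] = SpikeList(
            spikes=pd.concat(frames, ignore_index=True), duration=duration
        )
        metas[div] = RecordingMeta(plate_id=plate_id, div=div, duration=duration)
    return spikelists, pmap, metas


# ---------------------------------------------------------------------------
# TEVC traces


def standard_etx_protocol(
    etx_concs_mM=(0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0),
    nd96_s: float = 5.0,
    step_s: float = 30.0,
    ba_s: float = 30.0,
) -> list[ProtocolSegment]:
    """The standard inhibition protocol: ND96, HK24, ETX steps, Ba2+ block."""
    segments = [ProtocolSegment(label="ND96", start=0.0, end=nd96_s)]
    t = nd96_s
    segments.append(ProtocolSegment(label="HK24", start=t, end=t + step_s))
    t += step_s
    for c in etx_concs_mM:
        segments.append(ProtocolSegment(label="ETX", conc_mM=float(c), start=t, end=t + step_s))
        t += step_s
    segments.append(ProtocolSegment(label="BA", start=t, end=t + ba_s))
    validate_protocol(segments)
    return segments


def generate_tevc(
    protocol: list[ProtocolSegment],
    girk_max: float,
    leak: float,
    inhibition: DoseFitParams,
    noise_sd: float = 0.0,
    sampling: float = 100.0,
    seed: int | np.random.Generator = 0,
    settle_tau: float = 0.25,
) -> TEVCTrace:
    """Render a TEVC current trace for a protocol and inhibition model.

    Target current is ``leak`` in ND96 and BA segments and
    ``leak + girk_max * (1 - inh(x)/100)`` in HK24/ETX segments (x = 0 in
    plain HK24, where ``inh(0) = 0``).  At each solution switch the current
    relaxes exponentially toward the new target with time constant
    ``settle_tau`` (0 for instant switching); Gaussian noise of sd
    ``noise_sd`` is added throughout.  Deterministic given seed.
    """
    validate_protocol(protocol)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = protocol[-1].end
    n = int(round(total * sampling))
    t = np.arange(n) / sampling

    def target(seg: ProtocolSegment) -> float:
        if seg.label in ("ND96", "BA"):
            return leak
        x = seg.conc_mM if seg.label == "ETX" else 0.0
        inh = float(eval_model(inhibition.model, inhibition, x)) if x > 0 else 0.0
        return leak + girk_max * (1.0 - inh / 100.0)

    current = np.empty(n)
    level_prev = target(protocol[0])
    for seg in protocol:
        mask = (t >= seg.start) & (t < seg.end) if seg is not protocol[-1] else (t >= seg.start)
        lvl = target(seg)
        if settle_tau > 0:
            current[mask] = lvl + (level_prev - lvl) * np.exp(-(t[mask] - seg.start) / settle_tau)
        else:
            current[mask] = lvl
        level_prev = lvl
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=n)
    return TEVCTrace(time=t, current=current, protocol=list(protocol))
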