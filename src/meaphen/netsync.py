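"""Well-level network events and pairwise synchrony measures.

Three measures are provided:

* network spikes — fixed 10 ms bins (anchored at t=0) in which at least
  ``min_electrodes`` electrodes fire; consecutive supra-threshold bins merge
  into one :class:`~meaphen.types.NetworkEvent`;
* the spike-time tiling coefficient (STTC), a firing-rate-insensitive
  pairwise correlation in [-1, 1], computed with the standard published
  definition (the coincidence window ``sttc_dt`` defaults to 50 ms);
* plug-in mutual information (bits) between the binary bin occupancies of
  two trains, used for "nearby" (rook-adjacent) electrode pairs.

Network bursts (coincident electrode-level bursts) are a parameterized
reconstruction computed analogously over burst spans; the exact definition
used on the original platform is not public, so that function is offered as
a labelled approximation and is not part of the headline feature set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .types import Burst, NetworkEvent, rook_adjacent


@dataclass(frozen=True)
class SyncParams:
    """Binning and participation thresholds for the synchrony measures."""

    ns_bin: float = 0.01  # s, network-spike window
    min_electrodes: int = 5  # >25% of 16
    sttc_dt: float = 0.05  # s
    mi_bin: float = 0.1  # s

    def __post_init__(self) -> None:
        for name in ("ns_bin", "sttc_dt", "mi_bin"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_electrodes < 2:
            raise ValueError("min_electrodes must be >= 2")


def _occupancy(train: np.ndarray, bin_s: float, n_bins: int) -> np.ndarray:
    """Boolean per-bin occupancy of a train on a fixed grid from t=0."""
    idx = np.minimum((np.asarray(train, float) / bin_s).astype(np.int64), n_bins - 1)
    occ = np.zeros(n_bins, dtype=bool)
    occ[idx] = True
    return occ


def detect_network_spikes(
    trains: dict[str, np.ndarray], duration: float, p: SyncParams | None = None
) -> list[NetworkEvent]:
    """Network spikes of one well from its per-electrode trains.

    A bin is supra-threshold when >= ``min_electrodes`` electrodes have at
    least one spike in it; consecutive supra-threshold bins merge into one
    event whose participants are the union over its bins.
    """
    if p is None:
        p = SyncParams()
    if not duration > 0:
        raise ValueError("duration must be > 0")
    electrodes = [e for e, t in trains.items() if len(t)]
    if len(electrodes) < p.min_electrodes:
        return []
    n_bins = int(np.ceil(duration / p.ns_bin))
    occ = np.vstack([_occupancy(trains[e], p.ns_bin, n_bins) for e in electrodes])
    supra = occ.sum(axis=0) >= p.min_electrodes
    edges = np.flatnonzero(np.diff(np.concatenate(([False], supra, [False])).astype(np.int8)))
    events: list[NetworkEvent] = []
    for a, b in zip(edges[0::2], edges[1::2]):
        participants = frozenset(
            e for k, e in enumerate(electrodes) if occ[k, a:b].any()
        )
        events.append(
            NetworkEvent(start=a * p.ns_bin, end=b * p.ns_bin, participants=participants)
        )
    return events


def percent_spikes_in_ns(
    trains: dict[str, np.ndarray], events: list[NetworkEvent]
) -> float:
    """Percentage of the well's spikes falling inside any network event.

    Returns NaN when the well has no spikes at all, 0 when there are spikes
    but no events.
    """
    all_t = np.concatenate([np.asarray(t, float) for t in trains.values()]) if trains else np.array([])
    if all_t.size == 0:
        return float("nan")
    if not events:
        return 0.0
    starts = np.array([ev.start for ev in events])
    ends = np.array([ev.end for ev in events])
    idx = np.searchsorted(starts, all_t, side="right") - 1
    inside = (idx >= 0) & (all_t < ends[np.clip(idx, 0, None)])
    return 100.0 * float(inside.sum()) / all_t.size


def _tiled_fraction(train: np.ndarray, dt: float, T: float) -> float:
    """Fraction of [0, T] covered by +/- dt windows around the spikes."""
    lo = np.clip(train - dt, 0.0, T)
    hi = np.clip(train + dt, 0.0, T)
    prev_hi = np.concatenate(([-np.inf], np.maximum.accumulate(hi)[:-1]))
    covered = np.clip(hi - np.maximum(lo, prev_hi), 0.0, None).sum()
    return float(covered) / T


def _prop_within(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Proportion of spikes of ``a`` within dt of any spike of ``b``."""
    pos = np.searchsorted(b, a)
    left = np.where(pos > 0, a - b[np.clip(pos - 1, 0, None)], np.inf)
    right = np.where(pos < b.size, b[np.clip(pos, None, b.size - 1)] - a, np.inf)
    return float(np.mean(np.minimum(left, right) <= dt))


def sttc(
    train_a: np.ndarray, train_b: np.ndarray, dt: float = 0.05, T: float | None = None
) -> float:
    """Spike-time tiling coefficient of two trains on [0, T].

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ],
    where T_X is the fraction of the recording tiled by +/- dt around X's
    spikes (clipped to [0, T], overlaps counted once) and P_X the proportion
    of X's spikes within dt of any spike of the other train.  NaN when either
    train is empty.
    """
    if T is None or not T > 0:
        raise ValueError("recording length T must be > 0")
    a = np.asarray(train_a, float)
    b = np.asarray(train_b, float)
    if a.size == 0 or b.size == 0:
        return float("nan")

    ta = _tiled_fraction(a, dt, T)
    tb = _tiled_fraction(b, dt, T)
    pa = _prop_within(a, b, dt)
    pb = _prop_within(b, a, dt)

    def term(p: float, t: float) -> float:
        denom = 1.0 - p * t
        if denom <= 0.0:
            # p = t = 1: the train pair tiles everything; take the limit 1
            return 1.0 if p == 1.0 else 0.0
        return (p - t) / denom

    return 0.5 * (term(pa, tb) + term(pb, ta))


def mutual_information(
    train_a: np.ndarray, train_b: np.ndarray, bin_s: float = 0.1, T: float | None = None
) -> float:
    """Plug-in mutual information (bits) of binary bin occupancies.

    Each train is binarized into occupancy of consecutive ``bin_s`` bins on
    [0, T]; MI is computed from the empirical 2x2 joint distribution.  Always
    >= 0; exactly 0 when either marginal is degenerate (e.g. a silent train).
    """
    if T is None or not T > 0:
        raise ValueError("recording length T must be > 0")
    n_bins = int(np.ceil(T / bin_s))
    a = _occupancy(np.asarray(train_a, float), bin_s, n_bins)
    b = _occupancy(np.asarray(train_b, float), bin_s, n_bins)
    joint = np.array(
        [
            [np.sum(~a & ~b), np.sum(~a & b)],
            [np.sum(a & ~b), np.sum(a & b)],
        ],
        dtype=float,
    )
    p = joint / n_bins
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pa * pb))
    mi = float(np.nansum(terms))
    return max(mi, 0.0)


def well_synchrony(
    trains: dict[str, np.ndarray],
    duration: float,
    p: SyncParams | None = None,
    events: list[NetworkEvent] | None = None,
) -> tuple[float, float, float]:
    """(percent spikes in network spikes, mean MI over rook-adjacent pairs,
    mean STTC over all pairs) for one well.

    Pairwise measures run over electrodes with at least one spike; components
    are NaN when undefined (fewer than two usable electrodes / no adjacent
    pairs).
    """
    if p is None:
        p = SyncParams()
    if events is None:
        events = detect_network_spikes(trains, duration, p)
    pct = percent_spikes_in_ns(trains, events)

    active = sorted(e for e, t in trains.items() if len(t))
    sttc_vals = [
        sttc(trains[a], trains[b], dt=p.sttc_dt, T=duration)
        for a, b in itertools.combinations(active, 2)
    ]
    mi_vals = [
        mutual_information(trains[a], trains[b], bin_s=p.mi_bin, T=duration)
        for a, b in itertools.combinations(active, 2)
        if rook_adjacent(a, b)
    ]
    mean_sttc = float(np.mean(sttc_vals)) if sttc_vals else float("nan")
    mean_mi = float(np.mean(mi_vals)) if mi_vals else float("nan")
    return pct, mean_mi, mean_sttc


def detect_network_bursts(
    bursts: dict[str, list[Burst]],
    duration: float,
    p: SyncParams | None = None,
    bin_s: float = 0.01,
) -> list[NetworkEvent]:
    """Coincident electrode-level bursts across >= ``min_electrodes``.

    Reconstruction: the well is binned like network-spike detection, but a
    bin counts an electrode when it lies inside one of that electrode's burst
    spans.  Reported separately from the headline features.
    """
    if p is None:
        p = SyncParams()
    n_bins = int(np.ceil(duration / bin_s))
    electrodes = [e for e, bs in bursts.items() if bs]
    if len(electrodes) < p.min_electrodes:
        return []
    occ = np.zeros((len(electrodes), n_bins), dtype=bool)
    for k, e in enumerate(electrodes):
        for b in bursts[e]:
            i0 = int(b.start / bin_s)
            i1 = min(int(np.ceil(b.end / bin_s)), n_bins)
            occ[k, i0 : max(i1, i0 + 1)] = True
    supra = occ.sum(axis=0) >= p.min_electrodes
    edges = np.flatnonzero(np.diff(np.concatenate(([False], supra, [False])).astype(np.int8)))
    events: list[NetworkEvent] = []
    for a, b in zip(edges[0::2], edges[1::2]):
        participants = frozenset(e for k, e in enumerate(electrodes) if occ[k, a:b].any())
        events.append(NetworkEvent(start=a * bin_s, end=b * bin_s, participants=participants))
    return events
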