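"""Maximum-Interval burst detection on single-electrode spike trains.

The detector uses two inter-spike-interval (ISI) thresholds: a burst is
initiated at spike *i* when the ISI to the next spike is at most
``max_begin_isi`` and is extended while successive ISIs stay at or below
``max_end_isi``.  Raw bursts separated by less than ``min_ibi_merge`` are
then merged (transitively), and bursts shorter than ``min_duration`` or
holding fewer than ``min_spikes`` spikes are discarded.

Boundary semantics: the two ISI thresholds are maxima and compared with
``<=``; the merge gap is compared with strict ``<``.  Burst duration is
last spike time minus first spike time.  Simultaneous timestamps (ISI = 0)
are allowed and count as within-burst intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Burst


@dataclass(frozen=True)
class BurstParams:
    """Thresholds of the Maximum-Interval detector (all times in seconds)."""

    max_begin_isi: float = 0.1
    max_end_isi: float = 0.25
    min_ibi_merge: float = 0.8
    min_duration: float = 0.05
    min_spikes: int = 5
    #: if False, the size/duration filter runs before merging instead of after
    merge_before_filter: bool = True

    def __post_init__(self) -> None:
        for name in ("max_begin_isi", "max_end_isi", "min_ibi_merge", "min_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be >= 1")
        if self.max_end_isi < self.max_begin_isi:
            raise ValueError("max_end_isi must be >= max_begin_isi")


def detect_raw_bursts(
    train: np.ndarray, p: BurstParams, electrode: str | None = None
) -> list[Burst]:
    """Maximal, non-overlapping raw bursts of a sorted spike train.

    No merging or size filtering happens here; see :func:`merge_and_filter`.
    """
    t = np.asarray(train, float)
    if t.size < 2:
        return []
    isi = np.diff(t)
    if np.any(isi < 0):
        raise ValueError("spike train must be sorted non-decreasing")
    end_ok = isi <= p.max_end_isi
    begin_ok = isi <= p.max_begin_isi
    # maximal runs of end-qualifying ISIs; ISI j connects spikes j and j+1
    edges = np.flatnonzero(np.diff(np.concatenate(([False], end_ok, [False])).astype(np.int8)))
    bursts: list[Burst] = []
    for a, b in zip(edges[0::2], edges[1::2]):
        # burst starts at the first begin-qualifying ISI inside the run and
        # extends to the run's last spike (all later ISIs are end-qualifying)
        rel = np.flatnonzero(begin_ok[a:b])
        if rel.size:
            i = a + int(rel[0])
            bursts.append(
                Burst(start=float(t[i]), end=float(t[b]), n_spikes=int(b - i + 1), electrode=electrode)
            )
    return bursts


def merge_and_filter(bursts: list[Burst], p: BurstParams) -> list[Burst]:
    """Merge bursts closer than ``min_ibi_merge`` then drop sub-threshold ones.

    Merging is transitive: spike counts are summed and spans unioned.  With
    ``merge_before_filter=False`` the size/duration filter is applied first.
    """
    def _merge(bs: list[Burst]) -> list[Burst]:
        out: list[Burst] = []
        for b in bs:
            if out and (b.start - out[-1].end) < p.min_ibi_merge:
                prev = out[-1]
                out[-1] = Burst(
                    start=prev.start,
                    end=max(prev.end, b.end),
                    n_spikes=prev.n_spikes + b.n_spikes,
                    electrode=prev.electrode,
                )
            else:
                out.append(b)
        return out

    def _filter(bs: list[Burst]) -> list[Burst]:
        return [
            b
            for b in bs
            if b.duration >= p.min_duration and b.n_spikes >= p.min_spikes
        ]

    ordered = sorted(bursts, key=lambda b: b.start)
    if p.merge_before_filter:
        return _filter(_merge(ordered))
    return _merge(_filter(ordered))


def detect_bursts(
    train: np.ndarray, p: BurstParams | None = None, electrode: str | None = None
) -> list[Burst]:
    """Full Maximum-Interval detection: raw detection, merge, filters."""
    if p is None:
        p = BurstParams()
    return merge_and_filter(detect_raw_bursts(train, p, electrode=electrode), p)


def bursts_by_electrode(
    trains: dict[str, np.ndarray], p: BurstParams | None = None
) -> dict[str, list[Burst]]:
    """Detect bursts on every electrode train of a well."""
    if p is None:
        p = BurstParams()
    return {e: detect_bursts(t, p, electrode=e) for e, t in trains.items()}
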