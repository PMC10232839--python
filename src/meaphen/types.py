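"""Shared domain containers for the MEA and oocyte-pharmacology pipelines.

Conventions used throughout the package:

* time is in seconds, zero-based from the start of a recording;
* currents are in microamperes (uA);
* drug concentrations are stored in millimolar (mM);
* electrodes live on a 4x4 grid and are named ``r{row}c{col}`` (1-based,
  row-major), e.g. ``r1c1`` .. ``r4c4``;
* missing feature values are ``NaN`` (never silently zero).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_ROWS = 4
GRID_COLS = 4
MAX_ELECTRODES_PER_WELL = GRID_ROWS * GRID_COLS

GENOTYPES = ("WT", "K78R")

_ELECTRODE_RE = re.compile(r"^r([1-4])c([1-4])$")


def electrode_ids() -> list[str]:
    """All 16 electrode labels of the 4x4 grid, row-major."""
    return [f"r{r}c{c}" for r in range(1, GRID_ROWS + 1) for c in range(1, GRID_COLS + 1)]


def electrode_position(electrode: str) -> tuple[int, int]:
    """Parse an ``r{row}c{col}`` label into 1-based (row, col)."""
    m = _ELECTRODE_RE.match(electrode)
    if m is None:
        raise ValueError(f"not a valid electrode id: {electrode!r}")
    return int(m.group(1)), int(m.group(2))


def rook_adjacent(a: str, b: str) -> bool:
    """True when two electrodes are horizontal/vertical neighbours on the grid."""
    ra, ca = electrode_position(a)
    rb, cb = electrode_position(b)
    return abs(ra - rb) + abs(ca - cb) == 1


@dataclass(frozen=True)
class RecordingMeta:
    """Identity and extent of one recording session of one plate."""

    plate_id: str
    div: int
    duration: float  # s

    def __post_init__(self) -> None:
        if self.div < 0:
            raise ValueError("DIV must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")


@dataclass
class SpikeList:
    """Timestamped spikes grouped by electrode within wells.

    ``spikes`` has columns ``time_s`` (float), ``electrode`` (str) and
    ``well`` (str), sorted by (well, electrode, time).  This is the
    universal input of the MEA pipeline.
    """

    spikes: pd.DataFrame
    duration: float  # s

    def __post_init__(self) -> None:
        required = ["time_s", "electrode", "well"]
        missing = [c for c in required if c not in self.spikes.columns]
        if missing:
            raise ValueError(f"spike table lacks columns {missing}")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        df = self.spikes
        if len(df):
            t = df["time_s"].to_numpy(float)
            if np.any(t < 0):
                raise ValueError("spike times must be >= 0")
            if np.any(t > self.duration):
                bad = float(t[t > self.duration][0])
                raise ValueError(
                    f"spike time {bad:g} s exceeds recording duration {self.duration:g} s"
                )
            df = df.sort_values(["well", "electrode", "time_s"], kind="mergesort")
            df = df.reset_index(drop=True)
            for well, sub in df.groupby("well", sort=False):
                n_elec = sub["electrode"].nunique()
                if n_elec > MAX_ELECTRODES_PER_WELL:
                    raise ValueError(
                        f"well {well!r} has {n_elec} electrodes (max {MAX_ELECTRODES_PER_WELL})"
                    )
        self.spikes = df

    @classmethod
    def from_trains(
        cls, trains: dict[str, dict[str, np.ndarray]], duration: float
    ) -> "SpikeList":
        """Build from ``{well: {electrode: sorted spike times}}``."""
        times, elecs, wells = [], [], []
        for well in trains:
            for elec, t in trains[well].items():
                t = np.asarray(t, float)
                times.append(t)
                elecs.append(np.full(t.size, elec, dtype=object))
                wells.append(np.full(t.size, well, dtype=object))
        if times:
            df = pd.DataFrame(
                {
                    "time_s": np.concatenate(times),
                    "electrode": np.concatenate(elecs),
                    "well": np.concatenate(wells),
                }
            )
        else:
            df = pd.DataFrame({"time_s": [], "electrode": [], "well": []})
        return cls(spikes=df, duration=duration)

    def wells(self) -> list[str]:
        return sorted(self.spikes["well"].unique().tolist())

    def n_spikes(self) -> int:
        return len(self.spikes)

    def well_trains(self, well: str) -> dict[str, np.ndarray]:
        """Per-electrode sorted spike-time arrays for one well."""
        sub = self.spikes[self.spikes["well"] == well]
        return {
            elec: g["time_s"].to_numpy(float)
            for elec, g in sub.groupby("electrode", sort=True)
        }

    def trains(self) -> dict[str, dict[str, np.ndarray]]:
        out: dict[str, dict[str, np.ndarray]] = {}
        for (well, elec), g in self.spikes.groupby(["well", "electrode"], sort=True):
            out.setdefault(well, {})[elec] = g["time_s"].to_numpy(float)
        return out


@dataclass
class PlateMap:
    """Assignment of genotype and treatment to wells of one plate.

    ``table`` columns: well, plate, genotype, drug, dose_mM, condition.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["well", "plate", "genotype", "drug", "dose_mM", "condition"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"plate map lacks columns {missing}")
        if self.table["well"].duplicated().any():
            dups = self.table.loc[self.table["well"].duplicated(), "well"].tolist()
            raise ValueError(f"duplicate wells in plate map: {dups}")
        bad = set(self.table["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        if (self.table["dose_mM"].fillna(0) < 0).any():
            raise ValueError("doses must be >= 0")
        self.table = self.table.reset_index(drop=True)

    def wells(self) -> list[str]:
        return self.table["well"].tolist()

    def genotype(self, well: str) -> str:
        sub = self.table.loc[self.table["well"] == well, "genotype"]
        if sub.empty:
            raise KeyError(f"well {well!r} not in plate map")
        return str(sub.iloc[0])

    def genotype_series(self) -> pd.Series:
        return self.table.set_index("well")["genotype"]


@dataclass(frozen=True)
class Burst:
    """A detected burst on one electrode: [start, end] with n_spikes spikes."""

    start: float
    end: float
    n_spikes: int
    electrode: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("burst end before start")
        if self.n_spikes < 1:
            raise ValueError("burst must contain spikes")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class NetworkEvent:
    """A short well-level event with a set of participating electrodes."""

    start: float
    end: float
    participants: frozenset[str]

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("network event must have positive extent")


@dataclass
class FeatureTable:
    """Per (plate, well, DIV) activity features.

    ``data`` is indexed by a (plate, well, div) MultiIndex; columns are
    feature names; missing cells are NaN.  ``normalized`` marks tables whose
    values have been divided by the per-plate, per-DIV WT mean.
    """

    data: pd.DataFrame
    normalized: bool = False

    INDEX_NAMES = ("plate", "well", "div")

    def __post_init__(self) -> None:
        idx = self.data.index
        if list(idx.names) != list(self.INDEX_NAMES):
            raise ValueError(f"index must be named {self.INDEX_NAMES}, got {idx.names}")
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].tolist()
            raise ValueError(f"duplicate (plate, well, div) keys: {dups[:5]}")

    @classmethod
    def from_rows(cls, rows: list[dict], normalized: bool = False) -> "FeatureTable":
        """Build from dicts each holding plate/well/div plus feature values."""
        df = pd.DataFrame(rows)
        df = df.set_index(list(cls.INDEX_NAMES))
        return cls(data=df, normalized=normalized)

    def features(self) -> list[str]:
        return list(self.data.columns)


PROTOCOL_LABELS = ("ND96", "HK24", "ETX", "BA")


@dataclass(frozen=True)
class ProtocolSegment:
    """One solution period of a TEVC recording."""

    label: str
    start: float
    end: float
    conc_mM: float = float("nan")  # ETX only

    def __post_init__(self) -> None:
        if self.label not in PROTOCOL_LABELS:
            raise ValueError(f"unknown protocol label {self.label!r}")
        if not self.end > self.start:
            raise ValueError("segment must have positive extent")
        if self.label == "ETX" and not self.conc_mM > 0:
            raise ValueError("ETX segments need a positive concentration")

    @property
    def length(self) -> float:
        return self.end - self.start


def validate_protocol(segments: list[ProtocolSegment]) -> None:
    """Check ordering, coverage and label rules of a solution protocol.

    Segments must be contiguous from t=0, start with ND96, list ETX steps in
    strictly increasing concentration, and end with exactly one BA segment.
    """
    if not segments:
        raise ValueError("empty protocol")
    if segments[0].label != "ND96":
        raise ValueError("protocol must start with an ND96 segment")
    if not math.isclose(segments[0].start, 0.0, abs_tol=1e-9):
        raise ValueError("first segment must start at t=0")
    for prev, cur in zip(segments, segments[1:]):
        if not math.isclose(prev.end, cur.start, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"segments must be contiguous: {prev.label} ends {prev.end}, "
                f"{cur.label} starts {cur.start}"
            )
    ba = [s for s in segments if s.label == "BA"]
    if len(ba) != 1 or segments[-1].label != "BA":
        raise ValueError("protocol must end with exactly one BA segment")
    concs = [s.conc_mM for s in segments if s.label == "ETX"]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("ETX concentrations must be strictly increasing")


@dataclass
class TEVCTrace:
    """A uniformly sampled two-electrode voltage-clamp current trace."""

    time: np.ndarray  # s
    current: np.ndarray  # uA
    protocol: list[ProtocolSegment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.current = np.asarray(self.current, float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        if self.time.size < 2:
            raise ValueError("trace too short")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        validate_protocol(self.protocol)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass
class DoseFitParams:
    """Parameters of a fitted (or specified) dose-inhibition model.

    Models: ``one_site`` (binding isotherm with apparent dissociation constant
    ``kd_app``), ``hill`` (adds Hill coefficient ``n_h``) and ``two_site``
    (high/low affinity sites ``kd1_app``/``kd2_app`` with high-affinity
    fraction ``c``).  Concentrations are mM.
    """

    model: str
    kd_app: float = float("nan")
    n_h: float = float("nan")
    c: float = float("nan")
    kd1_app: float = float("nan")
    kd2_app: float = float("nan")
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")
    aicc: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("one_site", "hill", "two_site"):
            raise ValueError(f"unknown dose-response model {self.model!r}")
        for name in ("kd_app", "kd1_app", "kd2_app"):
            v = getattr(self, name)
            if not math.isnan(v) and not v > 0:
                raise ValueError(f"{name} must be > 0")
        if not math.isnan(self.n_h) and not self.n_h > 0:
            raise ValueError("Hill coefficient must be > 0")
        if not math.isnan(self.c) and not (0.0 <= self.c <= 1.0):
            raise ValueError("high-affinity fraction c must lie in [0, 1]")


@dataclass
class ActivationFitParams:
    """Hill activation fit of current vs. surface expression, n fixed at 4."""

    imax: float  # uA
    kd: float  # AU of surface fluorescence
    n: float = 4.0  # fixed, not fitted
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if not self.imax > 0:
            raise ValueError("Imax must be > 0")
        if not self.kd > 0:
            raise ValueError("Kd must be > 0")
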