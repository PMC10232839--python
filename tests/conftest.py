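import numpy as np
import pandas as pd
import pytest

from meaphen.types import FeatureTable, PlateMap, RecordingMeta, SpikeList


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_plate_map():
    return PlateMap(
        table=pd.DataFrame(
            {
                "well": ["A1", "A2", "A3", "A4"],
                "plate": "P1",
                "genotype": ["WT", "WT", "K78R", "K78R"],
                "drug": "none",
                "dose_mM": 0.0,
                "condition": "baseline",
            }
        )
    )


@pytest.fixture
def meta():
    return RecordingMeta(plate_id="P1", div=15, duration=180.0)


@pytest.fixture
def tiny_spikelist(meta):
    return SpikeList.from_trains(
        {
            "A1": {"r1c1": np.array([0.1, 0.2, 0.3])},
            "A2": {"r1c2": np.array([1.0, 5.0])},
        },
        duration=meta.duration,
    )


def random_feature_table(rng, plates=("P1",), wells=("A1", "A2", "A3", "A4"),
                         divs=(15, 18), features=("f1", "f2"), missing_frac=0.0):
    rows = []
    for p in plates:
        for w in wells:
            for d in divs:
                row = {"plate": p, "well": w, "div": d}
                for f in features:
                    v = float(rng.lognormal(0.0, 0.5))
                    if missing_frac and rng.random() < missing_frac:
                        v = float("nan")
                    row[f] = v
                rows.append(row)
    return FeatureTable.from_rows(rows)
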