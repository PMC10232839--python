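#!/usr/bin/env python
"""Simulate a demonstration MEA plate of WT and K78R wells.

Writes spike-list CSVs (one per DIV) and the plate map under
``results/mea/sim/``.  The demo plate is deliberately smaller than the
default study configuration (8+8 wells, three recording days, 5 min per
recording) so the whole analysis chain reruns in seconds; pass ``--full``
for the study-sized plate (24+24 wells, five days, 15 min).
"""

import argparse
from pathlib import Path

from meaphen import io
from meaphen.config import AnalysisConfig
from meaphen.synth import generate_plate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--full", action="store_true", help="study-sized plate")
    args = ap.parse_args()

    cfg = AnalysisConfig()
    if args.full:
        n, duration, divs = cfg.sim.n_wells_per_genotype, cfg.sim.duration, list(cfg.sim.divs)
    else:
        n, duration, divs = 8, 300.0, [15, 21, 27]

    outdir = ROOT / "results" / "mea" / "sim"
    outdir.mkdir(parents=True, exist_ok=True)
    spikelists, pmap, metas = generate_plate(
        n, duration, divs, seed=args.seed, presets={"WT": cfg.wt, "K78R": cfg.k78r}
    )
    io.write_plate_map(pmap, outdir / "plate_map.csv")
    total = 0
    for div, sl in spikelists.items():
        io.write_spike_list(sl, outdir / f"spikes_div{div}.csv")
        total += sl.n_spikes()
    (outdir / "meta.csv").write_text(
        "plate,div,duration_s\n"
        + "".join(f"{m.plate_id},{m.div},{m.duration}\n" for m in metas.values())
    )
    print(
        f"simulated {2 * n} wells x {len(divs)} DIVs ({duration:g} s each), "
        f"{total} spikes total -> {outdir}"
    )


if __name__ == "__main__":
    main()
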