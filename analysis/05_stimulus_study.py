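#!/usr/bin/env python
"""Transient and continuous pre-patterning stimuli on the sphere.

Applies k-spike equatorial, tetrahedral, ring and spatially uniform
stimuli to the activator — transiently (initial-condition perturbation,
uM) or continuously (forcing, uM/s) — over logarithmic amplitude grids,
on the wild-type and larger domains, and tabulates the resulting labels
together with whether a spike formed at a stimulus site.  Defaults are
scaled down; pass --reps/--amplitudes for denser grids.  Writes
results/stimulus_<mode>_<pattern>.csv.
"""

import argparse
import pathlib

import numpy as np

from pollenpat.experiments import stimulus_campaign, summarize

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

DEFAULT_GRIDS = {
    "transient": np.logspace(-6, 1, 8),   # uM
    "continuous": np.logspace(-6, -1, 6),  # uM/s
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--modes", nargs="*", default=["transient", "continuous"])
    ap.add_argument("--patterns", nargs="*",
                    default=["1-spike", "2-spike", "3-spike", "4-spike",
                             "tetrahedral", "ring", "uniform"])
    ap.add_argument("--amplitudes", nargs="*", type=float, default=None)
    ap.add_argument("--areas", nargs="*", type=float, default=[550.0, 750.0])
    ap.add_argument("--reps", type=int, default=3)
    ap.add_argument("--resolution", type=int, default=4)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    for mode in args.modes:
        amps = args.amplitudes or DEFAULT_GRIDS[mode]
        for pattern in args.patterns:
            result = stimulus_campaign(
                mode, pattern, amps, args.areas, args.reps, args.seed,
                resolution=args.resolution,
            )
            stem = f"stimulus_{mode}_{pattern}"
            result.save(OUT / f"{stem}.csv", OUT / f"{stem}_manifest.json")
            s = summarize(result)
            print(f"== {mode} {pattern} ==")
            print(s.to_string(index=False))


if __name__ == "__main__":
    main()
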