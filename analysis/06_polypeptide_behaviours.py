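#!/usr/bin/env python
"""Cleavage-site-usage behaviour classes of the two-cleavage-site model.

Samples transport/catalysis parameters from the behaviour prior,
classifies the drift of the per-site normalised cleavage usage, and
reports one exemplar parameter set per attainable class.  Also
demonstrates that the relative site usage drifts over time with product
re-entry disabled, so re-entry of products cannot explain usage
variation.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from proteokin.polypeptide import (FragmentSet, cleavage_site_usage,
                                   search_behaviors, simulate_polypeptide)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--samples", type=int, default=3000)
    ap.add_argument("--out", type=Path, default=Path("results/polypeptide"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    exemplars, counts, n_eval = search_behaviors(
        n_samples=args.samples, seed=args.seed, stop_when_complete=False)
    print(f"evaluated {n_eval} prior samples: "
          + ", ".join(f"{k} {v}" for k, v in counts.items()))
    pd.DataFrame([counts]).to_csv(args.out / "label_counts.csv", index=False)
    (args.out / "exemplars.json").write_text(json.dumps(
        exemplars, indent=1, default=float))

    fs = FragmentSet(vin=90.0, vout=3.0, tau=0.2, kon=0.1, kp=15.0,
                     KaS=2.0, KiP=0.2, site_rates=(1.0, 0.2),
                     transport_scale={"S": 1.0, "A": 0.2, "B": 1.6,
                                      "Cfrag": 0.09, "AB": 0.3, "BC": 0.06},
                     product_reentry=False)
    times = np.linspace(15.0, 360.0, 24)
    u = cleavage_site_usage(simulate_polypeptide(fs, 40.0, times))
    u.to_frame().to_csv(args.out / "usage_no_reentry.csv", index=False)
    share = u.flux[0] / (u.flux[0] + u.flux[1])
    print(f"site-1 flux share drifts {share[0]:.2f} -> {share[-1]:.2f} "
          "with product re-entry disabled")


if __name__ == "__main__":
    main()
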