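#!/usr/bin/env python
"""Scaled-down Bayesian model-selection experiments.

Two recovery experiments mirror the staged comparison scheme: the joint
comparison of the four non-compartmental models on Michaelis-Menten
data (the data-generating model M1 should win), and the pairwise
comparison of the transport skeleton M5 against the fully regulated M9
on strongly regulated M9 data (M9 should win).  With --full, the whole
iterative ladder (stage 1, pairwise ascent M5..M9, final re-test) runs
at reduced particle count.
"""

import argparse
from pathlib import Path

import numpy as np

from proteokin.inference import (_distance_matrices, _make_model_simulator,
                                 iterative_selection_scheme)
from proteokin.models import build_model
from proteokin.studies import (_SELECTION_CONCS, _SELECTION_TIMES, _SOLVER,
                               _strong_regulation_fixture,
                               make_selection_problems,
                               selection_m9_vs_m5_study,
                               selection_stage1_study)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/selection"))
    ap.add_argument("--full", action="store_true",
                    help="run the whole iterative ladder (slow)")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    s1 = selection_stage1_study(seed=args.seed)
    s1.probabilities.to_csv(args.out / "stage1_m1_data.csv", index=False)
    print(f"stage 1 (M1 data): winner {s1.winner}, "
          f"P = {s1.final_probabilities[s1.winner]:.3f} after "
          f"{len(s1.probabilities)} populations")

    s2 = selection_m9_vs_m5_study(seed=args.seed)
    s2.probabilities.to_csv(args.out / "m9_vs_m5.csv", index=False)
    print(f"M9 vs M5 (regulated M9 data): winner {s2.winner}, "
          f"P = {s2.final_probabilities[s2.winner]:.3f}")

    if args.full:
        rng = np.random.default_rng(args.seed)
        truth = _strong_regulation_fixture()
        sim = _make_model_simulator(build_model("M9"), truth,
                                    _SELECTION_CONCS, _SELECTION_TIMES,
                                    solver_opts=_SOLVER)
        obs = sim({}, rng) * np.exp(0.05 * rng.standard_normal((3, 6)))
        problems = make_selection_problems(
            obs, truth, [f"M{i}" for i in range(1, 10)])
        winner, history = iterative_selection_scheme(
            lambda mid: problems[mid], obs,
            lambda s, o: _distance_matrices(s, o), seed=args.seed,
            n_particles=60, max_populations=4)
        print(f"full ladder winner: {winner}")
        for label, res in history:
            res.probabilities.to_csv(
                args.out / f"ladder_{label.replace(':', '_')}.csv",
                index=False)
            print(f"  {label}: {res.winner} "
                  f"({res.final_probabilities[res.winner]:.2f})")


if __name__ == "__main__":
    main()
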