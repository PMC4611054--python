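# proteokin

Mechanistic kinetic modelling and likelihood-free inference of peptide
hydrolysis by the 20S proteasome.

The 20S proteasome is a barrel-shaped protease: its catalytic sites sit
inside a central chamber that substrates reach only through gated
antechambers. In fluorogenic digestion assays (Suc-LLVY-MCA, Bz-VGR-MCA,
Z-LLE-MCA) this architecture produces kinetics that Michaelis–Menten
models cannot describe — the reaction velocity *rises* over the first
~90–120 minutes, and product formation is *inhibited* at high substrate
concentrations. `proteokin` implements a family of nine ODE models that
dissect these effects, and the Bayesian machinery to discriminate among
them and to estimate their parameters from time-course data:

* **M1–M4** — non-compartmental rate laws: Michaelis–Menten, a
  two-site-modifier scheme with substrate *and* product inhibition, and
  two positive-feedback variants.
* **M5–M9** — compartmentalised transport models: gate binding
  (`kon`, `koff`), influx/efflux (`v_in`, `v_out`), translocation (`τ`),
  a chamber capacity `C` (molecules per proteasome, entering through a
  saturating `tanh(E0·C − S − P)` influx term), and non-catalytic
  regulatory sites — a transport *enhancer* and a transport *inhibitor*
  whose locations (inside the chamber vs on the outer surface)
  distinguish the variants. M9, the selected topology, has the enhancer
  inside and the inhibitor outside.

Hydrolysis follows the two-site-modifier law

    v_hydr = na·kp·E0 · (S^na/KaS) · (1 + β·S^ni/(α·KiS) + β·P^ni/(α·KiP)) / x
    x = 1 + A + B + A·B/α,   A = S^na/KaS + P^na/KaP,   B = S^ni/KiS + P^ni/KiP

Inference is approximate Bayesian computation with sequential Monte
Carlo (ABC-SMC): adaptive epsilon schedule, component-wise perturbation
kernels, importance weights, and joint (model, parameter) sampling for
Bayesian model selection, run as a staged ladder of comparisons of
increasing model complexity. On top of the fitted models the package
computes rate-limiting-step (fold-change) sensitivity analyses,
chamber-filling diagnostics, in-silico perturbation predictions
(open-gate ΔNα3-like mutant, gate-opening Rpt peptides, co-substrate
dose responses) and a two-cleavage-site polypeptide extension that
reproduces the observed drift of cleavage-site usage over time.

All experiments run on synthetic assay data generated by the package
itself (`proteokin.synthetic`); loading experimental CSV time courses
uses the same schema (`proteokin.dataio.read_timecourse_csv`).

## Worked example

```python
import numpy as np
from proteokin import (build_model, fixture_parameters, simulate_time_course,
                       observable_product, running_velocity, simulate_with_rpt)

m9 = build_model("M9")
p = fixture_parameters("LLVY")          # enhancer-dominated fixture
times = np.arange(5.0, 365.0, 5.0)
traj = simulate_time_course(m9, p, 160.0, times)
v = running_velocity(times, observable_product(traj)) * 1e3  # nM/min
print(f"velocity 15 min: {v[times == 15.0][0]:.2f} nM/min")
print(f"velocity 120 min: {v[times == 120.0][0]:.2f} nM/min")

fold = simulate_with_rpt(m9, p, 200.0, np.array([15.0, 240.0]), rpt_factor=5.0)
print(f"Rpt fold stimulation 15 -> 240 min: {fold[0]:.2f} -> {fold[1]:.2f}")
```

prints

```
velocity 15 min: 9.52 nM/min
velocity 120 min: 12.47 nM/min
Rpt fold stimulation 15 -> 240 min: 1.71 -> 1.16
```

The velocity climbs over the first two hours because substrate
accumulating inside the chamber occupies the internal enhancer site and
opens the gate; the Rpt-peptide stimulation (modelled as a constant
multiplicative increase of `v_in`) is strongest early, before the system
has opened its own gate.

The numbered scripts under `analysis/` run the full study: dataset
generation, kinetic signatures (dose–response inhibition, velocity
rise, chamber filling), model-selection and parameter-recovery
experiments, sensitivity and capacity checks, and the polypeptide
behaviour search. Each writes tidy CSV tables under `results/`. The
command-line entry point `proteokin` exposes the same operations driven
by YAML configuration files (`generate`, `simulate`, `fit`, `select`,
`sensitivity`, `predict`, `polypeptide`).

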