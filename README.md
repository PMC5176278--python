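# mirlung

A tested simulator of early non-small-cell lung cancer (NSCLC) driven by the
exosomal microRNAs miR-21/205 and miR-155.

Overexpressed miRs shed by lung tumors block the cell's own brakes: miR-21
blocks the tyrosine-kinase inhibitor TKI, miR-21/205 block PTEN, and miR-155
blocks the Apaf-1–caspase-9 apoptosome.  With the brakes off, the EGFR → MAPK
and EGFR → AKT pathways drive proliferation and damage-induced apoptosis is
suppressed.  `mirlung` implements the resulting mathematical model — a
six-protein signaling network per cancer cell, exosome/miR reaction–diffusion,
and two tissue-scale phases:

- **invasion**: a planar tumor front advancing through x ∈ [0, 2] cm with a
  degenerate directed-migration flux χ·C·∂C/∂x,
  `∂C/∂t − D_C ΔC − χ∇·(C∇C) = growth(M, A)·C·(1 − C/C_M) − death(Ap)·C`;
- **proliferation**: a spherical free-boundary tumor in which cancer (C) and
  normal (N) cells satisfy C + N = θ; net cell production drives a radial
  velocity u with `(1/r²)(r²θu)' = net production`, and `dR/dt = u(R)`.

The package targets modellers who want to reproduce, probe or extend the
model: every rate constant is derived from literature half-lives, molar
concentrations and copy numbers by closed-form steady-state inversion
(`mirlung.params`), and mutations, anti-miR drugs and chemotherapy
surrogates are multiplicative parameter scenarios (`mirlung.scenarios`).
Global sensitivity (Latin hypercube sampling + partial rank correlation) is
built in (`mirlung.sensitivity`).

## Worked example

Run the control invasion arm and the anti-miR-21 arm for 60 days:

```python
import numpy as np
from mirlung import default_parameter_set, builtin_scenario
from mirlung.invasion import run_invasion
from mirlung.scenarios import apply, efficacy

p = default_parameter_set("invasion")           # chi = 3e-2 cm^5/g/day
control = run_invasion(p, t_end=60.0, record_times=np.array([0.0, 60.0]))
treated = run_invasion(apply(p, builtin_scenario("anti_m1")),
                       t_end=60.0, record_times=np.array([0.0, 60.0]))
eff = efficacy(control, treated, day=60.0)
print(f"front: {control.front_position[-1]:.3f} -> {treated.front_position[-1]:.3f} cm")
print(f"phi_R = {eff.phi_R:.3f}, phi_M = {eff.phi_M:.3f}")
```

prints

```
front: 0.717 -> 0.540 cm
phi_R = 0.246, phi_M = 0.335
```

i.e. by day 60 the untreated front has advanced 0.717 cm; halving miR-21/205
production (both exosomal and cellular pools — the package's treatment
convention, see `docs/methods.md`) cuts the front advance by 24.6% and the
total linear cancer mass by 33.5%.  The front is rate-limited by the
diffusing exosomal-miR cloud: ahead of it, TKI/PTEN/apoptosome rise to
uninhibited levels and net growth is negative, which is why anti-miR therapy
is so effective against invasion in this model.

The proliferation phase, from a 0.01 cm seed with the published initial
conditions:

```python
from mirlung.proliferation import run_proliferation
p = default_parameter_set("proliferation", normal_cell_rates="derived")
res = run_proliferation(p, t_end=60.0)
print(f"R(60) = {res.radius_cm[-1]:.4f} cm, avg C = {res.averages['C'][-1]:.4f} g/cm^3")
```

prints `R(60) = 0.0192 cm, avg C = 0.4661 g/cm^3` — the cancer-cell density
plateaus near 0.463 g/cm³ while C + N stays within numerical round-off of
0.6 g/cm³ throughout.

A CLI wraps the same workflows:

```bash
mirlung invade --out out/invade              # metrics.csv: t, front, masses
mirlung grow --out out/grow                  # R(t), volume, averages, miR masses
mirlung scenario --name mut_EGFR --treat anti_m1_m2 --out out/egfr
mirlung scenarios                            # catalogue listing
mirlung sens --n 1000 --seed 0 --out out/sens   # prcc.csv + samples.csv
```

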