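# crowdactin

Quantitative analysis of actin filament assembly kinetics under
solution crowding.

The cytoplasm is crowded: polymers, proteins and small osmolytes occupy
a large fraction of the solution volume and change how actin monomers
(G-actin) find and bind the fast-growing barbed end of a filament
(F-actin). `crowdactin` implements the statistics used to quantify
those effects at three scales, together with seeded synthetic-data
generators so every pipeline can be exercised and validated end to end:

* **Molecular trajectories** (Å, ns) — mean square displacement of a
  monomer near a filament barbed end,
  `MSD(t) = ⟨|r_i(t) − r_i(0)|²⟩` averaged over Cα atoms; the diffusion
  coefficient from `MSD(t) = 6 D t`; and the filament–monomer
  inter-distance change `ΔL(t) = l(t) − l(0)` (negative = approach).
* **Single-filament imaging** (µm, s) — filament length extraction
  from timelapse stacks, kymographs, OLS elongation rates over a
  60–120 s window, nm/s → subunits/s conversion, and one-way ANOVA with
  post-hoc Tukey HSD across crowding conditions.
* **Bulk polymerization** — the pyrene-assay half-maximum-slope rate:
  baseline-correct, find the first crossing of half the plateau, fit a
  line through the 10 samples on either side, normalize to the control.
* **Electrostatics** — the polar solvation free-energy combination
  `ΔG = ⟨E_C⟩ − (⟨E_F⟩ + ⟨E_G⟩)` over per-frame energies of the
  complex, the filament alone and the monomer alone, backed by a
  closed-form screened-Coulomb point-charge model
  (`k_e q_i q_j e^{−κr}/(εr)`, k_e = 332.0636 kcal·mol⁻¹·Å·e⁻²).
* **Crowder arithmetic** — %w/w ↔ molarity for stock buffers and
  molecule-count ↔ mM for simulation boxes.

## Worked example

Convert a 15% w/w PEG-8000 stock to molarity, then simulate a
TIRF-style timelapse of a filament growing at the dilute-buffer control
rate (35.9 nm/s) with 10% image noise and recover the rate:

```console
$ crowdactin convert crowder --percent 15 --mw 8000
18.8 mM

$ crowdactin simulate tirf --rate 35.9 --noise-sd 0.1 --seed 11 --output-dir run
wrote run/timelapse.tif
$ crowdactin analyze elongation --stack run/timelapse.tif --output-dir run
rate = 36.181 ± 0.284 nm/s (13.40 subunits/s, r2=0.9964)
```

The fitted 36.2 ± 0.3 nm/s agrees with the generating 35.9 nm/s within
the fit standard error; the subunit rate uses the canonical 2.7 nm
axial rise per added subunit.

The same round trip at the molecular scale — a 5 ns Brownian monomer
trajectory at the control diffusion coefficient 5.36 µm²/s, analyzed
through a lag-averaged MSD and a linear fit over short lags:

```console
$ crowdactin simulate traj --d 5.36 --seed 11 --output-dir run
wrote run/trajectory.xyz
$ crowdactin analyze msd --traj run/trajectory.xyz --lag-averaged --output-dir run
wrote run/msd.csv
$ crowdactin analyze diffusion --msd run/msd.csv --fit-window 0:0.25
D = 5.73037 um2/s (method=linear-fit, r2=0.9993)
```

A single 5 ns trajectory carries limited information, so individual
estimates scatter around the truth (here 5.73 vs 5.36 µm²/s); the
median over many seeds converges to within a few percent (see
`scripts/acceptance.py`).

Library use mirrors the CLI:

```python
from crowdactin import (GrowthParams, simulate_filament_timelapse,
                        extract_filament_lengths, fit_elongation_rate)

track, stack = simulate_filament_timelapse(GrowthParams(elongation_rate=61.3,
                                                        noise_sd=0.1, seed=0))
est = fit_elongation_rate(extract_filament_lengths(stack), window=(60, 120))
print(f"{est.rate:.1f} ± {est.stderr:.1f} nm/s")
```

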