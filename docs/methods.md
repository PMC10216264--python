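# Methods

This note documents the models behind each analysis stage, the
synthetic data they are validated against, the defaults and why, and
the numerical choices that were genuinely open.

## Trajectory analysis: MSD, diffusion, inter-distance

**Model.** A monomer near a filament barbed end is treated as a set of
labeled Cα atoms in a trajectory with uniform frame times (ns) and
coordinates in Å. The MSD is the literal frame-0-referenced average

    MSD(t) = (1/N) Σ_i |r_i(t) − r_i(0)|²,

i.e. "how far has the monomer moved from where it started", with no
averaging over time origins. This is the right observable for asking
where a monomer *ended up* over a single short (~5 ns) run, and it is
what `compute_msd` returns by default.

For *estimating a diffusion coefficient*, however, the frame-0
estimator on a single trajectory is statistically poor: `MSD(t)` is
then a single χ²₃-distributed draw scaled by 2Dt per axis, so
per-trajectory linear-fit estimates of D are strongly right-skewed
(numerically, the median fitted D is only ~0.72–0.76 of the truth at
500 steps). `compute_msd(..., lag_averaged=True)` therefore also
provides the standard time-origin-averaged MSD; with a short lag
window (lags up to ~5–10% of the trajectory, the regime where the
time average has many effectively independent contributions) the
median fitted D across seeds is within ~1% of truth. The package uses
the lag-averaged variant wherever a diffusion coefficient must be
*recovered* and the literal variant wherever end-state displacement is
the question.

**Diffusion coefficient.** `MSD(t) = 6 D t` for free 3-D diffusion.
Two estimators: pointwise `D(t) = MSD(t)/(6t)` (headline value at the
final time) and a least-squares slope over a fit window divided by 6
(default window: the final 50% of the series, skipping the initial
regime). The time variable is elapsed (or lag) time — the only
dimensionally sensible reading for a time-dependent coefficient. D is
converted to µm²/s (1 Å²/ns = 10 µm²/s); a negative fitted slope is
clamped to 0 with a `clamped` flag rather than reported as
unphysical.

**Inter-distance.** `ΔL(t) = l(t) − l(0)` where `l` is the distance
between the centroid of the filament barbed-end selection and the
monomer centroid. The barbed end defaults to the single terminal
subunit group nearest the monomer at frame 0 (configurable to more
subunits); centroids are unweighted — for Cα-only selections
mass-weighting is nearly the identity, and an optional mass-weighted
mode exists. Negative ΔL means approach.

## Synthetic trajectories

The generator emulates an equilibrium run of a monomer beside a
five-subunit filament: subunit groups `F1`..`F5` stacked 27.5 Å apart
along z (the approximate axial rise between consecutive subunits of
the actin double helix), held static; the monomer group `G` starts
15 Å beyond the barbed-end subunit centroid along the axis and
receives one shared Gaussian displacement per step with per-axis
variance 2·D·Δt plus drift·Δt. Defaults: D = 5.36 µm²/s (the control
monomer value the analyses are calibrated around), Δt = 0.01 ns,
500 steps (5 ns).

Choices worth recording:

* **Rigid-body monomer** — one displacement applied to all monomer
  atoms, so the per-atom MSD average equals the center-of-mass MSD
  exactly and closed-form oracles apply.
* **Static filament** — the filament's own MSD is deliberately zero
  (its mobility is comparable across conditions and is not the signal
  of interest); a small-jitter option exists, default off.
* **Atom clouds are centered** golden-spiral point sets, so every
  group centroid sits exactly at its nominal position and distances
  like the initial 15 Å offset are exact.
* Crowding enters only through the user-chosen D and drift; no
  explicit crowder particles are simulated. Whether drift toward the
  barbed end should co-vary with D is left open — they are independent
  knobs.

What passing tests show: the analysis stack recovers known D and
drift-free behavior from data with exactly the assumed statistics.
What they do not show: robustness to anomalous diffusion, filament
flexibility, hydrodynamic coupling, or finite-box artifacts of real
simulations.

## Electrostatics

Energies are closed-form screened-Coulomb (Debye–Hückel-like) sums
over explicit point charges,
`E = Σ_{i<j} k_e q_i q_j e^{−κ r_ij} / (ε r_ij)`, with
k_e = 332.0636 kcal·mol⁻¹·Å·e⁻², coordinates in Å and charges in e.
Defaults ε = 1, κ = 0 (bare Coulomb) keep closed-form checks exact;
both are parameters. The combination
`ΔG = ⟨E_C⟩ − (⟨E_F⟩ + ⟨E_G⟩)` is computed per frame and averaged;
`components_from_structures` enforces that each complex is the exact
union of its parts, which makes ΔG identically the inter-part
cross-term — the property all tests are anchored to.

This model preserves the sign conventions and charge-distribution
reasoning of polar solvation analysis but is not a Poisson–Boltzmann
solver: grid PB magnitudes for full atomic structures are deliberately
out of scope, and no attempt is made to reproduce them.

## Elongation analysis

**Rendering.** Synthetic timelapses draw a filament as a 1-pixel-wide
horizontal segment from a fixed anchor (one end pinned, as for a
surface-anchored filament; two-ended growth is out of scope) with
sub-pixel endpoint coverage, blur it with a Gaussian PSF
(σ = 1 pixel), normalize so the blurred filament peak is 1 — making
`noise_sd` a true fraction of signal — and add Gaussian noise.
Defaults follow the imaging conditions the analysis is designed for:
0.07 µm/pixel, 1 s frame interval, rates specified in nm/s. Gaussian
additive noise only; Poisson shot noise and photobleaching are not
modeled.

**Extraction.** Per frame, the line profile through the filament row
is thresholded at half the stack's peak intensity (estimated on
3-pixel-smoothed profiles so noise spikes do not inflate it; Otsu on
the frame is the alternative policy), sub-threshold gaps of up to two
pixels are closed morphologically, and the length is the longest
contiguous run × pixel size. Half-peak thresholding cuts the blurred
edge at its half-maximum, i.e. at the true tip, so noiseless
extraction is within one pixel at every frame. This is a deliberately
simple straight-filament tracker; curved-filament tracing is a
non-goal.

**Rate fit.** OLS of length (nm) against time (s) over a window,
default 60–120 s — early enough that growing filaments have not yet
overlapped neighbours in the imaging scenario this mirrors. The
subunit-rate conversion divides by the axial rise per added subunit,
default 2.7 nm (canonical half-monomer rise of the actin helix); the
alternative constant 2.626 nm — the value implied by quoting
35.9 nm/s as 13.67 subunits/s — is shipped as
`ACTIN_RISE_NM_IMPLIED`. The two conventions disagree by ~3%; both
are available and the discrepancy is recorded rather than resolved.

**Group comparison.** One-way ANOVA (scipy) followed by Tukey HSD
(statsmodels, studentized-range CDF under the equal-variance
assumption), with significance stars at p ≤ 0.001 / 0.01 / 0.05. If
every group has zero internal variance the comparison is flagged
degenerate and no p-value is reported. Null calibration is verified by
simulation: identically distributed groups reject at the nominal 5%
rate within binomial error.

## Pyrene analysis

The generator emits a logistic rise
`baseline + A / (1 + e^{−k(t − t_half)})` sampled every 10 s over 2 h
with a 5 min flat pre-polymerization baseline; the logistic's maximum
slope is exactly `A·k/4` at `t_half`, which is the oracle for the
estimator.

The estimator: subtract the mean over the 5 min before polymerization
start; take the plateau as the mean of the top-5% intensities (robust
to single-sample noise; the literal global max is available); the
half-max point is the *first* sample at or above half the plateau
(first crossing, not nearest sample — the trace is assumed monotone at
that stage, ties broken by earliest time); fit OLS through the
21 samples centered there (10 per side; a 20-point exclude-center mode
exists because either reading of "10 points on either side" is
defensible). Windows that would extend past the series ends are an
error — no silent clipping. Chord-fitting a sigmoid underestimates the
tangent slope; the bias is bounded by ~2% when `Δt·k ≤ 0.1`, verified
numerically. Normalization divides point estimates by the control
slope (no error propagation), so the control is exactly 1.0 and the
whole pipeline is invariant to rescaling all intensities.

## Crowder arithmetic

`%w/w → mM` is `(pct/100)·ρ·10⁶/M_w` with solution density ρ
defaulting to 1.00 g/mL — the assumption under which the standard
stock recipes (15% PEG-8000, 30% BSA, 40% sucrose) come out at
~18.8 mM, ~4.5 mM and ~1.2 M. Sucrose uses the standard molar mass
342.30 g/mol; the 389.52 g/mol mass of a parameterized simulation
model of sucrose is shipped separately (`sucrose_md_model`) and does
*not* reproduce the 1.2 M stock figure. Box conversions use
`c = n/(N_A·V)` with N_A = 6.02214×10²³/mol; the 15-molecule,
6.5 mM PEG box implies V ≈ 3.83×10³ nm³, and 30 sucrose molecules in
that same box give 13 mM. The 2-molecule, ~0.4 mM BSA case implies a
larger box (~8.3×10³ nm³) — consistent with BSA's much larger size —
so no single shared volume is asserted across all three crowders.
Reporting rounds to one decimal (mM, or M at ≥1 M).

## Problem sizes and reproducibility

All generators are pure functions of their parameters including the
seed. The validation suites use: 100–300 trajectories of 500 steps for
diffusion recovery; 50 seeds per condition (at 10% and 20% image
noise) for the elongation round trip; 1000-replicate null simulations
for ANOVA calibration; 721-sample pyrene traces. These sizes give
stable medians and tight binomial intervals while keeping the full
suite fast. `scripts/acceptance.py` derives all of its seeds from a
single `--seed` argument.

## Known limitations

* The screened-Coulomb model is not a PB solver; absolute solvation
  magnitudes for real structures are out of scope.
* The length extractor assumes one straight, anchored filament per
  stack; no curvature, bundling or two-end discrimination.
* Single-trajectory diffusion estimates are intrinsically noisy; only
  ensemble medians are quantitative.
* No kinetic modeling of nucleation–elongation, critical
  concentration, or lag times for the pyrene assay.
* Rotational diffusion, periodic-boundary unwrapping and anisotropic
  diffusion tensors are not implemented.
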