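# Methods

This note records the models behind `tnckit`, their assumptions, the
defaults that matter, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The 3-state contraction model

States and rates (all in s⁻¹):

```
B (blocked)  --kON·α(pCa)-->  C (permissive, detached)  --f-->  M (attached)
B <--kOFF--                   C <--g--
```

Ca²⁺ enters only through the regulatory occupancy
α(pCa) = 1/(1 + 10^{n_act·(pCa − pCa50_act)}), a Hill function of site-II
binding; isometric force is proportional to the M occupancy and reported
relative to its value at pCa 4.0 (saturating Ca²⁺). This is the minimal
linear scheme consistent with the four named rates of the
tension-redevelopment literature: kON/kOFF describe regulatory-unit (thin
filament) switching, f/g cross-bridge attachment/detachment. Assumptions:
one mean-field regulatory unit (no nearest-neighbour cooperativity beyond
the phenomenological n_act), no sarcomere-length dependence, force
generation binary in M.

The stationary distribution has the closed form
B : C : M = kOFF/(kON·α) : 1 : f/g; the implementation uses it directly and
the test suite checks it against long-time `expm` integration on random
rate draws (tolerance 1e−8), with probability conservation along
trajectories to 1e−9.

**kTR.** Two definitions are provided. `eigen` returns the
smallest-magnitude nonzero eigenvalue of the rate matrix; `simulate`
re-enacts the release–restretch protocol (cross-bridges detached, M = 0,
B/C renormalized at their pre-release ratio), integrates M(t) by matrix
exponentials over 8 slow-mode time constants, and fits a mono-exponential
over the 5–95 % force-rise window — what an experimenter fits to the force
transient. The two agree within 5 % only when the slow mode both is
spectrally separated (≥3×) *and* carries the dominant share (≳50×) of the
M(t) amplitude; outside that regime the protocol fit reports the fast
phase, which is the physically measured quantity, and the eigenvalue is not
a good proxy. The classical saturating limit kTR → f+g requires the
regulatory pool to be both fast (kON, kOFF ≫ f+g) and strongly permissive
(kON·α ≫ kOFF); with kON·α ≈ kOFF the limit is f/2 + g. At the opposite
(low-force) end the slow rate tends to kOFF·g/(kOFF+f+g), so in this scheme
*smaller* kOFF lowers the low-force end of the force–kTR relation; an
elevation at low force under slower regulatory dynamics, as described for
cooperative multi-unit regulatory models, is outside what a one-compartment
linear scheme can produce. The genotype contrast that motivates the package
(≈2× faster f, ≈2× slower g, faster kOFF → lowered, more curvilinear
force–kTR relation at unchanged maximum) is reproduced.

**Fitting.** `fit_hill` is bounded least squares on the Hill equation with
2 (pCa50, n), 3 (+Fmax) or 4 (+Fmin) parameters, multi-started over pCa50;
standard errors come from the Jacobian. `fit_three_state` fits (f, g, kOFF)
jointly to force–pCa and force–kTR data at fixed kON (default 100 s⁻¹,
config-exposed), log-parameterized for positivity, with ≥8 seeded starts
and best-RSS selection; residuals of each curve are normalized by that
curve's data SD so the two observables contribute comparably. Noiseless
generator data invert to <0.1 %.

Reference rates for the synthetic study conditions: kON = 100, kOFF = 50,
f = 4, g = 2 s⁻¹ (saturating kTR ≈ f+g = 6 s⁻¹, the murine-preparation
scale), activation pCa50_act = 5.85, n_act = 2.

## Ensemble geometry

Ensembles travel as multi-model PDB (one frame = one MODEL); residue
numbers are the author numbering of the coordinate file, never remapped.

* **Helix axis** — principal direction (SVD) of the helix Cα trace,
  oriented N→C. A finite helix with a non-integer number of turns has a
  principal axis tilted a few degrees off its geometric screw axis; the
  synthetic two-helix generator therefore prescribes the angle between the
  *principal* axes, making its per-model ground truth exact for the
  estimator it feeds.
* **AB angle** — arccos of the oriented-axis dot product, degrees in
  [0, 180], helices A/B defaulting to residues 14–25/38–47. Open state:
  angle strictly < 110°; open fractions carry a seeded bootstrap CI
  (1000 resamples) and optional per-replicate values, compared between
  groups by a two-sided Welch test.
* **RMSF** — Kabsch superposition of every frame onto frame 1 over the
  backbone of residues 1–100 (intersected with what the ensemble
  contains), then per-residue Cα fluctuation about the mean.
* **Contacts** — `heavy-7A-sep6`: any heavy-atom pair within 7 Å for
  |i−j| ≥ 6; `calpha-5A`: Cα pairs within 5 Å, |i−j| ≥ 3 (the separation
  floor for this mode is a package choice to drop trivial backbone
  neighbours; it is config-exposed). Ensemble maps report per-pair
  occupancy and minimum distance; both modes are verified against a
  brute-force double loop.
* **PCA / FEL** — Cα covariance over residues 4–85 after the same
  alignment; eigendecomposition via SVD of the centered data matrix;
  projections centered. FELs use ΔG(bin) = −kT·ln(count/max count) in kT
  units (default 50 bins, temperature only labels the output), empty bins
  masked as NaN rather than assigned fake barriers, no pseudo-counts.

## Frustration index

For each native contact (from the Cα-5 Å map by default),
F = (⟨E_decoy⟩ − E_native)/SD(E_decoy) with decoys formed by resampling
both residue identities independently from the chain's composition
(default 1000 decoys, seeded). F is a z-score, hence invariant under any
affine rescaling of the potential — asserted numerically, and the
Monte-Carlo estimate is checked against exhaustive enumeration on
two-letter alphabets. Classification: minimal if F ≥ 0.78, high if
F ≤ −1.0, neutral between (the conventional cuts; config values, not
claims).

The default potential is a hydrophobicity-product matrix: Kyte–Doolittle
hydropathies scaled to [0, 1], E(a,b) = −h_a·h_b, so
hydrophobic–hydrophobic pairs are most favorable. This reproduces the
qualitative ordering of knowledge-based contact matrices and suffices for
the package's comparative maps; it is *not* the AWSEM-based energy function
of the published frustration server, which adds distance-, density- and
electrostatics-dependent terms — per-contact index values are therefore not
comparable to that server's output, only the minimal/neutral/high
patterning is. Any symmetric 20×20 matrix can be supplied as a CSV.

## NMR observables

* CSP = √(ΔδH² + 0.1·ΔδN²) over the shared residue set; unmatched residues
  are reported, never imputed. Outlier flags use the population SD
  (mean + k·σ, strict >).
* Temperature coefficients: OLS slope of δH (converted to ppb) vs °C,
  ≥3 temperatures per residue, degenerate (constant-shift) residues
  flagged with R² reported as 0.
* Relaxation: I(t) = I₀·e^(−Rt) by nonlinear refit of a log-linear start;
  a signal *rising* more than 5 % over the delay range is rejected as
  non-decaying, a flat one converges to R ≈ 0. Default delay ladders are
  the R1 (20–1500 ms) and R2 (16–304 ms) experiment lists.
* R2/R1 profiles split at the D/E linker (N: 1–85, C: 94–161 by default);
  flags at mean + 1σ per domain; R1 = 0 masked.
* CPMG: R2eff = (1/T)·ln(I₀/I_CPMG), positive for attenuated signal; the
  sign-flipped literal form is available behind `as_printed` for
  compatibility with how the formula is sometimes printed. Regime rules,
  relative to the cohort of all residues at the two standard refocusing
  frequencies (50/1000 Hz): *fast* = flat dispersion (|ΔR2eff| ≤ ε) but
  elevated above mean + 1σ; *intermediate* = decaying dispersion
  (ΔR2eff > δ) and R2eff(50 Hz) above mean + 1σ; defaults
  ε = δ = max(2 s⁻¹, 10 % of the cohort mean), config-exposed. The
  synthetic dispersions use the fast-exchange (Luz–Meiboom) closed form —
  enough to exercise qualitative classification, not a Carver–Richards
  global fit.
* Titrations: CSP(L) = CSPmax·(Pt+L+Kd − √((Pt+L+Kd)² − 4·Pt·L))/(2·Pt),
  fit globally with one shared Kd and per-residue CSPmax (matching the
  one-affinity-per-peptide convention); a series whose response never
  doubles its first nonzero point is flagged as ill-conditioned for Kd.
  The synthetic generator splits each total displacement √0.7/√3 between
  δH and δN so the CSP formula recovers it exactly.

## Spectroscopy

* MRE = θ·0.1·(MW/n)/(l·c) — the denominator groups as l·c; the literal
  left-to-right reading of the printed formula is dimensionally wrong and
  is not implemented.
* Melts: linear baseline + 1 or 2 Boltzmann sigmoids
  A/(1+exp((Tm−T)/k)), multi-started over a Tm grid, Tm bounded to the
  data range and widths to [0.5, 25] °C (a sigmoid narrower than the grid
  is unidentifiable and only chases single noise excursions). Model
  selection between 1 and 2 transitions is by AIC *among admissible
  models*: a second transition counts as resolved only if each amplitude
  carries ≥5 % of the total, both amplitudes share a sign (at 222 nm every
  unfolding step moves ellipticity the same way), and the Tm values are
  separated by more than the mean width. Without these identifiability
  rules a movable second sigmoid — unidentified under a single-transition
  truth — absorbs noise and raw AIC over-selects it in roughly 40 % of
  realizations; with them, single-transition data select one transition in
  ~97 % of seeded realizations and genuine two-transition data select two
  in all of them (rates the test suite recomputes at smaller n). Van't
  Hoff ΔH parameterization is deliberately omitted: only Tm is reported.
* SAXS: Kratky s²·I(s) elementwise without smoothing; Guinier Rg/I₀ by
  iteratively windowed regression of ln I vs s² (s·Rg ≤ 1.3); the
  dimensionless Kratky curve (sRg)²·I/I₀ of an ideal compact globule peaks
  at (√3, 3/e ≈ 1.104), the analytic check used in the tests. Synthetic
  profiles mix a Guinier globule with a Debye chain of equal Rg.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (spec, seed) and store their ground truth,
so every estimator is validated as an inversion — noiselessly to ≤0.1 %,
and under default noise at stated tolerances. Defaults encode the study
conditions: genotype pCa50 5.56 (WT) / 5.72 (C84Y) with additive force
noise SD 0.04 at 6 replicates (S.E.M.-scale, n = 5–6 preparations);
nHill 3.0 (typical permeabilized cardiac muscle, chosen once since the
source tables are not reprinted here); pCa grid 7.0→4.0 in 0.25 steps;
mechanics noise multiplicative 3 % for force/kTR pairs; ideal-helix
geometry 1.5 Å rise, 2.3 Å radius, 100° twist; titration ladder
0/15/40/70/120/150/200 μM at Pt = 100 μM; bimodal primed-state angles
(110°, 5°)/(150°, 5°) and unimodal open-state angles (102°, 5°).

What passing tests show is that the *estimators invert the stated
generative models* under realistic noise — not that real data obey those
models. The generators omit, among other things: baseline drift and
run-to-run offsets in mechanics rigs, cooperative regulatory-unit coupling
(so force–kTR shapes beyond the 3-state family), real helix irregularity
and side-chain packing (ensembles are Cα-only ideal helices), peak overlap
and assignment errors in spectra, Carver–Richards dispersion shapes,
aggregation and inter-particle effects in SAXS. In particular, no
experimental coordinate ensemble is bundled: open-state geometry statements
are exercised on the synthetic open-state ensemble, with the angle
machinery itself validated against constructed ground truth.

## Problem sizes and reproducibility

Default problem sizes (package choices): 400-model ensembles in the
analysis scripts, 2000-model ensembles where histogram modes are measured;
100 random parameter draws for steady-state oracle checks; 12–50 seeds for
noisy-recovery medians; 25–40 seeds for model-selection rates; 1000 decoys
and 1000 bootstrap resamples. Every source of randomness is a
`numpy.random.default_rng` seeded from an explicit argument;
`scripts/acceptance.py` derives all sub-seeds from `--seed` via
`SeedSequence`, and repeated runs with one seed are byte-identical.

## Known limitations

* The 3-state scheme is mean-field; regulatory-unit cooperativity and the
  low-force kTR phenomenology of multi-unit models are out of reach.
* kON is not identifiable from force/kTR pairs alone and is held fixed.
* The frustration index is comparative, not transferable across
  potentials; only class patterns are meaningful.
* Exchange classification is rule-based and qualitative; no kex/Δω are
  estimated (no Carver–Richards fitting).
* Rotational correlation times are not estimated from R2/R1.
* CD fits report Tm only; fraction-folded normalization is optional and
  off by default because pre/post baselines differ between liganded
  states.
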