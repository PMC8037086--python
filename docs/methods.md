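# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying protocols are
commonly under-specified.

## Spectrometer context and constants

All field-dependent constants derive from a single frozen
`SpectrometerContext`: ¹H frequency (default 800 MHz, the field of the
relaxation measurements this package targets), signed gyromagnetic ratios
γ_H = 2.6752218744×10⁸ and γ_N = −2.7126×10⁷ rad s⁻¹ T⁻¹, N–H bond length
r_NH = 1.02 Å (the standard amide value in relaxation analysis) and ¹⁵N CSA
Δσ = −160 ppm. The dipolar constant is the product
d = μ₀hγ_Nγ_H⟨r_NH⁻³⟩/(8π²) ≈ 7.21×10⁴ s⁻¹ at 1.02 Å, and c = ω_NΔσ/√3;
both enter only squared. μ₀ is taken at its classical value 4π×10⁻⁷, the
convention of the relaxation literature (the CODATA measured value differs
only at the 10⁻¹⁰ level).

Signs matter in two places and only two: the cross-relaxation rate
σ = R₁(NOE−1)·γ_N/γ_H uses the signed ratio, so a protein-regime NOE < 1
yields σ > 0; and the combination frequencies of the dipolar expressions
honour the negative ¹⁵N Larmor frequency, so the "sum" frequency ω_H+ω_N
has magnitude ≈ 0.9ω_H. The latter is what makes (6J(ω_H+ω_N) −
J(ω_H−ω_N))/5 a probe of J near 0.87ω_H; with magnitude-only frequencies the
mapping's high-frequency output would be biased low by tens of percent. For
frequency-axis purposes ω_N is reported as a magnitude.

## Forward model (generator only)

Synthetic relaxation data derive from the Lipari–Szabo spectral density
J(ω) = (2/5)[S²τc/(1+(ωτc)²) + (1−S²)τ/(1+(ωτ)²)], 1/τ = 1/τc + 1/τe, fed
through the standard dipolar + CSA expressions for R₁, R₂ and NOE; Rex adds
to R₂ and nothing else. The model-free form is used **only** to generate
data with known truth — the package deliberately contains no model-free
fitting of experimental data, because the analysis chain it implements is
the reduced-mapping one. An independently coded brute-force oracle for
J(ω) and the rate expressions lives in the test suite and the
implementation is held to ≤10⁻¹⁰ relative agreement with it.

## Exponential rate fitting

Two-parameter model I(t) = I₀e^(−Rt) with no baseline offset (the
experiments fit "a single-exponential decay"), solved by Levenberg–
Marquardt with an analytic Jacobian from a log-linear initial guess
(R₀ = −slope of ln I vs t). Tight tolerances (10⁻¹⁴) make the noiseless
round trip an identity to better than 10⁻⁹ and the fit exactly equivariant
under time rescaling in practice. Default delay grids are the experiment
protocols: T₁ 10–2560 ms (10 points) and T₂ 10–150 ms (8 points) for the
full-length construct, with the 8-point single-domain grids also provided.
Per-residue failures (constant intensities, non-positive rate at the
optimum, non-convergence) are returned as flagged records and excluded
downstream rather than aborting a run; fewer than four points is a hard
validation error.

Rate errors are Monte-Carlo: the best-fit curve is perturbed with Gaussian
noise of the duplicate-estimated sd and refit n_mc times (default 500; the
protocols this emulates state no count); the error is the sd (not sem) of
the refitted rates, deterministic under a seed. The duplicate-based noise
estimate is sd(paired differences)/√2, pooled over residues when several
pairs are supplied.

## Reduced spectral density mapping

Implements the printed mapping exactly: J(ω_N) = (4R₁−5σ)/(3d²+4c²),
J(0) = (6R₂−3R₁−2.72σ)/(3d²+4c²), J(0.87ω_H) = 4σ/(5d²), reported in
ns/rad (internal computation in SI). A `variant="literature"` switch
replaces the 5σ coefficient in J(ω_N) with the 5.6σ used by part of the
reduced-mapping literature; the printed form is the default. On noiseless
synthetic input the mapping recovers J(0), J(ω_N) and J(0.87ω_H) to within
~1% across S² ∈ [0.7, 1], τc ∈ [5, 15] ns (verified against the oracle, not
assumed; the acceptance tolerance is 10%). Chemical exchange shifts the
mapped J(0) by exactly 6·Rex/(3d²+4c²) — an algebraic identity of the J(0)
equation — so for exchange-bearing residues the mapped J(0) is the
exchange-inclusive effective value, which is precisely why elevated J(0)
flags µs–ms motion. J errors are Monte-Carlo propagated from independent
Gaussian rate errors (the plots this emulates name no propagation method);
the MC estimate agrees with first-order analytic propagation at small
errors.

## HSQC titration analysis

Peaks pair by assignment label, so row order is immaterial; residues absent
from the bound list are flagged (`missing_in_bound`) and count as
attenuated. The combined CSP is √(ΔδH² + (w·ΔδN)²) with the conventional
w = 0.14 (configurable).

Shift significance uses trimmed statistics: threshold = 10%-trimmed mean +
n_sd × 10%-trimmed sd of the CSP distribution, flagging strictly above it
(an all-equal CSP column therefore flags nothing). The default n_sd = 4 was
chosen so that the expected number of noise-only flags stays below one per
~100–300 residue protein: the null CSP distribution is Rayleigh-like, and a
mean+1·sd rule — which some titration studies quote — always flags its top
~16% regardless of how small the noise is. n_sd = 1 restores that
permissive convention when wanted.

Attenuation is the bound/free height ratio normalised by the median ratio
of unflagged residues (two passes), which absorbs concentration and
receiver-gain differences between spectra and makes the classification
exactly invariant to uniform rescaling of either list; residues below 0.5
(configurable) are flagged, and the flagged fraction plus mean normalised
ratio form the global-attenuation readout used to compare titrations.

## Thermal shift fitting

Dye-reported melt curves decay after the unfolding transition (dye
release), so curves are first truncated to the window from the global
fluorescence minimum preceding the rise through the global maximum; curves
with no rise (flat or monotonically decreasing) are flagged failures. The
Boltzmann sigmoid F(T) = LL + (UL−LL)/(1+exp((Tm−T)/a)) is fit by
least squares (lmfit) with the initial Tm at the steepest observed rise.
Tm is the sigmoid midpoint and inflection, which makes the estimate exactly
invariant to fluorescence scale/offset and exactly equivariant under
temperature shifts. Replicates aggregate as mean ± sd across repeats (sem
behind a flag), matching the ±-across-three-repeats convention of
thermal-shift reporting; ΔTm is the difference of aggregated means with
errors added in quadrature. The generator's default grid is 25–99 °C at
0.5 °C — the stated ramp endpoints with a sampling density instruments in
this class typically achieve; the readers accept any grid.

## Ensemble statistics

Multi-model PDBs are read through gemmi; alternate locations resolve to the
highest-occupancy conformer, and atoms absent from any model are dropped
from all models (logged) so the roster is identical and identically
ordered. Superposition is closed-form Kabsch (proper rotation, det +1),
checked in the tests against a brute-force rotation-search oracle.

"RMSD from mean structure" is computed the way the phrase implies: all
models are superposed on a current reference (model 1 seeds the first
round), the coordinate mean is taken, models are re-superposed on the mean,
and so on until the mean moves ≤ 10⁻⁶ Å (capped at 100 iterations); the
report is each model's RMSD to the converged mean over the selection, plus
mean ± sd across models. Backbone means N, CA, C — a common NMR-ensemble
convention; because structure tables rarely state their atom set, the
carbonyl-O-inclusive variant is available behind a flag and comparisons to
published ensemble RMSDs should be read with a ±0.1 Å convention
allowance.

Restraint categories are a pure function of |i−j| (0 / 1 / 2–4 / >4), so
the counts always partition the total. The permissive `.mr` reader takes
one (i, j) pair per XPLOR `assign` statement — ambiguous OR-groups are
counted once via their first pair, logged — and falls back to CYANA-style
columns; residue numbering follows the deposited construct numbering.

## Synthetic data: what it does and does not emulate

Generation starts at peak heights — there is no FID- or spectrum-level
simulation, no peak picking, and no deuteration-level effects on the
rates. Noise is additive Gaussian on heights with sd proportional to a
reference intensity (the standard treatment of thermal noise in peak
heights); melt-curve noise scales with the transition amplitude; peak
positions optionally jitter per spectrum (defaults off; the titration tests
use 0.002 ppm ¹H / 0.01 ppm ¹⁵N, about the picking uncertainty of a decent
HSQC). Ensembles are a template plus isotropic Gaussian scatter and a
random rigid-body motion per model, so superposition is genuinely
exercised. Everything is bit-for-bit reproducible under a seed, and ground
truth is always retained beside the generated data.

Passing recovery tests on these generators demonstrates that the analysis
chain is correct and self-consistent under its own noise model; it does not
demonstrate robustness to spectral artifacts real data carry (overlap,
baseline distortion, temperature drift, non-Gaussian tails), and the
intensity noise level of any particular instrument is a placeholder, not a
reconstruction.

## Problem sizes and known limitations

The test suite runs its stochastic checks at deliberately modest sizes
(500 fits for rate-recovery and bootstrap comparisons, 2 000–20 000 Monte-
Carlo draws for error propagation, 120-residue titrations, 20-model
ensembles), which keeps the whole suite under a minute while leaving the
statistical assertions with comfortable margins. Replicate seeds are fixed
in tests; the acceptance script derives all randomness from its `--seed`.

Out of scope by design: model-free fitting of experimental data,
anisotropic diffusion tensors, exchange-model (CPMG/T₁ρ) fitting, Kd
extraction from multi-point titrations, restraint-violation analysis, and
structure calculation itself. Mean experimental J(0) values published for
this system cannot be recomputed here because the underlying per-residue
rates are not deposited; the package instead proves the pipeline on
synthetic ground truth and checks the deposited-ensemble statistics it
*can* recompute.
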