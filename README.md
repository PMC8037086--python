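# nmrdyn

Analysis toolkit for protein NMR dynamics and stability studies of the kind
used to characterise the two-domain Hsp90 co-chaperone Aha1: backbone ¹⁵N
relaxation fitting, reduced spectral density mapping, HSQC titration
(chemical-shift-perturbation and attenuation) analysis, thermal-shift Tm
fitting, and multi-model ensemble/restraint statistics — together with
synthetic-data generators so that every stage can be validated against known
ground truth.

It is aimed at structural biologists who have per-residue peak heights,
Sparky-style peak lists, qPCR melt-curve exports and multi-model PDB
ensembles, and want a scripted, testable path from those files to the numbers
a structure/dynamics paper reports.

## What it computes

**Relaxation rates.** Peak intensities measured at a series of relaxation
delays are fit per residue to a single-exponential decay
I(t) = I₀·exp(−R·t), giving R₁ and R₂; errors come from Monte-Carlo refits of
noise-perturbed best-fit curves, with the noise level estimated from
duplicate spectra (sd of paired differences / √2). The heteronuclear NOE
(XNOE) is the ratio of peak heights with/without proton saturation, with
first-order error propagation.

**Reduced spectral density mapping.** Rates are converted to spectral
densities through the cross-relaxation rate σ:

    σ          = R₁ (NOE − 1) γ_N/γ_H
    J(ω_N)     = (4R₁ − 5σ) / (3d² + 4c²)
    J(0)       = (6R₂ − 3R₁ − 2.72σ) / (3d² + 4c²)
    J(0.87ω_H) = 4σ / (5d²)

with d = μ₀hγ_Nγ_H⟨r_NH⁻³⟩/(8π²) and c = ω_NΔσ/√3 (Δσ = −160 ppm,
r_NH = 1.02 Å, 800 MHz by default). J(0) reports slow (µs–ms) motions and
chemical exchange, J(0.87ω_H) fast (ps–ns) motions. Errors propagate by
Monte Carlo. Region summaries give the mean ± sem J(0) per domain.

**HSQC titrations.** Free/bound peak lists are paired by assignment; the
combined CSP is √(ΔδH² + (0.14·ΔδN)²); residues are flagged as shifted
(above a trimmed-statistics threshold) or attenuated (normalised bound/free
height ratio below 0.5), and titrations are compared by their global
attenuation.

**Thermal shift.** SYPRO-Orange melt curves are truncated to the transition
window and fit with the Boltzmann sigmoid
F(T) = LL + (UL − LL)/(1 + exp((Tm − T)/a)); replicate Tm values aggregate to
mean ± sd, and construct stabilities are compared as ΔTm.

**Ensemble statistics.** Multi-model PDBs are superposed by least-squares
(Kabsch) onto an iteratively converged mean structure; the per-model RMSD to
that mean over backbone (N, CA, C) or heavy atoms in a residue range is the
ensemble-precision statistic of structure tables. NOE restraints are
classified by sequence separation |i−j| into intra-residual (0), sequential
(1), medium-range (2–4) and long-range (>4).

## Worked example

Simulate a 30-residue protein whose first 15 residues carry chemical
exchange (Rex = 4 s⁻¹), fit rates, and map spectral densities:

```python
import nmrdyn as nd
from nmrdyn.context import SpectrometerContext
from nmrdyn.synthetic import simulate_relaxation_experiment, NoiseSpec
from nmrdyn.spectral_density import propagate_errors, summarize_region

ctx = SpectrometerContext()            # 800 MHz, Δσ = −160 ppm, r_NH = 1.02 Å
truth = [nd.ModelFreeParams(residue_id=i, S2=0.85, tau_c=9.0, tau_e=50.0,
                            Rex=4.0 if i <= 15 else 0.0) for i in range(1, 31)]
data = simulate_relaxation_experiment(truth, ctx, noise=NoiseSpec(0.01, seed=7))
# ... fit_exponential / mc_error / compute_xnoe on data, build a rates table ...
```

The fitted rates table and the mapped profile begin:

```
 residue       R1   R1_err        R2   R2_err      NOE  NOE_err
       1 0.906852 0.015629 17.246611 0.306158 0.653997 0.011706
       2 0.898733 0.015531 16.900496 0.316034 0.652947 0.011678

 residue       J0   J0_err      JwN      JwH
       1 4.114413 0.074624 0.141748 0.004894
       2 4.030556 0.078267 0.140459 0.004865
```

and the per-region summary separates the exchange-broadened region from the
rigid one:

```
mean J(0), exchange-broadened region:  4.06 +/- 0.02 ns/rad (n=15)
mean J(0), rigid region:               3.09 +/- 0.01 ns/rad (n=15)
```

The rigid-region mean matches the generator truth (J(0) = 3.06 ns/rad for
S² = 0.85, τc = 9 ns), and the exchange region sits higher by almost exactly
6·Rex/(3d² + 4c²) — elevated J(0) is the signature of µs–ms motion.

The same pipelines are scriptable from the shell:

```console
$ nmrdyn simulate melt --tm 72.41 --noise 0.01 --replicates 3 \
      --construct Aha1C --seed 1 --out melt.csv
wrote 3 curves to melt.csv
$ nmrdyn meltfit --curves melt.csv --out tm.csv && cat tm.csv
construct,Tm,Tm_sd,slope,window_low,window_high,n_replicates
Aha1C,72.41659292959044,0.007441002764462514,1.5127870661967548,37.0,87.0,3
```

Three 1%-noise replicates generated at 72.41 °C fit back to
72.42 ± 0.01 °C.

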