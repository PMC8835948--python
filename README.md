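# spectrobind

A tested, reusable pipeline for the biophysical characterisation of a
protein–nucleic-acid complex — built around the case of human serum albumin
(HSA) binding a short single-stranded microRNA through its lone tryptophan
(Trp214) pocket.  It is aimed at spectroscopists and structural modellers
who need the full quantitative chain from raw-ish instrument data to a
structural model, with every estimator testable against synthetic data of
known ground truth.

Five linked analyses:

1. **Stern–Volmer quenching** (`spectrobind.quench`) — fits
   F₀/F = 1 + K_SV[Q] (linear) and the 1:1 quadratic depletion model for
   (F₀−F)/F₀; classifies the mechanism (static vs dynamic) from
   k_q = K_SV/τ and the lifetime response; optional inner-filter correction
   10^((A_ex+A_em)/2).
2. **TCSPC lifetime fitting** (`spectrobind.tcspc`) — IRF-reconvolved
   multi-exponential fits I(t) = a₀ + Σ aᵢe^(−t/τᵢ) with Poisson weights;
   amplitude-weighted mean lifetime ⟨τ⟩ = Σaᵢτᵢ/Σaᵢ.
3. **FRET distance** (`spectrobind.fret`) — E = 1 − τ_DA/τ_D and
   R = R₀(1/E − 1)^(1/6), with delta-method error propagation; R₀ must be
   supplied explicitly.
4. **Dynamic force spectroscopy** (`spectrobind.forcespec`) — unbinding
   event detection on AFM retract curves (eFJC tether fit, PEG-window
   specificity), modal forces from Gaussian-fitted histograms, the
   Bell–Evans relation F* = (k_BT/x_β)·ln(r·x_β/(k_off·k_BT)) for k_off and
   x_β, plus effective-volume k_on and K_A = k_on/k_off estimates.
5. **Pose screening** (`spectrobind.poses`) — screens rigid docking poses by
   the FRET distance (Trp indole-ring centroid to RNA 5′-P, plus a dye
   offset), groups survivors by ligand RMSD after Cα superposition, selects
   rank-best representatives, and monitors the distance along trajectories.

A sixth module, `spectrobind.simulate`, generates every input the pipeline
consumes (titrations, decays, rupture-force ensembles, force curves, pose
sets and trajectories) as pure functions of (parameters, seed), each with a
recorded ground truth — so the whole chain is testable without instrument
data.

## Worked example

```python
from spectrobind import simulate, quench, tcspc, fret, forcespec, poses

# 1. quenching titration (5 uM protein, 0.5-15 uM quencher, 2% noise)
series, _ = simulate.gen_titration(K_SV_true=2.7e4, noise_cv=0.02, seed=1)
fit = quench.fit_sv_linear(series, tau_q=5.43)
mech, _ = quench.classify_quenching(fit.K_SV, 5.43, [5.43, 5.40, 5.33])

# 2. lifetime of the donor in the 1:1 complex
trace, _ = simulate.gen_decay(simulate.biexponential_for_mean(5.33), seed=1)
dfit = tcspc.fit_decay(trace, n_components=2)

# 3. FRET distance from the two donor lifetimes (R0 supplied explicitly)
m = fret.fret_distance_report(5.12, 5.33, R0=2.52, sigma_DA=0.02, sigma_D=0.06)

# 4. Bell-Evans from rupture ensembles at five loading rates
rates = (0.5, 2.0, 8.0, 40.0, 200.0)
pts = [forcespec.force_histogram(
           simulate.sample_rupture_forces(0.3, 0.26, r, n=1000, seed=i),
           loading_rate=r)
       for i, r in enumerate(rates)]
bfit = forcespec.fit_bell_evans(pts)
kon = forcespec.estimate_kon(10.0, 0.1)

# 5. screen 50 docking poses by the measured distance
pset, _ = simulate.gen_pose_set(n=50, dda_mean=4.0, dda_sd=0.7, seed=1)
report = poses.screen_poses(pset, measured_R=m.R, tolerance=0.5, dye_offset=0.1)
```

This prints (via the obvious f-strings):

```
K_SV = 2.738e+04 +/- 6.0e+02 M^-1, k_q = 5.04e+12 M^-1 s^-1
mechanism: static
<tau> = 5.324 ns (chi2_red = 1.08)
E = 0.0394, R = 4.29 +/- 0.22 nm
k_off = 0.34 s^-1, x_beta = 0.257 nm
k_on ~ 1.3e+04 M^-1 s^-1, K_A ~ 3.7e+04 M^-1
33/50 poses in window (3.79, 4.79), 33 groups
```

Reading the numbers: the recovered K_SV (~2.7e4 M⁻¹) matches the simulation
truth; k_q sits two orders of magnitude above the ~1e10 M⁻¹s⁻¹ diffusion
limit while lifetimes barely move, so the quenching is static (a
ground-state complex) and K_SV estimates the affinity.  The reconvolution
fit recovers the 5.33 ns mean lifetime to ~0.01 ns.  The two donor
lifetimes give a transfer efficiency of 3.9% and, conditional on
R₀ = 2.52 nm, a donor–dye distance of 4.29 nm.  The force-spectroscopy
branch recovers the simulated k_off = 0.3 s⁻¹ and x_β = 0.26 nm within
sampling error, and K_A ≈ k_on/k_off lands at the same ~1e4–1e5 M⁻¹ scale
as the fluorescence estimate — the cross-technique consistency check the
pipeline exists for.  Finally, 33 of 50 random poses fall inside the
distance window; with randomly oriented ligands no two poses coincide, so
each forms its own RMSD group.

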