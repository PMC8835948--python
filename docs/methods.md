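# Methods

`spectrobind` implements the quantitative chain used to establish and model a
protein–RNA complex — concretely, human serum albumin (HSA) binding a short
single-stranded microRNA — from four experimental observables: steady-state
fluorescence quenching of the protein's lone tryptophan (Trp214), its
time-resolved fluorescence decay, atomic-force-microscopy unbinding forces,
and rigid docking poses screened by a FRET-derived distance restraint.  This
note documents the models, the defaults and why they were chosen, what the
synthetic data do and do not emulate, and the numerical choices that matter.

## Stern–Volmer quenching (`spectrobind.quench`)

The quenching ratio is modelled two ways:

* **Linear**: F₀/F = 1 + K_SV[Q].  Because F₀ is a measured datum, the
  intercept is fixed at 1 and only the slope K_SV is estimated
  (through-origin least squares of F₀/F − 1 on [Q]).  Least squares is
  unweighted by default (equal-variance intensities); per-point weights can
  be added by the caller via the quadratic path if needed.
* **Quadratic (depletion) model**: the quenched fraction
  (F₀−F)/F₀ for 1:1 binding at comparable fluorophore and quencher
  concentrations,
  (1/2P₀)[(1/K+P₀+Q₀) − √((1/K+P₀+Q₀)² − 4P₀Q₀)],
  with the free-quencher approximation [Q]₀ ≈ [Q]free retained.  Fitted by
  bounded nonlinear least squares with restarts over several starting
  decades; tolerances 1e-14 so noiseless data are recovered to machine
  precision.

**Inner-filter correction**: the standard half-path cuvette form
F_corr = F·10^((A_ex+A_em)/2), applied only when absorbances are supplied —
measured absorbances are rarely archived with titrations, so the correction
is opt-in rather than silently assumed.

**Mechanism classification**: the apparent bimolecular constant
k_q = K_SV/τ_free is compared with a diffusion-control threshold (default
1e10 M⁻¹s⁻¹, configurable).  Static quenching requires k_q ≥ 10× the
threshold *and* lifetimes constant to ≤ 2%; dynamic requires k_q at or below
the threshold with lifetimes tracking the intensity drop; conflicting
evidence returns *indeterminate* rather than forcing a call.

## TCSPC lifetimes (`spectrobind.tcspc`)

Decays are modelled as I(t) = a₀ + Σᵢ aᵢ e^(−t/τᵢ) convolved with the
measured IRF (normalised to unit area; causal discrete convolution truncated
to the window).  Fitting is weighted nonlinear least squares with Poisson
weights 1/max(counts, 1); zero-count channels are retained.  The reduced
chi-square flags (at > 1.2) but never rejects a fit, since no hard criterion
exists for real data.  Two components are the default; model selection
beyond n ∈ {1,2,3} is out of scope.  An integer channel-shift parameter can
absorb IRF/decay timing offsets (default 0).

The summary statistic is the **amplitude-weighted** mean lifetime
⟨τ⟩ = Σaᵢτᵢ/Σaᵢ — deliberately not the intensity-weighted mean, a common
ambiguity; the formula is unit-tested directly.  Its standard error comes
from the delta method on the fitted (aᵢ, τᵢ) covariance.

## FRET distance (`spectrobind.fret`)

E = 1 − ⟨τ_DA⟩/⟨τ_D⟩ and R = R₀(1/E − 1)^(1/6).  Two conventions are
encoded and tested:

* τ_D is the donor lifetime **in the unlabelled complex** (binder bound, no
  acceptor), not the free protein — the acceptor is the only difference
  between the two measurements.
* R₀ is a **required input**: it depends on spectral overlap and quantum
  yield that this package cannot know.  No distance is emitted without an
  explicit R₀, and any distance is conditional on it.  With the measured
  lifetimes (5.12/5.33 ns) an R₀ of 2.52 nm reproduces R ≈ 4.3 nm.

σ_R is propagated to first order (delta method) through both relations; a
Monte-Carlo oracle in the tests confirms agreement within 10% when relative
input errors — including the relative error of E itself — are below ~5%.
At very small E (weak transfer) the delta method underestimates σ_R; the
measured condition here (E ≈ 0.04) is in that regime, so the reported σ_R
should be read as a lower-order estimate.

The dye-linker geometric offset (0.1 nm) belongs to the structural screen,
not here: FRET reports the spectroscopic donor–dye distance.

## Dynamic force spectroscopy (`spectrobind.forcespec`)

**Event detection**: a rupture is a sudden jump of the cantilever deflection
back toward baseline from a pulled state (jump ≥ max(0.15 nm, 5× the
baseline noise estimated from the curve tail)).  Force = |deflection| ×
k_eff.  The stretch preceding the jump is fitted with an extended
freely-jointed chain (Kuhn length 0.7 nm for PEG, stretch modulus 10 nN,
contour length free); an event is *specific* iff its rupture length falls in
the PEG window (default 10–40 nm, bracketing a 3.4 kDa PEG contour of
~27 nm plus the protein) and the tether fit reaches R² ≥ 0.9.  Ambiguous
events are simply non-specific; no flicker-noise disambiguation is
attempted.  Loading rate r = k_syst × v.

**Modal force**: rupture forces are histogrammed with Freedman–Diaconis
bins and the main mode fitted with a Gaussian.  The fit region is
*asymmetric* — from where counts fall below 0.8× the peak on the low-force
side to below 0.5× on the high-force side, extended one bin each way.  The
rupture-force density carries its heavy tail at low forces, and a symmetric
half-maximum region was measured (on simulated ensembles) to drag the fitted
centre ~2 pN below the true mode, biasing the recovered k_off upward by
~20%; the asymmetric region removes the bias (recovered k_off median 0.31
vs truth 0.30 over 50 replicate ensembles) at slightly higher variance.
Both fractions and the extension are arguments.

**Bell–Evans fit**: F* = (k_BT/x_β)·ln(r·x_β/(k_off·k_BT)) is linear in
ln r; ordinary regression gives x_β = k_BT/slope and k_off from the
zero-force intercept, with standard errors by the delta method from the
regression covariance.  A single 1000-events/rate ensemble leaves
sd(k_off) ≈ 0.05 s⁻¹, so recovery checks use the median over 11 seeded
ensembles, which is effectively deterministic.

**k_on heuristic**: k_on ≈ N_A·V_eff/t with V_eff = (2/3)πr_eff³, the
half-sphere a tethered partner explores during the dwell time.  This is an
order-of-magnitude estimate only and is documented as such; defaults
r_eff = 10 nm, t = 0.1 s give ~1.3e4 M⁻¹s⁻¹.  K_A = k_on/k_off.

## Pose screening (`spectrobind.poses`)

* Donor point: unweighted centroid of the nine indole-ring heavy atoms
  (CG, CD1, CD2, NE1, CE2, CE3, CZ2, CZ3, CH2) of the donor Trp (residue
  number configurable; 214 in the 1AO6 numbering).  Mass weighting is not
  used — the ring atoms' masses are nearly equal and the reference is a
  convention, not an observable.
* Acceptor point: the 5′-terminal phosphorus of the lowest-numbered
  nucleotide, falling back to O5′ then C5′ (recorded in the report).
* Selection: a pose passes when D_DA + dye offset (default 0.1 nm for the
  5′-attached dye) lies within measured R ± tolerance.  Defaults R = 4.3,
  tol = 0.5.  The equivalent bare-D_DA window is exposed as
  `DistanceReport.bare_window`.
* Grouping: greedy single-linkage in docking-rank order with an RMSD
  threshold (default 0.1 nm).  RMSD is computed over ligand phosphorus atoms
  after least-squares (Kabsch) superposition of receptor Cα atoms — the
  atom selections are explicit arguments because published screens rarely
  state them.  Rank-order greediness makes the partition deterministic and
  makes "first-ranked member = representative" automatic.
* `pocket_charge_descriptor` counts formal charges (+1 Arg/Lys, −1 Asp/Glu)
  of receptor residues with any atom within a cutoff (default 0.5 nm) of the
  ligand.  It is a descriptor of electrostatic complementarity, not a
  Poisson–Boltzmann energy.

Coordinates are Å in PDB files and nm in all reports; the conversion
constant lives in one place (`poses.A_PER_NM`).

## Synthetic data (`spectrobind.simulate`)

Every generator is a pure function of (parameters, seed) and returns its
ground truth alongside the data; `write_*` helpers persist a JSON provenance
sidecar so recovery tests never hard-code truths.

* **Titrations**: intensities from the chosen binding model at the study
  design (5 µM fluorophore, quencher grid 0 + 0.5–15 µM) with unit-mean
  multiplicative lognormal noise (positivity-preserving), CV 2% by default.
* **Decays**: multi-exponential × Gaussian IRF (FWHM 0.8 ns — the
  instrument is specified only as sub-nanosecond — centred 3 ns into a
  50 ns window at 0.055 ns/channel), scaled to 1e4 peak counts and
  Poisson-sampled; the IRF trace is Poisson-sampled too, as a measured IRF
  would be.  `biexponential_for_mean` builds two components (lifetimes 0.4×
  and 1.15× the target) whose amplitude-weighted mean equals a requested
  value exactly.
* **Rupture forces**: exact inverse-CDF sampling of the Bell–Evans
  distribution — no rejection step, so the sample law is analytic and the
  KS test against the closed-form CDF is a strict correctness check.
* **Force curves**: eFJC tether deflection on a z-grid with Gaussian
  read-out noise; the final pre-rupture sample sits exactly at the target
  rupture force so the inserted event's force is well-defined.
* **Poses/trajectories**: a rigid toy receptor (helical Cα scaffold, a
  complete idealised Trp, a few charged residues) and a 5-nucleotide toy
  RNA placed so the 5′-P sits at a Normal(mean, sd)-drawn distance from the
  ring centroid, written as standards-compliant multi-MODEL PDB so the
  screen exercises its real parser.

What the synthetic data do **not** emulate: spectral shapes and Raman
background (titrations start from already-reduced intensities), TCSPC
afterpulsing and drift, cantilever hydrodynamics and nonspecific adhesion
at small tip–surface separations, and realistic RNA conformational
ensembles.  Passing recovery tests therefore demonstrates the correctness
of the estimators under the stated noise models, not robustness to every
instrument artifact.

## Problem sizes

Recovery checks use 10 replicate titrations, 20 replicate decays per
lifetime condition (60 fits), 11 rupture ensembles of 5×1000 events, and
pose sets of up to 1000 models — sizes chosen so each estimator's sampling
error is comfortably below the tolerance it is checked against while the
whole suite runs in well under a minute.

## Known limitations

* The delta-method σ_R is biased low at very small FRET efficiencies (the
  measured regime); a Monte-Carlo propagation is the better estimate there.
* k_on (and hence K_A) is an effective-volume heuristic, order of magnitude
  only.
* The eFJC tether fit frees only the contour length; Kuhn length and
  elasticity are fixed at PEG-typical values.
* The distance window's dye offset enters additively on D_DA; anisotropic
  dye-linker geometry is not modelled.
* No command-line interface: the library functions and
  `scripts/acceptance.py` are the intended entry points.
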