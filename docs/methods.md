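# Methods

This note records the models implemented in `methyldyn`, the defaults and
conventions chosen where the field admits more than one, and what the
synthetic-data tests do and do not establish about real data.

## Chemical exchange simulators (`methyldyn.spin`)

Exchange is parameterized by first-order rates, never by (rate,
population) pairs: when a three-state probe shares only one of its two
processes with other probes, it is the rates of that process — not the
populations — that are common across probes, so rates are the natural
global parameters.  Stationary populations follow from detailed balance
on the star topology (B⇌A⇌C has no direct B–C exchange).

**CPMG convention.** The constant-time element train is
`n = 2·T_relax·νCPMG` repeats of (δ − 180° − δ) with `δ = 1/(4νCPMG)`,
i.e. `νCPMG = 1/(4δ)`.  The convention is arbitrary but must be shared by
simulator, fitter and any closed-form cross-check; all three here use it.
`n` must be an integer, and even for MQ (a single ¹H 180° sits between
two equal half-trains, interconverting zero- and double-quantum
coherences).  Pulses are ideal: a ¹³C 180° flips the sign of the ¹³C
offset terms, the ¹H 180° flips the ¹H offsets.  A single intrinsic R2
is shared by all exchanging states per simulated experiment (the data do
not constrain state-specific R2 and the literature default is a shared
value); CEST likewise uses a single R1 per probe, with no thermal
recovery term over the exchange period.  ²H decoupling during the CEST
period is treated as ideal.

**Propagation.** Evolution matrices are exponentiated by
eigendecomposition, vectorized over νCPMG delays or CEST offsets, and
echo trains are applied by matrix powers of the two-element block.
R2,eff is `−(1/T) ln |ΣM(T)| / |ΣM(0)|` from magnetization started at
the stationary populations.  Note that this finite-T observable differs
from the asymptotic decay rate by a `(1/T)·ln(projection amplitude)`
term; comparisons with rate expressions such as Carver–Richards are made
on rates, extracted from two propagation lengths (`S(2T)/S(T)`), which
cancels the amplitude exactly.  ppm↔rad/s conversions derive the ¹³C
(¹H ratio 0.251450) and ¹⁵N Larmor frequencies from the stated ¹H field
using gyromagnetic-ratio tables carried to 6 significant figures.

## Global fitting (`methyldyn.exchange`)

The two-stage strategy mirrors standard practice for a shared slow
process plus local fast processes:

1. **CEST-only two-state global fit** — `k_ab`, `k_ba` shared across the
   concerted probe set; per-probe Δω (sign determined by the dip
   position), R1 and R2.  Initialization uses a paired-sample asymmetry
   detector: the minor dip is measured against exactly mirrored offset
   pairs about the main dip (interpolating across the steep main-dip
   flanks would fabricate asymmetry, and the candidate center is chosen
   by symmetry of the innermost pairs because the noisy grid argmin can
   sit one step off a flat-bottomed dip).  Probes whose largest paired
   asymmetry is below 3·√2·σ(noise) are flagged non-identifiable.
2. **Per-probe joint fit** of SQ 850 MHz + MQ 850/600 MHz CPMG and both
   CEST powers to a two-state or bifurcated three-state model, with
   `k_ab`, `k_ba`, Δω_C,ab fixed from stage 1 for concerted probes.
   Geminal methyl pairs share rates.  ¹H Δω stays fixed at 0 unless
   explicitly released.  Intrinsic R2 is per (experiment, field).

Least squares is Levenberg–Marquardt on error-weighted residuals (CEST
as normalized intensities, CPMG as R2,eff; mixed units are commensurate
after weighting), with multi-start over log-spaced exchange-rate grids
and optional early stop when a start reaches the noise floor.  Per-probe
simulations are memoized so numerical-Jacobian steps on one probe's
parameters do not re-simulate the others.

Errors are standard deviations over refits of Monte Carlo simulations of
the data (curves + per-point Gaussian noise at the stated errors),
warm-started from the central solution; the default is 200 draws, and
the replicate-heavy tests use 15–25 draws per fit as their problem size.
Model choice between the nested two-/three-state fits uses AICc, with
the cross-probe coefficient of variation of the shared rates reported as
the consistency diagnostic.

## Synthetic scenario (`methyldyn.synthetic`)

The default scenario encodes the study conditions: 10 concerted probes
with `kex = 240 s⁻¹`, `p_B = 1.3 %` and Δω_C,ab between 0.3 and 1.4 ppm;
8 of the 10 carry an additional fast local process with kex between 1000
and 2500 s⁻¹, populations 0.11–0.24 % and ¹³C Δω about 3× the
slow-process value; five datasets per probe (SQ 850, MQ 850, MQ 600,
CEST 41 and 25 Hz at 600 MHz).  Noise is independent Gaussian:
fractional 0.01 on CPMG intensities (calibrated by the duplicate planes
the generator emits) and 0.008 absolute on normalized CEST intensities.
Acquisition parameters not otherwise determined were fixed once at
field-typical values: CPMG `T_relax = 40 ms` with a 25–1000 Hz νCPMG
grid and duplicates at two rates, CEST exchange period 0.4 s with a
25 Hz offset grid, ²H decay delays 0–5 ms (²H R2 of a ~40 ns tumbler
runs to several hundred s⁻¹), ¹⁵N rates at 600 MHz.

**CEST senses the slow process only.** The generated CEST profiles
contain, by default, only the concerted process
(`SyntheticScenario.cest_includes_fast = False`).  This encodes the
ms-timescale selectivity of the CEST experiment as observed in the study
the scenario emulates; it is a modelling assumption, not an emergent
property of these simulators — with the flag on, the broad shallow
contribution of the fast processes biases the two-state CEST stage's
shared kex upward by ~15–35 % at these noise levels.  Consequently the
passing recovery tests certify the fitting engine against data whose
CEST stage is uncontaminated; on real data the published procedure rests
on the empirical observation that unconstrained full fits agree with the
CEST-only fit.  A related artifact of the one-sided assumption is a mild
upward bias, with large Monte Carlo uncertainty, in the fast-process
exchange rate recovered by the joint fit (the model's fast process would
produce a small CEST dip the generated data lack); fast-process
populations and shift differences recover without noticeable bias.

Other limitations of the generator: noise is Gaussian and independent
(no peak-overlap, baseline or phase artifacts), reference planes carry
the same noise as data planes, probes never go missing, and ¹H Δω of the
fast processes is zero by default.

## Tumbling (`methyldyn.tumbling`)

Rigid isotropic rotor, `J(ω) = (2/5)·τc/(1+(ωτc)²)`, with ¹⁵N dipolar
(N–H 1.02 Å) and CSA (−160 ppm) constants; τc minimizes the
error-weighted misfit of per-residue R2/R1 ratios (bracketed 1–100 ns),
which cancels site-specific interaction amplitudes to first order.
Filtering: terminal residues out before statistics; log₂(R1) and
log₂(R2) trimmed at mean ± 1 SD (an SD of zero trims nothing); NOE
below 0.65 (configurable, 0.6 for the truncated apo construct) out.
Exchange-broadened residues can be excluded on a second pass (R2
residual above +3× the MAD-based scatter of a first-pass fit) — a
reproducible analogue of an Rex flag.  Anisotropic diffusion is out of
scope; the anisotropy of the system studied is slight.  The 5 %→99.8 %
D₂O correction is `τc,D₂O = 1.235·τc,5% / (0.95 + 0.05·1.235)` at 25 °C.

## Fast dynamics (`methyldyn.dynamics`)

`S²axis = 80·R2(²H) / ((2π·qcc)²·τc)` with qcc = 167 kHz; τc must be
solvent-matched (the D₂O value for samples in D₂O).  ΔS² errors are
root-sum-square of the two states' errors (independent measurements);
probes with ΔS² error ≥ 0.07 are dropped before the mean.  The entropy
meter is exactly linear, `−TΔS_conf = −T·s_d·⟨ΔS²⟩·Nχ`, with
s_d = −0.0011 kcal mol⁻¹ K⁻¹ and T = 298.15 K by default; Nχ is a
configuration input (1136 for residues 26–307 of the full-length
construct).  A helper counts χ dihedrals from sequence using a standard
per-residue-type table, but counting conventions differ (e.g. whether
terminal NH₃⁺/χ of C/S/T count), so an externally determined Nχ takes
precedence.  The thermodynamic cycle reports the coupling as
step1 + step3 of the truncation path and the closure residual
pathA − (step1+step2+step3); on a common probe set with a common error
filter the closure is exactly zero by construction (telescoping sums),
so a nonzero closure on real data measures probe-set inconsistency, not
physics.  Methyl CSPs use `sqrt(ΔωH² + 0.25·ΔωC²)`.

## RDC (`methyldyn.rdc`)

The alignment tensor is fit linearly: `D_i = uᵢᵀ S uᵢ` with S the
symmetric traceless order matrix carrying the dipolar prefactor (units
Hz), solved by weighted least squares over ≥ 5 bond vectors; one tensor
is fit jointly over both protomers of the homodimer.  Amide H positions
use explicit hydrogens when present, else the in-plane bisector
construction from N, Cα and the preceding carbonyl C.  Agreement is
reported as Pearson r (the discrimination statistic) and
`Q = rms(D_obs − D_calc)/rms(D_obs)`.  Excluded-by-default regions
(flexible termini, disordered loop) are caller-specified residue ranges.

## sPRE (`methyldyn.spre`)

The metric is `1 − I(2 mM Gd)/I(0 mM)`.  The reference curve `A·r⁻⁶`
has a closed-form weighted amplitude; robustness comes from a
median-ratio initial estimate and one refit excluding flagged probes.
A probe is `elevated` when its residual exceeds 2× the MAD-based scatter
(floored at the stated measurement error so exact data are not flagged
on rounding dust).  The structural depth fallback defines depth as the
distance from the methyl carbon to the nearest solvent-accessible
surface atom (Shrake–Rupley area > 1 Å²) — a deliberate approximation
to a true surface-distance computation, adequate for rank ordering;
externally computed depth tables take precedence.

## Numerical and testing notes

* Problem sizes in the test suite: recovery studies use 20 seeded
  replicates of the default scenario with 15–25 Monte Carlo draws per
  fit and 3–4 optimizer starts; oracle grids cover kex 100–5000 s⁻¹,
  p_B 0.005–0.1, Δω 0.2–3 ppm.
* CEST normalized intensities may undershoot zero slightly near
  resonance (coherent nutation under the lock); the bound checked is
  [−0.01, 1+1e−9].
* Duplicate-point RMSD is reported as the implied per-point noise,
  `√2 × RMS(half-differences)` pooled over probes of a dataset.
* Degenerate inputs: all-zero exchange rates raise; a forward rate with
  zero reverse rate raises (population trapped); flat CEST profiles are
  flagged non-identifiable rather than fitted to arbitrary rates;
  non-decaying decay series return the negative best-fit rate with a
  flag.
* Determinism: every stochastic routine takes a seed; equal seeds give
  bit-identical tables, fits and Monte Carlo error bars.
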