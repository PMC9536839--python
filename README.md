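# methyldyn

Analysis pipeline for methyl-based NMR dynamics of large proteins, built
around the study of substrate-binding cooperativity in the 72 kDa
homodimeric enzyme human thymidylate synthase (hTS).  The package covers
the complete chain of inference from peak-intensity tables to
thermodynamic conclusions:

* **µs–ms motions** — forward simulation of ¹³C single-quantum (SQ) and
  ¹H/¹³C multiple-quantum (MQ) CPMG relaxation dispersion and of ¹³C CEST
  profiles by numerical Bloch–McConnell propagation, for two-state
  (A⇌B) and bifurcated three-state (B⇌A⇌C) exchange; global fitting of
  multi-field, multi-experiment data with parameter sharing and fixing,
  Monte Carlo errors and AICc model selection.
* **ps–ns motions** — methyl symmetry-axis order parameters `S²axis` from
  ²H transverse relaxation of CHD₂ methyls, order-parameter differences
  between ligation states, and the conformational-entropy meter.
* **Rotational diffusion** — isotropic τc from ¹⁵N R₁/R₂/NOE with the
  log₂-trimming and NOE inclusion rules, and the D₂O viscosity correction.
* **Structure discrimination** — residual dipolar coupling (RDC)
  alignment-tensor fits (order-matrix SVD) scoring candidate conformations.
* **Solvent exposure** — solvent-PRE intensity ratios versus probe depth
  with an `A·r⁻⁶` reference curve and robust flagging of anomalously
  exposed probes.
* **Synthetic data** — generators reproducing the statistical structure of
  all of the above, so every stage is testable without spectrometer data.

## The models in brief

Chemical exchange between states with distinct shifts adds a contribution
to transverse relaxation.  CPMG experiments measure
`R2,eff(νCPMG) = −(1/T) ln I(νCPMG)/I(0)`; CEST measures normalized
intensity dips as a weak spin lock is stepped across the spectrum.  Both
observables are computed here by propagating the Bloch–McConnell
equations with the exchange generator `K` built from first-order rates
(k_ab, k_ba, k_ac, k_ca); populations follow from detailed balance.  In
the system studied, ten methyl probes share a slow concerted process
(kex ≈ 240 s⁻¹, p_B ≈ 1.3 %) assigned to switching between active and
inactive conformations, while eight of them also undergo faster local
excursions to low-populated "exposed states".

On the fast timescale, the ²H rate of a CHD₂ methyl obeys
`R2(²H) = (1/80)(2π·qcc)² S²axis τc` with qcc = 167 kHz, and the entropy
meter converts a mean order-parameter change to
`−TΔS_conf = −T · s_d · ⟨ΔS²axis⟩ · Nχ` (s_d = −0.0011 kcal mol⁻¹ K⁻¹,
Nχ the side-chain dihedral count, 1136 here).

## Worked example

```python
import numpy as np
from methyldyn import (CestGlobalModel, default_scenario, entropy_meter)
from methyldyn.synthetic import cest_datasets_from_table, generate_cest_tables

# concerted-process recovery from synthetic CEST data
scn = default_scenario(seed=7)
tables = generate_cest_tables(scn)
datasets = [d for t in tables.values() for d in cest_datasets_from_table(t)]
model = CestGlobalModel(datasets)
fit = model.fit(n_starts=4, seed=1)
fit = model.monte_carlo(fit, n=25, seed=3)
print(f"kex = {fit.kex_ab:.1f} +/- {np.std(fit.mc_values['kex_ab'], ddof=1):.1f} s^-1")
print(f"p_B = {100 * fit.p_b:.2f} %")

# the entropy meter on the published mean order-parameter change
value, _ = entropy_meter(0.027, n_chi=1136)
print(f"-T dS_conf = {value:.1f} kcal/mol")
```

prints (exact fit values vary slightly with the seed):

```
kex = 250.7 +/- 12.7 s^-1
p_B = 1.28 %
-T dS_conf = 10.1 kcal/mol
```

The fitted kex and p_B recover the generator's truth (240 s⁻¹, 1.3 %)
within their Monte Carlo errors, and a mean rigidification of
⟨ΔS²axis⟩ = 0.027 over 1136 dihedrals corresponds to an entropic free
energy penalty of ~10 kcal/mol — large enough to account for an
entropically driven binding cooperativity of a few kcal/mol if most of
the rigidification accompanies the first binding event.

The same steps are available from the shell:

```bash
methyldyn make-synthetic --seed 7 --out data/
methyldyn fit-exchange --data data/ --probe L198-CD1 --seed 1 --out fits/
methyldyn entropy --s2x apo.csv --s2y bound.csv --n-chi 1136
```

## Layout

| module | contents |
| --- | --- |
| `methyldyn.spin` | Bloch–McConnell forward simulators (SQ/MQ CPMG, CEST) |
| `methyldyn.relax` | intensity→rate conversions, monoexponential fits, NOE, two-plane Rex |
| `methyldyn.exchange` | global CPMG+CEST fitting, constraints, Monte Carlo, model selection |
| `methyldyn.tumbling` | ¹⁵N filtering rules, isotropic τc fit, D₂O correction |
| `methyldyn.dynamics` | S²axis, ΔS², entropy meter, thermodynamic cycle, methyl CSPs |
| `methyldyn.rdc` | RDCs from couplings, alignment-tensor SVD fit, structure RMSD |
| `methyldyn.spre` | sPRE ratios, r⁻⁶ depth curve, structural depth fallback |
| `methyldyn.synthetic` | scenario definitions and table generators |
| `methyldyn.io`, `methyldyn.cli` | CSV dialects, config, structures, subcommands |

See `docs/methods.md` for the modelling choices, default parameters and
known limitations.
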