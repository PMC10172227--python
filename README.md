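# mts — musculotendon parameter toolkit

`mts` is a toolkit for the four musculotendon parameters of Hill-type
muscle contraction dynamics — maximal isometric force `F_iso,max`, optimal
fiber length `l_opt^f`, optimal pennation angle `α_opt`, and tendon slack
length `l_sla^t` — aimed at users and builders of musculoskeletal models
(OpenSim-style lower-limb models and the muscle architecture datasets
behind them). It covers four tasks:

1. **Parameter derivation.** Turn raw architecture measurements (fiber
   length, sarcomere length, pennation angle, muscle volume) into
   model-ready parameters, with every simplification made explicit and
   logged: sarcomere-based optimal scaling of fiber length
   (`l_opt^f = l^f · l_opt^s / l^s`), pennation scaling under constant
   muscle thickness (`α_opt = asin(l^s sin α / l_opt^s)`), conventional
   and projected PCSA (`V/l_opt^f`, optionally `· cos α_opt`), specific
   tension σ to force (`F_iso,max = σ · A_PCS`), and tendon slack length
   from the MTU length at the optimal joint position
   (`l_sla^t = l_opt^mt − l_opt^f cos α_opt`).
2. **Isometric force.** The rigid-tendon Hill-type force
   `F = F_iso,max · cos α(l^mt) · (f_pe + a·f_ce)(l_norm^f)` with the
   constant-thickness pennation model and pluggable, differentiable
   force–length curves.
3. **Analytic sensitivity.** Closed-form partial derivatives ∂F/∂θ for all
   four parameters (including the volume-coupled case where PCSA = V/l_opt^f
   makes force capacity co-vary with fiber length), their normalized form
   `(∂F/∂θ)·θ/F_iso,max`, a finite-difference oracle, parameter-variation
   sweeps, and sensitivity heatmaps. The reproducible headline: force
   estimation is most sensitive to the tendon-side parameter (slack length /
   optimal joint position) and least sensitive to pennation angle.
4. **Calibration and auditing.** The analytic derivatives double as the
   gradient for bounded quasi-Newton calibration of parameters against
   force observations, and a provenance auditor encodes nine common
   derivation simplifications (optimal-at-rest, inherited fiber length,
   uniform specific tension, slack-at-rest, …) as machine-checkable rules
   with graded uncertainty and impact.

## Worked example

Derive a soleus-like muscle from raw measurements (fiber 44 mm at a
2.12 µm sarcomere, pennation 28.3°, volume 500 cm³, σ = 61 N/cm²,
MTU length 310 mm at the optimal joint position), then ask which parameter
the force estimate is most sensitive to:

```python
import math
from mts import (MusculotendonParams, MuscleState, muscle_force,
                 scale_fiber_length, scale_pennation, pcsa_conventional,
                 max_isometric_force, normalized_derivative)

l_opt_f_mm   = scale_fiber_length(44.0, 2.12, 2.7)
alpha_opt_deg = scale_pennation(28.3, 2.12, 2.7)
pcsa  = pcsa_conventional(500.0, l_opt_f_mm / 10.0)
f_max = max_isometric_force(61.0, pcsa)

print(f"optimal fiber length : {l_opt_f_mm:.1f} mm")
print(f"optimal pennation    : {alpha_opt_deg:.1f} deg")
print(f"PCSA                 : {pcsa:.1f} cm^2")
print(f"F_iso_max            : {f_max:.0f} N")

params = MusculotendonParams(
    f_iso_max=f_max, l_opt_f=l_opt_f_mm / 1000.0,
    alpha_opt=math.radians(alpha_opt_deg), l_opt_mt=0.310,
    sigma_iso_max=61.0, volume=500.0, name="soleus_like")
print(f"tendon slack length  : {params.l_sla_t*1000:.1f} mm")

f = muscle_force(params, MuscleState(0.310, 1.0))
print(f"force at optimum     : {f:.0f} N  (= F_iso_max*cos(alpha_opt))")
for which in ("f_iso_max", "l_opt_f", "l_opt_f_volume", "alpha_opt", "l_opt_mt"):
    nd = normalized_derivative(which, params, 0.305, 1.0)
    print(f"normalized dF/d{which:<14s}: {nd:+.2f}")
```

Output:

```
optimal fiber length : 56.0 mm
optimal pennation    : 21.9 deg
PCSA                 : 89.2 cm^2
F_iso_max            : 5443 N
tendon slack length  : 258.0 mm
force at optimum     : 5052 N  (= F_iso_max*cos(alpha_opt))
normalized dF/df_iso_max     : +0.90
normalized dF/dl_opt_f       : +0.04
normalized dF/dl_opt_f_volume: -0.86
normalized dF/dalpha_opt     : -0.16
normalized dF/dl_opt_mt      : -2.64
```

Reading the numbers: sarcomere scaling stretches the raw fiber by 27%
(2.12 → 2.7 µm) and corrects the pennation angle from 28.3° to 21.9°; at
the optimal position the muscle transmits `F_iso,max·cos α_opt`. At a
slightly shortened MTU length (305 mm), a 1% error in the tendon-side
parameter shifts the force estimate by 2.6% of `F_iso,max` — several times
the effect of a 1% error in any other parameter — while a 1% pennation
error moves it by only 0.16%. A normalized value of −0.86 for the
volume-coupled fiber length reflects that PCSA = V/l_opt^f makes force
capacity fall as fibers lengthen.

The same operations are available from the shell:

```sh
mts synth arch --n 5 --seed 1 --out arch.csv      # synthetic dataset
mts derive --input arch.csv --out params.csv      # raw -> parameters
mts grad --params p.json --which l_opt_mt --l-mt 0.305
mts sweep --params p.json --which l_opt_mt --variations -0.01,0.01 --out sweep.csv
mts calibrate --params init.json --obs obs.csv --free l_opt_f,l_opt_mt --out fit.json
mts audit --metadata examples/provenance/delp_1990_lineage.yaml
```

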