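# diastolefit

Joint estimation of **passive myocardial stiffness**, the **unloaded
left-ventricular reference state**, and the **residual diastolic active
tension (AT) profile** from a series of diastolic shapes with synchronous
cavity pressures.

In diastolic dysfunction the ventricle keeps generating contractile stress
while it fills, so the observed motion mixes two quantities that standard
passive-inflation fitting cannot separate: how stiff the tissue is and how
much tension is still decaying. `diastolefit` implements an estimation
pipeline that separates them, together with a reduced-order
left-ventricular mechanics model and an in silico harness that validates
every stage against known ground truth. It is aimed at researchers in
cardiac mechanics and model-based cardiology who want a desk-scale,
fully-testable implementation of this estimation strategy.

## Model

Passive myocardium is the four-parameter transversely isotropic
exponential (Guccione) law,

```
W = C1 (e^Q − 1),
Q = C2 Eff² + C3 (Ess² + Enn² + 2 Esn²) + C4 (2 Efs² + 2 Efn²),
```

with E the Green–Lagrange strain in the fiber/sheet/normal frame,
reformulated for estimation as a stiffness scale and anisotropy fractions

```
α = C2 + C3 + C4,   r_i = C_i / α  (r2 + r3 + r4 = 1).
```

The total second Piola–Kirchhoff stress is
`T = ∂W/∂E + p C⁻¹ + Ta f⊗f` with a length-dependent active fiber tension
`Ta = Tz (1 + β(√(2Eff+1) − 1))`. Given observed frames {y_i} and
pressures {P_i} (frame n = end-diastole, assumed fully relaxed:
`Tz(n) = 0`), the pipeline tries each earlier frame k as the approximate
unloaded state, estimates the constitutive parameters from the
end-diastolic frame by grid sweeps (C1 fixed at 1 kPa because of the C1–α
coupling), refines the unloaded state by deflation (inverse inflation)
from end-diastole, estimates Tz(i) for every frame by coarse-then-refined
1-D sweeps, and accepts the smallest k whose tension profile is positive
and monotonically decreasing. The forward model is an axisymmetric
thick-walled ellipsoidal LV with a rule-based ±60° fiber helix, exactly
incompressible Rayleigh–Ritz kinematics (radial + torsional modes) and
virtual-work equilibrium; see `docs/methods.md`.

## Worked example

Generate the six-frame synthetic diastole (pressures rising 0.33 → 2.00
kPa, AT decaying 8.00 → 0 kPa, noiseless) and run the full pipeline:

```python
import numpy as np
from diastolefit import SweepConfig, generate_insilico_case, run_algorithm1

case = generate_insilico_case()          # six frames + stored ground truth
result = run_algorithm1(case.frames, SweepConfig())
print("chosen reference frame k =", result.reference_frame)
print("AT profile (kPa):", np.round(result.at_profile, 3))
print("true AT (kPa):   ", case.true_at)
r = result.reformulated
print(f"alpha={r.alpha:.2f} r2={r.r2:.2f} r3={r.r3:.2f} r4={r.r4:.2f}")
```

prints

```
chosen reference frame k = 2
AT profile (kPa): [5.528 1.957 0.594 0.155 0.023 0.   ]
true AT (kPa):    [8.   2.35 0.68 0.21 0.05 0.  ]
alpha=39.34 r2=0.90 r3=0.00 r4=0.10
```

Reading this: the tension criterion correctly identifies frame 2 — where
inflating pressure and contracting tension roughly balance — as the best
stand-in for the unloaded state, the end-diastolic tension is zero by
construction, the stiffness scale α lands exactly on the ground-truth grid
cell (39.34), and the estimated tension decays monotonically like the
truth. The early-diastolic tension is underestimated (5.53 vs 8.00 kPa at
frame 1) because the frame-2 reference is pre-strained by the very tension
being estimated and the anisotropy fractions absorb part of that
pre-strain — softening or stiffening the fiber direction mimics residual
tension, the central confound this method is designed to mitigate.
`docs/methods.md` quantifies this limitation.

The same experiment from the shell:

```
diastolefit insilico generate --out frames/
diastolefit estimate --frames frames/ --out result/
diastolefit insilico scenarios --frames frames/ --out scen/ --plot
```

The scenario command scores six pipeline variants against the stored
truth (reference frame k = 1 vs criterion-selected, deflation off/on) and
writes a `scenario_report.csv`; in the run above the full pipeline attains
an AT RMSE of 1.12 kPa, omitting only deflation 1.50 kPa, and naively
taking the first frame as the unloaded state 3.70 kPa.

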