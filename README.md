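# wristsim

A synthetic physiological wrist simulator for studying how wrist muscle
forces redistribute when one muscle is removed from active control.

*In vitro* wrist simulators replicate active wrist motion in cadaveric
specimens by pulling on the distal tendons of the six muscles that insert
at the carpals or metacarpal bases — FCR, FCU, ECRL, ECRB, ECU and the
abductor pollicis longus (APL). The APL, although primarily a thumb
abductor, has a large moment arm about the radioulnar-deviation axis and is
a strong radial deviator of the wrist; nevertheless many simulator studies
leave it unactuated. `wristsim` re-creates this experiment entirely in
software so that the consequences of omitting the APL can be examined under
fully controlled, reproducible conditions: a cohort of synthetic specimens
is driven through cyclic planar and circumduction motions by a redundant
force-distribution controller, the APL is switched off, and the resulting
force changes are tested with paired nonparametric statistics.

It is intended for musculoskeletal-biomechanics researchers who want a
desk-scale, fully scripted counterpart of a cable-driven joint simulator:
every part of the loop — anatomy, moment-arm measurement, control,
statistics — is an inspectable, testable Python object.

## The model

The wrist is a two-axis joint (flexion–extension FE, radioulnar deviation
RUD; flexion and radial deviation positive). Each muscle *i* contributes
torque through its posture-dependent moment arms, collected in a 2 × m
matrix **R** (mm). A torque demand **τ** = (τ_FE, τ_RUD) in N·mm is
resolved across the muscles by static optimization:

```
minimize   Σᵢ (fᵢ / F_max,ᵢ)²
subject to R f = τ,   F_min,ᵢ ≤ fᵢ ≤ F_max,ᵢ
```

with F_max = PCSA × specific tension and F_min a minimum-activity fraction
of F_max (muscles are kept minimally taut, as on a cable-driven rig). The
criterion is strictly convex, so the solution is unique; a summed
cubed-muscle-stress criterion Σ(fᵢ/PCSAᵢ)³ is available to check that
conclusions do not hinge on the effort criterion. Demands outside the
achievable torque set (a zonotope in torque space) are reported with the
closest achievable torque, never silently clipped.

Around this core:

* **Specimens** are generated with log-normal inter-specimen scatter on
  PCSA and moment-arm magnitudes; muscle role signs (e.g. APL = weak
  flexor, strong radial deviator) are preserved by construction.
* **Moment arms** are estimated as on a physical rig, by the passive
  tendon-excursion method: the joint is rotated through an angle grid, the
  (noisy) tendon excursion E(θ) is fitted with a polynomial, and the moment
  arm is its derivative r = dE/dθ.
* **Control** is position feedback (PD, pole-placed per specimen) with
  exact gravity-compensation feedforward for the vertically upward hand,
  iterated every 4.5 ms; the plant integrates the hand segment's decoupled
  two-axis dynamics. A quasi-static mode snaps to the reference and uses
  inverse-dynamics torques directly.
* **Statistics**: forces are evaluated every 10° in FE and 5° in RUD and
  as per-cycle peaks (first cycle discarded as transient), then compared
  between conditions with a two-sided Wilcoxon signed-rank test
  (W = min(W⁺, W⁻); exact sign-flip null and tie-corrected normal
  approximation without continuity correction; α = 0.05, no
  multiple-comparison adjustment).

Cohort anatomical means are literature-scale placeholder values, declared
in the configuration — see `docs/methods.md` for every default and why.

## Worked example

```python
import wristsim as w

specimen = w.make_specimen(1)
trajectory = w.generate_trajectory("RUD15", cycles=5)   # 15 deg ulnar <-> radial
intact = w.run_controller(specimen, trajectory, w.ControllerConfig())
ablated = w.run_controller(specimen, trajectory, w.ControllerConfig(ablation={"APL"}))
for muscle in ("FCR", "ECRL", "ECU", "APL"):
    pi, pa = w.peak_force(intact, muscle), w.peak_force(ablated, muscle)
    print(f"{muscle:4s}  intact {pi:6.2f} N   APL off {pa:6.2f} N   change {100*(pa-pi)/pi:+6.1f}%")
```

prints

```
FCR   intact   1.87 N   APL off   6.29 N   change +235.8%
ECRL  intact   3.17 N   APL off   7.51 N   change +137.1%
ECU   intact   5.96 N   APL off   4.13 N   change  -30.7%
APL   intact   4.31 N   APL off   0.00 N   change -100.0%
```

With the APL switched off, its synergists FCR (flexor and radial deviator)
and ECRL (radial deviator) must supply the lost radial-deviation torque, so
their peak forces rise; its antagonist ECU needs to oppose less radial
torque, so its force falls. The magnitudes depend on this specimen's random
anatomy; the sign pattern is the robust finding.

The same experiment over a whole cohort, from the shell:

```bash
wristsim all --config run.yaml --out results/
```

writes the cohort manifest, trajectories, all simulation time series, the
per-grid-angle and peak paired comparisons (`comparisons.csv`), a markdown
summary table, and a provenance file with checksums. An empty `run.yaml`
reproduces the default experiment (7 specimens, 4 motions, 5 cycles, APL
ablation).

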