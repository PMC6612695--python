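# pbscatter

Collimator-scattered protons in spot-scanning proton therapy: a desk-scale
Monte Carlo study of their physical dose, dose-averaged LET and RBE impact.

Brass patient collimators sharpen the lateral penumbra of low-energy
scanned proton beams, but protons that graze the aperture edge are not
absorbed — they scatter into the patient with reduced energy and elevated
linear energy transfer. This package models a collimated scanning nozzle
(4-cm ABS energy absorber + 2/4-cm brass collimator) and a water phantom
and quantifies, for a systematic sweep of rectangular targets (range R,
SOBP width S, square field FS), how much dose the scattered protons add,
and whether their higher LET translates into a meaningful RBE increase.
It is aimed at medical-physics researchers who want a transparent,
reproducible, laptop-scale model of the effect rather than a full
treatment-head Monte Carlo.

## Model in brief

* **Transport**: condensed-history Monte Carlo (numba kernel) with Bethe
  stopping powers, Highland multiple Coulomb scattering, Bohr energy
  straggling and nuclear fluence attenuation; counter-based random streams
  per primary make every run bitwise reproducible.
* **Channels**: a proton is *collimator-scattered* (S) once it takes a
  step in brass; all others are *unscattered* (US). Per voxel and channel
  the tallies accumulate deposited energy and energy-weighted stopping
  power, so the dose-averaged LET is

      LET_d = ( Σ_n Σ_s L_sn ε_sn ) / ( Σ_n Σ_s ε_sn )

  with `ε_sn` the energy deposited in a step and `L_sn` the electronic
  stopping power of water at the mid-step energy.
* **RBE**: the LQ-based variable-RBE model

      RBE(D, α/β, LET_d) = (1/2D) ( sqrt( (α/β)² + 4D(α/β)·RBE_max
                             + 4·RBE_min²·D² ) − α/β )

  with `RBE_max = 0.99064 + 0.35605·LET_d/(α/β)` and
  `RBE_min = 1.1012 − 0.0038703·sqrt(α/β)·LET_d`; α/β = 3 Gy at the
  surface evaluation point and 10 Gy at the target centre.
* **Planning**: 5-mm energy layers and spot grids, nonnegative
  least-squares SOBP weights, a geometric aperture rule placing the 50%
  penumbra point on the field edge, and normalization to 2 Gy at the
  target centre.

See `docs/methods.md` for assumptions, calibration constants, estimator
windows and limitations.

## Worked example

Plan, simulate and evaluate one geometry — a 15-cm range, 5-cm SOBP,
8 × 8 cm² target — at the reduced-statistics profile:

```python
from pbscatter import TargetSpec
from pbscatter.study import run_geometry

record, extras = run_geometry(
    TargetSpec(15, 5, 8), n_primaries=200_000, seed=1017,
    voxel_size=0.2, max_step_water=0.2,
)
print(record.to_row())
```

Typical output (about 10 s on one core):

```
label              R15_S5_FS8
x_s                -4.0        # cm: scattered-dose maximum sits at the field edge
z_c                12.5        # cm: SOBP mid-depth
D_S_surface_frac   4.82        # % of the unscattered target-centre dose
D_S_center_frac    0.0         # scattered protons stop before 12.5 cm depth
letd_S_surface     0.94        # keV/um, scattered channel at (x_s, 0, 5 mm)
letd_US_surface    0.60
letd_tot_surface   0.72
rbe_US_surface     1.067
rbe_tot_surface    1.079
delta_rbe_surface  0.012
```

Read: the collimator adds ~5% extra dose at the surface near the field
edge for this geometry; the scattered protons carry higher LET, but after
dose-averaging the LET rise is ~0.1 keV/μm and the RBE increase ~0.01 —
the biological impact is dominated by the physical dose, not by the LET
change.

The same pipeline is scriptable from the shell:

```bash
pbscatter sweep --out sweep_configs --seed 1     # 32 fixture configs
pbscatter run   --out results_dir  --seed 1      # full study
pbscatter report --metrics results_dir/metrics.csv
```

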