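# Methods

`pbscatter` models the dosimetric and radiobiological impact of
collimator-scattered protons in spot-scanning proton therapy with a brass
patient collimator: a condensed-history Monte Carlo of the collimated
nozzle and a water phantom, per-channel (scattered / unscattered) dose and
dose-averaged-LET scoring, and a linear-quadratic variable RBE model. This
note records the model, its numerical choices, and what the desk-scale
results do and do not show.

## Beamline and scene

The short-range applicator consists of a 4-cm ABS energy absorber and a
brass collimator with a rectangular aperture; the collimator exit face sits
9 cm upstream of the isocenter, the water surface 6 cm downstream of that
face, and the isocenter 3 cm deep in water. The collimator is 2 cm thick
for target ranges up to 10 cm and 4 cm above that (the boundary case
R = 10 cm is assigned the thinner collimator, consistent with the 2-cm
configuration's 10-cm maximum range). The absorber sits 1 cm upstream of
the collimator entry; this gap is not a published dimension and is a fixed
configuration constant here. Coordinates are right-handed with +z along
the beam and the origin at the water-surface centre; voxel intervals are
half-open with zero-based indices.

The aperture is sized geometrically: the ray from the effective source
(the scanning magnet, at 200 cm for x and 240 cm for y upstream of the
isocenter) through the aperture edge crosses the proximal target plane at
half the field size, which places the 50% point of an unperturbed Gaussian
penumbra on the field edge. For an SOBP wider than the range the proximal
plane is the surface and the delivered proximal layers are clipped by the
applicator's 0.5-cm minimum residual range.

## Single-proton physics

Electronic stopping powers come from the uncorrected Bethe formula
(water I = 75 eV; brass as Cu70/Zn30 at 8.52 g/cm^3; ABS as C15H17N; dry
air at NTP), tabulated on a 400-point logarithmic grid from 0.1 to
300 MeV with log-log interpolation; CSDA ranges are cumulative integrals
of the reciprocal stopping power. Below the Bethe maximum the table is
extended with a velocity-proportional power law; transported protons are
absorbed locally below 1 MeV (sub-millimetre residual range), so the
extension only keeps the tables well-posed. Water stopping powers agree
with published reference tables within 5% at 10-200 MeV and the CSDA
range at 100 MeV is 7.71 cm.

The absorber is characterised by one water-equivalent thickness fitted by
least squares to the three published range-energy anchors
(74.9 MeV -> 0.5 cm, 142.5 -> 10, 192.4 -> 20 cm residual range); the fit
gives 4.26 cm WET and reproduces every anchor within +-0.16 cm. The ABS
bulk density is then adjusted (to 1.075 g/cm^3) so that transport through
the physical 4-cm slab realises the same WET at 142.5 MeV.

Multiple Coulomb scattering uses Highland's parameterisation with the
14.1 MeV constant. The logarithmic correction is evaluated once per
material on a characteristic slab thickness (absorber and collimator:
their physical thickness; air: the summed air path; water: the target
range) instead of per sub-step, which makes the accumulated angular
variance independent of the step size. Energy-loss fluctuations are
Gaussian with the Bohr variance. Nuclear interactions remove statistical
weight continuously with an 85 g/cm^2 mass interaction length; the removed
weight deposits nothing.

## Beam source model

Each spot is an uncorrelated Gaussian in position and angle at a source
plane just upstream of the absorber, plus the deterministic scanning tilt
(direction tangent = spot offset / magnet distance; the x and y magnets
sit at different distances, so the two transverse planes differ slightly).
The two Gaussian widths per energy are solved from (i) the published
collimator-free in-air sigma at the isocenter (11.7 -> 6.0 mm for the 2-cm
configuration, 11.7 -> 5.3 mm for the 4-cm one, interpolated linearly in
energy) and (ii) a configured 20% sigma growth between collimator exit and
isocenter. The multiple-scattering contribution of absorber and air is
predicted deterministically with the same Highland stepping the kernel
uses (deflect-after-advance lever arms) and subtracted in quadrature;
kinetic energy has a 0.6% relative Gaussian dispersion. Verification
transports reproduce all three printed anchors within 2%.

## Transport and scoring

Steps are limited by a per-material cap (1 mm in water and brass, 2 mm in
ABS, 5 mm in air; 2 mm in water for the reduced-statistics profile), the
distance to the next boundary, and 5% of the residual range, the latter
floored at 0.5 mm so end-of-range histories terminate in a bounded number
of steps. Energy loss is evaluated at the mid-step energy; the position
advances along the pre-deflection direction and the Highland kick is
applied afterwards. The attenuation factor uses exp(-x) expanded to
O(x^3) (x < 0.02 for every allowed step), and the same factor enters the
energy ledger, so energy bookkeeping (initial = deposited + removed +
escaped) holds to 1e-6 relative per history.

A proton is tagged collimator-scattered the first time it takes a step in
brass; the flag never resets, and absorber-scattered protons are not
tagged. In-phantom steps deposit energy into voxels split by exact slab
intersection; each deposit also accumulates eps * L with L the
unrestricted electronic stopping power of water at the mid-step energy
(keV/um), so the per-voxel dose-averaged LET is the ratio of the two sums
and the merged channel obeys the exact mixture identity. Tallies are
partitioned into batches by primary index for uncertainty estimates.
Randomness is a counter-based splitmix64 stream per primary index:
results depend only on (seed, primary index), never on execution order.

Not modelled: secondary protons and other products of nuclear reactions
(primaries are attenuated, the secondaries' dose — a few percent, mostly
forward — is dropped), delta-ray transport, neutrals and leptons, and
non-Gaussian beam-tail halo. The first and last omissions matter most for
the out-of-field unscattered dose, see Limitations.

## Planning

Energy layers descend in 5-mm residual-range steps from the target range
to the proximal depth (clipped at the 0.5-cm applicator minimum); layer
energies solve the calibrated residual-range relation. Spots form a 5-mm
square grid extending one spacing beyond the field edge, with uniform
weights within a layer: the collimator, not the spot weighting, shapes the
penumbra. Layer weights are a nonnegative least-squares fit of the
broad-beam (laterally integrated) per-layer depth doses to a flat 2-Gy
plateau; because small collimated fields lose lateral scatter equilibrium,
a short calibration simulation then measures the axis-column profile of
the collimated delivery, the fit is repeated against the correspondingly
corrected target profile, and a final short run scales the proton count so
the unscattered dose on an axis-centred column over the SOBP core equals
2 Gy. The prescription is therefore anchored to the axis target-centre
dose — the denominator of every reported fraction — rather than to the
box-mean dose; for small deep fields the two differ by tens of percent and
cannot both be 2 Gy.

## Evaluation

Per geometry the package reports the published metric set: the maximum
scattered dose at 5 mm depth along x (x_s) and at the target centre (the
SOBP mid-depth), both as percentages of the unscattered dose at the target
centre; dose-averaged LET of the scattered, unscattered and merged
channels at both points; and the LQ-model RBE (RBE_max/RBE_min
coefficients 0.99064, 0.35605, 1.1012, 0.0038703 with sqrt(alpha/beta) in
RBE_min) evaluated at the local total dose with alpha/beta = 3 Gy at the
surface and 10 Gy at the centre.

At the study's desk-scale statistics (2e5 primaries per geometry, 2-mm
voxels) a single simulated proton carries enough weight to deposit
~0.1 Gy in one voxel, so single-voxel point estimates are noise-dominated.
The estimators therefore (i) fold the tallies over the x/y mirror
symmetries of the square field, (ii) average the surface point over the
central 30% of the aperture height in y (the edge line is parallel to the
wall there), and (iii) average the centre point over a central square of
half-width min(5 mm, aperture/2); window LET_d recombines dose-weighted
numerator and denominator exactly. LET_d/RBE sweep summaries apply a
reliability filter, keeping only evaluation points receiving more than
15% of the target-centre dose (0.3 Gy), and the voxel scatter analysis
(LET_d increase vs scattered dose, 0.01 Gy inclusion threshold) excludes
voxels whose batch relative error of the scattered dose exceeds 0.35.

## Study harness and reproducibility

The canonical sweep crosses ranges {5, 10, 15, 20} cm, SOBP widths
{5, 10} cm and field sizes {2, 4, 8, 16} cm into 32 geometries
(R5_S10_* reaches the surface; its proximal layers are clipped at the
applicator minimum). Per-geometry seeds are base_seed * 1000 + index, so
partial re-runs are byte-identical. The reduced-statistics profile
(2e5 primaries, 2-mm voxels and step cap, 8 batches, ~20 s per geometry
on one core) is the problem size used for the sweep results and the
regression suite; single geometries at 1-mm resolution and more primaries
run through the same interfaces.

## Limitations

* No nuclear-secondary or beam-tail halo: the out-of-field unscattered
  dose is underestimated, so at shadow-edge evaluation points the LET_d
  mixture skews toward the scattered channel. The surface LET_d and RBE
  increases at the largest field size are the quantities most affected,
  and converge near or slightly above the published maxima (about
  0.4-0.65 keV/um and 0.04-0.06 respectively).
* The centre scattered-dose fraction for 2 x 2 cm fields converges to
  3.7-3.9%, above the published 2.6% maximum; it is sensitive to the
  back-projected aperture size and the uniform one-spacing spot overrun,
  neither of which the source publication specifies.
* SOBP flatness at the default 5-mm layer spacing is ~3% peak-to-valley,
  set by this model's Bragg-peak widths.
* Passing tests show internal consistency and agreement with the printed
  calibration anchors and survey bounds at reduced statistics; they do not
  validate the engine against measured depth-dose or profile data, which
  are not machine-readable here.
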