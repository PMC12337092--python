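# Methods

This note records the models, the numerical choices, and what the synthetic
data do and do not establish.  Units follow lab convention (um, s, mN/m,
degrees, kcal/mol, cm^-1, mM); computation is SI internally, with all
conversions in `memphys.constants`.

## Osmotic transport across a droplet-interface bilayer

Model: two adhering droplets exchange water through their bilayer contact
patch only.  With `c_i = n_i / V_i` the osmolarity of droplet *i* (osmoles
`n_i` fixed — the bilayer is treated as strictly solute-impermeable) the
volumetric flux follows the standard osmotic flow law

    dV1/dt = -P_f * A_b * v_w * (c2 - c1),    dV2/dt = -dV1/dt,

which carries water from the dilute droplet to the concentrated one.  This
is the accepted model for DIB osmotic assays and is dimensionally consistent
with `P_f` in um/s.  Assumptions: isothermal, no water loss to the oil
phase, no solute leakage, contact angle constant over a run.

*Geometry.*  Droplet volume from apparent radius defaults to a sphere,
`V = (4/3) pi R^3`; a `truncated_sphere` mode removes the spherical cap cut
off by the bilayer plane (`V = (pi/3) R^3 [4 - (1-cos t)^2 (2+cos t)]`, a
few-percent correction at contact angles near 30 deg).  When no measured
contact area is available the bilayer patch is a disc of radius
`R_small sin(theta)`; `theta` defaults to 32.41 deg, the measured PFAS-free
DOPC DIB value.

*Osmolarity of 0.1 M NaCl.*  Effective osmoles = molarity x van't Hoff
factor (2) x osmotic coefficient (0.932 near 0.1 M), i.e. a 1.864
multiplier, configurable; a measured osmolality overrides it when supplied.
Dissolved amphiphile in the saline droplet adds an optional fully
dissociated term (1 mM -> 1 osmol/m^3).

*Integration.*  `scipy.integrate.solve_ivp` (RK45, rtol 1e-8), with `V2`
carried as `V_tot - V1` so total volume is conserved to machine precision.
A terminal event stops the run when either droplet falls below
`stop_volume_fraction` (default 0.05) of its initial volume — a pure-water
droplet would otherwise drain without bound.

*Estimators.*  The slope estimator differentiates observed volumes
(`numpy.gradient`: central differences inside, one-sided at the ends) and
regresses both droplets' fluxes through the origin against
`-A_b v_w (c2 - c1)`; the fitted window defaults to the first half of the
trajectory, where the quasi-constant-gradient approximation is best.  Its
reported standard error treats residuals as independent, which they are not
(adjacent central differences share samples), so it is indicative only;
run-to-run scatter from `aggregate_runs` is the preferred uncertainty, and
is what the per-run SD in published assays reflects.  The ODE estimator
least-squares fits the full forward model over `P_f` (bounded at zero,
initial guess from `TransportParams`); both estimators agree to <0.5% on
noise-free data, and 50 noisy replicates at sigma_R = 0.2 um recover a
73 um/s truth to within 5% in the mean.

## Bilayer tension

`gamma_b = 2 gamma_m cos(theta)` with `theta` the half contact angle between
the monolayer tension vectors at the three-phase line; no factor-of-two
reinterpretation.  Valid for `0 <= theta < 90 deg` and positive `gamma_m`.
First-order propagation gives
`sd(gamma_b) = sqrt[(2 cos t * s_gm)^2 + (2 gm sin t * s_t)^2]`; note that
published table SDs are typically empirical scatter across trials and exceed
this analytic value, so the propagated SD is reported alongside, never in
place of, measured scatter.  Table presentation rounds half-even to two
decimals (`round_half_even`), under which every cell of the reference
monoolein and DOPC tables reproduces exactly.

## DSC thermograms

Heat flow (mW) converts to molar excess heat capacity via
`cp = P / (scan_rate * n_lipid)`; the sign is normalized so endotherms point
up regardless of instrument convention.  Baseline: a low-order polynomial
(default linear) fit to two flank windows that must exclude the transition
apex.  `Tm` is the vertex of the parabola through the maximum sample and
its neighbours (sub-grid); `dH` is the trapezoidal integral over the window
(total area when the transition splits); fwhm interpolates the two
half-maximum crossings and refuses multi-peak curves.

*Deconvolution.*  Components are Gaussians in excess Cp, parameterized by
apex temperature, integrated area and fwhm (the vendor software's exact
lineshape for such fits is generally unreported; Gaussian is the declared
default here and the peaks are broad enough that the choice is not
critical).  Auto-initialization seeds one component at the apex and the
other at the strongest curvature minimum of the smoothed curve inside the
signal region (>= 15% of peak, away from the apex) — the shoulder; a
symmetric split is the fallback.  The best of the direct fit plus five
jittered restarts (fixed seed) is kept.  Model-selection guard: the
two-component fit must beat the single-Gaussian RMSE by 10%
(`improvement_factor = 1.1`); a noise-dominated fit gains almost nothing
from three extra parameters, so this demands genuine two-population
structure, and a numerically perfect one-component fit short-circuits to the
flagged single-component result.  Components are reported higher-Tm first,
fractions as percent of total fitted area.

*Synthetic two-component truth.*  Component apex temperatures and area
fractions follow the strongly perturbed reference membrane (-17.26 degC at
31%, -18.77 degC at 69%, 6.03 kcal/mol total).  Component widths are not
published; the generator uses fwhm 1.8 and 2.6 degC — bracketing the
2.27 degC width of the unperturbed transition and producing the
characteristic shoulder morphology that makes the deconvolution
identifiable.  Widths near the printed composite width (~4.75 degC) at a
1.5 degC separation would make the two-component problem unidentifiable at
any realistic noise level; recovery claims below are therefore conditional
on shoulder-resolved morphology.  At SNR 50 (peak height / noise SD) on a
0.05 degC grid, ensemble means over 20 seeds recover component Tm to
<0.03 degC, fractions to <2 points, total dH to <0.5%; single-seed Tm error
can reach ~0.13 degC, which is a noise floor, not an estimator defect
(noise-free recovery is exact to ~1e-13 RMSE).

## Vibrational band metrics

Positions are apex metrics, since published shifts are apex shifts; a
center-of-gravity option exists.  The apex estimator fits a parabola to the
log intensity of the maximum sample +/- 2 neighbours ("Gaussian apex
interpolation"): for a Gaussian band this is exact regardless of where the
center falls between grid points, removing the grid-offset bias a
raw-intensity parabola has at 4 cm^-1 sampling while averaging noise over
five samples.  At SNR 100 the apex repeatability SD is ~0.09 cm^-1 on a
4 cm^-1 grid.  Because a single noisy spectrum pair cannot resolve a
~2 cm^-1 shift to 0.1 cm^-1, shift checks average positions over replicate
seeds, mirroring how such measurements average repeated scans of independent
samples.

Band fwhm subtracts a local linear baseline through the analysis-window
edges (neighbouring CH bands shoulder each other), then interpolates the
half-maximum crossings.  Pseudo-Voigt tails make the measured width sensitive
to window placement: a window ending where the band still holds ~1.5% of its
height clips ~0.3 cm^-1, so isolated-band width checks use a wide
(2845-3050 cm^-1-scale) window.

The Raman order ratio divides the apex intensity near 2930 cm^-1 (terminal
CH3) by that near 2848 cm^-1 (symmetric CH2).  Synthetic Raman spectra
include the 2890 cm^-1 antisymmetric band so the ratio is extracted against
a realistic shoulder; the generator therefore records both the configured
band heights and the *composite-model* apex positions/heights — the
shoulder adds to both apexes, so the composite values are the measurable
truth (configured heights 0.60/1.00 give a composite apex ratio of 0.6037).

## Synthetic data: what it does and does not establish

Generators draw Gaussian additive noise from an explicit seed (SNR = peak
height / noise SD; radius jitter as i.i.d. sigma_R), embed every truth
parameter in output metadata, and write byte-deterministic files.  Defaults
mirror the reference study conditions: 100 um droplets, pure water vs 0.1 M
NaCl, P_f 73 um/s, 1 s frames over 300 s, sigma_R 0.2 um; thermograms over
-40..0 degC at 0.05 degC steps, SNR 50, linear drift; spectra on a 4 cm^-1
grid at SNR 100 (FTIR bands 2853/2923.1 cm^-1; Raman 2850/2890/2930);
tension tables with per-trial scatter (0.02 mN/m, 0.5 deg) around
per-concentration truths.

Passing recovery tests shows the estimators are unbiased and precise under
these noise models.  Real data add effects the generators do not emulate:
droplet drift and pixelation artifacts, bilayer area measurement error
beyond what the radius noise induces, DSC scan-rate kinetics and hysteresis,
non-Gaussian detector noise, water-vapor bands and ATR penetration-depth
effects in FTIR.  Measured permeability shifts under additives are
measurements, not model outputs — the package recovers whatever `P_f`
generated the data; it does not predict how an additive changes it.

## Pipeline determinism

Stage seeds derive from the top-level seed via `numpy.random.SeedSequence`
spawning, so adding a stage does not reshuffle earlier ones.  Reports
serialize with sorted keys and 10-decimal rounding; identical config + seed
yields byte-identical text and JSON, and each report carries a SHA-256
digest of its input table.

## Known limitations

- The transport model ignores solute leakage, water partition into oil, and
  any temperature dependence of `P_f`.
- The truncated-sphere mode applies one contact angle to both droplets; for
  strongly unequal droplets the shared-patch geometry is approximate.
- The slope estimator's per-run standard error ignores residual correlation
  (see above).
- Two-component DSC fits assume Gaussian components; strongly asymmetric
  transitions need the exponentially-modified option or more components.
- Spectral metrics assume a single dominant band per analysis window;
  heavily overlapped fingerprint regions are out of scope.
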