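# Methods

## Compartment model and its assumptions

`pulmoperf` estimates pulmonary perfusion with a first-pass, whole-lung
compartment model. Both lungs are one lumped compartment merging the
intravascular, interstitial and cellular spaces; during the base-to-peak
interval of pulmonary arterial enhancement, indicator inflow alone accounts
for the compartment's contrast mass change, because that interval is
shorter than the pulmonary transit time (~6–8 s). Under those conditions

P = ΔM_c / (M_T · C_in · Δt),

with ΔM_c the integrated enhancement change (HU·mL) over the lung between
the pre-contrast volume V1 and the peak-enhancement volume V2, C_in the
average arterial input enhancement over the window (HU), M_T the lung
tissue mass (g) and Δt the window length (converted to minutes once,
inside the equation; every interface carries seconds). HU is linear in
iodine concentration at fixed tube voltage, so the HU scale cancels
between ΔM_c and C_in and P is an absolute flow in mL/min/g.

Assumptions, explicitly: (i) negligible outflow during the window (first
pass); (ii) V1 and V2 co-registered (only an optional integer-voxel
cross-correlation shift is provided — `align_by_shift` — not a deformable
registration); (iii) enhancement changes inside a voxel reflect iodine,
not motion or beam hardening.

### C_in: the two-volume gap

A genuinely two-volume acquisition observes the input function at only two
instants, so the *average* input concentration is not measurable from the
data alone. We use the two-point mean (E_base + E_peak)/2, which is exact
when the input rises linearly over the window, and expose the multivolume
estimator (trapezoidal AUC between base and peak frames divided by Δt) as
the reference when a full dynamic series exists. This is the method's
principal approximation; the package's equivalence test shows the two
coincide exactly under a linear rise, and the phantom quantifies the bias
for a gamma-variate rise.

### Tissue mass and the voxel map

Tissue fraction is linear in HU between the air anchor (−1000 HU, f = 0)
and the full-tissue anchor (0 HU, water, f = 1; density 1.0 g/mL). Both
anchors and the density are configurable in `MassModel` — soft tissue
(~55 HU) is a defensible alternative full-tissue anchor; water is the
default because it makes f exactly the CT-number fraction. Voxels with
f < 0.01 (configurable) are excluded from both the flow map and M_T:
near-air voxels otherwise divide a noisy ΔHU by a vanishing mass. Negative
voxel flows are retained — they are zero-mean noise, and clipping them
would bias the global sum. The mass-weighted mean of the voxel map equals
the global P as an algebraic identity (tested to 1e-9 relative), because
both are the same ratio summed in different orders.

Lobar perfusion is the mass-weighted mean over a six-label partition
(right upper/middle/lower, accessory, left upper/lower — the accessory
lobe exists in the swine lung this technique was developed in). Lobe
labels are consumed as input; vessel-based lobar segmentation is out of
scope.

## Timing

Bolus tracking triggers at the first sample whose enhancement reaches
80 HU above the baseline blood pool (the conventional trigger level;
configurable). The prospective time-to-peak delay is Δt = T_inj/2 +
dispersion_delay with T_inj = per-kg contrast dose × weight / rate; the
dispersion default of 2.0 s is a placeholder for a scanner/protocol
calibration that must be supplied by the user, not a value validated here.
For a sampled curve, the peak frame is the earliest argmax and the base
frame the last pre-peak sample at ≤ 5% of peak enhancement (configurable
`base_fraction`); "approximately the base" needs a deterministic rule, and
5% of peak matches the visual base of a gamma-variate.

## The phantom

`simulate_series` generates a dynamic series that embodies exactly the
physics the estimator inverts: per lung voxel,

ΔHU_v(t) · V_voxel = p_v · m_v · ∫₀^min(t, t0+T_transit) C_a(τ) dτ,

with C_a a normalized gamma-variate (peak 400 HU, onset 4 s, time-to-peak
6 s, shape α = 3 by default — a typical sharp pulmonary first-pass bolus)
or a linear ramp for the equivalence experiment. The cumulative integral
is evaluated analytically (regularized lower incomplete gamma; closed form
for the ramp), so recovered-vs-true discrepancies measure the estimator's
quadrature, not simulation error. After the transit time, accumulation
simply stops — the minimal outflow model, sufficient to demonstrate the
direction of first-pass-violation bias without inventing a washout shape.

Defaults are chosen as a realistic healthy-swine study condition: lobar
flows 9.7/7.8/14.5/9.9/8.8/14.1 mL/min/g (global ≈ 11 mL/min/g), uniform
tissue fraction 0.3 (inflated lung density ≈ 0.3 g/mL), arterial baseline
40 HU, frames every 1 s for 21 s (the multivolume protocol's 15–20 scans),
noise SD in HU additive Gaussian, scaled by √(300 mA / tube current) when
per-frame currents are given (emulating a low-dose pre-contrast scan).
One integer seed drives all randomness; identical spec + seed gives
bit-identical volumes.

Geometry is schematic: two axis-aligned ellipsoids, a cylindrical artery
along z between them, planar lobe partitions. What the phantom therefore
does *not* test: registration error, respiratory/cardiac motion, beam
hardening near the heart, airway/vessel exclusion, partial volume at lobe
fissures, reconstruction-kernel effects. Passing recovery tests shows the
estimator chain is a correct inverse of the stated kinetics at realistic
magnitudes — not that the technique is accurate on real animals.

Validation scales: exact-recovery runs use a 64³ grid (≈ 43,000 lung
voxels), invariance and violation experiments 24³–32³ with 20 seeded
replicates — sizes at which every effect tested is already far above
numerical noise.

## Agreement statistics

`full_report` assembles OLS slope/intercept with t-based 95% CIs
(statsmodels), Pearson r with a Fisher-z CI, Lin's concordance correlation
coefficient with Lin's (1989) Fisher-type z CI (population moments in the
point estimate; a seeded percentile bootstrap is available via
`bootstrap=True`), Bland–Altman mean difference and limits of agreement
(mean ± 1.96 × sample SD), a two-sided paired t test, Shapiro–Wilk p
values (scipy), and two RMS summaries. Definitions fixed by this package:
**RMSE** = √(mean squared residual about the fitted line); **RMSD** =
√(mean (y−x)²). They coincide as slope→1, intercept→0. No multiplicity
correction is applied. Degenerate inputs raise: constant x for the
regression, doubly-constant vectors for the CCC, zero-variance differences
for the paired t (inside `full_report` the paired t is reported as NaN in
that case so that identical vectors still yield a report).

## Dosimetry

Effective diameter = √(AP × LAT); SSDE = CTDIvol × f_size (f_size = 1.3
for a ~27 cm effective diameter on the 32-cm phantom scale); effective
dose = DLP × k with k = 0.014 mSv/(mGy·cm) (adult chest). DLP is accepted
as reported by the scanner (it includes overranging) rather than
reconstructed from CTDIvol × nominal z-coverage. SSDE is computed exactly
as CTDIvol × f_size; published tables produced with an unrounded f_size
(≈ 1.299) can differ in the second decimal. Display rounding is one
decimal for cm and mSv; full precision is kept internally.

## Numerical and I/O choices

- Volumes: single-file NIfTI, float32 HU, spacing on the affine diagonal;
  frame times and tube currents in a `frames.json` sidecar (NIfTI headers
  carry neither). Written-then-read volumes are bit-identical in float32.
- Coordinates: 0-based voxel-centered grid; voxel i sits at i × spacing mm.
- Tie-breaks: earliest argmax for the AIF peak; `align_by_shift` keeps the
  first-encountered best shift in lexicographic scan order.
- Determinism: `run_pipeline` outputs embed a config hash (output path and
  log level excluded) and the seed; reruns are byte-identical.
- Degenerate inputs raise typed errors (CLI exit code 2 for configuration,
  3 for data) rather than returning NaNs, except where a partial result is
  scientifically meaningful (a zero-mass lobe reports NaN with a warning).

## Known limitations

Two-volume C_in is biased for any non-linear input rise (quantified by the
phantom, not corrected); no deformable registration; no iodine calibration
in mg/mL (all concentrations stay in HU); lobar labels must be supplied;
the dispersion delay requires external calibration; repeated measurements
from the same subject are treated as independent pairs in the statistics
battery.
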