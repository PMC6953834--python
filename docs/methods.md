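# Methods

This note documents the models, algorithms, parameters and design choices of
`ioertdose`, and what its validation on synthetic phantoms does and does not
demonstrate.

## Problem setting

In intraoperative electron radiation therapy (IOERT) a rigid PMMA applicator
docked to a LINAC collimates a single-fraction electron beam (typically
4–20 MeV) onto a surgically exposed tumour bed. Beam energy is chosen under the
*conventional assumption*: a flat irradiation surface with water-equivalent
tissue at the applicator end. Two features of the real intraoperative scene
violate it: the **air gap** between the applicator's (possibly beveled) exit
face and the irregular resection surface, and **tissue heterogeneity**.

The package quantifies the dosimetric impact of each factor by building five
CT scenarios on a common 1.5 mm isotropic grid and comparing their 3D dose
distributions with a 3%/3 mm gamma analysis against the intraoperative gold
standard:

| scenario | content |
|---|---|
| `intraCT` | intraoperative CT (air gap + heterogeneity), applicator interior blanked to −1000 HU |
| `preCT_water` | registered preoperative CT, tissue → 0 HU, flat water medium from the bevel plane (the conventional assumption) |
| `preCT` | registered preoperative CT (heterogeneity, no air gap) |
| `preCT_water&air` | water-equivalent tissue plus the segmented air gap (−1000 HU) |
| `preCT_air` | registered preoperative CT plus the segmented air gap |

## Coordinate and data conventions

World coordinates are LPS millimetres; a volume's origin is the centre of voxel
(0,0,0); all processing happens on axis-aligned grids after resampling to
1.5 mm isotropic voxels (trilinear for HU and dose, nearest neighbour for
masks). Rigid transforms map moving-image world coordinates to fixed-image
world coordinates. The applicator pose is (bevel centre, distal unit axis,
roll), where roll is the angular position of the bevel's *shorter edge* about
the axis; the bevel-plane normal is `cos(b)·axis + sin(b)·e(roll)` for bevel
angle `b`. Roll is undefined (and flagged) for flat, 0° applicators.

## HU → density

A two-segment piecewise-linear calibration with knots (−1000 HU,
0.00121 g/cm³), (0 HU, 1.000 g/cm³), (+1000 HU, 1.59 g/cm³), clamped at the
table ends, ships as an editable table (YAML/JSON). Scanner-specific
calibrations differ in the bone segment; the air and water anchors are fixed by
the HU definition. Replace the table for quantitative work with real CTs.

## Synthetic phantoms

Patient CTs are not available to this package, so a seeded generator produces
paired pre/intraoperative cases with exact ground truth. It emulates:

* a torso-like soft-tissue ellipsoid (default half-axes 62×58×64 mm, 40 HU)
  with ~900 HU bone structures (two cylinders and a sphere) placed near, but
  deliberately outside, the beam cone — matching the observation that bone was
  at a distance from the tumour bed in the cases that motivated this analysis;
* a post-resection cavity carved along the applicator axis: a spherical-cap
  depth profile (default 22 mm) plus a sum of seeded 2D Gaussian bumps
  (default amplitude 8 mm), with taper to zero at the cavity rim. The depth
  function is closed-form, so the maximum cavity depth / air gap has an
  analytic oracle independent of the rasterisation;
* a PMMA applicator wall (120 HU, 5 mm thick; diameters/bevels per case)
  placed so the maximum axial air gap equals a configured target — defaults
  span the observed clinical range 8.5–30.5 mm (default 14.5 mm);
* optional pooled biological fluid (10 HU) flat-filling the cavity bottom;
* a rigid inter-acquisition motion (defaults: a few degrees / millimetres) and
  additive Gaussian HU noise (default sigma 15 HU).

The intraoperative anatomy is rasterised analytically from the transformed
shape parameters (not resampled from the preoperative volume), so truth masks
are exact. All randomness derives from a single seed; generation is
bitwise-reproducible. Not emulated: CT physics (beam hardening, scatter,
metal-artefact streaks), deformable anatomy, realistic organ texture, tissue
bulging into the applicator. Consequently, passing tests demonstrate correct
*algorithmic* behaviour under known geometry, not clinical performance on real
artefact-laden images.

## Segmentation

Region growing is implemented as connected-component labelling of the HU
window, keeping components that contain a seed (6-neighbour connectivity by
default), which is equivalent to flood fill and deterministic. The clinical
workflow's manual boundary delineation is replaced by explicit constraint-mask
arguments. Windows: air gap ≤ −500 HU (protocol constant), bone ≥ +200 HU
(plus 1-voxel closing), applicator wall ∈ [60, 200] HU within a generous tube
neighbourhood of a user-supplied approximate axis (an optional 1-iteration
binary opening removes noise specks), patient body ≥ −300 HU (largest
component, hole filling, minus the wall). The air-gap search is seeded just
distal to the bevel plane inside the aperture and confined to the cylinder's
distal extension; an empty result is a valid zero gap. The maximum air-gap
distance is the largest signed distance from the bevel plane along the
applicator axis over gap voxels.

## Registration

The preoperative image is rigidly aligned to the intraoperative image by
maximising Studholme-normalised mutual information, (H(A)+H(B))/H(A,B), over a
32-bin joint histogram (HU clamped to [−1000, 2000]) restricted to the fixed
image's bone mask dilated by 2 voxels. Optimisation uses Powell over Euler
angles + translation about the bone centroid, with a 4→2→1 mm Gaussian
multi-resolution schedule and deterministic voxel subsampling. When the caller
supplies no initial transform, a moments (bone-centroid) pre-alignment is used:
a bare identity start was not reliable across the full ±10 mm / ±10° motion
range. At the coarsest level a deterministic rotation grid search
(±8° in 4° steps per axis around the initialisation) selects the NMI basin
before the local optimiser runs — purely translational initialisation can
still land outside the basin for combined rotations near the range limit.
A gross initialisation (bone overlap below 10%) raises an error rather than
fitting silently; optimiser failure raises a convergence error with per-level
diagnostics. On the phantom family, mean bone target-registration error is
well below one voxel (the original clinical workflow verified registration
only visually; phantoms allow a quantitative check).

## Applicator pose recovery

The tube axis is found by minimising the spread of radial distances about the
candidate axis (seeded from the principal directions — near the eigenvalue
crossover length ≈ 2.4 radii PCA alone can mix axial and radial directions),
then refined as the line through centres of angularly complete rings
(incomplete rings at the beveled rim or clipped ends are excluded; outlier
ring centres are trimmed). The distal sign comes from the tissue fraction near
each tube end (override available). The distal rim is extracted per 5° angular
bin (72 bins, averaging ties to avoid scan-order bias); a least-squares plane
through the rim gives the bevel angle, the roll (angular position of the most
proximal rim point), and — intersected with the axis line, plus a half-voxel
distal correction for voxel-centre bias — the bevel centre. A manually clicked
shorter-edge point may override the automatic roll, mirroring the clinical
semiautomatic procedure. A fitted-diameter QC check warns when the wall
disagrees with the declared applicator spec by more than 10%.

## Dose engine

The external Monte Carlo engine and measured LINAC phase space used clinically
are not reproducible here; the package ships a deterministic divergent
pencil-beam stand-in, exposed behind a pluggable `compute_dose` contract so a
true MC engine can replace it. For each voxel distal to the bevel plane:

    D = PDD(z_we) · L(r, z_we) · (f / t)²

* `z_we` — water-equivalent depth: midpoint-rule line integral of density
  (step ≤ half the minimum voxel spacing) along the ray from a virtual point
  source (f = 1000 mm proximal of the bevel centre on the axis), starting at
  the ray's bevel-plane crossing. Rays are bucketed by length for speed; the
  quadrature is exact on piecewise-constant density to within the step size.
* `PDD` — monotone piecewise-cubic (PCHIP) curve through
  (0, surface), (R100, 1.0), (R90, 0.9), (R50, 0.5), (Rp, tail+0.015),
  (Rp+15 mm, tail), flat beyond. Default anchors per energy E (MeV) follow
  standard electron-beam rules of thumb: R100 = 2.2·E mm, R90 = 10E/3.2 mm,
  R50 = 10E/2.33 mm, Rp = 5·E mm, surface = 0.76+0.01E, tail = 0.005+0.002E;
  all ship as an editable configuration.
* `L` — error-function beam edge, 1 on axis and 0.5 at the divergently
  projected aperture radius, with penumbra width
  σ = σ₀ + k_scatter·z_we + k_air·(geometric depth − z_we)
  (σ₀ = 1.5 mm, k_scatter = 0.06, k_air = 0.03): the penumbra broadens with
  water-equivalent depth and, more weakly, with the air path, so an air gap
  widens the surface penumbra, as expected physically.
* inverse-square relative to the source–bevel-centre distance.

Distributions are normalised to their own maximum (= 100%); absolute dose uses
the prescription at the 90% isodose (Gy = % · prescription / 90). Voxels
outside a lateral 4σ margin of the projected aperture or beyond Rp + 50 mm
geometric depth receive zero dose (their true engine dose is below the
bremsstrahlung tail and far below the 10% analysis threshold). The engine
reproduces the qualitative behaviours that matter for the analysis — the 90%
isodose tracks a curved irradiation surface, an air gap shifts dose deeper and
broadens the penumbra — but not MC-specific effects such as scatter hot spots
under sharp surface irregularities or tissue bulging into the applicator.

## Gamma analysis

gamma(v) = min over evaluated sample points u within the search radius of
sqrt((|u−v|/DTA)² + ((D_eval(u) − D_ref(v))/ΔD)²), with ΔD = tolerance ×
normalisation dose. Defaults: 3%/3 mm, global normalisation to the reference
(intraCT) maximum, dose thresholds 10% and 70% of the normalisation dose,
voxels outside the patient-tissue mask excluded, search radius 3×DTA, and the
evaluated dose sampled on a trilinearly refined sub-voxel lattice (voxel/3).
Two implementations share the contract: `gamma_map` visits offsets in order of
increasing distance and prunes voxels whose current best gamma cannot improve
(exact pruning), and `gamma_bruteforce` scans every sample point. They agree
to 1e−6 (in practice exactly) on seeded field pairs. `gamma_map` additionally
accepts a `gamma_max` cap (≥ 1): the search stops once the distance term alone
exceeds the cap, so gamma values above it become upper bounds while values
below it — and therefore the pass rate — remain exact; the pipeline uses
`gamma_max = 1.5`. The comparison is asymmetric; the pipeline always uses
`intraCT` as the reference. Local normalisation and an explicit normalisation
dose are available as configuration switches.

## Pipeline and report

Per case: resample to 1.5 mm → bone segmentation (auto-seeded) → rigid
registration → applicator-wall segmentation (operator-style approximate axis
hint) → pose estimation → air-gap segmentation → body masks → scenario
construction → dose ×5 → gamma ×8 (4 comparisons × thresholds 10%/70%).
The report holds the 8 pass rates, 4 per-comparison averages, the RMS HU
difference between the intraoperative and registered preoperative images over
tissue voxels inside the bounding box of the nonzero reference dose, the
maximum air-gap distance, QC metrics and timings; it serialises to a CSV
(comparisons × thresholds table) and JSON with provenance. Identical
configuration and seeds give identical reports.

## Problem sizes and validation conditions

The default phantom grid is 96×96×144 voxels at 1.5 mm (a 14×14×22 cm field
of view), a 7 cm / 30° applicator at 9 MeV — a chondrosarcoma-like setting.
The validation suite runs: gamma oracle equivalence on twenty 40³ field pairs;
registration recovery over ten phantoms with motions up to 10 mm / 10°; pose
recovery at bevels 0/15/30°; air-gap segmentation and the full pipeline on the
three-phantom family with maximum gaps 8.5 / 14.5 / 30.5 mm (one synthetic
case per observed clinical gap, all at the default beam); and a zero-gap,
homogeneous (0 HU body) phantom in which all five scenarios are provably
identical inside the beam and every gamma comparison must return exactly 100%.
On this family the water-only scenario's agreement falls monotonically as the
gap grows while both gap-aware scenarios stay above 95% — the air gap, not
heterogeneity, drives the disagreement, which is the central claim this
package re-examines.

## Known limitations

* The dose engine is a parameterised stand-in; its PDD anchors are rules of
  thumb, not measured beam data. All dose-level conclusions are relative
  (scenario vs scenario on the same engine), never absolute dosimetry.
* The HU→density table is generic.
* Segmentation thresholds other than the −500 HU air-gap limit are package
  defaults (config-exposed), not protocol constants.
* Metal artefacts, deformable motion, and in-vivo dosimetry are out of scope.
* `fit_axis` needs the wall to span roughly 1.5 tube diameters axially and a
  mostly complete rim (≥75% of angular bins) to locate the bevel.
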