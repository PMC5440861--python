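# Methods

## The question and the model

The package estimates the anatomical component of uncertainty in the
lung-absorbed dose per fluence (LADF) for external mono-energetic photon
beams.  The model isolates one anatomical variable — total lung mass —
and holds everything else fixed: lung shape (up to uniform scaling), lobar
centroid positions, body envelope, and the inventory of surrounding
tissues.  A series of N phantoms is built from one template, each with its
lungs rescaled to a mass drawn from a Gaussian; every phantom is exposed
to the same idealized broad beams; the spread of the per-phantom doses is
the quantity of interest.

Lung mass follows N(μ=1246 g, σ=322 g), the published autopsy-based
distribution for adult males in a fixed height/weight percentile.  Draws
are converted to volumes by the whole-lung relative density
ρ_re = M_ref / V_ref with M_ref = 1208.37 g and V_ref = 2911.190 cm³ from
the reference inventory (tissue 1057.82 g at 0.382 g/cm³, blood 150.55 g
at 1.06 g/cm³); ρ_re is recomputed from these inputs (0.415078 g/cm³),
never entered as a rounded constant, so the reference mass maps exactly
back onto the reference volume.  Draws are truncated to
[max(μ−3σ, 300 g), μ+3σ]: beyond 3σ the masses are not anatomically
plausible and the truncation perturbs the distribution by <0.3% of draws
(clipped draws are flagged in the series plan).

Uncertainty statistics use the population forms SD = √(Σ(Dᵢ−D̄)²/N) and
CV = SD/D̄ (denominator N, matching the definition the dose tables use,
not the N−1 sample form).  A reference dose is flagged as compatible when
it lies within one SD of the series mean; the field is named
`within_one_sd` because this is an interval-containment convention, not a
formal confidence interval.  The RMS of the per-phantom MC relative errors
is reported alongside as the noise floor; an anatomical CV is only
interpretable when it clearly exceeds that floor.

## The template phantom

The template is procedural, not segmented from images.  It reproduces the
quantities that control broad-beam lung dose — lung volume, mass, density,
lobar centroids, and the amount and density of tissue between skin and
lung — and makes no claim about fine organ shape.  Components: an
elliptical body envelope (34 × 24 cm) with a 0.45 cm skin shell and a
1.6 cm muscle ring; residual soft tissue (1.03 g/cm³ — the reference
inventory does not print a residual-tissue density, so the standard
soft-tissue value is used and is configurable); a spine cylinder; heart
and liver as volume-matched ellipsoidal blobs (their exact shape is
irrelevant to lung dose, which the ablation check verifies); lung lobes as
superellipsoids fitted by iteration so that the *voxelized, clipped* lobes
hit the target volumes to ≲0.2% and the target centroids to a quarter
voxel; a banded rib-cage shell (14 bands, 0.65 cm thick) wrapped around
the thoracic cavity with a one-voxel residual gap; and per-lobe
bifurcating vessel trees grown from a hilum point and trimmed/extended to
the exact reference blood volume.  The anterior chest-wall thickness
(default 2.5 cm) is an explicit parameter because low-energy results are
sensitive to it.  Voxel pitch defaults to 2.137 mm in-plane and 8 mm in z;
the whole construction is resolution-independent (tests run most
series-level checks at twice the in-plane pitch, which preserves geometry
and physics while cutting runtime about eightfold).

## Deformation

Each lobe (tissue + vessels) is rescaled uniformly about its fixed
centroid.  The mask is resampled under the inverse scaling with trilinear
interpolation and re-binarized at 0.5; the linear factor is then corrected
by bisection until the clipped voxel count matches the target volume
(typically to ~2 voxels, far inside the 1% policy tolerance).  This is the
automatable equivalent of the mesh-rescale/revoxelize workflow: only the
re-binarized voxel result matters.  The rib cage is refit rigidly about
its own centroid with the same linear factor; because the cage is a thin
shell, it is resampled with nearest-neighbour interpolation (trilinear
thresholding erodes one-voxel bands), which preserves shell thickness to
within one voxel over the series' scale range.  Vessels scale with their
lobe and are then trimmed (most-distal voxels first, so the main trunk
survives) or grown (distal front into vessel-free lung) to the exact
proportional volume.  Inflated lungs claim soft tissue only; conflicts
with heart and liver are resolved by policy — `lung_wins` (default:
conflicted voxels become lung, so large-lunged phantoms have smaller
hearts/livers) or `organ_wins` (the lung is truncated and its achieved
volume re-measured).  Skin, spine and ribs are never consumed.  Deflation
voids fill with residual tissue, so the in-body voxel count is conserved
exactly.  Small lungs leave heart and liver untouched.

## Photon transport

Analog Monte Carlo on the voxel grid with the kerma approximation at all
energies: collision kerma is scored along every track as
w·E·(μ_en/ρ)·ρ·ℓ per traversed voxel, i.e. secondary electrons deposit on
the spot.  This is exact below a few hundred keV and biased at MeV
energies where electron ranges reach centimetres; the package's
conclusions rest on relative quantities (CVs, paired differences) that are
insensitive to this bias, and absolute doses at high energy should be read
with that caveat.  Interactions: photoelectric absorption, incoherent
scattering (free-electron Klein–Nishina, sampled by Kahn's rejection
method at all energies; the sampler is validated against a numerically
integrated KN oracle), and pair production above 1.022 MeV (the history
ends; two back-to-back 0.511 MeV photons with an isotropic axis are
emitted).  Coherent scattering and electron/positron tracking are
deliberately omitted.  Photons below 2 keV deposit locally.

Interaction coefficients come from a compact physical model rather than an
embedded bulk table: Klein–Nishina integrals give the incoherent cross
section and its energy-transfer moment exactly; photoelectric absorption
is a per-tissue-class power law calibrated to standard reference
coefficients at 15 keV; pair production is a Z²/A-scaled threshold form
anchored at 10 MeV.  Against standard water tables this reproduces μ_en/ρ
to ≲0.3% between 0.1 and 2 MeV and μ/ρ to a few percent at low energy
(the gap is mostly the excluded coherent part).  Four classes exist —
water-like soft tissue, bone, air, lung tissue (= soft class) — and all
soft tissues share the water-like class with their own densities, the
first-order quantity for photons.

Source models: AP/PA/LLAT/RLAT are plane-parallel beams covering the
grid face plus a configurable margin (default 5 cm); ROT is a parallel
beam with continuous uniform azimuth normal to the body axis; ISO samples
directions uniformly on the sphere with ray offsets on the disc of the
bounding sphere.  Fluence is Φ = N_h/A (source-plane area) for parallel
and rotational beams and Φ = N_h/(πR²) for ISO, making the LADF invariant
under margin changes.  Dose conversion: 1 MeV/g = 1.602×10⁻¹⁰ Gy,
reported in pGy·cm².  Statistical errors come from 25 equal history
batches; a chi-square test in the suite confirms the batch errors match
the scatter of independent seeds.  Each (phantom, beam, seed) triple is
bit-reproducible; all random draws come from one seeded generator in a
fixed order.  An optional rectangular-mesh energy-deposition map
(percent-of-maximum, mass-weighted-conservative) is available.

## Study orchestration and seeds

A study is a (phantom × energy × geometry) grid driven by one YAML config
and one master seed.  Stage seeds are SHA-256 hashes of (master seed,
stage name, index) truncated below 2³¹, so adding beam energies never
changes phantom geometry, and every phantom gets an independent beam seed
per cell.  Results are flushed per cell; a study resumes from its own
partial results file and reproduces byte-identical CSVs from an identical
config.

## Default problem sizes

Defaults are chosen so a desk-scale run resolves the physics it claims:
series size N = 100 (the published study size; N = 20 for the CV-trend
suite), 10⁵ histories per cell by default, raised to 1.6×10⁶ in the
CV-trend check so the MC noise floor (~0.27%) sits well below the ~0.6–2%
anatomical CV at 0.1–10 MeV, and 2×10⁵ histories for the two 1 MeV
robustness checks, where paired/correlated sampling makes sub-percent
differences resolvable.  The two overlap modes are compared on the
largest-lung phantom (μ+3σ = 2212 g), the case with maximal
heart/liver conflict.

## What the synthetic data can and cannot show

The template emulates the dosimetrically controlling features of a real
thorax but not its detail: no arms (lateral doses are higher than tables
computed with arms in the beam path), no air in the airways, simplified
rib and organ shapes, soft-tissue compositions collapsed to water.
Passing tests therefore demonstrate the *method* — volume-controlled
deformation, correct transport physics against closed forms, and the
qualitative energy dependence of the dose uncertainty (CV falling from
~100% at 15 keV to ~1% at MeV energies) — not agreement with any
individual's dosimetry.  Absolute LADF values agree with published
reference tables to within roughly 10% at mid energies on this geometry,
but are not a validation target.

## Numerical choices and degenerate inputs

Volume matching bisects on the linear factor with a ±2-voxel acceptance;
non-convergence raises an error carrying the best achieved volume.  σ = 0
populations are legal and produce identical phantoms (used as the MC null
check).  A zero vessel fraction builds a vessel-free lung.  Organ
operations validate IDs and report offenders by name; empty organs have
zero volume and undefined centroids (an error).  Log-log interpolation is
exact at grid points and refuses extrapolation.  Ties in vessel
trimming are broken by the deterministic distance ordering.

## Known limitations

Kerma approximation above ~0.5 MeV (no secondary-electron transport);
no coherent scattering; free-electron Compton (no binding/Doppler
effects); soft tissues share water coefficients; no neutron physics of
any kind; single-threaded transport.  The rib refit is rigid — per-rib
articulation is not modeled.  Lung shape and position variation are out
of scope by design: the series varies size only.
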