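# Methods

This note documents the physical model, the numerical choices and the
limits of validity of the `stainmap` pipeline, in the order data flows
through it.

## Units and conventions

Photon energy in keV, wavelength and electron densities in nm
(ρₑ in 1/nm³, projected ρₑ,⊥ in 1/nm²), linear attenuation μ in 1/cm,
mass density in g/cm³, molar mass in g/mol. Images use pixel (0, 0) at
the top-left with x the fastest axis; volumes are (y, x, z) with y the
vertical rotation axis and the beam along z. All Fourier-domain
operators use frequencies of the image-plane grid (effective pixel
size); magnification enters only through that pixel size, and the
whole chain is parallel-beam.

## Material properties

Electron number densities come from the stoichiometric Z/A-weighted
Avogadro scaling of the mass density. Attenuation coefficients come
from an embedded, NIST/XCOM-style elemental mass-attenuation table
(total, coherent scattering included) combined by mass fraction and
interpolated log-log; absorption edges are represented as duplicated
branch points so interpolation never crosses an edge. The table covers
H, C, N, O, F, Si, Cl and Pb from 1 keV (3 keV for Cl, 4 keV for Pb) to
200 keV. Accuracy notes: the Pb grid is coarse between the L edges
(13–16 keV) and the Cl row is good to ~10%; both are outside the
quantitative paths, which use Pb at 25 and 87/89 keV and never Cl
except inside self-consistent simulations. The refractive index
decrement is δ = rₑλ²ρₑ/2π; anomalous-dispersion fine structure near
edges is out of scope.

The compound registry ships literature bulk densities (PMMA 1.18,
PTFE 2.20, POM 1.41, PVC 1.40, ethanol 0.789, water 1.00, paraffin
0.90, lead 11.34, silicon 2.33 g/cm³), all overridable — real parts
can deviate from bulk density by a few percent, which rescales δ, μ
and ρₑ linearly. The soft-tissue basis material is empirical:
ρₑ = 299 /nm³ and μ = 0.567 /cm at 25 keV (values measured on
unstained kidney); at other energies its attenuation follows the water
curve, its electron density is energy-independent.

## Forward simulator

Phantoms are voxelised two-component scenes: a background material
label per voxel plus a stain volume-fraction map, mixed linearly
(δ, μ, ρₑ are all volume-weighted averages). The calibration phantom
is an ethanol cylinder holding POM, PVC, PMMA and PTFE rods; the
stained-tissue phantom is a soft-tissue ellipsoid in ethanol with
seeded spherical inclusions carrying lead fractions drawn uniformly
from [0, 0.013] (the physiologically observed display range; hard cap
0.05), an optional excess-stain rim at 1.5× the blob maximum, and a
PMMA rod for density calibration. The default inclusion radius is
4 voxels (~12 µm diameter at the default 1.44 µm voxel): stained
nuclear clusters large enough that their interiors are resolved at the
pipeline's few-micrometre resolution. Single-nucleus-scale features at
the resolution limit are available via `blob_radius_px`; their interior
means are necessarily partial-volume-diluted and are not a fair test of
the decomposition algebra. Blob statistics are not anatomical; they are
chosen to exercise the measurement chain.

Per projection angle, μ and ρₑ volumes are line-integrated (linear
interpolation under rotation about y), giving the exit transmission
τ = exp(−∫μ dz) and phase φ = −rₑλ∫ρₑ dz. Propagation to the detector
is the finite-difference transport-of-intensity step
I(Δ) = [1 − (δ/μ)_rel Δ ∇²] I(0), spectral Laplacian by default (total
intensity is conserved exactly; a 5-point stencil variant exists).
The modulator is rendered as an analytic intensity pattern at the
detector plane — a cosine-product array with period 10 µm, realised
visibility 0.4 (a 2π/3 Talbot array illuminator is high-contrast in
theory; detector blur brings measured visibility to a few tens of
percent) — or a band-limited speckle field. Refraction shifts the
pattern locally by the displacement field obtained by inverting
φₓ = (2π/λ) uₓ p/Δ; the analytic pattern is evaluated directly at the
displaced coordinates, so warping carries no interpolation bias.
Reference frames are rendered once per modulator position (as they are
measured in practice), nine positions on a golden-ratio offset
sequence by default. A Gaussian detector point-spread blur
(σ = 0.7 px by default) is applied to the sample-induced structure:
real optics never deliver voxel-sharp edges, and sub-pixel blur keeps
interface refraction within the regime explicit tracking can follow.
Photon noise is Poisson with a configurable mean count (default in the
validation studies: 10⁴ counts/pixel for the modulated scans; 10⁶ for
the K-edge absorption scans, whose experimental protocol uses roughly
an order of magnitude more exposure per projection, several times more
projections, and five-fold binning). Every stochastic stage requires
an explicit seed and is bit-reproducible.

Not modelled: Fresnel wave optics, partial coherence, cone-beam
geometry, detector response beyond the Gaussian PSF.

## Signal retrieval

The plain position-averaged transmission τ = meanᵢ Iᵢ/I₀ᵢ is
implemented as the mean (not the bare sum) so that τ ≈ 1 in air for
any number of positions; the logarithm is applied only when forming
line integrals. This estimator carries a positive Jensen-type bias of
order `visibility² (k·u)²/2` wherever the pattern is displaced —
negligible on real, large samples (u ≲ 0.1 px in homogeneous regions)
but visible on miniature phantoms, whose attenuation signals are tens
of times weaker at equal voxel size.

The tracker minimises, per pixel over a (2w+1)² window (w = 1 by
default) and all modulator positions,
Σᵢ Σ_w [Iᵢ − T·I₀ᵢ(x−uₓ, y−u_y)]². The search runs on a half-pixel
shift grid over ±2 px (integer shifts by exact replicate-padded
sampling; fractional shifts by Fourier shifting, which is unitary and
therefore does not bias the pattern-energy normalisation), with ties
broken toward zero displacement, followed by separable three-point
quadratic refinement and two Gauss-Newton iterations on the continuous
cost against spline-warped references (steps clamped to half a grid
step). The transmission is then re-fitted per pixel — without the
spatial window, which would re-introduce curvature bias — against the
reference warped to a low-pass-filtered copy of the displacement field
(σ = 1.5 px): the displacement field is physically smooth at the PSF
scale, and warping by the raw per-pixel estimate rectifies displacement
noise into a downward transmission bias quadratic in the displacement
error. Pixels whose window leaves the image are flagged in a validity
mask. Positive uₓ means the sample pattern appears shifted toward +x;
this sign convention and the sign of the Fourier-integration divisor
are fixed jointly by the simulator round trip.

The end-to-end chains use the tracker's T as the transmission estimate
(unbiased where the pattern is strongly displaced); the position-
averaged estimator remains available (`tau_source="average"`) and is
the appropriate choice for data in the small-displacement regime.

Attenuation line integrals are zero-referenced per view against air
strips near the lateral image edges (inset past the tracker margin) —
the attenuation analogue of defining the air phase to be zero. This
removes the constant transmission-scale offset that any retrieval
leaves behind and costs nothing when a few air columns exist on both
sides of the sample.

## Edge correction

τ′ = F⁻¹[F(τ)/(1 + (δ/μ)_rel Δ k²)], evaluated on the image mirror-
padded to twice its size (samples extend to the container edge, and
mirror padding avoids wrap-around while keeping unit DC gain per
quadrant, so total intensity is conserved to 1e-10). The filter gain is
in (0, 1], non-increasing in |k|, exactly the inverse of the simulator's
finite-difference propagation step, and identical for the ratio of any
two distinct mixtures of the basis pair. A negative ratio·Δ would
amplify high frequencies and is refused unless explicitly overridden.
The filter is applied per projection view, never to reconstructed
slices.

## Phase processing and calibration

Differential phase maps are mirror-extended with the correct parity
(odd along the differentiated axis, even along the other) and
integrated spectrally; the undefined DC term is set to zero and the
physical offset restored by zeroing the mean phase over an air region.
Projected density follows as ρₑ,⊥ = −φ/(λrₑ). After reconstruction,
the density volume is rescaled affinely so the air background averages
zero and a reference region hits its theoretical value (PMMA,
383 /nm³, by default; paraffin is supported). The calibration also
absorbs the tracker's small (<2%) multiplicative displacement bias,
which is uniform across the field.

## Reconstruction and stitching

The built-in filtered backprojection uses the discrete spatial-domain
Ram-Lak kernel (h[0] = 1/4, h[odd n] = −1/(πn)²; optional Hann
apodization). The kernel's frequency response has a non-zero DC
sample; a plain |f| ramp discards each projection's mean and offsets
homogeneous interiors — measurable as a ~10% error on these phantoms.
The rotation axis is assumed vertical at the central detector column;
no auto axis-finding. The implementation is cross-checked against the
scikit-image parallel-beam reconstruction in the test suite. Voxels
outside the inscribed field-of-view circle are never fully sampled and
are excluded from every quantitative region (including calibration
backgrounds).

Offset-axis scans blend each view with its horizontally mirrored
opposing view, α(x) falling linearly from 1 to 0 across the overlap
columns; the x-differential phase signal flips sign under mirroring.
The overlap position and width are configuration inputs, not
auto-registered.

## Decomposition and K-edge subtraction

The 2×2 basis change is solved in closed form; fractions are reported
raw (a material denser than both basis materials legitimately exceeds
1, and noise legitimately produces small negative values — clipping is
left to rendering). Volume conservation v₁+v₂ = 1 is not imposed.
Stain fractions convert to mol/L via c = vρ/M with the stain's bulk
density and molar mass. Basis-mismatch sensitivity is bounded and
small: perturbing the true tissue by ±5% in μ and ρₑ while decomposing
with the fixed kidney/lead basis moves the recovered stain
concentration by ≲1% relative at a 1% stain fraction, because the
perturbation vector lies almost entirely in the tissue column of the
basis; the tissue fraction absorbs the mismatch.

K-edge subtraction uses target-element attenuations at E_K ± ΔE
(ΔE = 1 keV default, i.e. 87/89 keV for lead) from the same embedded
table and assumes equal background attenuation at the two energies;
for water-like tissue across 2 keV that assumption holds to ~0.5%,
contributing ≪1% to the recovered fraction.

## Validation metrics

Fourier ring correlation uses rings one frequency bin wide and the
standard half-bit/full-bit information-threshold curves; the
resolution is the inverse of the first threshold crossing (linearly
interpolated), with a Nyquist sentinel when no crossing exists.
Bland-Altman agreement reports the mean difference, 1.96σ limits of
agreement and the Pearson correlation of paired ROI means. ROI
statistics support morphological erosion, the standard way to exclude
boundary voxels — material interfaces are exactly where any explicit
tracking method is least reliable, and interior means are the
quantity the method claims.

False-color rendering maps the tissue fraction (range [0.78, 1.04]) to
pink (#e75acc) and the stain fraction (range [0.0, 0.013]) to purple
(#480f62), each linearly to opacity over white, stain over tissue;
ranges and colors are configurable, and consecutive slices can be
averaged to emulate physical section thickness.

## Problem sizes used in validation

The end-to-end studies run 128³ phantoms (1.44 µm voxels, ~180 µm
object) with 9 modulator positions and 200 angles over 180°, Poisson
noise as above; the stitching study uses a 96³ phantom over 360°.
Miniature examples use 64³/100 angles. Note the scale asymmetry of a
desk-size phantom: per-pixel refraction displacements match the real
experiment (they depend on voxel size, not object size), but
attenuation signals are ~30× weaker because chords are ~30× shorter,
so transmission accuracy requirements are correspondingly stricter
than on real data. Passing the 2% interior-mean checks here therefore
exercises the estimators harder, not softer, than beamline-scale data
would; what miniature studies cannot probe are large-object effects
(beam hardening is absent by construction, ring artifacts, drift) and
real detector noise spectra, for which the noise-reduction and
resolution claims of the correction filter are checked only
qualitatively.

## Known limitations

* Edge zones: within ~2–3 px of strong interfaces (container walls),
  displacement saturation and window mixing corrupt both channels;
  these regions are excluded by erosion, exactly as interior means are
  computed on real data, and the container wall is masked in renderings.
* The tracker implements the explicit model only — no dark-field
  channel, no bias corrections beyond those described.
* Two-material assumption throughout: samples containing a third
  distinct component (e.g. bone mineral) violate both the correction
  filter and the decomposition.
* The Pb cross-section grid between the L edges is coarse; quantities
  evaluated at 13–16 keV should not be trusted to better than ~10%.
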