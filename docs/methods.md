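# Methods

This note records the model, the numerical scheme, the synthetic-data
generators and the design decisions behind `fibrilpfc`, in enough detail to
reproduce or re-derive every choice.

## Model

The phase-field-crystal (PFC) free energy used throughout is the canonical
Swift–Hohenberg-type functional

    F[φ] = ∫ { ½ φ [(q*² + ∇²)² − r] φ + ¼ φ⁴ } dx

with conserved dynamics ∂φ/∂t = ∇²μ, μ = [(q*² + ∇²)² − r]φ + φ³. The sign
convention makes `r` destabilizing: the uniform state φ₀ is linearly
unstable to pattern formation when r > 3φ₀², with growth rate
σ(k) = −k²[(q*² − k²)² − r + 3φ₀²] peaking near k = q*. The production
parameter point is r = 0.8, φ₀ = 0.4 (r − 3φ₀² = 0.32 > 0), which fills an
irregular domain densely with fibrils; lower r or higher φ₀ instead leaves
fibril-free voids, the localized states mapped by the (r, φ₀) sweep.

φ ≈ −1 is dense fibrillar collagen and φ ≈ +1 protomer-rich medium;
c = (1 − φ)/2 is the concentration proxy. Pixels with c ≥ ½ form the
fibrillar class (ties assigned to fibril; exact ties have measure zero and
were never observed). Protomer availability is the integral of c over the
in-mask region with c < ½; the crystallized fraction is the in-mask area
fraction with c ≥ ½.

Assumptions inherited from the model class: 2D (the plane normal to the
tendon axis; axial variation and anisotropic PFC extensions are out of
scope), no thermal noise in the dynamics (randomness enters only through
the initial condition), and a single-mode free energy (no two-mode or
correlation-function-fitted variants).

## Units and calibration

The solver is nondimensional with q* = 1; one 10-nm pixel spans
dx_model = 1.209 model length units, i.e. the physical calibration is
q* = 0.1209 nm⁻¹ ↔ one-mode hexagonal spacing 4π/(√3 q*) = 60.0 nm, the
median inter-fibril distance in EM cross-sections. Two calibrations are
exposed (`fibrilpfc.pipeline`):

* **one-mode**: lengths converted with the a-priori factor above. Under it,
  the realized median Delaunay spacing of boundary-grown masked-domain
  patterns measures 63–65 nm: the dynamically selected wavelength of a
  front-grown, geometrically frustrated lattice sits a few percent above
  the one-mode equilibrium value (periodic equilibrated boxes measure ~3%
  *below*; both offsets are resolution-independent, checked at 6–12 grid
  points per wavelength).
* **fitted** (production): the nm-per-pixel factor is set so a reference
  simulation with a fixed internal calibration seed realizes exactly 60 nm
  median spacing — the calibration procedure the study design prescribes
  (one length parameter adjusted to microscopy). The factor is ~9.46 nm/px.

Time is reported in the model's dimensionless units; the mapping to hours
involves an unknown mobility/free-energy-density factor, so only relative
statements (a fast formation scale vs. a ~10× slower maturation scale) are
physically meaningful.

## Initial condition

A Gaussian random field: seeded white noise filtered in Fourier space with
Ĝ(k) = exp(−k²λ²/8), giving autocorrelation exp(−r²/λ²) (λ is the e-folding
distance, in pixels; default λ = 10). The sample is tapered by the smoothed
domain indicator (no sharp step at the boundary, which the high-order
operator would amplify), then shifted and rescaled so the in-mask mean is
exactly φ₀ and the in-mask variance exactly m². Default m² = 0.01; the
equilibrium pattern statistics are insensitive to λ and m² in the explored
range, consistent with the study design. With λ = 10 px the initial field
has essentially no power at the pattern wavenumber, so the bulk stays
quiescent until the boundary-nucleated front arrives.

## Time stepping

Split semi-implicit pseudospectral scheme:

    φ̂ⁿ⁺¹ = [φ̂ⁿ − Δt k² (φ³)ⁿ̂ + Δt ĝⁿ] / [1 + Δt k² ((q*² − k²)² − r)]

(ĝ is the masked-domain flux correction below; zero on periodic boxes).
The k = 0 mode is untouched, so periodic runs conserve the mean to rounding
error (measured drift ≤ 10⁻¹⁰ relative over 10⁴ steps). Construction fails
fast if any implicit denominator is non-positive. The scheme overestimates
linear growth rates by O(Δt): ~48% at Δt = 0.5, ~15% at 0.2, ~7% at 0.1 at
the pattern scale for the production parameters. Production runs use
Δt = 0.1 (a 112² run to t = 1000 takes ~20 s on one CPU); the generic
default is Δt = 0.2 for exploratory work, and the dispersion-relation test
uses Δt = 0.02 where the residual bias is within its 2% tolerance.

## Irregular domains

The inter-cellular space enters as a binary mask Ω with a smoothed
indicator ψ (tanh profile over the signed Euclidean distance, width 2 px at
the production resolution). Three ingredients:

1. **Diffuse-domain no-flux term.** The conserved dynamics on a diffuse
   domain read ∂φ/∂t = (1/ψ)∇·(ψ∇μ) = ∇²μ + ∇(ln ψ)·∇μ. The advective
   correction is evaluated explicitly; for the tanh profile ∇(ln ψ) is
   globally bounded by 2/w, computed analytically from the signed distance.
   μ inside this term is low-passed with exp(−k²h²) (h = one pixel):
   the biharmonic-squared symbol otherwise amplifies pixel-scale kinks of
   the discrete distance transform by O(k_max⁴) and destabilizes fine
   grids.
2. **Exterior pinning.** After each step φ ← ψφ + (1−ψ)φ_b. The production
   wall value is φ_b = 0 (c = ½ at the wall): a weakly collagen-attracting
   cell surface, consistent with protomer being secreted at the surrounding
   cell membranes. This templates the first fibril row along the boundary,
   and the pattern then propagates inward — the experimentally observed
   sequence. With a neutral wall (φ_b = φ₀) nucleation instead starts at
   random bulk locations, which contradicts the observed boundary-first
   appearance; the neutral value remains available via `PFCParams.phi_b`.
3. **Band-local mass restoration.** The pinned exterior is an infinite
   reservoir and exchanges a small amount of protomer with the domain
   (order 10⁻² in the mean over a full run if uncompensated). After each
   step the deficit is paid back inside the smoothing band only, with
   weight ψ(1−ψ): the in-mask mean is then conserved exactly while the bulk
   dynamics remain untouched. Alternatives that spread the correction over
   the bulk (uniformly or weighted toward the medium phase) drive a steady
   current through the pattern and were rejected: they stretch the lattice
   by several percent and pump free energy visibly.

Consequences: masked runs conserve the in-mask mean to rounding error, but
the free energy is not strictly Lyapunov — the band forcing injects
fluctuations of ~10⁻³ relative size. Monotone decrease at 10⁻⁶ relative
tolerance holds on periodic runs and is asserted there; masked runs are
checked against a 5×10⁻³ relative bound.

## Synthetic data

* **Domains.** Star-convex blobs: radius R(1 + p(θ)) with p a seeded cosine
  series over angular modes 2..n+1, normalized so |p| ≤ roughness. Defaults:
  R = 420 nm, roughness 0.30, 8 modes on a 112² grid at 10 nm/px — a lobed
  outline ~880 nm across, matching the size and lobedness of embryonic
  inter-cellular spaces. Rasterization is by pixel-center inclusion; masks
  are validated to be single 4-connected components clear of the grid
  border. Not emulated: concave/multi-lobed topologies beyond what the
  cosine series produces, EM noise and texture.
* **Planted lattices.** Triangular patches generated as parallelograms
  aligned with the lattice vectors (a square clip would leave ragged-edge
  sites that are interior to the hull yet five-coordinated), optionally
  jittered, with vacancies/interstitials/voids planted afterwards. Ground
  truth (neighbor counts, interior flags) is computed by a deliberately
  independent brute-force empty-circumcircle Delaunay oracle plus the same
  pruning/periphery rules, so tests of the production (Qhull-based)
  pipeline are not self-confirming. Exactly cocircular configurations are
  tie-break-dependent; fixtures avoid them with ≥1%-spacing jitter.
* **Abundance tables.** Positive abundances from log-normal baselines times
  one of three noiseless trend profiles — peak-at-E13.5 (soluble collagen-I
  signature), monotone rise (biosynthesis machinery), flat — with
  mean-one multiplicative log-normal noise of a given CV and independent
  Bernoulli missingness. Not emulated: between-replicate structure (the
  n = 3 animals per time point are collapsed into one value), detection-
  limit-dependent missingness, protein-protein correlation.

Passing tests on these generators demonstrates the pipeline's correctness
and the model's qualitative phenomenology; they do not validate the model
against real micrographs or spectra, which would require the original EM
images and MS intensities.

## Analysis pipeline choices

* Fibril detection: 4-connected components of the in-mask c ≥ ½ region;
  components smaller than 25% of a disk of radius spacing/4 are discarded
  (boundary slivers); centers are c-weighted centroids, computed circularly
  on periodic boxes so wrap-crossing fibrils are not split. An independent
  local-maximum detector (Gaussian-smoothed c) serves as a cross-check;
  the two agree within ~2% on equilibrium patterns.
* Triangulation: scipy (Qhull) Delaunay; edges longer than 2× the median
  are pruned, which severs spurious adjacency across voids and boundary
  concavities. A point is peripheral iff it is incident to a pruned-graph
  edge bounding at most one surviving triangle (or is isolated); this is
  parameter-free and reduces to the convex-hull rule on convex, void-free
  bundles.
* Defect proportion d counts every interior fibril with neighbor count ≠ 6
  (fives, sevens and all other counts alike). With no interior fibrils d is
  NaN and flagged.
* Fold-change pipeline: complete-case filtering (any missing time point
  drops the protein), log2(a_t / a_E12.5), peak = argmax with ties to the
  earliest time point. No imputation and no significance testing.

## Timescale measurements

Formation time t90: first time protomer availability completes 90% of its
total net decline over [0, 1000] (linear interpolation between snapshots,
sampled every 5 time units). Maturation time t99: first time the
*cumulative* free-energy decline — the running sum of decreases, increases
not counted — completes 99% of its total. The cumulative form is used
because the last percent of the free-energy relaxation is carried by
sparse, discrete defect-annealing events on top of small boundary-band
fluctuations; a net-level crossing can trigger early on a transient dip and
miss late slow relaxation (for monotone series the two definitions
coincide, and `observables.decline_time` provides the net version).
Production medians over five seeds are t90 ≈ 26–29 and t99 ≈ 320–650; t99
remains seed-volatile because individual annealing histories differ.

## Known limitations

* The boundary treatment is approximate: no-flux holds only to the accuracy
  of the diffuse-domain term, the exterior is unphysical, and the band
  forcing perturbs free-energy monotonicity at the 10⁻³ level.
* The fitted length calibration makes the realized median spacing match
  60 nm by construction; the falsifiable content of the geometry lies in
  the lattice order (neighbor-count mode 6, narrow edge-length
  distribution), the defect statistics, and the one-mode offset being
  small, not in the median itself.
* Defect proportions of simulated patterns (d ≈ 0.15–0.28 at equilibrium)
  are not calibrated against micrograph-derived values, which depend on
  manual fibril picking not reproduced here.
* 2D only; no axial structure, no cross-linking, no cell-mediated
  (fibripositor) deposition; collagen biochemistry is collapsed into
  (r, φ₀).
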