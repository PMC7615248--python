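# Methods

## Signal model and the DiA metric

All computations assume a single-shell acquisition and the mono-exponential
model E(**u**) = S(**u**)/S0 = exp(−b·D(**u**)), so the apparent diffusion
coefficient along the gradient direction **u** is D(**u**) = −ln(E)/b
(mm²/s). The Diffusion Anisotropy is the normalized distance of the
angular profile D from its isotropic equivalent,

DiA = 1 − [∫_S D du]² / (4π ∫_S D² du),

which is 0 for isotropic profiles, < 1 always, and invariant to a global
rescaling of D (and hence to intensity scaling of the DWIs). For a tensor
profile D(u) = uᵀTu the integrals have the closed form ∫D = (4π/3)·tr T
and ∫D² = (4π/15)·[(tr T)² + 2 tr T²], giving

DiA_tensor = 1 − 5 (tr T)² / (3[(tr T)² + 2 tr(T²)]),

used throughout the tests as an exact oracle, alongside a dense
quadrature of the defining integrals.

## Spherical-harmonics estimator

`spherical_harmonics` implements the real, antipodally symmetric
(even-degree) SH basis on top of `scipy.special.sph_harm_y`, orthonormal
on the sphere with R⁰₀ = 1/√(4π); the exact sign convention is pinned by
tests (Y00 value, Gram matrix ≈ identity under a dense quadrature rule).
With the coefficient convention C₀₀{H} = (1/√(4π))∫H, the practical
estimator

DiA = 1 − C²₀₀{D} / (√(4π) · C₀₀{D²})

is algebraically identical to the integral definition. The printed
prefactors of the source formulas are typographically ambiguous between 4π
and √(4π); this pairing is the unique one that makes the SH form reduce
exactly to the integral form, and is the one implemented.

Fits minimize ‖Bc − d‖² + λ Σ l²(l+1)² c²_lm (Laplace–Beltrami penalty).
The l = 0 term is unpenalized, so the spherical mean — the only quantity
DiA needs — is never shrunk; at order 0 the fit returns the arithmetic
mean of the samples for any λ. λ defaults to 0.006 and is applied
identically to the D and D² fits (the simplest self-consistent choice; the
alternative of squaring the fitted D rather than fitting the squared
samples was considered and rejected because the D² fit is what the C₀₀
formula above calls for). Both fits share one precomputed solve, so whole
volumes are fitted with a single matrix product.

**Order rule.** For N sample directions the fit order is the largest even
L with (L+1)(L+2)/2 ≤ N, capped at 8 (N = 3–5 → 0, N = 6–14 → 2, …). This
makes the N = 3 estimator *exactly* the simplified closed form

DiA₃ = 1 − (Dx+Dy+Dz)²/(3(Dx²+Dy²+Dz²)),

for any orthonormal triad (order 0 ignores the directions altogether), and
lets N = 6 capture a tensor profile exactly. DiA₃ is bounded by 1 − 1/3 =
2/3, attained only when a single sample is nonzero, and for a tensor
sampled on its own eigenvectors satisfies the identity DiA₃ = (2/3)·FA².
`dia_simplified` is computed in the difference form
[(Dx−Dy)² + (Dy−Dz)² + (Dx−Dz)²]/(3ΣD²), which is algebraically identical
but exactly zero for equal samples and nonnegative by construction.

**Degenerate inputs.** Background voxels (all samples zero) are defined to
have DiA = 0 and RGB (0,0,0) so they render black; noise pushing the
signal above the baseline is clamped to E = 1 (D = 0), and E below 10⁻⁸ is
floored so the log stays finite. Tiny negative DiA values from float
cancellation are clipped at 0.

## Quadrature oracle

`dia_quadrature` evaluates the defining integrals with a
Gauss–Legendre-in-cos θ × uniform-in-φ product rule generated at run time
(default ≥ 2562 points). For band-limited integrands such as tensor
profiles the rule is exact to machine precision and rotation-robust, which
is why it serves as the ground truth the SH estimator is tested against; a
committed point-set fixture would add a data file without adding accuracy.

## Maps, masking and color code

S0 is the mean of the b0 volumes (policies: mean / median / first); the
foreground mask defaults to Otsu thresholding of S0 and can be overridden
by a user mask. bvecs are interpreted in the **image frame** (FSL
convention, 3×N or N×3 auto-detected), so the RGB code r,g,b =
DiA·D_{x,y,z}/D_AV refers to the image axes; channels are clipped to
[0, 1] (clipping preserves hue ordering, matching common FA-RGB practice,
rather than renormalizing). The `--estimator auto` CLI mode selects the
simplified formula only when exactly 3 directions are mutually orthogonal
within 2°; the RGB map is written only for 3-direction data, since the
per-axis code has no defined meaning for denser schemes.

## Simulator

Ground truth is a 3×3 symmetric PSD tensor assembled as VΛVᵀ; the
reference tensor has eigenvalues [1, 0.3, 0.3]×10⁻³ mm²/s (FA = 0.6444).
Two rotation families are provided: in-plane (about y, so one eigenvector
stays axis-aligned) and spatial — a Rodrigues rotation about (1,1,1)/√3,
whose diagonal is 1/3 + (2/3)cos θ and whose θ = 2π/3 case is the cyclic
coordinate permutation; for generic θ no eigenvector is axis-aligned.

Direction sets are deterministic: Cartesian axes (n = 3), tetrahedral
vertices (n = 4), icosahedral vertices (n = 6, the classic minimal DTI
scheme — as a spherical 5-design it integrates D and D² exactly at order
2, which is why the 6-direction DiA is orientation-independent), and for
n = 5 or n > 6 an electrostatic-repulsion optimum of the antipodal Coulomb
energy found by projected gradient descent from a fixed Fibonacci-lattice
start (cached per n; the 64-point set has a minimum folded angle of ≈ 17°,
near the packing ideal).

Phantoms are S0·exp(−b·uᵀTu) per voxel and direction with baseline
volumes prepended (defaults b = 1000 s/mm², S0 = 1000, one b0, 2 mm
isotropic voxels). The rotation-sweep study is noiseless by design; noise
is opt-in and Rician — the magnitude of the signal perturbed by two
independent Gaussian channels — seeded via `numpy.random.default_rng`.
The simulator emulates the angular behaviour of single-fiber voxels only:
no crossing fibers, partial volume, eddy-current or motion artifacts, and
no spatial correlation of noise. Passing tests therefore demonstrate the
estimator algebra and its orientation dependence, not robustness to real
acquisition artifacts.

## Experiments

* **Rotation sweep** — the reference tensor is rotated over θ (default 0°
  to 360° in 1° steps), sampled on each fixture scheme, and DiA estimated
  with the order rule. The 3-direction in-plane curve is 90°-periodic with
  its minimum at 45°, where DiA drops from 0.27684 to 0.08734; the
  6-direction curve is constant at the tensor value 0.13279.
* **Angular consistency** — a phantom of six prolate-tensor populations
  (fixed mean diffusivity 0.7×10⁻³ mm²/s, shape coefficients δ = 0.40 to
  0.90 giving ground-truth DiA ≈ 0.11–0.39, all above the 0.1 masking
  cutoff; one random orientation per voxel) is sampled on a 64-direction
  scheme. The reference map is thresholded at DiA < 0.1, clustered by 1-D
  k-means (k = 6, quantile-initialized with a single run, so the
  clustering is deterministic), and the per-cluster median recomputed on
  greedy max-min angular subsets of 3–48 directions. The default grid is
  12×12×6 (864 voxels), which keeps the study under a second while leaving
  144 voxels per population.
* **Orientation variability** — for tensors of increasing FA, DiA₃ is
  computed for every near-orthogonal triplet (pairwise angles within 15°
  of 90°, antipodally folded) drawn from a dense scheme, emulating an
  exhaustive search over acquisition orientations; an unrestricted
  all-triplets mode (optionally capped by a seeded subsample) is available
  behind a flag. Reported medians track FA monotonically while the spread
  quantifies the orientation-induced underestimation.

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| b0_tolerance | 50 s/mm² | b-value at or below which a volume is a baseline |
| λ (Laplace–Beltrami) | 0.006 | SH smoothness penalty, both D and D² fits |
| order rule | max even L with (L+1)(L+2)/2 ≤ N, cap 8 | SH fit order per direction count |
| epsilon_E | 10⁻⁸ | floor on the normalized signal before the log |
| quadrature points | ≥ 2562 | oracle integration rule size |
| DiA cluster cutoff | 0.1 | reference-map threshold before k-means |
| orthogonality tolerance | 2° (CLI), 15° (triplet search) | what counts as an orthogonal acquisition |

## Known limitations

The 3-direction estimator is a deliberate order-0 truncation: it
underestimates anisotropy for structures not aligned with the acquired
axes (by up to ≈ 3.2× for the reference tensor at 45°) and its absolute
value is not comparable to FA or to the densely sampled DiA. The RGB code
inherits the axis-alignment assumption. Multi-shell data are not modeled
(only the innermost shell's behaviour is represented), and no Rician bias
correction is applied to noisy data.
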