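# Methods

`mechprop` analyses mechanical signal propagation between epithelial
cells on adhesive micropatterns: how a contractility step induced in a
"sender" region (e.g. by optogenetic RhoA activation) propagates to a
"receiver" region, and how strongly the receiver responds actively.
Because the package is developed and validated desk-side, every input it
consumes can be generated synthetically with known ground truth; this
note describes the models, the estimators, the numerical choices, and
what the synthetic validation does and does not demonstrate about real
data.

## Traction force microscopy

**Forward model.** The substrate is a linear elastic half-space
(Young's modulus E, default 20 kPa; Poisson ratio ν, default 0.5, the
incompressible-polyacrylamide convention); only tangential displacement
and traction are considered.  The surface Green's function is

    G_ij(r) = (1+ν)/(πE) [ (1−ν) δ_ij/r + ν r_i r_j/r³ ].

`boussinesq.forward_displacement` evaluates the aperiodic convolution of
a traction field with this kernel via zero-padded FFTs; the singular
self-cell is replaced by its analytic cell average
(∫ dA/r over an h×h square = 4h·ln(1+√2)).  A brute-force summation
(`direct_displacement`, with sub-cell refinement near the evaluation
point) provides an independent quadrature; the two agree to <1% on
corner-patch fields and the FFT route is used everywhere else.

**Displacement recovery.** Bead images are cross-correlated in windows
of 13.8 µm, halved twice, each pass shifting the deformed subimages by
the current estimate (50% window overlap).  The correlation peak is
refined sub-pixel with a Gaussian three-point fit (a parabolic fit peak-
locks visibly at the ~0.3 px incremental displacements that matter for
photoactivation differences; the parabola remains as a fallback, and
ties in the integer peak break toward zero shift).  On the final
subimages, single-particle tracking measures per-bead displacements:
bead centres by Gaussian interpolation of the intensity peak,
mutual-nearest-neighbour matching within 2 px of the window-predicted
position.  Outliers are discarded and replaced by the mean of their
neighbours when the vector magnitude exceeds 2.5 µm or the difference
from the 8-neighbour mean exceeds 1 µm (median of a 24-point
neighbourhood when all neighbours are flagged).  The surviving vectors
are interpolated linearly on their Delaunay triangulation onto a regular
1.3 µm grid (exact for affine fields; zero outside the convex hull).
In a movie only the first frame is compared to the unstressed reference;
later frames are correlated with their predecessor and the incremental
grids accumulated — small displacements correlate much more precisely.

**Inversion.** Fourier-transform traction cytometry with zero-order
(Tikhonov) regularization: per wavevector, T̃ = (G̃ᵀG̃+λ²I)⁻¹G̃ᵀũ with the
analytic half-space kernel; the k=0 mode is set to zero (tractions of an
isolated cell balance).  The displacement field is cosine-tapered into
the padding (an abrupt zero-padding step rings spurious traction along
the field border).  λ defaults to 0; a generalized-cross-validation
selector (`select_regularization_gcv`, evaluated in the per-mode
eigenbasis) is provided for noisy data.  The forward model uses the
real-space kernel and the inverse the analytic Fourier kernel, so the
round-trip test exercises two independent discretizations; on the
corner-patch fixture the noise-free round trip is ~2–4% RMS.

**Strain energy.** Es = ½∫T·u dA over the cell, reported in joules and
split at the vertical midline.  Relative curves subtract the cell's own
baseline (mean of the first 20 frames) and divide by the cohort-average
baseline.

## Monolayer stress microscopy

The cell sheet is a thin, linear-elastic plane-stress layer loaded by
(minus) the measured traction as a body force, with traction-free
boundary.  The recovered sheet stress σ (units Pa·µm = 10⁻⁶ N/m)
satisfies ∇·σ = T; because the load is prescribed, σ is exactly
independent of the sheet modulus, and only weakly dependent on the sheet
Poisson ratio (fixed at 0.5 by convention, not asserted).  Elements are
bilinear quads *on the traction grid*: coarser meshes lose several
percent of the end load where element blocks straddle the mask boundary,
which would break the discrete force balance that the strip oracle
checks (mean interior σxx = end force / strip height, exact here).
Residual net force and torque are removed from the load before the
Neumann solve, whose rigid modes are eliminated with three Lagrange
constraints.  Mechanical polarization is
(σ̄xx − σ̄yy)/(σ̄xx + σ̄yy): +1 horizontal, 0 isotropic, −1 vertical.

## Structure-tensor polarization

Per pixel, J = ⟨∇I ∇Iᵀ⟩ averaged over a Gaussian window of waist 3 px;
gradients are Gaussian derivatives at σ = 1 px — keeping the derivative
scale below the window is what lets a structureless image decorrelate
inside the window (white noise then has mean coherency ≈ 0.2; with
derivative = window scale it would sit near 0.45 and the 0.4 coherency
cutoff would be meaningless).  The structure orientation
θ = ½·atan2(2J12, J22−J11) ∈ [0°,180°) is the direction of least
intensity variation; coherency = √((J22−J11)²+4J12²)/(J11+J22).  Pixels
with coherency < 0.4 (and a 2×waist border) are excluded; θmean is the
circular mean of 2θ and the polarization degree ⟨cos 2(θ−θmean)⟩.  An
axis-referenced variant (θmean → 0°) gives a signed value comparable to
the mechanical polarization.  Rotation equivariance is verified to ±2°
on synthetic textures.  Half-cell actin intensity curves erode the mask
by 1 µm (configurable) to exclude peripheral fibers, then normalize each
half's summed intensity by its first-20-frame mean.

## Anisotropic-tension contour model (ATM)

A free peripheral stress fiber spanning a non-adhesive gap obeys
d(λt̂)/ds + Σ·n̂ = 0 with line tension λ and surface-tension tensor
Σ = diag(σx, σy).  Axis-aligned ellipses with **σx·b² = σy·a²** solve
this balance with a position-dependent line tension
λ(u) = σx b²·g(u)/(ab); at the midpoint of a fiber spanning a horizontal
chord, λ = σx·b.  The isotropic limit is the circular arc with
R = λ/σ.  Given σx (measured on the traction maps as |ΣTx dA|/height in
a 4×10 µm window at the adherent-fiber centre), the fitter constrains
the ellipse through both adhesion points and minimizes orthogonal
point-to-ellipse distance (Newton projection) over the axis ratio and
size — a bounded, multi-start trust-region search, because the flat-arc
limit (σy < σx) has a long shallow cost valley in which single-start
Levenberg–Marquardt can run away.  Noise-free recovery is exact to
<10⁻⁸; at 0.2 µm point noise the per-fit distribution is heavy-tailed
for flat arcs, and accuracy statements are made on the Monte-Carlo
median (≈1–6% error across σy/σx ∈ {0.5, 1, 2} at 50 tracked points).

Fiber tracking draws profiles perpendicular to the operator-defined
chord and takes the sub-pixel peak of the smoothed intensity (a
gradient-magnitude criterion would lock onto the fiber's edges, not its
centre), flagging low-contrast profiles.  Filtering runs in the stated
order: 5-frame temporal median, 2σ outlier removal in 10-frame windows,
3σ spatial removal, then an angle criterion that removes points whose
adjacent segments *turn* by more than 15° — the turn angle, not the
angle to the chord, since a legitimate free fiber meets its chord at up
to ~50°.  Corner forces sum traction over a 12 µm disc around the local
traction peak (ties toward the pattern corner); λ and Fa are the
projections onto the contour tangent and the y-axis, optionally after
subtracting the surface-tension pull σx·L/2 on the adherent fiber (a
strategy hook, since the exact correction is model-dependent).

## Active viscoelastic sheet and coupling estimation

The cell is a plane-stress sheet of Kelvin–Voigt elements
(σ = Cε + C_η ε̇ + σa·I) on an elastic foundation (traction = Y·u),
integrated implicitly at Δt = 1 min to match the acquisition cadence.
During the activation window (frames 20–30 of 60 by default) the active
stress rises by Δσ in the sender (left) half and ε·Δσ in the receiver,
with the sender boundary smoothed over 2 µm.  Defaults —
E_s = 1.1×10⁵ Pa·µm, Y = 500 Pa/µm (localization length √(E_s/Y) ≈ 15 µm),
σa = 1.5×10⁴ Pa·µm, Δσ = 1400 Pa·µm, η = 2.2×10⁵ Pa·µm·min (τ = 2 min) —
are chosen so the simulated system reproduces the scales seen on 20 kPa
gels: edge tractions of order 1 kPa, substrate displacements of order
1 µm, and a ~20% relative strain-energy rise under global activation.
The 1D steady state is verified against the analytic spring-foundation
solution u ∝ sinh(x/ℓ) to <2%.

The *fluidized* variant exchanges the body for Maxwell elements from
activation onward, relaxing the **total** stored stress (passive +
active): σ̇ = Cε̇ + σ̇a − σ/τ_M (τ_M = 10 min).  A Maxwell body with a
*constant* active stress would creep indefinitely and its traction would
grow — the opposite of fluidization; relaxing the total stress makes
traction keep decaying during and after activation, the observed
signature of the destabilized response.

**Coupling curves and ε̂.**  For each ε on a grid, the after−before
stress-change map is y-averaged and the *signed* right-half area
fraction of the profile taken (the absolute-area convention is computed
and stored alongside; the signed one maps receiver relaxation to
negative responses and is the default).  At ε = −1 the response is
antisymmetric, the signed total vanishes, and the point is flagged
degenerate and dropped.  By symmetry the response at ε = 1 is exactly
0.5.  The curve is monotone and is inverted at the experimental response
by linear interpolation (out-of-range values clamped and flagged).
Consistency of operator is essential: the model curve is computed by
pushing the model's *traction* through the same MSM solve used for data
(only the σxx y-profile is pinned by force balance; the σyy profile of
an MSM reconstruction differs systematically from the simulation's
internal stress, and using the latter biases ε̂ by several tenths).
For imaged data the curve additionally passes through the noise-free
imaging chain ("imaging" response source), sharing the measurement
operator's smoothing.

**Measuring the stress change.**  Differencing two independently
recovered absolute traction maps does not cancel per-bead localization
error and buries the ~0.1 µm incremental displacement signal.  The
pipeline instead correlates the before and after frames *directly*
(window correlation only; SPT is bypassed for this step), averages five
frame pairs as the acquisition protocol averages frames, and feeds the
difference displacement through FTTC and one MSM solve — every step is
linear.  With this route, on the σyy channel, noise-free recovery of
ε ∈ {−0.5 … 1} is exact to the curve-interpolation level and cohort
means of three simulated cells at 10% image noise recover ε within
±0.1.  The contour channel drives the active-contour model (semi-
implicit relaxation of a discretized fiber with position-dependent
isotropic surface tension; equilibrium is the λ/σ circular arc to
machine precision) and uses the strain profile d_after/d_before − 1.

The attenuation distance d is measured from the peak of the y-averaged
stress-change profile to its first crossing of 20% of the maximum
(sub-grid by linear interpolation); when the profile never drops below
the threshold inside the pattern the result is flagged "beyond domain"
(this happens for ε ≳ 0.5 on the 45 µm doublet, where the response
saturates the pattern).

A model property worth stating: the σxx coupling curve lies *above* the
σyy curve for ε < 1.  Forces in x must balance across the junction (the
"tug of war"), so even a passive receiver shows a substantial σxx
response, whereas y-forces balance locally between each cell and the
substrate and the σyy response stays with the sender.  The same
experimental response therefore implies a smaller ε when read on the σxx
curve — the direction of the x/y asymmetry seen in real doublets.

## Synthetic data: what it does and does not show

The generators emulate (i) corner-concentrated traction on H/rectangle
patterns (Gaussian patches, auto-balanced, 100 nN per corner by default,
16 µm field margin so the 12 µm corner-force disc stays inside the
view), (ii) bead images (0.4 beads/µm² ≈ 5 per final PIV window, PSF
σ = 0.45 µm at 0.3 µm pixels, Gaussian read noise of 10% of the bead
amplitude), (iii) oriented actin-like textures (anisotropically filtered
noise), (iv) ATM contour tracks, and (v) photoactivation series from the
active FEM with known ε.  They do *not* emulate photobleaching, optical
aberrations, bead polydispersity, out-of-plane substrate deformation,
cytoskeletal remodelling beyond the single active-stress field, material
anisotropy (so the experimentally observed amplification perpendicular
to the polarization axis is outside the model), or cell-to-cell
variability.  Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated conditions, not the
biological conclusions themselves.

## Problem sizes

Validation runs use a 0.3 µm working pixel (vs 0.1 µm acquisition), a
1.5–2.5 µm FEM mesh, 24–60 simulated minutes, 3-seed noise cohorts in
the test suite (50-seed Monte-Carlo for the contour fits), and contour
discretizations of 61 nodes.  All sizes are configurable; the defaults
were chosen so a full validation pass completes in minutes while every
tolerance is met at the stated level.
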