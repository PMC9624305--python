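# Methods

This note documents the models, the numerical choices, what the
synthetic data do and do not emulate, and the known limitations.

## Elastic model and Fourier solver

The substrate is a linear-elastic, isotropic, semi-infinite half-space.
Only tangential surface tractions and in-plane surface displacements are
modelled (2D TFM). The real-space Boussinesq/Cerruti surface Green
tensor

    G_ij(r) = (1+σ)/(πE r) [ (1−σ) δ_ij + σ x_i x_j / r² ]

has the Fourier transform

    G̃(k) = 2(1+σ)/(E k³) [ (1−σ)k² + σk_y²  −σk_x k_y
                            −σk_x k_y         (1−σ)k² + σk_x² ],

with k in rad/µm, E in Pa, G̃ in µm/Pa. Both forms are implemented
independently (`greens_tensor_hat` vs `boussinesq_point_displacement` /
`boussinesq_convolve`) and the package's tests require them to agree:
the Fourier forward model matches the brute-force real-space convolution
within 2% away from grid boundaries, which fixes the prefactor and the
off-diagonal sign against the classical closed form. Note that this
prefactor is equivalent to A = 4π(1+σ)/E in the A/(2πk³) form sometimes
quoted; a prefactor proportional to E rather than 1/E is dimensionally
impossible since stiffer gels must deform less.

Discrete convention: with G̃ expressed in physical units of rad/µm the
grid-spacing factors of the discrete transform cancel, so
`u = IFFT2(G̃ · FFT2(T))` directly. The k = 0 mode is singular (a net
force on a half-space has no bounded displacement) and is nulled in both
directions — the standard zero-net-force convention; cells exert
balanced force systems, so no information is lost. Fields are
zero-padded to twice the linear size before transforming because the
physical convolution is aperiodic (default `pad_factor=2`; the
round-trip identity test uses matched periodic conventions,
`pad_factor=1`, where inversion is exact to machine precision).

Inversion solves, per wave vector, the 2×2 system exactly (λ = 0) or the
Tikhonov normal equations (G̃² + λI)T̃ = G̃ũ (λ > 0, units (µm/Pa)²).
λ defaults to 0; it is exposed because noisy experimental bead data
generally require it. The mean displacement (a rigid translation) is
subtracted before inversion.

Point forces on the grid deserve a caveat: a single-cell impulse has
super-Nyquist content, so the band-limited solution deviates from the
continuum point solution by ≈ 0.45·(Δx/r)² locally — about 9% two grid
spacings away, under 2% beyond six. Validation against closed forms is
therefore done either with band-limited (Gaussian) sources or in the far
field.

## Displacement measurement

Beads are detected as local maxima above a fractional intensity
threshold and refined by a background-subtracted, recentred intensity
centroid; at high density the refinement deblends overlapping spots by
iteratively subtracting each spot's fitted Gaussian (CLEAN-style).
Detection accuracy on isolated synthetic spots is ≈ 0.005 px.

Linking the two frames is the failure-prone stage. Whenever the local
displacement approaches the bead spacing, nearest-neighbour linking can
lock whole neighbourhoods onto wrong partners that remain mutually
consistent — no posterior vector filter can repair that. The tracker
therefore works predictor-corrector:

1. a multi-pass window-correlation predictor (phase cross-correlation
   of 16 → 12 → 8 µm windows, each later pass correlating the loaded
   window pre-shifted by the current prediction) supplies an initial
   displacement field that is immune to bead identity;
2. for 8 iterations, each reference bead is linked to the loaded bead
   nearest its predicted position, accepted only if mutual and either
   within 0.3 µm of the prediction or within 0.9 µm while beating the
   second-nearest candidate by a 0.45 distance ratio;
3. a local-median outlier filter runs between iterations and a
   smoothing-spline consistency filter at the end.

Plain mutual-nearest-neighbour matching remains available
(`match_beads`) and is adequate when displacements are well below the
bead spacing (e.g. drift measurement).

Gridding uses a thin-plate-spline surface by default (exact at beads,
smooth between; its degree-1 polynomial term reproduces constant and
linear fields exactly); piecewise-linear Delaunay interpolation is
available via `method="linear"` but loses curvature at realistic bead
spacings and is measurably worse upstream of the inversion. Cells
outside the bead convex hull are flagged in the validity mask. Stage
drift, when a cell mask is supplied, is the median displacement of
outside-mask beads and is subtracted.

## AFM force curves

The Sneddon cone model F = (2/π)tan(α)·E·δ²/(1−ν²) is fitted to the
approach segment. The contact point is first located by a robust
baseline (median, MAD noise) threshold crossing that must persist for
three samples, then refined jointly with the quadratic coefficient by a
bounded 1-D minimisation — the threshold estimate alone lands late and
biases E low by a few percent at high modulus. Indentation is corrected
for cantilever bending, δ = Δz − F/k (k in N/m; 1 N/m = 1000 nN/µm),
which is what makes 0.03 and 2.8 N/m levers agree. Cell Poisson ratio
defaults to ν = 0.5. Fits return `converged=False` (never raise) on
non-positive moduli or too few post-contact samples; maps flag
`unreliable` when over half the fits fail, and pixels with relative
residual > 20% are excluded from the quality mask. Measured on
simulated curves with 2% multiplicative force noise: bias < 0.1%,
CV ≈ 1.2% across 0.4–2.3 kPa.

## Traction metrics and units

Per-cell quantities are defined over the cell mask only: mean and peak
stress magnitude, total force Σ|T|·A_px, and net vector force ΣT·A_px.
The unit contract is exact and unit-tested: 1 Pa·µm² = 1 pN = 10⁻³ nN
(so 50 Pa over 150 µm² = 7.5 nN, and 1 Pa over 10⁶ µm² = 1 µN). Time
series keep the trace and report mean/SEM/min/max plus a convenience
growing-like/quiescent-like label (stress range above/below a 15 Pa
threshold); a single-point series reports SEM 0 with a flag. The
stress–modulus join takes the mean modulus over quality-passing map
pixels; the overlap statistic uses the stiff-pixel count as denominator
(the reverse fraction is also reported) and Otsu's threshold for the
actin mask unless a fixed fraction-of-range rule is configured.

## Synthetic data: what it emulates, what it does not

Scene defaults are the study conditions: 470 Pa incompressible gel
(σ = 0.5), mean stresses of tens of Pa (28–70 Pa growing, ~17 Pa
quiescent), contact areas 100–250 µm², forces of a few nN, cell moduli
coupled to stress as E = 0.4 kPa + 0.027 kPa/Pa (spanning ≈ 0.4–2.3
kPa), 16×16 force volumes at 1 µm pitch with a 30° cone and 0.03 or 2.8
N/m levers, and 10-min sampling over 2 h. Traction patterns are
Gaussian adhesion patches (σ = 5 µm) on the cell periphery pulling
toward the cell centre, rescaled so the mask-mean stress is planted
exactly, then projected to zero mean force. Displacement truth is the
package's own forward model (shared code path, asserted identical).
Beads are rendered as Gaussian spots (PSF σ = 0.2 µm, 0.25 µm pixels)
with Poisson shot noise at a usable areal density of 0.1 beads/µm²
(mean spacing ≈ 3.2 µm) — a conservative stand-in for the in-focus
layer of a 5%-volume bead loading; sparser fields undersample the
displacement features these stresses produce and make accurate
reconstruction information-theoretically impossible. Growing cells
alternate high/low stress phases (±30% around a characteristic value,
2–3 sample dwell); quiescent cells hold a constant low stress, which
with `growth_fraction=0` doubles as the constant-stress cohort in which
total force tracks contact area alone (the contact-guidance harness).
Colocalization scenes plant a connected stiff blob and derive the actin
mask from it with a deterministic 18% jitter, so the planted overlap is
82% — inside the experimentally observed 78–85% band by construction;
that test demonstrates the measurement chain, not the biology.

Not emulated: optical aberrations beyond a Gaussian PSF, bead
polydispersity and out-of-focus light, gel viscoelasticity or finite
thickness, cell-shape dynamics between frames, molecular-clutch
mechanics. Passing tests therefore certify the analysis chain on
idealised-but-noisy data; they do not certify robustness to every
artifact of real microscopy.

Measured end-to-end performance at these conditions (render → track →
grid → invert → integrate): mean-stress error typically 2–5% per scene,
occasional ~6–8% outliers from locally unresolvable bead
configurations; shot noise at the default photon budget adds little
because detection is photon-limited at ≈ 0.1 px per bead while the
error budget is dominated by sampling. The documented tolerances (5%
noise-free, 15% noisy) are checked as means over several scenes.

## Pipeline and reproducibility

All randomness flows through explicit integer seeds; regenerating any
scene or cohort with the same seed is bit-exact, and a pipeline re-run
under an identical config reproduces its CSV outputs checksum-identical.
The staged runner records a manifest (config hash, seed, version, stage
outputs); coordinates are 0-based pixel-centre, x = column/east,
y = row/south; all table columns carry unit suffixes.

Problem sizes used in the shipped tests and acceptance script — 64×64 µm
fields, 100-seed Hertz ensembles, 4-scene recovery means, a 30-cell
single-timepoint cohort — were chosen as the smallest sizes at which the
statistics above are stable.

## Known limitations

* The inverse problem is solved unregularised by default; real data with
  uncorrected outliers or strong noise need λ > 0, and the choice of λ
  is left to the user (no L-curve automation).
* Tracking assumes mostly-overlapping fields of view and displacements
  below roughly half the correlation-window size; gross stage shifts
  should be removed beforehand.
* The half-space assumption fails for gels thinner than a few times the
  cell size; no finite-thickness correction is provided.
* AFM fitting covers conical tips only, with a single elastic modulus
  per curve (no viscoelastic or multi-layer models).
* Automatic cell segmentation is out of scope: masks are inputs.
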