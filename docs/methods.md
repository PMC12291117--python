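# Methods

This note records the models implemented in `oligogrowth`, the
assumptions behind them, the defaults that matter, and the choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Anisotropic growth model

**Model.** An oligomer of `n` identical, densely packed subunits whose
overall shape is convex has a rotationally averaged projected area
(the quantity ion mobility measures as CCS) of

    CCS(n) = σ · Ω₀ · n^(2/3),

with Ω₀ the monomer CCS and σ a distortion factor. The n^(2/3) law is
volume scaling of a compact body; σ captures shape. Writing assembly
and monomer as ellipsoids with semi-axis folds (1, i, j) and
(1, i₀, j₀), Cauchy's theorem (mean shadow = surface area / 4 for
convex bodies) plus the Knud Thomsen three-term power-mean surface
formula

    S ≈ 4π · ((aᵖbᵖ + aᵖcᵖ + bᵖcᵖ)/3)^(1/p),  p = 1.6075,

gives the closed form for σ implemented in `distortion_factor`. Three
assumptions are inherited by everything downstream: orientations are
sampled uniformly (no alignment in the drift cell), packing has no
voids, and the envelope is convex. Surface ruggedness violates the
third assumption and inflates fitted σ values; the convexity shape
factor (below) is the diagnostic for that.

**The exponent.** `optimal_power_exponent` recomputes Thomsen's
constant rather than trusting it: exact areas come from Legendre
incomplete elliptic integrals (`ellipsoid_area_exact`, cross-checked
in the tests against direct surface-integral quadrature), and a
bounded scalar minimization finds the p with the smallest worst-case
relative error over a geometric grid of axis ratios. The optimum is a
property of the shape family: over ratios up to 10 it is ≈1.602 (max
error ≈0.8%), and it converges to 1.6075 (max error ≈1.061%) once the
family includes strongly flattened and elongated shapes (default
`ratio_max=1e4`, 60-point geometric grid — converged to <1e-5 in p).

**Identifiability.** In a single power-law fit σ and Ω₀ enter only
through their product, so `fit_growth` resolves the ridge by
convention: the default fixes Ω₀ to the measured monomer CCS (the n=1
point, or a user-supplied value) and leaves σ free. The alternative
`omega0='free'` co-fits both with Ω₀ bounded to ±20% of the monomer
reference and a weak quadratic anchor (scaled at 1e-3 of the data
norm) pulling Ω₀ toward that reference; on noiseless data this
reproduces the fixed-convention answer while letting the monomer CCS
absorb small calibration offsets. Selection keeps, per oligomer
number, the highest-intensity conformer (`most_abundant`), matching
the practice of fitting dominant species; `all` and intensity
weighting are available but off by default. Fitting ranges (e.g.
n = 2–16 vs larger oligomers) are explicit user input — no changepoint
detection.

**σ-contour inversion.** For fixed i, σ(i, ·) on j ∈ [1, 50] has a
single interior minimum; `solve_axis_ratios` brackets each monotone
branch and bisects (`brentq`, verified by re-evaluation to 1e-8).
Distinct (i, j) pairs on one contour are genuinely different shapes
with identical mean shadow — the inversion is deliberately
multivalued. Roots closer than 1e-4 in (i, j) are merged to avoid
reporting the contour's tangency point twice.

**Monte-Carlo oracle.** `mean_projected_area_mc` averages the
closed-form ellipse shadow area over uniformly random directions. It
shares no code path with the power-mean formula, so the test-suite
comparison (shadow ≈ area/4 within max(3·SE, 1.1%)) is a genuine
two-route consistency check of the σ algebra.

## Structures and surface geometry

Structures are parsed from fixed-column PDB (ATOM/HETATM/MODEL;
HETATM residues such as the acylated lysine D6M are retained; altLoc
other than blank/'A' dropped; each MODEL is one trajectory frame).
Masses and Bondi van der Waals radii come from a bundled element
table; unknown elements fall back to 1.7 Å with a logged warning.
Chains are monomers — the only partition the analyses use.

SASA is Shrake–Rupley with a golden-spiral point set (defaults: probe
1.4 Å, 960 points — standard practice; the tests check a two-sphere
configuration against an independent dense latitude–longitude
quadrature).

The convexity shape factor is SES-area / hull-area. The molecular
surface is approximated as the outer zero level set of the signed
distance to the probe-inflated union of atom spheres, sampled on a
0.5 Å grid and triangulated by marching cubes; interior cavities are
flood-filled first so only outward-facing surface counts. The hull is
the convex hull of the same inflated spheres (each sampled at 200
surface points). Two caveats are documented deliberately: (i) the
ratio is ~1 for convex bodies and grows with surface *roughness*, but
for two smooth equal-radius lobes the zone/cylinder area identity
makes surface and hull areas cancel exactly — concavity registers only
when the lobes are flattened enough that facing walls add area (the
test fixtures use disk-shaped lobes for this reason); (ii) absolute
values depend on probe and grid resolution, so the shape factor is a
trend diagnostic, not an absolute observable.

## Fuzzy-oil-drop profiles (1D)

Residue hydrophobicities are Kyte–Doolittle values normalized by the
scale's maximum absolute value, H(r) = h(r)/max|h| ∈ [−1, 1]. The
bundled table assigns D6M the scale maximum (+1.0 normalized),
reflecting its palmitoyl tail; this is configurable. Coordinates are
centred at the geometric centre and scaled isotropically so the
largest |coordinate| maps to 1 — a shared scale across axes, chosen
over per-axis scaling to preserve the relative spreads σ_{r,i}. Each
residue contributes H(r)·exp(−(x−μ)²/2σ²) per axis, with μ the
unweighted mean atom position and σ the RMS deviation of its atoms
(floored at 0.02 normalized units so single-atom residues stay
finite); profiles are evaluated on 201 points over [−1, 1] and the
average profile is the pointwise mean of x, y, z. The core/edge
diagnostic reports means over |x| ≤ 0.25 and |x| ≥ 0.7 and flags a
central dip when the value at 0 lies below flanking local maxima
within |x| ≤ 0.5. All atoms contribute (not heavy atoms only), and μ
is unweighted by mass — the spread is positional, not inertial.

## Protonation planning

The plan models gas-phase charge assignment after native electrospray:
existing positive charges (Lys, Arg, His side chains, chain N-termini)
are fixed and never removed; the charge deficit target − (basics −
acids) is met by protonating acidic sites (Asp, Glu, chain C-termini,
and declared groups of nonstandard residues — D6M contributes its
appended glutamate carboxylate; its acylated amine is not basic) in a
deterministic order: accessible non-bridged acids by descending pKa
then descending SASA; then accessible salt-bridged acids by ascending
bridge distance, then pKa, then SASA; buried acids last (descending
pKa, then enumeration order — a convention, since this tier is rarely
reached at typical native charge states). Defaults that are
conventions, not measurements: salt bridge = any acidic-O to basic-N
heavy-atom distance ≤ 4.0 Å; buried = titratable-group SASA < 5 Å²;
intrinsic pKa table Asp 3.65, Glu 4.25, C-term 3.55, His 6.0, Lys
10.4, Arg 12.5, N-term 8.0 (all configurable). The output is a plan —
ordered sites with a protonated prefix — not modified coordinates;
hydrogen placement belongs to the modelling package consuming it. The
tie-break chain ends at enumeration order, making the full ordering
total and the plan reproducible; raising the target by one extends the
prefix without reordering.

## Free-energy landscapes

Densities are estimated by a two-stage Abramson-style adaptive KDE: a
Scott's-rule pilot (h_d = std_d·n^(−1/6), floored at 1e-3 of the grid
span so degenerate clouds stay finite), then per-point bandwidth
factors λ_k ∝ pilot(x_k)^(−1/2) normalized to unit geometric mean,
clipped to e^±3. Points are binned to the grid and λ is quantized into
32 geometric levels, each applied by Gaussian filtering of its
sub-histogram — evaluation cost is then independent of sample size,
which is what makes bootstrap bands affordable. The default grid is
100×100 padded 5% beyond the data range; the density is renormalized
to integrate to 1.

Optional total-variation denoising (Rudin–Osher–Fatemi via Chambolle's
projection, `skimage.restoration.denoise_tv_chambolle`) stabilises
plateaus; weight 0 is an exact no-op, output is clipped at zero and
renormalized. TV never increases; large weights eventually flatten
shallow wells, so well *ordering* is only guaranteed at moderate
weights (the two-well test uses 0.01 on a unit-max-scaled grid).

Boltzmann inversion uses ΔG = −k_B·T·ln(ρ/ρ_ref) with k_B = 0.0019872
kcal·mol⁻¹·K⁻¹ and T = 300 K by default. Cells with ρ below 1e-6 of
the maximum are masked (NaN), not infinite. Because only free-energy
*differences* are identifiable from populations, surfaces are
min-referenced (global minimum = 0) by default, with a
maximum-density reference as the alternative; absolute well depths
quoted against any external baseline are outside what densities can
determine. Bootstrap bands resample trajectory points with
replacement, rerun the full pipeline per replicate, and report
per-cell 2.5/97.5 percentiles under a fixed seed.

Minima are strict 8-neighbourhood minima ranked by persistence (a
union-find sweep in ascending ΔG; a basin's depth is the merge level
minus its minimum), filtered by minimum depth and separation, and
labelled α, β, γ, … by ascending ΔG. Persistence rather than raw
local-minimum detection is what keeps KDE ripple from spawning
spurious states. No kinetics are derived from the surface — the
estimator sees populations only, and trajectories produced under
annealing or resampling do not carry usable rate information.

## Monomer conformations

Per-monomer Rg is mass-weighted and computed per chain per frame;
frame statistics are the mean and population SD across monomers.
Free-monomer ensembles are clustered by 1D k-means on Rg
(k-means++, 10 restarts, fixed seed; k = 4 named compact / extended /
twisted / unfolded in ascending centroid order). Monomers inside
oligomers — too few per frame to cluster — are classified against
fixed boundaries at consecutive-centroid midpoints; boundary ties go
to the lower (more compact) class. Clustering is deliberately 1D:
secondary-structure features are out of scope, and Rg alone supports
the class definitions used.

Trajectory PCA builds the covariance of flattened coordinates, by
default one site per residue (geometric centre — uniform across
coarse and atomistic input), after Kabsch superposition of every frame
onto the first to remove rigid-body motion (`superpose=False` uses raw
coordinates and leaves frame alignment to the caller). Per-residue
contributions to the leading modes are eigenvalue-weighted squared
loadings summed over each residue's coordinates, normalized to 100%;
the default uses 2 components, matching the plotted landscape
dimensions. This squared-loading definition is an explicit design
choice — other dissections (e.g. per-mode without eigenvalue weights)
are linear variations the user can compute from the returned
eigenvectors.

## Synthetic data: what it does and does not show

The generators produce data with the *statistical or geometric*
structure each analysis assumes, plus serialized ground truth, and are
deterministic under a fixed seed:

- **CCS series** follow the growth law exactly up to multiplicative
  Gaussian noise (default conditions used in the recovery tests:
  σ = 1.28, Ω₀ = 439.7 Å², n = 2–16, 1% noise) with optional
  low-intensity satellite conformers at inflated CCS, emulating
  trailing minor species. They contain no charge-state physics.
- **Micelles** are radial bead chains (2.3 Å beads, 72 Da) on a
  near-uniform ellipsoidal shell, inner 60% of beads hydrophobic
  (normalized H = +1), outer beads hydrophilic (−1), with ≥3.5 Å
  separation between chains enforced by retry with shrinking angular
  jitter (inner radius 6 Å, bead spacing 3.8 Å — chosen so 14 chains
  pack at the minimum separation). They guarantee a hydrophobic core
  by construction; they are not energy-minimized and their shell of
  discrete chains is rougher than a real oligomer surface.
- **2D trajectories** are i.i.d. Gaussian-mixture samples shuffled
  into pseudo-time (test conditions: weights 0.7/0.3, component
  variance 0.15, 5×10⁴ points). They have no temporal correlation, so
  they validate density→energy recovery, not any kinetic property.
- **Assembly trajectories** are straight bead chains whose per-monomer
  Rg follows a prescribed drift exactly (collinear equal-mass chains
  have closed-form Rg), with fixed symmetric monomer offsets so frame
  mean and SD equal the spec. They validate bookkeeping and
  classification trends, not physics.

Passing tests on these fixtures shows the estimators recover known
structure under the stated noise; it does not certify behaviour on
real trajectories with correlated sampling, force-field artefacts, or
instrument-specific CCS calibration.

## Numerical conventions

Coordinates are Å throughout, energies kcal/mol, temperatures K.
Degenerate inputs fail loudly (empty structures, coplanar geometry for
hulls, fewer than 100 trajectory points, k exceeding distinct values)
rather than returning defaults. Seeds: every stochastic routine takes
an explicit integer seed and uses an isolated `numpy` Generator; no
global state. Problem sizes in the test suite (200 fit replicates, 20
landscape seeds, 10⁵ Monte-Carlo orientations, ≤60 bootstrap
replicates on ≤16k-point trajectories) were chosen as the smallest
sizes at which the estimators' statistical tolerances are comfortably
resolved.

## Known limitations

- No CCS computation from atomic structures (trajectory, projection
  approximation, or exact-hard-sphere methods) and no instrument
  calibration — the growth model consumes measured CCS tables.
- The SES approximation is grid-based; absolute areas depend on
  resolution and probe. Shape factors are comparative diagnostics.
- The 3D fuzzy-oil-drop formalism (full Gaussian ellipsoid with
  divergence statistics) is not implemented; only the 1D adaptation.
- Protonation thresholds (bridge cutoff, burial) are conventions; the
  tier ordering is exact, absolute site assignments on borderline
  geometries will track the thresholds.
- Landscape estimation assumes equilibrium-like sampling of the
  projected coordinates; populations from biased or annealed sampling
  yield surfaces whose differences must be interpreted with care.
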