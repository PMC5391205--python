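# Methods

`peldock` turns sparse pulsed-EPR (PELDOR/DEER) distance measurements into a
rigid-body model of a two-domain protein and cross-checks the result against
small-angle X-ray scattering. This note records the models, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Spin-label rotamer clouds

A nitroxide label (MTSL conjugated to an engineered cysteine) reports a
*cloud* of positions, not a point: five side-chain dihedrals separate the
nitroxide from the backbone. We grow an idealized label side chain
(CB–SG–SD–CE–ring, coarse bond lengths and angles) off the site's backbone
N/CA/C by internal-coordinate construction, over a discrete rotamer set of
three states per dihedral (gauche−/gauche+/trans, 3⁵ = 243 rotamers).
A sampled subset (default 64, seeded, without replacement) keeps docking
costs linear. Conformers with any side-chain heavy atom closer than 2.5 Å
to a host heavy atom outside the site residue are discarded; survivors are
Boltzmann-weighted at T = 298 K over a capped soft-sphere contact energy
(onset 3.5 Å, stiffness 15 kJ mol⁻¹ Å⁻², cap 40 kJ mol⁻¹), with a
uniform-weights mode for ablation. The reporter point is the N–O bond
midpoint. This is a deliberately coarse stand-in for molecular-dynamics
label ensembles: it reproduces the cloud's role (width, anisotropy,
surface-steering) without claiming rotamer populations are accurate.

The predicted inter-label distribution P(r) between two clouds is the
weighted histogram of all cross-pair distances on a 15–80 Å grid at 0.5 Å,
convolved with a 1.0 Å Gaussian and normalized to unit trapezoid integral.
The *modal distance* (global maximum; ties break to smaller r) is the
docking restraint, matching the practice of restraining on the most
prominent peak of each measured distribution.

## DEER forward model and inversion

The time trace of a doubly labelled molecule is modelled as
V(t) = [1 − λ + λ·(K P)(t)]·B(t), with modulation depth λ, a homogeneous
background B(t) = exp(−k t^(d/3)) (spin-bath dimension d defaults to 3,
the pure exponential of a three-dimensional solution; fractal d is
supported in the forward model while the background fit assumes d = 3),
and the powder-averaged dipolar
kernel K(t, r) = ∫₀¹ cos[(1 − 3x²) ω t] dx, ω = 2π·52.04 MHz nm³ / r³
(free-electron dipolar constant). The kernel is evaluated in closed form
with Fresnel integrals and verified against direct quadrature.

Background correction first fits ln V linearly on the tail
(t ≥ 0.25·t_max). Because slowly decaying long-distance modulation biases
a pure tail fit (badly so for r ≳ 45 Å at t_max = 3 µs), the estimate is
refined by separable optimization: a Nelder–Mead walk over (k, λ) in which
each trial inverts the implied form factor (non-negative Tikhonov at
α = 1) and scores the fully reconstructed trace. The objective adds the
squared fraction of probability mass in the top 10 % of the distance
window; a distribution pressed against the window edge is the signature
of background misassignment, and the penalty lifts the well-known
degeneracy between background decay and long distances. Fitted λ outside
[0, 1] is clamped with a warning; λ < 0.01 raises (no detectable
modulation).

Inversion solves min‖K P − F‖² + α²‖L P‖² with P ≥ 0 by NNLS on the
stacked system, L the second-difference operator on the 15–80 Å grid.
α is either fixed or chosen at the maximum-curvature corner of the
L-curve (log residual vs log roughness over a log-spaced candidate grid,
default 61 points in 10⁻³–10³; a flat curve falls back to the mid-range
candidate with a warning). `DeerInversion(trace).fit()` packages
background correction, α selection and inversion into a results object
with diagnostics.

## Restraint-driven rigid-body docking

The fixed domain defines the frame; a pose is a proper rotation plus
translation of the mobile domain. The score is
Σᵢ wᵢ((dᵢ − d_exp,ᵢ)/σᵢ)² plus a clash penalty (default 10 per CA–CA pair
closer than 4 Å), where σᵢ is the standard deviation of the measured
distribution. Three distance functionals are used where each is
appropriate:

- *centroid* — distance between cloud centroids; cheapest, used to rank
  the large random decoy pool;
- *linear average* — ⟨‖x_f − x_m‖⟩ over cross pairs, the rotamer analogue
  of NOE linear distance averaging, computed by an exact-covariance
  second-order expansion around the centroid separation (agrees with the
  exact weighted mean to < 0.01 Å and is smooth in the pose); centroid
  distances alone are systematically ~1 Å short for wide clouds;
- *modal* — mode of the full predicted cross-pair histogram (0.5 Å bins,
  1.0 Å smoothing, parabolic peak interpolation), the same estimator that
  defines d_exp; piecewise smooth, used for final scoring.

**Decoy engine.** 100,000 random poses (uniform rotations by the
quaternion construction; mobile centroid placed in d_exp ± 3σ shells
around randomly chosen fixed sites) are scored in centroid mode; decoys
are generated in 1,000-pose chunks under child seeds so pools are nested
in the seed. The best 200 are refined by Nelder–Mead over
(rotation-vector, translation) under modal scoring, two rounds with a
fresh simplex and a 5 % admixture of the smooth linear-average score to
break plateau ties of the piecewise-constant modal objective. Accepted
poses are those within the modal estimator's resolution (0.25 Å per
restraint, in score units) of the best refined score, with an absolute
2σ-per-restraint cap.

**Minimization engine.** 500 independent Powell minimizations of the
harmonic energy Σ wᵢ(dᵢ − d_exp,ᵢ)² (linear-average distances) from random
poses; solutions are accepted when every restraint is satisfied within 2σ
and the posed mobile body makes no CA contact below 4 Å.

Accepted poses are single-linkage clustered at 4 Å CA RMSD. More than one
cluster raises a degeneracy flag (mirror-related families arise when the
restraint sites are near-coplanar or the restraints are too few), and the
ensemble statistics — quaternion-averaged mean pose, mean pairwise CA RMSD
and mean CA RMSD to the mean pose — are computed over the primary cluster
(the one holding the best score) rather than averaged across families.
Cross-engine agreement is the CA RMSD between the two averaged models in
the fixed-domain frame, with no re-superposition. A residual table lists
d_exp against the modal distance predicted from the averaged model per
restraint, with the mean absolute residual as a summary row.

## SAXS cross-validation

Model curves use the Debye formula with one unit-weight scattering point
per CA — no hydration shell or excluded-volume term, so absolute χ²
values are not comparable with solvent-corrected fits (e.g. CRYSOL); the
module's role is relative ranking and low-q consistency. Guinier fits use
a two-pass window (fit the lowest-q quarter, shrink to q·Rg ≤ 1.3, refit;
≥ 5 points required) of ln I against q². χ² is the error-weighted,
scale-fitted reduced discrepancy with the closed-form optimal scale and
N − 1 normalization; the model is linearly interpolated onto the data
grid, and disjoint grids raise.

## Synthetic benchmarks

Ground-truth domains are three-helix bundles of ideal α-helical backbone
(φ = −57°, ψ = −47°, N/CA/C/O atoms; helices 11 Å apart, middle helix
antiparallel). The mobile domain is placed at a random orientation along a
random direction, stepped outward until heavy-atom clash-free at 3 Å plus
a 6 Å gap. Label sites are spread surface positions (greedy farthest-point
selection among CAs most distant from the domain centroid); 16 site pairs
(the measurement count the workflow is built around) are chosen to span
the accessible distance range, keeping every cross-pair distance inside
the 15–80 Å window. Each pair's ground-truth distribution at the true pose
defines d_exp (its mode, optionally jittered) and σ (its standard
deviation, floored at 1 Å), and a dipolar trace is simulated at the
default conditions: t_max = 3 µs, dt = 16 ns, λ = 0.35, k = 0.08 µs⁻¹,
noise σ = 0.01 — values chosen to resemble a typical Q-band data set on a
two-domain protein. An idealized Debye curve of the true complex
accompanies each benchmark. All generation is reproducible bitwise from
(manifest, seed).

What the benchmarks do not emulate: conformational exchange between
domain arrangements (the experimental reality that some site pairs give
multiple distributions), orientation selection, multi-spin effects,
experimental SAXS noise and buffer subtraction, and real side-chain
packing at labelling sites. Passing tests therefore demonstrate the
correctness and convergence of the *procedure* under its stated model,
not the accuracy of any experimental structure.

## Problem sizes and runtime choices

The acceptance script runs the full protocol (100,000 decoys / top-200
refinement; 500 minimizations) on three benchmark seeds, a few minutes
per seed on one core. The test suite runs the full protocol once and
scales the repeated studies down (e.g. 4,000-decoy pools in the 20-seed
parameter-recovery study, 25-candidate α grids) — the search problem and
all thresholds are unchanged, only the sampling effort; these sizes are
the package's default test configuration.

## Known limitations

- The rotamer library is geometric, not energetic; cloud widths are
  realistic but populations are approximate.
- The linear-average distance functional differs from the modal restraint
  for skewed or bimodal distributions, which biases the minimization
  engine's optimum by up to ~1 Å; the decoy engine's modal scoring does
  not share this bias, and the residual cross-engine disagreement this
  causes is part of what the cross-method RMSD reports.
- Tikhonov α selection by L-curve can over-smooth very narrow
  distributions; modal positions are robust, widths less so.
- The clash model is CA-only during docking (4 Å) and heavy-atom (3 Å)
  elsewhere; neither models side chains beyond the label.
- χ² values are not comparable to hydration-corrected predictions from
  atomistic SAXS programs.
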