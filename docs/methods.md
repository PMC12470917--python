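# Methods

## Model and assumptions

The package replaces a patient-specific mandible–plate FE model with a
prismatic segmental-defect surrogate that preserves the essential load
path: bending of a plated defect span between rigidly fixed ends. The
construct is a box of length `2·bone_block_length + defect_span` whose
cross-section is `section_width × section_height`. Both end blocks are
cortical bone and their outer faces are fully constrained (the
"condylar" boundary condition). Across the defect span the cross-section
is, from the top down: a solid Ti-6Al-4V face plate of thickness
`t_plate`, a homogenised lattice core of thickness `t_lat`, and graft
bone filling the rest. The plate runs `plate_overlap` onto each bone
block — deliberately stopping short of the fixed faces, because a plate
terminating in a rigid clamp creates a corner singularity whose peak
stress does not converge under refinement and which has no counterpart
in the real construct. Screws are bonded stiff element clusters tying
the plate into the bone blocks (two mirrored clusters per configured
axial offset, Ti properties, full bicortical depth); no contact or
friction is modelled, so the system `K u = F` is exactly linear — which
is also what the observed exact 2× response scaling between the 300 N
and 600 N load cases requires.

All materials are isotropic linear-elastic: Ti-6Al-4V (E = 110 GPa,
ν = 0.33, ρ = 4.43 g/cm³, σ_y = 880 MPa, σ_u = 950 MPa), cortical bone
(E = 13 GPa, ν = 0.30). The lattice region uses the effective modulus
from the calibrated porosity law with the titanium Poisson ratio.

### Porosity law

Four coupon measurements anchor the map from designed porosity to
effective modulus. The model form is the Gibson–Ashby open-cell law
`E_eff = C · E_s · (1 − p)^n`, fitted by least squares on
`log(E_eff/E_s)` versus `log(1 − p)` — the standard cellular-solids
model, linear in log space. `C` is left unconstrained rather than pinned
to `C = 1` at `p = 0`; the unconstrained fit agrees better with the
coupons, and predictions are clipped at `E_s`. The fit gives C = 0.883,
n = 2.233, log-scale R² = 0.9989, and reproduces every coupon within 2%.

The strut-to-porosity map uses a simple-cubic strut cell,
`ρ_rel = (3π/4)(d/a)²`, with the coefficient exposed on `LatticeCell` so
other topologies can be swapped in. Ratios `d/a > 0.5` are flagged
infeasible (struts merge); the DOE quality-control filter consumes the
flag. The map is a small-`d/a` scaling, adequate over the design grid's
ratio range 0.10–0.50.

## Finite elements

8-node trilinear hexahedra on a structured grid, full 2×2×2 Gauss
integration, no hourglass control needed. Grid planes are forced onto
every material interface and the load-patch boundary, so region volumes
partition the prism exactly and the patch area is
refinement-independent. The bite load is applied as consistent
(tributary-area) nodal forces over the patch, along −z by default; this
makes uniform-traction states exact (patch test to round-off, bar
solution to 1e−6). The constrained system is solved by sparse LU
(SuperLU, minimum-degree ordering); no iterative tolerance enters any
result.

Stress recovery evaluates the constitutive stress at the integration
points and volume-averages the tensor per element before taking the von
Mises invariant. The plate summary additionally averages von Mises
values over each (x, y) column of plate elements before the maximum is
taken — the thickness-averaging that suppresses mesh-sensitive local
peaks at screw/plate junctions.

Two numerical choices deserve emphasis:

* **Mesh density.** The canonical mesh is 36×4×8 divisions (fixed
  per-band stack: 3 graft / 3 lattice / 2 plate layers, ≈1150 elements),
  selected by the refine-until-<3% procedure: a 20% per-axis refinement
  changes the peak thickness-averaged plate stress by 2.1% at the
  canonical design. The same division counts are propagated to the whole
  sweep, which keeps one mesh topology (only node coordinates move with
  t_lat/t_plate) and hence smooth responses across the design grid.
  Extreme corners of the grid (d/a = 0.10, p ≈ 0.98, near-foam lattice)
  carry a larger discretisation error; the surrogate absorbs that as a
  consistent model bias — it learns the discrete operator — but absolute
  stresses there should not be over-interpreted.
* **Parity of the plate stack under refinement.** The thickness average
  samples an approximately |z|-shaped bending profile at element
  midpoints, which is exact for even stacks and biased ~10% low for odd
  ones. Refinement therefore keeps the plate band even (2 → 2 at factor
  1.2, 2 → 4 at factor 1.5 or 2.0) instead of applying a blind ceiling;
  without this, the convergence metric conflates a sampling-parity
  artifact with genuine discretisation error.

## Design of experiments

The canonical corpus is the full factorial
6(d) × 5(a) × 4(t_lat) × 2(t_plate) × 2(P) = 480 runs; 16 rows
(d = 1.15 mm, a = 2.0 mm) violate the d/a cap and are dropped by QC,
leaving 464. A seeded Latin-hypercube generator (scipy `qmc`) is
available for continuous exploration and accepts extra variables. The
sweep exploits problem structure: designs sharing (t_lat, t_plate) share
a mesh; lattice/bone moduli scale their region stiffness matrices
linearly, so each design's K is a linear combination of three
pre-assembled matrices; both load levels reuse one factorisation. Every
reported row is still an exact FE solve of its own system.

## Surrogate

Multi-output MLP (5 inputs → 64–32–16 ReLU → 3 linear outputs), He
initialisation, dropout 0.10 after the first two hidden layers, L2
weight decay 1e−4, Adam (lr 1e−3, β₁ 0.9, β₂ 0.999, ε 1e−8), batch 64,
Huber loss (δ = 1.0, on z-scored targets so δ acts on a common scale;
MSE by switch), early stopping on validation MAE with patience 80 inside
a 2000-epoch cap and best-checkpoint restore. This default configuration
is the selected one; `random_search` offers a seeded random sweep over
depth/width/learning-rate/decay/dropout/batch ranges for users who want
to re-tune (sequential Bayesian tuning is deliberately out of scope).
Implemented in numpy:
the network is tiny, a framework buys nothing, and the closed
implementation keeps training bit-reproducible under one seed.

The 70/15/15 split is stratified over the joint levels of
(P, t_plate, t_lat); strata below 3 rows are pooled before allocation,
and rounding remainders go to the split with the largest global deficit,
so per-stratum and global proportions both hold to within one row.
Inputs (and internally targets) are z-scored with training-split
statistics only; the residual model's σ is the untouched-test RMSE per
output. On the canonical sweep the surrogate reaches held-out R² ≈ 0.99
and MAE 3–5% of the target means, comfortably beyond the acceptance
bands (R² ≥ 0.962 for plate stress, MAE ≤ 6%), because the underlying
map is smooth and exactly linear in P.

## Uncertainty and risk

The input-uncertainty graph has three root nodes — bone-modulus scale,
bite-force scale, porosity offset — whose children are the three
outputs; each output also receives its Gaussian residual. "±x%" scatter
is read as a uniform multiplicative factor on [1−x, 1+x] (bounded,
assumption-light); a normal family with ±x% as a 95% interval is
available per node. The graph has no observed nodes to condition on, so
forward Monte-Carlo sampling of the factorised joint is the operative
computation (10 000 samples by default; binomial standard errors
reported).

Bone-modulus scatter cannot travel through the five canonical surrogate
inputs, so risk uses an augmented six-input surrogate trained on the
factorial × bone-modulus levels {0.8, 1.0, 1.2} with the load axis
extended to {300, 450, 600, 780} N — the ±30% bite scatter around the
600 N worst case reaches 780 N and must stay inside the training hull.
Porosity scatter is folded into an equivalent strut diameter by
inverting the density map at the perturbed porosity, so it too flows
through the net's own inputs. An out-of-hull sample counter reports
extrapolation.

Thresholds: σ_allow = 0.9·σ_y = 792 MPa, displacement limit 1 mm, risk
cap 3% — all configurable. During the GA search the constraint is
applied to the one-sided 95% upper confidence bound (p̂ + 1.645·SE at
2000 common-random-number samples), so finite-sample search noise cannot
admit a design whose true risk sits above the cap; the final archive is
re-audited member-by-member with a fresh seed at 10 000 samples.

## Optimisation

NSGA-II-style loop (binary tournament on constraint-dominated rank and
crowding distance, simulated binary crossover η = 15, polynomial
mutation η = 20, p = 1/n_var), population 48 for 40 generations over the
continuous hull of the factorial levels, load fixed at 600 N. Objectives:
implant mass (plate + screws + lattice scaled by 1−p, from meshed region
volumes), peak plate stress from the surrogate, and the fatigue margin
340/σ_vM,max. Geometric infeasibility (d/a cap) and risk-cap violations
are handled by Deb constraint domination. The returned archive is the
non-dominated subset of every feasible candidate evaluated anywhere in
the run, so a larger budget can only improve it; a brute-force pairwise
Pareto extractor serves as the independent test oracle.

The "optimisation-efficiency" index scores each design as
`w_mass·minmax(mass saving vs the solid-plate baseline) +
w_stiff·minmax(−|E_construct − 13 GPa|)` with default weights 0.5/0.5;
`E_construct` converts load-point compliance to a uniaxial-equivalent
modulus `P·span/(A·δ_max)`. Min–max normalisation over the evaluated set
forces best = 1.00 and worst = 0 by construction; a porosity-decade
binned table summarises the landscape.

## Pipeline and reproducibility

Stage seeds derive from the global seed via
`SeedSequence(seed, spawn_key=(stage_index,))`, truncated below 2³¹, so
any stage reruns in isolation and a full rerun is byte-identical
(fixed CSV float format, sorted JSON keys). Logs record the config hash,
stage seeds, dataset and QC counts, and all thresholds.

## What the synthetic benchmark does and does not show

The generator emulates: the load path of a plated segmental defect, the
porosity→stiffness→response chain, the factorial design grid, the
stated scatter magnitudes, and the scale-free structural claims (exact
load linearity, <3% mesh sensitivity, surrogate fidelity bands, the
risk cap). It does not emulate: anatomical curvature or patient CT
geometry, contact/friction at interfaces, plasticity, fatigue-cycle
damage, bone remodelling, or the absolute stress/displacement magnitudes
of a real mandible (those depend on geometry we deliberately replaced).
Passing tests therefore validate the method chain — solver correctness,
training hygiene, probabilistic bookkeeping, constraint handling — not
the clinical safety of any specific implant.

## Problem sizes

Canonical runs use: 480-point factorial (464 after QC) at the 36×4×8
mesh; augmented risk corpus 6×5×4×2×4×3 = 2880 runs (2784 after QC);
10 000 Monte-Carlo samples per risk report (2000 during the GA search);
GA 48×40. A full pipeline run completes in a few minutes on one CPU.

## Known limitations

* The simple-cubic strut density map is a stand-in for the graded
  gyroid of a real implant; only its monotone (d/a)² scaling matters to
  the loop's logic.
* Uncertainty inputs are independent; correlated bone/force scatter is
  not modelled.
* The screw summary reports a region-max stress in bonded stiff
  clusters; thread-level mechanics, preload and pull-out are out of
  scope.
* Plate-stress convergence is verified at the canonical design, not at
  every factorial corner; near-foam corners carry larger discretisation
  bias (see above).
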