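# Methods

`unbend` studies force-induced unbending of a bent, two-chain multidomain
molecule — the integrin αVβ3 ectodomain is the motivating case — with
three ingredients: (i) pulling protocols (constant-velocity spring,
constant force, free dynamics) applied to a coarse-grained bent model,
(ii) trajectory metrics that characterize the unbending pathway (buried
solvent-accessible surface area of the headpiece–tailpiece interface,
geometric hydrogen bonds, inter-domain hinge angles, head–tail
extension), and (iii) Bell-model kinetics connecting constant-force
waiting times to an activation barrier.

## The two-state kinetic model

Unbending under constant force is treated as thermally activated escape
over a single barrier.  The Bell model gives the mean waiting time

  t(F) = t0 · exp(−F·Δx / kB·T)

with t0 the zero-force waiting time and Δx the width of the energy well
trapping the bent state.  `fit_bell` regresses ln t on F by ordinary
least squares, so Δx = −slope·kB·T and t0 = exp(intercept); standard
errors come from the regression covariance, with the delta method for
t0.  All fits use kB = 0.0138065 pN·nm/K, i.e. kB·T = 41.4195 pN·Å at
300 K.

Fitting a single sampled waiting time per force biases t0 low by the
factor e^(−γ_Euler) ≈ 0.561, because E[ln t] = ln τ − γ for an
exponential variable.  The recovery experiments therefore fit ln(mean
waiting time) per force; a dedicated test demonstrates the bias of the
single-sample variant.

The parameter-recovery experiment (`cmd_recover`, and the acceptance
script) uses the five-force design 97, 122, 146, 170 and 195 pN at
300 K with t0 = 728 ns and Δx = 1.2 Å as simulation truth, 100
exponential waiting times per force, and 200 replicate fits.  The fifth
force level between 146 and 195 pN is not uniquely determined by the
published design ("five forces from 97–195 pN"); the shipped grid uses
170 pN, the midpoint.

## The coarse-grained bent molecule

The synthetic model (`build_bent_model`) is a pseudo-atomic stand-in
for an integrin-like ectodomain: twelve domains of twelve beads each
(144 beads), two chains.  Chain A (the α-subunit analog) is
β-propeller — thigh — calf-1 — calf-2 with long 70 Å inter-domain
spacing so that its three links match the extended contour of the
seven-link β-chain; chain B (the β-subunit analog) is the
PSI/hybrid/βA head plus the EGF1–EGF4/βTD leg at 30 Å spacing.  The
bent conformation is a planar hairpin: the β-leg rises from the βTD
anchor, the β-knee (EGF1/EGF2 region) folds the arm back down, and the
hybrid domain wedges against βTD and EGF4.  The built head–tail
distance (βA pull group to βTD anchor group) is ≈ 45 Å; full extension
reaches ≈ 185–230 Å depending on tension.

Energy terms, all with equilibria set to the as-built geometry so the
built structure is an exact mechanical equilibrium:

* **Intra-domain springs** — all bead pairs within a domain
  (k = 20 pN/Å), keeping each domain rigid-ish.
* **Pin joints** — each backbone link is articulated by two coincident
  bead pairs (zero-rest springs, k = 250 pN/Å) placed at the parent
  domain's center ± 3 Å along the hinge axis (the normal of the bending
  plane).  Zero-rest springs are isotropically stiff, so a joint bends
  freely about the pin axis while twist and rocking are suppressed, and
  bending preserves every center–center distance.  The head-region
  links (βA–hybrid, hybrid–PSI) and the two inter-chain couplings use
  plain nearest-bead springs (k = 200 pN/Å) plus cosine torsion
  restraints.
* **Bending angles** on domain-center triplets.  The knees carry
  double-well potentials U(θ) = ε·[(θ−θ_bent)(θ−180°)]²/Δ⁴ with one
  well at the built bent angle and one at 180°, which makes the
  molecule bistable: ε = 350 pN·Å for the β-knee and 600 pN·Å for the
  α-genu (the higher α barrier keeps the genu closed until the
  interface ruptures, so both knees then open together under the shared
  tension).  All other vertices are harmonic singles
  (k = 2000 pN·Å/rad²; the built hairpin shape, including the tucked
  head, is their equilibrium).
* **Twist and planarity restraints** — cosine dihedral restraints
  (400 pN·Å) on the unpinned links and on well-bent domain-center
  quadruplets stop the folded arm from precessing out of the bending
  plane; near-collinear quadruplets exert no torque (the twist is
  undefined there), with a guard at sin ≈ 0.2.
* **Leg–leg zip springs** (k = 60 pN/Å) — the "closed legs" contacts:
  the lower-leg pairs calf-1↔EGF2/EGF3/EGF4 and calf-2↔EGF3/EGF4 keep
  the same separation in the bent and the extended state and are plain
  springs; thigh↔EGF1 comes closer on extension and is a stretch-only
  tether.  Zipping the lower legs closes the kinematic loop
  (lower legs — α upper leg — head — β arm), which is what makes the
  two knees open concurrently, mirroring the observed hinge
  cooperativity.
* **Breakable interface contacts** — truncated harmonic wells between
  annotated beads: four polar contacts (donor + hydrogen stalk beads on
  hybrid facing acceptor beads on βTD, built at the 3.0 Å rest length
  so they satisfy the H-bond criterion) with ε = 200 pN·Å each, and
  three hydrophobic contacts (flagged beads on hybrid facing EGF4) with
  ε = 140 pN·Å.  A contact exerts force only within the 8 Å
  capture/break radius and is stateless: re-entering the radius
  re-engages it, which is what lets the hydrophobic cluster re-form
  during rebending.

The α-genu marker beads (an acidic-sidechain analog on the thigh and an
ion analog on calf-1, ≈ 14 Å apart in the bent state) exist so the
shipped `genu_ion_D457` distance metric is defined on the synthetic
model; at this resolution their separation does not reproduce the
coordination-formation drop seen in the real molecule on extension, and
the contact-event detector is exercised on the hydrophobic-cluster
recontact and on constructed traces instead.

## Dynamics

Overdamped Langevin (Euler–Maruyama): per bead and step,
dx = (F/γ)·dt + sqrt(2·kB·T·dt/γ)·ξ with γ = 1 pN·ns/Å, dt = 2 ps and
T = 300 K by default.  A conservative per-bead stiffness estimate
enforces dt < 2γ/k_max at start, and any step moving a bead more than
5 Å aborts the run with a diagnostic.  One `numpy` `Generator` seeded
per run makes trajectories bit-reproducible.  Forces are evaluated in a
single compiled (numba) kernel.

Pulling follows the steered-MD conventions: force acts on the COM of
the pulled Cα-analog group (distributed equally over the beads) along a
unit vector fixed at t = 0 from the constraint COM to the pull COM
(a tracking mode is available); the constraint COM is tethered by a
10 kcal mol⁻¹ Å⁻² (694.8 pN/Å) harmonic spring.  Constant-velocity
mode applies F = k(vt−x) with k = 0.5 kcal mol⁻¹ Å⁻² (34.7 pN/Å) and
v = 2 Å/ns by default; x is the pull-COM displacement along the
pulling direction.  The synthetic molecule is geometrically smaller
than a real ectodomain, and its force and time scales are its own: the
pipeline mirrors protocol and analysis shapes, not absolute
nanometer/nanosecond values.  Config files accept kcal mol⁻¹ Å⁻² and
nm ns⁻¹ with the conversions 1 kcal mol⁻¹ Å⁻¹ = 69.479 pN and
1 nm ns⁻¹ = 10 Å/ns.

## Analysis conventions

* **SASA** — Shrake–Rupley with a 1.4 Å probe and a deterministic
  960-point golden-spiral quadrature per atom (bit-stable outputs).
  vdW radii: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, pseudo-bead
  1.80 Å.  Buried SASA of part A against B is SASA(A alone) −
  SASA(A with B); restricting the per-atom sum to one domain gives that
  domain's share.  Absolute areas depend on the radius set and point
  count, so comparisons are made on the package's own scale.
* **H-bonds** — strictly geometric: donor–acceptor distance < 3.5 Å
  and donor–hydrogen–acceptor angle > 120°, both strict inequalities;
  at most one bond per (donor, acceptor) pair, so bifurcated
  geometries count once; counts between groups are direction-agnostic.
* **Hinge angles** — the frame is Kabsch-superposed onto the reference
  using side A, and the residual best-fit rotation of side B gives the
  angle arccos((tr R − 1)/2); the rotation axis is reported for
  inspection.  Each side of a shipped hinge pair is a whole leg segment
  (two domains) rather than a single domain: the coarse beads leave
  individual domains some orientational slack and the elongated
  segments pin the fitted orientation to the backbone geometry.
  Angles are reported as changes from the reference frame; an additive
  offset supports absolute inter-domain angles.
* **Cooperativity** — hinge series are smoothed by a 25-frame (≈ 5 ns)
  centered rolling mean, then the EGF1/EGF2 and EGF2/EGF3 angles are
  regressed on the thigh/calf-1 angle over the pre-straightening
  window, which ends when either hinge first exceeds 95% of its final
  plateau (after one hinge completes, the relation leaves the linear
  regime).
* **Waiting times** — the baseline is the mean head–tail distance over
  the first 5 ns; the waiting time is the first time the trace exceeds
  baseline + 20 Å and stays above for ≥ 1 ns.  The published onset
  marks carry no stated rule, so these defaults are the package's own.
  Per-force run caps (500 ns at 97 pN down to 120 ns at 195 pN) keep
  the constant-force suite at desk scale; a run that never escapes
  enters the per-force median as +inf.
* **Force peaks** — local maxima of the force–extension curve after a
  centered moving average in the extension domain (4 Å window in the
  pipeline), ranked by topographic prominence; the rank-1 peak is the
  major peak.  The coincidence check asks whether the major peak's time
  falls inside the window over which the smoothed hybrid buried-SASA
  series makes its 85%→15% drop.

## What the generator does and does not emulate

It reproduces the qualitative mechanics of forced unbending: a bent
metastable state held by a breakable polar + hydrophobic interface
whose rupture produces the dominant force peak coinciding with the
buried-SASA drop; concurrent opening of the two knees; thermally
activated escape whose waiting time shortens with force in Bell-like
fashion; rebending of partially extended states with hydrophobic
recontact; and metastability of the fully extended state.  It does not
emulate atomistic detail: no solvent, electrostatics or sterics, no
sequence, absolute areas/forces/times on their own scale, a planar
bent geometry, and interface contacts that re-engage without
hysteresis.  Passing tests therefore demonstrate that the analysis
stack measures these phenomena correctly, not that the model predicts
real integrin energetics.

## Numerical and design choices

* Deterministic golden-spiral SASA quadrature rather than random
  sampling, so areas are bit-stable; quadrature error is ≈ 1% at 960
  points on fixture models.
* COM weighting is uniform over selected pseudo-atoms (coarse beads
  have no meaningful masses); mass weighting is available.
* RMSD defaults to least-squares superposition (the usual Cα-RMSD
  convention).
* Trace-based arccos inputs are clamped to [−1, 1]; degenerate
  (collinear) Kabsch inputs raise.
* The double-well gradient is polynomial in θ and exactly zero at both
  wells, so the built geometry exerts no force.
* Problem sizes used by the shipped suites: 100 ns constant-velocity
  pulls at 2 Å/ns; five forces × five seeds with 120–500 ns caps for
  the constant-force ladder; six 60 ns free relaxations per snapshot
  kind; 200 replicates × 100 samples/force for parameter recovery.

## Known limitations

The hinge-angle signal carries ≈ 10–20° of orientational wobble even
with pin joints, which is why the cooperativity analysis smooths
before regressing.  The genu marker distance is flat under extension
(above).  The constant-force ladder's low-force medians (97 pN) have
wide seed-to-seed spread, as expected for medians of five exponential
samples.  Real PDB input is supported through the same analysis stack,
but the chemical H-bond annotation heuristic (N/O donors/acceptors,
nearest hydrogen within 1.2 Å) is minimal.
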