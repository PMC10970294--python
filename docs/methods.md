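# Methods

`ringscape` analyses the continuous conformational variability of a
six-fold ring complex from an ensemble of per-particle Cα models — the kind
of output produced when an atomic structure is flexibly fitted to every
particle image of a cryo-EM data set.  The motivating system is the AAA+
ATPase p97: a C6 double ring of D1 and D2 ATPase domains with six flexible
N-terminal domains at the periphery, whose swinging motion averages out of
conventional reconstructions.  Because no public per-particle model set
exists for such a system, the package pairs the analysis pipeline with a
procedural stand-in complex and a seeded ensemble generator, so that every
stage can be validated by parameter recovery against planted ground truth.

## The toy complex

`toy_complex.build_template` constructs a C6-symmetric Cα model from three
atom blobs per protomer (N, D1, D2; deterministic golden-angle ball of 30
atoms each by default).  Geometry defaults (Å): ring radius 40, D1–D2 axial
spacing 25, N-domain lever arm 25, core blob radius 18, N blob radius 16.
These reproduce the length scales that matter for the physics of the
analysis: a rigid two-ring core and peripheral domains on long lever arms,
so that a modest hinge rotation produces large Cartesian displacements and
a characteristic RMSF contrast between N-domains and core.  Monomers 1–5
are exact 60° rotations of monomer 0, making the C6 invariant hold to float
round-off.

Each protomer has a hinge at the N–D1 junction whose axis is tangential to
the ring, so a positive swing lifts the N-domain along the symmetry axis,
away from the D2 ring.  The stored template keeps the N-domain raised 75°
above the coplanar (in-D1-plane) orientation — the up-conformation of the
real complex — and `swing_n_domain` applies rigid rotations about the hinge
on top of that.  `apply_ring_split` turns the closed ring into a
split-washer: monomer *m* rises by *m*·rise (default 5 Å) and rotates by
−*m*·gap/6 (default gap 30°), opening a seam between monomers 5 and 0, the
geometry adopted by substrate-engaged AAA+ rings.

An anisotropic elastic network (`enm_hessian` / `enm_modes`) provides
normal modes of any Cα cloud: pairwise harmonic springs inside a distance
cutoff, dense symmetric PSD Hessian, `eigh` spectrum, rigid-body null space
removed by a relative tolerance (1e-8).  The default cutoff is 16 Å: the
toy blobs sample a ~30 kDa domain with 30 atoms, giving a nearest-neighbour
spacing of ~8–10 Å, and 16 Å keeps the same cutoff-to-spacing ratio (~1.5×)
that residue-level Cα networks use with their conventional 12 Å.  At 12 Å
the toy network is disconnected; sparser toy templates can also be
connected yet floppy (mechanism modes beyond the six rigid-body modes), so
the exactly-six-zero-modes property is guaranteed only at the default
sampling density.  Five modes are returned by default, matching common
practice for normal-mode-guided flexible fitting.

## The ensemble generator

`ensemble_sim.sample_ensemble` draws, per particle: a cluster assignment
(split-ring with probability `split_fraction`, default 0.02), six N-domain
swing angles, optional ring-split deformation, isotropic Gaussian
coordinate noise, a random global pose, and a random six-fold ring
register.  The seed expands into five independent sub-streams (cluster,
angles, noise, pose, register), so runs are bitwise reproducible and
toggling one stage leaves the others' draws unchanged.

Angles are marginally uniform on (−30°, +30°) about the up-position.  The
flat, half-circle-shaped monomer landscape this produces is the reading of
the source data this package targets; the distribution is pluggable via
`sample_correlated_angles` if a different prior is wanted.  Ring coupling
uses a Gaussian copula on the 6-cycle with correlation ρ^d(i,j) (d = ring
distance, circulant and positive definite for ρ ∈ [0,1)): a single knob
that moves neighbouring N-domains toward similar positions while leaving
every marginal exactly uniform.  The default is ρ = 0 (independent
domains); coordination is a hypothesis to test, not a baked-in assumption.

Other defaults, chosen once as realistic study conditions: noise 0.25 Å per
coordinate (per-particle fitting jitter, small against the 2–15 Å
conformational displacements, so hinge-angle measurement error stays ~0.2°,
far below the 20° region width); pose translations uniform in ±5 Å with
uniform random rotations; register uniform over 0..5, applied as block
relabelling plus the compensating −60°·r rotation.  Register randomization
is deliberately ON by default: for the C6-symmetric main population it is
exactly invisible (a cyclic permutation of the planted angles), while for
the split population it reproduces the register ambiguity that complicates
the hexamer-level landscape of real partially symmetric particles.

What the generator does **not** emulate: image formation (projection, CTF,
image noise), fitting failures, model bias from the fitting reference, or
correlations between pose accuracy and conformation.  Passing recovery
tests therefore demonstrates that the analysis correctly inverts its own
generative model at realistic geometry and noise scales — not that any
particular experimental data set would behave as cleanly.

## Superposition

`superpose.kabsch` is the SVD least-squares fit restricted to proper
rotations (protein chirality; reflections are never considered), with
masked-atom support and degeneracy checks (≥3 atoms, non-collinear).  The
default frame for both hexamers and monomers is the D1+D2 core, excluding
the N-domains, so that domain motion is measured rather than absorbed into
the pose; an all-atom option exists.  `canonicalize_register` resolves the
six-fold relabelling ambiguity by brute force over the six cyclic rotations
(ties to the smallest shift); it is OFF in the default hexamer pipeline —
against a C6-symmetric reference the six candidates are degenerate for the
main population, and keeping it off preserves the register-ambiguity
artifact the landscape stage has to cope with.  `split_monomers` /
`regroup_monomers` are exact bookkeeping inverses.

## Landscape and free energy

Aligned conformers are flattened and embedded with PCA by default
(deterministic, order-invariant up to component sign) or UMAP behind the
same interface (seed-pinned, hyperparameters recorded); both default to 10
dimensions.  Point density converts to free energy by Boltzmann inversion,
ΔG/k_BT = −ln(n/n₀), with n₀ the most populated 2-D bin; energies are
reported only in k_BT units (temperature never materializes) and empty bins
are masked rather than set to infinity, so no arithmetic path ever sees
ΔG = ∞.  Interactive density picking is replaced by scriptable axis-aligned
region bounds plus a local-maxima peak suggester on the 2-D histogram.

**Major/minor partition.**  A minority population that differs from the
consensus by a global core deformation is smeared over symmetry-related
directions when the register is unresolved: its centroid coincides with the
main mode and 2-means or mixture-posterior clustering systematically
under-counts it (part of the scatter also falls outside any 10-component
linear basis).  `two_cluster_partition` therefore scores each particle by
robust Mahalanobis distance — minimum-covariance-determinant fit over the
embedding coordinates augmented with the PCA reconstruction-residual norm
(the Q-statistic of multivariate monitoring) — and flags particles beyond
the Bonferroni-corrected χ² quantile (0.01 expected false positives per
run).  The landscape is declared two-clustered only when at least
max(5, 0.1 %·N) particles are flagged.  On default synthetic ensembles the
flagged population sits 2–3 orders of magnitude beyond the threshold, and
the recovered minor fraction tracks the planted binomial draw.

## Monomer states and ring combinatorics

Hinge angles are measured after core alignment as the signed angle of the
hinge→N-centroid vector about the hinge axis, relative either to the
template up-orientation (swing angle) or to the coplanar orientation
(absolute rotation; the template itself reads 75°).  The monomer landscape
(or the angle axis directly) is discretized into K contiguous regions of
equal particle count (K = 3 default, display labels −20°/0°/+20° — names
for tertile indices, not measured angles); region sizes differ by at most
one, earlier regions absorb the remainder, and ties break by input order.
The first landscape component is sign-oriented by its correlation with the
measured hinge angle so region order always runs downward → upward.

Per-particle label six-tuples are identified up to cyclic rotation
(lexicographically smallest rotation; C6 only — the ring is chiral, so
reflections are excluded), collapsing 3⁶ = 729 ordered tuples to 130
classes; `enumerate_states` counts by exhaustive canonicalization and
asserts the closed-form necklace count (1/6)Σ_{d|6} φ(d)K^{6/d} as a
cross-check.  State histograms report counts per canonical class;
adjacency statistics report the longest equal-label run on the cycle
(with wraparound) and the fraction of hexamers with ≥5 domains in the same
state — under independent uniform labels exactly 39/729 ≈ 5.35 %, so any
excess is evidence of coordination.  Observed and theoretical state counts
are always reported separately.

## Orchestration and problem sizes

`workflow.RunConfig` serializes a complete run (template geometry, ensemble
spec, alignment/embedding/discretization options); each stage writes its
tables plus a manifest (config hash, seed, library versions) under one run
directory, and the `ringscape` CLI (`simulate`, `analyze`, `states`,
`report`) wraps the same functions.  The default test-suite problem sizes —
3,000-particle shared fixture, 20,000 particles for cluster recovery,
120,000 monomers for angle statistics, 300,000 draws for the tertile
boundaries — were chosen so every statistical assertion has comfortable
Monte-Carlo margins while the whole suite stays interactive (about a
minute); the acceptance script uses the same sizes.

## Known limitations

- The toy template is not the real complex: domain shapes, contact
  topology and mass distribution are idealized, so ENM spectra and RMSF
  magnitudes are qualitative.
- PCA treats the swing arc linearly; the arc's curvature lands in the
  reconstruction residual.  This is exploited by the partition but means
  component-1 coordinates are only monotonically, not linearly, related to
  the hinge angle.
- The register ambiguity is modelled but not resolved; canonicalization
  against a symmetric reference is degenerate by construction, and a
  second-stage canonicalization against an asymmetric (e.g. split-cluster
  mean) reference is left to the caller.
- `enumerate_states` is exhaustive (K^6 tuples) and practical only for the
  small K this analysis uses.
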