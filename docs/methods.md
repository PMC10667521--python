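# Methods

This note documents the models and numerical choices behind `condmix`:
what is simulated, what the analysis statistics mean, what the synthetic
data do and do not emulate, and where the design was genuinely open.

## Lattice sticker-spacer model

Polymers live on a simple cubic lattice with periodic boundaries; each
bead occupies one site (strict excluded volume) and consecutive beads are
joined by implicit linkers of length two lattice units (Euclidean
distance <= 2, i.e. squared distance <= 4, giving 32 legal relative
placements).  Every bead is a sticker of one of three classes: the
protein sticker (class `whi3`) or one of two RNA-mimic stickers (`rna1`,
`rna2`).  The reference three-component design uses 3-bead protein
trimers and 8-bead RNA octamers; at full scale 5000/1000/1000 molecules
on an L = 100 lattice, at desk scale 200/40/40 on L = 40.

Interactions split into two channels, both parameterized by symmetric
3x3 matrices in units of k_B T* (T* = 1):

* **Anisotropic (bonding)**: realized as explicit, mutually exclusive
  one-to-one bonds between stickers within the contact radius sqrt(3)
  (the 26-site neighborhood).  A bead holds at most one bond; a bond
  contributes the matrix energy regardless of exact distance while it
  remains within range.  The base case sets the protein-RNA entries to
  eps = -2 and everything else to zero; the homotypic-scaling model adds
  RNA-RNA self-attraction h*eps; the asymmetric model scales the
  protein-RNA1 entry by a.
* **Isotropic (contact)**: summed over all occupied neighbor pairs
  within the contact radius, bonded or not.  The repulsion model sets the
  RNA1-RNA2 entry to s*eps_rep with eps_rep = 0.04 ~ 1/26 k_B T*, so
  that a bead fully surrounded by the other RNA pays about s k_B T*.

### Move set and acceptance

The elementary move set (relative default weights in parentheses):
single-bead local displacement to one of the 26 neighbor sites (40),
end-bead pivot to a random linker-legal site (10), slithering-snake
reptation (15), whole-chain translation by a unit offset (15),
translation of a bond-connected molecule cluster (10), and explicit bond
make/break proposals (10).  The published engine's exact move frequencies
live in supplementary material not available here; these defaults form a
standard ergodic lattice-polymer set and are fully configurable.

Acceptance is Metropolis, min(1, exp(-dE/T)).  Two technical points:

* Bond make and break proposals have asymmetric proposal probabilities (a
  make picks one of n eligible neighbors; a break is proposed from either
  bond partner), so both directions carry the exact Metropolis-Hastings
  proposal-ratio correction computed from the candidate counts of both
  partners.
* Cluster translations are accepted only when the cluster has no
  isotropic contacts with external beads before or after the move; the
  cluster composition is then identical in the reverse move and detailed
  balance holds without energy bookkeeping.

Moves that would stretch an existing bond beyond the contact radius, or a
linker beyond reach, are rejected outright; reptation is proposed only
for bond-free chains.  Correctness of the whole kernel is checked against
exact Boltzmann weights on a fully enumerable two-bead system (L = 4, one
protein bead, one RNA bead, bond energy -2 plus a 0.3 contact term; 89
distinguishable relative states): a chi-square test across all states at
about 1.1 million sweeps with 100-sweep thinning (thinning keeps the
samples effectively independent so the test's null distribution applies)
gives p between 0.3 and 0.98 across seeds.

### Protocol

A run has three phases, following the reference designs: (1) t_EQ steps
at T_EQ (10 T* for ternary runs, 100 T* for two-component phase-diagram
runs) with anisotropic interactions off and a constraining potential
pushing all beads toward the box center — V(r, T) = T H(r - R_B) r^2
with H(0) = 0 (ternary; R_B = 35 at full scale, 14 at desk scale) or
V(r, T) = (T - T0) r^2 (two-component); r is the unwrapped distance of a
bead from the geometric box center.  (2) Annealing with interactions on:
T(t) = T0 + T_EQ exp(-4 t / t_EQ) until the decay term falls below
0.005, at which point T is clamped to T0 and the constraint switched off
(the crossing is rounded up to the next sampling interval).  (3)
Production at T0.  Samples are taken every f_data steps and kept only
from the last half of the annealing+production window, giving exactly
(t_total/2)/f_data samples (2000 for the full ternary schedule, 1000 for
the two-component schedule).  An "MC step" is one elementary move
attempt.  Replicate r runs with seed `rng_seed + r`.

The kernel tracks the interaction energy incrementally; every test and
the protocol itself verify agreement with a from-scratch recomputation to
1e-9 k_B T*.  The constraint energy is recomputed at sampling times
(it depends on the instantaneous temperature during annealing).

Desk-scale presets (L = 40, 280 molecules, t_EQ = 1e5, t_total = 2e6,
f_data = 2.5e4, 40 samples) complete in seconds and reproduce the
qualitative physics: condensates form, the base case co-enriches both
RNA mimics at the condensate center (Hellinger score D_12 ~ 0.3-0.45),
and the s = 10 isotropic repulsion raises D_12 to ~0.55-0.6 in every
seed tested.  They are facsimiles, not replicas: full-scale runs are four
orders of magnitude longer and their quantitative binodals and profiles
are out of reach on a desk machine.

## Density profiles and the demixing score

The radial profile about a chosen center is rho(r_n) = H(r_n)/H0(r_n),
bin width 0.25 lattice units from r = 0 to sqrt(3) L/2, distances under
the minimum-image convention.  H0 — the number of lattice sites per bin —
is enumerated explicitly for the actual (generally fractional) center and
sums to exactly L^3; bins with H0 = 0 are flagged undefined and dropped
from normalization sums.  Coexisting densities average rho over the first
13 bins (dense phase) and over a 20-bin window ending 15 bins before the
last bin (dilute phase); both windows are arguments, since their defaults
were chosen for L = 100 boxes.

Cluster centers use connectivity at the interaction range (26-site
neighborhood; the underlying definition of "cluster" is not fixed by the
physics, so the interaction range is the natural choice) with ties broken
toward the cluster holding the lowest bead index.  Cluster COMs unwrap
beads by minimum-image displacement from a reference bead before
averaging, which is exact for any cluster of diameter below L/2; the
whole-system COM uses the per-axis circular mean, which is the standard
estimator when no unwrapping exists.

Demixing between components i and j is the Hellinger distance between
their unit-normalized radial profiles about component i's largest-cluster
COM: D_ij = sqrt(1 - BC), BC = sum_n sqrt(rho~_ii rho~_ij).  Profiles
are averaged across samples before computing D (per-sample scores are
available by passing single samples).  D is symmetric in its arguments,
bounded in [0, 1], zero for identical profiles and one for disjoint ones.

## Apparent sticker valence from phase boundaries

Inputs are labeled concentration points: two-phase (P) points near the
lower boundary of the two-phase regime and one-phase (N) points beyond
it, protein on x, RNA on y.  Under the null hypothesis that heterotypic
sticker interactions dominate, rescaling the RNA axis by the true sticker
valence s makes the dilute arm symmetric about the diagonal; the scan
seeks the s that maximizes that symmetry.

The objective is evaluated in log-concentration coordinates, where the
rescaling y -> s y is a rigid vertical translation by log s and the
diagonal mirror is a rigid reflection.  The symmetrized two-phase region
is the convex hull of the translated two-phase hull together with its
mirror image: it collapses onto the arm when the arm is symmetric and
fills the lens between arm and mirror when it is not.  The minimized
quantity is the fraction of one-phase points covered by that region — a
sampling-measure estimate of the fractional overlap area.  Counting
points rather than intersecting traced polygons was a deliberate
robustness choice: polygon-area objectives proved dominated by single
outliers (one mislabeled point displaces a hull edge and with it the
whole minimum), whereas a mislabeled point changes a coverage count by at
most 1/m.  A linear-axis polygon overlap (`overlap_area`), matching the
source construction directly, is retained for direct use; it is not
suitable as a scan objective because linear-space areas scale with s and
its hulls degenerate into slivers over the default five-decade grid.

Before scanning, label-inconsistent points are pruned
(`prune_inconsistent_labels`): a point is dropped when >= 70% of its 7
nearest log-space neighbors carry the opposite label, or when it lies
strictly inside the concave region traced by the opposite class.  The two
filters are complementary (interior flips vs flips near the sparse ends
of the sampled arm); a plain-majority vote proved too aggressive, eroding
honest boundary-adjacent points and shifting the optimum.  Clean data
pass through unchanged.

The default grid is 200 log-spaced values on [0.1, 1e4], refined once
(~10x) across the argmin region.  The objective typically bottoms out on
a plateau of zero coverage (the data's finite concentration resolution
maps to a range of s that all symmetrize equally well); the reported
s_star is the geometric center of the argmin set, and the reported band
contains every evaluated s within 5% of the minimum.  A completely flat
objective is flagged rather than resolved.

Round-trip behavior on synthetic binodals: planted valences
{1, 2, 10, 133, 689} are recovered within one coarse grid step (~6%)
without noise, and with 5% label-flip noise the 5% band contains the
planted valence in >= 90% of seeded trials.

The guaranteed ellipse fit is the numerically stable direct
least-squares conic fit with the ellipse constraint 4ac - b^2 = 1
enforced in the eigenproblem, so the result is an ellipse for any input,
including hyperbola-like noisy data.  Goodness of fit is reported as
R^2 = 1 - SS_res/SS_tot with orthogonal (geometric) point-to-ellipse
residuals — computed by root-finding the projection angle per point —
against the squared scatter of the points about their centroid; a
Sampson (gradient-normalized algebraic) variant is reported alongside,
since the source analysis does not specify its residual type.

Non-cognate:cognate sticker ratios are
(apparent_valence - cognate_sites)/cognate_sites, with the cognate count
the number of UGCAU consensus motifs: 0.2, 25.6, 61.6 for valences
6/133/689 with 5/5/11 cognate sites.

Tie lines connect coexisting dilute and dense compositions; the slope is
reported on linear axes and the log-log representation is exposed because
straight tie lines curve there.

## Imaging statistics

Spot colocalization operates in 2D on maximum-intensity-projection
coordinates: a reference spot is colocalized when any other-channel
center lies strictly closer than 2r (default r = 1.389 px = 150 nm).
The pixel-shift control translates reference centers by +2r in both axes
and re-tests; shifted spots leaving the field are kept (the distance test
remains valid, and wrap-around would manufacture coincidences).  Nuclear
proximity compares spot-to-centroid distance against r + R per nucleus,
R = sqrt(A/pi) recomputed from the segmented area; distances >= r + R
are "not nuclear proximal".  Thresholds follow the strict inequalities of
the definitions exactly.

Pixel-wise colocalization is the plain Pearson correlation over in-mask
pixels; an optional intensity threshold approximates
threshold-regression behavior, while randomization-based significance
testing is out of scope.

FRAP processing: acquisitions whose unbleached-condensate trace varies by
>= 5% (relative range (max - min)/mean) are excluded; the bleached-spot
traces of passing acquisitions are averaged per time point, the mean
background is subtracted, and the trace is normalized to the maximum of
the averaged trace (pre-bleach frames included in the denominator; only
max_recovery excludes them).  SEM is the across-acquisition standard
deviation (ddof = 1, on the common normalization scale) over sqrt(n),
per time point and for the post-bleach maxima.

## RNA complementarity

A complementary site is a maximal antiparallel duplex in which every
aligned pair is G:C, A:U or (by default) G:U, of length >= 11.  The
search builds the pairing-compatibility matrix of sequence 1 against the
reversed sequence 2 and extracts maximal runs along its diagonals; T is
auto-converted to U.  Maximal matches are reported even when they
overlap, but sub-runs of longer runs are suppressed, since the analysis
counts sites rather than windows.  Mean reactivity averages the supplied
per-nucleotide values over the union of matched positions, counting each
position once and reporting how many matched positions lacked data.

## Synthetic data

Every generator is deterministic given (parameters, seed) and returns a
manifest recording all planted values.

* `gen_phase_boundary` scatters points through an annular band around an
  elliptical dilute arm in sticker space (center (c, c), semi-axes 30
  and 12 with c = 40, radial factor uniform in 1 +/- 0.45, polar angle
  within 1.2 rad of the point nearest the origin, 120 points), labels
  them by side, leaves an 8% radial margin unsampled at the boundary —
  the finite resolution of a titration series — and divides the RNA axis
  by the planted valence.  Label noise is a symmetric flip with the given
  probability; real measurement error surely has structure (gradients
  near the boundary, pipetting correlations) that a flip does not
  capture, so the noisy round trip demonstrates robustness to mislabeled
  points, not to every real-data pathology.
* `gen_spot_fields` plants a colocalized fraction with sub-radius
  Gaussian jitter plus a uniform Poisson background; it emulates point
  patterns only — no PSF, intensity structure, or chromatic shift.
* `gen_frap_traces` uses a single-exponential recovery
  plateau*(1 - exp(-t/tau)) above a constant background, pre-bleach
  level 1; the source analysis fits no model, so the generator is
  deliberately minimal.
* `gen_sequences` embeds exact antiparallel duplexes (optionally with
  wobble substitutions) in uniform random background; at the default
  lengths spurious >= 11-nt matches are vanishingly rare
  (~4 n^2 (6/16)^11).
* `gen_lattice_toy` returns the desk-scale presets described above plus
  the enumerable Boltzmann toy.

Passing tests on these generators show the estimators recover planted
structure under the stated noise models at desk-scale problem sizes;
they do not certify full-scale simulation output or real microscope
data.

## Known limitations

* The move-set frequencies and the full-scale simulation lengths are not
  reproduced exactly; quantitative comparison with published binodals
  would need cluster-scale runs.
* The cluster-translation move's no-external-contact acceptance rule is
  conservative; in dense systems it mostly rejects, and mixing then rests
  on the local/chain moves.
* Ellipse R^2 values depend on the residual definition; both geometric
  and algebraic variants are reported but neither is certified to match
  the source's unspecified choice.
* The valence scan assumes strictly positive concentrations (log axes)
  and at least three points per phase label after pruning.
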