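# Methods

## The model

`recolorpoly` simulates a coarse-grained chromatin fibre as a bead-spring
polymer whose beads carry dynamic epigenetic "colours", coupled to a small
population of diffusing protein bridges that *read* one histone mark and
*write* another.  The model captures the minimal mechanism by which a
transient burst of Polycomb-protein binding can leave behind a stably
compacted chromatin domain:

1. **Reading.** Proteins are attracted to beads carrying the H3K27me3
   mark (binding well depth 4 kBT).  Multivalent binding of one protein
   to several marked beads bridges distant chain segments
   (bridging-induced attraction).
2. **Writing.** At regular intervals a Monte-Carlo sweep deposits the
   H2AK119Ub mark on randomly selected beads that have an engaged protein
   within the 60 nm writing radius.  Writing is irreversible and never
   erases K27me3; neutral beads become Ub-only, K27me3 beads carry both.
3. **Remembering.** Ub-bearing beads attract one another (3 kBT).  This
   self-attraction persists after protein binding is switched off, so the
   compacted state outlives the binders — compaction is "written into"
   the fibre.

The package also implements the quantitative image statistics used to
characterize the corresponding optogenetic condensate experiments —
masked Pearson colocalization, pixel-variance traces with min-max
normalization and running integrals, inactive-X partition coefficients,
FRAP-style region traces and concentration/valence phase-diagram assembly
— together with synthetic-image generators that produce data with known
ground truth for all of them.

## Polymer mechanics and units

Reduced units: bead diameter sigma (= 30 nm = 3 kbp) is the unit of
length, kBT the unit of energy, bead mass m = 1, friction gamma = 1.
With these choices the LJ time sigma*sqrt(m/eps) and the Brownian time
gamma*sigma^2/kBT coincide and define the time unit tau.

* **Excluded volume** — WCA potential (Lennard-Jones shifted up by eps/4,
  truncated at 2^(1/6) sigma) between all bead pairs, including bonded
  neighbours.
* **Bonds** — FENE springs, k = 30 eps/sigma^2, maximum extension
  R0 = 1.5 sigma.  Together with WCA the equilibrium bond length is
  ~0.97 sigma.  A bond reaching R0 aborts the run with a named error.
* **Bending** — k_bend (1 - cos alpha) per consecutive tangent pair with
  k_bend = 3 kBT, so a straight chain costs nothing and a reversal costs
  2 k_bend.  This convention makes the persistence length ~ k_bend sigma.
* **Attractions** — truncated LJ at cutoff 1.8 sigma *without* the +1/4
  shift, so the quoted well depths (4 kBT reader binding, 3 kBT Ub-Ub)
  are the true minima.  Applying the WCA shift out to 1.8 sigma would
  make the "attraction" non-negative everywhere, which cannot be what the
  stated well depths mean; the ~0.114 eps energy step at the cutoff is
  the standard price of plain truncation and does not affect forces.

Default geometry: N = 1000 chromatin beads, 20 protein beads (one per
150 kbp), 85 K27me3 beads drawn uniformly from the index window
[400, 600) (0-based, half-open), cubic periodic box of edge 60 sigma.
The box size is a package choice (it is not part of the stated model):
large enough that the expanded coil fits, small enough that the binders
find the chain.

## Dynamics

Langevin dynamics at kBT = 1 with gamma = 1 and dt = 0.01 tau, integrated
with the BAOAB splitting: half momentum kick, half drift, exact
Ornstein-Uhlenbeck thermostat step, half drift, half kick.  BAOAB was
chosen over the impulse-style Langevin velocity-Verlet because its
configurational sampling error at fixed dt is markedly smaller and its
thermostat sub-step is exact for any dt.  One subtlety: the *step
boundary* velocities of BAOAB under-sample the Maxwell-Boltzmann
distribution by O((omega dt)^2) for stiff modes (about 2% here, dominated
by the bond-vibration frequency), while the mid-cycle velocity after the
first half-kick samples it exactly.  The kinetic-energy diagnostic
therefore evaluates (1/2)|v + (dt/2) f|^2, which is unbiased; equipartition
holds to well under 1% in the tests.

Neighbour search uses a linked-cell grid over occupied cells with a
half-stencil sweep, feeding a Verlet pair list with per-kind search radii
(WCA cutoff + skin for repulsive pairs, 1.8 sigma + skin for attractive
pairs; skin 0.5 sigma, rebuilt when any bead has moved more than
skin/2).  The pair list stores the resolved well depth and cutoff per
pair, so the force loop is branch-free; recoloring events and the
binding-on/off switches invalidate the list.  The analytic forces of both
the production kernel and the transparent numpy reference implementation
are validated against central finite differences (1e-6 eps/sigma) and
against each other.

Randomness is split per replica into three documented numpy streams
(initialization, thermostat noise, recoloring) spawned from the replica
seed, so recoloring choices never perturb the thermostat sequence;
replica k of an ensemble uses seed base_seed + k.  Runs are bit-for-bit
reproducible given the seed.

### Initialization

The chain starts as a freely jointed random walk (bond length sigma)
centred in the box with binders placed uniformly.  Overlaps are removed
by a pairwise positional resolver (push overlapping pairs apart by a
fraction of their overlap depth, clamp bonds into [0.8, 1.2] sigma,
jitter on stall) until the largest pair energy is below 10 kBT; rare
topologically tangled walks that the resolver cannot open are discarded
and redrawn from the same stream.  Velocities are Maxwell-Boltzmann.

### Protocol

Three phases: equilibration with binding off; a binding window with the
protein-K27me3 attraction on and a recoloring sweep attempted every
10 tau (one sweep = N independent uniform selections with replacement; a
without-replacement permutation sweep is available); a post window with
binding off again — proteins stay in the box but are decoupled, the
minimal intervention — and recoloring stopped, Ub-Ub attraction retained.
Control runs disable recoloring only.  Times are reported relative to
binding-on; trajectory frame 0 is the end of equilibration.

The writing rule is stated ambiguously in terms of a protein "within
60 nm from that bead and it has a H3K27me3 mark"; since neutral beads
demonstrably acquire Ub, the "it" is read as the *protein* being engaged
with H3K27me3.  Default `write_condition="bound_protein"` therefore
requires the writer to sit within the binding cutoff of some marked bead;
`"any_protein"` is provided for sensitivity analysis.

## Observables

* Squared radius of gyration, (1/N) sum (r_i - r_CM)^2 over unwrapped
  chromatin coordinates.  The monitoring quantity is defined as this
  squared length and the code keeps it literal (`radius_of_gyration_sq`);
  a square-rooted accessor exists for convenience.
* Local density: chromatin beads within 2 sigma (60 nm) of each chromatin
  bead, self included, over the sphere volume.  Protein beads are
  excluded on both ends.  The headline trace is the *square of the
  spatial mean* density, one curve per replica (the mean-of-squares
  variant is available behind a flag); ensembles report pointwise mean
  and sample SD over replicas.
* Bond tangent-tangent correlations and an origin-constrained
  least-squares fit of log C(s) against s for the persistence length.
  With k_bend = 3 kBT the discrete-chain prediction from
  <cos alpha> = coth(k) - 1/k is l_p ~ 2.5-2.6 bonds; self-avoidance
  slows the decay at larger lags, and the fitted value over s = 1..10
  comes out near 3 sigma (~90 nm), consistent with the nominal stiffness.
  The fit window [1, 10] keeps the estimate in the exponential regime.

## Imaging statistics

All metrics operate on masked pixel sets; segmentation masks (nucleus,
nucleoli, inactive X) are *inputs*.  Colocalization excludes nucleoli and
the inactive X (both would skew the correlation); co-expression and
variance analyses exclude only nucleoli.  Pixel variance uses the sample
estimator (n - 1) exactly as defined.  Variance traces are normalized
min -> 0, max -> 1 per trace; the history integral uses trapezoidal
quadrature on the sampled grid (the quadrature rule is unstated in the
source definition; trapezoid is the natural choice for irregular
sampling).  The partition coefficient is the mean intensity on the
inactive X over the mean elsewhere in the nucleus.  Phase diagrams take
per-cell (core concentration, sspB concentration, human classification)
records — valence = sspB/core — and drop cells without a classification
(observer disagreement).  No photobleaching correction is applied
anywhere.

## Synthetic data

Generators produce images with the statistical structure the metrics
assume, with tunable ground truth: elliptical nucleus masks with interior
nucleoli/inactive-X subregions; channel pairs built by Gaussian mixing of
smooth random fields (low-pass-filtered white noise, correlation length a
few pixels) so the masked PCC equals the requested rho in expectation;
partition images with an exact target ratio; and condensation time series
whose condensate-channel variance rises during an activation window and
collapses after it, while the chromatin channel responds with a lag as a
saturating integral of the drive and either persists (epigenetic-memory
shape) or relaxes (reversible shape).  Intensities are emitted around an
offset of 1000 with ~8x headroom so they round-trip through 16-bit TIFF.

What the generators deliberately do **not** model: optics (PSF beyond
Gaussian smoothing), camera noise statistics, photobleaching, cell
motion, or segmentation error.  Passing tests therefore demonstrate the
*estimators* are correct on data satisfying their assumptions, not that
the assumptions hold for any particular microscope.

## Problem sizes used by the shipped checks

The full study design (N = 1000, 36 replicas, 1e6 tau equilibration) is
supported but long-running; the shipped tests and the benchmark script
run desk-scale versions chosen to preserve the physics at manageable
cost:

* Sustained compaction: N = 300 chain (proportional marked window
  [120, 180) with 25 marked beads), 6 binders, 8 replicas per condition,
  t_equil = 3e3 tau, t_bind = 1e4 tau, t_post = 6e3 tau, landmarks
  averaged over trailing 1e3-tau windows.  At these sizes the
  recoloring-on ensemble retains its termination density squared
  essentially unchanged and the control relaxes to baseline within a few
  percent, so the contrast being tested is far larger than the
  thresholds.
* Persistence length: N = 200 neutral chain, 1e4 tau equilibration,
  1e5 tau production, tangent correlations sampled every 10 tau
  (test variant: N = 100, 2e4 tau).
* Thermostat check: 50-bead chain + 4 binders, 1e5 steps.
* Recoloring invariants: full N = 1000 geometry over a short protocol.
* Chain collapse (Rg^2 decrease): tested on a chain whose marked window
  spans half the beads (N = 100, 40 marked, 4 binders), where Rg^2 drops
  about ten-fold during binding.  At the 300-bead ensemble conditions
  only about a third of the chain compacts and the global Rg^2 change is
  smaller than coil fluctuations at 8 replicas, so the collapse is probed
  where the signal is unambiguous.
* Benchmark script: persistence length at N = 200 with 1e5 tau
  production; the pixel-set worked examples; a 60-frame synthetic
  condensation series; one short full-geometry protocol run.

## Known limitations

* No hydrodynamics, twist, supercoiling or electrostatics; binders are
  single beads with isotropic attraction (no explicit valence cap).
* No eraser enzymes, replication dilution or PRC2 spreading of K27me3 —
  the mark dynamics are write-only by design.
* The Ub-Ub quench (3 kBT) is deep; the compacted domain is closer to a
  collapsed globule than a liquid droplet at these parameters.
* Phase-separation classification is a human-provided input label; the
  package only assembles and plots the diagrams.
* The attractive-cutoff energy step and the unstated box size are
  documented choices, not fitted quantities.
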