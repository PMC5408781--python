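# Methods

`latcirc` simulates, screens and analyzes two-gene paracrine patterning
circuits that can perform lateral induction (a propagating wave of gene
activation ending in a uniform high-expression field) and/or lateral
inhibition (an alternating "salt and pepper" pattern), and asks when one
circuit can perform both depending on a tissue context signal.

## The multicellular model

A one-dimensional tissue of `n = 33` cells carries two genes per cell.  Gene
0 by convention is the signaling gene D, whose product regulates target
genes in the two adjacent cells (juxtacrine signaling); gene 1 (A) acts only
within its own cell.  The concentration `g_ij` of gene `i` in cell `j`
evolves as

    dg_ij/dt = phi_i(x_ij) - lambda * g_ij,
    phi_i(x) = 1 / (1 + exp(alpha_i - beta * x)),

where the net input `x_ij` sums intra-cellular regulation
`sum_k intra[i][k] g_kj`, inter-cellular regulation `inter[i] * (D_left +
D_right)`, a trigger `T = 1` delivered to one gene of the central cell, and
a context signal `C` delivered to one gene of every cell.  `lambda = 0.05`,
so concentrations live on a 0-20 scale (`phi/lambda <= 20`).  `alpha_i`
sets a gene's basal behavior (-60 means constitutive expression, large
positive values demand strong net activation); `beta` (5 or 10) sets the
sigmoid steepness.  Production is clamped at zero; since `phi` is positive
the clamp is formally redundant and kept for safety.

Numerical choices:

* **Integrator** -- explicit Euler with `dt = 1`.  The noise model is
  defined per time step, which fixes the discretization; a convergence
  check (halving `dt` on noise-free runs changes final states by < 1%) is
  part of the test suite.
* **Noise** -- after each deterministic update every concentration is
  multiplied by `1 + u`, `u ~ Uniform(-0.01, 0.01)` independently per gene
  and cell.  The stream is *counter-based* (a murmur3-finalizer hash of
  (seed, step, gene, cell)): a trace is bit-for-bit reproducible whether it
  is simulated alone or as one row of a vectorized screening batch, and
  enlarging a screen never changes the noise of earlier samples.  Note
  that, integrated through the AR(1) dynamics (per-step retention
  `1 - lambda`), the stationary state noise is ~1.9% of the expression
  level, about twice the per-step amplitude -- this matters for the scoring
  tolerances below.
* **Boundary** -- "reflective / zero-flux" is realized as a mirror ghost
  cell: each edge cell's missing neighbor is a copy of the edge cell
  itself.  A `"zero"` alternative (missing neighbor contributes nothing) is
  configurable, as contact signaling does not uniquely determine the
  reflective rule.
* **Neighbor input scale** -- the inter-cellular input can be the *sum*
  (default) or the *mean* of the two neighbor concentrations
  (`neighbor_mode`).  The mean convention makes an interior cell's input
  scale match the reduced two-cell model (one neighbor at weight `w`); the
  published text does not disambiguate, so both are implemented and the
  worked-example calibration searches over both.
* **Initial condition** -- every gene in every cell starts at 0.1; T and C
  are constant throughout a simulation (except in explicit context ramps).

## Objective functions

Profiles are binarized under two schemes.  The *absolute* scheme calls a
cell high when its concentration is at least 10 (half the maximal steady
level).  The *adaptive* scheme calls a cell high when it exceeds the
midpoint of the profile range, provided the range is at least 2.0
concentration units, else all cells are low.  The contrast floor and the
equilibrium tolerances are set by the model's own stationary noise: the
instantaneous cross-tissue spread at a uniform high state is ~1.6 units
(so instantaneous adaptive labels would flicker), while 100-step windowed
means fluctuate by only ~0.2 units.  Inside the classifiers the adaptive
scheme is therefore applied to 100-step window means.

*Equilibrium*: a run has settled when, over the last 100 steps, (i) the
absolute patterns of both genes are unchanged, (ii) every cell's windowed
mean drifts less than a noise-aware tolerance, and (iii) the adaptive
patterns of consecutive window means agree.  The drift tolerance per cell
is `max(2.5 * std_within, 5% of level, 1.0)`: cells resting on the steep
shoulder of the sigmoid have stationary window-mean wander of order 1 unit
(local gain amplifies the noise) that carries no pattern information,
while a genuine linear trend makes the window-mean difference ~3.4x the
within-window standard deviation and still fails; the absolute floor is 5%
of the 0-20 dynamic range.  Runs not settled by the step cap (default
5000) are classified `none`.

*Lateral induction* is a dynamical verdict: the **expansion** -- the length
of the contiguous run of absolute-high cells containing the central,
triggered cell (zero if the center is low) -- must strictly exceed its
running maximum on at least five distinct steps and finish equal to the
tissue size at equilibrium.  Counted increases must be at least 5 steps
apart: a genuine wave advances roughly one cell per >= 10 steps, whereas a
uniform constitutive rise crosses the threshold near-simultaneously
everywhere and noise would otherwise split that crossing into several
spurious one-cell increments (the empty topology must never score).

*Lateral inhibition* is an end-state verdict: the number of adjacent
high-to-low transitions (left to right) of the equilibrium adaptive
pattern must reach `min_switches` (default 14, the strict reading of
"more than 13"; a perfect alternating 33-cell pattern counts 16; the
permissive reading, 13, is available as a config override).

A *circuit-level* verdict requires four independent noise runs (seeds
derived from the run seed) to all reach equilibrium and agree.  Both genes
are evaluated and either can carry the verdict.  When the two genes of one
run qualify for different functions — typically one gene holds an
alternating pattern while the passive readout gene ends uniform-high with
a noise-timed rise that technically satisfies the expansion rule —
inhibition takes precedence: a settled alternating pattern cannot arise
spuriously, whereas the uniform end state is exactly what the dynamical
induction rule guards against.

Model behavior worth knowing: pure mutual-repression patterns freeze with
a few defects (typically 13-15 switches of a possible 16), so parameter
sets near the switch bar flip verdicts across noise seeds.  This is real
kinetic trapping of the lateral-inhibition process, not a scoring bug, and
it is why the screen's hit counts are probabilistic.

## Topology enumeration

The labeled space pairs six ternary interaction entries (four
intra-cellular, two inter-cellular) with the choice of signaling gene:
`2 * 3^6 = 1458` labeled topologies.  Exchanging the two gene labels (the
signaling designation travelling with its gene) is a free involution, so
there are exactly `3^6 = 729` isometry classes, canonically represented
with the signaling gene at index 0.  The published count of 1,200
"non-isometric" topologies lies strictly between the labeled and the
reduced space and cannot be reproduced by any label-consistent reduction
we could construct; the package reports the raw (1458) and canonical (729)
counts and documents the discrepancy.  A corroborating observation: the
published per-function success counts sum to more than 729 distinct
topologies, so the published universe indeed retained most mirror twins --
which also explains why the published minimal-circuit lists come in pairs
(below).

## Screens

The *mono screen* samples, for each topology, random parameter sets
(weight magnitudes uniform on (0, 10] with the topology's signs, `alpha`
uniform on [-60, 60] per gene, `beta` equiprobably 5 or 10), simulates
each sample at `C = 0` with the trigger delivered to each gene in turn and
four noise runs per combination, and counts induction/inhibition
verdicts.  Seeding is hierarchical and content-addressed (master seed +
canonical topology encoding + sample index + run index), so results are
independent of execution order and nested in the sample budget: enlarging
a screen preserves every earlier sample's parameters and noise exactly.

The *context screen* re-simulates every stored mono hit at `C = 1`, adding
the context to each gene in turn with topology and weights unchanged, and
keeps circuits whose verdict switches to the opposite function -- strong
bi-functionality.

The published screen used 10^7 parameter sets per topology on a cluster;
the package's defaults are desk-scale (10^2-10^4 per topology).  At these
scales the hit *sets* are sparse subsets of the full-scale ones; the
package's tests exercise subset consistency and seed-nesting rather than
the full-scale counts.

## The minimal-circuit library

A reduced screen of every canonical topology with at most three links
(1,000 parameter sets each, both trigger genes, four noise runs) finds
three robust canonical induction cores and three inhibition cores:

| core | links | mechanism |
|------|-------|-----------|
| induction | `inter[D] +` | intercellular auto-activation: D activates D in neighbors; the wave is autonomous to the signaling gene |
| induction | `inter[A] +, intra[D][A] +` | activate-activator: neighbor D activates A, A activates D; both genes expand in phase |
| induction | `inter[A] -, intra[D][A] -` | inhibit-inhibitor: neighbor D represses A, A represses D; D expands by silencing its repressor, out of phase with A |
| inhibition | `inter[D] -` | mutual intercellular repression of D |
| inhibition | `inter[A] +, intra[D][A] -` | activate-inhibitor: neighbor D activates A, A represses D (the classic juxtacrine inhibition loop) |
| inhibition | `inter[A] -, intra[D][A] +` | inhibit-activator: neighbor D represses A, A activates D |

The screen also yields a few rare (<= 5 hits in 2,000) "induction" calls
for purely intra-cellular bistable topologies, in which noise-timed
autonomous switching mimics a slow spread; these are artifacts of the
objective function's tolerance and are excluded from the library.

The library ships as twelve entries, `D0`..`D5` and `H0`..`H5`: the six
canonical cores plus their mirror-labeled twins, mirroring the published
presentation in which each mechanism family has two members.  Module
containment and unions always compare canonical forms, so twin entries act
identically in the decomposition algebra.

## Atlas and decomposition

The complexity atlas has successful topologies as nodes (annotated
induction-only / inhibition-only / both / strong-bifunctional and layered
by link count) and edges between topologies differing by the gain or
removal of exactly one interaction (a sign flip is distance two).
Stalactites are maximal connected subgraphs of a capability class; minimal
topologies are successful topologies none of whose single-link-removal
sub-topologies is successful.  A strong bi-functional topology is *hybrid*
when it contains (sign-consistent, canonical alignment, extra links
allowed) at least one library induction module and one inhibition module,
else *emergent*, recording the module-less function.  The hybrid/emergent
call is structural; the dynamics toolkit provides corroborating evidence,
not the classifier.

Pairwise unions of the canonical library cores give 9 candidate pairs of
which 4 are conflict-free; in the published labeled universe this doubles
to 36 pairs / 8 union topologies.  Neither matches the published "42
hypothetical combinations / 7 possible", which we could not reconstruct
from any universe; the discrepancy is documented rather than forced.

The robustness score perturbs every weight and alpha of a strong hit by
independent factors uniform on [1-delta, 1+delta] and reports the fraction
of perturbed circuits that reproduce the hit's function map.  It is a
simplified perturbation protocol defined by this package, not a
reproduction of any published robustness pipeline.

## Two-cell phase-space toolkit

The reduced model keeps two coupled cells (state `D_c1, A_c1, D_c2,
A_c2`), T applied to the trigger gene of cell 1 only, C to the context
gene of both.  Fixed points are found by batched damped Newton iteration
(backtracking line search; fixed points on the steep sigmoid shoulder have
tiny undamped basins) from a grid of starts over `[0, 20]^4` augmented
with low-concentration values and, in a second round, with points
interpolated between already-found roots (symmetric saddles lie on those
segments).  Roots are deduplicated at 1e-4 in the max norm and accepted at
residual < 1e-8; stability is labeled from the Jacobian eigenvalues
(stable iff all real parts < -1e-6, unstable iff all > 1e-6, saddle
otherwise).

*Instantaneous portraits* freeze `A_c1, A_c2` at trajectory values and
analyze the two-variable D-subsystem: nullclines by marching squares on a
dense grid, attractors by the same Newton machinery, identities aligned
across time points by nearest-neighbor matching.  *Bifurcation sweeps*
re-solve the fixed points along a monotone grid in T or C (warm-started
from the previous branch points) and classify events from the change in
branch configuration.  Pitchfork detection is configuration-based rather
than matching-based, because near the bifurcation the three colliding
states approach within any matching tolerance: the signature is a
same-stability exchange-symmetric pair present on one side of the event
only, with the near-diagonal state at the pair's centroid carrying the
opposite stability on the other side (subcritical when the pair is
unstable).  Saddle-node events are recognized when the disappearing (or
appearing) states decompose into close pairs at least one of which joins
a stable state and a saddle -- simultaneous folds on replicated branches
count once.  Anything else is reported as "other"; ambiguity is flagged,
not guessed.

*Pursuit detection* discriminates by residence.  In attractor switching
the system initially rests on an attractor (the state starts within
`distance_min = 1.0` of one) which is later destroyed — the instantaneous
attractor count drops — and the state jumps to another.  In pursuit the
state is never at rest: it starts away from every attractor and chases a
target (the nearest attractor at each sample) whose cumulative positional
displacement exceeds `displacement_min = 2.0` while the state trails by at
least `distance_min` over a sustained interval, finally catching it.
Target displacement is positional rather than identity-matched because
with steep regulation a pursued attractor can traverse most of the 0-20
range between two samples.  A trajectory that barely moves is `neither`.
Thresholds are config-overridable.

*Context ramps* raise C stepwise (default +0.01 every 50 steps) through a
full-tissue simulation and report per-plateau expansion, switch count and
pattern amplitude (mean high minus mean low under the adaptive scheme);
the transition is `abrupt` when the amplitude jumps by more than half its
overall range between adjacent plateaus.

## Worked-example calibration

The three reference circuits (hybrid C, AI1, G') ship with printed weight
values and alphas but not with a machine-readable assignment of weight
labels to links, trigger/context genes, steepness, or neighbor-input
convention.  These are resolved by behavior: every assignment consistent
with the printed signs (all sign-compatible topologies of the right link
count, label permutations, both trigger genes, both context genes, both
beta values, both neighbor modes) is simulated in both contexts, and the
assignment reproducing the documented qualitative behaviors (function
switch across contexts; pursuit-based induction for AI1; abrupt ramp
transition for G') is persisted as fixture data with the package.
`load_worked_example(..., validate=True)` re-runs the behavioral checks
and raises on any deviation.

## What the synthetic data does and does not show

All inputs are generated internally: enumerated topologies, seeded
parameter draws, and the calibrated reference circuits.  The generator
reproduces the study conditions (33 cells, uniform 0.1 start, T = 1
central trigger, C in {0, 1}, +/-1% per-step noise, the published
parameter ranges).  It does not emulate real Notch-Delta biochemistry
(no cis-inhibition, ligand trafficking, delays, 2-D tissue geometry or
diffusible signals), so passing tests demonstrate properties of this model
class, not of any measured biological tissue.

## Known limitations

* Desk-scale screens cannot reproduce cluster-scale hit counts; only
  set-inclusion and seeding properties are asserted.
* Bifurcation classification is heuristic from branch topology; no normal
  forms or arclength continuation.
* The fixed-point search is stochastic-free but still a heuristic
  multi-start method; pathological circuits could hide fixed points
  between grid starts (mitigated by the enrichment round and warm starts).
* The published 1,200-topology count and the 42/7 hybrid-combination
  counts are not reproducible from the text alone and are documented as
  discrepancies rather than forced.
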