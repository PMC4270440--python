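# Methods

## Overview

`animats` simulates the evolution of small logic-gate agents in a
block-catching task and quantifies the causal structure of their brains
with the IIT 3.0 measures.  The pipeline is: genome → gates → deterministic
network (TPM) → task fitness → genetic algorithm → line of descent →
per-generation causal and informational measures → cross-condition
statistics.  Everything is generated internally; there is no external data.

## Animat brains

A brain has 8 binary elements: sensors S1, S2 (indices 0–1), hidden
elements A–D (2–5), motors M1, M2 (6–7).  States are packed integers with
bit *i* holding element *i* (state strings such as `00-1010-10` read left
to right, element 0 first).  The genome is a circular string of 1,000 to
20,000 integer loci in [0, 255].  Each occurrence of the start codon
(42, 213) opens a 28-locus gene encoding one hidden Markov gate: two count
loci (`n = 1 + locus mod 4` inputs and outputs, 1–4 each), eight address
loci (four input slots mapping via `locus mod 6` onto the 6 legal inputs —
sensors and hidden; four output slots mapping onto the 6 legal outputs —
hidden and motors), and sixteen table loci of which the first `2**n_in`
are active (`row value = locus mod 2**n_out`).  Reserving all sixteen
table loci makes the encoding robust: a mutation of the input/output
counts only grows or shrinks the active part of the table.

Decoding choices the encoding text leaves open, fixed here once:
addresses are kept with duplicates (effective fan-in shrinks); table row
bit order is ascending element index; genes may wrap the genome origin;
the ancestral genome is all zeros (contains no codon, so generation zero
has no connections).  Gates write elements by OR when several gates target
the same element (the standard Markov-brain convention, isolated in one
function).  Sensors are exogenous (their TPM successor is always 0; the
environment overwrites them), and motors have no effects inside the brain.

## Task environment

A 16-column world with periodic boundaries; blocks fall for 36 steps,
moving one unit down and one sideways per step.  The animat is 3 units
wide with sensors on its outer units.  One evaluation is exactly 128
trials: 16 start columns × 2 directions × 4 block-size slots (two-size
tasks show each size twice).  Tasks: 1 = catch {1} avoid {3},
2 = catch {1} avoid {2}, 3 = catch {1,4} avoid {2,3}, 4 = catch {3,6}
avoid {4,5}.  Variants disable one sensor or one motor (forced to 0) or
flip each sensor independently with probability 0.01 per step, with each
trial repeated 20 times and fitness averaged.

Per step: sense (a sensor is on iff a block unit is directly above it),
update the brain, move one column for motor patterns 01 (right) / 10
(left) (00 and 11 stand still), then the block advances.  A block is
caught if it overlaps the animat after step 36; fitness F is the fraction
of correct trials (catch-blocks caught, avoid-blocks avoided).  A
stationary brain scores exactly 56/128 = 0.4375 on Task 1 (verified
analytically and by enumeration).  The recorded trajectory holds, per
step, the state the update acted on — fresh sensor reading plus the
hidden/motor values from the previous update — giving 36 states per
trial; the pre-trial all-zero state is not recorded.  This is the state
set used for both the IIT state weighting and the Shannon measures, and
it is the convention under which an analyzed state can show sensors and
motors simultaneously active.

## Genetic algorithm

Population 100, roulette-wheel selection without elitism with score
`S = 1.02**(128 F)` (one more correct trial multiplies the weight by
1.02), asexual reproduction.  Mutation per offspring: point mutations at
0.5% per locus (uniform replacement), a 2% chance of deleting and a 5%
chance of duplicating a fragment of 16–512 adjacent loci, suppressed when
the result would leave [1,000, 20,000] loci.  Ancestral genomes are 5,000
all-zero loci.  Randomness uses named per-generation substreams (selection
vs mutation), so runs are bit-reproducible from the seed.  The line of
descent of a final-generation animat is traced through the archived parent
indices; populations are snapshotted every 512 generations (the LOD
sampling interval; at the full experiment scale of 60,000 generations the last
sample falls at 59,904).

The inner loop (codon scan, gene decode, TPM assembly, and the 128 trials
for all 100 candidates) is compiled with numba; a plain numpy/python path
produces bit-identical TPMs and fitness and is cross-checked in the tests.
Point mutation is sampled as a binomial count plus uniform distinct
positions — the same per-locus Bernoulli distribution with far fewer
draws.

## IIT 3.0 engine

For a candidate set of elements (everything else clamped to its current
state as background), the engine computes cause and effect repertoires
under uniform perturbation: effect repertoires factorize over purview
elements (independent-noise convention); cause repertoires factorize over
mechanism elements (virtual-element convention) and are undefined — φ = 0
— when the mechanism state is unreachable.  Mechanism φ is the
earth-mover's distance (Hamming ground metric) between the intact
repertoire and that of the minimum-information partition, over all
bipartitions of (mechanism, purview) with two non-degenerate parts; empty
mechanism parts contribute unconstrained repertoires.  No partition-size
normalization is applied.  φ^Max maximizes each side over purviews pruned
to elements connected to the mechanism (unconnected elements only add
unconstrained factors and cannot raise φ); ties go to the larger purview,
then lexicographically.  The tie direction matters: the system-level
distance depends on the winning purview's repertoires, and the
larger-purview convention is the one that reproduces the worked example's
reference Φ.

System-level Φ evaluates all unidirectional bipartitions (connections
from one part to the other replaced by independent noise, which makes the
node conditionals probabilistic) and takes the minimal extended EMD
between whole and partitioned conceptual structures: concept ground
distance = cause-side EMD + effect-side EMD of repertoires expanded over
the full candidate set; φ mass is transported between the structures with
any surplus going to the null concept (the unconstrained repertoires,
identical in cut and uncut systems since cutting replaces inputs by the
very noise the unconstrained repertoire marginalizes over).  Main-complex
search evaluates all hidden-element subsets of size ≥ 2 — sets containing
sensors or motors are feed-forward-attached and have Φ = 0 a priori, and
single elements cannot be partitioned.  Candidate graphs that are not
strongly connected short-circuit to Φ = 0 (some directed cut severs
nothing).

Mechanisms are restricted to hidden elements (sensors lack causes, motors
lack effects), so a whole-brain analysis has at most 2⁴−1 = 15 concepts.
Whole-brain measures (#concepts, Σφ^Max) and main-complex measures
(#MC elements, #MC concepts, Φ^Max) are averaged over all states
experienced during the 128 test trials, weighted by visit probability.

### Numerics

EMD is solved exactly: the transport LP (HiGHS) runs on the net mass
differences only, with closed forms for product distributions (the
coordinate-separable ground metric makes the EMD between factorized
repertoires equal the sum of per-element marginal differences — this
covers every effect-side distance) and single-source/sink cases.  φ below
10⁻⁹ is treated as exactly zero (LP noise floor).  Repertoires, concepts
and cut systems are memoized per (network, candidate, background) so that
state-weighted summaries over many experienced states share almost all of
their work.

## Worked-example networks

The three-node example (state ABC = 101) is fixed by its reference values.
Only C = XOR(A, B) with outputs to A and B is given explicitly; the gates
of A and B were recovered by exhaustive search over all deterministic
1–3-input gates under the constraints that the effect of C alone on A and
B is deterministic, that φ_E(AB→ABC) = 0.25, φ_C(AB→ABC) = 1/3 and
φ_E(AB→C) = 0.5 are the attained maxima, that the conceptual structure is
exactly {A, B, C, AB}, that Φ(ABC) = 0.92, and that ABC is the main
complex (no 2-element subset with the third element as background reaches
its Φ).  Eight gate assignments survive; the package ships the simplest:
A = B ∧ ¬C, B = ¬(A ∨ C), C = A ⊕ B, with Φ = 11/12 ≈ 0.92.  The reference
values carry 2-decimal precision, so tests compare at ±0.005.

The eight-element example animat embeds this triad as hidden A, B, C and
is likewise a reconstruction pinned by its reference values: exactly the
six whole-brain concepts {A, B, C, D, AB, AC}; main complex ABC with
Φ^Max = 0.92 and 4 concepts; and the enclosing set ABCD integrated but
excluded (0 < Φ(ABCD) < Φ(ABC)).  The adopted wiring is D = AND(A, B, C)
with C = (A ⊕ B) ∨ D (so clamping D = 0 as background leaves the core
exactly the triad), and sensors driving the motors directly (which gives
every element a causal role without entering any hidden mechanism's
purview).  Its Σφ^Max is 15/14 ≈ 1.0714, the closest value the searched
wiring space attains to the reference 1.08 (the achievable sums quantize
and skip the ±0.005 band around 1.08; all other reference quantities are
met exactly).  Details of the search are in `animats.examples` and the
test suite.

## Synthetic data and what the tests show

All inputs are generated: genomes, networks, trials.  The random-network
generators produce controlled wiring classes (recurrent, feed-forward —
acyclic among hidden elements, self-loop-only) used for property tests;
`random_small_network` builds fully random deterministic 3–4-node systems
for oracle equivalence against an independent, deliberately simple
reference implementation (dict-based, no purview pruning, dense transport
LPs) that shares the conventions but none of the code.  The scaled-down
evolutionary experiment (Task 1, 10 seeds, 5,000 generations, the
package's standard experiment size) reproduces the expected early fitness
trajectory (~82% at generation 5,000); it does not probe
the 60,000-generation regime, where the full-scale statistics (final
fitness levels, Table-style correlations, structure counts) live — the
pipeline supports that scale but the shipped tests do not exercise it.
Sensor noise, disabled sensors/motors and Tasks 2–4 are implemented and
unit-tested, but no claim about their long-run evolutionary outcomes is
tested.

## Known limitations

* The worked-example networks are reconstructions pinned by their
  reference measure values, not by an explicit gate listing; any gate
  assignment in the surviving equivalence class is observationally
  identical with respect to every value the tests check.
* The extended-EMD null-concept convention (surplus φ transported to the
  unconstrained repertoires) follows the standard IIT 3.0 formulation;
  alternative CES distances (e.g. sum of small-φ differences) are out of
  scope.
* Observational measures use plug-in estimators without bias correction;
  with 128×35 transition pairs over at most 256 states this is adequate
  for the comparative use they serve.
* Whether the original state weighting included the pre-trial state is
  not documented; the 36-states-per-trial convention here is isolated in
  the trial runner.
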