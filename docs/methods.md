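# Methods

## Model and assumptions

The package treats trunk segmentation as purely combinatorial.  A modeled
trunk region is `P` primary segments, each expanded through `k` cycles of
binary antero-posterior division into `2^k` leaf units (leg pairs).  There is
no tissue mechanics, no timing model, and no molecular identity for markers:
a marker is a label on a node of the binary splitting tree, inherited by the
node's whole dyadic block of leaf descendants.  Two marker kinds exist,
matching the two gonopod types of julidan millipedes: the early posterior
marker (on tree nodes, before splitting completes) and the late anterior
marker (on fixed global positions, after segmentation of the region is
complete).  Under the polydesmidan profile both collapse to the single generic
gonopod type.  Everything in the generative module is deterministic.

### Coordinates and the anchor

Leg pairs are numbered 1-based excluding the collum; offsets within a primary
segment are 1-based; dyadic node indices 0-based.  The anterior truncation
`t < 2^k` removes the first `t` virtual offsets of primary segment 1, so
`leg_pair = (ps − 1)·2^k + offset − t` and the realized trunk has
`L = P·2^k − t` leg pairs.

The collum is *not* a leaf of the splitting grid; it is a body-plan element
only.  Modeling it inside the grid would make the truncation ambiguous,
whereas keeping it outside leaves `t` a single well-defined integer.

The default julidan anchor is `t = 5`: it is the unique anchor modulo `2^k`
that places the homeotic gonopod runs (leg pairs 8–11 and 24–27) on the
*posterior quarter* node of two consecutive primary segments, i.e. the unique
anchor under which the observed pattern is a posterior subset of each module —
the model's reading of marker inheritance.  Under `t = 5` the normal gonopod
pair (legs 8–9, offsets 13–14) is *not* the absolute posterior-most leaf pair;
the observations do not pin the anchor more finely (see "identifiability"
below).  The polydesmidan default anchor is `t = 0` (primary segments = leg
pairs 1–4, 5–8, 9–12, gonopods on the posterior leaf, spacing 4).

## Body plan

The ring map is the standard layout — legless collum, three haplosegmental
rings (leg pairs 1–3), then diplosegments with comparative ring `r ≥ 5`
carrying leg pairs `2r−6` and `2r−5`.  Fusion anomalies merge two adjacent
diplosegment positions into one physical ring with four leg pairs; every ring
carries both a comparative index (normal-specimen-equivalent) and a physical
index, because fused specimens are counted in comparative terms.  Apodous
rings and the telson are not modeled (the motivating specimen has none); a
trailing odd leg pair is flagged `incomplete`.  Dorsoventral decoupling is
represented only as the fusion mechanism — the package does not decide whether
a fused ring is a dorsal fusion product or a locally truncated dorsal
splitting pattern, which the observations cannot distinguish.

## Inference

`dyadic_fit(G, k)` searches all anchors `t̂ ∈ [0, 2^k)`.  At an anchor, each
position maps to `(module, offset)`; the fit is feasible iff all occupied
modules carry one identical offset set, that set equals the leaf interval of a
single node, and the occupied modules are contiguous.  Feasibility is
certified by regeneration: the fitted spec is re-expanded through the
generative model and must reproduce `G` exactly (an internal assertion).
Markers clipped by the anterior truncation are not accepted as explanations:
a clipped marker produces unequal run lengths, which is a different
observable.

**Identifiability and tie-breaking.**  The run length fixes the node depth
uniquely, and the spacing fixes `2^k`; but the observed set constrains the
pair (anchor, node index) only up to a joint rotation modulo `2^k`.  Ties are
broken toward the most posterior node of the determined depth, then the
smallest anchor — the posterior-subset reading of marker inheritance.  For
the homeotic julidan set this selects anchor 5 with the posterior-quarter node
`(2,3)`; for a pattern like the normal male's `{8, 9}` alone, any odd anchor
is equally feasible and the tie-break returns the posterior pair `(3,7)` at
anchor 7.  Tests therefore assert exact recovery of depth, block size and the
marked set, and membership of the generating parameters in the feasible
equivalence class, not recovery of the raw node index.

**Parsimony.**  The multiplicative cost of a feasible fit is 1 (one marker
event).  For infeasible sets it is the minimal number of
(node, contiguous-block) events whose union is exactly `G`, found by
exhaustive depth-first exact cover over all anchors (practical for the ≤ 32
positions this package analyzes).  The sequential cost is the number of
maximal runs — the most charitable concrete reading of a model in which each
contiguous transformed stretch is one independent determination event.

**Classifier.**  `compare_models` runs the fit over `k = 1..6` by default (no
observation constrains `k` above 4; the range is a search window, not a
claim).  Verdicts: *multiplicative-consistent* (some `k` admits a single-event
fit and the spacing is a power of 2), *uninformative: one run* (no spacing
evidence, e.g. a normal male), *contiguous-extension* (a single run
overlapping or abutting the taxon's normal gonopod positions — explicable as a
locally less-circumscribed marker, no multiplicative model required), and
*contiguous-anomaly* (several runs that fit no single dyadic event, e.g. the
Madeira case with spacing 3).  Anterior-gonopod positions count as part of the
pattern: the anterior identity is modeled as a late overlay on an
early-marked position, not as a separate early marker.  A flag
(`exclude_normal`) exposes the alternative scoring in which the normal
positions are baseline; for the homeotic julidan specimen that mode leaves
unequal runs (2 and 4) at spacing 14 and no dyadic fit, which is why the
periodic pattern is read as including the normal gonopods.

A tolerance mode (`max_mismatch > 0`) accepts fits with up to the given number
of mismatched positions; the default is 0 because the pattern argument is
exact.

## Synthetic data

The generators define the study conditions, not tunable benchmarks.

* **Multiplicative regime** (defaults `k = 4`, `P = 2`, `t = 5`, the julidan
  anterior trunk): node drawn uniformly over depths `1..k` then uniformly over
  indices; contiguous primary-segment block uniform over all blocks.  Draws
  whose marker would be clipped by the truncation are rejected and redrawn
  (clipped markers produce unequal run lengths — a different observable, and
  one under which exact recovery is ill-posed).
* **Sequential regime** (default `L = 27`, matching the analyzed anterior
  region): 1–3 runs of length 1–4 (bounds covering the observed teratologies),
  placed uniformly subject to no overlap and no adjacency, by rejection.
* **Noise** mimics the described teratologies: per transformed position, with
  probability `p_asym` one uniformly chosen side reverts to a walking leg
  (unilateral incompleteness); per untransformed position, with probability
  `p_atrophy` the pair atrophies.  Noise never adds gonopods, so it degrades
  only bilateral-strict queries; default noise is 0.

All distributions are uniform because the observations suggest no other shape;
a single root seed drives per-replicate derived streams
(`numpy.random.SeedSequence`), making every experiment reproducible and every
phenotype file byte-identical under an identical configuration.

The discrimination experiment reports, over informative draws (≥ 2 runs), the
fraction classified multiplicative-consistent: the recovery rate for
multiplicative data and the false-positive rate for sequential data.  For the
two-run null the exact rate is also computed by exhaustive enumeration of all
placements (averaging over the length distribution), and the Monte-Carlo
estimate is required to agree within the binomial 99% interval.

### What the generators do not emulate

Real specimens have graded, asymmetric reduction of individual gonopod
substructures (recorded here only as free-text annotations), uncertain trunk
lengths for most literature cases, and possibly dorsal anomalies co-occurring
with ventral ones.  Passing tests show that the inference machinery is sound
and specific under the model's own assumptions; they cannot show that real
millipede segmentation is multiplicative.

## Numerical and scale choices

All computations are exact integer combinatorics; there are no tolerances.
Test and experiment sizes (500 recovery seeds, 400-replicate experiments,
enumeration at `L = 27`) were chosen as the smallest sizes at which the
statistical checks are meaningful; the whole suite runs in a few seconds.

## Known limitations

* The anchor/node-index rotation is unidentifiable by construction; reported
  anchors are canonical under the posterior tie-break, not measurements.
* Single-run phenotypes are never evidence for or against the model.
* The sequential null's cost model (one event per run) is a design choice;
  other nulls (e.g. bisegmental addition) would need their own cost rules.
* Ring-fusion semantics are a pure merge; no alternative dorsal-truncation
  mechanism is modeled.
* Trunk lengths of literature specimens other than the homeotic julidan male
  are conventions (91 and 31 leg pairs), flagged in the records; they do not
  affect any inference, which depends only on the anterior positions.
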