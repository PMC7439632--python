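# Methods

## Problem and model

`trajkg` asks whether an ordered pair of diseases (A, B) forms a *disease
trajectory* — a sequence in which A is commonly diagnosed before B — using
only the protein-level knowledge about the two diseases.  Each disease is
represented by its set of disease proteins (proteins encoded by genes
curated as associated with the disease); the biological substrate is a
knowledge graph of subject–predicate–object triples between proteins, where
the predicate direction runs from subject to object ("P1 inhibits P2" means
P1 is the inhibitor).

All paths of length ≤ 2 between the two protein sets are enumerated and
classified into three scenarios:

* **overlap** — a protein shared by both sets, optionally carrying a
  self-loop predicate (e.g. homodimerization, "binds with" itself);
* **direct** — one triple joining a protein of A and a protein of B;
* **indirect** — a two-triple path through one intermediate protein.

Each edge of a path carries a traversal orientation: *forward* when the
triple's subject lies on the A side of the traversal, *reverse* otherwise.
Because the candidate (A, B) is ordered, orientation encodes how the
molecular directionality of a predicate aligns with the hypothesized
temporal order of the diseases — the quantity of interest.

## Feature sets

Paths are reduced to binary *signatures* (`scenario|component` strings).
Four primary feature sets arise from a 2 × 2 grid:

* representation of indirect paths: **metapath** (the ordered predicate
  sequence is one feature, `indirect|p->q`) vs **split** (each predicate is
  its own feature, `indirect|p`, `indirect|q`);
* direction mode: **undirected** (orientation discarded everywhere) vs
  **mixed** (orientation kept only for predicates assessed as *directed* in
  the expert directionality table; undirected predicates and all self-loop
  predicates stay orientation-free).

A fifth, supplementary **directed** mode orients every predicate, loops
included (marked `:loop`).  Direct paths are length-1 metapaths and are
identical under both representations.  Features record presence, never
counts.

A metapath whose components have all lost their orientation has no
intrinsic direction, so its component sequence is canonicalized (sorted).
This makes undirected feature vectors exactly invariant under candidate
reversal, and makes mixed mode with an all-undirected table bit-identical
to undirected mode; a mixed metapath anchored by at least one directed
component keeps its traversal order.

## Predicate directionality table

The packaged table lists 47 predicates: 12 undirected (the published expert
assessment, e.g. "binds with", "interacts with") and 35 directed.  Only
"inhibits" and "catalysis precedes" among the directed predicates are
attested in the published text; the remaining 33 are synthetic stand-ins in
the same vocabulary style, and the data file is labelled accordingly.
Negated predicates ("does not interact with") are categorized automatically
like their de-negated base ("interacts with"); the lookup re-inflects the
verb after stripping the prefix and an explicit entry for a negated form
must agree with its base.  Predicates are compared case-insensitively after
whitespace normalization.  Unknown predicates raise an error by default
(guessing directionality would silently corrupt the mixed variants); an
opt-in flag treats them as undirected.

## Disease mapping

Disease codes are mapped to concept identifiers (a code may map to several
concepts), concepts are expanded with their full transitive subclass
closure via "narrower"/"child" relations (cycle-guarded; a depth-limit flag
supports sensitivity analyses), and the disease protein set is the union of
the curated associations over all expanded concepts.  Diseases with an
empty protein set are unmappable and are dropped before pair construction.
Negative (non-trajectory) candidates are built either as all ordered pairs
of included diseases minus the given positives, or by reversing each
positive unless that reversal is already present.

## Path-extraction conventions

Direct and indirect paths require distinct endpoint proteins; a shared
protein is the overlap scenario and a two-triple excursion a–m–a back to
the same protein is not counted as an indirect path (it would reuse one
protein pair for both legs).  The intermediate protein of an indirect path
may itself be a disease protein of either set (a flag can exclude this).
Parallel edges — several predicates between the same pair, or the same
predicate asserted in both directions — yield distinct path instances;
provenance never multiplies paths.  Each shared protein contributes one
bare `overlap` instance plus one instance per distinct self-loop predicate.

## Evaluation protocol

Random forests (default 500 trees, √p features per split, probability
output; all overridable) classify candidates as trajectory vs
non-trajectory.  Performance is the area under the ROC curve of out-of-fold
class probabilities under 10 repeats of stratified 10-fold
cross-validation.  Stratification is a deliberate choice so that rare
positives appear in every fold at small-cohort scale.  The *same* fold
assignment, derived deterministically from one run seed, is reused by every
feature variant of a run; variants are then compared with a two-sided
paired t-test over the 100 matched fold AUCs (a per-repeat-mean pairing is
available behind a flag, since the pairing granularity is a protocol
choice).  Identical AUCs everywhere are reported as "no difference"
(t = 0, p = 1).  The reported spread is the standard deviation over all
repeat × fold AUCs (ddof = 1); per-repeat means are also exposed.  Class
prevalence is controlled by seeded undersampling to exact class counts.
Operating points are reported at the probability cutoff maximizing the
Youden index J = sensitivity + specificity − 1, computed on pooled
out-of-fold scores of one CV repeat; ties at the maximal J are broken by
higher sensitivity, then lower threshold.

All randomness flows from a single run seed expanded deterministically
(`numpy.random.SeedSequence`) into per-repeat fold seeds and per-fold
forest seeds.

## Synthetic benchmark

The generator emulates the statistical shape of the real inputs with no
download: a protein graph over the packaged 47-predicate vocabulary,
log-uniform disease protein-set sizes (the skew of curated gene–disease
catalogues), a concept mapping/hierarchy in which each disease keeps ~75%
of its proteins on its main concept and the rest on a "narrower" subclass
(so the mapping pipeline is exercised end to end), and labelled ordered
disease pairs.

The planted signal lives **in orientation only**.  The unordered edge
skeleton (which protein pairs connect, with which predicate) is sampled
independently of the labels, so edge existence carries no class information
and undirected variants are a proper chance baseline.  Diseases receive a
latent temporal rank and every positive pair runs from lower to higher
rank, mirroring staged disease progression; this keeps each disease's
proteins on a consistent side of all its trajectories.  For each positive
(A, B), every directed-predicate edge on an A–B path of length ≤ 2 is
oriented subject-on-the-A-side with probability ½ + β/2 (β ∈ [0, 1];
conflicting per-pair preferences cancel, and across pairs each edge takes
the majority preference).  Undirected-predicate edges and unclaimed edges
are oriented uniformly.  Orientation consumes one uniform draw per edge in
a fixed order regardless of β, so runs differing only in β share an
identical skeleton and identical undirected feature matrices — the
property that isolates directionality as the only added information.

Reversal negatives (the positive's diseases in the opposite order) share
all paths with their positive; only the fwd/rev annotation distinguishes
the rows, forcing a classifier to read temporal order from predicate
orientation.  Random negatives never coincide with a reversal of a
positive, and can optionally be *degree-matched* — recombined from the
positives' own disease multisets — which removes disease-marginal
imbalance as a nuisance signal at the cost of inducing slight
anti-correlation between training and test folds; uniform sampling is the
default.

Default study conditions (chosen once): 500 proteins, 50 diseases with 4–25
proteins each (median ≈ 10), background edge probability 0.016 (mean degree
≈ 8, giving each candidate ≈ 1–2 direct and ≈ 10–20 indirect paths),
self-loop rate 0.05, 200 positives + 200 reversal negatives, β = 0.8.
Presets scale the two reference-cohort shapes: `jensen_like` (hospital
registry style: ≥ 50 negatives per positive, set-size median near 29) and
`vandenakker_like` (general-practice cohort style: 55 positives / 370
negatives including one reversal per positive, set-size median near 49).

The null design (`null_benchmark_config`) spreads 200 + 200 candidates over
200 diseases in a 2000-protein graph with homogeneous 12-protein sets and
uniform negatives.  A single finite dataset of this size still shows
chance feature–label association of a few AUC points either way, so null
AUC is estimated as the average over several generator replicates; the
package's own null check uses five replicates of a 2 × 10-fold CV.

What the generator does **not** emulate: the real graph's topology and
degree distribution, literature provenance structure, the true co-morbidity
correlations between overlapping disease pairs, or any edge-existence
difference between trajectories and non-trajectories (a knob exists for
orientation-independent realism but is off by default).  Passing the
planted-signal tests therefore shows that the pipeline *can recover a pure
orientation signal when one exists*, not that real trajectory data carries
one of this strength.

A structural consequence of the all-reversal negative design is worth
noting: positive and reversal rows are identical under undirected features,
so a forest memorizes each row's oppositely-labelled twin and the
undirected variants score *below* chance (near 0) rather than at chance in
the planted experiment.  This makes the mixed-vs-undirected contrast
conservative in direction and very large in magnitude at β = 0.8.

## Problem sizes and numerical choices

The packaged experiments use 200-tree forests (AUC estimates are
indistinguishable from the 500-tree default at these sample sizes), 10 × 10
CV for the planted experiment and 2 × 10 CV per null replicate.  Sparse
int8 matrices hold the features; Matrix Market text files, TSV row/column
glossaries and an optional dense TSV are the on-disk formats.  Fold seeds
and forest seeds stay below 2³¹.  Degenerate inputs are errors, not
silent: single-class label vectors, folds that would lack a class,
mismatched fold maps in a paired test, empty protein sets at featurization,
and unknown predicates in mixed mode.

## Known limitations

* The 35 directed predicates are stand-ins; analyses of real exports must
  supply their own directionality table.
* Indirect paths are capped at one intermediate protein by design; longer
  mechanisms are invisible.
* The Youden operating point is computed on out-of-fold scores of one CV
  repeat rather than a held-out set; at small n it inherits that repeat's
  variance.
* Real reference sets mix reversal and observed non-trajectories; the
  planted benchmark's pure-reversal negative design is intentionally
  adversarial for undirected features and should not be read as a
  performance forecast for real data.
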