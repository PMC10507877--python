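# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `chromphylo`. It is the
design record a maintainer needs; empirical numbers are only those the
test suite and `scripts/acceptance.py` compute themselves.

## Data model

One candidate cis-regulatory element (cCRE) is one independent binary
character: 1 = reproducible ATAC-seq/DNase-seq peak in that cell type,
0 = none. Genomic coordinates identify sites but are never used
arithmetically; synthetic output documents them as BED-style 0-based
half-open intervals. Missing values do not exist in this data model — the
upstream peak index is a complete 0/1 table — so any non-binary token is a
parse error, never an imputation.

The reader takes an explicit list of cell columns and ignores everything
else, because real cCRE tables carry extra annotation columns and their
layout drifts between releases.

## Study system

The hematopoietic panel: LSK stem cells (root and outgroup), myeloid
progenitors CMP/GMP/MEP, terminals Neu, Mon, Ery, iMK, B, TCD4, TCD8, NK.
Lineage paths used for classification are the four myeloid paths through
the observed progenitors (e.g. LSK→CMP→GMP→Neu) and four one-step lymphoid
paths (LSK→B, …), because lymphoid progenitor profiles are not observed.
Tree inference uses the eight terminals plus LSK; the progenitor columns
are held out to validate ancestral reconstructions.

## Site classification

Along one path, a site is STABLE iff constant, UP iff monotone
non-decreasing with ≥1 change, DOWN iff monotone non-increasing with ≥1
change, OTHER otherwise. "Gradually opening" is formalised as monotone
with at least one change — for a binary sequence, exactly one transition
point — the only reading under which a two-step path can never be OTHER.
The cross-path summary uses the precedence OTHER > mixed-direction >
STABLE; sites that are UP on some paths and DOWN on others are recorded
with their direction set ("UP+DOWN") rather than forced into one class.

Two derived masks drive the analysis variants: *OTHER on ≥1 path* (removed
in the "without OTHER" variants, since non-monotone sites are the
homoplasy-prone fraction) and *STABLE on all paths* (removed before
validating reconstructions, since constant sites carry no signal and would
inflate specificity).

## Synthetic generator

The generator is the package's ground truth; it is the minimal process
that produces the four observable site classes.

* STABLE_open / STABLE_closed: constant 1 / 0 rows.
* UP: root closed, exactly one 0→1 event on a branch drawn uniformly at
  random (the known hierarchy has no branch lengths that would justify a
  non-uniform choice), no reversals. DOWN is the mirror image. Single-event
  sites make true ancestral states analytically recoverable and make the
  pairwise difference counts exactly tree-additive — the basis of the exact
  recovery tests.
* OTHER: random root state, independent per-branch flips with probability
  `other_flip_rate` (default 0.25), rejection-sampled until the realised
  pattern is non-monotone on at least one observed path. `other_flip_rate
  = 0` with a positive OTHER share is a configuration error.

Default class mix: STABLE_open 0.10, STABLE_closed 0.35, UP 0.12,
DOWN 0.16, OTHER 0.27. These were chosen once so the realised per-path
tallies loosely resemble published lineage summaries for this kind of data
(UP a few-to-ten percent, DOWN somewhat more, OTHER a quarter to a third
on myeloid paths); they are approximations of figure-level summaries, not
a calibration, and the tests do not depend on their exact values.

Two generating trees are provided: the literal hierarchy with a lymphoid
polytomy, and a fully resolved variant with lymphoid topology
(B, ((TCD4, TCD8), NK)). Recovery tests use the resolved tree, because a
polytomy leaves some splits of a binary inferred tree without any signal
and Robinson–Foulds distance would count their arbitrary resolution as
error. The truth sidecar records internal-node states (including
unobserved lymphoid nodes), per-path generating labels, and every
state-change event with a flag for events on root-incident branches —
where an outgroup, observing only the root state, cannot polarise the
change. Identical seed and config give byte-identical outputs.

What the generator does **not** emulate: continuous accessibility signal,
read-level noise, linkage between neighbouring sites, lineage-specific
rate variation, or population heterogeneity within a cell type. Passing
tests therefore demonstrate algorithmic correctness and the qualitative
effects of homoplasy, not performance on real chromatin data.

## Tree inference

*Distances* are raw pairwise difference counts — deliberately uncorrected,
matching the analysis design this package reproduces.

*Neighbor-joining* wraps the scikit-bio Saitou–Nei implementation;
negative branch-length estimates are clamped to zero, with the clamp count
logged and stored on the tree.

*Parsimony* treats characters as undirected (open→closed costs the same
as closed→open). The exhaustive search enumerates topologies by stepwise
addition — each labelled topology exactly once, (2n−5)!! in total — with a
cap at 10 taxa (2,027,025 topologies); the analysis panel never exceeds
9 leaves. All co-optimal topologies are returned; ties are surfaced, not
silently broken. Above the cap, `mp_search` falls back to NNI
hill-climbing with an explicit warning.

*Likelihood*: reversible two-state model, Q = μ[[−π₁, π₁], [π₀, −π₀]] with
μ = 1/(2π₀π₁) so one unit of branch length is one expected change per site
at relative rate 1. Closed-form transition probabilities
P_ij(t) = π_j + (δ_ij − π_j)e^{−μt}. Rate mixtures: +I (invariant class at
rate 0, weight p_inv), +G (4 discrete-gamma categories, category means),
+Rn (free rates and weights). Rates are normalised so the expected rate
over *all* classes equals 1: (1 − p_inv)·Σ w_k r_k = 1. This keeps branch
lengths and AIC values internally comparable across models; they need not
be bit-identical to any external tool's parameterisation. Frequencies are
ML-optimised by default (empirical frequencies are an option).

Parameter counts for AIC = 2k − 2lnL: frequencies 1; +I adds 1; +G adds 1;
+Rn adds 2n−2; branch lengths 2·n_taxa−3 for every model (topologies are
always fitted in unrooted form, so the two root-adjacent half-branches of
a rooted input are fitted as one edge and re-split at the midpoint on
return).

### Numerical choices

* Branch-length bounds [1e−8, 100] expected changes/site.
* Per-branch optimisation: the likelihood saturates on long branches, so a
  plain bounded line search can stall on the flat tail; each branch is
  first scanned on a 21-point geometric grid and then refined by a bounded
  search (in log space) around the best grid point.
* Coordinate ascent over branches, π₁, p_inv, α (log-scale) or the free
  rates/weights (L-BFGS-B on log/softmax coordinates); every step is
  accepted only if it improves lnL, so lnL is non-decreasing by
  construction. Convergence: lnL improvement < 1e−6 per sweep; cap 100
  sweeps, with a warning and a best-so-far result on non-convergence.
* Pattern compression: likelihoods are computed over unique site patterns
  with multiplicities (at most 2^n_taxa ≤ 512 patterns for the 9-leaf
  panel), which bounds runtime regardless of site count.
* Topology search: NNI hill-climbing from the NJ tree, refitting after
  each accepted move; exhaustive mode for ≤ 8 taxa.

*Bootstrap*: sites resampled with replacement, one RNG stream keyed by the
seed; the support of each internal split of the point-estimate tree is the
percentage of replicate trees containing it. Replicate trees are not
stored. For the MP method the first co-optimal tree in deterministic
enumeration order represents each replicate.

## Ancestral reconstruction

On the fixed constraint topology
(LSK, ((B, ((TCD4, TCD8), NK)), ((Neu, Mon), (Ery, iMK)))) rooted on LSK,
with internal nodes mapped CMP = myeloid MRCA, GMP = MRCA(Neu, Mon),
MEP = MRCA(Ery, iMK).

*Parsimony.* Subtree change costs come from a vectorised Sankoff pass;
the preorder resolution then chooses, at every branch where the minimum
allows either, a change (ACCTRAN — accelerates changes toward the root) or
no change (DELTRAN — delays them toward the tips). Both resolutions always
realise the Fitch minimum; the test suite verifies they are exactly the
change-first / change-last lexicographic extremes over the complete
enumerated set of minimum-change labelings. An ambiguous root set is
resolved toward the outgroup's observed state — the outgroup is rooted
precisely to polarise changes.

*ML marginals.* P(open) at each internal node combines below-likelihoods
(pruning) and above-likelihoods, mixed over rate categories by their
per-site posterior weights; the invariant class contributes only at
constant patterns, where it pins the node to the constant state. Calls are
the argmax state; "ambiguous" defaults to an exact tie (|P − ½| ≤ 1e−9),
with an optional minimum-posterior threshold mode for sensitivity
analysis, since the exact ambiguity rule of external tools is not
published. Ambiguous-call counts are reported per node.

Branch lengths and model parameters for the constraint tree are fitted
from the terminal + LSK columns only; the progenitor columns are held out,
mirroring the design of predicting progenitors from differentiated cells.

## Validation and treelikeness

Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) with open (1) as
the positive class. Ambiguous calls and everywhere-STABLE sites are
excluded; a site hit by both masks is removed once and reported on its own
overlap line. Undefined ratios (empty denominator) are reported as
not-applicable rather than 0.

δ-plots: per quartet, δ = (m₁−m₂)/(m₁−m₃) on the ordered pairwise-distance
sums; δ = 0 when m₁ = m₃ (all three sums equal), the limit-consistent
"perfectly treelike" value. Both the per-quartet distribution, the grand
mean and per-taxon means are emitted — no single scalar is privileged.
Lymphoid treelikeness is computed over {LSK, B, TCD4, TCD8, NK}, myeloid
over {LSK, Neu, Mon, Ery, iMK}.

Robinson–Foulds distances are computed from the package's own canonical
split sets and cross-checked against dendropy in the tests (the
implementation and the oracle stay separate).

## Pipeline and problem sizes

`run_analysis` executes: input (simulate or load) → classification →
tree inference for each method × {all sites, without OTHER} × {full panel,
without iMK} → ancestral reconstruction on the constraint tree after
dropping everywhere-STABLE sites → validation against progenitor columns
(all sites and without OTHER) → δ summaries → lineage-specific
branch-change counts. All randomness descends from the configured seed;
reruns are byte-identical up to timestamps.

Default problem sizes are chosen for interactive turnaround: the demo
configuration simulates 2,000 sites; the acceptance script uses 4,000
sites, 200 bootstrap replicates and 20-replicate batches for the
directional comparisons. Pattern compression makes likelihood costs
insensitive to site count, so these sizes already produce stable
statistics (binomial standard errors < 1%).

## Known limitations

* Sites are treated as independent; real cCREs are linked along the
  genome and co-regulated.
* The two-state model assumes a single reversible process shared by all
  branches; no covarion-style or branch-specific behaviour.
* Exhaustive searches (MP, ML) are capped at 10 and 8 taxa; beyond that
  only NNI hill-climbing is available, without optimality guarantees.
* The ML ambiguity rule is a documented in-package convention (exact tie
  by default); counts of ambiguous sites are therefore not comparable
  across tools that use different, unpublished rules.
* The generator's OTHER class is a per-branch flip model — adequate for
  producing homoplasy, not a mechanistic model of enhancer turnover.
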