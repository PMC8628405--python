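# Methods

## Scope and design

The package chains five stages: pairwise/progressive alignment, reference-
numbered site mapping, per-sequence functional classification, distance-based
tree inference with bootstrap clade assignment, and a generative simulator
that produces ground-truthed inputs for all of the above.  The heavy
inference used for published opsin phylogenies (ML tree search under
empirical or data-set-specific matrices, Bayesian sampling, AU tests) is
deliberately out of scope; the tree stage here is a desk-scale, fully
deterministic stand-in whose outputs are always labeled
"NJ + Poisson distance, nonparametric bootstrap" so they cannot be conflated
with ML bootstrap percentages or posterior probabilities.

## Alignment model

Global alignment uses the three-state Gotoh dynamic program.  A gap of k
columns costs `gap_open + k*gap_extend`, i.e. opening and the first
extension are both charged; defaults are `gap_open=11`, `gap_extend=1` with
BLOSUM62 (loaded from Biopython), the standard protein setting.  Terminal
gaps are penalized exactly like internal gaps: site mapping needs end-to-end
coordinates, and un-penalized overhangs would let queries slide.  Traceback
tie-breaking is fixed (diagonal, then gap-in-query, then gap-in-reference)
so identical inputs always give identical alignments.  `X` is accepted as a
wildcard scoring 0 against everything and never counts as a site match;
any other non-alphabet symbol is rejected with its position.  The module
also carries an explicit brute-force enumerator (`exhaustive_best_score`)
and an independent objective evaluator (`alignment_score`); the test suite
holds the DP to exact agreement with the enumerator on short sequences and
cross-checks it against Biopython's `PairwiseAligner` on longer ones.

The progressive MSA aligns all pairs, builds an NJ guide tree on the
pairwise p-distances, and merges profiles post-order with profile–profile
alignment (column score = mean pairwise residue score, gaps scoring 0;
once-a-gap-always-a-gap).  It is a guide-order heuristic, not an optimal
MSA; the simulator's no-indel regime keeps its job easy by construction.

Manual alignment curation (as practiced with real data) is replaced by an
automatic, reproducible column-occupancy filter: columns with a non-gap
fraction below `min_occupancy` (default 0.5) are dropped before distances.

## Site mapping and classification

A reference scheme is a reference protein plus named sites in its 1-based
numbering.  Two schemes are packaged:

* `bovine_rhodopsin` — the genuine 348-aa Bos taurus rhodopsin (UniProt
  P02699); counterion E113; coupling pairs D83/N302, R135/Y223, K231/E247,
  Y306/F313; NPXXY anchors N302/P303/Y306.
* `human_RLBP1` — the ten retinoid-binding-critical residues (W166, Y180,
  F198, C199, M209, Q211, M223, V224, M226, W245) in human RLBP1 numbering,
  on a **synthetic backbone**: a fixed pseudo-random 317-residue sequence
  carrying the ten residues at their literature positions.  Mapping and
  scoring behave exactly as against the real protein, but conservation
  tallies of *real* orthologs are only meaningful against the genuine
  P12271 sequence, which users must supply as their own scheme config.

Queries are mapped by pairwise alignment to the scheme reference (not
through an MSA), which keeps calls order-independent of whatever other
sequences are in the input.  "Conserved" means identity with the site's
expected residue set, defaulting to the single reference residue; the
config format accepts larger sets for a similarity-based mode.

Classification rules:

* counterion: observed in {E, D} → charged → monostable-like (D is the only
  other negatively charged residue); any other residue → uncharged →
  bistable-like; a gap or the X wildcard → indeterminate.  X is treated as
  ambiguity rather than as "some uncharged residue" because transcriptome
  translations routinely contain it.
* pairs: intact iff both members match; indeterminate iff both members are
  unaligned; broken otherwise (one absent member is a deviation, matching
  how complete residue loss is interpreted in real RGR sequences).
* motif: intact iff all three anchors match; indeterminate iff all three are
  unaligned; broken otherwise.
* `signaling_intact_count` = intact pairs + intact motif (0–5);
  indeterminate never contributes.
* `rlbp1_score` = matches among the ten critical sites (0–10); unaligned
  counts as non-match.  Exactly ten critical sites are required.

## Tree stage

Distances are Poisson-corrected p-distances, `d = -ln(1 - p)`, computed over
columns non-gap in both rows.  p is capped at 0.95 (logged) because the
correction diverges as p → 1; saturated pairs thus share a finite ceiling of
`-ln(0.05) ≈ 3.0`.

Neighbor joining follows the Saitou–Nei Q criterion with Studier–Keppler
distance updates.  Determinism is enforced structurally: node sums and the
Q scan run in lexicographic order of cluster representative labels and exact
Q ties are broken by the lexicographically smallest label pair, so the tree
is invariant to input row order.  A negative branch-length estimate is
clamped to zero with the deficit moved to its sister branch, preserving path
lengths through the joined node.

Clade assignment roots the tree on the edge whose one side holds the most
outgroup leaves (fewest non-outgroup leaves as tie-break — this is the
outgroup-MRCA edge whenever the outgroup is monophyletic, and degrades
gracefully on bootstrap replicates where it is not; remaining ties fall back
to label order).  A query is assigned to clade C iff the smallest rooted
clade containing the query and at least one reference leaf contains only C
references besides the query; anything else is "unassigned".

Bootstrap support is a plain nonparametric bootstrap with a fixed replicate
count (default 100) and a mandatory seed: columns are resampled with
replacement, distances/NJ/assignment recomputed, and the modal label's
replicate fraction reported (modal ties give "unassigned"; replicates where
some pair shares no columns are excluded and counted).

## Simulator

Sequences evolve along a user-supplied rooted tree under the 20-state
equal-exchangeability CTMC with uniform stationary frequencies.  Over a
branch of length t (expected substitutions/site) a site changes with
probability `p_diff(t) = (19/20)(1 - exp(-(20/19) t))`, uniform over the 19
alternatives — the closed form the calibration tests check at 3 binomial
standard errors.  There is no indel process, so the true alignment equals
the leaf sequences and oracle tests stay exact.  Planted sites are set to a
clade's residue at the clade's stem (MRCA) and held invariant below it,
emulating clade-diagnostic contrasts (charged vs uncharged counterion,
present vs absent critical residues).  Uniform frequencies rather than an
empirical matrix are a deliberate simplification: they admit closed-form
checks, and no pipeline stage assumes the generative model.

What the simulator does **not** emulate: indels and alignment uncertainty,
rate heterogeneity across sites, realistic amino-acid composition, or the
taxon sampling of real opsin datasets.  Passing recovery tests therefore
demonstrates the machinery is correct and internally consistent — not that
site calls on deeply divergent real sequences are error-free.  In
particular, at large query-to-reference divergence (p-distance beyond
roughly 0.6) optimal global alignments can place compensating gap pairs
across a site and shift its mapping; profiles of such sequences should be
read together with their alignments.

## The recovery experiment (reference conditions)

Defaults: four clades of three reference leaves plus one held-out query
each, a two-leaf outgroup, 200 sites, 50 trials, bootstrap 100.  The tree is
a star of clade stems — the only internal branches are the five stems
(outgroup + four clades) of length 0.3 — with 0.1 terminal branches, so
root-to-leaf divergence is 0.4 and reference-numbering mapping is
unambiguous at 200 sites.  Planted truth: counterion E in cladeA, F/Y/S in
cladeB–D; ten critical sites at 10/8/6/3 intact per clade (non-intact sites
planted L).  Each query is profiled against a scheme whose backbone is the
trial's root sequence with the expected residues imposed, and is
bootstrap-assigned on the filtered MSA restricted to references + outgroup +
that query, so the strict purity rule is not confounded by the other
held-out queries.  Metrics are fractions over trials x queries of correct
clade labels, correct counterion states, and exactly recovered scores.

## Numerical and degenerate-input choices

* Alignment DP uses -1e300 as the unreachable-state sentinel; scores are
  float64 throughout.
* Q-scan tie tolerance is 1e-10 (relative); additive-matrix tests require
  path-length recovery at 1e-9.
* Newick round-trips format branch lengths with 10 significant digits.
* Empty-vs-nonempty alignment is allowed (one affine gap); empty-vs-empty is
  an error.  Zero shared non-gap columns is an error for p-distance and a
  recorded, excluded replicate inside the bootstrap.
* Profiling a scheme reference against itself must be all-match (asserted in
  tests for both packaged schemes).

## Known limitations

* Progressive MSA quality degrades with real indel-rich data; no iterative
  refinement is implemented.
* NJ supports are not comparable to ML/Bayesian supports; the package never
  claims to reproduce published tree topologies or support values.
* The packaged RLBP1 scheme's synthetic backbone cannot be used to tally
  real orthologs; a genuine P12271-based scheme is required for that.
* Bistability prediction from the counterion alone is a sequence-level
  heuristic; its biochemical reliability is limited and the output labels
  are accordingly "-like" predictions, not assays.
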