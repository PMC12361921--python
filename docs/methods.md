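# Methods

`cytodisc` detects and characterizes reticulate taxa — hybrids,
introgressants, chloroplast-capture products — from the disagreement
between plastid and nuclear (ITS) signal in a single concatenated
alignment.  This note documents the model, the algorithmic and numerical
choices, and what the synthetic benchmarks do and do not establish.

## The three-phase procedure

**Phase 1 — conflict scan and core phylogeny.**  Maximum-likelihood trees
are inferred separately from the plastid-class and nuclear-class columns,
with per-edge support from the approximate-Bayes (aBayes) test and,
optionally, a nonparametric bootstrap.  A *hard conflict* is a pair of
strongly supported splits, one per class tree, that cannot be displayed on
any single tree over the shared taxon set (all four intersection blocks of
the two splits non-empty).  Strong support means bootstrap ≥ 95 % and/or
aBayes ≥ 0.95; by default either criterion suffices (`mode="or"`), and both
thresholds and the mode are configurable.  Conflicts are attributed to
specimens by greedy leave-one-out: candidates are the taxa appearing in a
smallest intersection block of at least one conflict; for each candidate
both class trees are re-inferred without it, and the specimen whose removal
resolves the most conflicts is flagged (ties broken lexicographically; a
candidate that resolves every current conflict is accepted immediately,
which is equivalent under the tie-break rule).  Resolution is judged after
restricting the earlier conflict to the surviving taxon set, so a conflict
does not count as "resolved" merely because the taxon labels changed.  The
*core phylogeny* is then inferred from all regions combined, using only the
congruent specimens; combining is guarded by a hard invariant — if the
reduced class trees still show a strong conflict, core construction fails
rather than silently concatenating discordant data.

**Phase 2 — taxon duplication and placement.**  Every flagged specimen
re-enters as two single-class entries (`X_PL`, `X_ITS`), the complementary
class coded missing.  The default screen holds the core topology and branch
lengths fixed: the entry is attached at the midpoint of each core edge, its
pendant branch length is optimized (bounded 1-D search), and per-edge
likelihoods are normalized into likelihood weight ratios (LWR).  Each
specimen is screened with no other flagged specimen present, so placements
cannot confound one another and are order-independent by construction.
`expanded_inference` is the faithful full-re-search mode: core taxa plus one
group's duplicated entries, starting from the screened placements, with a
complete NNI search and fresh supports.

**Phase 3 — classification.**  Placements are labelled against named core
clades — user-supplied by exemplar pairs (unrooted MRCA convention) or
auto-generated as the maximal disjoint strongly supported core clades.  An
edge inside (or at the stem of) clade `A` is labelled `A`; a backbone edge
is labelled `between(X,Y)` by the two topologically nearest named clades.
Specimens are grouped two ways: *patterns* are exact
(plastid clade, ITS clade) pairs; *expanded datasets* are connected
components of "shares a clade destination in either class" — deliberately
coarser, because a homogenized ITS clade spanning divergent plastid donors
is only observable when its members co-occur in one expanded tree.  A
*floating ITS group* is a maximal strongly supported clade of the expanded
tree that contains ≥ 2 duplicated ITS entries, no core taxa, and whose
members' plastid entries are assigned to ≥ 2 distinct named clades.

## Substitution models and likelihood

The model family is JC, K80, HKY, GTR, each optionally with discrete-gamma
rate heterogeneity (K equal-probability categories; category rates are the
conditional means computed from the incomplete gamma function and average
exactly to 1).  Q is always rescaled to one expected substitution per site
per unit branch length, so lengths are comparable across models.  HKY/GTR
use empirical base frequencies (+F, with a one-count pseudofrequency);
selection among candidates is by AIC on a fixed topology with
free-parameter counts JC 0, K80 1, HKY 4, GTR 8, +Γ +1 (branch lengths
excluded — all candidates share the same branch set).  Richer components
seen in real-data model selection (+I, free-rate +R) are intentionally
outside the family: GTR+Γ is the family's supremum and the pipeline's
conclusions ride on topology and support, not on fine model identity.

Likelihoods are computed by Felsenstein pruning over site patterns
(columns compressed to unique patterns with weights).  Ambiguity codes
become indicator vectors over their compatible states; `-`, `?` and `N`
are all-ones (missing).  Per-node rescaling with per-pattern log
accumulators prevents underflow; the total log-likelihood is invariant to
the traversal root (tested to 1e-9) and matches exhaustive enumeration
over internal-node states to 1e-8 on random instances.

Branch lengths are optimized coordinate-wise by bounded Brent search on
the per-edge likelihood assembled from two-directional conditional
vectors; each 1-D step is accepted only if it does not lower the
objective, so the log-likelihood is non-decreasing across sweeps.  Bounds
are [0, 10] expected substitutions/site; saturated pairwise distances are
capped at 5.0.

## Tree search and supports

The search is deliberately simple and deterministic: a neighbor-joining
starting tree from JC distances (exact on additive matrices; Q-criterion
ties broken toward the lowest cluster-index pair; negative length
estimates clamped to zero), then a steepest-ascent NNI hill-climb.  Both
NNI resolutions of every internal edge are scored from the four message
vectors meeting at that edge, with only the central branch length
re-optimized — the standard quartet shortcut, which makes a move
evaluation O(1) likelihood contractions instead of a full tree pass.  The
best improving move is applied and the scan repeats until no move improves
the log-likelihood by more than 1e-6 (bootstrap replicates use trimmed
search settings).  Partitioned analyses sum per-region engines that share
one tree; per-region rate multipliers are profiled by 1-D optimization and
renormalized to a weighted mean of 1, with branch lengths rescaled
accordingly.

aBayes support for an edge is the softmax weight of the best of the three
NNI resolutions under a uniform prior, hence always in [1/3, 1].  The two
alternative resolutions get the central branch re-optimized; the current
resolution keeps its globally optimized length (it is already at a
full-length optimum, so a local re-pass cannot improve it beyond
tolerance).  Bootstrap support resamples columns with replacement *within
each partition region* (region sizes preserved), re-infers every replicate
(NJ + fast NNI), and reports the percentage of replicates displaying each
reference split.  The run-directory default is 200 replicates — far below
the 10,000 of a publication-grade analysis and chosen for desk-scale
turnaround; with `mode="or"` an aBayes-only screen (`B=0`) is equivalent in
its strong-call behaviour and is what the validation studies use.

## Synthetic benchmarks

The generator emulates the data shape of a two-class grass supermatrix:
four plastid spacer/intron regions sharing one gene tree (a single
non-recombining plastid) and a faster-evolving nuclear ITS region with its
own gene tree.  Species trees are Yule (pure-birth) trees started from two
lineages; branch lengths are rescaled so the mean root-to-tip path is
0.15 expected substitutions/site, then floored at 0.01 — the floor defines
"strong signal": every internal edge carries tens of expected
substitutions across a class alignment, so true edges are resolvable.
Hybridization is clean tip-regrafting: per class, the hybrid tip is pruned
and reattached at the midpoint of its donor edge with a 0.02 pendant, so
the ground truth is unambiguous.  Donor edges respect a minimum
topological separation (default 4, midpoint convention: edges sharing a
node are at distance 1).  Three scenarios: `capture` (ITS stays at the
original position, the plastid jumps — classic chloroplast capture),
`shared_its` (hybrids also move their ITS to one shared donor edge,
stacking into a cherry — the floating-ITS setup), and `shared_all` (both
donor edges shared).  Default conditions: 24 taxa, 2 non-sister hybrids,
4×500 bp plastid + 800 bp ITS (ITS rate multiplier 2 — mirroring the
roughly five-fold plastid/ITS column ratio and the higher ITS information
density of real matrices), GTR+Γ4 with mildly uneven exchangeabilities and
AT-rich composition, no missing data.  Missing whole regions (coded `?`)
and lognormal branch-length jitter are available but off by default.

What the benchmarks do *not* emulate: incomplete lineage sorting and gene
flow (gene trees differ from the species tree only by the planted
regrafts), indel evolution and alignment error (data are simulated
aligned), intra-individual ITS polymorphism, and partial genomic
introgression.  Passing the recovery studies therefore shows the pipeline
correctly reads clean reticulation signal of realistic size — not that it
separates hybridization from ILS on real data, which the descriptive
classification deliberately does not attempt.

## Validation study sizes

The recovery studies run 20 replicates of each condition: the full
pipeline on `capture` bundles (flag sensitivity, per-replicate false-flag
rate, placement adjacency to the true donor edges), `shared_all` bundles
for pattern grouping and the floating-group null, and 16-taxon
`shared_its` bundles for floating-group recovery (phases 2–3 scored with
truth-derived flags, since flagging accuracy is measured separately).  The
acceptance script recomputes the same metrics at 8/6/4 replicates.  The
likelihood oracle uses 100 random instances of ≤ 5 taxa and ≤ 25 sites;
split compatibility is checked against exhaustive display over all 945
seven-taxon topologies; NJ exactness over 100 additive 8-taxon matrices;
bootstrap monotonicity over 100 replicates at lengths 500/2000/8000 with
B=100.

## Numerical choices and degenerate inputs

* Optimizer tolerances: final branch sweeps xatol 1e-4–1e-6 with capped
  Brent iterations; NNI/aBayes screens xatol 1e-2–1e-3 (move ranking needs
  far less precision than final lengths).  Model-parameter fits use
  Nelder–Mead on log-parameters.
* Pattern likelihoods are floored at 1e-300 before logs; engine-internal
  P(t) skips row renormalization (eigh roundoff ~1e-15), while the public
  `transition_matrix` clips and renormalizes exactly.
* A duplicated entry with no informative columns places with a uniform LWR
  and a warning; a specimen lacking a whole class yields a single entry.
* Taxon pairs with no shared defined columns raise a missing-distance
  signal rather than returning 0.
* Attribution that exhausts its candidate set with conflicts remaining
  reports "unattributable conflicts" instead of forcing removals.
* All randomness flows from one seeded generator per run; bundles are
  byte-identical under a fixed seed, and a repeated `run_all` reproduces
  its output checksums.

## Known limitations

Steepest-ascent NNI can stop at local optima that SPR/TBR would escape;
the greedy leave-one-out attribution is a formalization of "individual
testing" and may mis-attribute when several specimens jointly cause one
conflict; `between(X,Y)` labels formalize narrative "sister to"
placements and need not match an author's prose; and the descriptive
classification makes no claim about process (hybridization vs ILS vs gene
flow).
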