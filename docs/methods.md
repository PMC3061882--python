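# Methods

This note records the models, conventions and numerical choices behind
`maxpars`, in the order a user meets them.

## Character model and scoring

A character is a column of state sets over taxa: singleton = fixed
scoring, multi-element = polymorphism, empty = missing (`?`; the
inapplicable symbol `-` is read as missing, the PAUP*/TNT parsimony
default).  States are integers 0–9.  Unordered characters change at unit
cost; ordered characters cost the absolute state difference, the
morphocline assumption.  Both step functions are metrics (symmetric, zero
diagonal, triangle inequality), so tree length is invariant to rooting
and child order — asserted by tests on random instances.

Lengths are computed by the Sankoff dynamic programme over the 10-state
alphabet, vectorised with numpy across characters.  A missing leaf has an
all-zero cost vector; a polymorphic leaf is zero on its member states.
Multifurcating nodes are scored *as given* (minimum-cost assignment on the
multifurcating tree).  This is the convention under which the star tree
realises a character's maximum conceivable length `g_c`, which the
ensemble indices require; it is *not* in general the minimum over binary
resolutions (a four-leaf star on states 0,0,1,1 scores 2 while its best
resolution scores 1).  The two conventions coincide on the polytomies
this package itself produces (see "Collapse rule").

Per-character bounds: `m_c` is the fewest steps any tree allows — for
unordered characters one less than the smallest number of states that can
cover every scored cell (polymorphic cells may settle on any member,
found by subset search over the ≤ 10 states), for ordered characters the
smallest achievable observed range; `g_c` is the star-tree length,
`min_v Σ_t step(cell_t, v)`.  `CI = Σm/Σs`, `RI = (Σg−Σs)/(Σg−Σm)`,
`RCI = CI·RI`; a zero `Σs` reports CI = 1 (perfect fit), a zero RI
denominator reports RI = 1.  Whether uninformative characters enter the
sums is a flag (`include_uninformative`), since both conventions
circulate; characters with `g = m` contribute nothing to the RI sums
either way.

## Search engine

Topologies are nested tuples over taxon indices, rooted on a designated
leaf (the constrained outgroup; only the outgroup's position is fixed, no
further outgroup structure is imposed).  The scorer packs every unit-cost
character into one big integer, 10 bits per character, and runs Fitch
with word-parallel bit operations.  Ordered characters are decomposed
into additive binary factors (threshold indicators), which is exact
whenever polymorphic scorings form contiguous state intervals — checked
per character, with a Sankoff fallback for the rare non-interval cells.
The packed scorer and the general DP are cross-checked on random trees.

*Heuristic*: random-addition-sequence Wagner construction (greedy
insertion, first-best tie-break) refined by best-improvement SPR to a
local optimum; deterministic given the seed; replicates share one RNG.

*Branch and bound*: taxa are added most-complete-first (alphabetical
tie-break, stated for reproducibility).  A partial tree on taxon set *P*
is pruned when its length plus `Σ_c (m_c(all) − m_c(P))` — the extra
steps the unplaced taxa must create, an admissible bound — exceeds the
incumbent, initialised by a quick heuristic run.  All optimal trees are
collected (ties are explored), up to `max_trees` (default 10,000).
Enforced clades prune partial trees as soon as a non-member is trapped
inside the clade's spanning subtree (irreparable); prohibitions are
checked on complete trees.  Exactness is verified against full
enumeration on a hundred random 6–8-taxon matrices.

*Constraints*: a clade is enforced/prohibited in the rooted sense
(relative to the outgroup).  Clades must have 2 to n−2 members — the full
ingroup is present in every outgroup-rooted tree, so prohibiting it is
unsatisfiable and Bremer support for it undefined.

## Collapse rule and tree identity

After a search, every branch of a binary optimal tree whose minimum
length over all most-parsimonious assignments is zero is contracted (a
branch qualifies exactly when contracting it alone leaves the length
unchanged, which is how it is tested; the branch spanned by a degree-2
root is one unrooted edge and is contracted as one).  All qualifying
branches are contracted in a single pass.  The collapsed tree is a
summary of its binary resolutions: the optimum is always among those
resolutions, but re-scoring the polytomous summary directly can exceed it
when nested branches were individually, not jointly, zero — the test
suite demonstrates such a case at six taxa and therefore checks collapse
against the minimum over refinements.  Distinct MPTs are counted on
bipartition sets after collapse, making "a single MPT" well defined.

## Support

Bootstrap replicates resample characters with replacement (original
count), keeping each character's ordering flag, and re-run the heuristic
search with the caller's settings; each replicate is summarised by the
strict consensus of its optimal trees (conservative; majority-rule is a
flag) and a reference clade scores the percentage of replicates whose
summary contains it.  Bremer support is computed exactly, one converse
(prohibit) branch-and-bound per clade — exactness over speed.

## Stratigraphic congruence

Ages are in Ma, larger = older.  Nodes are dated to the oldest descendant
FAD.  `MIG = Σ_edges (age(parent) − age(child))`, the summed ghost-lineage
duration; note the perfectly age-ordered ladder still has `MIG` equal to
the total FAD range `L_min` (its ghosts are unavoidable), so the
congruence metrics work with the *excess* `MIG − L_min`:

* `G_min = L_min` (any root-to-youngest path telescopes to at least the
  range; the ladder attains it) and `G_max = Σ_i (oldest − FAD_i)`
  (attained when the oldest taxon is nested deepest, every other lineage
  ghosting back to it).  Both closed forms are verified against
  exhaustive enumeration of rooted topologies in the tests, which also
  makes interval ranges cheap.
* `GER = 1 − (MIG − G_min)/(G_max − G_min)`; degenerate spread (all FADs
  equal) reports 1.
* `MSM* = L_min / L_obs`, where `L_obs` is the optimised length of the
  FAD character under irreversible (toward-younger only) parsimony,
  computed by a prefix-minimum Sankoff pass over the sorted age values.
  `L_obs = MIG` identically (raising any node above its oldest descendant
  strictly increases cost), giving the closed form
  `MSM* = L_min/(L_min + excess)` that the tests check against the DP.
* `SCI` counts non-root internal nodes whose subtree FAD is no older than
  the oldest FAD among their siblings; ties are consistent (otherwise
  undefined), leaves are not scored, the root is excluded.

Point metrics default to the *oldest* interval bound of each taxon's
first appearance.  Interval uncertainty is propagated by evaluating the
metric at every combination of per-taxon interval endpoints (2^n cases,
exact because each metric is monotone in each FAD between endpoints;
verified against dense enumeration at 9 taxa); the exact enumeration is
capped at 15 taxa, beyond which an explicit coordinate-descent
approximation must be requested.  The permutation test reassigns the FADs
across leaves; Monte-Carlo p-values use (r+1)/(n+1) with the observed
arrangement included, and complete enumeration replaces sampling whenever
n! permutations fit the budget.

A stage-boundary lookup (Middle Jurassic–Cretaceous, 2009-era chart
values) converts stage assignments to Ma intervals.

## Body size

A taxon is larger-bodied when *every* available measurement exceeds its
threshold (10 m body, 1 m skull, 1 m femur), smaller when any available
measurement is at or below, unknown with none.  The conjunctive reading
matters for exactly one case-study taxon: *Allosaurus* (skull 100.8 cm
but body 970 cm) stays smaller-bodied, as the source analysis classifies
it.  Estimated and measured values are treated identically.  Fitch
optimization treats unknown as free; optimal binary reconstructions are
enumerated (feasible at case-study size) to report whether the changes
are gains, losses, or ambiguous in direction.

## Synthetic data

`simulate_tree` draws uniformly over rooted binary labelled shapes by
uniform edge insertion.  `simulate_matrix` evolves each character with a
fixed per-edge change probability (uniform redraw if unordered, ±1 step
if ordered) — an Mk-like process without branch lengths, because
parsimony testing needs homoplasy control rather than rates — then masks
per-taxon missing fractions without touching the underlying states.
`simulate_ages` builds perfectly congruent FADs by declining ages along
one lineage per node (off-path subtrees tie at the node's age, so
SCI = GER = MSM* = 1 by construction) and shuffles them for the null
mode; intervals always contain their point FADs.

The packaged study-scale generator produces 18 taxa × 177 characters,
mostly binary with 13 ordered characters, and the per-taxon missing-data
profile of the case study (two near-complete taxa at 0 %/6 %, three
fragmentary ones above 80 %, worst 91.5 %).  What these simulations do
not emulate: correlated characters, clock-like rates, character-state
ascertainment, or real polymorphism frequencies — so passing tests show
algorithmic correctness and desk-scale calibration, not robustness to
every property of real matrices.  "Low homoplasy" in the recovery
experiments means a per-edge change probability of 0.01 (under one
expected change per character at 8 taxa), where ≥ 90 % of runs keep the
generating topology in the certified optimal set.

## Problem sizes

Exhaustive enumeration is capped at 9 taxa (≥ 2,027,025 shapes at 10).
The test suite uses 6–8 taxa wherever an enumeration oracle backs the
check, 50 replicates for recovery rates, and hundreds (not thousands) of
bootstrap replicates; the acceptance script runs the case study at its
natural size (12 taxa, 2^12 endpoint combinations, 1,000 permutations)
and the synthetic end-to-end search at 18 × 177 with five heuristic
replicates.  These sizes were chosen as the package's desk-scale
defaults; all scale up by argument.

## Known limitations

* No implied weighting, likelihood or Bayesian scoring (out of scope).
* Hard-polytomy input trees are scored as such; soft semantics are only
  guaranteed for polytomies produced by the collapse rule.
* The branch-and-bound completion bound ignores interactions between
  unplaced taxa; pathological matrices (all characters uninformative
  until late additions) degrade it to near-enumeration.
* The bootstrap uses heuristic replicate searches; replicates that fail
  to find their optimum can understate support slightly (mitigated by
  `search_replicates`).
* The case-study age table is a reconstruction from stage assignments,
  not a transcription of the original supplement, and the original
  character matrix is not distributed; printed search statistics that
  need it are checked only when a user supplies a transcription.
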