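# Methods

This note documents the models and procedures implemented in `rnaneutralset`,
the parameters that matter, the numerical choices, and what the validation
machinery does and does not show.

## Secondary-structure model

Structures are nested dot-bracket strings: hairpin loops enclose at least
three unpaired bases, pseudoknots are excluded, and — by default everywhere in
this package — every base pair belongs to a helix of at least two adjacent
pairs ("no lonely pairs"), since isolated pairs cannot form stabilising stacks
and are thermodynamically marginal.  Positions are 0-based internally.

Loop decomposition assigns every unpaired base to exactly one loop (hairpin,
bulge, internal, multi, exterior); the exterior loop is always present, even
when empty.  From the decomposition three counts drive the estimator:

* **n_bp** — number of base pairs;
* **n_stack** — stacking free-energy terms: one per pair of directly adjacent
  base pairs, plus one per length-one bulge bridging two helices (the Turner
  model attaches energies to stacking interactions, not to pairs themselves).
  The *number of stacks* (used as a baseline indicator) instead counts maximal
  runs of adjacent pairs, so a length-one bulge separates two stacks while
  still carrying a bridging stacking term;
* **n_eos** — "end-of-stack" terms, a merged stand-in for dangling ends and
  terminal mismatches: one per stack end facing a hairpin of length ≥ 4, one
  per stack end facing an internal loop with ≥ 2 unpaired bases on each strand
  and ≥ 3 on the longer strand, and one per stack end at a multi-loop or
  exterior loop (no length condition).  Stack ends facing bulges receive no
  term — the qualifying loop list is exhaustive, and bulges are not on it.
  A 2×2 internal loop therefore contributes nothing; a 2×3 contributes one
  term per adjacent stack end.

## Loop free energy G_loop

`G_loop` sums Turner-2004 loop *initiation* terms over all loops: hairpin,
bulge and internal initiation by size (tabulated to size 30, extrapolated as
G(s) = G(30) + 1.07856·ln(s/30) beyond), the internal-loop asymmetry penalty
0.6·|s1 − s2| capped at 3.0 kcal/mol, and the linear multiloop model
9.3 − 0.9·(branches, closing pair included) + 0.0·(unpaired) kcal/mol.
Exterior loops contribute nothing.  All sequence-dependent loop terms
(tetraloop bonuses, special 1×1/2×2 tables, AU end penalties, coaxial stacks)
are deliberately dropped so that G_loop is a pure function of the structure.
Multiloop initiation *is* included: it is an initiation free energy, and
omitting it would only shift G_loop by a constant per multiloop.  Every
contribution, and the final sum, is rounded to 0.1 kcal/mol (the resolution of
the parameter tables).

The parameter tables ship as a trimmed plain-text `.par` file
(`data/turner2004_loops.par`) so the estimator needs no folding engine; any
file in the same dialect can be substituted via `load_params`.

## The set-size estimator

For a structure A and cut-off x (all energies signed, stabilising negative):

1. `G_max = x − (G_loop − a·n_eos)` with a = 0.5 kcal/mol — every end-of-stack
   term is assumed to supply at least that much stabilisation.
2. `G_stacking = G_max / n_stack` is the stabilisation each stacking term must
   deliver.
3. If `G_stacking ≥ −0.5` (the least stabilising stacking term worth counting)
   no sequence constraints are needed: v_bp = v_eos = 1 and the estimate is
   exactly N_c.
4. If `−3.0 ≤ G_stacking < −0.5`, v_bp interpolates linearly between
   (−0.5, 1) and (−3.0, 2/6); v_eos = 1.
5. Otherwise pairs are pinned to GC/CG (v_bp = 2/6) and each end-of-stack term
   contributes an extra −0.2 kcal/mol (ends of GC stacks are more
   stabilising).  If `−3.0·n_stack − 0.2·n_eos ≤ G_max` that suffices
   (v_eos = 1).  If not, the residual per-eos requirement
   e = (G_max + 3.0·n_stack + 0.2·n_eos)/n_eos constrains the end-of-stack
   sites: v_eos interpolates between (0, 1) and (−0.9, 1/4), the −0.9 chosen
   so the maximal total end-of-stack contribution is 1.6 kcal/mol.  Beyond
   that (or when n_eos = 0 and there is nothing left to constrain) the
   structure cannot be stabilised within the model: v_bp = 2/6, v_eos = 1/4
   and the result is multiplied by 0.1, the assumption being that the input is
   designable and rare combinations of terms outside the model make up the
   difference.

The estimate `N = N_c · v_eos^n_eos · v_bp^n_bp` is carried in log10 space
(N_c is kept as an exact integer separately).  The cascade is continuous in x
except for the single ×0.1 drop at the infeasibility boundary; size is
otherwise non-decreasing in x and never exceeds N_c.  These properties are
enforced by tests.

Numerical conventions: G_loop is rounded before G_max is formed; x is used as
given; interpolation uses the raw (unrounded) G_stacking.  The interpolation
endpoints −0.5/−3.0 approximate the stacking parameter table (only two of its
36 entries are weaker than −0.5; −3.0 is a typical GC/CG-on-GC/CG value).

**mfe set sizes** are estimated as N(G ≤ x) at the per-structure cut-off
x = (1.5 − n_bp) kcal/mol: structures with many pairs accumulate many
competing low-energy structures, so a stricter criterion is needed for the
low-energy set to track the mfe set.  An optional additive log10 offset
b = 0.05·L − 0.6 is available for workflows that expect systematically low
estimates; it is off by default, and estimates are reported uncorrected —
whether it helps depends on how conservative the G_loop bookkeeping is for a
given structure set, and the acceptance script reports the RMSD both ways.
The estimator deliberately does not screen for designability — an undesignable
input still receives a non-zero estimate.

## Structure space: counting, enumeration, sampling

Counting uses a dynamic-programming recursion over region lengths with
explicit helix/loop states to enforce the no-lonely-pair rule; enumeration is
an independent algorithm (symbol-by-symbol string extension with feasibility
pruning), and the two must agree — they are cross-checked exhaustively for
L ≤ 12 against a third, brute-force filter over all 3^L strings at small L.
At L = 35 with the defaults the space holds 13,399,136 structures (including
the fully unpaired one, which counts but is excluded from samples because it
has no folded set).  Uniform sampling unranks random indices from the DP
tables — equivalent to shuffling the full list and taking a prefix, without
materialising 10^7 strings.  An optional designability filter keeps only
structures for which inverse folding finds a sequence within 10 attempts
(configurable), mirroring how reference structure samples are usually built;
the witness sequence is retained to seed the reference estimator.

Four constrained families reproduce the structured test sets used in the
trend analyses: (A) a single helix with an 11-base hairpin and variable helix
depth/exterior split; (B) a fixed two-helix core whose outer helix is
extended; (C) seeded constructive samples with exactly 9 base pairs in a given
number of stacks (random helix-size compositions and nesting trees, validated
through the parser); (D) the complete two-helix/one-internal-loop/one-hairpin
family with 6 base pairs.

## Reference estimator (nested-set Monte Carlo)

The sample-based reference wraps a pluggable folding backend (the bundled one
uses ViennaRNA with lonely pairs disabled; its energies must reproduce the
mfe energy of its own predictions to 0.01 kcal/mol).  Set sizes are estimated
by nested sets: 11 sets defined by a distance d — for the low-energy criterion
d = max(G_A − x, 0) binned at d = 0, ≤ 1, …, ≤ 9 kcal/mol plus one unbounded
set; for the mfe criterion the analogous base-pair-distance bins.  For each
adjacent pair of sets a random walk restricted to the outer set (point
mutations at unpaired sites, legal pair swaps at paired sites, mixed 50/50;
moves leaving the set are rejected and the current state re-counted) measures
the fraction of time spent in the inner set after a burn-in.  Because the
moves preserve compatibility, the product of the ten fractions times N_c
estimates the innermost set size.  Defaults: 3 measurements averaged in log
space, 2000 initialisation + 2000 measurement steps; a walk with zero hits is
retried with ten-fold more steps and flagged if it still fails (the logged
estimate then uses a one-hit floor and the result is marked non-converged).

Seed sequences for strict energy criteria come from three guesses — GC pairs
with A loops, the backend's inverse folding, and a greedy per-pair assignment
— followed, if needed, by a downhill walk of up to 5000 mutations.  The greedy
third guess replaces an external design tool's initialisation step; the
estimator is insensitive to seeding bias, so the substitution is benign.  The
seed search can fail even when solutions exist; failures are reported, never
silently ignored, and downstream they count as empty sets (an upper limit on
the true empty-set rate).

Exhaustive oracles provide exact ground truth at small L by evaluating every
compatible sequence (only compatible sequences can meet either criterion, so
scanning N_c sequences is exact while 4^L is not needed).

## Baselines

* **Stack count**: the number of stack regions, compared against references on
  a linear–log scale.
* **Two-versatility line**: log10 N = a·n_bp + b, fitted by OLS on a reference
  table (the package hard-codes no asymptotic versatilities; any affine choice
  of (a, b) yields identical r², which is what the comparisons use).  An
  optional 2^n_bp neutral-component correction flag exists, off by default,
  and is likewise invisible to r².
* **Contiguity**: the mean paired-site density over stem-loop arms, where arms
  are the substructures hanging off exterior *and* multi-loops (multi-loops
  are treated like exterior loops when delimiting arms).  The original
  statistic's exact formula was not reconstructible from available sources, so
  this package defines its own documented variant with the same qualitative
  behaviour (helices split by large internal loops score lower; the open
  structure scores 0); it is validated against an independent
  re-implementation, but its absolute comparison scores should not be read as
  a re-evaluation of the original statistic.

## Evaluation

Comparisons use Pearson correlation of log10 sizes, the r² of an OLS log–log
fit (prediction regressed on reference; r² is identical either way), and the
RMSD of log10 values.  Rows with zero or failed sizes are excluded from
metrics and reported as percentages.

## Problem sizes and what the tests show

The full-scale study conditions (5000 structures of L = 35; nested-set walks
of 3 × 2000/2000 steps) are the defaults of the respective components.  The
bundled end-to-end runs use reduced sizes chosen as a compromise between
statistical stability and runtime on a single CPU: `scripts/acceptance.py`
uses 80 designability-filtered structures and single 600/600-step
measurements (~10 min); the corresponding test uses 60 structures and
500/500-step walks.  At these scales the correlation and r² values carry
sampling noise of roughly ±0.1, so the test thresholds sit below the
full-scale values by a corresponding margin; the L = 13 cross-checks and all
structure-space counts are exact.  Passing tests demonstrate internal
consistency and agreement with exhaustive ground truth and the sample-based
reference at reduced scale — they do not by themselves establish accuracy on
natural RNA structures, longer sequences, or energy parameter sets other than
Turner 2004.

## Known limitations

* No pseudoknots, no tertiary contacts, no coaxial stacking.
* Sequence-dependent loop bonuses are ignored; mixed stabilisation
  combinations (e.g. dangling ends substituting for stacking) are not
  enumerated combinatorially, which makes the estimator systematically
  conservative.
* The estimator assumes designability; it cannot flag structures with empty
  mfe sets.
* Enumeration is guarded above L = 35; structure samples for longer sequences
  should come from external structure sources.
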