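# Methods

## Model and problem

A metabolic network with m metabolites and r internal reactions inside a
cell growing at a steady exponential rate is described by the augmented
stoichiometric matrix

    S = (S0 | -Λ),    Λ = diag(λ1, …, λm),  λi > 0,

where S0 (m × r, exact rationals) holds the internal stoichiometry and the
trailing diagonal block is one dilution pseudo-reaction per metabolite:
exponential growth drains every pool at a rate proportional to its
concentration. Λ defaults to the identity — the convention in which the
growth rate has been absorbed into the dilution fluxes; per-metabolite λ
covers first-order degradation with or without growth. At steady state the
flux vector v (length n = r + m, internal fluxes then dilution fluxes)
satisfies S·v = 0, and chemical feasibility additionally demands v ≥ 0.
The feasible set N₊ = {v ≥ 0 : Sv = 0} is a pointed convex polyhedral
cone.

The package computes a *basic-pathways basis*: a set of r = n − m
entrywise-nonnegative vectors that is a linear basis of Null(S). Unlike
extreme-pathway or elementary-flux-mode enumeration (NP-hard, output often
exponential), this costs polynomial time, and any steady pathway is an
easily computed linear combination of the basis columns.

All arithmetic is exact rational (`fractions.Fraction`). This is not a
nicety: singleton counting, sparsity, rank, and cone membership all hinge
on exact zero tests, and floating point would corrupt every one of them.
Rank uses fraction-free (Bareiss) elimination after row-wise denominator
clearing.

## Pipeline

1. **Reduction.** A row of S0 with no strictly positive entry means the
   metabolite can only be consumed or diluted, so its steady-state
   concentration — and every flux touching it — is forced to zero.
   `reduce_network` removes such rows and their incident columns to a
   fixed point (removals can expose new positive-free rows). Removed
   metabolites are reported with that interpretation, not silently
   dropped. The fixed-point closure is order-independent (verified by
   property test rather than assumed).
2. **Fundamental basis.** With every row of S0 owning a positive entry,
   G = (I_r ; Λ⁻¹S0) is a null basis in closed form: v = (v0; v1) is
   steady iff v1 = Λ⁻¹S0·v0. The embedded identity makes G a fundamental
   null basis and trivially *singleton complete* (below).
3. **Elimination.** Positive column operations (scale by a positive
   rational, swap, add a positive multiple of another column) preserve
   both the null-basis property and nonnegativity of the top r rows. The
   engine removes every negative entry of the bottom block: a negative
   w_ij is cancelled exactly by c_j ← c_j + a·c_k with w_ik > 0 and
   a = −w_ij/w_ik. Result: W ≥ 0, S·W = 0, rank r. Columns are finally
   scaled to primitive integer form (positive scalings, logged like every
   other operation; replaying the log on G reproduces W bit-exactly).
4. **Sparsification (on by default, separable).** A guarded subtraction
   pass: for ordered column pairs, c_j ← c_j − a·c_k with the largest
   a > 0 keeping c_j ≥ 0 (a = min over rows with w_ik > 0 of w_ij/w_ik,
   so at least one new exact zero appears), accepted only when it strictly
   lowers (deficiency index, nonzero count) lexicographically, iterated to
   a fixed point. Subtraction sits outside the positive-coefficient
   elimination, which is why it is a separate, optional pass.

## Singleton theory and the pivot rule

A *singleton row* has exactly one nonzero; that entry is a singleton
element of its column; a matrix with a singleton element in every column
is *singleton complete*, and the number of columns lacking one is the
*deficiency index*. Singletons matter because a singleton row pins its
column's mixing coefficient: v = W·r implies r_j = v_i(j)/w_i(j)j. For a
singleton-complete W, v ≥ 0 holds iff r ≥ 0, and the columns of W are
exactly the extreme rays of N₊ (both implications are property-tested,
the second against a brute-force ray enumerator).

Column operations are scored by their *singleton cost*: Type I = drop in
singleton row rank, Type II = rise in deficiency index (positive = worse).
Scales and swaps always cost (0, 0). The elimination picks pivots by the
lexicographic key (measured Type-I cost, measured Type-II cost, pivot
nonzero count, pivot index): the cost terms implement cost minimization,
the sparsity term limits fill-in, the index makes the rule deterministic.
Within a row, negatives are cleared left to right (choices within one row
commute, so this is presentation only). Costs are measured by diffing full
profiles; matrices here are small and correctness beats micro-optimization.

## Completing the elimination: search, not just a sweep

The canonical description — process bottom-block rows from row n upward —
is incomplete as an algorithm: a greedy pivot choice can cancel the last
positive entry that a *later* row was counting on, and on some networks
(including reversibility variants of the packaged case study) *no* pivot
sequence under the strict bottom-up order reaches a nonnegative basis even
though one exists. Two observations repair this without leaving the
method's vocabulary:

- A row that is entrywise nonnegative can never regain a negative entry
  (a new negative in row p needs an existing negative there), so rows can
  be repaired in *any* order, each becoming permanently clean; repairing
  in a different order is the same as running the bottom-up sweep on a
  row-permuted S0 — precisely the non-uniqueness device that generates
  alternative bases.
- A row holding a negative entry but no positive entry anywhere is
  unreparable forever, which gives a sound early prune.

`eliminate_negatives` therefore runs a deterministic depth-first search:
first the strict bottom-up order with backtracking over pivot choices,
then (only if that tree is exhausted) an adaptive order that repairs the
most-constrained row (fewest positive columns) first. A node budget
(50 000 candidate evaluations) bounds the search; exceeding it raises the
same degeneracy error as a proven dead end. On feasible inputs the greedy
branch almost always succeeds immediately — across the randomized test
corpus no backtracking is observed — and the budget exists for adversarial
inputs, where a genuinely infeasible instance is reported rather than
looped on.

Infeasibility is real, not hypothetical: for a sign-random S0 the cone
{u ≥ 0 : S0·u ≥ 0} frequently hides implicit equalities that force fluxes
to zero, and then no nonnegative basis exists at all (checked in the test
corpus against the brute-force ray enumerator: every refusal corresponded
to a cone of deficient dimension). The random-model generator used by the
property suites therefore resamples each row of S0 until its sum is
strictly positive, which makes the all-ones flux an interior point of the
cone and guarantees a nonnegative basis exists. This emulates a healthy
growing-cell network (every metabolite can be net-produced simultaneously);
it deliberately does not emulate blocked or mass-balanced-closed networks,
so passing suites say nothing about those — they are exercised separately
through the degeneracy paths.

## Decomposition, bounds, extreme rays

Given any v with S·v = 0, coefficients of singleton-complete columns are
read off their singleton rows; the d coefficients of deficient columns
solve the exact residual system restricted to the rows where those columns
appear (d is small in practice; the system is solved by exact rref, and
reconstruction is verified to residual exactly zero). The flux components
split into r independent parameters (one per column) and m dependent ones
— the compatibility relations enforcing steadiness.

For a deficient basis, coefficients of deficient columns may legitimately
be negative. With fixed nonnegative coefficients on the complete columns,
deficiency one yields the exact closed lower bound
r₁ ≥ −min over rows i with w_i1 > 0 of (Σ_j r_j w_ij)/w_i1; for d ≥ 2 the
package exposes the inequality system over rows whose deficient entries
are all positive, plus a direct membership predicate, plus a directional
bound r_Min(g) = min over rows of c_i/(Σ_k g_k w_ik). Two deliberate
closures: strict inequalities are implemented as their closures (the
admissible cone includes its boundary), and r_Min minimizes over *all*
rows with positive projected weight, not only rows where every deficient
entry is positive — otherwise boundary tightness (some component of W·r
exactly zero at ρ = r_Min) fails for directions touching mixed-support
rows.

Extreme-ray testing uses the standard support-rank criterion: admissible
v ≠ 0 spans an extreme ray iff rank(S[:, supp(v)]) = |supp(v)| − 1. The
brute-force enumerator (support enumeration + exact nullspace + sign
check) is exponential and guarded to ≤ 16 columns; it exists as an
independent oracle for tests, not as a production path.

## The case network

Thirteen species (glucose A, glyceraldehyde-3-P B, 1,3-bisphosphoglycerate
C, pyruvate D, lactate E, citrate F, a lumped succinate/fumarate/malate
pool G, isocitrate H, succinyl-CoA I, NADH K, NAD⁺ L, ATP T, ADP P),
twelve internal reactions (imports of A, L, P; the glycolysis chain;
lactate fermentation; four TCA steps), unit dilution everywhere. Metabolite
and reaction order are frozen so flux positions are reproducible
(v1..v12 then δ_A..δ_P).

Two stoichiometric choices deserve record. The qualitative reaction list
for the TCA steps omits cofactor coefficients; requiring the closed TCA
cycle (v2, 3·v3, v9–v12, δ_K, 3·δ_T) to be a steady flux pins H → I as
cofactor-free and the lumped step as I + 3P → G + 3T. The investment step
is taken as A + 2T → 2B + 2P — one hexose yields two trioses, so
glycolysis nets +2 ATP per glucose, as in textbook stoichiometry. The
alternative 1:1 reading (A + 2T → B + 2P) renders the whole analysis
degenerate: the ATP row then forces v6 ≤ v5 ≤ v4, glycolysis can never be
a net ATP source, the reversed-TCA variant's cone collapses
(v9 = v10 = v11 ≡ 0), and the partially-utilized-B pathway does not exist
— all of which contradict the analyses this model is meant to support.

Computed summary for the forward model: S is 13 × 25 with nullity 12; G
has 13 singleton rows (the 12 identity rows plus lactate, the only
metabolite made by a single reaction) and sparsity 253/300 = 0.84. The
sparsified basis W_s has singleton row rank 12, deficiency index 1 (the
textbook-glycolysis column is the lone deficient one), sparsity 0.69
(91 nonzeros), and all 12 columns pass the extreme-ray test, including the
closed-TCA-cycle column, which the elimination produces directly and
bit-exactly.

### Divergence from the published summary statistics

The analysis this model reproduces reports, for its own W (published only
in supplementary material that cannot be reconstructed from the printed
text): singleton row rank 11, Type-I transformation cost 2, deficiency
index 2, sparsity 0.84. Basic-pathway bases are not unique, and the basis
computed here is a different — measurably better — one: rank 12, cost 1,
deficiency 1. The published sparsity figure is not merely unmatched but
unattainable: every nonnegative null basis of this S must contain a column
with δ_B > 0 and a column with δ_C > 0 (otherwise the span lies inside
{u4 = u5} or {u5 = u6}), any admissible column with v4 > v5 forces a
TCA-coupled support of a dozen nonzeros, and summing per-column minimum
supports bounds the nonzero count of any such W above ~90 of 300 entries —
sparsity at most ≈ 0.72. The reported 0.84 coincides with the sparsity of
G. For the same reason the published full-TCA column (cycle + citrate
route, non-extreme, whose difference with the citrate column is the
closed cycle) does not arise here: the row-order of the sweep forces the
bare cycle column directly. The relation is still exercised in tests by
constructing the composite column explicitly: it is admissible, fails the
support-rank test, and the guarded sparsification recovers the cycle
column from it by exact subtraction.

Variant results: reversing v9 alone (either by column negation or by
adding the reverse column and forcing the forward flux to zero) makes
isocitrate degenerate — its concentration must vanish, as reduction
reports. Reversing the full cycle leaves a reducible-free network whose
basis this pipeline computes with 12 columns. Splitting v9 into forward
and reverse columns gives a 26 × 13 basis. Reversing v12 gives singleton
row rank 12 (deficiency 1 here; 2 is reported for the published variant
basis).

## Tunables

- `dilution_rates` (per metabolite, 1/time, default 1): Λ above.
- `sparsify_result` (default on): the guarded subtraction pass; off
  reproduces the raw elimination output.
- `pivot_key`: the pivot-ranking callable; the default implements the
  cost-minimizing rule described above and is the frozen, documented
  tie-break.
- `max_nodes` (default 50 000): elimination search budget.
- `max_columns` (default 16): brute-force ray-enumeration guard; `force`
  overrides for oracle use.
- `random_model(m, r, density, seed, degenerate_rows)`: property-test
  generator; entries are small integers in ±3, density is the per-entry
  occupancy probability (default 0.5), rows resampled to positive sums as
  above; `degenerate_rows` plants positive-free rows with ground truth
  recorded in provenance.

## Known limitations

- The elimination's search is complete only over single-pivot exact
  cancellations; repairs that would need a *combination* of pivots for one
  entry are not explored. No such case has been observed (feasible test
  corpus plus all case variants), but a refusal on an exotic feasible
  network is conceivable.
- The brute-force ray enumerator is exponential by design and guarded;
  it is an oracle, not a tool for real networks.
- No kinetic rate laws, no ODE integration, no flux-balance optimization
  layer, no SBML writing; reversible reactions are handled only through
  the two rewriting schemes (column negation, column splitting).
- JSON model files and TSV matrices are the only interchange formats.
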