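# basicpathways

Basic-pathway decomposition of steady-state metabolic networks in growing
cells, in exact rational arithmetic.

## The problem

For a network of m metabolites and r irreversible internal reactions in a
cell growing exponentially, steady-state fluxes v satisfy S·v = 0 with

    S = (S0 | −Λ),    Λ = diag(λ1, …, λm) ≻ 0,

where the trailing block is one *dilution* pseudo-reaction per metabolite
(growth drains every pool in proportion to its concentration; Λ = I by
default). Chemically feasible fluxes are additionally nonnegative, so the
solution set is the pointed polyhedral cone N₊ = {v ≥ 0 : Sv = 0}.
Enumerating its extreme rays (extreme pathways, elementary flux modes,
and relatives) is NP-hard and the output can be exponential.

This package instead computes a **basic-pathways basis**: r = n − m
nonnegative vectors that form a *linear basis* of Null(S), in polynomial
time. The dilution structure gives a closed-form fundamental null basis

    G = ( I_r ; Λ⁻¹ S0 ),

and a sequence of positive column operations — guided by *singleton
theory*, which scores operations by how much coefficient-pinning
structure they destroy — turns G into an entrywise-nonnegative W whose
columns (basic pathways) each have a direct chemical reading. Any steady
pathway decomposes as v = W·r where most coefficients are read off single
components of v; for singleton-complete W, v ≥ 0 ⇔ r ≥ 0 and the columns
of W are exactly the extreme rays of N₊. Exact coefficient lower bounds,
pathway decomposition, degeneracy reduction, and a support-rank extreme-ray
test round out the toolkit. It is aimed at systems-biology researchers and
methods developers who want exact (not floating-point) null-space analysis
of small-to-medium reaction networks.

## Worked example

The packaged case network couples glycolysis to a simplified TCA cycle
(13 metabolites, 12 internal reactions, unit dilution):

```python
from basicpathways import (
    build_glycolysis_tca_model, augment_with_dilution,
    compute_basic_pathways, nullity, singleton_profile,
)

model = build_glycolysis_tca_model()
S = augment_with_dilution(model).S
print(S.shape, nullity(S))          # (13, 25) 12

basis = compute_basic_pathways(model)   # elimination + sparsification
prof = singleton_profile(basis.W)
print(basis.W.shape, prof.row_rank, prof.deficiency_index)
# (25, 12) 12 1

labels = model.flux_labels()
for j in (0, 11):
    col = basis.column(j)
    print(f"BP{j+1}:", {labels[i]: str(x) for i, x in enumerate(col) if x})
# BP1:  {'v1': '1', 'delta_A': '1'}
# BP12: {'v2': '1', 'v3': '3', 'v9': '1', 'v10': '1', 'v11': '1',
#        'v12': '1', 'delta_K': '1', 'delta_T': '3'}
```

The numbers mean: the augmented matrix is 13 × 25 with a 12-dimensional
null space; the computed basis W is 25 × 12, nonnegative, with 12
singleton rows (12 reactions live in exactly one basic pathway) and a
single column lacking a singleton (the textbook-glycolysis pathway).
BP1 is the trivial glucose import-and-dilute pathway; BP12 is the closed
TCA cycle — NAD⁺ plus three ADP in, the four cycle steps turning, NADH
plus three ATP out to dilution — and passes the extreme-ray rank test.

The same pipeline as a command line:

```sh
basicpathways compute case.json --out out/     # W.tsv, profile.json, oplog.jsonl
basicpathways casestudy --variant forward      # computed vs published summary
basicpathways reduce reversed.json --out red/  # degeneracy diagnosis
```

`casestudy` prints a table of published-versus-computed summary metrics
and exits nonzero when they differ. Several of the published W statistics
describe a different (non-unique, and in part provably unreachable) basis
than the one this deterministic pipeline finds; docs/methods.md analyses
the divergence in detail.

Reversibility is handled by the two pointed-cone-preserving rewrites:
`reverse_reactions` (negate a column) and `split_reversible` (append the
reverse as an extra column). Reversing the TCA entry step v9 alone makes
isocitrate degenerate — `reduce` reports its concentration forced to zero
— while reversing the whole cycle, or splitting v9, yields valid bases.

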