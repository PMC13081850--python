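# Methods

## State algebra

A pool of cardinality `N` is indexed by states `0 … N−1`.  Two layouts
exist:

* **Product** — an operation with internal cardinality `m` over inputs
  of cardinality `N_1 … N_k` spans `m · ∏ N_k` states.  Decomposition is
  mixed-radix with the internal state as the *least-significant* digit
  and inputs following in declaration order with increasing
  significance.  The convention is a free choice (any fixed bijection
  gives the same pool); this one makes consecutive states enumerate an
  operation's own variants before advancing any parent, so "all
  variants of parent 0" are contiguous.
* **Union** — stacking assigns inputs consecutive state blocks in
  declaration order (cumulative offsets).  Exactly one branch is active
  per state; inactive branches receive the `None` marker and contribute
  nothing to the sequence, name, or card beyond schema nulls.

All cardinalities are arbitrary-precision Python integers; layouts far
beyond 2⁶³ compose and decompose exactly.  Every state space is finite:
random-mode operations must declare a sample count, so `size` is always
an O(nodes) computation that constructs no sequences.

## Generation and reproducibility

`generate(pool, state, master_seed)` is pure.  Each random draw stream
is seeded by `blake2b(master_seed | node_id | internal_state)`, where
`node_id` is derived from graph topology (kind + topological index),
never from runtime object identity.  Changing the master seed changes
random-mode outputs only; sequential- and fixed-mode outputs are
seed-invariant.  A small per-pool memo caches subtree results keyed by
(state, seed, node id); it is a pure-function cache and does not affect
results.

A pool may feed several consumers (a DAG, not a tree).  A node reached
twice on one active path emits its card variables and name token once
per traversal; card writes are applied depth-first with the last write
winning, and the duplicate-prefix guard rejects only two *different*
operations sharing a name prefix.

## Sequence model

Coordinates are 0-based half-open everywhere.  Regions may nest
properly; partial crossing is rejected at parse time and at edit time.
For an edit replacing `[es, ee)` with `r` (`δ = len(r) − (ee − es)`):
boundaries left of the edit are fixed, boundaries right of it shift by
δ, a region containing the edit stretches by δ, and boundaries strictly
inside a replaced span clamp into the replacement.  Tie-breaks at edit
boundaries: a region that merely *ends* at the edit start stays left of
it; for insertions, a region *starting* at the insertion point
stretches to cover the inserted text, and a zero-length anchor exactly
at the point grows over it — so serial operations can keep targeting
the same region, and nesting is preserved in every combination.
Partial-overlap edits raise an error rather than silently splitting a
region: there is no principled split semantic, and failing loudly is
safer at half-million-sequence scale.

Styles are per character, not per region, because overlays must compose
attribute-wise (an underlined mutation inside a blue region keeps the
blue background).  Rendering emits one ANSI SGR escape pair per maximal
styled run; stripping escapes always recovers the raw characters.
Input sequences are uppercase-canonical IUPAC; lowercase is uppercased
with a warning.

## Operation catalog conventions

Fixed enumeration orders make sequential states meaningful: nucleotide
substitutes in A<C<G<T order minus the current base; substitute
residues in alphabetical single-letter order minus the wild type;
position pairs lexicographic; IUPAC expansions with the leftmost
position as the least-significant digit.

`mutagenize_orf` defaults to all codons except an initial ATG and a
terminal stop (overridable), giving `P·19` single and `C(P,2)·19²`
pairwise variants.  The `missense_only_first` codon policy writes the
most frequent codon (packaged human usage fractions, overridable)
encoding the substitute residue; since the substitute is never the wild
type, emitted codons never re-encode the wild-type residue.  Random
codon mutagenesis draws per-codon Bernoulli(rate) and keeps
zero-mutation draws: resampling them would bias the per-position
marginal away from the declared rate.

`get_barcodes` guarantees pairwise-distinct barcodes without global
bookkeeping by mapping each incoming state through a seeded affine
bijection `s ↦ (a·s + b) mod 4^L` (`a` odd, hence invertible mod a
power of two) and base-4-encoding the image.  A length too small for
the parent pool is rejected with the minimal sufficient `L`.

`insert_multiscan` owns the choice of site-pool members: its internal
cardinality is the declared sample count `n`, and for each internal
state its keyed RNG draws one member per site pool, then disjoint
placements by rejection sampling (default budget 1,000 attempts;
exhaustion raises an error naming the node and state).  Sites replace
the region background in place (equal-length substitution), keeping
the region and all downstream coordinates fixed.  A Cartesian product
over site-pool states would multiply the pool size by the site-pool
cardinalities; sample-count semantics is what makes "n arrangements"
designs come out at exactly n per template.

Operations that need parent structure to declare cardinality
(region-targeted mutagenesis, deletion scanning, barcode capacity,
multiscan geometry) probe parent state 0 once at construction time and
assume that structure — region coordinates, ORF content, lengths — is
shared by all parent states.  Every catalog operation preserves that
homogeneity.  `filter` is the one exception to pure layout algebra: its
cardinality requires evaluating the predicate, so the kept-state index
is materialized by a one-time scan at the first size query (an eager,
documented cost), with the predicate evaluated against the parent as
its own generation root under a fixed materialization seed — intended
for deterministic upstream graphs.

## Names and cards

A tracked operation contributes `prefix_<internal>` zero-padded to
`max(2, digits(m−1))`; a labeled stack contributes its active branch
label as a bare token placed *before* the branch's own tokens, so names
read source-to-sink (`wt.mut_03.bc_01`).  DAGs with no tokens fall back
to `s<state>`.  Card variables are qualified by the operation's prefix,
or by its node id when unprefixed (so unrelated operations never share
a column by accident, while same-prefixed operations on alternative
stack branches deliberately share one).  Inactive-branch variables are
emitted as nulls, keeping tables rectangular for covariate use.

## Packaged example designs

The builders are first-class, tested code.  `build_gb1` encodes the
56-residue GB1 domain with most-frequent human codons; every published
count depends only on P = 55 eligible positions, not on the specific
codons.  `build_mpra` uses consensus-style binding sites for HNF4A,
PPARA, and XBP1 in a synthetic inert template; the design logic
(orientation flips, disjoint placement in a 100-bp region, 3×
replication, 10-nt barcodes) is what the example exercises, not the
biology of the specific motifs.  `build_splice` samples 9-mers from a
packaged 9-position 5'ss frequency matrix with the donor GT invariant
(a cryptic donor requires it, and the matched control — T>A at +2 —
must always change exactly one base), scores them with a pluggable
strength scorer (default: PWM log-odds against a uniform background,
probabilities floored at 1e−9), ranks scores with stable, index-tied
sorting into 100 equal-count bins from a 10,000-draw candidate set, and
draws 20 per bin.  The flanking scan substitutes the 9-mer at 50
exonic and 50 intronic windows abutting a synthetic canonical junction;
coordinates, not genomic context, are the point.  These synthetic
stand-ins reproduce the *construction* counts and properties of the
corresponding published designs; they do not reproduce downstream model
scores, which require external model weights and genomic context and
are out of scope.

## Numerical and testing choices

PWM columns must sum to 1 within 1e−9.  Statistical tests of sampling
(PWM column frequencies, random-branch mutation counts) use fixed seeds
and 3σ bands at n = 10,000; the k-mer uniformity check uses a χ²
threshold at the 0.999 quantile.  Exhaustive bijection checks run on
randomized layouts with total ≤ 10,000.  The full-scale acceptance
checks generate all 547,230 GB1 and all 30,000 MPRA sequences — chosen
as the complete published design sizes, which the engine enumerates in
well under a minute each on one core.

## Limitations

No sequence optimization, synthesis-constraint screening, or mutagenic
primer design.  Regions cannot partially overlap.  `filter` and the
splice-library binning step are eager.  Structure probing assumes
structurally homogeneous parents; an upstream operation that varied
region geometry per state would need explicit position lists.  The
operation catalog is a representative core, not an exhaustive one;
new operations are expected to be added by subclassing.
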