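# poolforge

Declarative, lazily evaluated design of DNA oligonucleotide libraries.

Designed sequence libraries — oligo pools — are the raw material of
massively parallel reporter assays (MPRAs), deep mutational scanning
(DMS), and other multiplex assays of variant effect, and are
increasingly used for in-silico experiments on genomic AI models.  A
realistic pool mixes several generation procedures (exhaustive
substitutions, sampled higher-order mutants, motif arrangements,
wild-type replicates, barcodes), and coordinating that combinatorics in
one-off scripts is tedious and error-prone.

poolforge represents a library as a directed acyclic graph of
composable **operations** over **pools** of sequences.  The graph is
cheap to build and inspect; no sequence exists until you ask for one.

## The model

Every sequence in a pool is indexed by a single non-negative integer,
its **state**.  For an operation whose output combines an internal
choice with choices made by its input pools, the output state space is
the Cartesian product

```
N_out = N_internal × ∏_k N_k
```

and a received state `s` is split by mixed-radix decomposition (the
internal state is the least-significant digit; inputs follow in
declaration order).  Stacking pools side by side instead takes the
disjoint union `N_out = Σ_k N_k`, with `s` selecting the unique active
branch by cumulative offsets; inactive branches receive no state.
Generation is therefore two passes over the graph: a **backward pass**
that resolves every operation's internal state from the root state, and
a **forward pass** that constructs the sequence bottom-up.  Together
with a master seed that keys every random draw by
`(seed, node id, internal state)`, a state determines one sequence
exactly — generation is a pure function, independent of call order and
process identity, and pool sizes are exact arbitrary-precision integers
computed without generating anything.

Sequences carry named **regions** written as XML-style tags
(`AAA<cre>CCCGGG</cre>TTT`, self-closing anchors `<ins/>`) whose
0-based half-open coordinates survive length-changing edits, per-character
display **styles** rendered as ANSI escape codes, automatic **names**
built from per-operation tokens (`wt.mut_03.bc_01`), and **design
cards** — flat records of the tracked parameters that produced each
sequence, compiled into a rectangular table usable directly as
covariates in downstream analyses.

The catalog covers source operations (explicit sequences, PWM and IUPAC
motif expansion, random k-mers, guaranteed-distinct barcodes),
transformations (nucleotide- and codon-aware mutagenesis, deletion
scanning, insertion, shuffling, recombination, orientation flips),
composition (join, stack, non-overlapping multi-site placement), and
state operations (select, reorder, filter, repeat).  New operations are
small subclasses of `Operation`; they inherit state tracking, naming,
cards, and rendering.

## Worked example

```python
import poolforge as pf

base = pf.from_seq("AAA<t>CCCGGG</t>TTT")
muts = pf.mutagenize(base, scheme="single", region="t", prefix="mut")
lib  = pf.stack(pf.repeat(base, 2, prefix="rep"), muts,
                labels=["wt", "single"], prefix="lib")
print(lib.print_dag())
print("size:", lib.size)
print(lib.to_frame().head(5).to_string(index=False))
```

prints

```
    [0] from_seqs  mode=sequential  size=1
  [1] repeat  mode=sequential  size=2  inputs=[0]  prefix=rep
  [2] mutagenize  mode=sequential  size=18  inputs=[0]  prefix=mut
[3] stack  mode=fixed  size=20  inputs=[1,2]  prefix=lib
root: [3] size=20
size: 20
         name     sequence  n0.from_seqs.index  rep.replicate mut.positions mut.ref mut.alt lib.component
    wt.rep_00 AAACCCGGGTTT                   0            0.0          None    None    None            wt
    wt.rep_01 AAACCCGGGTTT                   0            1.0          None    None    None            wt
single.mut_00 AAAACCGGGTTT                   0            NaN           [3]     [C]     [A]        single
single.mut_01 AAAGCCGGGTTT                   0            NaN           [3]     [C]     [G]        single
single.mut_02 AAATCCGGGTTT                   0            NaN           [3]     [C]     [T]        single
```

The library holds 2 wild-type replicates plus one variant per possible
substitution at each of the six tagged positions (6 × 3 = 18), 20
sequences in all.  Mutagenesis touched only the `<t>` region; each row's
design card records the mutated position and the base change, and
wild-type rows carry nulls in the mutation columns.

Three full-scale example designs are packaged (also reachable from the
CLI: `poolforge example gb1|mpra|splice`, plus `build`, `inspect`,
`preview`, and `validate` for YAML design files):

* `build_gb1()` — a GB1 deep mutational scan: 100 wild-type replicates,
  all 1,045 single and 536,085 pairwise amino-acid substitutions over
  55 eligible codons, 10,000 random higher-order variants; 547,230
  sequences in total.
* `build_mpra()` — 10,000 non-overlapping arrangements of three
  orientation-flipped liver TF binding sites in a 100-bp CRE, three
  replicates each, one distinct 10-nt barcode per sequence; 30,000
  sequences.
* `build_splice()` — 2,000 cryptic 5' splice-site 9-mers (PWM-sampled,
  strength-scored, 100 quantile bins × 20 draws) substituted at 100
  positions flanking a canonical donor site, each paired with a
  GT-disrupted control; cards record strength, position, and the
  control flag.

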