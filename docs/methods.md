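# Methods

This note records the models, algorithms, numerical choices and open design
decisions behind corephylo, in the order the pipeline applies them.

## Input handling

Proteome files are protein multi-FASTA, one file per genome, at least five
files per run (fewer cannot support a meaningful comparative analysis and is
rejected with the observed count). File names become genome labels: known
FASTA extensions are stripped repeatedly (so the mapping is idempotent),
every character outside `[A-Za-z0-9_.-]` becomes `_` (a Newick-safe
whitelist), and collisions get `_2`, `_3`, … suffixes in sorted-filename
order. A file whose residues are >90% in `{A,C,G,T,U,N,-}` is rejected as
nucleotide data; the threshold is a composition heuristic — real proteomes
sit far below it, real nucleotide data far above.

Newick supports are normalized to [0, 1] on read: when any numeric internal
label exceeds 1 the whole set is treated as a 0–100 scale and divided by
100. Internally only the [0, 1] scale exists. The writer emits lengths and
supports with `%.12g`, so read∘write round-trips are exact to well below
1e-9. Quoted Newick labels are not supported; the label whitelist guarantees
the writer never needs them.

## Profile HMMs and E-values

One model per marker gene, estimated from a training-cluster alignment:

* **Match states** are the alignment columns with gap fraction ≤ 0.5, in
  order (the common profile-HMM heuristic). An alignment with no such
  column cannot yield a model and is an error naming the gene.
* **Match emissions**: `P(a|c) = (count_a(c) + α·bg_a) / (residues(c) + α)`
  with pseudocount weight α (default 1) and `bg` the Robinson–Robinson
  amino-acid frequencies. Ambiguity codes (X, B, Z, U, *) are not counted as
  residues and score as background at search time (log-odds 0).
* **Transitions** are position-specific 3×3 rows over {M, I, D}, counted
  from the observed state paths of the training rows with add-one
  smoothing; position 0 acts as the begin state and position L routes to the
  end state (its delete destination is zeroed and the row renormalized).
* **Insert emissions** equal the background, so inserts are score-neutral.

Scoring is **glocal**: the model must be traversed begin-to-end (deletions
allowed) while the target's flanks are free — appropriate for full-length
marker detection, and simpler than a local/multi-hit architecture. The score
is the forward (sum over paths and over substrings) log-odds in bits. The
dynamic program runs in scaled probability space, vectorized over batches of
equal-length sequences; the insert self-loop is a linear recurrence solved
with an IIR filter. Values leaving [1e-200, 1e200] trigger rescaling with
the log-scale accumulated separately. The implementation is checked against
exhaustive path enumeration on small models (L ≤ 4, sequences ≤ 5).

**E-values.** At build time each model is calibrated by scoring `n_random`
(default 200, minimum 100) i.i.d. background sequences of length L and
fitting a Gumbel by the method of moments (`β = s·√6/π`,
`μ = mean − γ·β`). Then `E(score) = k · N · exp(−λ·score)` with `λ = 1/β`,
`k = exp(μ/β)/L`, and `N` the residue count of the proteome searched — i.e.
the expected number of equally good hits in a random database of that size,
normalized per model length. These E-values share HMMER's *threshold
semantics* (true homologs pass 1e-10 by ~20 orders of magnitude in the
synthetic study; shuffled decoys sit at E ≫ 1e-3) but are not numerically
HMMER's; the tblout reader provides exact interoperability when users run
real hmmsearch. A zero-variance calibration score distribution is an error
rather than a silent degenerate fit.

Whether thresholding should use full-sequence or best-domain E-values is an
open question for glocal scoring; full-sequence is used, matching the single
full-length-hit model architecture.

## Hit screening and prevalence cutoffs

Hits above the E-value threshold are discarded; per (gene, genome) cell the
minimal-E hit wins, ties broken by higher bit score, then lexicographically
smallest sequence id — full determinism with no dependence on input order.
Cutoffs are fractions in [0, 1] (defaults 0.8/0.8, this artifact's own
choice) applied in one genome-then-gene pass: genome fractions are computed
over the *whole* gene set, gene prevalence over the *retained* genomes, and
fractions are not recomputed after gene exclusion (no fix-point iteration —
a second pass could silently change which exclusions occur). Retaining fewer
than 4 genomes is a hard error: no informative unrooted topology exists.

## Alignment

The internal engine is classic progressive alignment: a neighbor-joining
guide tree on 3-mer fractional-common-count distances
(`d = 1 − shared/(min_len − k + 1)`), then profile–profile global DP in the
guide tree's merge order. Column-pair score = mean BLOSUM62 over member
pairs (pairs involving a gap contribute 0); affine gaps with open −10,
extend −1, a run of g gaps costing −(10 + (g−1)); terminal gaps are charged.
The DP is vectorized row-wise; the in-row gap recurrence is a max-plus
prefix scan (`y_j = e·j + cummax(a_j − e·j)`). The pairwise case is the
exact DP optimum (verified against an independent scalar implementation);
the multiple case is heuristic, as all progressive aligners are. External
aligners plug in through `{input}`/`{output}` command templates.

## Trimming

Per column: gap fraction `g(c)`, and similarity `s(c)` = fraction of
residue–residue pairs with BLOSUM62 ≥ 1 (0 with fewer than 2 residues —
bounded in [0, 1] and monotone in conservation). Thresholds are chosen from
the data as the *elbow* of the ascending sorted curve: the point of maximum
perpendicular distance **below** the chord joining the endpoints. The
below-chord (convex) knee marks the end of the low cluster — gappy columns
for g, garbage columns for s; a curve that never dips below the chord has no
low cluster and the threshold collapses to the minimum, cutting nothing.
This directionality matters: the above-chord knee of a similarity curve
whose mass sits on the conserved plateau would be ≈ 1 and would strip every
variable — i.e. phylogenetically informative — column.

The three modes are nested by construction, ordered in aggressiveness as
their names imply: `gappyout` removes `g(c) > g*` and always removes all-gap
columns; `strict` starts from gappyout's retained set, removes `s(c) < s*`
(s* from the full-alignment similarity curve), then drops columns not in a
run of ≥3 consecutive retained columns; `strictplus` starts from strict's
set, keeps only runs of ≥5, then — in one simultaneous pass — drops any
column with ≥3 of its up-to-4 nearest original neighbors (c±1, c±2, clipped
at the ends) outside the set. `none` is the identity. Trimming only selects
columns; residues are never edited. An empty result is an error recommending
`none`. The exact thresholds of the trimAl heuristics these modes are named
after are not reproduced; the elbow rule is this artifact's concretely
specified, deterministic equivalent.

## Supermatrix

Genes concatenate in lexicographic gene-id order (reproducibility; no
natural order exists); a taxon missing from a gene contributes a gap-only
segment of that gene's trimmed length. Partition coordinates are 1-based
inclusive (`PROT, <gene> = <start>-<end>`), the de-facto partition-file
convention, and tile [1, L] contiguously. Output as FASTA and relaxed
PHYLIP.

## Internal tree inference

The internal engine is distance-based: p-distance over co-resident columns,
or Poisson correction `−ln(1−p)` capped at 3.0 (finite trees for saturated
pairs; pairs sharing zero comparable sites get the cap with a logged
warning). Neighbor joining uses the standard Q-criterion; ties break on the
lexicographically smallest pair of cluster representatives (each cluster
represented by its smallest member label), negative branch lengths clamp to
0, output is unrooted. NJ is exact on additive matrices — the engine's
provable correctness surface, exercised in the tests. ML programs (FastTree,
IQ-TREE) remain available through the external command template; the
internal default keeps the pipeline runnable with no binaries at all.

Supports come from a seeded column bootstrap: resample columns with
replacement, re-estimate distances + NJ, report per-edge bipartition
frequency on the point tree. For the supermatrix this is a bootstrap of the
concatenation; per-gene jackknife is out of scope.

## Consensus and supertree

**Majority-rule-extended consensus** over gene trees with identical taxon
sets (guaranteed in consensus mode by forcing `gene_cutoff = 1`): include
every bipartition with frequency > 0.5; consider the rest by descending
frequency (ties: lexicographic on the canonical split) and accept each one
compatible with everything accepted, until the tree is fully resolved
(n − 3 splits) or candidates are exhausted. Supports are the exact
frequencies k/n; no branch lengths. Bipartitions are kept canonically as the
side not containing the lexicographically smallest taxon, which turns split
compatibility into disjoint-or-nested and tree assembly into cluster
nesting.

**Weighted quartet supertree** over gene trees that may miss taxa: the
returned topology maximizes `Σ_g Σ_q w(q,g) · 1[S and g agree on q]`, where
q ranges over 4-subsets of each gene tree's leaves and `w(q,g)` is the
minimum support on the internal path defining q in g (1 where supports are
absent). The min-support weight is this artifact's defined, testable
uncertainty weighting; branch-length signal is deliberately not used. Up to
`exact_limit` taxa (default 8; 10,395 topologies — desk-scale) the search is
exhaustive over all unrooted binary topologies with ties broken by smallest
canonical Newick; above that, a majority-rule consensus seed (greedy leaf
insertion for taxa missing from the seed, deterministic polytomy
resolution) is refined by nearest-neighbor-interchange hill climbing to a
local optimum. Candidate quartet topologies are read off the four-point
condition on unit-length path sums. Output supports are the weighted
fraction of each edge's defining quartets on which the gene trees agree
(0 when no gene covers any such quartet).

## Tree comparison

* **RF distance**: symmetric-difference count of non-trivial bipartitions
  (equals "twice the number of differing internal branches" for binary
  trees); normalized form divides by |B1| + |B2| and is defined 0 for two
  stars.
* **Branch score** (Kuhner–Felsenstein): √Σ(ℓ₁(b) − ℓ₂(b))² over the union
  of bipartitions including pendant edges, absent splits counting 0.
  Requires lengths on both trees.
* **CCC**: Pearson correlation of the n(n−1)/2 upper-triangle cophenetic
  entries in shared label order. Trees without lengths get unit lengths for
  cophenetic purposes only (logged), so consensus/supertree outputs remain
  comparable; a zero-variance matrix (equal-length star) yields NaN with a
  warning rather than an arbitrary number.

## Synthetic data

The generator emulates a complete study: a Yule species tree (uniform
random leaf split; exponential branch lengths, mean 0.1 substitutions/site),
gene trees equal to the species tree or (with probability `discordance`)
one random NNI away — so discordance 1 means every gene tree is exactly RF 2
from truth — with optional lognormal branch-length jitter; sequences evolved
site-independently (substitution probability `1 − exp(−rate·t)` per branch,
replacement uniform over the other 19 residues); per genome one sequence per
gene under opaque ORF-style ids plus background-random decoys; and held-out
training clusters evolved from the same per-gene root sequences on an
independent realization of the tree with fresh taxon labels — training and
test taxa are disjoint, so homolog search is a generalization test, not
memorization. The whole bundle is a pure function of its parameter record
including the seed.

Defaults are the canonical study conditions: 8 taxa, 15 genes, rate 0.2,
discordance 0, 5 decoys per genome, seed 42. Gene length defaults to 400
residues — the scale of classic conserved single-copy markers (EF-Tu,
GroEL) — long enough that each gene individually carries signal for every
internal branch of a typical Yule tree at these rates, which is what the
concordant-gene-tree conditions presume.

What the generator does *not* emulate: indels (per-gene sequences are
equal-length, so the aligner faces no real gap placement), empirical
amino-acid exchangeabilities (uniform replacement keeps the expected
divergence in closed form for testing), rate variation across sites, and
paralogy. Passing end-to-end tests therefore demonstrates the pipeline's
internal correctness and determinism, not alignment or model adequacy on
real, indel-rich, heterotachous proteomes.

## Determinism

Every stage is a pure function of (inputs, config, seed): hit tie-breaks,
guide trees, NJ ties, consensus ordering, supertree ties, and all sampling
(calibration, bootstrap) are either deterministic or seeded. Re-running an
identical configuration reproduces `final_tree.nwk` byte for byte; the test
suite asserts this.

## Known limitations

* Internal tree engine is distance-based; for publication-grade trees route
  the supermatrix through IQ-TREE/FastTree via the adapter.
* One HMM = one marker gene; multi-domain markers are not merged.
* Internal E-values are calibrated, not HMMER-compatible; mixed-source hit
  lists should come from one scoring route only.
* The supertree hill climb above 8 taxa is a local optimizer; only the
  exhaustive regime carries an optimality guarantee.
* No checkpoint/resume; stages always rerun (intermediates are retained for
  inspection and for feeding other tools).
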