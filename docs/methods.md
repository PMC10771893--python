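# Methods

This note records the models, conventions and design choices behind
`domaindrift`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open decisions were made.

## The conservation-plane statistic

For an aligned protein family with a designated domain (alignment columns
`[start, end)`), every unordered species pair contributes a point
(x, y): x is percent identity over all columns, y over the domain columns
only. The statistic attached to each point is its Euclidean distance from
the full-conservation corner (100, 100),

    d = sqrt((100 − x)² + (100 − y)²),   d ∈ [0, 100·√2],

and its class relative to the slope-1 diagonal y = x: `domain_conserved`
above the line, `domain_accelerated` below, `balanced` within a tolerance
`tol` of it. `tol` defaults to 1e-9 — an exact-tie guard only, because the
diagonal is treated as a strict demarcation, not a fuzzy band.

Group-pair clusters are explicit configuration: the caller supplies a
partition of group pairs (e.g. merging D:D with P:D when their point clouds
overlap), and the package reports each cluster's n, mean distance, and SEM.
SEM is the n−1 sample standard deviation divided by √n and is *absent* (not
zero) for single-pair clusters. Clusters are numbered by ascending mean
distance. Distances are computed from unrounded identities and rounded to
2 decimals only for display; identities display at 1 decimal. No automatic
cluster discovery is attempted — the merged clusters in the motivating
analysis arise from visual overlap, which is a judgment, not an algorithm.

## Percent identity

Identity uses the *both-ungapped* denominator: a column counts for a pair
only when neither sequence has a gap there, and the value is
100 · matches / counted columns. This convention is symmetric, stable under
region restriction, and recorded as a tag on every `IdentityMatrix` so that
alternative denominators (shorter-sequence length, full alignment length)
could be added without ambiguity. When an MSA is supplied, pairwise values
are read off its columns; per-pair Needleman–Wunsch re-alignment is
available separately (`global_align`) for ungapped inputs. NW uses linear
gap scoring with a deterministic traceback preferring diagonal over
gap-in-second over gap-in-first; an empty sequence aligns against all gaps
(score = gap × length) rather than erroring. A pair with *no* mutually
ungapped columns has undefined identity and raises a distinct error.

Lineage-specific residues are columns where the target is non-gap, all
background species are non-gap and mutually identical, and the target
differs. Columns with any background disagreement are excluded regardless
of the target.

## Coiled-coil calling

The caller is a single-residue positional log-odds scorer: a window of 28
residues (four heptads) is scored as the sum of table entries
`T[residue, heptad position]` with position (offset + phase) mod 7, and a
residue's track value is the best score of any covering window at any
phase. Calls are maximal runs of residues at or above the table threshold,
merged when separated by fewer than 7 residues (a single broken heptad
should not split a domain). Unknown residues (`X`, `*`) score at the table
minimum, which biases *against* calling through uncertain sequence.

The shipped table (`data/heptad_propensities_synthetic.tsv`) is synthetic:
authored for this package, favoring hydrophobics (L, I, M, V) at core
positions a/d and charged/polar residues elsewhere, with strong penalties
for proline and glycine. It is calibrated so an ideal heptad scores 7.0 per
repeat (28.0 per window) while a scrambled 100-residue background tops out
around 16; the threshold 18 sits between. It is *not* a trained model of
real coiled coils: real predictors use pairwise residue statistics fitted
to curated databases. For that reason every downstream analysis accepts
user-supplied domain coordinates, and the predictor is a fallback for when
none are given. `map_region_across_msa` converts a reference-sequence
domain to alignment columns (skipping reference gaps) and thence to each
species' own coordinates, flagging species that are entirely gapped there.

## The sequence-evolution generator

`synthetic_data` simulates CDS evolution along a fixed tree under HKY85
with discrete-gamma rate variation:

* **Substitution model.** Base frequencies (A, C, G, T) =
  (0.2844, 0.2519, 0.2947, 0.1690), Ti/Tv = 2.2233, gamma shape 0.9665,
  proportion of invariable sites 0 — an HKY+G fit for a mammalian
  coiled-coil gene family, adopted as generator defaults. The printed Ti/Tv
  ratio is converted to κ via
  Ti/Tv = κ(π_A π_G + π_C π_T) / ((π_A+π_G)(π_C+π_T)); the matrix is scaled
  to one expected substitution per unit branch length at stationarity.
* **Rates across sites.** Four equal-probability gamma categories using
  category medians, renormalized to mean exactly 1; rates are drawn once at
  the root and shared across the tree. Four categories is the field
  convention; an invariable-sites fraction is supported but defaults to 0.
* **Domain rates.** Sites inside the (codon-space) domain multiply the
  branch rate by a per-edge factor: `domain_multiplier[edge]` where given,
  else `domain_background_rate`. The mammal preset sets the background to
  0.25 — a functional domain under purifying selection, which is the
  empirically typical state and what makes non-primate within-group points
  land above the diagonal — and the acceleration scenario raises the three
  primate terminal edges to 3× the whole-protein rate.
* **Open reading frames.** Codons that would become stops (at the root draw
  or after an edge) are redrawn until stop-free. This is rejection sampling
  from the stop-conditioned codon law, so it is exactly reproducible in
  closed form: `expected_pairwise_stats` enumerates the 61 sense codons and
  the per-codon rate-category triples to give the exact expected p-distance
  and leaf base composition for 2-leaf trees. Calibration tests compare
  against these exact values rather than the unconditioned HKY site formula,
  whose expectation the stop rejection shifts by a small but detectable
  amount (and the leaf composition likewise: conditioning against stops
  depletes T/A and enriches C by roughly half a percentage point).
* **Reproducibility.** One master seed; per-edge streams are derived by
  hashing the edge's descendant leaf set, so traversal order and edge
  insertion order cannot change the output. Same seed ⇒ bit-identical
  alignments.

### The mammal preset and what it does (and does not) emulate

`mammal_config` encodes the study conditions: 9 taxa (Hsa/Ptr/Mml primates,
Cfa/Eca/Ssc/Bta domesticated, Mmu/Rno rodents) on a clock-like tree with
within-primate terminal edges of 0.015–0.04 substitutions/site, a rodent
stem of 0.3, and a 300-codon protein with a 91-codon (13-heptad) domain at
codons [140, 231). These sizes give within-group whole-protein identities
above 90%, between-group identities of roughly 40–70%, and a rodent pair
near (89, 96) — the qualitative pattern of a divergent mammalian ortholog
family with a conserved functional domain.

The acceleration effect (3× on primate terminals over a 0.25 background) is
deliberately stronger than what a real protein family shows: with a
91-codon domain and primate branches this short, a subtler contrast would
drown in binomial sampling noise at single-protein scale. A power check at
these settings puts the probability that any one within-primate pair lands
on the wrong side of the diagonal below ~1%, so 20-seed recovery runs are
informative. Consequences of the design: passing recovery tests demonstrate
that the *pipeline* detects a domain-rate contrast of this magnitude, not
that such contrasts are detectable at real-data effect sizes. The generator
also omits indels (alignments are gap-free by construction), codon-level
selection (dN/dS), CpG effects and among-lineage composition drift; results
on real alignments inherit none of these guarantees.

## Phylogenetics

* **Distances.** p-distance with column-wise pairwise deletion;
  JC = −(3/4)ln(1 − 4p/3); K2P = −(1/2)ln((1−2P−Q)√(1−2Q)) with P, Q the
  transition/transversion proportions. Log-domain violations (saturation)
  are signaled per pair and stored as NaN, never as infinities; NJ refuses
  saturated matrices, and bootstrap replicates containing one are skipped
  and counted.
* **Neighbor joining.** Standard Saitou–Nei Q-criterion agglomeration.
  Ties in Q are broken by the smallest (i, j) index pair for determinism.
  Negative branch estimates are clamped to 0 with the deficit moved to the
  sister edge, preserving the pair sum. Output is unrooted, represented
  with a trifurcating root; the final three edges come from the three-point
  formulas.
* **Bootstrap.** Columns resampled with replacement at constant width; an
  internal edge's support is the fraction of successful replicates whose
  NJ tree contains its bipartition. Default 2000 replicates in the CLI
  (tests use 20–200 for speed; supports are tallies, so replicate count
  trades only precision, not correctness).
* **Consensus.** Majority rule keeps bipartitions with frequency strictly
  above the cutoff (≥ 0.5), which guarantees pairwise compatibility by
  pigeonhole; frequencies are attached as supports; branch lengths are not
  assigned.
* **Parsimony.** Fitch scoring of a *fixed* topology with unordered states
  and gaps as missing data, implemented with Hartigan's multifurcation-exact
  upward pass (it reduces to Fitch intersection/union on binary nodes); tree
  search is out of scope.
* **Newick.** Canonical output orders children by lexicographically
  smallest descendant leaf, prints branch lengths to 6 significant digits
  and supports as internal node labels in [0, 1]; the parser reports
  character offsets on malformed input. Gap character is `-` only.

## Numerical and testing notes

Transition probabilities use the spectral form of the reversible rate
matrix (symmetrized via the π^{1/2} similarity transform), clipped and
row-renormalized against round-off; the public `transition_probabilities`
uses the scipy matrix exponential and the two agree to ~1e-15. Stochastic
tests are seeded and sized for stable margins: 20-seed recovery checks at
thresholds with ≥ 3σ headroom, 50-replicate exchangeability checks at
α = 0.01, calibration at 100 × 2000-codon replicates compared within 3
Monte-Carlo SE of the exact expectation. Brute-force oracles (alignment
enumeration, internal-state enumeration for parsimony, per-pair identity
recomputation, independent bipartition tallies) are kept fully independent
of the implementations they check. The NJ implementation is additionally
cross-checked against an independent library implementation on a generic
matrix.

## Known limitations

* The identity convention of legacy desktop alignment tools is
  undocumented; values computed here can differ in the second decimal from
  such tools on gapped pairs.
* The coiled-coil table is a synthetic stand-in: adequate for implanted
  ideal heptads and for exercising the pipeline, not validated on real
  proteins.
* Maximum-likelihood and Bayesian tree inference, parsimony tree *search*,
  codon models, indel simulation and model selection are out of scope.
* `expected_pairwise_stats` covers 2-leaf trees with a uniform domain
  factor; multi-taxon expectations would require conditioning through
  internal nodes and are not implemented.
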