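# Methods

## The problem

Genotyping every SNP in a region is wasteful because nearby SNPs are
strongly correlated (linkage disequilibrium, LD).  Tag SNP selection picks
a subset T of SNPs such that every other SNP can be predicted from SNPs in
T with squared correlation at least `min_r2`.  `tagsnp` implements the
multi-marker variant of this problem on phased haplotype data: a *tagging
rule* S → SNP_x predicts the alleles of SNP_x from the joint haplotype
over a small SNP set S (|S| ≤ `max_size`, every pair of SNPs in the rule
within `max_dist` base pairs), and the tag set must cover every SNP either
directly or through a rule whose left-hand side lies entirely inside T.

## The r² statistic over SNP sets

Let H range over the observed haplotypes of S and let A/a be the major and
minor allele of SNP_x.  A grouping assigns every H to one of two classes,
turning S into a derived bi-allelic marker (H_A, H_a); its association
with SNP_x is the ordinary r²:

    r² = (P(H_A A) − P(H_A)·P(A))² / (P(H_A)·P(H_a)·P(A)·P(a))

with all probabilities relative frequencies over haplotype rows, no
small-sample correction.  Two grouping models are supported:

- **co-occurrence** — H goes to the allele it co-occurs with more often;
  a tie f(HA) = f(Ha) sends H to the minor allele a (the model's
  "otherwise" branch; documented because it changes the numerator for tied
  haplotypes).  If every haplotype lands in one class, no bi-allelic
  derived marker exists and the statistic is defined as 0 for |S| ≥ 2.
- **one-vs-the-rest** — every grouping isolating a single *observed*
  haplotype is scored and the maximum is kept.  Unobserved haplotypes
  yield an empty class and are skipped.  Which class maps to which allele
  flips the sign of the covariance and leaves r² unchanged; the
  orientation is fixed (for the prediction mapping only) by maximising the
  number of correctly co-occurring haplotypes.

Single-SNP rules (|S| = 1) use the ordinary pairwise r² under both models.
Both groupings coincide with the allele split there, and treating length-1
rules as the pairwise model keeps all three statistics identical at k = 1,
including in the degenerate corner where the majority mapping would
collapse to one class.

### Numerical policy

Every r² is evaluated in integer arithmetic before the single final
division:

    r² = (n·c_HAA − c_HA·c_A)² / (c_HA·(n−c_HA)·c_A·(n−c_A))

where the c's are haplotype counts.  Counts are exact, so perfect LD gives
exactly 1.0, the Cauchy-Schwarz bound holds exactly and every value lies
in [0, 1] without clamping; threshold comparisons (`r² ≥ min_r2`) are
reproducible bit for bit across the scalar, vectorized and evaluation code
paths.  Equivalence (r² = 1) is tested without floating point at all: two
columns are equivalent iff they are identical or complementary.

## Rule generation

1. **Equivalence merging.**  A left-to-right sweep assigns each SNP to the
   leftmost existing group whose representative is within `max_dist` and
   in perfect LD with it, else it founds a new group.  Anchoring on the
   representative (rather than chaining) bounds the group span.  The
   representative is the leftmost member — determinism, nothing deeper.
2. **Candidate enumeration.**  Rules are enumerated over representatives
   only, size-layered (all |S| = 1, then 2, then 3; lexicographic within a
   size, targets in ascending order), which guarantees every subset of S
   is processed before S.  Positions are one-dimensional, so the pairwise
   distance constraint is simply span ≤ `max_dist`.
3. **Redundancy pruning.**  A rule is redundant if a proper subset of its
   LHS already tags the same target.  Emitted rules are hashed per target
   by their LHS; the subset lookup (≤ 2^|S| − 2 probes) runs *before* the
   r² computation.
4. **Skipping.**  With `skip_threshold = t`, a SNP that has been the
   target of t emitted rules stops being considered as a target for all
   later candidate sets.  Counting is over emitted (non-redundant) rules
   in visit order; the rationale is that a SNP taggable t times over will
   almost surely be covered anyway.
5. **Member expansion.**  A representative rule stands for every
   combination of group members on either side; instantiations violating
   the distance constraint are dropped.  A representative rule is emitted
   whenever *some* member instantiation is distance-valid, and the
   selector only consumes rules valid at the representatives' own
   positions — this split keeps the expanded member-level rule set exactly
   equal to what an unmerged enumeration would produce, while selection
   never relies on a geometrically impossible rule.  Perfect within-group
   pairs (member ↔ member, distance-valid) complete the expansion.

## Tag selection

Mandatory tags first: SNPs that are the target of no rule must be tags.
Then greedy covering: repeatedly pick the candidate covering the most
uncovered SNPs — a candidate covers an uncovered SNP_j if some rule
lhs → SNP_j has the candidate in its LHS and the rest already in T, and
always covers itself — breaking ties toward the smaller genomic position.
Each iteration removes at least the picked SNP from the uncovered set, so
termination is structural.

After the representative-level cover, every non-representative member is
checked: it is covered if its representative is a tag (the within-group
rule is distance-valid by construction) or if one of the representative's
covering rules expands validly to it; otherwise the member is promoted to
a tag.  This makes the coverage guarantee exact at the individual-SNP
level rather than approximate at the group level.

`verify_full_coverage` re-derives coverage from the haplotype matrix by
exhaustive subset search over the tags near each SNP — it shares no state
with the selector and is run in the test suite after every selection.

## Chunked (memory-bounded) execution

The rule budget is expressed as a maximum rule count, not bytes — portable
and directly testable.  Chunk boundaries are forced at adjacent-SNP gaps
wider than `max_dist` (such SNPs cannot interact) and inserted wherever
the accumulated rule count would exceed the budget.  Rule counts per SNP
(attributed to the rightmost SNP of each rule) come from a counting
enumeration per gap-delimited segment — in a two-step deployment these
counts are known from the rule-generation step.  Each chunk re-enumerates
only its own rules.  Adjacent chunks overlap by the SNPs within `max_dist`
of the next chunk's first new SNP; tags selected there carry over, and
SNPs covered by an earlier chunk are not re-covered.  Chunking is
worthwhile when chunks are large relative to the `max_dist` window; the
boundary overhead measured in the tests is a fraction of a percent of the
tag count at 500 SNPs and 5–8 chunks.

## Cross-panel evaluation (portability)

A rule's haplotype→allele mapping is frozen at training time.  On a test
panel, alleles are matched by symbol (major/minor orientation may flip
between populations), each test haplotype's LHS pattern is looked up in
the mapping, and accuracy is the fraction of target alleles predicted
correctly.  A pattern unseen in training falls back to the test panel's
major allele of the target and is counted (`n_unseen`); for the r²
recomputation such patterns join the class of the fallback allele.  The
test-panel r² uses the frozen grouping, not a refit — the alternative
(regrouping on the test panel) would measure the population's LD rather
than the rule's portability.  Rules referencing SNPs absent from the test
panel are excluded and counted.

## Synthetic panels

The generator is a founder-template mosaic: each LD block draws
`n_founders` random founder haplotypes; every sample haplotype copies one
founder through the block, switching to a random founder between adjacent
SNPs with probability `mosaic_rate`.  Columns violating the MAF floor are
redrawn at the founder level (bounded retries, then an error for
infeasible settings).  Planted structure: duplicated columns (perfect-LD
pairs) and `plant_rule`, which overwrites a target column with a parity or
random-lookup function of k other columns plus optional flip noise.

Defaults — 120 haplotypes (60 diploid individuals), blocks of ~8 SNPs with
5 founders, mosaic rate 0.03, spacing ~3 kb, MAF floor 0.05 — emulate the
block structure and common-variant spectrum of a phased reference panel at
desk scale.  What the generator does *not* emulate: recombination-map
heterogeneity, demography and drift, allele-frequency site spectra from a
coalescent, genotyping error, or missing data.  Passing tests therefore
demonstrate algorithmic correctness and the direction of the method's
trade-offs on block-LD data, not calibrated performance on any real
population.

## Default parameters

| parameter        | default        | meaning                                      |
|------------------|----------------|----------------------------------------------|
| `min_r2`         | 0.95           | rule admission threshold (0.8–0.95 typical)  |
| `max_dist`       | 100 000 bp     | max span of any rule, inclusive comparison   |
| `max_size`       | 3              | max LHS size; larger over-fits               |
| `maf_cutoff`     | 0.05           | inclusive minor-allele-frequency filter      |
| `model`          | co-occurrence  | grouping model                               |
| `skip_threshold` | disabled (5 when used) | target-multiplicity cut-off          |
| `rule_budget`    | unlimited      | max rules in memory; finite ⇒ chunking       |

Coordinates are 1-based; distance is the absolute position difference and
the `max_dist` comparison is inclusive.  A 50/50 allele-frequency tie
makes the lexicographically smaller symbol the major allele, so recoding
is deterministic across populations.  Missing alleles and unphased
genotypes are rejected, not imputed.

## Problem sizes in the test suite

The test suite and the acceptance script run the pipeline at desk scale,
chosen so each property is exercised in its intended regime: brute-force
oracle comparisons on 18–24-SNP panels (where exhaustive enumeration is
exact and fast), set-cover optimality on ≤ 15 representatives, coverage
audits on 30–60-SNP panels across models and thresholds, and chunking on
500-SNP chromosomes with `max_dist` well below the chromosome span and
budgets forcing 5–8 chunks.

## Known limitations

- Phased, complete, bi-allelic input only; phasing and EM-based haplotype
  frequency estimation from unphased genotypes are out of scope.
- When several rules could impute the same untyped SNP their predictions
  are not reconciled; evaluation is per rule.
- The greedy cover has no approximation guarantee beyond the usual set
  cover bound; the exhaustive comparison in the tests is feasible only on
  small panels.
- The skip heuristic makes the rule set (not the coverage guarantee)
  depend on enumeration order; order is fully deterministic, so results
  are reproducible but not order-free.
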