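# Methods

`metalloprof` estimates the inventory of iron- and copper-dependent
protein fold families in a microbial community from shotgun meta-omic
reads, assigns the reads' taxonomy, and relates the inventories to
water-column geochemistry in oxygen minimum zones (OMZs). This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not demonstrate.

## Reference construction

The counting unit is the *fold family*: the family level of a SCOP-style
structural classification, identified by a dotted `class.fold.superfamily.family`
string (sccs, e.g. `b.6.1.3`) and an integer node id (sunid). A metal
reference is built by recursively expanding curated seed sunids for Fe-
and Cu-binding families into all domain-level descendants and collecting
their sequences into one labeled FASTA per metal. Expansions are
deterministic (ascending sunid) so reference builds are diffable.

Two curation rules are built in:

* **Aconitase exclusion.** Family `c.83.1.1` is an Fe *regulatory*
  protein; it is removed by default so the Fe inventory reflects
  catalytic Fe proteins. Exclusions are configuration (`--exclude`),
  recorded in a report with removal counts; an exclusion matching
  nothing warns rather than fails.
* **Dual-metal proteins.** A protein reachable from both Fe and Cu seeds
  is kept once per metal and flagged, never silently dropped;
  downstream consumers can deduplicate.

File dialect: tree topology is recovered from the description table
(`des`) alone — internal levels link by sccs prefix, domains link to the
family sharing their sccs — while classification (`cla`) rows are used
as a cross-check of domain ancestry. Comment lines and trailing columns
are tolerated. Identical sequences appearing under multiple sunids are
retained (and surface as ties during assignment) rather than
deduplicated.

## Search model

The search emulates a translated protein search. Reads are
quality-filtered on mean Phred (default 25), paired mates merged by 3′
overlap (minimum overlap 10 nt, mismatch fraction ≤ 0.25,
higher-quality base wins), translated in six frames, masked for low
complexity by a DUST-style triplet score (a stand-in for the
min-complexity pre-filter of interactive binning tools; no numeric
parity claimed), and each stop-free peptide segment is aligned locally
against every reference entry.

Scoring uses BLOSUM62 with affine gaps (open 11, extend 1; a gap of
length L costs 11 + L). Raw scores are rescaled to bits with the
Karlin–Altschul parameters λ = 0.267, k = 0.041 (gapped BLASTX
conventions), and the expectation is E = m·n·2^(−bits) over m query
residues × n database residues. Hits are retained at **bit ≥ 50 and
E ≤ 0.1** (both configurable). Segments mathematically unable to reach
the bit cutoff (length × best diagonal score < required raw score) are
skipped, and an exact-k-mer prescreen (k = 4) avoids aligning entry
pairs sharing no peptide k-mer; both are accelerators that cannot remove
a hit capable of passing a 50-bit cutoff in practice, and the prescreen
can be disabled. Alignment scoring and traceback are delegated to a
C implementation of Smith–Waterman; the test suite checks it against an
independent pure-Python Gotoh dynamic program on random pairs.

Genome mode accepts protein FASTA, skips translation, and reports
frame 0; protein- and nucleotide-mode scores of the same peptide are
identical. Externally produced 12-column tabular hits can be substituted
for the built-in search.

## Inventory rules

Per query and per metal (a read hitting both metal references is
assigned within each independently):

1. **Fractional top hits.** The k hits sharing the best bit score — 
   compared after rounding to 1 decimal, matching tabular output
   precision — each receive weight 1/k, so every hit-bearing query
   contributes exactly weight 1.
2. **Cupredoxin split.** Multidomain cupredoxins (`b.6.1.3`) contain
   both the copper nitrite reductase NirK and the multicopper oxidases;
   parts are relabeled `b.6.1.3/nirK` or `b.6.1.3/MCO` by ordered,
   case-insensitive substring rules on the subject description (nirK
   rules first). The rules are editable configuration. Unmatched
   remainder keeps the plain label and is later folded into "others".
   Splitting precedes minor-family clustering because the split labels
   are reported as major categories.
3. **Minor-family clustering.** Families below 4% of the metal's total
   weighted count in the sample are merged into "others" (exact-threshold
   labels retained; totals conserved exactly). The 4% rule is applied
   per sample and per metal.
4. **Normalization.** Weighted counts are scaled per 100,000
   protein-coding sequences. The denominator is external (the sample's
   total protein-coding sequence count); it is never inferred from the
   metal hits themselves.

## Taxonomy

MEGAN-style lowest common ancestor per query: drop hits below 50 bits or
above E = 0.01, retain hits within 10% of the best bit score
(multiplicative, the usual convention), and return the LCA of the
retained subjects' taxa in an NCBI `nodes.dmp`/`names.dmp` taxonomy.
Raising the top-percent window can only coarsen the assignment. Phylum
rollups divide by assigned queries; assignments without a phylum-rank
ancestor count as "unclassified"; `min_support` (default 1) pools
weakly supported phyla.

## Geochemistry and statistics

* **Oxygen zones.** Five boxes jointly on O2 and depth: upper oxic
  (15–30 m, > 200 µM), upper oxycline (50–85 m, 10–200 µM), upper OMZ
  (70–125 m, < 10 µM), core OMZ (200–300 m, < 5 µM), lower oxycline
  (500–1000 m, 5–50 µM). O2 is primary and depth disambiguates zones
  sharing an O2 band. O2 bands are lower-inclusive/upper-exclusive and
  depth windows inclusive (the source ranges are printed without
  inclusivity; this choice makes the classifier a partition, verified
  exhaustively). Anything outside every box is "unclassified" — e.g.
  shallow anoxia, or the 300–500 m gap.
* **Fe:Cu regression.** Ordinary least squares of the dissolved Fe:Cu
  molar ratio on O2. The fitted value at 0 µM O2 (the intercept) is the
  predicted maximum ratio of an anoxic water mass when the slope is
  negative; a nonnegative slope returns the value with a "not a
  maximum" warning.
* **Spearman screen.** rho is Pearson correlation of mid-ranks (ties
  averaged); two-sided p by exact permutation enumeration below n = 10
  and by the t approximation otherwise. Pairs are pairwise-complete;
  constant vectors are skipped with a note, never imputed. Raw p is
  primary; Benjamini–Hochberg q-values are reported alongside because
  the screen is a family of tests.
* **Rarefaction** subsamples each sample without replacement to a common
  depth, repeatedly (default 999 draws), and returns per-label means;
  seeded and reproducible. The repeated-subsampling reading is
  implemented (rather than the analytic expected-richness formula)
  because the procedure is specified by its permutation count; means
  converge to the hypergeometric expectation either way.
* **Partial CCA.** The community matrix is converted to relative totals
  P with row/column weights r, c; the chi-square-standardized residual
  Q̄_ij = (P_ij − r_i c_j)/√(r_i c_j) carries total inertia equal to the
  chi-square statistic over the grand total. Constraints are
  weighted-centered and scaled by √r; with covariates, both Q̄ and the
  constraints are first residualized on them (constraint columns fully
  absorbed by the covariates are zeroed rather than left as numerical
  noise). The SVD of the projection of Q̄ onto the constraint span gives
  constrained eigenvalues; the residual gives unconstrained axes.
  Species scores use scaling 2 (scaled by the singular value), stated in
  the result metadata. Rank-deficient constraints raise an error naming
  the collinear columns.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline needs, seeded and
byte-reproducible:

* a fold-family hierarchy with the rule-exercising families always
  present (`b.6.1.3` with NirK-, MCO-, and neither-styled domain
  descriptions, `c.81.1.1`, `c.83.1.1`, `f.24.1.1`), random domain
  sequences of 120–240 aa;
* reads drawn from a configurable family mixture: uniform synonymous
  codon back-translation (no organism bias — the simplest defensible
  null), per-base substitutions (default 0.005), random strand, and
  constant Phred qualities consistent with the substitution rate rather
  than a learned error profile;
* depth profiles with surface O2 ≈ 220 µM declining through an oxycline
  to < 5 µM at 200–300 m and partly recovering below; dissolved Fe
  rising sigmoidally across the ~90 m oxic–anoxic transition from
  0.15 nM to a 1.9 nM plateau; dissolved Cu near-constant in
  0.9–1.6 nM (the observed open-ocean range); nutrient and temperature
  curves shaped accordingly, including a secondary nitrite maximum at
  the core;
* community matrices on the O2 gradient: summed Fe labels decreasing
  with O2, a cytochrome-c-oxidase-like Cu label increasing with O2,
  noise elsewhere;
* a ~40-node synthetic NCBI-dialect taxonomy with five phyla, with Cu
  families mapped to Thaumarchaeota species and Fe families to
  Planctomycetes, so the metal-vs-bulk taxonomic contrast is testable
  directionally.

Because reference families are *random, unrelated* sequences, the
synthetic benchmark measures the pipeline's bookkeeping (weighting,
splitting, clustering, normalization, LCA, statistics) under ideal
discrimination. It does not measure cross-family homology confusion,
database incompleteness, compositional codon bias, indels or chimeras —
so passing tests bound implementation correctness, not real-data
annotation accuracy.

## Problem sizes and numerical choices

Default desk-scale conditions: 2,000 reads of 150 nt per composition
experiment (mixture 0.40/0.30/0.15/0.10/0.05 across five families, where
a 3-percentage-point tolerance corresponds to ~2.7 binomial SD), 500
reads for end-to-end runs, 15-depth profiles, 12-sample correlation
replicates. Weight bookkeeping is exact to 1e-9 per query; CCA
identities hold to 1e-10; eigen tie-breaking and axis signs are not
contractual (tests compare up to sign). Degenerate inputs fail loudly:
empty references, all-identical O2, depth exceeding a sample's total,
rank-deficient constraints, zero denominators.

## Known limitations

* The built-in aligner is exhaustive Smith–Waterman at fixture scale; it
  is not a competitor to BLAST/DIAMOND, and composition-based statistics
  and HSP chaining are out of scope. For real datasets, import external
  tabular hits.
* The low-complexity mask approximates, but is not numerically
  equivalent to, MEGAN's min-complexity filter; assignment counts may
  differ from MEGAN on the same input.
* The read merger is a documented stand-in (mean-quality filter,
  overlap-consensus merge); real library structures (adapters, indels)
  are not modeled.
* CCA axis significance testing by permutation is not implemented.
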