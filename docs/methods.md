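# Methods

This note documents the models, defaults, and design choices behind
`synfun`, and what the synthetic validation does and does not demonstrate.

## Charge model

Each residue carries an integer charge: aspartate and glutamate −1;
arginine, histidine, and lysine +1; every other residue, unknown residues
('X'), and gaps 0.  Histidine is counted fully positive by convention of
this scheme even though its physiological pKa (~6) leaves it mostly neutral
at cytosolic pH; the integer scheme keeps region scores interpretable as
net counts of charged residues and is the convention used in comparative
charge profiling of calsequestrins.  Region net charge is `n⁺ − n⁻` over
the non-gap columns of a named alignment interval.  Regions (whole protein,
structural domains, C-terminal tail) are user-supplied alignment-column
intervals: domain boundaries come from structural literature and are not
computed here.  Raw net charge is the default comparison statistic; a
per-residue normalization is available (`per_residue=True`) for alignments
with very different region occupancies.

**Group comparisons.** All unordered group pairs are tested with Welch
(unequal-variance) t-tests; the paper-style alternative of pooled-variance
testing is deliberately not used because clade groups have no reason to
share variances.  P-values are Bonferroni-corrected by the number of pairs
actually tested, and tiers assigned at corrected P < 0.05 / 0.01 / 0.001.
Zero within-group variance (legal degenerate input, e.g. identical
sequences) is floored at machine-epsilon scale with a warning so a clear
mean difference still registers; under equal means the statistic is 0 and
the pair is reported `ns`.

**Acidic tail.** The tail is the longest ungapped C-terminal suffix with
D/E fraction ≥ `min_acidic_frac` (default 0.7) and length ≥ `min_len`
(default 5), found by exhaustive suffix scan.  Note the longest-suffix rule
will absorb isolated non-acidic residues as long as the overall fraction
stays above threshold; use `min_acidic_frac=1.0` for strictly acidic tails.
Tail truncation removes an alignment column when it lies inside the
detected tail of at least 50% of the records that are non-gap at that
column (`consensus=0.5`); with no qualifying columns the input set is
returned unchanged.

## Distances and MDS

Distances are simple mismatch counts (every difference = 1).  Default gap
handling is pairwise deletion; `count-as-mismatch` scores a gap opposite a
residue as a difference (both-gap columns are never compared).  Pairwise
deletion means different pairs may be compared on different column sets, so
the matrix need not satisfy the triangle inequality; nothing downstream
assumes metricity.  Distances are raw counts, not per-site proportions, for
comparability with count-based practice; mixing sequences of very different
ungapped lengths makes raw counts incomparable, which is a known caveat.

The 2-D embedding minimizes raw stress Σᵢ<ⱼ (dᵢⱼ − ‖xᵢ − xⱼ‖)² by SMACOF
(Guttman-transform majorization).  Initialization is classical scaling
(double-centered eigendecomposition); rank-deficient starts get a small
seeded jitter, which is the only use of the seed.  The iteration budget
defaults to 10 000 with early stopping at relative stress decrease < 10⁻⁹;
stress is non-increasing by construction and asserted per run.  Outputs are
canonicalized (centered, rotated to principal axes, axis signs fixed), so
configurations are comparable only up to rigid motion — tests use
Procrustes residuals, never raw coordinates.  Cluster separation reports a
silhouette score plus exact strict linear separability per label pair,
decided by a linear-programming feasibility problem.

## Paralog assignment and gene status

A query is assigned to the paralog family minimizing the mean proportional
mismatch distance (mismatches / compared columns, pairwise-deleted) to that
family's references.  The margin is the second-best minus best mean
distance; calls with margin ≥ 0.05 (5% of compared columns) are flagged
confident.  Exact ties return `ambiguous`.  References sharing no columns
with the query are excluded with a warning.  This operationalizes
identity-based paralog identification without a homology-search engine,
which is out of scope.

Gene status from exon maps (reference layout: 11 exons): `absent` is an
explicit input assertion (typically synteny-based evidence of deletion) and
is distinct from `no-data` (locus not assayed); any missing or modified
exon — "modified" meaning present but not homologous, counted as not
intact — or an intact fraction below 0.9 yields `pseudogenized`; otherwise
`present`.  Raising the intact threshold can never turn a pseudogenized
call into present (monotonicity, tested).

## Expression shares and shift detection

cpm = estimated counts / total mapped reads × 10⁶; quantifier outputs are
consumed, never recomputed.  TPM columns pass through untouched (computing
TPM would require effective transcript lengths, which this model does not
track).  Samples are aggregated per species × tissue × paralog by mean
(median by flag), family totals and shares follow; zero-family shares are
NaN, never 0/0.  Dominance requires share > 0.5 *and* family cpm ≥ 10 —
the floor prevents calling dominance from noise-level family expression.

Dominance states are mapped onto the cladogram with small parsimony.
Minimum change counts use Hartigan's algorithm (exact for multifurcations;
reduces to Fitch on binary trees); validated against exhaustive enumeration
on all trees ≤ 7 leaves.  `ambiguous` and `no-data` leaves are pruned
before parsimony rather than treated as a free state — an uninformative
leaf should not license reconstructions through itself.  Per-branch change
status is decided exactly with a unit-cost dynamic program: for each branch,
the minimum total cost with the branch forced equal vs forced different is
compared against the global minimum, yielding "changes in all MPRs"
(unambiguous) vs "changes in some MPRs" (ambiguous).  Ambiguity is
surfaced per event, never averaged.

The synfunctionalization report joins, per event branch: the dominance
change; gene-status decay of the displaced paralog among species below the
branch; and the peak charge-comparison tier of the shifted clade's group
per region.  It may also include the gaining paralog's skeletal/cardiac
mean-cpm ratio within the clade, explicitly flagged as assuming
cross-tissue cpm comparability (library normalization differs between
tissues and no correction is applied).  The report asserts no causality.

## Synthetic scenario generator

The generator emits every pipeline input with planted ground truth.  The
shipped defaults are the study conditions used by the tests and the
acceptance script:

| parameter | default | rationale |
|---|---|---|
| species | 3 non-focal clades × 4 + 6 focal | enough per-group replication for clade t-tests on a desk-scale tree |
| alignment length / regions | 300 columns; domains [20,260); tail [270,300) | tail of 30 columns, domain block an order of magnitude larger |
| inter-paralog divergence | 0.30 of columns | families clearly separated (MDS clusters, unambiguous assignment) |
| within-family substitution | 0.004 per column per branch | keeps within-family tip-to-tip divergence under ~5% of columns, well inside the regime where identity-based assignment is unambiguous |
| tail boost | P = 0.30 per tail column → D (90%) or E (10%) | expected focal tail net-charge offset −boost·30·(1+1/20) = −9.45 |
| expression | log-normal cpm, σ = 0.3; dominant 900 / minor 100 cpm; 2 samples; 2 × 10⁷ mapped reads | ≈0.9 dominant share over a family total well above the 10-cpm floor; σ matches typical gene-level bulk RNA-seq dispersion.  A modeling choice, not a finding |
| flipped skeletal scale | ×2.5 | the flipped clade's skeletal expression of the gaining paralog exceeds its cardiac level |
| exon deletions | CASQ1 exons 2,3 missing in a 3-species focal subclade | partial-deletion pseudogenization pattern |

Trees are random rooted binary topologies (recursive bisection) with
monophyletic non-focal clades; the focal subtree is grafted onto a random
non-root branch so the focal stem is always internal, making the planted
one-change reconstruction unique.  The tail boost is applied **once on the
focal stem** of the boosted paralog and inherited — a single ancestral
event, which both matches the scenario being modeled and keeps within-clade
variance free of the boost draw.  All randomness flows from the config seed
through fixed named streams, so identical configs give byte-identical
output files.

**What the generator does not emulate:** rate-matrix or site-heterogeneous
sequence evolution (substitutions are i.i.d. per column along branches);
indels/alignment error; read-level sequencing noise, mapping bias, or
library-composition effects on cpm; correlated expression evolution along
branches (expression is drawn i.i.d. per species around clade-determined
locations); incomplete lineage sorting or gene-tree/species-tree discordance.
Passing tests therefore demonstrate correctness of the *computations* and
recoverability of planted effects under this clean model — not robustness
to the full messiness of real comparative RNA-seq data.

## Numerical choices and degenerate inputs

- Welch t-test with Satterthwaite df; variance floor `eps · max(1, |mean|)²`
  on zero-variance groups (warned).
- Ties in paralog assignment and in dominance (share exactly at threshold)
  resolve to `ambiguous`, never arbitrarily.
- Distance pairs with zero compared columns are NaN with a warning;
  embedding refuses incomplete matrices with guidance to impute or remove.
- Shares sum to 1 within 10⁻⁹ whenever the family total is positive
  (tested on every generated dataset).
- Alignment coordinates are 0-based half-open internally; exon numbers and
  human-facing reports are 1-based inclusive.

## Problem sizes used in validation

Oracle equivalence uses 1000 random sequences (charge) and 500 random pair
comparisons (distances); MDS recovery uses 20 known planar points;
parsimony exactness uses 100 random trees of ≤ 7 leaves against exhaustive
enumeration; planted-shift recovery uses 200 generator replicates;
family-wise error control uses 2000 null replicates of 4 groups × 10
values.  These sizes give tight Monte-Carlo error on the checked rates
while keeping the full validation suite runnable in minutes on one CPU.

## Known limitations

- Charge is sequence-derived only: no pKa, structure, or calcium-binding
  capacity modeling.  The \*\*\* C-terminal tier is evidence of composition
  change, not a functional measurement.
- The cross-tissue expression ratio has no normalization correction and is
  reported with its assumption flagged.
- `absent` status encodes an upstream synteny assertion; the package does
  not verify deletions against genome assemblies.
- Raw-count distances make sequences of very different post-truncation
  lengths incomparable; prefer per-site distances (not implemented) or
  consistent truncation when lengths vary widely.
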