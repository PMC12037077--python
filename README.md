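# synfun

Tools for detecting **paralog expression shifts** — including
*synfunctionalization*, where one paralog functionally replaces another — in
deep-time comparative data, built around the two-paralog calsequestrin
(CASQ1/CASQ2) scenario in vertebrate muscle.

After a gene duplication, paralogs often subfunctionalize (e.g. CASQ1
specializing to skeletal muscle and CASQ2 to cardiac muscle).  Much later,
one paralog can take over the other's role, leaving the displaced copy free
to decay into a pseudogene.  Detecting such an event requires joining three
lines of evidence across a species tree:

1. **Expression shares.** Per species × tissue, each paralog's share of the
   gene family's total expression, with cpm computed as
   `cpm = est_counts / total_mapped × 10⁶`.  The *dominance state* of a
   tissue is the paralog whose share exceeds 1/2 above an expression floor.
2. **Tree parsimony.** Dominance states are mapped onto the species
   cladogram with Fitch small parsimony (Hartigan's generalization for
   multifurcating nodes).  Branches that change state in every
   most-parsimonious reconstruction are reported as unambiguous shift
   events; branches changing in only some reconstructions are flagged
   ambiguous rather than averaged away.
3. **Protein charge.** Per-residue charges (D,E → −1; R,H,K → +1; all
   others 0) summed over named alignment regions (whole protein, structural
   domains, C-terminal tail) give region net charges
   `q = n⁺ − n⁻`, compared between clades with pairwise Welch t-tests and
   Bonferroni correction (tiers \*, \*\*, \*\*\* at corrected
   *P* < 0.05, 0.01, 0.001).  An acidic C-terminal tail — the main
   calcium-binding segment of calsequestrin — can be detected and truncated.

Supporting components: simple amino-acid distance matrices (every aligned
difference counts 1, gaps pairwise-deleted by default) with 2-D metric MDS
by SMACOF stress majorization; nearest-reference-set paralog assignment;
gene-status calls (present / pseudogenized / absent) from exon presence
maps; and a fully seeded synthetic-scenario generator that plants a known
dominance flip, tail-acidity boost, and exon deletions for end-to-end
validation.

## Worked example

Generate the shipped scenario (12 non-focal species in three clades, a
6-species focal clade with a planted skeletal dominance flip, a C-terminal
acidity boost on the focal stem, and CASQ1 exon 2–3 deletions in a
3-species focal subclade), then run the shift analysis:

```bash
synfun simulate --config examples/default_scenario.yaml --out demo
synfun shift --expression demo/expression.tsv --tree demo/tree.nwk --out shift_out
```

```
1 shift event(s) detected; tables written to shift_out
```

`shift_out/events.tsv` names the planted focal stem branch:

```
branch  tissue    from_state  to_state  unambiguous  n_clade_species  clade_species
N11     skeletal  CASQ1       CASQ2     True         6                aves_1,...,aves_6
```

meaning: the skeletal-muscle dominant paralog switches from CASQ1 to CASQ2
on branch N11 (the focal clade's stem) in *every* most-parsimonious
reconstruction, while cardiac dominance never changes.  The charge
comparison on the same data

```bash
synfun charge --alignment demo/alignment.fasta --regions demo/regions.yaml \
              --paralog CASQ2 --out charge_out
```

shows the focal clade's CASQ2 C-terminal tail is far more negative than
every other clade's (e.g. AVES vs CRO: t = −39.5, corrected
*P* = 1.9 × 10⁻⁸, tier \*\*\*) while no domain-region comparison involving
the focal clade is significant — the planted tail-only acidity gain.
The MDS view (`synfun mds --alignment demo/alignment.fasta --out mds_out`,
final stress 2098.9 after 58 majorization iterations) shows the two paralog
families as separate, linearly separable clusters (silhouette 0.90), and
the gene-status calls from `demo/exons.tsv` mark exactly the three
subclade species' CASQ1 as pseudogenized (missing exons 2,3).  Joined into
the synfunctionalization report, the single event row records the branch,
the 3 pseudogenized displaced copies below it, the \*\*\* C-terminal tier,
and a skeletal/cardiac cpm ratio of 2.35 for the gaining paralog (flagged
as assuming cross-tissue cpm comparability).

All of this is equally available as a library; see the docstrings in
`synfun.shift`, `synfun.charge`, `synfun.mds`, `synfun.classify`, and
`synfun.simulate`.

## Method docs

See `docs/methods.md` for the model assumptions, parameter defaults and
their rationale, what the synthetic generator does and does not emulate,
and known limitations.
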