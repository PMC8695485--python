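# Methods

## The diagnostic model

`hybridiag` models a panel of *species-diagnostic, codominant* marker loci:
at every nuclear locus each species in the panel carries a distinct fixed
allele, and both alleles of a genotype are observable (on a gel, both
species' amplicon bands appear). Under this idealisation the multi-locus
genotype of an individual is a direct readout of its ancestry class:

- a **pure** individual is homozygous for the same species' allele at every
  locus;
- an **F1 hybrid** (first-generation interspecific cross) is heterozygous
  for the same species pair at every locus, with probability 1;
- any **post-F1** individual (F2, backcross, later generations) segregates,
  so it generally shows a mixture of homozygous and heterozygous loci.

A single mitochondrial locus, maternally inherited, identifies the dam-side
species of the most recent maternal lineage; it never enters the category
decision.

Model assumptions, all explicit in the code: loci are fully diagnostic for
*every* pairwise species contrast (allele codes and species are in
bijection per locus), unlinked, and mutation-free. Real marker panels may
violate full diagnosticity (shared alleles between closely related
species); such panels are out of scope and are rejected by
`validate_panel`.

## Classification rule and its edge policies

The classifier uses only typed (non-missing) nuclear loci. The three
clauses above do not cover every genotype vector, so the remaining
patterns are resolved by fixed, deterministic policies:

- **All homozygous, for different species across loci** → post-F1 with
  advisory flag `all_hom_discordant`. Under fully diagnostic unlinked loci
  this pattern cannot arise without hybrid ancestry (a pure individual is
  homozygous for one species everywhere), so pooling it with post-F1 is the
  only category-consistent choice.
- **All heterozygous, but spanning different species pairs** (possible with
  three or more panel species) → post-F1 with flag `multispecies_ancestry`;
  the parental species pair is left unset. An F1 of two species cannot
  carry alleles of a third.
- **Purity is genetic, not nominal.** An individual homozygous everywhere
  for species *s* is PURE(*s*) regardless of its morphological label; a
  mismatch is reported as `label_concordant = no`, never as a different
  category. The morphological label is metadata. The concordance field is
  `unknown` for hybrids and for samples without a label, so both readings
  of "pure for the initially classified species" remain recoverable.
- **Cytonuclear discordance** (e.g. nuclear-pure for one species with
  another species' mitochondria) is flagged (`cytonuclear_discordance`) but
  never changes the category: the mitochondrial marker is maternal-lineage
  evidence only.
- **Missing data** drop out before the rule is applied. The policy
  parameter `min_typed_nuclear_loci` (default 1) sets the minimum evidence
  to classify at all; below it the sample is UNRESOLVED — a value, not an
  error, and never silently merged into pure or hybrid in reports.

Classification is fully deterministic; there is no randomness anywhere in
the classifier or reporting paths.

## Cross simulator

Pedigrees are explicit recursive structures (`CrossSpec`): a species leaf,
or a dam × sire cross (dam first; the text notation is e.g.
`(Pret x Pcor) x Pret`). Simulation is plain Mendelian transmission: a leaf
is homozygous at every nuclear locus with its species' mitochondrial
allele; a cross draws one gamete from each freshly simulated parent, where
a gamete carries one of the parent's two alleles per locus with probability
1/2, independently across loci; the mitochondrial allele is copied from the
dam lineage (strict maternal transmission).

Noise model, applied per locus and per individual after simulation:
with probability `genotyping_error_rate` the call is replaced by a
uniformly random *valid* genotype at that locus (a whole-lane miscall — the
simplest one-parameter corruption for a multiplex band readout, chosen over
single-allele flips because band miscalls corrupt the lane's genotype, not
one allele); then with probability `missing_rate` the call is dropped.
Defaults for both are 0: the reference survey reports no error or
missingness rates, so noise is strictly opt-in.

One `numpy` Generator stream per dataset with a mandatory seed and
counter-based sample ids makes every dataset byte-reproducible. Each cross
node draws fresh, independent parents per offspring; shared-broodstock
pedigrees (the same dam mothering many offspring) are a documented
non-goal, as are linkage, mutation, drift and selection.

**What the simulator does and does not emulate.** It generates exactly the
genotype process the classifier assumes (fully diagnostic unlinked loci),
so simulation-based tests demonstrate internal consistency — that the
classifier realises the intended partition of genotype space and that
empirical frequencies match the exact Mendelian laws — not robustness to
real-data pathologies such as partially diagnostic markers, null alleles,
linkage or contamination.

## Reference dataset

`make_table2_fixture()` reconstructs, deterministically, the 84-specimen
institutional survey whose per-group category counts are published
(A: 49 pure / 0 F1 / 0 post-F1; B: 3/1/1; C: 0/0/6; D: 1/1/13; E: 9/0/0),
because the raw per-sample genotypes were never deposited. Each category
gets a canonical genotype vector: pure and F1 vectors are forced by the
model; for post-F1 samples — whose true generating cross (F2 vs backcross
vs later) is not identifiable from these markers — the fixture uses
homozygous-at-the-first-locus, heterozygous-elsewhere, an arbitrary but
documented representative of the class. Maternal (mitochondrial) species
are likewise arbitrary and set to the morphological species of the lot.
Category counts, and therefore every percentage the package reports for
this dataset, are invariant to these canonical choices.

## Exact panel power

For a pedigree with per-locus genotype law *q* (computed recursively from
gamete laws: a parent passes each of its two alleles with probability 1/2)
and L exchangeable loci:

- P(called pure for *s*) = q(ss)^L,
- P(called F1) = Σ over species pairs {s,t} of q(st)^L,
- P(called post-F1) = the remaining mass (combined patterns plus both
  edge-policy patterns above).

Heterogeneous panels reduce to per-locus products of the same terms;
exchangeability holds for any fully diagnostic panel, where the law is the
same at every locus in species space. All probabilities use ordinary double
precision — at L ≤ 20 the error is far below reporting precision, so exact
rational arithmetic is not used. Monte-Carlo estimates
(`mc_category_distribution`) run the simulator and attach 95% Wilson score
intervals (well-behaved at boundary proportions 0 and 1; computed via
`statsmodels`). `detection_curve` tabulates P(post-F1 detected) against L:
it is 0 at L = 1 (one locus can never show a combined pattern) and
nondecreasing in L for segregating crosses.

## Numerical and formatting choices

- Distribution invariants (masses sum to 1) are enforced at 1e-12.
- Percentages are computed at full precision and rendered half-up to two
  decimals via `decimal.Decimal`; integer-valued percentages render without
  decimals. Group-level hybrid percentages use resolved samples as the
  denominator, with UNRESOLVED shown in its own column.
- Genotype CSVs are UTF-8, comma-separated, missing token `?`, nuclear
  alleles written in lexicographic order so output is byte-stable;
  write→read is the identity on valid datasets.
- Gel band decoding matches each observed size to the unique expected
  species band within ±`tolerance_bp`; the default tolerance is 0 because
  no amplicon sizes are published for the default panel — slack is opt-in,
  and any ambiguity (0 or ≥2 candidate bands) is an error rather than a
  guess.

## Problem sizes used in tests and the acceptance script

The survey quantities are exact and run on the 84-sample fixture.
Stochastic checks use 10,000 simulated individuals per pedigree (the scale
at which 3 binomial standard errors separate the hypotheses of interest
comfortably) with fixed seeds; the exhaustive classifier–oracle comparison
enumerates all 216 three-locus genotype vectors of the default panel, and
the exact-power oracle enumerates genotype spaces up to L = 6.

## Known limitations

- F2 cannot be distinguished from backcrosses (or later generations) for a
  single individual; "post-F1" is deliberately a pooled class.
- Panels with shared (partially diagnostic) alleles, linked loci or null
  alleles are outside the model.
- The default catfish panel assumes all three nuclear markers are
  diagnostic for all three pairwise species contrasts; users with markers
  diagnostic for only some contrasts should encode only the species those
  markers separate.
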