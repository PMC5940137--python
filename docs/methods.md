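# Methods

## Scope and model

`modscreen` analyzes the sequencing endpoint of an EMS modifier screen in
*C. elegans*: S independently derived surviving strains, each sequenced and
variant-called against the reference, sharing the unmutagenized parental
strain's variant background. The package models only homozygous
single-nucleotide substitutions — strains are propagated 3–5 generations
before sequencing, so screen-relevant mutations are homozygosed, and the
candidate alleles of interest are SNVs. Indels, MNVs, structural variants,
heterozygous calls and transcript isoforms are out of scope; each gene is a
single CDS chain.

### Variant triage

1. **Parental subtraction** removes every call whose (contig, position,
   alt) triple occurs in the parental strain. It is a pure set difference:
   idempotent, order-preserving, never an error on empty results.
2. **Coding-effect classification** locates each SNV in the gene models
   (1-based closed coordinates throughout; conversion to 0-based happens
   only when slicing sequence). A position inside a CDS interval is mapped
   to its spliced-CDS offset in translation order (reverse-complement
   handling on the minus strand), the containing codon is substituted, and
   both codons translated with the standard nuclear code. Effect priority:
   alt codon is a stop → `nonsense`; ref codon is a stop → `stop_loss`;
   first codon ATG destroyed → `start_loss`; amino acid unchanged →
   `synonymous`; otherwise `missense`. Inside the gene span but outside
   the CDS → `intronic`; outside every span → `intergenic`. Splice sites
   are not modeled; intronic/flanking positions within 2 bp of a CDS edge
   carry a `near_splice` flag instead. A variant overlapping several genes
   is annotated against each of them, so incidence counting never silently
   drops a candidate. A ref allele that disagrees with the genome raises a
   data-integrity error rather than being skipped: silent skips hide
   coordinate-convention bugs.
3. **The hit matrix** is boolean genes × strains incidence. Two alleles of
   the same gene in one strain count that strain once. The default
   qualifying effects are {missense, nonsense, stop_loss, start_loss};
   synonymous and intronic variants can be included via the `qualifying`
   argument since reasonable screens differ on this.

### Recurrence probability

With panel count m over a panel of N strains, p = m/N and the score for a
gene hit in k of S strains is the binomial point mass C(S,k)·p^k·(1−p)^(S−k).
The point mass — the probability of *exactly* k hits — is the default
because it is the formulation under which the screen's published summary
table reproduces row for row; the statistically conventional upper tail
P(X ≥ k) is one keyword away (`mode="tail"`) and is documented as the
better default for prospective use. N defaults to 2007 (the Million
Mutation Project strain count) and is overridable everywhere. An optional
`scale` factor multiplies p to model a mutagenesis weaker than the
panel's; at the default 1.0 the scores over-estimate the chance of
recurrence for a weaker screen, i.e. they are conservative in the
direction that matters. Genes absent from the panel table are scored with
the table's median count and flagged `m_imputed` — imputation is explicit,
never silent. No multiple-testing correction is applied to the per-gene
scores; `expected_multihit_genes` (the sum of per-gene tail probabilities)
provides the genome-wide expected number of chance recurrences instead.

Formatting is one significant digit, half-up, with exponent carry
(0.095 → `1.E-01`), matching the convention such summary tables print.

### Screen design

`haploid_genomes(n_p0, fertile_per_p0)` multiplies by 2 because each
fertile F1 from a mutagenized P0 carries two independently mutagenized
gamete genomes; the factor is overridable. The default per-gene
loss-of-function rate is 2.5×10⁻⁴ per gamete — half of Brenner's classic
5×10⁻⁴ at 50 mM EMS — reflecting a milder 25 mM regime. Detection counts
are Poisson(G·r); `detection_probability` is its upper tail.

### Motif scanning

The taspase cleavage tetrad Q-x-D|G with x ∈ {F, I, L, M} (Drosophila
consensus; add V for the human enzyme's tolerance). Matching is
case-insensitive, overlap-friendly, and stops at a `*` stop character. The
proteome census counts proteins with ≥ 1 site, once each. A census of any
particular annotation release is deliberately not asserted anywhere: the
count depends on the release's isoform handling, so the scanner is
validated against brute-force enumeration on synthetic proteomes.

### Embryo statistics

* Intensities are normalized per experiment batch to the mean of a
  reference strain measured in the same batch (arbitrary fluorescence
  units are only comparable within a session). Fold-change summaries are
  mean ± sample SD (n−1).
* The rank test is Wilcoxon–Mann–Whitney, exact by enumeration when
  n_x + n_y ≤ 20 without ties, otherwise normal approximation with tie and
  continuity corrections (delegated to `scipy.stats.mannwhitneyu`).
* Notch half-widths are 1.6·IQR/√n with type-7 (linear interpolation)
  quantiles; the 1.6 constant is fixed by convention.
* Proportions round half-up to integer percent.
* smFISH comparisons are two-sided t-tests on per-embryo target/control
  molecule ratios, pooled-variance (Student) by default with Welch by
  flag, because the original analysis names Student's test.

## Synthetic data

The simulator generates everything the pipeline consumes, with ground
truth recorded, and exists as first-class tested code.

* **Genome**: 2 contigs × 60 kb, 80 non-overlapping genes of 40–100
  codons in 2–3 exons, strand random, every CDS starting ATG, ending at a
  stop, free of internal stops. Toy scale — the real genome is ~100 Mb
  with ~20k genes — chosen so whole-screen simulations run in seconds
  while keeping the per-gene background hit probability low, as in the
  real screen.
* **Screen**: 17 strains by default. 50 parental background variants
  appear in every strain; each strain adds Poisson(30) private SNVs. The
  true per-strain SNV count of such screens is not something the toy
  genome can mirror (it scales with genome size); 30 keeps background
  recurrences present but rare. The EMS substitution spectrum defaults to
  87% G:C→A:T transitions, the standard EMS signature. Injected modifiers
  (default: one gene hit in 4 strains with panel count 6, one in 2 strains
  with panel count 4 — the outcome of the screen being emulated) receive a
  guaranteed qualifying coding variant per designated strain, nonsense for
  even-numbered injections and missense otherwise, mirroring the mixture
  seen among real candidate alleles.
* **Mutability panel**: counts are 1 + gamma-Poisson (negative binomial,
  mean 30, shape 1 — right-skewed, like real per-gene panel counts). The
  +1 shift keeps every per-genome probability positive, as expected for
  genome-wide counts over ~2000 mutagenized strains, and avoids the
  degenerate p = 0 score.
* **Intensities**: raw value = batch scale × fold × unit-mean lognormal
  noise (σ = 0.6 on the log scale, matching the ~0.7 coefficient of
  variation typical of embryo immunostaining). Unit-mean noise makes
  `fold_change_summary` unbiased for the true fold.
* **smFISH**: negative-binomial counts (size 10, modest overdispersion
  beyond Poisson) around stage means 47/109/214 molecules per embryo for
  the target and 444 for the control, 20 embryos per group.

One numpy `Generator` seeded from the config drives a run, with fixed draw
order (genome → parental → per-strain backgrounds in strain order →
injections → panel counts), so fixtures are byte-reproducible.

**What passing on synthetic data does not show**: the generator draws
variant positions uniformly (no mutational hotspots, no chromatin or
sequence-context bias), panel counts independently of gene length, and
noise independently across embryos. Real screens violate all three, which
is precisely why the mutability calibration exists; conclusions about real
data rest on the calibration inputs being real panel counts.

## Numerical choices and degenerate inputs

* Binomial and Poisson masses come from scipy; the score is exact to
  floating point, and the formatter uses decimal arithmetic so half-up
  rounding is not corrupted by binary representation.
* Probability 0 formats to `0.E+00`; m = 0 gives p = 0 and a zero score
  for k ≥ 1.
* Ties in the candidate ranking break by descending k, then gene id, so
  output order is total and stable.
* Empty variant sets, empty matrices and empty mutability tables are
  valid inputs with empty/zero outputs; malformed files and out-of-range
  values raise immediately with the offending location.

## Problem sizes

Default test and simulation sizes: 17-strain screens on the 2×60 kb toy
genome; 10⁶-draw Monte Carlo checks of the binomial score; 10⁴
oracle-checked codon classifications; 1000-replicate type-I-error runs at
20 embryos per group. The full suite runs in well under a minute.

## Known limitations

* One CDS chain per gene; no isoforms, no splice-effect calls.
* The point-mass default reproduces the published table but is not the
  conventional tail statistic; prospective users should pass
  `mode="tail"`.
* The mutability calibration inherits whatever ascertainment biases the
  panel has; no gene-length or sequence-context correction is applied.
* Survival/brood-size summaries are covered only through the generic
  statistics (no dedicated brood model): per-brood percentage averaging
  conventions differ and raw brood data are not modeled.
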