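# Methods

## Scope and coordinate conventions

`cnvmap` builds a population CNV map from per-sample call sets of two
independent array-based callers and analyses the result (reference
comparison, gene annotation, SNP taggability). Raw-intensity CNV calling
is upstream of the package: inputs are call tables (PennCNV `rawcnv` text
or a generic TSV), integer CNP genotype matrices, SNP dosage matrices,
BED blacklists, refFlat-like gene models and reference SV panels
(VCF or BED+AF TSV).

All intervals are half-open `[start, end)` on autosomes 1–22, and a locus
length is exactly `end − start`. This convention is load-bearing: published
locus tables print `chr:start–end` next to a kb length, and only the
half-open reading reproduces those lengths with no ±1 adjustment. Internal
tables are TSV with fixed headers and `#`-prefixed provenance lines, so
write-then-read round-trips are bit-exact.

## Quality control

Sample-level exclusion fires when **any** of the five metrics is out of
range (strict comparisons): LRR SD > 0.4, waviness > 0.05, BAF drift >
0.0125, > 100 calls, QC contrast > 0.4. The OR combinator is a deliberate
choice — the callers' own QC practice treats each metric as sufficient
grounds, and OR is the conservative reading; an AND-style combinator would
keep samples failing a single metric badly.

Call-level filters (each drop records exactly one reason code, first match
in a fixed order): probe support below the per-caller minimum (10 for the
HMM caller, 3 for the rare-CNV caller), confidence below 5 for the
rare-CNV caller or not above 0.1 for the CNP genotyper, length outside
[1 kb, 3 Mb], or ≥ 1 bp overlap with a blacklist region. "Any overlap"
rather than an overlap fraction is used for blacklists because the point of
those regions (telomeric, centromeric, immunoglobulin) is that calls merely
touching them are unreliable.

SNP QC keeps markers with MAF > 1%, call rate > 95% and exact
Hardy–Weinberg p > 1e-4. The HWE test is the exact conditional test:
conditioning on allele counts, it sums the probabilities of all
heterozygote counts no more probable than the observed one, computed by the
standard ratio recurrence anchored mid-range for numerical stability. It is
validated against a log-factorial full-enumeration oracle (exact agreement
to ~1e-14).

## CNVR construction

HMM-based callers split large events, so same-sample, same-state adjacent
calls are first re-joined when the inter-call gap is ≤ `gap_frac` × the
merged span; `gap_frac` defaults to 0.2, matching the cleaning convention
of the calling tools, and is configurable. Probe counts sum; the minimum
confidence is kept.

Population loci are the transitive closure of ≥ 1 bp overlap across all
samples' calls, computed by a sorted sweep per chromosome (equivalent to
connected components of the pairwise overlap graph; the test suite checks
this equivalence against an explicit graph oracle on randomized instances
up to 200 calls). A locus spans the union of its members, is typed loss /
gain / mixed by whether member states sit below, above, or on both sides of
2, and its id `CNVR_<chrom>_<rank>` ranks loci by (chromosome, start, end).
A sample carrying both a deletion and a duplication at one locus counts
once toward the carrier count. Frequencies are percentages rounded to two
decimals; a singleton among 102 samples is 0.98%.

No overlap fraction is applied at this clustering step — the 50% criterion
belongs to *cross-set* comparisons only.

## Concordance validation

A locus of caller A is validated when some locus of caller B shares at
least fraction `f` (default 0.5, inclusive at the boundary) of **both**
lengths. Validated loci keep the set-A boundaries. State concordance
compares direction only (deletion vs duplication), because the two callers'
state alphabets differ; mixed loci are concordant with either direction.
The pair criterion is symmetric and the validated count is non-increasing
in `f` (both property-tested).

## Global map

Validated CNVRs and *allelic* CNP loci (≥ 1 non-diploid genotype) merge by
transitive ≥ 1 bp overlap into map loci: the interval is the union, the id
concatenates contributing ids in positional order, the carrier set is the
union of CNVR carriers and non-diploid CNP genotypes, and the type
(DEL/DUP/MIX) comes from the combined states. Where a published map was
"checked manually", this package instead emits a deterministic merged-locus
report; there are no silent edits.

Reference matching uses reciprocal overlap ≥ `f` in both directions and,
among qualifying records, selects the one maximizing the product of the two
overlap fractions (the spec of multiple matches is genuinely open; the
product prefers mutually snug records). The matched value is the sum of the
record's alternate-allele frequencies, so multi-allelic reference records
contribute their whole non-reference mass.

Two screens use the panels differently:

- **False positives**: loci with frequency > 90% that match *no* panel are
  removed. With zero panels the filter is a no-op — absence from databases
  cannot be established without databases.
- **Novelty**: one-sided — a locus is novel when no record in any panel
  covers ≥ 50% of the locus's *own* length (inclusive). This deliberately
  differs from the reciprocal rule: a small locus inside a large known
  variant region is not novel, even though the reciprocal criterion would
  reject the match.

Frequency concordance with a panel is the sample Pearson correlation over
matched loci with a Fisher-z 95% CI.

## Gene annotation

Two overlap modes exist because they serve different questions: `any`
(≥ 1 bp) for disruption labelling of individual genes, `reciprocal50` for
map-level genic/non-genic tallies. Disruption spans are labelled 5′→3′ in
transcript orientation over the vocabulary txStart / txEnd / ExonK /
IntronK, with exon and intron numbers 1-based in transcript orientation —
on the minus strand "txStart" is the genomically-right end and exon 1 the
genomically-last exon. Labels are invariant under coordinate translation
(property-tested).

The functional filter keeps deletions hitting ≥ 1 exon and duplications
that either contain an entire gene (dosage increase) or are internal to the
gene body and exonic (potential frame disruption); wholly intronic events
are discarded, and straddling partial duplications fail both branches.
Mixed loci pass if either rule passes, since they contain both event kinds.

Disease tallies count per (gene, phenotype) record — a gene with two
phenotypes of different inheritance contributes to both — and report
percentage breakdowns by inheritance mode (AD/AR/Mito/Unk) and by ICD
class, with unmapped phenotypes under "unclassified". Gene-set enrichment
is the plain hypergeometric upper tail with fold `(k/m)/(K/N)` and optional
Benjamini–Hochberg across sets; no attempt is made to replicate
web-service-specific modified statistics whose backgrounds are external.

## Linkage disequilibrium

LD analysis is restricted to polymorphic bi-allelic deletions: CNP loci
whose cohort genotypes lie in {0, 1, 2} with ≥ 4 carrier individuals, so a
single deletion allele with dosage `2 − CN` explains the data. r² between a
deletion and a SNP is computed from two-locus haplotype frequencies
estimated by EM on the unphased 3×3 genotype table (tolerance 1e-8, ≤ 1000
iterations; only the double heterozygote is phase-ambiguous, and every EM
step preserves the sample allele frequencies). r² = D²/(p_A p_a p_B p_b).
If the EM fails to converge the squared genotype correlation is used and
the choice is visible in the code path. The haplotype-EM estimator (rather
than a composite genotypic correlation) matches the default of standard LD
tools for unphased data. Because the EM margins are fixed, the independent
oracle is a grid search over the single free haplotype frequency at step
1e-4; agreement is within 1e-3 on randomized tables.

Distance from a SNP to a deletion is measured to the nearer breakpoint and
is 0 inside the locus; windows (200 kb … 3 Mb) are inclusive at the
boundary. The tag-SNP is the candidate with maximal r², ties broken by
smaller distance then lower position; "strong LD" is r² ≥ 0.8 (inclusive),
while the GWAS cross-reference uses a strict r² > 0.5. Missing genotypes
are dropped pairwise. Trend summaries use tie-corrected Spearman
correlations.

## Synthetic cohorts

The generator emulates the study conditions of an array-based population
CNV survey and is the package's test bed:

- cohort of 102 diploid samples; 200 loci by default;
- locus lengths log-uniform on [1 kb, 2 Mb]; singleton mass 0.28; other
  carrier frequencies `0.01 + 0.98·Beta(0.6, 2.4)` (right-skewed: most
  loci uncommon, a tail near fixation);
- locus state model del-only / dup-only / mixed with probabilities
  (0.57, 0.22, 0.21); pure loci segregate one allele at Hardy–Weinberg
  proportions, mixed loci assign carriers a deletion or duplication state
  with a 15% homozygous/amplified fraction;
- loci are non-overlapping with a ≥ 2 Mb gap on synthetic 250 Mb
  chromosomes, so distinct truth loci can never fuse under the adjacent-
  merge rule and recovered region boundaries are unambiguous;
- caller noise: Gaussian boundary jitter (sd 200 bp), false-negative rate
  0.01 per event, Poisson false positives (mean 2 per sample), large calls
  (> 500 kb) split into 100–150 kb fragments with small gaps at
  probability 0.1, and a Gamma(20, 1) confidence model for the rare-CNV
  caller so almost all true events clear the confidence cut;
- probe counts are deterministic, `round(12 · length_kb)`, reflecting the
  array's probe enrichment inside CNV regions; determinism makes the
  zero-noise caller output identical to the truth events, which the
  end-to-end identity check relies on;
- each generator draws from its own stream seeded at a fixed offset from
  the master seed, so adding a generator never perturbs another's output,
  and fixture bundles are byte-identical across runs for the same seed.

Tagged SNPs are constructed, not sampled: starting from a SNP whose
haplotype alleles copy the deletion allele (r² = 1), individual haplotype
alleles are greedily flipped until the EM r² is within ±0.03 of the target;
an unreachable target (allele-count granularity at small carrier counts)
raises an error reporting the closest feasible value. Tag injection in the
bundled panels targets deletions with ≥ 8 carriers for that reason.

What the simulator does **not** model — and hence what passing tests do not
show about real data: genotyping error in the CNP matrix, boundary
uncertainty of predefined CNP loci, locus-specific probe density, real
recombination structure (LD arises only through the constructed tags),
population stratification, and sex chromosomes.

## Verification strategy and problem sizes

Every non-trivial statistic is checked against an independent oracle:
CNVR clustering against an explicit overlap-graph union-closure (500
random instances up to 200 calls), the exact HWE test against full
enumeration (exhaustive over all genotype tables up to n = 60, randomized
up to n = 200), and the EM r² against the likelihood grid (500 random
tables, tolerance 1e-3). Recovery suites run ten simulated cohorts
(102 samples, 200 loci, default noise) and require ≥ 93% of truth loci
recovered within binomial 95% bounds and ≥ 95% of injected 0.9-r² tags
returned as the top tag; a noiseless cohort must reproduce the truth set
exactly. These problem sizes keep the full suite under ten seconds while
leaving the binomial bounds meaningfully tight.

## Known limitations

- The adjacent-merge `gap_frac = 0.2` is a convention, not an inference;
  datasets cleaned with a different rule should override it.
- Reference matching returns the single best record; summing across all
  qualifying records is a defensible alternative for fragmented panels.
- The EM r² assumes random mating within the cohort; strong inbreeding
  biases haplotype-frequency estimates.
- The CLI's `report` command summarises one fixture-bundle layout; bespoke
  datasets should use the library API directly.
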