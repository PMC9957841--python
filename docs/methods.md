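# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `pgxstar`, in the order the pipeline runs them.

## Catalog model

A star allele is a named haplotype defined by a set of core variants on a
1-based RefSeqGene coordinate system (the bundled *CYP2D6* fixture uses
NG_008376.4 numbering; the schema is gene-agnostic). Identity of a variant
is `(position, ref, alt)`; rsid, consequence class, and protein change are
annotations carried as inputs — the package never recomputes effect
predictions. Suballeles attach only neutral variants (synonymous,
intronic, other-neutral) to a core. Structural alleles — the \*5 gene
deletion, \*13/\*36 hybrids, \*68 tandems, and all xN/tandem tokens — are
symbolic: they have no variant expansion because they are detected by
SV-aware callers upstream, not by variant-set matching.

Validation collects all problems in one report: duplicate names, two
definitions with identical cores, ref = alt, non-neutral suballele
variants, an activity value on an uncertain/unknown-function allele, rsid
reuse across distinct sites.

The bundled `cyp2d6_catalog.json` is a **synthetic model catalog**:
variants with an rsid sit at documented NG_008376.4 positions (the \*2
backbone rs16947 7870C>T / rs1135840 8588G>C, the \*41 splice variant
rs28371725 8008G>A, the \*17 and \*29 defining missense variants, the \*4
splice defect, the Table-style novel-recipe variants); alleles whose
definitions the sources do not print carry placeholder cores (rsid null)
chosen to keep all cores distinct and to preserve the real nesting
structure (\*2 ⊂ \*17, \*29, \*41, \*45; \*45 ⊂ \*46; \*10 ⊂ \*4, \*70). It
asserts no biology beyond that structure.

### Token grammar

`*<number><uppercase suffix?>` with optional `x<N>` copy number or
`+*<base>` tandem partner; `*68 + *4` (printed spacing) normalizes to
`*68+*4`, which is one allele token on one chromosome. Parsing and
rendering are mutually inverse; `*5` cannot take xN (a deletion has no
copies). Diplotypes order their two tokens by (star number, suffix, copy
number, partner), making `*17/*1` and `*1/*17` the same call.

## Consensus

The rule is absolute: the consensus diplotype is the unique normalized
call shared by at least two callers; no-calls count toward neither support
nor the informative denominator. Ties at maximal support (e.g. 2–2) and
maxima below two are `unresolved` — deliberately *not* broken by a caller
hierarchy, because discordance is escalated to manual review in practice.
Manual adjudications enter as overrides with `manual` provenance after the
automated pass. Agreement is at the whole-diplotype level; allele-level
partial agreement is not used to rescue calls (the conservative reading of
the ≥ 2 rule; a per-haplotype variant would accept more samples at some
risk of chimeric diplotypes).

## Matching and novel-allele nomination

For an observed phased variant set S, candidates are all SNV-defined
alleles whose core is contained in S (the empty-core reference guarantees
one). The background maximizes core size; ties go to the smallest star
number, then lexicographic, and are flagged in the result — the sources do
not state a tie-break, so this is a repository convention chosen for
determinism. Classification of the leftover set S \ core(B):

- empty → known allele B;
- all neutral, equal to a catalogued suballele set → known (B, that
  suballele); suballele matching requires exact set equality;
- all neutral, uncatalogued → novel suballele of B;
- any core-eligible variant → novel star-allele candidate on background B.

Core-eligibility is purely the consequence class carried on the variant
(missense, frameshift, stop-gain, splice, in-frame deletion, high-impact
regulatory). Benign-predicted missense variants therefore still nominate
candidates; nomination is a triage output for human review, not a
PharmVar decision. Candidates deduplicate by (background, extra core set)
with carrier counts. Phasing is trusted as given: the VCF reader rejects
unphased heterozygotes rather than guessing.

## Activity-score phenotype

Per-copy activity: normal 1, decreased 0.5, no-function 0; per-allele
overrides apply before copy scaling (\*10 → 0.25, so \*10x2 → 0.5).
xN tokens multiply the per-copy value by N — a duplicated decreased allele
(\*17x2) scores 1.0, consistent with grouping such alleles as
normal-function. Tandem tokens score 0 (the catalogued hybrid tandems are
no-function arrangements). Uncertain/unknown-function alleles have no
activity; a diplotype containing one is wholly Indeterminate, even when
the other allele alone would force PM — Indeterminate accounting is kept
separate from the four score classes. All scores are `fractions.Fraction`
quarters, so the 1.25/2.25 category boundaries are compared exactly, with
no float-boundary artifacts.

## Population statistics

Allele frequencies are chromosome counts: each resolved diplotype
contributes two tokens, and an xN or tandem token is one chromosome.
Carrier, diplotype, and phenotype proportions are individual counts.

Distinct-allele counting groups structural forms: xN tokens of one base
collapse to a single `*<base>xN` group, tandems and symbolic bases are
their own groups, and SNV-defined alleles count individually; the count
ignores row order and zero-frequency rows.

Function-class rollups apply copy-number scaling to the class (so \*17x2
rolls up as normal, \*1x2 as increased, \*4x2 stays no-function), matching
how published tables group CN-restored alleles.

The structural-carrier proportion has an observed mode (count individuals
with ≥ 1 structural token) and an HWE mode, 1 − (1 − p_SV)², from the
summed structural allele frequency of a table column.

**Hardy–Weinberg exact test.** The locus is highly multi-allelic, so HWE
is tested per allele on a biallelic collapse (focal allele vs. all others
pooled) — the standard reduction when only a generic exact test is named.
The test is the exact conditional (Levene–Haldane) distribution of the
heterozygote count given the allele counts; the p-value sums probabilities
of all heterozygote counts no more probable than observed. It is computed
in exact integer arithmetic (multinomial weights 2^h·n!/(n_AA! h! n_aa!)),
and the unit tests check it to 10⁻¹² against an independent
`fractions.Fraction` oracle built from the allele-pairing formula.
Monomorphic input returns p = 1 with a note. On 1,000 simulated HWE
cohorts (n = 100) the rejection rate at α = 0.05 was 0.038 — exact tests
are conservative.

**Fisher comparisons.** Two-sided Fisher exact p-values on 2×2 tables
(scipy), defined by summing all tables at fixed margins with probability ≤
the observed table's; property tests sweep margins ≤ 30 against a
Fraction-enumeration oracle at 10⁻¹². Raw p-values are reported at the
conventional α = 0.05; an optional Benjamini–Hochberg helper exists for
users who want adjustment, which the headline analyses do not apply.

## Synthetic cohorts

The generator embodies the null hypotheses the statistics assume:

- **HWE sampling**: each individual's two haplotypes are i.i.d. draws from
  the frequency specification. A chi-square GOF of genotype counts against
  HWE expectations was non-significant in 98 of 100 seeded replicates
  (n = 100, biallelic collapse).
- **Caller errors**: independent per (sample, caller): no-call with
  probability `nocall_rate`, else miscall with probability `miscall_rate`
  (one uniformly chosen allele replaced by a uniformly chosen different
  catalog allele), else truth. Defaults 0.05/0.02 are arbitrary knobs —
  the sources report no caller-specific error rates — chosen so that
  five-caller consensus recovers truth for ≥ 99% of samples, the regime
  the consensus rule is designed for. Correlated caller errors (shared
  failure modes on structural alleles) are not modeled.
- **Phased observations**: SNV-defined haplotypes expand to their expected
  variant sets, with optional neutral noise drawn from a fixed pool of
  synonymous/intronic variants shipped with the catalog (exercising
  suballele detection without inventing biology). Structural haplotypes
  emit no observation.
- **Novel injection**: a recipe (background, extra core variants, carrier
  count) replaces phase 0 of deterministically chosen carrier samples with
  `expand(background) ∪ extras`.

All draws flow through one seeded numpy Generator; identical
configurations reproduce cohorts bit-for-bit. Sample ids are `S%06d`.

What the generator does **not** emulate: read-level evidence, depth
profiles, SV breakpoints, linkage with other loci, population
substructure within a column, or caller-correlated errors. Passing tests
therefore validate the analysis logic under its stated assumptions, not
caller behavior on real sequence data.

## Printed-table fixtures

The frequency fixtures transcribe published population columns rounded to
0.1%. Consequences: columns do not total 100 exactly (the primary overall
column sums to 99.0; one per-population column reaches 94.1; comparison
columns are deliberately partial, listing only alleles seen in the primary
cohort), so fixtures load as-printed with no sum check, and validation
happens where a column becomes a simulation source — `SimulationConfig`
renormalizes and requires the pre-renormalization sum within a tolerance
(strict default 0.005; printed-table loaders pass 0.015). The
per-population sample sizes in the population fixture sum to 919 although
the "All" column states 947; both are recorded as printed and the
discrepancy is documented, not resolved. Frequencies derived from these
rounded columns consequently differ from text-derived figures by up to
~0.1 pp (e.g. summed uncertain+unknown rows give 3.5% where the source
text, presumably computed from raw counts, states 3.6%).

## Problem sizes and numerical choices

The acceptance script uses n = 20,000 individuals for the
structural-carrier estimate (binomial SE ≈ 0.3 pp), 50 replicates of the
full n = 947 pipeline for deletion-frequency recovery (SE of the mean
≈ 0.09 pp), and 200 replicates at n = 49 for the single-population
recovery (SE ≈ 0.33 pp) — sizes at which Monte-Carlo error is comfortably
inside the reported precision while a full run stays under a minute.
Display rounding is half-away-from-zero to one decimal, matching printed
tables; internal arithmetic is unrounded.

## Known limitations

- The catalog is a structural model, not a PharmVar release; a live
  importer is future work, and suballele numbering semantics are opaque
  names.
- Consensus is diplotype-level only; no partial-credit rescue.
- The GRCh38 ↔ RefSeqGene coordinate conversion is a single affine
  offset-plus-reverse-complement map adequate for SNVs and simple indels
  inside the gene region; it does not left-normalize against a reference
  sequence.
- Phenoconversion, drug-specific dosing, hybrid/CNV detection from variant
  sets, and deleteriousness scoring are out of scope.
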