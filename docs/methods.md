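# Methods

## The translation model

`pgxtranslate` infers a diplotype — an unordered pair of named haplotypes —
for each sample at each pharmacogene from unphased genotypes. The model
rests on two conventions of curated PGx haplotype tables:

* the first haplotype column is the reference (wild-type) haplotype and its
  alleles define each variant's **major** allele; every other allele seen in
  a row is a **minor** allele of that variant;
* haplotypes are identified by their combination of minor alleles, compared
  as verbatim strings, so SNVs and short indels are handled identically.

Alleles are mapped to the integer codes 0 (major) and 1, 3, 5 (minors, in
order of first appearance scanning haplotype columns left to right). A
haplotype becomes a code vector over the gene's variants; a diplotype is
the elementwise sum of two haplotype vectors; a sample's unphased genotype
becomes the per-variant sum of its two allele codes. Matching a sample is
then exact vector equality against the gene's n(n+1)/2 enumerated
diplotype sums. Because only sums are compared, phase information is never
needed — which is also the model's main limitation: it cannot distinguish
arrangements of the same allele multiset across chromosomes, and treats
identical sums as identical diplotypes.

### Why all matches are returned

With at most two minor alleles per variant, the sums of any two codes from
{0, 1, 3} are distinct over unordered pairs, so a sum vector identifies at
most one diplotype. With three minors, 1 + 5 = 3 + 3 = 6: two different
haplotype pairs can share a sum vector. A first-match loop would silently
depend on enumeration order, so the matcher collects *every* diplotype with
an equal sum, flags the result ambiguous when there is more than one, and
reports the most severe phenotype class among the candidates (Var/Var >
WT/Var > WT/WT). An empty match set is a NoCall, never a nearest-neighbour
guess.

### Phenotype classes

The three-colour scheme is deliberately coarse: WT/WT (green) when both
matched haplotypes are the reference, WT/Var (yellow) with exactly one
reference haplotype, Var/Var (red) otherwise. It encodes the assumption
that carrying more variant haplotypes makes an abnormal metabolic status
more likely; it does not attempt poor/intermediate/extensive/ultrarapid
metabolizer categories, activity scores, or copy-number alleles (`*1xN`),
all of which need functional annotation this package does not model.
Per-variant translation applies the same scheme to a single genotype call:
zero, one or two minor alleles → WT/WT, WT/Var, Var/Var.

## Curation rules and their rationale

* **rsID recognition** is the regex `^rs[0-9]+$`; HGVS-style or positional
  labels are treated as unregistered and their rows dropped, restricting
  translation to dbSNP-registered variants that a VCF ID column can carry.
* **Dependent-haplotype removal**: any haplotype carrying a minor allele at
  a dropped row is removed (the reference never is), so every surviving
  haplotype is still completely defined by the surviving variants.
* **Duplicate columns** keep the earliest-listed name; dropped names are
  recorded as aliases rather than discarded, since star-allele synonyms are
  common in practice.
* **Blank cells** in source tables are read as the reference allele of
  their row, the prevailing dialect of published tables.
* Minor-allele metadata is captured from the *full* table at load time, so
  the variant annotation still knows a minor allele whose only carrier
  haplotype was curated away (such variants simply contribute 0 to every
  surviving vector).
* The unified cross-gene annotation refuses to merge conflicting rsID
  definitions (different major allele, or incompatible minor orderings);
  conflicts are surfaced as errors because any silent resolution would
  change genotype encodings behind the user's back.

## Missing data and VCF handling

Genotypes are matched by the VCF ID column only; coordinates never enter
the math and no liftover is attempted. Both `/` and `|` separators are
accepted and phase is discarded. `./.` and half calls (single-allele GTs,
e.g. hemizygous males on chrX, which the model does not otherwise treat)
are explicit missing values. For a gene variant absent from a sample's
profile, two policies exist:

* `assume_ref` (default): the variant contributes 0 and its rsID is
  recorded in `missing_rsids` — appropriate for sparse genotyping panels
  where absence usually means "not assayed, assumed reference";
* `no_call`: the whole gene becomes NoCall for that sample — appropriate
  when absence means the call failed.

The choice is explicit in the API and CLI because it changes results for
incomplete profiles; reports carry the missing rsIDs either way.

## Summary statistics

Per-gene and per-sample tables report the percentage of samples/genes in
each of the four classes, rounded to one decimal; the rounding residual is
assigned to the largest category so every row sums to exactly 100.0.

## Landscape statistics

The shared-drug gene graph has one node per gene and an undirected edge
between two genes that metabolize at least one common drug (exact match
after case-folding and trimming; no synonym resolution). Density is
|E| / (|V|(|V|−1)/2); per-class densities use the class-restricted record
subset and are reported as undefined for classes with fewer than two
genes. All input genes count toward |V|, including genes with no drug
annotations. "Squareness" is the haplotype/variant count ratio of each
curated table. Chromosome × ADMET-class counts always list all 24 human
chromosome labels so empty chromosomes are visible.

## Knowledge-base updates

`add_haplotype` appends a column (and, for brand-new rsIDs, a row whose
existing haplotypes all take the major allele — extending every code
vector with zeros, which provably leaves all previous diplotype matches
unchanged). `create_gene_table` builds a table whose first listed haplotype
is the all-major reference. Both validate structure only (no functional
evidence checking), reject duplicates of existing columns, and return
tables that are fixed points of the curation pipeline. Updates are written
as timestamp-versioned files with a JSON provenance sidecar rather than
mutating tables in place, so any past translation run remains reproducible.

## Synthetic data

The fixture generator emulates the structure of curated tables and cohort
VCFs, not population genetics: alleles are drawn uniformly from the four
bases with a 10% chance of a 2–4 bp indel string (to exercise verbatim
comparison), every non-reference haplotype gets ≥1 minor allele, columns
are pairwise distinct, and cohort genotypes are derived *exactly* from
per-sample diplotypes drawn uniformly (or from user-supplied frequencies)
over each gene's diplotypes. There is no linkage disequilibrium, no
Hardy–Weinberg structure, no genotyping error model, and fabricated
coordinates; passing round-trip tests therefore demonstrates correctness
of the encoding/matching algebra, not robustness to real-world genotyping
noise. A dedicated generator builds tables with deliberate 1+5 = 3+3 sum
collisions to exercise the ambiguity contract. All generation is
deterministic under a seed.

Default problem sizes used by the test suite and the acceptance script —
200 random tables (≤10 variants, ≤8 haplotypes, ≤3 minors) for oracle
equivalence, 10 genes × 100 samples (≈1000 sample-genes) for round-trip
recovery — were chosen as the smallest cohorts that exercise every code
path including ambiguous collisions; all checks run in seconds.

## Worked-example fixtures

The UGT1A5-, TPMT- and ASIC2-style tables in `pgxtranslate.examples` are
synthetic reconstructions that preserve the instructive structure of those
genes' published tables (which variants are registered, which haplotype
each minor allele defines, the resulting code vectors) but are not copies
of any database release and must not be used clinically.

## Known limitations

* No phasing, imputation, copy-number alleles, or CPIC metabolizer
  categories; recommendation links are emitted as opaque keys.
* Cross-gene rsID conflicts abort annotation building rather than being
  resolved heuristically.
* Positional (chrom/pos) VCF matching is unsupported; records without an
  rsID in the ID column are skipped.
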