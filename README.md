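# pgxtranslate

Star-allele haplotype curation and diplotype translation for pharmacogenes.

Clinical pharmacogenomics (PGx) asks which version of a drug-metabolism gene
a patient carries. The community encodes that knowledge as *haplotype
tables*: for each pharmacogene, a variant × haplotype matrix of alleles in
which columns are named star alleles (`*1`, `*2`, …) and the first column is
the reference (wild-type) haplotype, whose alleles define each variant's
major allele. `pgxtranslate` turns such tables plus a multi-sample VCF of
unphased genotypes into per-sample, per-gene diplotype calls (e.g. `*2/*3`)
and a three-colour metabolic status, without requiring phased data.

## Method

For each gene the pipeline:

1. **Curates** the table — drops variant rows without a dbSNP rsID, drops
   haplotypes that were defined by a minor allele of a dropped row (so every
   retained haplotype is still fully described), and collapses duplicate
   columns (earliest name kept, aliases recorded).
2. **Encodes** alleles numerically: the major allele of each variant → 0,
   its minor alleles → 1, 3, 5 in order of first appearance (at most three
   minors per variant).
3. **Enumerates** all n(n+1)/2 unordered diplotypes of the n haplotypes;
   each diplotype is represented by the elementwise sum of its two
   haplotype code vectors.
4. **Encodes each sample** the same way — the two allele codes at every
   variant are summed, so phase never matters — and **matches** the sample
   vector against the enumerated diplotype sums.
5. **Classifies** the match: both haplotypes reference → `WT/WT` (green),
   one reference → `WT/Var` (yellow), none → `Var/Var` (red), no match →
   `NoCall` (grey).

The code set {0, 1, 3, 5} makes pair sums unique for up to two minor
alleles per variant, but 1 + 5 = 3 + 3 can collide at tri-minor variants,
so the matcher returns **all** equal-sum diplotypes and flags ambiguity
instead of stopping at the first hit.

The package also ships per-variant translation, cohort summary statistics,
knowledge-base updates (add a haplotype, create a gene table — written as
versioned files), pharmacogene landscape statistics (shared-drug gene graph
density, table "squareness", chromosome × ADMET-class counts), and a
synthetic-data module that generates tables and cohort VCFs with known
ground truth.

## Worked example

```python
from pgxtranslate import (curate, derive_annotation, encode_numeric,
                          encode_sample, enumerate_diplotypes, match_diplotype)
from pgxtranslate.examples import ugt1a5_table, ugt1a5_sample

table = curate(ugt1a5_table())          # drops 'c.776G>C' row, then *4
encoded = encode_numeric(table)
print(list(encoded.code_vector("*2")))  # [1, 0, 0, 0]
print(list(encoded.code_vector("*3")))  # [0, 1, 0, 0]

diplotypes = enumerate_diplotypes(encoded)
print(len(diplotypes))                  # 6

annotation = derive_annotation([table])
vector = encode_sample(ugt1a5_sample(), encoded, annotation)
print(vector.sum_vector)                # (1, 1, 0, 0)

result = match_diplotype(vector, diplotypes)
print(result.diplotype, result.phenotype.value, result.phenotype.color)
# *2/*3 Var/Var red
```

The sample is heterozygous (C/G) at rs12475068 — the variant defining `*2`
— and heterozygous at the `*3`-defining variant, so its sum vector
`<1,1,0,0>` equals the `*2` + `*3` diplotype sum: the sample carries one
copy of each variant haplotype and is reported as the "abnormal" Var/Var
class.

The same workflow is available from the shell:

```sh
pgxtranslate translate --vcf cohort.vcf --tables tables/ -o report.tsv
pgxtranslate stats --metadata gene_drugs.csv -o landscape.tsv
pgxtranslate update --tables tables/ --update new_haplotype.json
```

`translate` writes the five-column report (sample_id, gene, diplotype,
phenotype_color, recommendation_link) plus per-gene and per-sample
phenotype percentage summaries and a JSON run manifest.

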