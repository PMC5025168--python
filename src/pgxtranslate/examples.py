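"""Small illustrative fixtures used in the documentation and tests.

These are synthetic reconstructions shaped like well-known pharmacogene
tables (UGT1A5, TPMT, ASIC2). They preserve the structural facts that make
the examples instructive — which variants are dbSNP-registered, which
haplotype each minor allele defines, the resulting code vectors — but are
not copies of any curated database release and must not be used for
clinical interpretation.
"""

from __future__ import annotations

from .genotypes import GenotypeCall, GenotypeProfile
from .haplotypes import HaplotypeTable, VariantDef, load_haplotype_table

#: UGT1A5-style table. Four haplotypes; *2 and *3 are each defined by one
#: registered SNP, while *4 is defined by minor alleles of the HGVS-labelled
#: row (plus two registered companions), so curation removes that row and
#: then *4 itself. The curated table is 4 variants × 3 haplotypes with
#: *2 → <1,0,0,0> and *3 → <0,1,0,0>.
UGT1A5_TEXT = """\
variant\t*1\t*2\t*3\t*4
rs12475068\tC\tG\tC\tC
rs28898617\tT\tT\tC\tT
rs28946877\tA\tA\tA\tG
rs35386426\tG\tG\tG\tA
c.776G>C\tG\tG\tG\tC
"""


def ugt1a5_table() -> HaplotypeTable:
    """The UGT1A5-style example table, uncurated."""
    return load_haplotype_table(UGT1A5_TEXT, gene="UGT1A5")


def ugt1a5_sample(sample_id: str = "SAMPLE1") -> GenotypeProfile:
    """A genotype profile heterozygous at the *2- and *3-defining variants.

    Encodes to <1,1,0,0>, the sum vector of the *2/*3 diplotype.
    """
    return GenotypeProfile(
        sample_id=sample_id,
        calls={
            "rs12475068": GenotypeCall(alleles=("C", "G")),
            "rs28898617": GenotypeCall(alleles=("C", "T")),
            "rs28946877": GenotypeCall(alleles=("A", "A")),
            "rs35386426": GenotypeCall(alleles=("G", "G")),
        },
    )


#: TPMT-style table carrying rs1800460 and rs2842934 in separate haplotypes;
#: the knowledge-base update example appends a haplotype named
#: "rs1800460, rs2842934" engaging both and just these two variants.
TPMT_TEXT = """\
variant\t*1\t*3B\t*3C
rs1800460\tC\tT\tC
rs2842934\tT\tT\tC
rs1142345\tA\tA\tG
"""


def tpmt_table() -> HaplotypeTable:
    return load_haplotype_table(TPMT_TEXT, gene="TPMT")


def asic2_variants() -> list[VariantDef]:
    """The single lithium-response variant used to create the ASIC2 table."""
    return [VariantDef("rs11869731", "ASIC2", major_allele="G", minor_alleles=("C",))]
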