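"""Diplotype inference from unphased genotypes by sum-vector matching.

A gene with *n* curated haplotypes has n(n+1)/2 unordered diplotypes
(self-pairs included). Each diplotype is represented by the elementwise sum
of its two haplotypes' numeric code vectors; a sample's unphased genotypes
are encoded the same way (the two allele codes at each variant are summed)
and matched against the enumerated sums.

Because the minor-allele code set {1, 3, 5} admits the collision
1 + 5 = 3 + 3 at a tri-minor variant, a sum vector does not always identify
a unique diplotype. Matching therefore returns *all* diplotypes whose sum
vector equals the sample's, and flags the result ambiguous when there is
more than one. An empty match set yields a NoCall.

Phenotype classes follow the three-colour scheme: WT/WT (green) when both
matched haplotypes are the reference, WT/Var (yellow) with one reference
haplotype, Var/Var (red) with none; NoCall is grey. When ambiguous matches
disagree, the most severe class is reported and the ambiguity flag kept.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, UnknownAlleleError
from .genotypes import GenotypeProfile
from .haplotypes import (
    AnnotationEntry,
    EncodedTable,
    VariantAnnotation,
)


class Phenotype(str, enum.Enum):
    """Three-colour metabolic status classes plus NoCall."""

    WT_WT = "WT/WT"
    WT_VAR = "WT/Var"
    VAR_VAR = "Var/Var"
    NO_CALL = "NoCall"

    @property
    def color(self) -> str:
        return _COLORS[self]

    @property
    def severity(self) -> int:
        """Ordering WT/WT < WT/Var < Var/Var used to resolve ambiguity."""
        return _SEVERITY[self]


_COLORS = {
    Phenotype.WT_WT: "green",
    Phenotype.WT_VAR: "yellow",
    Phenotype.VAR_VAR: "red",
    Phenotype.NO_CALL: "grey",
}
_SEVERITY = {
    Phenotype.WT_WT: 0,
    Phenotype.WT_VAR: 1,
    Phenotype.VAR_VAR: 2,
    Phenotype.NO_CALL: -1,
}


class MissingPolicy(str, enum.Enum):
    """How to handle a gene variant absent from a sample's genotype profile.

    ``assume_ref`` treats the missing variant as homozygous major (code 0),
    recording the rsID; ``no_call`` abandons the gene for that sample.
    """

    ASSUME_REF = "assume_ref"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class DiplotypeVector:
    """An unordered haplotype pair and the sum of their code vectors."""

    gene: str
    haplotype_pair: tuple[str, str]
    sum_vector: tuple[int, ...]

    @property
    def name(self) -> str:
        return "/".join(self.haplotype_pair)


@dataclass
class SampleGeneVector:
    """A sample's summed genotype codes over one gene's variants."""

    sample_id: str
    gene: str
    sum_vector: tuple[int, ...]
    missing_rsids: tuple[str, ...] = ()
    policy_applied: MissingPolicy = MissingPolicy.ASSUME_REF
    usable: bool = True


@dataclass
class TranslationResult:
    """Outcome of matching one sample at one gene."""

    sample_id: str
    gene: str
    matches: tuple[tuple[str, str], ...]
    phenotype: Phenotype
    missing_rsids: tuple[str, ...] = ()
    link_key: str | None = None

    @property
    def ambiguous(self) -> bool:
        return len(self.matches) > 1

    @property
    def diplotype(self) -> str:
        """``A/B`` or ``A/B|C/D`` when ambiguous; empty for NoCall."""
        return "|".join("/".join(pair) for pair in self.matches)

    def to_record(self) -> dict:
        return {
            "sample": self.sample_id,
            "gene": self.gene,
            "diplotype": self.diplotype,
            "phenotype": {"category": self.phenotype.value, "color": self.phenotype.color},
            "ambiguous": self.ambiguous,
            "missing_rsids": list(self.missing_rsids),
            "link": self.link_key or "",
        }


def enumerate_diplotypes(e: EncodedTable) -> list[DiplotypeVector]:
    """All n(n+1)/2 unordered haplotype pairs with their sum vectors.

    Order is deterministic: the reference haplotype first, remaining
    haplotypes lexicographically, then pairs in combinations-with-replacement
    order over that sequence.
    """
    ref = e.reference_name
    names = [ref] + sorted(n for n in e.haplotype_names if n != ref)
    vectors = {n: e.code_vector(n) for n in names}
    out = []
    for a, b in itertools.combinations_with_replacement(names, 2):
        s = vectors[a] + vectors[b]
        out.append(DiplotypeVector(e.gene, (a, b), tuple(int(x) for x in s)))
    return out


def encode_sample(
    profile: GenotypeProfile,
    e: EncodedTable,
    annotation: VariantAnnotation,
    missing_policy: MissingPolicy = MissingPolicy.ASSUME_REF,
) -> SampleGeneVector:
    """Numerically encode a sample's genotypes over one gene's variants.

    Each observed allele is mapped to its code through the unified
    annotation and the pair is summed per variant. Variants absent from the
    profile (or explicitly missing calls) are handled per *missing_policy*.
    """
    missing_policy = MissingPolicy(missing_policy)
    sums: list[int] = []
    missing: list[str] = []
    for rsid in e.rsids:
        call = profile.calls.get(rsid)
        if call is None or call.missing:
            missing.append(rsid)
            sums.append(0)
            continue
        entry: AnnotationEntry = annotation[rsid]
        total = 0
        for allele in call.alleles:
            try:
                total += entry.code(allele)
            except KeyError:
                raise UnknownAlleleError(
                    f"{profile.sample_id}/{rsid}: allele {allele!r} not among "
                    f"major {entry.major_allele!r} / minors {entry.minor_alleles}"
                ) from None
        sums.append(total)
    usable = not (missing and missing_policy is MissingPolicy.NO_CALL)
    return SampleGeneVector(
        sample_id=profile.sample_id,
        gene=e.gene,
        sum_vector=tuple(sums),
        missing_rsids=tuple(missing),
        policy_applied=missing_policy,
        usable=usable,
    )


def match_diplotype(
    s: SampleGeneVector, diplotypes: Sequence[DiplotypeVector]
) -> TranslationResult:
    """Find every diplotype whose sum vector equals the sample's.

    All matches are returned (not the first found); more than one sets the
    ambiguity flag, none yields NoCall. The phenotype is assigned from the
    match set, most-severe-wins under ambiguity.
    """
    if not s.usable:
        return TranslationResult(
            s.sample_id, s.gene, (), Phenotype.NO_CALL, s.missing_rsids
        )
    target = np.asarray(s.sum_vector)
    matches: list[tuple[str, str]] = []
    reference = None
    for d in diplotypes:
        if len(d.sum_vector) != len(s.sum_vector):
            raise ConsistencyError(
                f"{s.gene}: sample vector length {len(s.sum_vector)} vs "
                f"diplotype vector length {len(d.sum_vector)}"
            )
        if reference is None:
            reference = d.haplotype_pair[0]
        if np.array_equal(np.asarray(d.sum_vector), target):
            matches.append(d.haplotype_pair)
    result = TranslationResult(
        s.sample_id, s.gene, tuple(matches), Phenotype.NO_CALL, s.missing_rsids
    )
    result.phenotype = assign_phenotype(result, reference or "")
    if matches:
        result.link_key = f"{s.gene}:{result.diplotype}"
    return result


def assign_phenotype(r: TranslationResult, reference_name: str) -> Phenotype:
    """Classify a match set against the reference haplotype.

    ref/ref → WT/WT, ref/other → WT/Var, other/other → Var/Var; no match
    → NoCall. Disagreeing ambiguous matches report the most severe class.
    """
    if not r.matches:
        return Phenotype.NO_CALL
    worst = Phenotype.WT_WT
    for a, b in r.matches:
        n_ref = (a == reference_name) + (b == reference_name)
        cat = (Phenotype.VAR_VAR, Phenotype.WT_VAR, Phenotype.WT_WT)[n_ref]
        if cat.severity > worst.severity:
            worst = cat
    return worst


def translate_variant(
    call_alleles: Sequence[str] | None, rsid: str, annotation: VariantAnnotation
) -> Phenotype:
    """Per-variant translation: classify a single genotype call.

    Both alleles major → WT/WT; exactly one minor → WT/Var; two minor
    alleles (equal or not) → Var/Var; a missing call → NoCall.
    """
    if call_alleles is None or len(call_alleles) != 2:
        return Phenotype.NO_CALL
    entry = annotation[rsid]
    n_minor = 0
    for allele in call_alleles:
        try:
            if entry.code(allele) != 0:
                n_minor += 1
        except KeyError:
            raise UnknownAlleleError(
                f"{rsid}: allele {allele!r} not among {entry.alleles}"
            ) from None
    return (Phenotype.WT_WT, Phenotype.WT_VAR, Phenotype.VAR_VAR)[n_minor]


def translate_cohort(
    profiles: Iterable[GenotypeProfile],
    encoded_tables: Sequence[EncodedTable],
    annotation: VariantAnnotation,
    missing_policy: MissingPolicy = MissingPolicy.ASSUME_REF,
) -> list[TranslationResult]:
    """Translate every sample at every gene; results sorted (sample, gene)."""
    diplotypes = {e.gene: enumerate_diplotypes(e) for e in encoded_tables}
    results = []
    for profile in profiles:
        for e in encoded_tables:
            vec = encode_sample(profile, e, annotation, missing_policy)
            results.append(match_diplotype(vec, diplotypes[e.gene]))
    results.sort(key=lambda r: (r.sample_id, r.gene))
    return results


_CATEGORIES = [p.value for p in (Phenotype.WT_WT, Phenotype.WT_VAR, Phenotype.VAR_VAR, Phenotype.NO_CALL)]


def _percentage_table(
    results: Iterable[TranslationResult], by: str
) -> pd.DataFrame:
    rows: dict[str, dict[str, int]] = {}
    for r in results:
        key = r.gene if by == "gene" else r.sample_id
        rows.setdefault(key, dict.fromkeys(_CATEGORIES, 0))
        rows[key][r.phenotype.value] += 1
    out = {}
    for key in sorted(rows):
        counts = rows[key]
        total = sum(counts.values())
        pct = {c: round(100.0 * n / total, 1) for c, n in counts.items()}
        # pin the rounding residual on the largest category so rows sum to 100.0
        residual = round(100.0 - sum(pct.values()), 1)
        if residual:
            largest = max(_CATEGORIES, key=lambda c: counts[c])
            pct[largest] = round(pct[largest] + residual, 1)
        out[key] = pct
    frame = pd.DataFrame.from_dict(out, orient="index", columns=_CATEGORIES)
    frame.index.name = by
    return frame


def summarize_by_gene(results: Iterable[TranslationResult]) -> pd.DataFrame:
    """Per gene, the percentage of samples in each phenotype class."""
    return _percentage_table(results, by="gene")


def summarize_by_sample(results: Iterable[TranslationResult]) -> pd.DataFrame:
    """Per sample, the percentage of its genes in each phenotype class."""
    return _percentage_table(results, by="sample")
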