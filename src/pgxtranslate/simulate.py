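"""Synthetic fixtures: haplotype tables and cohort VCFs with known truth.

Every other module is testable offline against data produced here: random
but reproducible star-allele tables (alleles drawn from the four bases plus
occasional short indel strings, exercising verbatim allele comparison), and
multi-sample VCFs whose genotypes are generated *from* known diplotypes so
translation can be checked against ground truth.

No population-genetic realism is attempted (no linkage, no Hardy–Weinberg):
diplotype frequencies are plain sampling knobs, uniform by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PgxError
from .haplotypes import HaplotypeTable, _derive_variants, curate

BASES = ("A", "C", "G", "T")

#: Enumerate-all-columns threshold; above this, rejection sampling is used.
_ENUM_LIMIT = 8192


def _draw_allele(rng: np.random.Generator, exclude: set[str], indel_prob: float) -> str:
    """A single-base allele, or occasionally a 2–4 bp indel-style string."""
    while True:
        if rng.random() < indel_prob:
            length = int(rng.integers(2, 5))
            allele = "".join(rng.choice(BASES, size=length))
        else:
            allele = str(rng.choice(BASES))
        if allele not in exclude:
            return allele


def generate_table(
    gene: str,
    n_variants: int,
    n_haplotypes: int,
    max_minors: int = 2,
    seed: int = 0,
    indel_prob: float = 0.1,
) -> HaplotypeTable:
    """A random, reproducible haplotype table.

    The first haplotype (``*1``) is the all-major reference; every other
    haplotype carries at least one minor allele and all columns are pairwise
    distinct. Raises if more distinct haplotypes are requested than the
    allele pools allow.
    """
    if n_variants < 1 or n_haplotypes < 1:
        raise PgxError("need at least one variant and one haplotype")
    if not 1 <= max_minors <= 3:
        raise PgxError("max_minors must be between 1 and 3")
    rng = np.random.default_rng(seed)

    rsids = [f"rs{n}" for n in rng.choice(9_000_000, size=n_variants, replace=False) ]
    pools: list[tuple[str, ...]] = []
    for _ in range(n_variants):
        major = _draw_allele(rng, set(), indel_prob)
        n_minor = int(rng.integers(1, max_minors + 1))
        minors: list[str] = []
        while len(minors) < n_minor:
            minors.append(_draw_allele(rng, {major, *minors}, indel_prob))
        pools.append((major, *minors))

    n_possible = 1
    for pool in pools:
        n_possible *= len(pool)
        if n_possible > _ENUM_LIMIT:
            break
    if n_possible <= _ENUM_LIMIT and n_haplotypes > n_possible:
        raise PgxError(
            f"{gene}: {n_haplotypes} distinct haplotypes requested but only "
            f"{n_possible} allele combinations exist"
        )

    reference = tuple(pool[0] for pool in pools)
    columns: list[tuple[str, ...]] = [reference]
    if n_possible <= _ENUM_LIMIT:
        candidates = [c for c in itertools.product(*pools) if c != reference]
        order = rng.permutation(len(candidates))
        columns.extend(candidates[i] for i in order[: n_haplotypes - 1])
    else:
        seen = {reference}
        while len(columns) < n_haplotypes:
            col = tuple(pool[int(rng.integers(len(pool)))] for pool in pools)
            if col not in seen:
                seen.add(col)
                columns.append(col)

    frame = pd.DataFrame(
        {f"*{i + 1}": list(col) for i, col in enumerate(columns)}, index=rsids
    )
    return HaplotypeTable(gene=gene, alleles=frame, variants=_derive_variants(gene, frame))


def generate_ambiguous_table(gene: str = "AMBIG1", seed: int = 0) -> HaplotypeTable:
    """A table whose diplotype sum vectors deliberately collide.

    The first variant carries three minor alleles coded 1, 3 and 5; the
    haplotypes carrying codes 1 and 5 sum to 6, exactly the self-pair sum of
    the code-3 haplotype (1 + 5 = 3 + 3). This exercises the all-matches
    ambiguity contract of the matching layer.
    """
    rng = np.random.default_rng(seed)
    rsids = [f"rs{n}" for n in rng.choice(9_000_000, size=2, replace=False)]
    # variant 1: major A, minors C, G, T (codes 1, 3, 5); variant 2 binary
    frame = pd.DataFrame(
        {
            "*1": ["A", "T"],
            "*2": ["C", "T"],  # code 1 at variant 1
            "*3": ["G", "T"],  # code 3
            "*4": ["T", "T"],  # code 5
            "*5": ["A", "C"],  # minor only at variant 2
        },
        index=rsids,
    )
    return HaplotypeTable(gene=gene, alleles=frame, variants=_derive_variants(gene, frame))


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort: one row per sample × gene."""

    table: pd.DataFrame  # columns: sample, gene, haplotype_a, haplotype_b, diplotype


def generate_cohort_vcf(
    tables: Sequence[HaplotypeTable],
    n_samples: int,
    diplotype_frequencies: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[str, pd.DataFrame]:
    """Simulate a multi-sample VCF with known per-gene diplotypes.

    Each sample draws one diplotype per gene — uniformly over that gene's
    n(n+1)/2 unordered haplotype pairs unless *diplotype_frequencies* gives
    a distribution — and its genotype at every variant is the unordered
    allele pair contributed by the two haplotypes, written unphased. With
    *missing_rate* > 0, calls are independently replaced by ``./.``.

    Returns the VCF text and the truth table (sample, gene, haplotype_a,
    haplotype_b, diplotype).
    """
    rng = np.random.default_rng(seed)
    tables = [t if t.curated else curate(t) for t in tables]
    samples = [f"S{i:04d}" for i in range(n_samples)]

    header = ["##fileformat=VCFv4.2"]
    for i, _ in enumerate(tables):
        header.append(f"##contig=<ID=chr{i + 1}>")
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )

    truth_rows = []
    body = []
    for gi, t in enumerate(tables):
        names = list(t.haplotype_names)
        pairs = list(itertools.combinations_with_replacement(names, 2))
        if diplotype_frequencies and t.gene in diplotype_frequencies:
            freq = diplotype_frequencies[t.gene]
            keys = list(freq)
            probs = np.array([freq[k] for k in keys], dtype=float)
            if not np.isclose(probs.sum(), 1.0):
                raise PgxError(f"{t.gene}: diplotype frequencies must sum to 1")
            chosen = [keys[i] for i in rng.choice(len(keys), size=n_samples, p=probs)]
        else:
            chosen = [pairs[i] for i in rng.integers(len(pairs), size=n_samples)]
        for sample, (a, b) in zip(samples, chosen):
            truth_rows.append(
                {
                    "sample": sample,
                    "gene": t.gene,
                    "haplotype_a": a,
                    "haplotype_b": b,
                    "diplotype": f"{a}/{b}",
                }
            )
        for vi, v in enumerate(t.variants):
            alt = list(v.minor_alleles)
            allele_index = {v.major_allele: 0}
            allele_index.update({m: j + 1 for j, m in enumerate(alt)})
            fields = [
                f"chr{gi + 1}",
                str(1000 + vi * 100),
                v.identifier,
                v.major_allele,
                ",".join(alt) if alt else ".",
                ".",
                "PASS",
                ".",
                "GT",
            ]
            for sample, (a, b) in zip(samples, chosen):
                if missing_rate and rng.random() < missing_rate:
                    fields.append("./.")
                    continue
                ia = allele_index[t.alleles.at[v.identifier, a]]
                ib = allele_index[t.alleles.at[v.identifier, b]]
                fields.append(f"{min(ia, ib)}/{max(ia, ib)}")
            body.append("\t".join(fields))

    truth = pd.DataFrame(
        truth_rows, columns=["sample", "gene", "haplotype_a", "haplotype_b", "diplotype"]
    )
    return "\n".join(header + body) + "\n", truth
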