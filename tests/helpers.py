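"""Independent oracles used by the test suite.

These recompute expected results from first principles — directly from the
allele matrix, with none of the package's encoding/enumeration machinery —
so the implementation is checked against a genuinely separate path.
"""

from __future__ import annotations

import itertools

import pandas as pd

MINOR_CODES = (1, 3, 5)


def oracle_codes(alleles: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-variant allele→code map, derived by scanning the raw matrix:
    column 1 allele → 0, other alleles → 1/3/5 in order of appearance."""
    maps: dict[str, dict[str, int]] = {}
    ref = alleles.columns[0]
    for rsid, row in alleles.iterrows():
        codes = {row[ref]: 0}
        for allele in row:
            if allele not in codes:
                codes[allele] = MINOR_CODES[len(codes) - 1]
        maps[str(rsid)] = codes
    return maps


def oracle_pair_sums(alleles: pd.DataFrame) -> dict[tuple[str, str], tuple[int, ...]]:
    """Sum vector of every unordered haplotype pair, from the raw matrix."""
    codes = oracle_codes(alleles)
    vectors = {
        name: tuple(codes[str(rsid)][alleles.at[rsid, name]] for rsid in alleles.index)
        for name in alleles.columns
    }
    sums = {}
    for a, b in itertools.combinations_with_replacement(alleles.columns, 2):
        sums[(a, b)] = tuple(x + y for x, y in zip(vectors[a], vectors[b]))
    return sums


def oracle_match(
    alleles: pd.DataFrame, genotype: dict[str, tuple[str, str]]
) -> set[tuple[str, str]]:
    """Brute-force matching: encode the genotype against the raw matrix and
    return every unordered pair whose sum vector equals it."""
    codes = oracle_codes(alleles)
    sample = tuple(
        codes[str(rsid)][genotype[str(rsid)][0]] + codes[str(rsid)][genotype[str(rsid)][1]]
        for rsid in alleles.index
    )
    return {
        tuple(sorted(pair))
        for pair, s in oracle_pair_sums(alleles).items()
        if s == sample
    }


def oracle_tally(results, by: str) -> dict[str, dict[str, float]]:
    """Direct percentage tally of translation results, rounded to 1 dp."""
    groups: dict[str, list[str]] = {}
    for r in results:
        key = r.gene if by == "gene" else r.sample_id
        groups.setdefault(key, []).append(r.phenotype.value)
    out = {}
    for key, cats in groups.items():
        out[key] = {
            c: round(100.0 * cats.count(c) / len(cats), 1)
            for c in ("WT/WT", "WT/Var", "Var/Var", "NoCall")
        }
    return out
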