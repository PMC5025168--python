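"""Pharmacogene landscape statistics.

Builds the shared-drug gene graph — nodes are pharmacogenes, an edge joins
two genes that participate in the metabolism of at least one common drug —
and computes its density, per-ADMET-class subgraph densities, haplotype
table "squareness" (haplotypes per variant), chromosome × class counts and
the number of drugs metabolized by two or more genes.

Input is a long-format gene metadata table (one row per gene–drug pair)
with columns gene, chromosome, admet_class, drug. Drug names are matched
exactly after case-folding and whitespace trimming; no synonym resolution.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import networkx as nx
import pandas as pd

from .errors import PgxError, TableFormatError
from .haplotypes import HaplotypeTable

ADMET_CLASSES = ("phase I", "phase II", "transporter", "modifier", "unknown")

#: Human chromosome labels reported in the chromosome × class contingency
#: table (chromosomes with zero pharmacogenes are reported explicitly).
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


@dataclass
class GeneRecord:
    """One pharmacogene's metadata: location, ADMET class, associated drugs."""

    gene: str
    chromosome: str
    admet_class: str = "unknown"
    drugs: frozenset[str] = frozenset()
    n_variants: int = 0
    n_haplotypes: int = 0

    def __post_init__(self) -> None:
        if self.admet_class not in ADMET_CLASSES:
            raise ValueError(
                f"{self.gene}: admet_class {self.admet_class!r} not in {ADMET_CLASSES}"
            )
        if self.n_variants < 0 or self.n_haplotypes < 0:
            raise ValueError(f"{self.gene}: negative counts")


def _norm_drug(name: str) -> str:
    return name.strip().casefold()


def read_gene_metadata(source: TextIO | str | os.PathLike) -> list[GeneRecord]:
    """Load gene metadata from delimited text (gene, chromosome, admet_class,
    drug; one row per gene–drug pair, blank drug allowed)."""
    if isinstance(source, (str, os.PathLike)):
        frame = pd.read_csv(source, sep=None, engine="python", dtype=str)
    else:
        frame = pd.read_csv(io.StringIO(source.read()), sep=None, engine="python", dtype=str)
    required = {"gene", "chromosome", "admet_class", "drug"}
    missing = required - set(frame.columns)
    if missing:
        raise TableFormatError(f"gene metadata missing columns: {sorted(missing)}")
    records = []
    for gene, grp in frame.groupby("gene", sort=True):
        chroms = set(grp["chromosome"].dropna().astype(str))
        classes = set(grp["admet_class"].dropna().astype(str))
        if len(chroms) != 1 or len(classes) != 1:
            raise TableFormatError(f"{gene}: inconsistent chromosome/class metadata")
        drugs = frozenset(
            _norm_drug(d) for d in grp["drug"].dropna().astype(str) if d.strip()
        )
        records.append(
            GeneRecord(
                gene=str(gene),
                chromosome=chroms.pop(),
                admet_class=classes.pop(),
                drugs=drugs,
            )
        )
    return records


def build_gene_drug_graph(records: Sequence[GeneRecord]) -> nx.Graph:
    """Simple undirected graph: edge {a, b} iff genes a ≠ b share a drug."""
    if not records:
        raise PgxError("no gene records supplied")
    symbols = [r.gene for r in records]
    if len(set(symbols)) != len(symbols):
        dupes = sorted({g for g in symbols if symbols.count(g) > 1})
        raise PgxError(f"duplicate gene symbols: {dupes}")
    g = nx.Graph()
    ordered = sorted(records, key=lambda r: r.gene)
    g.add_nodes_from(r.gene for r in ordered)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if a.drugs & b.drugs:
                g.add_edge(a.gene, b.gene)
    return g


def graph_density(g: nx.Graph) -> float:
    """|E| over the simple-graph maximum |V|(|V|−1)/2."""
    if g.number_of_nodes() < 2:
        raise PgxError("graph density requires at least 2 nodes")
    return nx.density(g)


def class_densities(records: Sequence[GeneRecord]) -> dict[str, float | None]:
    """Overall and per-ADMET-class shared-drug graph densities.

    Classes with fewer than two genes report ``None`` (density undefined).
    """
    out: dict[str, float | None] = {}
    out["all"] = graph_density(build_gene_drug_graph(records)) if len(records) >= 2 else None
    for cls in ADMET_CLASSES:
        sub = [r for r in records if r.admet_class == cls]
        out[cls] = graph_density(build_gene_drug_graph(sub)) if len(sub) >= 2 else None
    return out


def squareness(tables: Iterable[HaplotypeTable]) -> pd.DataFrame:
    """Per-gene variant and haplotype counts with their ratio.

    A ratio near 1 means roughly one haplotype per variant ("square"
    tables); large ratios mean few variants recombined into many haplotypes.
    """
    rows = []
    for t in tables:
        if not t.curated:
            raise ValueError(f"{t.gene}: squareness requires curated tables")
        rows.append(
            {
                "gene": t.gene,
                "n_variants": t.n_variants,
                "n_haplotypes": t.n_haplotypes,
                "ratio": t.n_haplotypes / t.n_variants,
            }
        )
    frame = pd.DataFrame(rows, columns=["gene", "n_variants", "n_haplotypes", "ratio"])
    return frame.sort_values("gene").reset_index(drop=True)


def count_by_chromosome_and_class(records: Sequence[GeneRecord]) -> pd.DataFrame:
    """Chromosome × ADMET-class gene counts, zero chromosomes included."""
    counts = pd.DataFrame(0, index=list(CHROMOSOMES), columns=list(ADMET_CLASSES))
    for r in records:
        chrom = r.chromosome.removeprefix("chr")
        if chrom not in counts.index:
            counts.loc[chrom] = 0
        counts.at[chrom, r.admet_class] += 1
    counts["total"] = counts.sum(axis=1)
    counts.index.name = "chromosome"
    return counts


def multi_gene_drug_count(records: Sequence[GeneRecord]) -> tuple[int, int]:
    """(drugs metabolized by ≥2 genes, total distinct drugs)."""
    if not records:
        raise PgxError("no gene records supplied")
    drug_genes: dict[str, set[str]] = {}
    for r in records:
        for d in r.drugs:
            drug_genes.setdefault(d, set()).add(r.gene)
    shared = sum(1 for genes in drug_genes.values() if len(genes) >= 2)
    return shared, len(drug_genes)
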