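"""Knowledge-base updates: extend a haplotype table or create a new one.

Two operations keep the translation tables current as new pharmacogenomic
evidence appears: ``add_haplotype`` appends a newly described haplotype
(optionally registering brand-new variants) to an existing gene table, and
``create_gene_table`` builds a table from scratch for a gene that gained a
drug association. Both return fully curated tables that are fixed points of
the curation pipeline, so the translation engine can use them immediately.

Updates are file-based: ``write_versioned_table`` emits a timestamped table
file plus a JSON provenance sidecar, so every translation run can name the
exact table version it used.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import UpdateError
from .haplotypes import (
    HaplotypeTable,
    VariantDef,
    _derive_variants,
    curate,
    is_rsid,
    to_text,
)


def add_haplotype(
    t: HaplotypeTable,
    name: str,
    minor_assignments: Mapping[str, str],
    new_variant_majors: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Append haplotype *name*, defined by *minor_assignments* (rsID → allele).

    Assigned rsIDs must either already be variants of the table — the
    allele must then be one of that variant's known major/minor alleles —
    or be new registered rsIDs, in which case the major allele must be
    supplied via *new_variant_majors* and a new variant row is added (all
    existing haplotypes get the major allele there, so their code vectors
    extend with zeros and no existing diplotype assignment changes).
    """
    new_variant_majors = dict(new_variant_majors or {})
    if name in t.haplotype_names:
        raise UpdateError(f"{t.gene}: haplotype {name!r} already present")
    if not minor_assignments:
        raise UpdateError(f"{t.gene}: a new haplotype needs at least one assignment")

    known = {v.identifier: v for v in t.variants}
    alleles = t.alleles.copy()
    variants = list(t.variants)
    for rsid, allele in minor_assignments.items():
        if rsid in known:
            v = known[rsid]
            if allele not in v.alleles:
                raise UpdateError(
                    f"{t.gene}/{rsid}: allele {allele!r} not among known "
                    f"alleles {v.alleles}"
                )
        else:
            if not is_rsid(rsid):
                raise UpdateError(f"{t.gene}: new variant {rsid!r} is not a registered rsID")
            major = new_variant_majors.get(rsid)
            if major is None:
                raise UpdateError(
                    f"{t.gene}/{rsid}: new variant requires its major allele"
                )
            v = VariantDef(rsid, t.gene, major, (allele,) if allele != major else ())
            known[rsid] = v
            variants.append(v)
            alleles.loc[rsid] = [major] * alleles.shape[1]

    # new column: assigned alleles where given, the major allele elsewhere
    column = [
        minor_assignments.get(v.identifier, v.major_allele)
        for v in variants
    ]
    alleles = alleles.reindex([v.identifier for v in variants])
    alleles[name] = column
    for existing in t.haplotype_names:
        if list(alleles[existing]) == column:
            raise UpdateError(
                f"{t.gene}: haplotype {name!r} duplicates existing {existing!r}"
            )
    # re-derive minor orderings so genuinely new alleles get stable codes
    merged = _merge_variant_defs(variants, alleles)
    updated = HaplotypeTable(
        gene=t.gene,
        alleles=alleles,
        variants=merged,
        curated=False,
        aliases=dict(t.aliases),
    )
    return curate(updated)


def _merge_variant_defs(
    variants: Sequence[VariantDef], alleles: pd.DataFrame
) -> tuple[VariantDef, ...]:
    """Keep each variant's established minor ordering, appending any allele
    newly observed in the matrix (codes of existing minors never change)."""
    observed = _derive_variants(variants[0].gene, alleles)
    merged = []
    for old, new in zip(variants, observed):
        extra = tuple(a for a in new.minor_alleles if a not in old.minor_alleles)
        merged.append(replace(old, minor_alleles=old.minor_alleles + extra))
    return tuple(merged)


def create_gene_table(
    gene: str,
    variants: Sequence[VariantDef],
    haplotype_defs: Sequence[tuple[str, Mapping[str, str]]],
) -> HaplotypeTable:
    """Build a curated table for a newly associated gene.

    The first haplotype listed becomes the reference and must carry only
    major alleles; later haplotypes assign minor alleles per rsID and
    default to the major allele elsewhere.
    """
    if not variants:
        raise UpdateError(f"{gene}: at least one variant required")
    for v in variants:
        if not v.registered:
            raise UpdateError(f"{gene}: variant {v.identifier!r} is not a registered rsID")
    ids = [v.identifier for v in variants]
    if len(set(ids)) != len(ids):
        raise UpdateError(f"{gene}: duplicate variant definitions")
    if not haplotype_defs:
        raise UpdateError(f"{gene}: at least one haplotype (the reference) required")

    by_id = {v.identifier: v for v in variants}
    ref_name, ref_assign = haplotype_defs[0]
    for rsid, allele in ref_assign.items():
        if allele != by_id[rsid].major_allele:
            raise UpdateError(
                f"{gene}: reference haplotype {ref_name!r} assigns non-major "
                f"allele {allele!r} at {rsid}"
            )
    columns: dict[str, list[str]] = {}
    for name, assign in haplotype_defs:
        if name in columns:
            raise UpdateError(f"{gene}: duplicate haplotype name {name!r}")
        col = []
        for v in variants:
            allele = assign.get(v.identifier, v.major_allele)
            if allele not in v.alleles:
                raise UpdateError(
                    f"{gene}/{v.identifier}: allele {allele!r} not among {v.alleles}"
                )
            col.append(allele)
        for other, existing in columns.items():
            if existing == col:
                raise UpdateError(
                    f"{gene}: haplotype {name!r} duplicates {other!r}"
                )
        columns[name] = col
    frame = pd.DataFrame(columns, index=ids)
    table = HaplotypeTable(gene=gene, alleles=frame, variants=tuple(variants))
    return curate(table)


def write_versioned_table(
    t: HaplotypeTable,
    directory: str | os.PathLike,
    note: str = "",
    timestamp: datetime.datetime | None = None,
) -> Path:
    """Write *t* as ``<gene>.<UTC timestamp>.tsv`` with a JSON sidecar.

    The sidecar records gene, haplotype names, variant count, aliases and a
    free-text note, so downstream runs can cite the exact table version.
    Returns the table path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if timestamp is None:
        timestamp = datetime.datetime.now(datetime.timezone.utc)
    stamp = timestamp.strftime("%Y%m%dT%H%M%SZ")
    path = directory / f"{t.gene}.{stamp}.tsv"
    path.write_text(to_text(t))
    sidecar = {
        "gene": t.gene,
        "written": stamp,
        "haplotypes": list(t.haplotype_names),
        "n_variants": t.n_variants,
        "aliases": {k: list(v) for k, v in t.aliases.items()},
        "note": note,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path
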