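"""Star-allele haplotype tables: loading, curation and numeric encoding.

A haplotype table is a variant × haplotype matrix of allele strings for one
pharmacogene. Rows are keyed by variant identifier (dbSNP rsID or a free-text
label such as an HGVS expression), columns by haplotype name (star alleles,
e.g. ``*1``). By convention the first haplotype column is the reference
(wild-type) haplotype and its alleles define the major allele of every
variant; any other allele appearing in the row is a minor allele.

Curation proceeds in three sub-steps:

1. drop variants whose identifier is not a registered rsID;
2. drop haplotypes that were defined by a minor allele of a dropped variant
   (so every retained haplotype is still fully described by the retained
   variants);
3. drop duplicate haplotype columns, keeping the earliest-listed name.

The curated table is then encoded numerically: the major allele of each
variant maps to 0 and its minor alleles, in order of first appearance
scanning haplotype columns left to right, to the codes 1, 3 and 5. At most
three distinct minor alleles per variant are supported. Sums of two codes
are unique for up to two minors per variant; with three minors the pair
sums 1+5 and 3+3 collide, which the matching layer handles by reporting all
matches (see :mod:`pgxtranslate.translate`).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import (
    AnnotationConflictError,
    EmptyTableError,
    TableFormatError,
    UnsupportedVariantError,
)

RSID_PATTERN = re.compile(r"^rs[0-9]+$")

#: Numeric codes assigned to minor alleles, in order of first appearance.
MINOR_CODES = (1, 3, 5)


def is_rsid(identifier: str) -> bool:
    """True iff *identifier* is a dbSNP-registered rsID (``rs`` + digits)."""
    return bool(RSID_PATTERN.match(identifier))


@dataclass(frozen=True)
class VariantDef:
    """A variant row: identifier, gene, major allele and ordered minor alleles.

    The major allele is the reference-haplotype allele; minor alleles are
    every other allele observed in the row, ordered by first appearance
    scanning haplotype columns left to right. Alleles are compared verbatim,
    so indel strings are supported.
    """

    identifier: str
    gene: str
    major_allele: str
    minor_alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("variant identifier must be non-empty")
        if not self.major_allele:
            raise ValueError(f"{self.identifier}: major allele must be non-empty")
        if any(not a for a in self.minor_alleles):
            raise ValueError(f"{self.identifier}: minor alleles must be non-empty")
        if self.major_allele in self.minor_alleles:
            raise ValueError(
                f"{self.identifier}: major allele {self.major_allele!r} "
                "cannot also be a minor allele"
            )
        if len(set(self.minor_alleles)) != len(self.minor_alleles):
            raise ValueError(f"{self.identifier}: duplicate minor alleles")

    @property
    def registered(self) -> bool:
        return is_rsid(self.identifier)

    @property
    def alleles(self) -> tuple[str, ...]:
        """Major allele followed by the ordered minor alleles."""
        return (self.major_allele, *self.minor_alleles)


@dataclass
class HaplotypeTable:
    """A gene's variant × haplotype allele matrix.

    ``alleles`` is indexed by variant identifier with one column per
    haplotype; the first column is the reference haplotype. ``variants``
    records each variant's major/minor alleles as observed in the full
    table at load time, so minor alleles stay known even after the
    haplotypes that carried them are curated away.
    """

    gene: str
    alleles: pd.DataFrame
    variants: tuple[VariantDef, ...]
    curated: bool = False
    removed_variants: tuple[VariantDef, ...] = ()
    removed_rows: pd.DataFrame | None = None
    aliases: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def haplotype_names(self) -> tuple[str, ...]:
        return tuple(self.alleles.columns)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(self.alleles.index)

    @property
    def reference_name(self) -> str:
        return str(self.alleles.columns[0])

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    def variant(self, identifier: str) -> VariantDef:
        for v in self.variants:
            if v.identifier == identifier:
                return v
        raise KeyError(identifier)

    def __post_init__(self) -> None:
        if self.alleles.shape[0] == 0 or self.alleles.shape[1] == 0:
            raise EmptyTableError(f"{self.gene}: empty haplotype table")
        ids = list(self.alleles.index)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TableFormatError(f"{self.gene}: duplicate variant rows {dupes}")
        if tuple(v.identifier for v in self.variants) != tuple(ids):
            raise TableFormatError(
                f"{self.gene}: variant metadata out of sync with allele matrix"
            )


def _derive_variants(gene: str, alleles: pd.DataFrame) -> tuple[VariantDef, ...]:
    """Build VariantDefs from a matrix: column 1 defines the major allele,
    minors are ordered by first appearance left to right."""
    defs = []
    ref = alleles.columns[0]
    for identifier, row in alleles.iterrows():
        major = row[ref]
        minors: list[str] = []
        for allele in row:
            if allele != major and allele not in minors:
                minors.append(allele)
        defs.append(VariantDef(str(identifier), gene, major, tuple(minors)))
    return tuple(defs)


def load_haplotype_table(
    source: TextIO | str, gene: str, delimiter: str | None = None
) -> HaplotypeTable:
    """Parse a delimited haplotype table into an (uncurated) HaplotypeTable.

    The header row holds haplotype names (first cell is an arbitrary row-key
    label); each following row holds a variant identifier and its allele per
    haplotype. Blank cells denote the reference allele of that variant and
    are filled in at load time. The delimiter is sniffed (tab/comma/semicolon)
    unless given.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{gene}: empty table source")
    if delimiter is None:
        try:
            delimiter = csv.Sniffer().sniff(lines[0], delimiters="\t,;").delimiter
        except csv.Error:
            delimiter = "\t"
    rows = list(csv.reader(lines, delimiter=delimiter))
    header = [c.strip() for c in rows[0]]
    if len(header) < 2:
        raise TableFormatError(f"{gene}: header must name at least one haplotype")
    hap_names = header[1:]
    if len(set(hap_names)) != len(hap_names):
        raise TableFormatError(f"{gene}: duplicate haplotype names in header")
    if len(rows) < 2:
        raise TableFormatError(f"{gene}: table has no variant rows")

    data: dict[str, list[str]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        cells = [c.strip() for c in row]
        if len(cells) != len(header):
            raise TableFormatError(
                f"{gene}: row {lineno} ({cells[0] if cells else ''!r}) has "
                f"{len(cells)} fields, expected {len(header)}"
            )
        identifier, alleles = cells[0], cells[1:]
        if not identifier:
            raise TableFormatError(f"{gene}: row {lineno} has no variant identifier")
        if identifier in data:
            raise TableFormatError(f"{gene}: duplicate variant row {identifier!r}")
        if not alleles[0]:
            raise TableFormatError(
                f"{gene}: row {lineno} ({identifier}) has a blank reference allele"
            )
        # blank cells carry the reference (major) allele implicitly
        data[identifier] = [a if a else alleles[0] for a in alleles]

    frame = pd.DataFrame.from_dict(data, orient="index", columns=hap_names)
    return HaplotypeTable(gene=gene, alleles=frame, variants=_derive_variants(gene, frame))


def drop_unregistered_variants(t: HaplotypeTable) -> HaplotypeTable:
    """Curation sub-step 1: delete variant rows without a dbSNP rsID.

    The removed variants (and their allele rows) are recorded on the result
    so the dependent-haplotype sweep can use them.
    """
    keep = [v.identifier for v in t.variants if v.registered]
    if not keep:
        raise EmptyTableError(f"{t.gene}: no dbSNP-registered variants remain")
    removed = tuple(v for v in t.variants if not v.registered)
    if not removed:
        return t
    return replace(
        t,
        alleles=t.alleles.loc[keep],
        variants=tuple(v for v in t.variants if v.registered),
        removed_variants=t.removed_variants + removed,
        removed_rows=t.alleles.loc[[v.identifier for v in removed]],
    )


def drop_orphaned_haplotypes(
    t: HaplotypeTable, removed: Sequence[VariantDef] | None = None
) -> HaplotypeTable:
    """Curation sub-step 2: delete haplotypes defined by a removed variant.

    A haplotype is dropped iff it carried a minor allele at any variant
    removed in sub-step 1, so every retained haplotype is still completely
    described by the retained variants. The reference haplotype carries only
    major alleles and therefore always survives.
    """
    if removed is None:
        removed = t.removed_variants
    if not removed or t.removed_rows is None:
        return t
    keep = []
    for name in t.haplotype_names:
        orphaned = any(
            t.removed_rows.at[v.identifier, name] != v.major_allele
            for v in removed
            if v.identifier in t.removed_rows.index
        )
        if not orphaned or name == t.reference_name:
            keep.append(name)
    if len(keep) == t.n_haplotypes:
        return t
    return replace(t, alleles=t.alleles[keep])


def dedupe_haplotypes(t: HaplotypeTable) -> HaplotypeTable:
    """Curation sub-step 3: collapse identical haplotype columns.

    Among duplicates the earliest-listed name is kept; dropped names are
    recorded as aliases of the survivor. Marks the table curated.
    """
    seen: dict[tuple[str, ...], str] = {}
    aliases: dict[str, list[str]] = {}
    keep = []
    for name in t.haplotype_names:
        key = tuple(t.alleles[name])
        if key in seen:
            aliases.setdefault(seen[key], []).append(name)
        else:
            seen[key] = name
            keep.append(name)
    merged = dict(t.aliases)
    for k, v in aliases.items():
        merged[k] = tuple(merged.get(k, ())) + tuple(v)
    return replace(t, alleles=t.alleles[keep], aliases=merged, curated=True)


def curate(t: HaplotypeTable) -> HaplotypeTable:
    """Run the full curation pipeline (sub-steps 1–3). Idempotent."""
    return dedupe_haplotypes(drop_orphaned_haplotypes(drop_unregistered_variants(t)))


@dataclass
class EncodedTable:
    """Numeric form of a curated haplotype table.

    ``codes`` is the variant × haplotype integer matrix over {0, 1, 3, 5};
    the reference column is all-zero. ``variants`` carries the allele↔code
    mapping (index in ``VariantDef.minor_alleles`` i → code MINOR_CODES[i]).
    """

    gene: str
    codes: pd.DataFrame
    variants: tuple[VariantDef, ...]

    @property
    def haplotype_names(self) -> tuple[str, ...]:
        return tuple(self.codes.columns)

    @property
    def reference_name(self) -> str:
        return str(self.codes.columns[0])

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(self.codes.index)

    def code_vector(self, haplotype: str) -> np.ndarray:
        return self.codes[haplotype].to_numpy()


def allele_code(v: VariantDef, allele: str) -> int:
    """Numeric code of *allele* at variant *v* (0 for major; 1/3/5 for minors)."""
    if allele == v.major_allele:
        return 0
    try:
        return MINOR_CODES[v.minor_alleles.index(allele)]
    except ValueError:
        raise KeyError(allele) from None


def code_allele(v: VariantDef, code: int) -> str:
    """Inverse of :func:`allele_code`."""
    if code == 0:
        return v.major_allele
    return v.minor_alleles[MINOR_CODES.index(code)]


def encode_numeric(t: HaplotypeTable) -> EncodedTable:
    """Encode a curated table: major allele → 0, minors → 1/3/5 in order."""
    if not t.curated:
        raise ValueError(f"{t.gene}: table must be curated before encoding")
    for v in t.variants:
        if len(v.minor_alleles) > len(MINOR_CODES):
            raise UnsupportedVariantError(
                f"{t.gene}/{v.identifier}: {len(v.minor_alleles)} minor alleles; "
                f"at most {len(MINOR_CODES)} supported"
            )
    codes = pd.DataFrame(
        {
            name: [allele_code(v, t.alleles.at[v.identifier, name]) for v in t.variants]
            for name in t.haplotype_names
        },
        index=list(t.variant_ids),
    )
    return EncodedTable(gene=t.gene, codes=codes, variants=t.variants)


@dataclass(frozen=True)
class AnnotationEntry:
    """Unified per-rsID allele registry entry."""

    rsid: str
    gene: str
    major_allele: str
    minor_alleles: tuple[str, ...]

    def code(self, allele: str) -> int:
        if allele == self.major_allele:
            return 0
        try:
            return MINOR_CODES[self.minor_alleles.index(allele)]
        except ValueError:
            raise KeyError(allele) from None

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.major_allele, *self.minor_alleles)


@dataclass
class VariantAnnotation:
    """Mapping rsID → (gene, major allele, coded minor alleles).

    Built from curated tables; the reference-haplotype convention defines
    the major allele. Conflicting definitions across genes raise
    :class:`AnnotationConflictError` rather than being silently merged.
    """

    entries: dict[str, AnnotationEntry] = field(default_factory=dict)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.entries

    def __getitem__(self, rsid: str) -> AnnotationEntry:
        return self.entries[rsid]

    def __len__(self) -> int:
        return len(self.entries)


def derive_annotation(tables: Iterable[HaplotypeTable]) -> VariantAnnotation:
    """Unify the per-gene variant definitions into one rsID registry.

    Two tables may share an rsID only if they agree on the major allele and
    their minor-allele orderings are compatible (one a prefix of the other,
    so every code assignment agrees); anything else is a conflict.
    """
    ann = VariantAnnotation()
    for t in tables:
        if not t.curated:
            raise ValueError(f"{t.gene}: derive_annotation requires curated tables")
        for v in t.variants:
            if not v.registered:
                continue
            new = AnnotationEntry(v.identifier, v.gene, v.major_allele, v.minor_alleles)
            old = ann.entries.get(v.identifier)
            if old is None:
                ann.entries[v.identifier] = new
            elif old.major_allele != new.major_allele:
                raise AnnotationConflictError(
                    f"{v.identifier}: major allele {old.major_allele!r} ({old.gene}) "
                    f"vs {new.major_allele!r} ({new.gene})"
                )
            else:
                short, long_ = sorted(
                    (old.minor_alleles, new.minor_alleles), key=len
                )
                if long_[: len(short)] != short:
                    raise AnnotationConflictError(
                        f"{v.identifier}: minor alleles {old.minor_alleles} "
                        f"({old.gene}) vs {new.minor_alleles} ({new.gene})"
                    )
                if len(new.minor_alleles) > len(old.minor_alleles):
                    ann.entries[v.identifier] = replace(
                        old, minor_alleles=new.minor_alleles
                    )
    return ann


def to_text(t: HaplotypeTable, delimiter: str = "\t") -> str:
    """Serialize a table back to the delimited layout accepted by the loader."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter=delimiter, lineterminator="\n")
    writer.writerow(["variant", *t.haplotype_names])
    for rsid in t.variant_ids:
        writer.writerow([rsid, *t.alleles.loc[rsid]])
    return out.getvalue()
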