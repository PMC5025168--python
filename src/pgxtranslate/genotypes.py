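"""Sample genotype I/O: VCF reading, rsID restriction lists, reports.

Genotypes are keyed by the VCF ID column (rsID) — positional matching is
deliberately out of scope since the whole translation pipeline operates on
rsIDs. Phase separators ``|`` and ``/`` are both accepted and phase is
discarded: matching works on unordered allele pairs. Records whose ID is
absent from the variant annotation (or from an optional user-supplied rsID
list) are skipped; ``./.`` and half calls are recorded as missing.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence, TextIO

import pysam

from .errors import FilterError, ReportError, VcfFormatError
from .haplotypes import VariantAnnotation, is_rsid

if TYPE_CHECKING:  # pragma: no cover
    from .translate import TranslationResult

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ("sample_id", "gene", "diplotype", "phenotype_color", "recommendation_link")


@dataclass(frozen=True)
class GenotypeCall:
    """One unphased call: an unordered allele pair, or an explicit missing."""

    alleles: tuple[str, ...] = ()
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing and len(self.alleles) != 2:
            raise ValueError("a non-missing call must carry exactly two alleles")


MISSING_CALL = GenotypeCall(missing=True)


@dataclass
class GenotypeProfile:
    """A sample's genotypes over the pharmacovariants, keyed by rsID."""

    sample_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)


@dataclass(frozen=True)
class RsidFilter:
    """An optional restriction of translation to a set of rsIDs."""

    rsids: frozenset[str]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.rsids

    def __len__(self) -> int:
        return len(self.rsids)


def read_rsid_list(source: TextIO | str | os.PathLike) -> RsidFilter:
    """Parse a plain-text rsID list (one per line; ``#`` comments allowed).

    Malformed tokens are skipped with a warning naming the line number; a
    list with no valid rsIDs is an error.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    rsids: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        token = line.split("#", 1)[0].strip()
        if not token:
            continue
        if is_rsid(token):
            rsids.add(token)
        else:
            logger.warning("rsID list line %d: skipping malformed token %r", lineno, token)
    if not rsids:
        raise FilterError("rsID list contains no valid rsIDs")
    return RsidFilter(frozenset(rsids))


def read_vcf(
    path: str | os.PathLike,
    annotation: VariantAnnotation,
    rsid_filter: RsidFilter | None = None,
) -> list[GenotypeProfile]:
    """Read genotype profiles from a VCF v4.x file (plain or bgzipped).

    One profile per sample. Only records whose ID column holds an rsID known
    to *annotation* (and present in *rsid_filter*, when given) are kept.
    Multi-allelic records are supported: GT indices are resolved against the
    record's REF/ALT allele strings. ``./.`` and half calls (a single-allele
    GT, e.g. hemizygous calls) are stored as missing.
    """
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no sample columns")
    profiles = {s: GenotypeProfile(sample_id=s) for s in samples}
    for rec in vcf:
        rsid = rec.id
        if not rsid or rsid == "." or rsid not in annotation:
            continue
        if rsid_filter is not None and rsid not in rsid_filter:
            continue
        alleles = rec.alleles  # REF first, then ALTs
        for sample in samples:
            data = rec.samples[sample]
            gt = data.get("GT")
            if gt is None:
                raise VcfFormatError(f"{path}: record {rsid} lacks a GT field")
            indices = [i for i in gt if i is not None]
            if len(indices) != 2 or len(gt) != 2:
                if len(gt) == 1:
                    logger.warning(
                        "%s/%s: half call treated as missing", sample, rsid
                    )
                profiles[sample].calls[rsid] = MISSING_CALL
                continue
            profiles[sample].calls[rsid] = GenotypeCall(
                alleles=(alleles[indices[0]], alleles[indices[1]])
            )
    vcf.close()
    return [profiles[s] for s in samples]


def write_report(
    results: Sequence["TranslationResult"],
    format: str = "tsv",
    destination: TextIO | str | os.PathLike | None = None,
) -> str:
    """Serialize translation results to the five-column report.

    Columns: sample_id, gene, diplotype, phenotype_color,
    recommendation_link (empty when no diplotype matched). Rows are ordered
    by sample then gene. ``format`` is ``tsv`` or ``json``; the rendered
    text is returned and, when *destination* is given, also written there.
    """
    if not results:
        raise ReportError("no translation results to report")
    if format not in ("tsv", "json"):
        raise ReportError(f"unknown report format {format!r}")
    ordered = sorted(results, key=lambda r: (r.sample_id, r.gene))
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for r in ordered:
            lines.append(
                "\t".join(
                    (r.sample_id, r.gene, r.diplotype, r.phenotype.color, r.link_key or "")
                )
            )
        text = "\n".join(lines) + "\n"
    else:
        text = json.dumps([r.to_record() for r in ordered], indent=2) + "\n"
    if destination is not None:
        if isinstance(destination, (str, os.PathLike)):
            with open(destination, "w") as fh:
                fh.write(text)
        else:
            destination.write(text)
    return text
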