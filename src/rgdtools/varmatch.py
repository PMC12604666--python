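"""Cohort-VCF versus pathogenic-catalog variant matching.

A cohort variant is classified against a catalog of ClinVar-like records:

IDENTICAL
    some catalog entry matches chromosome, position, reference and alternate
    allele exactly;
SIMILAR
    no exact match, but some entry shares the mutation site (chromosome and
    position) with a different allele representation;
UNMATCHED
    no catalog entry at the site.

Summaries are reported at the level of distinct mutation sites (chrom, pos):
a site with any identically matching allele counts as identical. Pathogenic
totals cover the pathogenic, likely-pathogenic and conflicting-interpretation
significance buckets. No allele normalization (trimming / left-alignment) is
applied by default, so representation differences such as C>T versus AC>A at
one position classify as similar; opt-in trimming is available for users who
want representation-robust matching.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from cyvcf2 import VCF

from .catalog import (
    PATHOGENIC_CATEGORIES,
    CatalogVariant,
    GenomicVariant,
    InheritanceMode,
    SignificanceCategory,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MatchClass",
    "MatchRecord",
    "MappingSummary",
    "read_vcf",
    "build_catalog_index",
    "CatalogIndex",
    "classify_match",
    "annotate_cohort",
    "summarize",
    "filter_by_inheritance",
    "count_distinct_sites",
    "trim_alleles",
]


class MatchClass(enum.Enum):
    IDENTICAL = "identical"
    SIMILAR = "similar"
    UNMATCHED = "unmatched"


# severity order used to pick the "best" significance among matched entries
_SEVERITY = [
    SignificanceCategory.PATHOGENIC,
    SignificanceCategory.LIKELY_PATHOGENIC,
    SignificanceCategory.PATHOGENIC_CONFLICTING,
    SignificanceCategory.OTHER,
    SignificanceCategory.BENIGN_OR_LIKELY_BENIGN,
]
_SEVERITY_RANK = {c: i for i, c in enumerate(_SEVERITY)}


@dataclass(frozen=True)
class MatchRecord:
    """One cohort variant with its class and matched catalog entries."""

    cohort_variant: GenomicVariant
    match_class: MatchClass
    matched_entries: tuple[tuple[CatalogVariant, MatchClass], ...] = ()
    significance: SignificanceCategory | None = field(init=False, default=None)
    inheritance: InheritanceMode = field(init=False, default=InheritanceMode.UNKNOWN)

    def __post_init__(self) -> None:
        if (self.match_class is MatchClass.UNMATCHED) != (not self.matched_entries):
            raise ValueError("matched_entries must be empty iff UNMATCHED")
        if not self.matched_entries:
            return
        # significance of the best-matched entry: identical entries take
        # precedence over similar ones, then most severe category wins
        best = min(
            self.matched_entries,
            key=lambda ec: (
                ec[1] is not MatchClass.IDENTICAL,
                _SEVERITY_RANK[ec[0].significance],
            ),
        )
        object.__setattr__(self, "significance", best[0].significance)
        modes = {
            mode
            for entry, _ in self.matched_entries
            for _, mode in entry.conditions
            if mode is not InheritanceMode.UNKNOWN
        }
        if len(modes) == 1:
            object.__setattr__(self, "inheritance", next(iter(modes)))
        elif len(modes) > 1:
            object.__setattr__(self, "inheritance", InheritanceMode.MULTI)


@dataclass(frozen=True)
class MappingSummary:
    """Site-level count partition of a cohort-vs-catalog mapping.

    Invariants: ``n_mapped_total = n_identical_sites + n_similar_sites`` and
    ``n_pathogenic_total = n_pathogenic_identical + n_pathogenic_similar``;
    each pathogenic count is bounded by its mapped counterpart.
    """

    n_identical_sites: int
    n_similar_sites: int
    n_pathogenic_identical: int
    n_pathogenic_similar: int
    by_significance: dict[str, int] = field(default_factory=dict)
    by_inheritance: dict[str, int] = field(default_factory=dict)
    n_mapped_total: int = field(init=False)
    n_pathogenic_total: int = field(init=False)

    def __post_init__(self) -> None:
        counts = (
            self.n_identical_sites,
            self.n_similar_sites,
            self.n_pathogenic_identical,
            self.n_pathogenic_similar,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_pathogenic_identical > self.n_identical_sites:
            raise ValueError("pathogenic identical exceeds identical sites")
        if self.n_pathogenic_similar > self.n_similar_sites:
            raise ValueError("pathogenic similar exceeds similar sites")
        object.__setattr__(
            self, "n_mapped_total", self.n_identical_sites + self.n_similar_sites
        )
        object.__setattr__(
            self,
            "n_pathogenic_total",
            self.n_pathogenic_identical + self.n_pathogenic_similar,
        )

    def to_dict(self) -> dict:
        return {
            "n_identical_sites": self.n_identical_sites,
            "n_similar_sites": self.n_similar_sites,
            "n_mapped_total": self.n_mapped_total,
            "n_pathogenic_identical": self.n_pathogenic_identical,
            "n_pathogenic_similar": self.n_pathogenic_similar,
            "n_pathogenic_total": self.n_pathogenic_total,
            "by_significance": dict(self.by_significance),
            "by_inheritance": dict(self.by_inheritance),
        }


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def read_vcf(path) -> list[GenomicVariant]:
    """Read a VCF (plain or gzip) into per-ALT-allele variants.

    Multi-allelic records are split into one variant per alternate allele.
    Symbolic alleles (``<DEL>``-style), breakends and spanning-deletion
    ``*`` alleles are skipped; the skip count is logged.
    """
    variants: list[GenomicVariant] = []
    skipped = 0
    vcf = VCF(str(path))
    try:
        for record in vcf:
            rid = record.ID
            for alt in record.ALT:
                if not alt or alt == "*" or any(c in alt for c in "<>[]."):
                    skipped += 1
                    continue
                try:
                    variants.append(
                        GenomicVariant(
                            chrom=record.CHROM,
                            pos=record.POS,
                            ref=record.REF,
                            alt=alt,
                            id=rid,
                        )
                    )
                except ValueError as exc:
                    skipped += 1
                    logger.warning("skipping %s:%s: %s", record.CHROM, record.POS, exc)
    finally:
        vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d non-sequence ALT allele(s)", skipped)
    return variants


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal-representation trimming (right then left) of an allele pair.

    Used only by the opt-in normalized matching mode; the default pipeline
    compares allele strings verbatim.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


class CatalogIndex:
    """Hash index over a variant catalog: exact-allele and site lookup."""

    def __init__(
        self, catalog: Iterable[CatalogVariant], normalize: bool = False
    ) -> None:
        self.normalize = normalize
        self._exact: dict[tuple[str, int, str, str], list[CatalogVariant]] = {}
        self._site: dict[tuple[str, int], list[CatalogVariant]] = {}
        for entry in catalog:
            self._exact.setdefault(self._key(entry.variant), []).append(entry)
            self._site.setdefault(entry.variant.site, []).append(entry)

    def _key(self, v: GenomicVariant) -> tuple[str, int, str, str]:
        if self.normalize:
            pos, ref, alt = trim_alleles(v.pos, v.ref, v.alt)
            return (v.chrom, pos, ref, alt)
        return v.key

    def exact(self, v: GenomicVariant) -> list[CatalogVariant]:
        return self._exact.get(self._key(v), [])

    def at_site(self, v: GenomicVariant) -> list[CatalogVariant]:
        return self._site.get(v.site, [])


def build_catalog_index(
    catalog: Sequence[CatalogVariant], normalize: bool = False
) -> CatalogIndex:
    """Build exact and per-site lookup over the catalog (O(1) expected)."""
    return CatalogIndex(catalog, normalize=normalize)


def classify_match(v: GenomicVariant, index: CatalogIndex) -> MatchRecord:
    """Classify one cohort variant as IDENTICAL / SIMILAR / UNMATCHED.

    ``matched_entries`` carries every catalog entry sharing the site, each
    tagged with its own per-entry class; identical matches take precedence
    over similar ones for the record-level class.
    """
    site_entries = index.at_site(v)
    if not site_entries:
        return MatchRecord(cohort_variant=v, match_class=MatchClass.UNMATCHED)
    exact = set(map(id, index.exact(v)))
    entries = tuple(
        (e, MatchClass.IDENTICAL if id(e) in exact else MatchClass.SIMILAR)
        for e in site_entries
    )
    cls = MatchClass.IDENTICAL if exact else MatchClass.SIMILAR
    return MatchRecord(cohort_variant=v, match_class=cls, matched_entries=entries)


def annotate_cohort(
    vcf_variants: Iterable[GenomicVariant],
    catalog: Sequence[CatalogVariant],
    normalize: bool = False,
) -> list[MatchRecord]:
    """Classify every cohort variant against the catalog, in input order."""
    index = build_catalog_index(catalog, normalize=normalize)
    return [classify_match(v, index) for v in vcf_variants]


def _site_class(records: Sequence[MatchRecord]) -> MatchClass:
    classes = {r.match_class for r in records}
    if MatchClass.IDENTICAL in classes:
        return MatchClass.IDENTICAL
    if MatchClass.SIMILAR in classes:
        return MatchClass.SIMILAR
    return MatchClass.UNMATCHED


def _site_pathogenic(records: Sequence[MatchRecord]) -> bool:
    return any(
        r.significance in PATHOGENIC_CATEGORIES for r in records if r.significance
    )


def summarize(matches: Iterable[MatchRecord]) -> MappingSummary:
    """Aggregate match records into the site-level count partition.

    Cohort variants are grouped into distinct (chrom, pos) sites; a site is
    identical if any allele at it matched identically, else similar if any
    matched by site. Pathogenic counts restrict to sites whose best-matched
    significance is pathogenic / likely pathogenic / conflicting. The
    inheritance breakdown covers identical pathogenic sites.
    """
    by_site: dict[tuple[str, int], list[MatchRecord]] = {}
    for r in matches:
        by_site.setdefault(r.cohort_variant.site, []).append(r)

    n_ident = n_sim = n_path_ident = n_path_sim = 0
    by_significance: dict[str, int] = {}
    by_inheritance: dict[str, int] = {}
    for records in by_site.values():
        cls = _site_class(records)
        if cls is MatchClass.UNMATCHED:
            continue
        pathogenic = _site_pathogenic(records)
        best = min(
            (r.significance for r in records if r.significance is not None),
            key=_SEVERITY_RANK.__getitem__,
        )
        by_significance[best.value] = by_significance.get(best.value, 0) + 1
        if cls is MatchClass.IDENTICAL:
            n_ident += 1
            if pathogenic:
                n_path_ident += 1
                mode = next(
                    r.inheritance
                    for r in records
                    if r.match_class is MatchClass.IDENTICAL
                )
                by_inheritance[mode.value] = by_inheritance.get(mode.value, 0) + 1
        else:
            n_sim += 1
            if pathogenic:
                n_path_sim += 1
    return MappingSummary(
        n_identical_sites=n_ident,
        n_similar_sites=n_sim,
        n_pathogenic_identical=n_path_ident,
        n_pathogenic_similar=n_path_sim,
        by_significance=by_significance,
        by_inheritance=by_inheritance,
    )


def filter_by_inheritance(
    matches: Iterable[MatchRecord], mode: InheritanceMode
) -> list[MatchRecord]:
    """Keep records with at least one matched condition of the given mode."""
    return [
        r
        for r in matches
        if any(
            m is mode for entry, _ in r.matched_entries for _, m in entry.conditions
        )
    ]


def count_distinct_sites(matches: Iterable[MatchRecord]) -> int:
    """Number of distinct (chrom, pos) cohort sites among the records."""
    return len({r.cohort_variant.site for r in matches})
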