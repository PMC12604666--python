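"""Domain model and delimited-text I/O for rare-genetic-disorder catalogs.

The interchange format is tab-delimited UTF-8 text with a mandatory header
row; missing values are written as ``"."``. All genomic coordinates are
1-based inclusive and chromosome labels are normalized to the ``chr``-prefixed
convention (GRCh38-style).

Four catalog tables are supported:

``disorders.tsv``
    one disorder per row: name, aliases, category, subcategory, inheritance
    modes, associated genes, reported-in-India flag.
``symptoms.tsv``
    one (disorder, symptom) association per row with an ordinal frequency
    term (``always`` … ``rarely``).
``variants.tsv``
    ClinVar-like pathogenic-variant records: site, alleles, accession,
    clinical significance, condition string(s) with inheritance tokens.
``genes.tsv``
    gene models: symbol, chromosome, strand, span, exon intervals.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "."

__all__ = [
    "CatalogFormatError",
    "GenomicVariant",
    "CatalogVariant",
    "SignificanceCategory",
    "InheritanceMode",
    "Disorder",
    "SymptomAssociation",
    "FrequencyTerm",
    "GeneModel",
    "normalize_chrom",
    "parse_inheritance",
    "categorize_significance",
    "read_variant_catalog",
    "write_variant_catalog",
    "read_disorders",
    "write_disorders",
    "read_symptom_associations",
    "write_symptom_associations",
    "read_gene_models",
    "write_gene_models",
]


class CatalogFormatError(ValueError):
    """A catalog file violates the expected schema (e.g. missing column)."""


# ---------------------------------------------------------------------------
# enumerations
# ---------------------------------------------------------------------------


class SignificanceCategory(enum.Enum):
    """ClinVar-style clinical-significance buckets.

    The three pathogenic-leaning buckets (PATHOGENIC, LIKELY_PATHOGENIC,
    PATHOGENIC_CONFLICTING) together form the "pathogenic" superset used in
    cohort summaries.
    """

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC_CONFLICTING = "pathogenic_conflicting"
    BENIGN_OR_LIKELY_BENIGN = "benign_or_likely_benign"
    OTHER = "other"


#: buckets counted as "pathogenic" in cohort-level summaries
PATHOGENIC_CATEGORIES = frozenset(
    {
        SignificanceCategory.PATHOGENIC,
        SignificanceCategory.LIKELY_PATHOGENIC,
        SignificanceCategory.PATHOGENIC_CONFLICTING,
    }
)


class InheritanceMode(enum.Enum):
    """Mendelian transmission pattern of a monogenic condition."""

    AD = "AD"
    AR = "AR"
    X_LINKED = "XL"
    MULTI = "MULTI"
    UNKNOWN = "UNKNOWN"


class FrequencyTerm(enum.Enum):
    """Ordinal descriptor of how often a symptom accompanies a disorder."""

    ALWAYS = "always"
    VERY_FREQUENTLY = "very frequently"
    FREQUENTLY = "frequently"
    SOMETIMES = "sometimes"
    UNUSUALLY = "unusually"
    RARELY = "rarely"
    NONE = "none"

    @classmethod
    def parse(cls, raw: str) -> "FrequencyTerm":
        """Parse raw text case- and whitespace-insensitively.

        Unrecognized text degrades to :attr:`NONE` (weight zero) with a
        logged warning rather than raising — frequency vocabularies in
        curated tables are not guaranteed exhaustive.
        """
        key = re.sub(r"[\s_]+", " ", str(raw)).strip().lower()
        for term in cls:
            if term.value == key:
                return term
        if key not in ("", MISSING):
            logger.warning("unrecognized frequency term %r; treating as NONE", raw)
        return cls.NONE


# ---------------------------------------------------------------------------
# chromosome / condition / significance parsing
# ---------------------------------------------------------------------------

_SPECIAL_CHROMS = {"M": "M", "MT": "M", "X": "X", "Y": "Y"}


def normalize_chrom(label: str) -> str:
    """Return the canonical ``chr``-prefixed chromosome label.

    ``"13"`` and ``"chr13"`` both map to ``"chr13"``; mitochondrial ``"MT"``
    maps to ``"chrM"``. Idempotent for every input it accepts.
    """
    if not label or not str(label).strip():
        raise ValueError("empty chromosome label")
    name = str(label).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    upper = name.upper()
    name = _SPECIAL_CHROMS.get(upper, name.lower() if not name.isdigit() else name)
    return f"chr{name}"


_MODE_TOKEN = re.compile(r"\s*\((AD|AR|XL)\)\s*$", re.IGNORECASE)

_TOKEN_TO_MODE = {
    "AD": InheritanceMode.AD,
    "AR": InheritanceMode.AR,
    "XL": InheritanceMode.X_LINKED,
}


def _strip_mode(fragment: str) -> tuple[str, InheritanceMode]:
    m = _MODE_TOKEN.search(fragment)
    if m:
        return fragment[: m.start()].strip(), _TOKEN_TO_MODE[m.group(1).upper()]
    return fragment.strip(), InheritanceMode.UNKNOWN


def parse_inheritance(condition: str) -> list[tuple[str, InheritanceMode]]:
    """Split a condition string into ``(name, mode)`` pairs.

    A trailing parenthesized token ``(AD)``/``(AR)``/``(XL)`` names the
    inheritance mode; absent a token the mode is UNKNOWN. ``" and "``-joined
    strings are split into multiple pairs only when *every* fragment carries
    its own mode token — condition names may legitimately contain "and".
    Never raises on non-empty input.
    """
    if not condition or not condition.strip():
        raise ValueError("empty condition string")
    fragments = condition.split(" and ")
    if len(fragments) > 1 and all(_MODE_TOKEN.search(f) for f in fragments):
        return [_strip_mode(f) for f in fragments]
    return [_strip_mode(condition)]


def categorize_significance(raw: str) -> SignificanceCategory:
    """Map a verbatim clinical-significance string to its category.

    Case-insensitive and total on non-empty strings: anything not matching a
    known pattern falls into :attr:`SignificanceCategory.OTHER`.
    """
    if not raw or not raw.strip():
        raise ValueError("empty significance string")
    key = raw.strip().lower()
    if key in ("pathogenic", "pathogenic/likely pathogenic"):
        return SignificanceCategory.PATHOGENIC
    if key == "likely pathogenic":
        return SignificanceCategory.LIKELY_PATHOGENIC
    if "conflicting" in key:
        return SignificanceCategory.PATHOGENIC_CONFLICTING
    if key in ("benign", "likely benign", "benign/likely benign"):
        return SignificanceCategory.BENIGN_OR_LIKELY_BENIGN
    return SignificanceCategory.OTHER


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicVariant:
    """A single-site allele substitution/indel in chrN:POS:REF>ALT notation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= set("ACGTN"):
                raise ValueError(f"invalid allele {allele!r}")
        if len(self.ref) == 1 == len(self.alt) and self.ref == self.alt:
            raise ValueError("ref and alt are identical")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # chr13:51944170:C>T
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CatalogVariant:
    """One pathogenic-variant catalog record with significance and conditions."""

    variant: GenomicVariant
    clinvar_id: str
    significance_raw: str
    conditions: tuple[tuple[str, InheritanceMode], ...]
    gene_symbol: str | None = None
    significance: SignificanceCategory = field(init=False)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("catalog variant needs at least one condition")
        object.__setattr__(
            self, "significance", categorize_significance(self.significance_raw)
        )

    @property
    def modes(self) -> frozenset[InheritanceMode]:
        return frozenset(mode for _, mode in self.conditions)


@dataclass(frozen=True)
class Disorder:
    """A rare genetic disorder with its genes and inheritance modes."""

    name: str
    aliases: tuple[str, ...] = ()
    category: str = MISSING
    subcategory: str | None = None
    inheritance_modes: frozenset[InheritanceMode] = frozenset()
    genes: tuple[str, ...] = ()
    reported_in_india: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("disorder name must be non-empty")
        if self.reported_in_india and not self.genes:
            raise ValueError(
                f"disorder {self.name!r} reported in India must list genes"
            )


@dataclass(frozen=True)
class SymptomAssociation:
    """A (disorder, symptom, frequency) triple driving prediction scores."""

    disorder_name: str
    symptom: str
    frequency_term: FrequencyTerm
    medical_term: str | None = None
    description: str | None = None


@dataclass(frozen=True)
class GeneModel:
    """A gene span with exon intervals, 1-based inclusive coordinates."""

    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid gene span [{self.start}, {self.end}]")
        exons = tuple(sorted(self.exons))
        for s, e in exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"exon ({s}, {e}) outside gene span")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogFormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)}"
        )
    return df


def _write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def _opt(value: str) -> str | None:
    return None if value in ("", MISSING) else value


def _fmt_opt(value: str | None) -> str:
    return MISSING if value in (None, "") else str(value)


def _join(values: Iterable[str]) -> str:
    out = ";".join(values)
    return out if out else MISSING


def _split(value: str) -> tuple[str, ...]:
    if value in ("", MISSING):
        return ()
    return tuple(v for v in value.split(";") if v)


def _format_conditions(conditions: Iterable[tuple[str, InheritanceMode]]) -> str:
    parts = []
    for name, mode in conditions:
        if mode is InheritanceMode.UNKNOWN:
            parts.append(name)
        else:
            parts.append(f"{name} ({mode.value})")
    return " and ".join(parts)


VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "clinvar_id",
    "significance",
    "condition",
    "gene",
]


def read_variant_catalog(
    path, default_mode: InheritanceMode | None = None
) -> list[CatalogVariant]:
    """Read a ClinVar-like pathogenic-variant table.

    Rows whose position is not a positive integer (or whose alleles are
    malformed) are rejected with a logged warning; the rest are returned in
    file order. ``default_mode`` replaces UNKNOWN inheritance for conditions
    without an explicit ``(AD)``/``(AR)``/``(XL)`` token — useful when the
    table's provenance fixes the mode for every row.
    """
    df = _read_table(path, VARIANT_COLUMNS[:7])
    records: list[CatalogVariant] = []
    for row in df.itertuples(index=False):
        try:
            variant = GenomicVariant(
                chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s: rejected row %s: %s", path, tuple(row), exc)
            continue
        conditions = tuple(
            (name, default_mode)
            if default_mode is not None and mode is InheritanceMode.UNKNOWN
            else (name, mode)
            for name, mode in parse_inheritance(row.condition)
        )
        records.append(
            CatalogVariant(
                variant=variant,
                clinvar_id=row.clinvar_id,
                significance_raw=row.significance,
                conditions=conditions,
                gene_symbol=_opt(getattr(row, "gene", MISSING)),
            )
        )
    return records


def write_variant_catalog(records: Iterable[CatalogVariant], path) -> None:
    rows = [
        {
            "chrom": r.variant.chrom,
            "pos": r.variant.pos,
            "ref": r.variant.ref,
            "alt": r.variant.alt,
            "clinvar_id": r.clinvar_id,
            "significance": r.significance_raw,
            "condition": _format_conditions(r.conditions),
            "gene": _fmt_opt(r.gene_symbol),
        }
        for r in records
    ]
    _write_table(pd.DataFrame(rows, columns=VARIANT_COLUMNS), path)


DISORDER_COLUMNS = [
    "name",
    "aliases",
    "category",
    "subcategory",
    "inheritance_modes",
    "genes",
    "reported_in_india",
]


def read_disorders(path) -> list[Disorder]:
    df = _read_table(path, ["name", "category"])
    disorders = []
    for row in df.itertuples(index=False):
        disorders.append(
            Disorder(
                name=row.name,
                aliases=_split(getattr(row, "aliases", MISSING)),
                category=row.category,
                subcategory=_opt(getattr(row, "subcategory", MISSING)),
                inheritance_modes=frozenset(
                    InheritanceMode(m)
                    for m in _split(getattr(row, "inheritance_modes", MISSING))
                ),
                genes=_split(getattr(row, "genes", MISSING)),
                reported_in_india=getattr(row, "reported_in_india", "0")
                in ("1", "true", "True"),
            )
        )
    return disorders


def write_disorders(disorders: Iterable[Disorder], path) -> None:
    rows = [
        {
            "name": d.name,
            "aliases": _join(d.aliases),
            "category": d.category,
            "subcategory": _fmt_opt(d.subcategory),
            "inheritance_modes": _join(sorted(m.value for m in d.inheritance_modes)),
            "genes": _join(d.genes),
            "reported_in_india": "1" if d.reported_in_india else "0",
        }
        for d in disorders
    ]
    _write_table(pd.DataFrame(rows, columns=DISORDER_COLUMNS), path)


SYMPTOM_COLUMNS = ["disorder", "symptom", "medical_term", "frequency", "description"]


def read_symptom_associations(path) -> list[SymptomAssociation]:
    df = _read_table(path, ["disorder", "symptom", "frequency"])
    return [
        SymptomAssociation(
            disorder_name=row.disorder,
            symptom=row.symptom,
            frequency_term=FrequencyTerm.parse(row.frequency),
            medical_term=_opt(getattr(row, "medical_term", MISSING)),
            description=_opt(getattr(row, "description", MISSING)),
        )
        for row in df.itertuples(index=False)
    ]


def write_symptom_associations(assocs: Iterable[SymptomAssociation], path) -> None:
    rows = [
        {
            "disorder": a.disorder_name,
            "symptom": a.symptom,
            "medical_term": _fmt_opt(a.medical_term),
            "frequency": a.frequency_term.value,
            "description": _fmt_opt(a.description),
        }
        for a in assocs
    ]
    _write_table(pd.DataFrame(rows, columns=SYMPTOM_COLUMNS), path)


GENE_COLUMNS = ["symbol", "chrom", "strand", "start", "end", "exons"]


def read_gene_models(path) -> list[GeneModel]:
    df = _read_table(path, GENE_COLUMNS[:5])
    genes = []
    for row in df.itertuples(index=False):
        exon_field = getattr(row, "exons", MISSING)
        exons = tuple(
            (int(s), int(e))
            for s, e in (iv.split("-") for iv in _split(exon_field))
        )
        genes.append(
            GeneModel(
                symbol=row.symbol,
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                exons=exons,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    rows = [
        {
            "symbol": g.symbol,
            "chrom": g.chrom,
            "strand": g.strand,
            "start": g.start,
            "end": g.end,
            "exons": _join(f"{s}-{e}" for s, e in g.exons),
        }
        for g in genes
    ]
    _write_table(pd.DataFrame(rows, columns=GENE_COLUMNS), path)
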