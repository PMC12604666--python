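"""Bundled worked-example catalogs.

Two published annotation tables of identically mapped pathogenic variants
found in a healthy-cohort whole-genome screen: 14 variants linked to
autosomal dominant disorders and 37 linked to autosomal recessive disorders.
Both are shipped in the standard ``variants.tsv`` schema (coordinates from
the reference-catalog column) with the verbatim cohort variant string
preserved in an extra ``cohort_variant`` column — including the handful of
rows where the two printed notations disagree, which are kept as printed
rather than reconciled.
"""

from __future__ import annotations

from importlib import resources

from ..catalog import CatalogVariant, InheritanceMode, read_variant_catalog

__all__ = [
    "dominant_variants_path",
    "recessive_variants_path",
    "dominant_variant_catalog",
    "recessive_variant_catalog",
]


def _path(name: str):
    return resources.files(__package__) / name


def dominant_variants_path():
    return _path("dominant_variants.tsv")


def recessive_variants_path():
    return _path("recessive_variants.tsv")


def dominant_variant_catalog() -> list[CatalogVariant]:
    """The 14 autosomal-dominant pathogenic-variant annotations."""
    with resources.as_file(dominant_variants_path()) as p:
        return read_variant_catalog(p)


def recessive_variant_catalog() -> list[CatalogVariant]:
    """The 37 autosomal-recessive pathogenic-variant annotations.

    One row ("GM1 gangliosidosis type 2") prints no inheritance token; the
    table's scope fixes every row as autosomal recessive, so UNKNOWN modes
    default to AR here.
    """
    with resources.as_file(recessive_variants_path()) as p:
        return read_variant_catalog(p, default_mode=InheritanceMode.AR)
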