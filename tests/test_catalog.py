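"""Catalog domain model, parsing and round-trip TSV I/O."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgdtools import catalog as cat
from rgdtools.catalog import (
    CatalogFormatError,
    CatalogVariant,
    Disorder,
    FrequencyTerm,
    GeneModel,
    GenomicVariant,
    InheritanceMode,
    SignificanceCategory,
    SymptomAssociation,
    categorize_significance,
    normalize_chrom,
    parse_inheritance,
)


class TestNormalizeChrom:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("13", "chr13"),
            ("chr13", "chr13"),
            ("MT", "chrM"),
            ("chrMT", "chrM"),
            ("x", "chrX"),
            ("CHR2", "chr2"),
        ],
    )
    def test_canonical_form(self, raw, expected):
        assert normalize_chrom(raw) == expected

    @given(st.from_regex(r"(chr)?([0-9]{1,2}|[XYxy]|MT|M)", fullmatch=True))
    def test_idempotent(self, label):
        once = normalize_chrom(label)
        assert normalize_chrom(once) == once

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            normalize_chrom("  ")


class TestParseInheritance:
    def test_single_mode_token(self):
        assert parse_inheritance("Wilson disease (AR)") == [
            ("Wilson disease", InheritanceMode.AR)
        ]

    def test_and_joined_pair_splits(self):
        pairs = parse_inheritance(
            "Van der Woude syndrome 1 (AD) and Popliteal pterygium syndrome (AD)"
        )
        assert pairs == [
            ("Van der Woude syndrome 1", InheritanceMode.AD),
            ("Popliteal pterygium syndrome", InheritanceMode.AD),
        ]

    def test_no_token_is_unknown(self):
        assert parse_inheritance("GM1 gangliosidosis type 2") == [
            ("GM1 gangliosidosis type 2", InheritanceMode.UNKNOWN)
        ]

    def test_and_inside_name_not_split(self):
        # only one fragment carries a token: the name keeps its "and"
        [(name, mode)] = parse_inheritance(
            "Hypotonia with psychomotor retardation and characteristic facies 1 (AR)"
        )
        assert "and characteristic facies" in name
        assert mode is InheritanceMode.AR

    def test_x_linked_token(self):
        assert parse_inheritance("Some condition (XL)") == [
            ("Some condition", InheritanceMode.X_LINKED)
        ]

    @given(st.text(min_size=1).filter(lambda s: s.strip()))
    def test_never_raises_and_strips_token(self, condition):
        for name, _ in parse_inheritance(condition):
            assert not cat._MODE_TOKEN.search(name)


class TestCategorizeSignificance:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Pathogenic", SignificanceCategory.PATHOGENIC),
            ("pathogenic/likely pathogenic", SignificanceCategory.PATHOGENIC),
            ("Likely pathogenic", SignificanceCategory.LIKELY_PATHOGENIC),
            (
                "Conflicting interpretations of pathogenicity",
                SignificanceCategory.PATHOGENIC_CONFLICTING,
            ),
            ("Benign", SignificanceCategory.BENIGN_OR_LIKELY_BENIGN),
            ("Likely benign", SignificanceCategory.BENIGN_OR_LIKELY_BENIGN),
            ("Uncertain significance", SignificanceCategory.OTHER),
            ("drug response", SignificanceCategory.OTHER),
        ],
    )
    def test_mapping(self, raw, expected):
        assert categorize_significance(raw) is expected

    @given(st.text(min_size=1).filter(lambda s: s.strip()))
    def test_total_and_case_insensitive(self, raw):
        assert categorize_significance(raw) is categorize_significance(raw.upper())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            categorize_significance("")


class TestFrequencyTerm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Always", FrequencyTerm.ALWAYS),
            ("  very   frequently ", FrequencyTerm.VERY_FREQUENTLY),
            ("VERY_FREQUENTLY", FrequencyTerm.VERY_FREQUENTLY),
            ("rarely", FrequencyTerm.RARELY),
        ],
    )
    def test_parse(self, raw, expected):
        assert FrequencyTerm.parse(raw) is expected

    def test_unrecognized_degrades_to_none(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert FrequencyTerm.parse("weekly") is FrequencyTerm.NONE
        assert "weekly" in caplog.text


class TestGenomicVariant:
    def test_normalizes_on_construction(self):
        v = GenomicVariant(chrom="13", pos=51944170, ref="c", alt="t")
        assert str(v) == "chr13:51944170:C>T"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="chr1", pos=0, ref="A", alt="G"),
            dict(chrom="chr1", pos=5, ref="A", alt="A"),
            dict(chrom="chr1", pos=5, ref="", alt="G"),
            dict(chrom="chr1", pos=5, ref="AZ", alt="G"),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicVariant(**kwargs)


class TestVariantCatalogIO:
    def test_worked_example_row_counts(self):
        from rgdtools import data

        assert len(data.dominant_variant_catalog()) == 14
        assert len(data.recessive_variant_catalog()) == 37

    def test_recessive_loader_defaults_unknown_to_ar(self):
        from rgdtools import data

        rec = data.recessive_variant_catalog()
        assert all(
            mode is InheritanceMode.AR for r in rec for _, mode in r.conditions
        )

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tpos\tref\n", encoding="utf-8")
        with pytest.raises(CatalogFormatError):
            cat.read_variant_catalog(p)

    def test_non_integer_pos_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "v.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tclinvar_id\tsignificance\tcondition\n"
            "chr1\t100\tA\tG\t1\tPathogenic\tFoo (AD)\n"
            "chr1\tabc\tA\tG\t2\tPathogenic\tBar (AR)\n",
            encoding="utf-8",
        )
        with caplog.at_level(logging.WARNING):
            records = cat.read_variant_catalog(p)
        assert len(records) == 1
        assert "rejected" in caplog.text

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("\t".join(cat.VARIANT_COLUMNS) + "\n", encoding="utf-8")
        assert cat.read_variant_catalog(p) == []


# --- round-trip property tests ---------------------------------------------

_names = st.text(
    alphabet=st.characters(whitelist_categories=("L", "N"), max_codepoint=0x2FF),
    min_size=1,
    max_size=20,
).map(str.strip).filter(bool)

_variants = st.builds(
    GenomicVariant,
    chrom=st.sampled_from([f"chr{i}" for i in range(1, 23)] + ["chrX"]),
    pos=st.integers(1, 10**8),
    ref=st.text("ACGT", min_size=1, max_size=5),
    alt=st.text("ACGT", min_size=1, max_size=5),
).filter(lambda kw: True)

_catalog_variants = st.builds(
    CatalogVariant,
    variant=st.builds(
        GenomicVariant,
        chrom=st.sampled_from(["chr1", "chr2", "chrX"]),
        pos=st.integers(1, 10**8),
        ref=st.sampled_from(["A", "C", "AC"]),
        alt=st.sampled_from(["T", "G", "TA"]),
    ),
    clinvar_id=st.integers(1, 10**7).map(str),
    significance_raw=st.sampled_from(
        ["Pathogenic", "Likely pathogenic", "Benign", "Uncertain significance"]
    ),
    conditions=st.lists(
        st.tuples(
            _names,
            st.sampled_from(
                [InheritanceMode.AD, InheritanceMode.AR, InheritanceMode.X_LINKED]
            ),
        ),
        min_size=1,
        max_size=3,
    ).map(tuple),
    gene_symbol=st.none() | st.sampled_from(["ATP7B", "LIPA", "IRF6"]),
)


@settings(max_examples=100, deadline=None)
@given(st.lists(_catalog_variants, max_size=8))
def test_variant_catalog_round_trip(tmp_path_factory, records):
    p = tmp_path_factory.mktemp("rt") / "v.tsv"
    cat.write_variant_catalog(records, p)
    back = cat.read_variant_catalog(p)
    assert [
        (r.variant, r.clinvar_id, r.significance_raw, r.conditions, r.gene_symbol)
        for r in back
    ] == [
        (r.variant, r.clinvar_id, r.significance_raw, r.conditions, r.gene_symbol)
        for r in records
    ]


_disorders = st.builds(
    Disorder,
    name=_names,
    aliases=st.lists(_names, max_size=2).map(tuple),
    category=_names,
    subcategory=st.none() | _names,
    inheritance_modes=st.frozensets(
        st.sampled_from([InheritanceMode.AD, InheritanceMode.AR]), max_size=2
    ),
    genes=st.lists(_names, min_size=1, max_size=3).map(tuple),
    reported_in_india=st.booleans(),
)


@settings(max_examples=100, deadline=None)
@given(st.lists(_disorders, max_size=6))
def test_disorders_round_trip(tmp_path_factory, disorders):
    p = tmp_path_factory.mktemp("rt") / "d.tsv"
    cat.write_disorders(disorders, p)
    assert cat.read_disorders(p) == disorders


_associations = st.builds(
    SymptomAssociation,
    disorder_name=_names,
    symptom=_names,
    frequency_term=st.sampled_from(list(FrequencyTerm)),
    medical_term=st.none() | _names,
    description=st.none() | _names,
)


@settings(max_examples=100, deadline=None)
@given(st.lists(_associations, max_size=6))
def test_symptom_associations_round_trip(tmp_path_factory, assocs):
    p = tmp_path_factory.mktemp("rt") / "s.tsv"
    cat.write_symptom_associations(assocs, p)
    assert cat.read_symptom_associations(p) == assocs


@st.composite
def _gene_models(draw):
    start = draw(st.integers(1, 10**6))
    length = draw(st.integers(1, 5000))
    end = start + length - 1
    n_exons = draw(st.integers(0, min(3, length // 2)))
    bounds = sorted(
        draw(
            st.lists(
                st.integers(start, end),
                min_size=2 * n_exons,
                max_size=2 * n_exons,
                unique=True,
            )
        )
    )
    exons = tuple(
        (bounds[i], bounds[i + 1] - 1)
        for i in range(0, len(bounds) - 1, 2)
        if bounds[i] <= bounds[i + 1] - 1
    )
    return GeneModel(
        symbol=draw(st.sampled_from(["BRCA1", "ATP7B", "LIPA"])),
        chrom=draw(st.sampled_from(["chr1", "chr13"])),
        strand=draw(st.sampled_from(["+", "-"])),
        start=start,
        end=end,
        exons=exons,
    )


@settings(max_examples=100, deadline=None)
@given(st.lists(_gene_models(), max_size=4))
def test_gene_models_round_trip(tmp_path_factory, genes):
    p = tmp_path_factory.mktemp("rt") / "g.tsv"
    cat.write_gene_models(genes, p)
    assert cat.read_gene_models(p) == genes
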