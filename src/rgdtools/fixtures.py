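"""Deterministic synthetic-data generators with planted ground truth.

Every generator is a pure function of an integer seed and writes plain-text
outputs (TSV catalogs, a v4.2 VCF) plus a machine-readable truth record, so
the matching, prediction and profiling modules are testable offline. The
generated data emulates the *structure* of a healthy-cohort screen against a
ClinVar-like pathogenic catalog — planted identical / similar / unmatched
variants, a seven-term symptom-frequency vocabulary, gene models with exons
— without imitating any real resource's content.

Each generator owns its RNG stream (seeded independently), so regenerating
one file never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import (
    CatalogVariant,
    Disorder,
    FrequencyTerm,
    GeneModel,
    GenomicVariant,
    InheritanceMode,
    SignificanceCategory,
    SymptomAssociation,
    write_disorders,
    write_gene_models,
    write_symptom_associations,
    write_variant_catalog,
)
from .predict import DEFAULT_TOP_K, FrequencyWeightTable

__all__ = [
    "PlantedTruth",
    "generate_variant_catalog",
    "generate_cohort_vcf",
    "generate_symptom_catalog",
    "generate_gene_models",
    "simulate",
    "write_vcf",
]

#: chromosome universe for fixtures (autosomes + X)
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

_SIGNIFICANCE_RAW = {
    SignificanceCategory.PATHOGENIC: "Pathogenic",
    SignificanceCategory.LIKELY_PATHOGENIC: "Likely pathogenic",
    SignificanceCategory.PATHOGENIC_CONFLICTING: "Conflicting interpretations of pathogenicity",
    SignificanceCategory.BENIGN_OR_LIKELY_BENIGN: "Benign",
    SignificanceCategory.OTHER: "Uncertain significance",
}

_BASES = "ACGT"


@dataclass
class PlantedTruth:
    """Machine-readable ground truth emitted next to generated fixtures."""

    seed: int
    n_identical: int = 0
    n_similar: int = 0
    n_unmatched: int = 0
    by_significance: dict[str, int] = field(default_factory=dict)
    by_inheritance: dict[str, int] = field(default_factory=dict)
    expected_ranking: list[dict] = field(default_factory=list)
    selection: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_identical": self.n_identical,
            "n_similar": self.n_similar,
            "n_unmatched": self.n_unmatched,
            "by_significance": dict(self.by_significance),
            "by_inheritance": dict(self.by_inheritance),
            "selection": list(self.selection),
            "expected_ranking": list(self.expected_ranking),
        }


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, sum(map(ord, stream))])


def _random_site(rng: np.random.Generator, used: set[tuple[str, int]]) -> tuple[str, int]:
    while True:
        chrom = CHROMOSOMES[rng.integers(len(CHROMOSOMES))]
        pos = int(rng.integers(10_000, 50_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


DEFAULT_SIGNIFICANCE_MIX: dict[SignificanceCategory, float] = {
    SignificanceCategory.PATHOGENIC: 0.4,
    SignificanceCategory.LIKELY_PATHOGENIC: 0.2,
    SignificanceCategory.PATHOGENIC_CONFLICTING: 0.1,
    SignificanceCategory.BENIGN_OR_LIKELY_BENIGN: 0.2,
    SignificanceCategory.OTHER: 0.1,
}

DEFAULT_MODE_MIX: dict[InheritanceMode, float] = {
    InheritanceMode.AD: 0.35,
    InheritanceMode.AR: 0.5,
    InheritanceMode.X_LINKED: 0.1,
    InheritanceMode.UNKNOWN: 0.05,
}


def generate_variant_catalog(
    seed: int,
    n: int = 100,
    significance_mix: Mapping[SignificanceCategory, float] | None = None,
    mode_mix: Mapping[InheritanceMode, float] | None = None,
    out: str | Path | None = None,
) -> tuple[list[CatalogVariant], PlantedTruth]:
    """Generate a pathogenic-variant catalog with known composition.

    Significance categories and inheritance modes are drawn from the given
    proportion maps (multinomial sampling); sites are unique per (chrom,
    pos). Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sig_mix = dict(significance_mix or DEFAULT_SIGNIFICANCE_MIX)
    m_mix = dict(mode_mix or DEFAULT_MODE_MIX)
    for mix in (sig_mix, m_mix):
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("mix proportions must sum to 1")
    rng = _rng(seed, "catalog")
    used: set[tuple[str, int]] = set()
    sig_keys = list(sig_mix)
    mode_keys = list(m_mix)
    truth = PlantedTruth(seed=seed)
    records = []
    for i in range(n):
        chrom, pos = _random_site(rng, used)
        ref, alt = _random_snv(rng)
        sig = sig_keys[rng.choice(len(sig_keys), p=[sig_mix[k] for k in sig_keys])]
        mode = mode_keys[rng.choice(len(mode_keys), p=[m_mix[k] for k in mode_keys])]
        records.append(
            CatalogVariant(
                variant=GenomicVariant(chrom=chrom, pos=pos, ref=ref, alt=alt),
                clinvar_id=str(100000 + i),
                significance_raw=_SIGNIFICANCE_RAW[sig],
                conditions=((f"Synthetic condition {i}", mode),),
                gene_symbol=f"GENE{i % max(1, n // 3)}",
            )
        )
        truth.by_significance[sig.value] = truth.by_significance.get(sig.value, 0) + 1
        truth.by_inheritance[mode.value] = truth.by_inheritance.get(mode.value, 0) + 1
    if out is not None:
        write_variant_catalog(records, out)
    return records, truth


def write_vcf(variants: Sequence[GenomicVariant], path) -> None:
    """Write variants as a minimal single-sample-free VCF v4.2 file."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom in CHROMOSOMES:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        vid = v.id or "."
        lines.append(f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def generate_cohort_vcf(
    seed: int,
    catalog: Sequence[CatalogVariant],
    k_identical: int,
    m_similar: int,
    u_unmatched: int,
    out: str | Path | None = None,
) -> tuple[list[GenomicVariant], PlantedTruth]:
    """Plant a cohort with exactly known identical/similar/unmatched counts.

    Identical variants copy catalog alleles verbatim; similar variants reuse
    a catalog site with a perturbed alternate allele (never colliding with
    any catalog allele at that site); unmatched variants use fresh sites.
    Identical and similar sites are disjoint so site-level counting recovers
    (k, m, u) exactly.
    """
    sites: dict[tuple[str, int], list[CatalogVariant]] = {}
    for e in catalog:
        sites.setdefault(e.variant.site, []).append(e)
    n_sites = len(sites)
    if k_identical + m_similar > n_sites:
        raise ValueError(
            f"cannot plant {k_identical}+{m_similar} matches on {n_sites} catalog sites"
        )
    if min(k_identical, m_similar, u_unmatched) < 0:
        raise ValueError("planted counts must be non-negative")
    rng = _rng(seed, "cohort")
    site_keys = sorted(sites)
    order = rng.permutation(n_sites)
    ident_sites = [site_keys[i] for i in order[:k_identical]]
    sim_sites = [site_keys[i] for i in order[k_identical : k_identical + m_similar]]

    cohort: list[GenomicVariant] = []
    for site in ident_sites:
        entry = sites[site][int(rng.integers(len(sites[site])))]
        cohort.append(entry.variant)
    for site in sim_sites:
        entries = sites[site]
        taken = {(e.variant.ref, e.variant.alt) for e in entries}
        ref = entries[0].variant.ref
        base_ref = ref[0] if len(ref) > 1 else ref
        alt = None
        for b in _BASES:
            if b != base_ref and (base_ref, b) not in taken:
                alt = b
                break
        if alt is None:  # all three SNV alts taken: fall back to an insertion
            alt = base_ref + "T"
            while (base_ref, alt) in taken:
                alt += "T"
        cohort.append(
            GenomicVariant(chrom=site[0], pos=site[1], ref=base_ref, alt=alt)
        )
    used = set(sites)
    for _ in range(u_unmatched):
        chrom, pos = _random_site(rng, used)
        ref, alt = _random_snv(rng)
        cohort.append(GenomicVariant(chrom=chrom, pos=pos, ref=ref, alt=alt))

    truth = PlantedTruth(
        seed=seed,
        n_identical=k_identical,
        n_similar=m_similar,
        n_unmatched=u_unmatched,
    )
    if out is not None:
        write_vcf(cohort, out)
    return cohort, truth


_SYMPTOM_POOL = [
    "short stature", "seizures", "muscle weakness", "hearing loss",
    "vision loss", "developmental delay", "anemia", "hepatomegaly",
    "ataxia", "hypotonia", "coarse facies", "cardiomyopathy",
    "skeletal dysplasia", "intellectual disability", "failure to thrive",
    "microcephaly", "spasticity", "photosensitivity", "joint laxity",
    "recurrent infections", "nephropathy", "corneal clouding",
    "night blindness", "sensory neuropathy", "dystonia", "alopecia",
    "ichthyosis", "macroglossia", "splenomegaly", "osteopenia",
]

_CATEGORY_POOL = [
    "Metabolic disorders", "Neuromuscular disorders", "Skin disorders",
    "Eye disorders", "Blood disorders",
]

_FREQ_TERMS = [t for t in FrequencyTerm if t is not FrequencyTerm.NONE]


def generate_symptom_catalog(
    seed: int,
    n_disorders: int = 20,
    n_symptoms: int = 12,
    out_dir: str | Path | None = None,
) -> tuple[list[Disorder], list[SymptomAssociation], PlantedTruth]:
    """Generate disorders plus symptom associations with a scored selection.

    The truth record carries one scripted symptom selection together with
    the exhaustive brute-force score table and the resulting expected
    ranking (score descending, name ascending, zero scores dropped,
    truncated to the default top-k).
    """
    if n_disorders < 1 or n_symptoms < 1:
        raise ValueError("need at least one disorder and one symptom")
    rng = _rng(seed, "symptoms")
    symptoms = [
        _SYMPTOM_POOL[i % len(_SYMPTOM_POOL)]
        + ("" if i < len(_SYMPTOM_POOL) else f" type {i // len(_SYMPTOM_POOL) + 1}")
        for i in range(n_symptoms)
    ]
    disorders = []
    associations = []
    for i in range(n_disorders):
        name = f"Synthetic disorder {i + 1:03d}"
        category = _CATEGORY_POOL[int(rng.integers(len(_CATEGORY_POOL)))]
        n_assoc = int(rng.integers(1, min(n_symptoms, 8) + 1))
        picked = rng.choice(n_symptoms, size=n_assoc, replace=False)
        disorders.append(
            Disorder(
                name=name,
                category=category,
                genes=(f"SYN{i + 1}",),
                reported_in_india=True,
                inheritance_modes=frozenset({InheritanceMode.AR}),
            )
        )
        for j in sorted(int(p) for p in picked):
            term = _FREQ_TERMS[int(rng.integers(len(_FREQ_TERMS)))]
            associations.append(
                SymptomAssociation(
                    disorder_name=name, symptom=symptoms[j], frequency_term=term
                )
            )

    # scripted selection: three symptoms (or fewer if the pool is smaller)
    n_sel = min(3, n_symptoms)
    sel_idx = rng.choice(n_symptoms, size=n_sel, replace=False)
    selection = sorted(symptoms[int(i)] for i in sel_idx)

    # exhaustive oracle: score every disorder by direct summation
    table = FrequencyWeightTable()
    scored = []
    for d in disorders:
        score = sum(
            table[a.frequency_term]
            for a in associations
            if a.disorder_name == d.name and a.symptom in selection
        )
        if score > 0:
            scored.append({"disorder": d.name, "score": score})
    scored.sort(key=lambda r: (-r["score"], r["disorder"].casefold()))
    truth = PlantedTruth(
        seed=seed, selection=selection, expected_ranking=scored[:DEFAULT_TOP_K]
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_disorders(disorders, out_dir / "disorders.tsv")
        write_symptom_associations(associations, out_dir / "symptoms.tsv")
    return disorders, associations, truth


def generate_gene_models(
    seed: int, n_genes: int = 5, out: str | Path | None = None
) -> list[GeneModel]:
    """Generate gene models with sorted non-overlapping exons."""
    rng = _rng(seed, "genes")
    genes = []
    for i in range(n_genes):
        chrom = CHROMOSOMES[int(rng.integers(len(CHROMOSOMES)))]
        start = int(rng.integers(10_000, 1_000_000))
        length = int(rng.integers(800, 20_000))
        end = start + length - 1
        n_exons = int(rng.integers(1, 9))
        bounds = sorted(
            {int(b) for b in rng.integers(start, end + 1, size=2 * n_exons)}
        )
        exons = tuple(
            (bounds[j], bounds[j + 1] - 1)
            for j in range(0, len(bounds) - 1, 2)
            if bounds[j] <= bounds[j + 1] - 1
        )
        genes.append(
            GeneModel(
                symbol=f"SYNG{i + 1}",
                chrom=chrom,
                strand="+" if rng.integers(2) else "-",
                start=start,
                end=end,
                exons=exons,
            )
        )
    if out is not None:
        write_gene_models(genes, out)
    return genes


def simulate(
    seed: int,
    out_dir: str | Path,
    n_catalog: int = 100,
    k_identical: int = 5,
    m_similar: int = 3,
    u_unmatched: int = 2,
    n_disorders: int = 20,
    n_symptoms: int = 12,
    n_genes: int = 5,
) -> PlantedTruth:
    """Emit the full fixture set (all TSVs, cohort VCF, truth.json)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog, cat_truth = generate_variant_catalog(
        seed, n=n_catalog, out=out_dir / "variants.tsv"
    )
    _, vcf_truth = generate_cohort_vcf(
        seed, catalog, k_identical, m_similar, u_unmatched,
        out=out_dir / "cohort.vcf",
    )
    _, _, sym_truth = generate_symptom_catalog(
        seed, n_disorders=n_disorders, n_symptoms=n_symptoms, out_dir=out_dir
    )
    generate_gene_models(seed, n_genes=n_genes, out=out_dir / "genes.tsv")
    truth = PlantedTruth(
        seed=seed,
        n_identical=vcf_truth.n_identical,
        n_similar=vcf_truth.n_similar,
        n_unmatched=vcf_truth.n_unmatched,
        by_significance=cat_truth.by_significance,
        by_inheritance=cat_truth.by_inheritance,
        selection=sym_truth.selection,
        expected_ranking=sym_truth.expected_ranking,
    )
    (out_dir / "truth.json").write_text(
        json.dumps(truth.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    return truth
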