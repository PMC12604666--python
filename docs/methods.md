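# Methods

## Scope and data model

`rgdtools` operates on five plain-text inputs: a disorder catalog, a
disorder–symptom association table, a ClinVar-like pathogenic-variant
catalog, a cohort VCF (v4.x, GRCh38-style coordinates), and gene models.
All tabular files are tab-delimited UTF-8 with a mandatory header and `"."`
for missing values; all coordinates are 1-based inclusive internally, with
the 0-based half-open convention used only at the BED boundary. Chromosome
labels are normalized once on ingestion to the `chr`-prefixed form
(`13 → chr13`, `MT → chrM`); normalization is idempotent, so mixed dialects
join cleanly.

Clinical-significance strings are bucketed case-insensitively into five
categories: *pathogenic* (including the combined "Pathogenic/Likely
pathogenic" assertion), *likely pathogenic*, *conflicting* (any string
containing "conflicting"), *benign/likely benign*, and *other* (uncertain
significance, drug response, …). The first three together form the
"pathogenic" superset used in summaries; whether profiling should instead
count strictly-pathogenic records is configurable by pre-filtering the
variant list handed to the profiler.

Condition strings carry inheritance as a trailing parenthesized token —
`(AD)`, `(AR)`, or `(XL)` for X-linked. `" and "`-joined strings split into
several conditions only when every fragment carries its own token, because
condition names legitimately contain "and" ("… psychomotor retardation and
characteristic facies 1 (AR)" is one condition). Absent a token the mode is
UNKNOWN; a variant whose matched conditions span ≥ 2 distinct known modes is
summarized as MULTI. Readers accept a `default_mode` for tables whose
provenance fixes the mode globally (the bundled recessive table uses AR).

## Disorder prediction

The scoring model is a weighted sum over the user's symptom selection:
each selected symptom associated with a disorder contributes the weight of
its frequency term; everything else contributes zero. Default weights are
always → 4, very frequently → 3, frequently → 2, sometimes → 1,
unusually → 0.5, rarely → 0.5, no frequency → 0. The published weight
sequence maps three low-frequency terms onto the two printed values "1 and
0.5"; this package fixes sometimes → 1 and the last two terms → 0.5, the
only assignment preserving the monotone ordering of the listed sequence,
and the whole table is overridable via JSON so the alternative reading is a
one-line config change. Scores are raw sums — no normalization by a
disorder's total symptom count, since the model is defined purely as
summation of frequency weights.

Ranking is score-descending with case-insensitive alphabetical tie-break on
the disorder name (names are unique keys, so ordering is total and
deterministic), truncated to the top k = 10 by default. Zero-score
disorders are dropped: a disorder sharing no selected symptom is not a
prediction. Consequences that the tests exercise: adding a symptom to the
selection never decreases any score; output is invariant to the ordering of
catalog rows and of the selection; and scores over disjoint selections are
exactly additive.

## Variant matching

A cohort variant is IDENTICAL when some catalog entry matches
(chrom, pos, ref, alt) exactly, SIMILAR when entries share only
(chrom, pos), UNMATCHED otherwise — a total three-way partition, with
identical taking precedence when both hold at one site against different
entries. "Same site, different genotypes" is interpreted at the allele
level (different ref/alt strings), not via VCF GT fields: the canonical
similar example pair (`C>T` vs `AC>A` at one position) is an
allele-representation difference, and sample columns are not consulted.

No allele trimming or left-alignment is applied by default: normalizing
would silently reclassify representation-difference pairs that the
allele-level definition treats as similar. An opt-in `--normalize` flag
(minimal-representation trimming before key lookup) is available and
clearly labeled as a deviation from verbatim comparison.

VCF ingestion (cyvcf2) splits multi-allelic records into one variant per
alternate allele and skips symbolic alleles, breakends and spanning
deletions with a logged count. Matching uses hash indexes keyed on the
exact allele tuple and on the site, so classification is O(1) expected per
variant; a brute-force O(n·m) double loop serves as the oracle in tests.

Summaries count **distinct mutation sites**, not raw VCF rows: cohort
variants are grouped by (chrom, pos) after classification, a site is
identical if any allele at it matched identically, and pathogenic counts
use the three-category pathogenic superset with the best-matched (most
severe) significance representing the site. The partition identities
`mapped = identical + similar` and `pathogenic = pathogenic_identical +
pathogenic_similar` hold by construction and are asserted on every input.
The inheritance breakdown covers identical pathogenic sites. Coordinates
are treated as GRCh38 by convention; no liftover is performed.

The two bundled annotation tables are ingested with their reference-catalog
coordinates as both catalog and cohort (self-match), which reproduces their
distinct-site counts (14 dominant, 37 recessive). A few printed rows carry
discrepant cohort-vs-catalog position notations (almost certainly
typographical); both strings are stored verbatim, and the cohort column is
deliberately not used as the match key for the worked example.

## Gene profiling

Windows of width 500 bp (configurable, ≥ 1) start at the gene's genomic
start coordinate regardless of strand and tile the span exactly; only the
last window may be shorter. Window intervals are closed, so a variant at a
window's end position belongs to that window, and each in-span variant
falls in exactly one window — totals are conserved for any width. Variants
on another chromosome are excluded with a warning. A strand-relative
renumbering exists for display only; coordinates never change. The numeric
profile is the product; histogram rendering is out of scope. The four-tier
track model (chromosome context ⊇ gene span ⊇ exons, variants) exports to
BED with the window count in the score column, and BED import restores all
intervals and scores.

## Synthetic fixtures

The generators emulate the *structure* of a healthy-cohort screen against a
pathogenic catalog, not the content of any real resource: catalog sites are
unique uniform draws over chr1–chr22 + chrX (matching the autosomal/X scope
of the bundled tables), significance and inheritance compositions follow
user-specified multinomial mixes (defaults: 40/20/10/20/10% across the five
significance buckets; 35/50/10/5% AD/AR/XL/unknown), and cohorts are
planted with exact identical/similar/unmatched counts — identical variants
copy catalog alleles verbatim, similar variants reuse a catalog site with a
non-colliding perturbed alternate allele, unmatched variants use fresh
sites, and the identical and similar site sets are kept disjoint so
site-level counting recovers the planted triple exactly. The default
planted configuration is a 100-record catalog with a (5, 3, 2) cohort —
small enough to verify by hand, structured like the real analysis. Symptom
catalogs draw 1–8 associations per disorder from a fixed symptom vocabulary
and script one selection whose exhaustive brute-force score table is stored
as truth. Every generator is a pure function of one integer seed with its
own RNG stream, and outputs are byte-identical across runs.

What passing these tests shows — and does not. Planted-truth recovery and
oracle equivalence validate the classification, aggregation and ranking
logic. They do not validate robustness to real-data messiness the
generator omits: multi-sample VCFs, non-normalized indel representations,
overlapping catalog records with contradictory assertions, or symptom
vocabularies outside the seven-term list (unknown terms degrade to weight 0
with a warning rather than erroring).

## Numerical and design notes

- Published cohort-scale totals (8645 mapped = 4826 identical + 3819
  similar; 1131 pathogenic = 432 + 699) are checked as aggregation
  identities through the summary type; regenerating them from raw data
  would require the external cohort release and a specific catalog
  snapshot, which is out of scope.
- Significance severity order for picking a site's representative category:
  pathogenic > likely pathogenic > conflicting > other > benign.
- All scoring is plain floating-point summation of small weights; no
  tolerance issues arise at these magnitudes (exact binary fractions).
- Degenerate inputs: single-base genes yield one length-1 window; an empty
  match set yields an all-zero summary; an empty symptom selection and
  k < 1 are input errors; an empty chromosome label is an input error.
- Identifier-based joining (e.g. dbSNP rs ids) is not implemented; matching
  is purely positional/allelic.
- Acceptance and test problem sizes — 100-seed planted-recovery loops over
  20–100-record catalogs, ≤ 50-disorder prediction fixtures — were chosen
  as the smallest sizes that exercise every code path with clear margins;
  the full suite runs in seconds.

## Known limitations

- No GT-level (zygosity) comparison and no allele-frequency estimation;
  sample columns are ignored.
- No phenotype-ontology expansion of symptom terms: selections must use the
  catalog's own symptom vocabulary.
- No liftover between genome builds; inputs must share coordinates.
- The similar/identical distinction is representation-sensitive by design;
  users comparing differently normalized call sets should enable
  `--normalize` and interpret the deviation accordingly.
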