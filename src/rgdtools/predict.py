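"""Symptom-frequency-weighted rare-disorder prediction.

Each disorder d carries symptom associations with ordinal frequency terms
(always … rarely). A weight table w maps each term to a number; given a user
selection of symptoms S, a disorder scores

    S(d) = sum over s in S of w(freq(s, d))

where symptoms not associated with d contribute zero. Disorders are ranked
by score descending, ties broken alphabetically (case-insensitive), and the
top k (default 10) are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .catalog import Disorder, FrequencyTerm, SymptomAssociation

__all__ = [
    "DEFAULT_TOP_K",
    "DEFAULT_WEIGHTS",
    "FrequencyWeightTable",
    "PredictionResult",
    "frequency_weight",
    "score_disorder",
    "predict",
    "list_symptoms",
]

#: default number of top-ranked disorders reported
DEFAULT_TOP_K = 10

#: default frequency-term weights: "always" marks the strongest association
#: (4), down through very frequently (3), frequently (2), sometimes (1),
#: unusually/rarely (0.5); an absent frequency contributes nothing.
DEFAULT_WEIGHTS: dict[FrequencyTerm, float] = {
    FrequencyTerm.ALWAYS: 4.0,
    FrequencyTerm.VERY_FREQUENTLY: 3.0,
    FrequencyTerm.FREQUENTLY: 2.0,
    FrequencyTerm.SOMETIMES: 1.0,
    FrequencyTerm.UNUSUALLY: 0.5,
    FrequencyTerm.RARELY: 0.5,
    FrequencyTerm.NONE: 0.0,
}

_ORDER = [
    FrequencyTerm.ALWAYS,
    FrequencyTerm.VERY_FREQUENTLY,
    FrequencyTerm.FREQUENTLY,
    FrequencyTerm.SOMETIMES,
    FrequencyTerm.UNUSUALLY,
    FrequencyTerm.RARELY,
    FrequencyTerm.NONE,
]


@dataclass(frozen=True)
class FrequencyWeightTable:
    """Mapping from frequency term to a non-negative score weight.

    Weights must be monotone non-increasing along the ordinal frequency
    scale (always >= very frequently >= ... >= rarely >= none).
    """

    weights: Mapping[FrequencyTerm, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )

    def __post_init__(self) -> None:
        missing = [t for t in FrequencyTerm if t not in self.weights]
        if missing:
            raise ValueError(f"weight table missing terms: {missing}")
        values = [self.weights[t] for t in _ORDER]
        if any(v < 0 for v in values):
            raise ValueError("weights must be non-negative")
        if any(a < b for a, b in zip(values, values[1:])):
            raise ValueError("weights must be monotone non-increasing")

    def __getitem__(self, term: FrequencyTerm) -> float:
        return self.weights[term]

    @classmethod
    def from_json(cls, path) -> "FrequencyWeightTable":
        """Load overrides from a JSON object of term-name -> weight."""
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        weights = dict(DEFAULT_WEIGHTS)
        for name, value in raw.items():
            weights[FrequencyTerm.parse(name)] = float(value)
        return cls(weights)


@dataclass(frozen=True)
class PredictionResult:
    """One ranked disorder with its score and contributing symptoms."""

    disorder_name: str
    score: float
    matched_symptoms: tuple[tuple[str, FrequencyTerm, float], ...]
    category: str


def frequency_weight(
    term: FrequencyTerm, table: FrequencyWeightTable | None = None
) -> float:
    """Weight of one frequency term under ``table`` (default table if None)."""
    return (table or FrequencyWeightTable())[term]


def score_disorder(
    selected: Iterable[str],
    associations: Iterable[SymptomAssociation],
    table: FrequencyWeightTable | None = None,
    *,
    disorder_name: str | None = None,
    category: str = ".",
) -> PredictionResult:
    """Score one disorder against a symptom selection.

    Only selected symptoms that the disorder is associated with contribute;
    each contributes the weight of its frequency term.
    """
    selected_set = set(selected)
    if not selected_set:
        raise ValueError("symptom selection must be non-empty")
    table = table or FrequencyWeightTable()
    assocs = list(associations)
    name = disorder_name or (assocs[0].disorder_name if assocs else "")
    matched = tuple(
        sorted(
            (
                (a.symptom, a.frequency_term, table[a.frequency_term])
                for a in assocs
                if a.symptom in selected_set
            ),
            key=lambda t: t[0],
        )
    )
    return PredictionResult(
        disorder_name=name,
        score=sum(w for _, _, w in matched),
        matched_symptoms=matched,
        category=category,
    )


def _check_category(
    category_filter: str | None, disorders: Sequence[Disorder]
) -> str | None:
    if category_filter is None or category_filter.upper() == "ALL":
        return None
    valid = sorted({d.category for d in disorders})
    if category_filter not in valid:
        raise ValueError(
            f"unknown category {category_filter!r}; valid categories: "
            + ", ".join(valid)
        )
    return category_filter


def predict(
    selected: Iterable[str],
    disorders: Sequence[Disorder],
    associations: Iterable[SymptomAssociation],
    category_filter: str | None = "ALL",
    table: FrequencyWeightTable | None = None,
    k: int = DEFAULT_TOP_K,
) -> list[PredictionResult]:
    """Rank disorders by weighted symptom-frequency score.

    Disorders scoring zero (no selected symptom shared) are dropped; the
    remainder are sorted by score descending then name ascending
    (case-insensitive) and truncated to the top ``k``. Deterministic and
    independent of input ordering.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    selected_set = set(selected)
    if not selected_set:
        raise ValueError("symptom selection must be non-empty")
    category = _check_category(category_filter, disorders)
    table = table or FrequencyWeightTable()

    by_disorder: dict[str, list[SymptomAssociation]] = {}
    for a in associations:
        by_disorder.setdefault(a.disorder_name, []).append(a)

    results = []
    for d in disorders:
        if category is not None and d.category != category:
            continue
        result = score_disorder(
            selected_set,
            by_disorder.get(d.name, ()),
            table,
            disorder_name=d.name,
            category=d.category,
        )
        if result.score > 0:
            results.append(result)
    results.sort(key=lambda r: (-r.score, r.disorder_name.casefold()))
    return results[:k]


def list_symptoms(
    disorders: Sequence[Disorder],
    associations: Iterable[SymptomAssociation],
    category_filter: str | None = "ALL",
) -> list[str]:
    """Unique, sorted symptom terms, optionally restricted to one category."""
    category = _check_category(category_filter, disorders)
    if category is None:
        names = {d.name for d in disorders}
    else:
        names = {d.name for d in disorders if d.category == category}
    return sorted({a.symptom for a in associations if a.disorder_name in names})
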