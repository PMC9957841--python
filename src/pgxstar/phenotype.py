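"""Activity-score phenotype translation (CPIC-style).

Each haplotype carries an activity value: 1 for normal function, 0.5 for
decreased, 0 for no function, with per-allele overrides (*10 -> 0.25) applied
before copy-number scaling, so an xN duplication contributes N times the
per-copy value. Tandem hybrid tokens (e.g. *68+*4) are no-function and score
0. Alleles of uncertain or unknown function have no activity value.

The diplotype activity score (AS) is the sum over both haplotypes, and maps
to a metabolizer category: poor (AS = 0), intermediate (0 < AS < 1.25),
normal (1.25 <= AS <= 2.25), ultrarapid (AS > 2.25). A diplotype containing
an allele without an activity value is Indeterminate. Scores are exact
rationals (quarters), so the category boundaries are compared exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Union

from .consensus import DiplotypeCall
from .star_catalog import AlleleToken, Catalog, DEFAULT_CLASS_ACTIVITY

__all__ = [
    "ActivityModel",
    "PhenotypeResult",
    "haplotype_activity",
    "diplotype_activity_score",
    "token_function_class",
    "cohort_phenotype_distribution",
]

IM_UPPER = Fraction(5, 4)  # AS below this (and above 0) is intermediate
NM_UPPER = Fraction(9, 4)  # AS above this is ultrarapid

CATEGORIES = ("PM", "IM", "NM", "UM", "Indeterminate")


@dataclass(frozen=True)
class ActivityModel:
    """Function-class -> per-copy activity mapping with per-allele overrides."""

    class_values: Mapping[str, Fraction] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ACTIVITY)
    )
    allele_overrides: Mapping[str, Fraction] = field(
        default_factory=lambda: {"*10": Fraction(1, 4)}
    )

    def per_copy_value(self, catalog: Catalog, base: str) -> Optional[Fraction]:
        if base in self.allele_overrides:
            return Fraction(self.allele_overrides[base])
        definition = catalog.definitions[base]
        if definition.activity_value is not None:
            return definition.activity_value
        value = self.class_values.get(definition.function)
        return Fraction(value) if value is not None else None


def haplotype_activity(
    model: ActivityModel, catalog: Catalog, token: Union[str, AlleleToken]
) -> Optional[Fraction]:
    """Activity of one haplotype token; None when function is uncertain/unknown.

    The override (or class value) is the per-copy activity, multiplied by the
    xN copy number. Tandem tokens score 0: the catalogued hybrid tandems are
    no-function arrangements.
    """
    token = catalog.resolve(token)
    if token.tandem_partner is not None:
        return Fraction(0)
    per_copy = model.per_copy_value(catalog, token.base)
    if per_copy is None:
        return None
    return per_copy * token.copy_number


def token_function_class(catalog: Catalog, token: Union[str, AlleleToken]) -> str:
    """Function class of a token with copy-number scaling applied.

    A duplication of a decreased-function allele restores normal activity
    (*17x2 -> normal), a duplicated normal allele is increased (*1x2), and a
    no-function allele stays no-function at any copy number. Uncertain and
    unknown classes are unaffected by copy number; tandems are no-function.
    """
    token = catalog.resolve(token)
    if token.tandem_partner is not None:
        return "no_function"
    base_class = catalog.definitions[token.base].function
    if token.copy_number == 1 or base_class in ("uncertain", "unknown"):
        return base_class
    model = ActivityModel()
    activity = haplotype_activity(model, catalog, token)
    if activity == 0:
        return "no_function"
    if activity < 1:
        return "decreased"
    if activity == 1:
        return "normal"
    return "increased"


@dataclass(frozen=True)
class PhenotypeResult:
    activity_score: Optional[Fraction]
    category: str

    @property
    def score_float(self) -> Optional[float]:
        return None if self.activity_score is None else float(self.activity_score)


def _classify(score: Fraction) -> str:
    if score == 0:
        return "PM"
    if score < IM_UPPER:
        return "IM"
    if score <= NM_UPPER:
        return "NM"
    return "UM"


def diplotype_activity_score(
    model: ActivityModel, catalog: Catalog, call: Union[str, DiplotypeCall]
) -> PhenotypeResult:
    """AS = sum of the two haplotype activities; Indeterminate if either is undefined."""
    if isinstance(call, str):
        from .consensus import normalize_diplotype

        call = normalize_diplotype(call)
    activities = [haplotype_activity(model, catalog, t) for t in call.tokens]
    if any(a is None for a in activities):
        return PhenotypeResult(activity_score=None, category="Indeterminate")
    score = sum(activities, Fraction(0))
    return PhenotypeResult(activity_score=score, category=_classify(score))


def cohort_phenotype_distribution(
    results: Iterable[PhenotypeResult],
) -> dict[str, dict[str, float]]:
    """Category counts and percentages; Indeterminate is reported separately
    from the four activity-score classes but over the same denominator."""
    results = list(results)
    counts = Counter(r.category for r in results)
    n = len(results)
    return {
        cat: {"count": counts.get(cat, 0), "pct": 100.0 * counts.get(cat, 0) / n if n else 0.0}
        for cat in CATEGORIES
    }
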