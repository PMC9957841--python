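"""Haplotype-to-star-allele matching and novel-allele nomination.

A phased per-chromosome variant set is matched against the catalog by
containment: every definition whose core is a subset of the observed set is
a candidate, and the *background* is the candidate with the largest core
(most specific allele; nested backbones such as *2 within *41 resolve to the
larger core). Variants left over after subtracting the background core are
split by consequence class: neutral leftovers make a (possibly novel)
suballele, while any core-eligible leftover nominates a novel star-allele
candidate attributed to the background.

Ties between equally large contained cores are broken toward the smallest
star number (then lexicographically) and flagged for review.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .star_catalog import Catalog, VariantKey, _star_number

__all__ = [
    "PhasedHaplotypeObservation",
    "MatchResult",
    "NovelAlleleGroup",
    "MatchSummary",
    "match_haplotype",
    "batch_match",
    "render_novel_table",
]


@dataclass(frozen=True)
class PhasedHaplotypeObservation:
    """One phased chromosome's variant set, awaiting catalog matching."""

    sample: str
    phase_index: int
    variants: frozenset[VariantKey]

    def __post_init__(self) -> None:
        if self.phase_index not in (0, 1):
            raise ValueError(f"phase_index must be 0 or 1, got {self.phase_index}")


@dataclass
class MatchResult:
    classification: str  # known | known_novel_suballele | novel_star_candidate | unresolved
    matched_allele: Optional[str]
    background: Optional[str]
    suballele: Optional[str] = None
    extra_core_variants: frozenset[VariantKey] = frozenset()
    extra_neutral_variants: frozenset[VariantKey] = frozenset()
    tied_backgrounds: tuple[str, ...] = ()
    sample: str = ""
    phase_index: int = 0


def match_haplotype(catalog: Catalog, obs: PhasedHaplotypeObservation) -> MatchResult:
    """Classify one phased variant set against the catalog.

    The empty-core reference allele guarantees at least one candidate, so a
    result is always produced. Structural alleles never participate (they are
    symbolic and handled upstream by SV-aware callers).
    """
    observed = frozenset(obs.variants)
    candidates = [
        d
        for name, d in catalog.definitions.items()
        if name not in catalog.structural_alleles and d.core_variants <= observed
    ]
    best_size = max(len(d.core_variants) for d in candidates)
    leaders = sorted(
        (d.name for d in candidates if len(d.core_variants) == best_size),
        key=_star_number,
    )
    background = leaders[0]
    extras = observed - catalog.definitions[background].core_variants
    extra_core = frozenset(v for v in extras if v.is_core_eligible)
    extra_neutral = frozenset(v for v in extras if not v.is_core_eligible)

    suballele = None
    if not extras:
        classification = "known"
    elif extra_core:
        classification = "novel_star_candidate"
    else:
        for sub, sub_set in catalog.definitions[background].suballeles.items():
            if extra_neutral == sub_set:
                suballele = sub
                break
        classification = "known" if suballele else "known_novel_suballele"

    return MatchResult(
        classification=classification,
        matched_allele=background if classification.startswith("known") else None,
        background=background,
        suballele=suballele,
        extra_core_variants=extra_core,
        extra_neutral_variants=extra_neutral,
        tied_backgrounds=tuple(leaders) if len(leaders) > 1 else (),
        sample=obs.sample,
        phase_index=obs.phase_index,
    )


@dataclass(frozen=True)
class NovelAlleleGroup:
    """Deduplicated novel star-allele candidate: background + extra core set."""

    background: str
    extra_core_variants: frozenset[VariantKey]
    carriers: int
    samples: tuple[str, ...]


@dataclass
class MatchSummary:
    counts: dict[str, int]
    novel_groups: list[NovelAlleleGroup] = field(default_factory=list)


def batch_match(
    catalog: Catalog, observations: Iterable[PhasedHaplotypeObservation]
) -> tuple[list[MatchResult], MatchSummary]:
    """Match a batch of haplotypes; group novel candidates by recipe.

    Novel candidates are deduplicated by (background, extra core variant set);
    the carrier count is the number of observed haplotypes in the group.
    """
    results = [match_haplotype(catalog, obs) for obs in observations]
    counts = Counter(r.classification for r in results)
    grouped: dict[tuple[str, frozenset[VariantKey]], list[MatchResult]] = {}
    for r in results:
        if r.classification == "novel_star_candidate":
            grouped.setdefault((r.background, r.extra_core_variants), []).append(r)
    groups = [
        NovelAlleleGroup(
            background=bg,
            extra_core_variants=extras,
            carriers=len(members),
            samples=tuple(sorted(m.sample for m in members)),
        )
        for (bg, extras), members in grouped.items()
    ]
    groups.sort(key=lambda g: (_star_number(g.background), sorted(v.label() for v in g.extra_core_variants)))
    return results, MatchSummary(counts=dict(counts), novel_groups=groups)


_CONSEQUENCE_DISPLAY = {
    "missense": "Missense",
    "frameshift": "Frameshift",
    "stop_gain": "Stop-gained",
    "splice": "Splice defect",
    "inframe_del": "In-frame deletion",
    "regulatory_high_impact": "Regulatory (high impact)",
}


def _variant_type(variants: Iterable[VariantKey]) -> str:
    ordered = sorted(variants)
    parts = [_CONSEQUENCE_DISPLAY.get(v.consequence, v.consequence) for v in ordered]
    proteins = [v.protein_change for v in ordered if v.protein_change]
    text = "/".join(dict.fromkeys(parts))
    if proteins:
        text += f" ({', '.join(proteins)})"
    return text


def render_novel_table(groups: Iterable[NovelAlleleGroup]) -> pd.DataFrame:
    """Novel-candidate report: background, extra core variants, type, count."""
    rows = [
        {
            "background_allele": g.background,
            "additional_core_variants": " + ".join(v.label() for v in sorted(g.extra_core_variants)),
            "variant_type": _variant_type(g.extra_core_variants),
            "count": g.carriers,
        }
        for g in groups
    ]
    return pd.DataFrame(
        rows, columns=["background_allele", "additional_core_variants", "variant_type", "count"]
    )
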