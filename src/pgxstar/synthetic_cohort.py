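"""Synthetic cohort generation with the statistical structure the analysis assumes.

Individuals receive two i.i.d. haplotype draws from an allele-frequency
specification (Hardy-Weinberg equilibrium is the generative null, matching
the deviation test applied downstream). Per-caller outputs then add
independent no-call and miscall errors, phased variant-set observations are
emitted for SNV-defined haplotypes (optionally with neutral suballele-style
noise from the catalog's pool), and novel-haplotype recipes
(background allele + extra core variants) can be injected into designated
carriers to exercise novel-allele nomination.

All randomness flows through one seeded numpy Generator, so identical
configurations reproduce cohorts bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .consensus import DiplotypeCall
from .matcher import PhasedHaplotypeObservation
from .star_catalog import AlleleToken, Catalog, VariantKey, expand_allele_to_variants

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "NovelRecipe",
    "simulate_cohort",
    "simulate_caller_outputs",
    "inject_novel_haplotypes",
]

#: Widest acceptable pre-renormalization deviation for printed (rounded) tables.
PRINTED_TABLE_SUM_TOLERANCE = 0.015


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for a synthetic cohort.

    ``frequency_spec`` maps allele tokens to fractions; they are renormalized
    to sum to one but must already be within ``sum_tolerance`` of it (printed
    frequency tables carry rounding error, so loaders for such fixtures pass
    a wider tolerance than the strict default).
    """

    frequency_spec: Mapping[str, float]
    n_individuals: int
    seed: int = 0
    miscall_rate: float = 0.05
    nocall_rate: float = 0.02
    n_callers: int = 5
    neutral_noise_rate: float = 0.0
    sum_tolerance: float = 0.005

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_callers < 1:
            raise ValueError("n_callers must be >= 1")
        for name in ("miscall_rate", "nocall_rate", "neutral_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not self.frequency_spec:
            raise ValueError("frequency_spec is empty")
        if any(f < 0 for f in self.frequency_spec.values()):
            raise ValueError("frequencies must be non-negative")
        total = float(sum(self.frequency_spec.values()))
        if abs(total - 1.0) > self.sum_tolerance:
            raise ValueError(
                f"frequencies sum to {total:.4f}, outside 1 +/- {self.sum_tolerance}"
            )


@dataclass
class SyntheticCohort:
    """Truth diplotypes, per-caller calls, and phased observations for one cohort."""

    truth_diplotypes: dict[str, DiplotypeCall]
    caller_calls: dict[tuple[str, str], Optional[DiplotypeCall]]
    phased_observations: list[PhasedHaplotypeObservation]
    novel_carriers: dict[str, int] = field(default_factory=dict)  # sample -> recipe index

    @property
    def samples(self) -> list[str]:
        return sorted(self.truth_diplotypes)

    @property
    def callers(self) -> list[str]:
        return sorted({caller for _, caller in self.caller_calls})


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:06d}" for i in range(1, n + 1)]


def _caller_ids(n: int) -> list[str]:
    return [f"caller{i}" for i in range(1, n + 1)]


def simulate_cohort(config: SimulationConfig, catalog: Catalog) -> SyntheticCohort:
    """Draw a cohort under HWE and emit caller calls and phased observations.

    Every allele token in the frequency spec must resolve in the catalog. Phased
    observations are produced only for SNV-defined haplotypes (structural
    tokens are caller territory) and contain the allele's expected variant
    set plus, with ``neutral_noise_rate``, one extra neutral-pool variant.
    """
    tokens = [catalog.resolve(t) for t in config.frequency_spec]
    weights = np.asarray([float(config.frequency_spec[t]) for t in config.frequency_spec])
    probs = weights / weights.sum()
    rng = np.random.default_rng(config.seed)
    draws = rng.choice(len(tokens), size=(config.n_individuals, 2), p=probs)

    truth: dict[str, DiplotypeCall] = {}
    observations: list[PhasedHaplotypeObservation] = []
    for sample, (i, j) in zip(_sample_ids(config.n_individuals), draws):
        truth[sample] = DiplotypeCall(tokens[int(i)], tokens[int(j)])
        # phases follow the normalized token order so observations line up
        # with the truth diplotype
        for phase, token in enumerate(truth[sample].tokens):
            if catalog.is_structural_token(token):
                continue
            variants = set(expand_allele_to_variants(catalog, token))
            if config.neutral_noise_rate and catalog.neutral_pool:
                if rng.random() < config.neutral_noise_rate:
                    extra = catalog.neutral_pool[int(rng.integers(len(catalog.neutral_pool)))]
                    variants.add(extra)
            observations.append(
                PhasedHaplotypeObservation(
                    sample=sample, phase_index=phase, variants=frozenset(variants)
                )
            )
    caller_calls = simulate_caller_outputs(truth, config, catalog, rng=rng)
    return SyntheticCohort(
        truth_diplotypes=truth,
        caller_calls=caller_calls,
        phased_observations=observations,
    )


def simulate_caller_outputs(
    truth: Mapping[str, DiplotypeCall],
    config: SimulationConfig,
    catalog: Catalog,
    rng: Optional[np.random.Generator] = None,
) -> dict[tuple[str, str], Optional[DiplotypeCall]]:
    """Independent per-(sample, caller) error model.

    With ``nocall_rate`` the caller abstains; otherwise with ``miscall_rate``
    one uniformly chosen allele of the diplotype is replaced by a uniformly
    chosen different catalog allele; otherwise the truth is reported. With
    both rates zero every emitted call equals the truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    universe = sorted(catalog.definitions)
    calls: dict[tuple[str, str], Optional[DiplotypeCall]] = {}
    for sample in sorted(truth):
        call = truth[sample]
        for caller in _caller_ids(config.n_callers):
            if rng.random() < config.nocall_rate:
                calls[(sample, caller)] = None
            elif rng.random() < config.miscall_rate:
                which = int(rng.integers(2))
                keep = call.tokens[1 - which]
                old = call.tokens[which]
                choices = [b for b in universe if b != old.base]
                wrong_base = choices[int(rng.integers(len(choices)))]
                calls[(sample, caller)] = DiplotypeCall(keep, AlleleToken(base=wrong_base))
            else:
                calls[(sample, caller)] = call
    return calls


@dataclass(frozen=True)
class NovelRecipe:
    """A novel-haplotype construction: background allele plus extra core variants."""

    background: str
    extra_variants: frozenset[VariantKey]
    carriers: int = 1


def inject_novel_haplotypes(
    cohort: SyntheticCohort,
    catalog: Catalog,
    recipes: Sequence[Union[NovelRecipe, tuple]],
    carriers: Optional[int] = None,
) -> SyntheticCohort:
    """Replace one haplotype of designated carriers with a novel construction.

    Each recipe's haplotype is ``expand(background) | extras``; carriers are
    taken deterministically as the first not-yet-novel samples in id order,
    with phase 0 replaced and the sample annotated as a novel carrier.
    ``carriers`` overrides each recipe's own count when given.
    """
    normalized: list[NovelRecipe] = []
    for recipe in recipes:
        if not isinstance(recipe, NovelRecipe):
            background, extras = recipe
            recipe = NovelRecipe(background=background, extra_variants=frozenset(extras))
        if carriers is not None:
            recipe = replace(recipe, carriers=carriers)
        if not recipe.extra_variants:
            raise ValueError(f"recipe on {recipe.background}: extra variant set is empty")
        token = catalog.resolve(recipe.background)
        if catalog.is_structural_token(token):
            raise ValueError(f"background {recipe.background} is structural, not SNV-defined")
        normalized.append(recipe)

    obs_by_key = {(o.sample, o.phase_index): o for o in cohort.phased_observations}
    novel_carriers = dict(cohort.novel_carriers)
    available = (s for s in cohort.samples if s not in novel_carriers)
    for index, recipe in enumerate(normalized):
        variants = frozenset(expand_allele_to_variants(catalog, recipe.background)) | recipe.extra_variants
        for _ in range(recipe.carriers):
            try:
                sample = next(available)
            except StopIteration:
                raise ValueError("not enough samples to host all novel carriers") from None
            obs_by_key[(sample, 0)] = PhasedHaplotypeObservation(
                sample=sample, phase_index=0, variants=variants
            )
            novel_carriers[sample] = index

    observations = sorted(obs_by_key.values(), key=lambda o: (o.sample, o.phase_index))
    return SyntheticCohort(
        truth_diplotypes=dict(cohort.truth_diplotypes),
        caller_calls=dict(cohort.caller_calls),
        phased_observations=observations,
        novel_carriers=novel_carriers,
    )
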