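"""Star-allele catalog: data model, token grammar, and variant expansion.

A *star allele* is a named haplotype of a pharmacogene (``*2``, ``*17``, ...)
defined by a set of *core* sequence variants; *suballeles* add functionally
neutral (synonymous/intronic) variants on top of a core. Structural alleles
(gene deletion ``*5``, hybrids ``*13``/``*36``, tandem arrangements such as
``*68+*4``, and ``xN`` duplications) are represented symbolically: they have
no variant expansion and are detected upstream by structural-variant-aware
callers.

Coordinates are 1-based positions on a RefSeqGene-style reference sequence
(the bundled CYP2D6 fixture uses NG_008376.4 numbering); the catalog schema
itself is gene-agnostic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "VariantKey",
    "AlleleToken",
    "HaplotypeDefinition",
    "Catalog",
    "CatalogValidationError",
    "TokenParseError",
    "parse_allele_token",
    "render_allele_token",
    "allele_sort_key",
    "expand_allele_to_variants",
    "load_catalog",
    "write_catalog",
]

#: All consequence classes a variant may carry (annotation input, not recomputed).
CONSEQUENCE_CLASSES = frozenset(
    {
        "missense",
        "frameshift",
        "stop_gain",
        "splice",
        "inframe_del",
        "regulatory_high_impact",
        "synonymous",
        "intronic",
        "other_neutral",
    }
)

#: Consequences eligible to define a (potentially function-altering) core variant.
CORE_ELIGIBLE_CONSEQUENCES = frozenset(
    {"missense", "frameshift", "stop_gain", "splice", "inframe_del", "regulatory_high_impact"}
)

#: Consequences allowed in suballele (neutral) variant sets.
NEUTRAL_CONSEQUENCES = frozenset({"synonymous", "intronic", "other_neutral"})

FUNCTION_CLASSES = frozenset(
    {"normal", "decreased", "no_function", "increased", "uncertain", "unknown"}
)

#: Default per-copy activity value by function class. Uncertain/unknown have none.
DEFAULT_CLASS_ACTIVITY: Mapping[str, Fraction] = {
    "normal": Fraction(1),
    "decreased": Fraction(1, 2),
    "no_function": Fraction(0),
    "increased": Fraction(1),
}


class CatalogValidationError(ValueError):
    """Raised with the full list of validation problems found in a catalog."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid catalog:\n" + "\n".join(f"  - {p}" for p in self.problems))


class TokenParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single small variant, uniquely identified by (position, ref, alt).

    ``rsid``, ``consequence`` and ``protein_change`` are annotations carried
    along for reporting; they do not take part in identity or hashing.
    """

    position: int
    ref: str
    alt: str
    rsid: Optional[str] = field(default=None, compare=False)
    consequence: str = field(default="other_neutral", compare=False)
    protein_change: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")
        if self.ref == self.alt:
            raise ValueError(f"variant at {self.position} has ref == alt ({self.ref!r})")
        for allele in (self.ref, self.alt):
            if not allele or not re.fullmatch(r"[ACGTN]+", allele):
                raise ValueError(
                    f"variant at {self.position}: alleles must be uppercase nucleotides, got {allele!r}"
                )
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")

    @property
    def is_core_eligible(self) -> bool:
        return self.consequence in CORE_ELIGIBLE_CONSEQUENCES

    @property
    def is_neutral(self) -> bool:
        return self.consequence in NEUTRAL_CONSEQUENCES

    def label(self) -> str:
        """Render as ``rsid~<pos><ref>><alt>`` (Table-style denotation)."""
        change = f"{self.position}{self.ref}>{self.alt}"
        return f"{self.rsid}~{change}" if self.rsid else change


# Bases are a star number with an optional uppercase letter suffix (*2,
# *10B). The suffix is lazy (and excludes lowercase) so the xN copy-number
# marker is never swallowed into the base.
_BASE_RE = r"\d+[A-Z]*?"
_TOKEN_RE = re.compile(rf"\*({_BASE_RE})(?:x(\d+))?(?:\+\*({_BASE_RE}))?")


@dataclass(frozen=True)
class AlleleToken:
    """A star-allele token: base name, xN copy number, optional tandem partner.

    ``*4x2`` -> base ``*4``, copy_number 2; ``*68+*4`` is ONE token with base
    ``*68`` and tandem partner ``*4``.
    """

    base: str
    copy_number: int = 1
    tandem_partner: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.base.startswith("*"):
            raise TokenParseError(f"allele base must start with '*', got {self.base!r}")
        if self.copy_number < 1:
            raise TokenParseError(f"copy number must be >= 1, got {self.copy_number}")
        if self.copy_number != 1 and self.tandem_partner is not None:
            raise TokenParseError(f"token cannot be both xN and tandem: {self.render()}")
        if self.base == "*5" and self.copy_number != 1:
            raise TokenParseError("the gene deletion *5 has a fixed copy number of 1")

    def render(self) -> str:
        text = self.base
        if self.copy_number != 1:
            text += f"x{self.copy_number}"
        if self.tandem_partner is not None:
            text += f"+{self.tandem_partner}"
        return text

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def is_structural(self, structural_bases: Iterable[str] = ("*5", "*13", "*36", "*68")) -> bool:
        """True for xN tokens, tandem tokens, and symbolic (deletion/hybrid) bases."""
        return (
            self.copy_number != 1
            or self.tandem_partner is not None
            or self.base in set(structural_bases)
        )


def parse_allele_token(text: str) -> AlleleToken:
    """Parse a star-allele token such as ``*2``, ``*4x2`` or ``*68+*4``.

    Whitespace (including spaces around ``+`` as printed in tables) is
    stripped. Parsing then rendering is the identity.
    """
    cleaned = re.sub(r"\s+", "", text)
    m = _TOKEN_RE.fullmatch(cleaned)
    if m is None:
        raise TokenParseError(f"malformed allele token: {text!r}")
    base, xn, partner = m.groups()
    return AlleleToken(
        base=f"*{base}",
        copy_number=int(xn) if xn else 1,
        tandem_partner=f"*{partner}" if partner else None,
    )


def render_allele_token(token: AlleleToken) -> str:
    return token.render()


def _star_number(base: str) -> tuple[int, str]:
    m = re.match(r"\*(\d+)", base)
    return (int(m.group(1)) if m else 10**9, base)


def allele_sort_key(token: AlleleToken) -> tuple:
    """Canonical ordering: numeric star number, base, copy number, partner."""
    return (*_star_number(token.base), token.copy_number, token.tandem_partner or "")


@dataclass(frozen=True)
class HaplotypeDefinition:
    """One star allele: core variant set, suballeles, function class, activity.

    ``activity_value`` is the per-copy activity (CPIC-style): 1 for normal,
    0.5 for decreased, 0 for no-function unless explicitly overridden (the
    bundled fixture overrides *10 to 0.25). It is undefined (None) exactly
    when the function class is uncertain or unknown.
    """

    name: str
    core_variants: frozenset[VariantKey]
    suballeles: Mapping[str, frozenset[VariantKey]] = field(default_factory=dict)
    function: str = "unknown"
    activity_value: Optional[Fraction] = None
    evidence: str = ""

    @property
    def is_reference(self) -> bool:
        return len(self.core_variants) == 0


class Catalog:
    """Validated collection of star-allele definitions for one gene.

    ``variant_index`` maps each VariantKey to the set of definition names
    whose core contains it (exactly the inverse of core membership).
    Structural alleles are symbolic: present as definitions (so their
    function class resolves) but with no variant expansion.
    """

    def __init__(
        self,
        definitions: Mapping[str, HaplotypeDefinition],
        structural_alleles: Iterable[str] = (),
        neutral_pool: Iterable[VariantKey] = (),
        gene: str = "",
        coordinate_system: str = "",
        note: str = "",
    ):
        self.definitions: dict[str, HaplotypeDefinition] = dict(definitions)
        self.structural_alleles: frozenset[str] = frozenset(structural_alleles)
        self.neutral_pool: tuple[VariantKey, ...] = tuple(neutral_pool)
        self.gene = gene
        self.coordinate_system = coordinate_system
        self.note = note
        self._validate()
        self.variant_index: dict[VariantKey, frozenset[str]] = {}
        index: dict[VariantKey, set[str]] = {}
        for name, definition in self.definitions.items():
            for v in definition.core_variants:
                index.setdefault(v, set()).add(name)
        self.variant_index = {v: frozenset(names) for v, names in index.items()}
        self._by_site = {(v.position, v.ref, v.alt): v for v in self.all_variants()}

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        problems: list[str] = []
        for name, definition in self.definitions.items():
            if name != definition.name:
                problems.append(f"definition keyed {name!r} is named {definition.name!r}")
            if definition.function not in FUNCTION_CLASSES:
                problems.append(f"{name}: unknown function class {definition.function!r}")
            elif definition.function in ("uncertain", "unknown"):
                if definition.activity_value is not None:
                    problems.append(
                        f"{name}: activity_value given for {definition.function}-function allele"
                    )
            elif name not in self.structural_alleles and definition.activity_value is None:
                problems.append(f"{name}: missing activity value for {definition.function} allele")
            for sub, extras in definition.suballeles.items():
                bad = [v.label() for v in extras if not v.is_neutral]
                if bad:
                    problems.append(
                        f"{name}.{sub}: suballele variants must be neutral, got {', '.join(bad)}"
                    )
            if name in self.structural_alleles and definition.core_variants:
                problems.append(f"{name}: structural alleles are symbolic (no core variants)")
        # distinct core sets among SNV-defined alleles
        seen: dict[frozenset[VariantKey], str] = {}
        for name, definition in sorted(self.definitions.items()):
            if name in self.structural_alleles:
                continue
            if definition.core_variants in seen:
                problems.append(
                    f"{name} and {seen[definition.core_variants]} share an identical core set"
                )
            else:
                seen[definition.core_variants] = name
        # rsid uniqueness across distinct variant keys
        rsid_seen: dict[str, VariantKey] = {}
        for v in self.all_variants():
            if v.rsid is None:
                continue
            other = rsid_seen.get(v.rsid)
            if other is not None and other != v:
                problems.append(f"rsid {v.rsid} attached to both {other.label()} and {v.label()}")
            rsid_seen[v.rsid] = v
        if problems:
            raise CatalogValidationError(problems)

    # -- queries ----------------------------------------------------------

    def all_variants(self) -> Iterable[VariantKey]:
        seen = set()
        for definition in self.definitions.values():
            for v in definition.core_variants:
                if v not in seen:
                    seen.add(v)
                    yield v
            for extras in definition.suballeles.values():
                for v in extras:
                    if v not in seen:
                        seen.add(v)
                        yield v
        for v in self.neutral_pool:
            if v not in seen:
                seen.add(v)
                yield v

    def lookup_site(self, position: int, ref: str, alt: str) -> Optional[VariantKey]:
        """Return the annotated catalog VariantKey at a site, if catalogued."""
        return self._by_site.get((position, ref, alt))

    def snv_defined_names(self) -> list[str]:
        return sorted(
            (n for n in self.definitions if n not in self.structural_alleles),
            key=lambda n: _star_number(n),
        )

    def is_structural_token(self, token: AlleleToken) -> bool:
        return token.is_structural(self.structural_alleles)

    def resolve(self, token: Union[str, AlleleToken]) -> AlleleToken:
        """Parse (if needed) and check that base and partner exist here."""
        if isinstance(token, str):
            token = parse_allele_token(token)
        if token.base not in self.definitions:
            raise KeyError(f"allele {token.base} is not in the catalog")
        if token.tandem_partner is not None and token.tandem_partner not in self.definitions:
            raise KeyError(f"tandem partner {token.tandem_partner} is not in the catalog")
        return token

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_dict(cls, payload: Mapping) -> "Catalog":
        problems: list[str] = []
        variants: dict[str, VariantKey] = {}
        for entry in payload.get("variants", []):
            vid = entry.get("id") or f"{entry['position']}{entry['ref']}>{entry['alt']}"
            try:
                variants[vid] = VariantKey(
                    position=int(entry["position"]),
                    ref=str(entry["ref"]),
                    alt=str(entry["alt"]),
                    rsid=entry.get("rsid"),
                    consequence=entry.get("consequence", "other_neutral"),
                    protein_change=entry.get("protein_change"),
                )
            except ValueError as exc:
                problems.append(f"variant {vid}: {exc}")

        def resolve_ids(ids: Iterable[str], context: str) -> frozenset[VariantKey]:
            out = []
            for vid in ids:
                if vid not in variants:
                    problems.append(f"{context}: unknown variant id {vid!r}")
                else:
                    out.append(variants[vid])
            return frozenset(out)

        definitions: dict[str, HaplotypeDefinition] = {}
        for entry in payload.get("alleles", []):
            name = entry["name"]
            if name in definitions:
                problems.append(f"duplicate allele name {name}")
                continue
            function = entry.get("function", "unknown")
            activity = entry.get("activity_value")
            if activity is not None:
                activity = Fraction(str(activity))
                if function in ("uncertain", "unknown"):
                    problems.append(f"{name}: activity_value given for {function}-function allele")
                    activity = None
            elif function in DEFAULT_CLASS_ACTIVITY:
                activity = DEFAULT_CLASS_ACTIVITY[function]
            definitions[name] = HaplotypeDefinition(
                name=name,
                core_variants=resolve_ids(entry.get("core", []), name),
                suballeles={
                    sub: resolve_ids(ids, f"{name}.{sub}")
                    for sub, ids in sorted(entry.get("suballeles", {}).items())
                },
                function=function,
                activity_value=activity,
                evidence=entry.get("evidence", ""),
            )
        if problems:
            raise CatalogValidationError(problems)
        return cls(
            definitions,
            structural_alleles=payload.get("structural_alleles", []),
            neutral_pool=[variants[vid] for vid in payload.get("neutral_pool", [])],
            gene=payload.get("gene", ""),
            coordinate_system=payload.get("coordinate_system", ""),
            note=payload.get("note", ""),
        )

    def to_dict(self) -> dict:
        variant_ids = {}
        variant_entries = []
        for v in sorted(self.all_variants()):
            vid = f"{v.position}{v.ref}>{v.alt}"
            variant_ids[v] = vid
            entry = {"id": vid, "position": v.position, "ref": v.ref, "alt": v.alt,
                     "consequence": v.consequence}
            if v.rsid:
                entry["rsid"] = v.rsid
            if v.protein_change:
                entry["protein_change"] = v.protein_change
            variant_entries.append(entry)
        allele_entries = []
        for name in sorted(self.definitions, key=_star_number):
            d = self.definitions[name]
            entry: dict = {
                "name": name,
                "function": d.function,
                "core": sorted(variant_ids[v] for v in d.core_variants),
            }
            if d.suballeles:
                entry["suballeles"] = {
                    sub: sorted(variant_ids[v] for v in extras)
                    for sub, extras in sorted(d.suballeles.items())
                }
            if (
                d.activity_value is not None
                and d.activity_value != DEFAULT_CLASS_ACTIVITY.get(d.function)
            ):
                entry["activity_value"] = str(d.activity_value)
            if d.evidence:
                entry["evidence"] = d.evidence
            allele_entries.append(entry)
        payload: dict = {
            "gene": self.gene,
            "coordinate_system": self.coordinate_system,
            "variants": variant_entries,
            "alleles": allele_entries,
            "structural_alleles": sorted(self.structural_alleles, key=_star_number),
            "neutral_pool": sorted(variant_ids[v] for v in self.neutral_pool),
        }
        if self.note:
            payload["note"] = self.note
        return payload


def load_catalog(path: Union[str, Path]) -> Catalog:
    """Load and validate a star-allele catalog from its JSON dialect.

    Validation failures are collected and reported together in a single
    :class:`CatalogValidationError`.
    """
    with open(path) as fh:
        payload = json.load(fh)
    return Catalog.from_dict(payload)


def write_catalog(catalog: Catalog, path: Union[str, Path]) -> None:
    """Write a catalog back to JSON with canonical key ordering."""
    with open(path, "w") as fh:
        json.dump(catalog.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def expand_allele_to_variants(
    catalog: Catalog,
    token: Union[str, AlleleToken],
    suballele: Optional[str] = None,
) -> frozenset[VariantKey]:
    """Expected variant set of an SNV-defined allele: core plus suballele extras.

    Structural alleles (deletion/hybrid bases, xN and tandem tokens) are
    symbolic and raise a ``not expandable`` error.
    """
    token = catalog.resolve(token)
    if catalog.is_structural_token(token):
        raise ValueError(f"allele {token.render()} is structural and not expandable")
    definition = catalog.definitions[token.base]
    variants = definition.core_variants
    if suballele is not None:
        if suballele not in definition.suballeles:
            raise KeyError(f"{token.base} has no suballele named {suballele!r}")
        variants = variants | definition.suballeles[suballele]
    return frozenset(variants)
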