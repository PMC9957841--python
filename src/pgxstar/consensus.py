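"""Consensus diplotyping across multiple star-allele callers.

Star-allele callers frequently disagree on complex loci, so a diplotype is
accepted only when at least two callers agree on it after normalization
(``*17/*1`` and ``*1/*17`` are the same call). Ties at maximal support and
samples with no two concordant callers are flagged ``unresolved`` for manual
review rather than broken by any caller hierarchy; adjudicated outcomes can
be applied afterwards as overrides with ``manual`` provenance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .star_catalog import AlleleToken, TokenParseError, allele_sort_key, parse_allele_token

__all__ = [
    "DiplotypeCall",
    "ConsensusResult",
    "DiscordanceReport",
    "normalize_diplotype",
    "consensus_call",
    "apply_overrides",
    "summarize_discordance",
    "NO_CALL",
]

#: Literal used for a caller that returned no call in TSV inputs.
NO_CALL = "NA"

#: Minimum number of agreeing callers for a consensus (absolute rule).
MIN_SUPPORT = 2


@dataclass(frozen=True)
class DiplotypeCall:
    """A normalized, unordered pair of allele tokens for one sample."""

    allele_a: AlleleToken
    allele_b: AlleleToken

    def __post_init__(self) -> None:
        a, b = sorted((self.allele_a, self.allele_b), key=allele_sort_key)
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def normalized(self) -> str:
        return f"{self.allele_a.render()}/{self.allele_b.render()}"

    @property
    def tokens(self) -> tuple[AlleleToken, AlleleToken]:
        return (self.allele_a, self.allele_b)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.normalized


def normalize_diplotype(text: Union[str, DiplotypeCall]) -> DiplotypeCall:
    """Parse ``"tokenA/tokenB"`` into a canonical :class:`DiplotypeCall`.

    Idempotent: normalizing an already-normalized string yields the same call.
    """
    if isinstance(text, DiplotypeCall):
        return text
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise TokenParseError(
            f"a diplotype must have exactly two alleles separated by '/': {text!r}"
        )
    return DiplotypeCall(parse_allele_token(parts[0]), parse_allele_token(parts[1]))


@dataclass
class ConsensusResult:
    sample: str
    consensus: Optional[DiplotypeCall]
    support: int
    n_informative: int
    status: str  # "consensus" or "unresolved"
    per_caller: Mapping[str, Optional[DiplotypeCall]] = field(default_factory=dict)
    provenance: str = "consensus"


def consensus_call(
    per_caller: Mapping[str, Union[str, DiplotypeCall, None]],
    sample: str = "",
) -> ConsensusResult:
    """Derive the consensus diplotype from one sample's caller calls.

    The consensus is the unique diplotype with maximal support >= 2 among the
    informative (non-no-call) callers. A tie at the maximum, or maximal
    support below 2, leaves the sample unresolved. No-calls (``None`` or the
    literal ``"NA"``) count toward neither support nor ``n_informative``.
    The result is invariant under relabeling of callers.
    """
    if not per_caller:
        raise ValueError("consensus requires at least one caller entry")
    calls: dict[str, Optional[DiplotypeCall]] = {}
    for caller, raw in per_caller.items():
        if raw is None or (isinstance(raw, str) and raw.strip().upper() == NO_CALL):
            calls[caller] = None
        else:
            calls[caller] = normalize_diplotype(raw)
    informative = [c for c in calls.values() if c is not None]
    counts = Counter(c.normalized for c in informative)
    if counts:
        top_support = max(counts.values())
        leaders = [d for d, n in counts.items() if n == top_support]
    else:
        top_support, leaders = 0, []
    if top_support >= MIN_SUPPORT and len(leaders) == 1:
        consensus = normalize_diplotype(leaders[0])
        status = "consensus"
    else:
        consensus, status = None, "unresolved"
    return ConsensusResult(
        sample=sample,
        consensus=consensus,
        support=top_support,
        n_informative=len(informative),
        status=status,
        per_caller=calls,
    )


def apply_overrides(
    results: list[ConsensusResult],
    overrides: Mapping[str, Union[str, DiplotypeCall]],
) -> list[ConsensusResult]:
    """Replace results for overridden samples with manual adjudications.

    Mirrors visual read-depth/alignment review: the override wins regardless
    of the automated status, and is marked with ``manual`` provenance.
    """
    out = []
    for res in results:
        if res.sample in overrides:
            call = normalize_diplotype(overrides[res.sample])
            out.append(
                ConsensusResult(
                    sample=res.sample,
                    consensus=call,
                    support=res.support,
                    n_informative=res.n_informative,
                    status="consensus",
                    per_caller=res.per_caller,
                    provenance="manual",
                )
            )
        else:
            out.append(res)
    return out


@dataclass
class DiscordanceReport:
    n_total: int
    n_consensus: int
    n_unresolved: int
    support_histogram: dict[int, int]
    unresolved_samples: list[str]


def summarize_discordance(results: list[ConsensusResult]) -> DiscordanceReport:
    """Counts by status, support histogram, and the unresolved sample list."""
    hist: Counter[int] = Counter(r.support for r in results)
    unresolved = sorted(r.sample for r in results if r.status == "unresolved")
    return DiscordanceReport(
        n_total=len(results),
        n_consensus=sum(r.status == "consensus" for r in results),
        n_unresolved=len(unresolved),
        support_histogram=dict(sorted(hist.items())),
        unresolved_samples=unresolved,
    )
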