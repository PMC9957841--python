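"""Population statistics for star-allele cohorts.

Covers observed allele-frequency estimation from diplotypes, distinct-allele
counting with structural-variant grouping, function-class rollups, carrier
proportions for structural alleles, an exact Hardy-Weinberg test, and
two-sided Fisher exact comparisons between populations.

Conventions: allele frequencies are chromosome-based (each resolved sample
contributes two allele tokens; a tandem token such as ``*68+*4`` is one
chromosome, as is an ``xN`` token), while carrier/diplotype/phenotype
proportions are individual-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from scipy import stats

from .consensus import DiplotypeCall
from .phenotype import token_function_class
from .star_catalog import AlleleToken, Catalog, parse_allele_token, _star_number

__all__ = [
    "FrequencyTable",
    "TestResult",
    "estimate_allele_frequencies",
    "count_distinct_alleles",
    "function_class_summary",
    "sv_carrier_proportion",
    "hwe_exact_test",
    "hwe_test_for_allele",
    "fisher_compare",
    "round_pct",
]

#: Symbolic structural bases used when no catalog is supplied.
DEFAULT_STRUCTURAL_BASES = frozenset({"*5", "*13", "*36", "*68"})

#: Printed-table rounding tolerance for column sums, in percentage points.
FIXTURE_SUM_TOLERANCE = 0.8


def round_pct(value: float, digits: int = 1) -> float:
    """Round half away from zero, matching printed frequency tables."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FrequencyTable:
    """Population x allele-token percentage table with sample sizes.

    ``provenance`` distinguishes tables observed from diplotypes (frequencies
    sum to exactly 100 per population before display rounding) from fixture
    transcriptions of printed tables (sums are checked within a rounding
    tolerance only).
    """

    populations: list[tuple[str, int]]
    freqs: dict[tuple[str, str], float]
    provenance: str = "observed"
    functions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, n in self.populations:
            if n <= 0:
                raise ValueError(f"population {name} has non-positive size {n}")

    def population_names(self) -> list[str]:
        return [name for name, _ in self.populations]

    def n_individuals(self, population: str) -> int:
        for name, n in self.populations:
            if name == population:
                return n
        raise KeyError(f"unknown population {population!r}")

    def alleles(self, population: str, nonzero: bool = True) -> list[str]:
        self.n_individuals(population)
        out = [
            allele
            for (pop, allele), f in self.freqs.items()
            if pop == population and (f > 0 or not nonzero)
        ]
        return sorted(out, key=lambda a: (_star_number(a), a))

    def frequency(self, population: str, allele: str) -> float:
        return self.freqs.get((population, allele), 0.0)

    def column(self, population: str) -> dict[str, float]:
        return {allele: self.frequency(population, allele) for allele in self.alleles(population)}

    def column_total(self, population: str) -> float:
        return sum(self.column(population).values())

    @classmethod
    def from_csv(cls, path, provenance: str = "fixture",
                 sum_tolerance: Optional[float] = FIXTURE_SUM_TOLERANCE) -> "FrequencyTable":
        """Read a long-format ``population,n_individuals,allele[,function],freq_pct`` CSV.

        ``sum_tolerance=None`` skips the column-sum check (for deliberately
        partial columns, e.g. comparison populations transcribed only for
        the alleles present in the primary cohort).
        """
        df = pd.read_csv(path)
        populations = []
        freqs: dict[tuple[str, str], float] = {}
        functions: dict[str, str] = {}
        for pop, group in df.groupby("population", sort=False):
            n = int(group["n_individuals"].iloc[0])
            populations.append((str(pop), n))
            for _, row in group.iterrows():
                freqs[(str(pop), str(row["allele"]))] = float(row["freq_pct"])
                if "function" in row and isinstance(row["function"], str):
                    functions[str(row["allele"])] = row["function"]
        table = cls(populations=populations, freqs=freqs, provenance=provenance,
                    functions=functions)
        if sum_tolerance is not None:
            for pop, _ in populations:
                total = table.column_total(pop)
                if abs(total - 100.0) > sum_tolerance:
                    raise ValueError(
                        f"population {pop}: frequencies sum to {total:.1f}%, outside "
                        f"100 +/- {sum_tolerance}"
                    )
        return table

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": pop, "n_individuals": self.n_individuals(pop),
             "allele": allele, "freq_pct": f}
            for (pop, allele), f in sorted(
                self.freqs.items(), key=lambda kv: (kv[0][0], _star_number(kv[0][1]), kv[0][1])
            )
        ]
        return pd.DataFrame(rows, columns=["population", "n_individuals", "allele", "freq_pct"])


def estimate_allele_frequencies(
    diplotypes: Mapping[str, DiplotypeCall],
    population_labels: Optional[Mapping[str, str]] = None,
    default_population: str = "ALL",
) -> FrequencyTable:
    """Chromosome-count allele frequencies from resolved diplotypes.

    Each sample contributes its two allele tokens; unresolved samples should
    be excluded (and counted) by the caller before this step.
    """
    if not diplotypes:
        raise ValueError("no resolved diplotypes to estimate frequencies from")
    by_pop: dict[str, list[str]] = {}
    for sample, call in diplotypes.items():
        pop = population_labels.get(sample, default_population) if population_labels else default_population
        by_pop.setdefault(pop, []).extend(t.render() for t in call.tokens)
    populations = []
    freqs: dict[tuple[str, str], float] = {}
    for pop in sorted(by_pop):
        tokens = by_pop[pop]
        populations.append((pop, len(tokens) // 2))
        n_chrom = len(tokens)
        for allele in set(tokens):
            freqs[(pop, allele)] = 100.0 * tokens.count(allele) / n_chrom
    return FrequencyTable(populations=populations, freqs=freqs, provenance="observed")


def _token_group(token: AlleleToken, structural_bases: frozenset[str]) -> tuple[str, bool]:
    """Group label and structural flag for distinct-allele counting.

    xN tokens of the same base collapse into one ``*<base>xN`` group; tandem
    tokens and symbolic bases are their own structural groups; every other
    token is an SNV-defined allele counted individually.
    """
    if token.tandem_partner is not None:
        return token.render(), True
    if token.copy_number != 1:
        return f"{token.base}xN", True
    if token.base in structural_bases:
        return token.base, True
    return token.base, False


def count_distinct_alleles(
    table: FrequencyTable,
    population: str,
    catalog: Optional[Catalog] = None,
) -> tuple[int, int]:
    """(total distinct allele groups, structural groups) at nonzero frequency.

    Invariant to row order and zero-frequency rows. The total counts each
    SNV-defined allele individually plus one group per structural form.
    """
    structural_bases = catalog.structural_alleles if catalog else DEFAULT_STRUCTURAL_BASES
    snv: set[str] = set()
    structural: set[str] = set()
    for allele in table.alleles(population, nonzero=True):
        group, is_structural = _token_group(parse_allele_token(allele), frozenset(structural_bases))
        (structural if is_structural else snv).add(group)
    return len(snv) + len(structural), len(structural)


def function_class_summary(
    table: FrequencyTable,
    catalog: Catalog,
    population: str,
) -> dict[str, dict]:
    """Percentage of haplotypes per function class, with each class's top allele.

    Token classes apply copy-number scaling (a duplicated decreased-function
    allele is grouped as normal), mirroring how frequency tables group
    CN-restored alleles.
    """
    totals: dict[str, float] = {}
    top: dict[str, tuple[str, float]] = {}
    for allele in table.alleles(population, nonzero=True):
        freq = table.frequency(population, allele)
        token = parse_allele_token(allele)
        if token.base not in catalog.definitions:
            raise KeyError(f"allele {allele} has no function class in the catalog")
        cls = token_function_class(catalog, token)
        totals[cls] = totals.get(cls, 0.0) + freq
        if cls not in top or freq > top[cls][1]:
            top[cls] = (allele, freq)
    return {
        cls: {
            "total_pct": totals[cls],
            "top_allele": top[cls][0],
            "top_share_pct": 100.0 * top[cls][1] / totals[cls] if totals[cls] else 0.0,
        }
        for cls in sorted(totals)
    }


def sv_carrier_proportion(
    diplotypes: Optional[Mapping[str, DiplotypeCall]] = None,
    table: Optional[FrequencyTable] = None,
    population: Optional[str] = None,
    catalog: Optional[Catalog] = None,
) -> float:
    """Percentage of individuals carrying at least one structural allele.

    Observed mode (``diplotypes``) counts individuals directly. HWE mode
    (``table`` + ``population``) sums the structural allele frequency p and
    returns ``100 * (1 - (1 - p)^2)``, the random-mating carrier probability.
    """
    structural_bases = frozenset(catalog.structural_alleles if catalog else DEFAULT_STRUCTURAL_BASES)
    if diplotypes is not None:
        if not diplotypes:
            return 0.0
        carriers = sum(
            any(t.is_structural(structural_bases) for t in call.tokens)
            for call in diplotypes.values()
        )
        return 100.0 * carriers / len(diplotypes)
    if table is None or population is None:
        raise ValueError("provide either diplotypes or (table, population)")
    p_sv = sum(
        table.frequency(population, allele) / 100.0
        for allele in table.alleles(population, nonzero=True)
        if parse_allele_token(allele).is_structural(structural_bases)
    )
    return 100.0 * (1.0 - (1.0 - p_sv) ** 2)


@dataclass
class TestResult:
    p_value: float
    counts: tuple
    method: str  # "fisher_2x2" or "hwe_exact"
    note: str = ""


def _hwe_weights(n_focal: int, n_individuals: int) -> dict[int, int]:
    """Integer enumeration weights of the conditional heterozygote-count
    distribution given allele counts (Levene-Haldane): w(h) is proportional
    to the probability of h heterozygotes."""
    weights = {}
    for h in range(n_focal % 2, min(n_focal, 2 * n_individuals - n_focal) + 1, 2):
        n_aa = (n_focal - h) // 2
        n_bb = n_individuals - n_aa - h
        weights[h] = (
            2**h
            * math.factorial(n_individuals)
            // (math.factorial(n_aa) * math.factorial(h) * math.factorial(n_bb))
        )
    return weights


def hwe_exact_test(n_hom_focal: int, n_het: int, n_hom_other: int) -> TestResult:
    """Exact conditional Hardy-Weinberg test for one allele vs. all others.

    Given the genotype counts of a biallelic collapse (focal allele against
    the pooled remainder), the heterozygote count is compared with its exact
    conditional distribution given the allele counts; the p-value sums the
    probabilities of all heterozygote counts no more probable than observed.
    Computed in exact integer arithmetic.
    """
    counts = (n_hom_focal, n_het, n_hom_other)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("no individuals")
    n_focal = 2 * n_hom_focal + n_het
    if n_focal == 0 or n_focal == 2 * n:
        return TestResult(p_value=1.0, counts=counts, method="hwe_exact", note="monomorphic")
    weights = _hwe_weights(n_focal, n)
    observed = weights[n_het]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= observed)
    return TestResult(p_value=tail / total, counts=counts, method="hwe_exact")


def hwe_test_for_allele(
    diplotypes: Mapping[str, DiplotypeCall], allele: Union[str, AlleleToken]
) -> TestResult:
    """Biallelic collapse of a multi-allelic locus: focal token vs. pooled others."""
    if isinstance(allele, str):
        allele = parse_allele_token(allele)
    target = allele.render()
    hom = het = other = 0
    for call in diplotypes.values():
        k = sum(t.render() == target for t in call.tokens)
        if k == 2:
            hom += 1
        elif k == 1:
            het += 1
        else:
            other += 1
    return hwe_exact_test(hom, het, other)


def fisher_compare(count_a: int, total_a: int, count_b: int, total_b: int) -> TestResult:
    """Two-sided Fisher exact test comparing two proportions (2x2 table).

    ``total_*`` are chromosome counts for allele-frequency comparisons or
    individual counts for carrier/diplotype/phenotype proportions. Two-sided
    by summing all tables (at fixed margins) with probability no larger than
    the observed table's.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must lie within their totals")
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    p = stats.fisher_exact(table, alternative="two-sided").pvalue
    return TestResult(p_value=float(min(p, 1.0)), counts=tuple(map(tuple, table)), method="fisher_2x2")


def benjamini_hochberg(p_values: Iterable[float]) -> list[float]:
    """BH-adjusted q-values, preserving input order (optional reporting column)."""
    p = list(p_values)
    order = sorted(range(len(p)), key=lambda i: p[i])
    q = [0.0] * len(p)
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = len(p) - rank_from_end
        prev = min(prev, p[idx] * len(p) / rank)
        q[idx] = prev
    return q
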