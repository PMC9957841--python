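"""Bundled fixtures: the synthetic catalog, printed frequency tables, and
novel-allele recipes.

The frequency tables are transcriptions of published population columns
(percentages rounded to 0.1, so columns sum to 100 only within rounding);
``simulation_spec`` converts one column into a frequency specification a
:class:`~pgxstar.synthetic_cohort.SimulationConfig` accepts.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

from .popstats import FrequencyTable
from .star_catalog import Catalog, VariantKey, load_catalog
from .synthetic_cohort import NovelRecipe, PRINTED_TABLE_SUM_TOLERANCE, SimulationConfig

__all__ = [
    "load_default_catalog",
    "load_global_frequency_table",
    "load_ssa_population_table",
    "load_novel_recipes",
    "simulation_spec",
]


def _data_path(name: str):
    return resources.files("pgxstar").joinpath("data", name)


def load_default_catalog() -> Catalog:
    """The bundled synthetic CYP2D6 model catalog (PharmVar-style dialect)."""
    with resources.as_file(_data_path("cyp2d6_catalog.json")) as path:
        return load_catalog(path)


def load_global_frequency_table() -> FrequencyTable:
    """SSA-wide column plus prior-study averages and global biogeographic groups.

    Populations: SSA (n=947), PREV_SSA (prior-study averages), AAC, EUR,
    AMR, SAS, EAS. Only the SSA column is a complete frequency spectrum;
    the comparison columns list just the alleles seen in the primary cohort.
    """
    with resources.as_file(_data_path("ssa_global_frequencies.csv")) as path:
        return _load_rounded_table(path)


def load_ssa_population_table() -> FrequencyTable:
    """Per-population SSA columns (All, FNB, BRN, BFA, GHA, CAM, BSZ, BOT,
    SA, ESN, YRI, GWD, MSL, LWK)."""
    with resources.as_file(_data_path("ssa_population_frequencies.csv")) as path:
        return _load_rounded_table(path)


def _load_rounded_table(path) -> FrequencyTable:
    # Columns are transcribed as printed: rounding and partial listings mean
    # they do not total 100 exactly (some per-population columns stray by
    # several points). Sum validation therefore happens where a column is
    # used as a simulation source (SimulationConfig), not at load time.
    return FrequencyTable.from_csv(path, provenance="fixture", sum_tolerance=None)


def simulation_spec(
    table: FrequencyTable,
    population: str,
    n_individuals: Optional[int] = None,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Build a SimulationConfig from one population column of a printed table.

    Frequencies are taken as printed (percent / 100) and renormalized at
    sampling time; the config tolerance is widened to the printed-table
    rounding window.
    """
    spec = {
        allele: table.frequency(population, allele) / 100.0
        for allele in table.alleles(population, nonzero=True)
    }
    return SimulationConfig(
        frequency_spec=spec,
        n_individuals=n_individuals or table.n_individuals(population),
        seed=seed,
        sum_tolerance=PRINTED_TABLE_SUM_TOLERANCE,
        **overrides,
    )


def load_novel_recipes(catalog: Optional[Catalog] = None) -> list[NovelRecipe]:
    """Novel star-allele recipes (background + extra core variants + carriers).

    Variants are annotated VariantKeys; the catalog (default: bundled) is
    used only to re-use catalogued annotations where a recipe variant is
    itself a catalogued site (e.g. a backbone SNP recombined onto another
    background).
    """
    catalog = catalog or load_default_catalog()
    with resources.as_file(_data_path("novel_allele_recipes.csv")) as path:
        df = pd.read_csv(path)
    recipes = []
    for hap, group in df.groupby("haplotype", sort=True):
        backgrounds = set(group["background"])
        assert len(backgrounds) == 1, f"recipe {hap} mixes backgrounds"
        variants = set()
        for _, row in group.iterrows():
            catalogued = catalog.lookup_site(int(row["position"]), str(row["ref"]), str(row["alt"]))
            if catalogued is not None:
                variants.add(catalogued)
            else:
                protein = row.get("protein_change")
                variants.add(
                    VariantKey(
                        position=int(row["position"]),
                        ref=str(row["ref"]),
                        alt=str(row["alt"]),
                        rsid=str(row["rsid"]) if pd.notna(row["rsid"]) else None,
                        consequence=str(row["consequence"]),
                        protein_change=str(protein) if pd.notna(protein) else None,
                    )
                )
        recipes.append(
            NovelRecipe(
                background=backgrounds.pop(),
                extra_variants=frozenset(variants),
                carriers=int(group["count"].iloc[0]),
            )
        )
    return recipes
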