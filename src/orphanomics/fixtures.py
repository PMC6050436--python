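"""Accessors for the packaged reference fixtures.

Ships: the GC-MS metabolite table with KEGG ids and chemical families, the
mini KEGG-style pathway definitions behind the coverage table, a constructed
demo detection set (protein/transcript EC layers), a fictional five-species
enzyme-set table for the Venn comparison, and a demo pipeline configuration.
Fixture files live under ``orphanomics/data`` and are plain TSV/YAML, meant
to be readable and editable.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .interspecies import SpeciesEnzymeSet, read_species_ec_sets
from .metabolites import CompoundMap, MetaboliteRecord, read_metabolite_table
from .pathways import PathwayDefinition, load_pathway_definitions

__all__ = [
    "fixture_path",
    "table1_metabolites",
    "table1_compound_map",
    "table2_pathways",
    "demo_detected_ecs",
    "demo_species_sets",
]

_DATA = files("orphanomics").joinpath("data")


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    path = Path(str(_DATA.joinpath(name)))
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path


def table1_metabolites() -> list[MetaboliteRecord]:
    """The 61 identified metabolites as records (name + KEGG id + family)."""
    return read_metabolite_table(fixture_path("table1_metabolites.tsv"))


def table1_compound_map() -> CompoundMap:
    """Compound map (names, synonyms, families) built from the same table."""
    return CompoundMap.load(fixture_path("table1_metabolites.tsv"))


def table2_pathways() -> list[PathwayDefinition]:
    """Mini KEGG-style pathway definitions for the coverage-table pathways."""
    return load_pathway_definitions(fixture_path("table2_pathways.tsv"))


def demo_detected_ecs() -> tuple[frozenset[str], frozenset[str]]:
    """Constructed demo detection sets -> (protein ECs, transcript ECs)."""
    df = pd.read_csv(
        fixture_path("demo_detected_ecs.tsv"), sep="\t", dtype=str, comment="#"
    )
    protein = frozenset(df.loc[df["layer"] == "protein", "ec"])
    transcript = frozenset(df.loc[df["layer"] == "transcript", "ec"])
    return protein, transcript


def demo_species_sets() -> list[SpeciesEnzymeSet]:
    """Fictional five-species enzyme sets for Venn demonstrations."""
    return read_species_ec_sets(fixture_path("species_ecs_demo.tsv"))
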