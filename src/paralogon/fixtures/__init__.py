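"""Packaged fixtures: the published SSTR locus chart, the two
neighboring-family screens, the canonical vertebrate species tree with its
dating windows, and the explicit SSTR evolutionary scheme."""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd
import yaml

from ..genome_model import Genome
from ..io_tables import genomes_from_tables
from ..species_tree import SpeciesTree
from ..tree_timing import DuplicationWindow
from .sstr_scenario import (  # noqa: F401 (re-exported)
    scenario_ancestor,
    scenario_history,
    scenario_species_tree,
)


def _read_text(name: str) -> str:
    return (
        resources.files("paralogon.fixtures").joinpath("data", name).read_text()
    )


def sstr_genomes() -> dict[str, Genome]:
    """Genomes for the surveyed species, carrying only SSTR-family loci."""
    return genomes_from_tables(
        _read_text("sstr_loci.tsv"), _read_text("sstr_chrom_lengths.tsv")
    )


def neighbor_families(paralogon_name: str) -> pd.DataFrame:
    """The screened neighboring-family list for one paralogon:
    ``"SSTR146"`` (SSTR1/-4/-6 blocks) or ``"SSTR235"`` (SSTR2/-3/-5)."""
    files = {
        "SSTR146": "families_sstr146.tsv",
        "SSTR235": "families_sstr235.tsv",
    }
    try:
        name = files[paralogon_name]
    except KeyError:
        raise KeyError(
            f"unknown paralogon {paralogon_name!r}; expected one of "
            f"{sorted(files)}"
        ) from None
    return pd.read_csv(
        StringIO(_read_text(name)),
        sep="\t",
        comment="#",
        keep_default_na=False,
    )


def combined_neighbor_families() -> pd.DataFrame:
    """Both screens combined (the full syntenic-family set)."""
    return pd.concat(
        [neighbor_families("SSTR146"), neighbor_families("SSTR235")],
        ignore_index=True,
    )


def vertebrate_tree_config() -> dict:
    return yaml.safe_load(_read_text("vertebrate_tree.yaml"))


def vertebrate_species_tree() -> SpeciesTree:
    return SpeciesTree.from_config(vertebrate_tree_config())


def dating_windows(config: dict | None = None) -> list[DuplicationWindow]:
    """The 2R and 3R relative-dating windows of the canonical tree."""
    config = config or vertebrate_tree_config()
    return [
        DuplicationWindow(
            label=w["label"],
            older_bound=w["older_bound"],
            younger_bound=w["younger_bound"],
        )
        for w in config.get("windows", [])
    ]
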