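"""End-to-end orchestration: simulate (or load) genomes and gene trees,
run the conserved-synteny screen, date duplications, assemble paralogons,
infer rearrangements and reconstruct the event scenario, writing all
module outputs plus a summary JSON."""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import yaml

from . import fixtures
from .errors import ConfigurationError, ParalogonError
from .evo_sim import PlantedEvent, SimParams, simulate_history
from .io_tables import genomes_to_tables, read_gene_table
from .paralogons import (
    assemble_paralogons,
    infer_fusion_timing,
    reconstruct_scenario,
)
from .species_tree import SpeciesTree
from .synteny import tabulate_family_locations
from .tree_timing import GeneFamilyTree, classify_family_verdict

log = logging.getLogger("paralogon")


@dataclass
class PipelineConfig:
    """Pipeline configuration; see the YAML schema in docs/methods.md."""

    mode: str = "simulate"  # "simulate" | "tables"
    out_dir: str = "paralogon_out"
    seed: int = 0
    radius_mb: float = 15.0
    anchor_mode: str = "dual_anchor"
    support_threshold: float = 50.0
    min_support: int = 2
    log_level: str = "INFO"
    species_tree: dict | None = None
    sim: dict = field(default_factory=dict)
    gene_tables: list[str] = field(default_factory=list)
    lengths_table: str | None = None
    tree_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.radius_mb <= 0:
            raise ConfigurationError("radius must be > 0")
        if self.mode not in {"simulate", "tables"}:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.min_support < 1:
            raise ConfigurationError("min_support must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _check_paths(paths: list[str]) -> None:
    missing = [p for p in paths if not pathlib.Path(p).exists()]
    if missing:
        raise ParalogonError(
            "missing input file(s): " + ", ".join(sorted(missing))
        )


def _sim_params(config: PipelineConfig) -> SimParams:
    sim = dict(config.sim)
    planted = [
        PlantedEvent(
            kind=p["kind"],
            branch=p["branch"],
            payload=dict(p.get("payload", {})),
            before_wgd=p.get("before_wgd"),
        )
        for p in sim.pop("planted_events", [])
    ]
    return SimParams(seed=config.seed, planted_events=planted, **sim)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured pipeline; returns (and writes) the summary."""
    logging.basicConfig(level=config.log_level)
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline mode=%s seed=%d", config.mode, config.seed)

    if config.mode == "tables":
        return _run_tables(config, out)
    return _run_simulate(config, out)


def _run_tables(config: PipelineConfig, out: pathlib.Path) -> dict:
    """Precomputed-families mode: chart the packaged (or supplied) genomes
    against the packaged neighboring-family screens."""
    if config.gene_tables:
        _check_paths(config.gene_tables + (
            [config.lengths_table] if config.lengths_table else []
        ))
        genomes = {}
        for path in config.gene_tables:
            genomes.update(read_gene_table(path, config.lengths_table))
    else:
        genomes = fixtures.sstr_genomes()
    screens = {
        "SSTR146": list(fixtures.neighbor_families("SSTR146")["symbol"]),
        "SSTR235": list(fixtures.neighbor_families("SSTR235")["symbol"]),
    }
    families = screens["SSTR146"] + screens["SSTR235"]
    table = tabulate_family_locations(families, genomes)
    (out / "family_locations.tsv").write_text(table.to_tsv())
    (out / "family_locations.json").write_text(table.to_json())
    summary = {
        "mode": "tables",
        "seed": config.seed,
        "n_species": len(genomes),
        "n_families_screen_sstr146": len(screens["SSTR146"]),
        "n_families_screen_sstr235": len(screens["SSTR235"]),
        "n_families_tabulated": table.n_families,
        "sstr_counts": {
            sp: genomes[sp].count_family_loci("SSTR") for sp in sorted(genomes)
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _run_simulate(config: PipelineConfig, out: pathlib.Path) -> dict:
    tree_config = config.species_tree or fixtures.vertebrate_tree_config()
    st = SpeciesTree.from_config(tree_config)
    windows = fixtures.dating_windows(tree_config)
    if len(windows) < 2:
        raise ConfigurationError(
            "simulate mode needs the 2R and 3R dating windows in the "
            "species-tree config"
        )
    w2, w3 = windows[0], windows[1]
    params = _sim_params(config)
    sim = simulate_history(st, params)
    for name, text in sim.serialize().items():
        (out / name).write_text(text)

    verdicts = {}
    for fam, newick in sim.gene_trees.items():
        gt = GeneFamilyTree.from_newick(newick, family_id=fam)
        verdicts[fam] = classify_family_verdict(
            [gt],
            st,
            w2,
            support_threshold=config.support_threshold,
            extra_windows=(w3,),
            family_id=fam,
        )
    verdict_lines = ["family\tverdict\twindow\tsupport\tmethod_agreement"]
    for fam in sorted(verdicts):
        v = verdicts[fam]
        verdict_lines.append(
            f"{fam}\t{v.verdict}\t{v.window_label}\t"
            f"{'' if v.support is None else v.support}\t"
            f"{'' if v.method_agreement is None else v.method_agreement}"
        )
    (out / "verdicts.tsv").write_text("\n".join(verdict_lines) + "\n")

    table = tabulate_family_locations(sorted(sim.gene_trees), sim.genomes)
    paralogons = assemble_paralogons(
        table, verdicts, min_support=config.min_support
    )
    (out / "paralogons.json").write_text(
        json.dumps(
            [
                {
                    "id": p.id,
                    "wgd": p.wgd_label,
                    "regions": [list(r) for r in p.member_regions],
                    "families": {
                        fam: [list(r) for r in info["regions"]]
                        for fam, info in p.supporting_families.items()
                    },
                }
                for p in paralogons
            ],
            indent=1,
        )
    )
    calls = infer_fusion_timing(
        paralogons, verdicts, sim.genomes, st, min_support=config.min_support
    )
    scenario = reconstruct_scenario(
        calls,
        paralogons,
        st,
        ancestor=sim.ancestor,
        genomes=sim.genomes,
    )
    (out / "scenario.jsonl").write_text(scenario.to_jsonl())

    verdict_tally: dict[str, int] = {}
    for v in verdicts.values():
        verdict_tally[v.verdict] = verdict_tally.get(v.verdict, 0) + 1
    summary = {
        "mode": "simulate",
        "seed": config.seed,
        "n_species": len(sim.genomes),
        "n_families": len(sim.gene_trees),
        "verdict_tally": verdict_tally,
        "n_paralogons": len(paralogons),
        "n_calls": len(calls),
        "calls": [
            {
                "kind": c.kind,
                "timing": c.timing,
                "regions": [list(r) for r in c.regions],
                "n_families": len(c.evidence_families),
            }
            for c in calls
        ],
        "inferred_events": [json.loads(e.to_json()) for e in scenario],
        "truth_events": [json.loads(e.to_json()) for e in sim.truth],
        "events_match": scenario.events == sim.truth.events,
        "scenario_notes": getattr(scenario, "notes", []),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    gene_tsv, lengths_tsv = genomes_to_tables(sim.genomes)
    (out / "genomes.tsv").write_text(gene_tsv)
    (out / "chromosome_lengths.tsv").write_text(lengths_tsv)
    return summary
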