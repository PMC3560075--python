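"""Paralogon assembly, fusion timing and scenario reconstruction against
simulator truth."""

import pytest

from paralogon.errors import ParalogonError
from paralogon.evo_sim import (
    PlantedEvent,
    SimParams,
    replay_events,
    simulate_history,
)
from paralogon.paralogons import (
    RearrangementCall,
    assemble_paralogons,
    infer_block_rearrangements,
    infer_fusion_timing,
    reconstruct_scenario,
)
from paralogon.synteny import tabulate_family_locations
from paralogon.tree_timing import GeneFamilyTree, classify_family_verdict


def _verdicts(sim, species_tree, windows):
    w2, w3 = windows
    return {
        fam: classify_family_verdict(
            [GeneFamilyTree.from_newick(nwk, family_id=fam)],
            species_tree,
            w2,
            extra_windows=(w3,),
            family_id=fam,
        )
        for fam, nwk in sim.gene_trees.items()
    }


def _table(sim, genomes=None):
    return tabulate_family_locations(
        sorted(sim.gene_trees), genomes or sim.genomes
    )


def test_noiseless_2r_gives_one_4_region_paralogon_per_ancestral_chromosome(
    noiseless_sim, species_tree, windows
):
    """With full retention and no rearrangements, each of the two
    ancestral chromosomes yields exactly one paralogon of four regions in
    each genome."""
    verdicts = _verdicts(noiseless_sim, species_tree, windows)
    table_human = _table(
        noiseless_sim, {"human": noiseless_sim.genomes["human"]}
    )
    paralogons = assemble_paralogons(table_human, verdicts)
    assert len(paralogons) == 2
    assert all(len(p.member_regions) == 4 for p in paralogons)


def test_min_support_above_evidence_gives_empty_set(
    noiseless_sim, species_tree, windows
):
    verdicts = _verdicts(noiseless_sim, species_tree, windows)
    table = _table(noiseless_sim)
    assert assemble_paralogons(table, verdicts, min_support=1000) == []


def test_assembly_invariant_to_row_order(noiseless_sim, species_tree, windows):
    verdicts = _verdicts(noiseless_sim, species_tree, windows)
    table = _table(noiseless_sim)
    shuffled = type(table)(
        table.frame.sample(frac=1.0, random_state=5), table.all_families
    )
    a = assemble_paralogons(table, verdicts)
    b = assemble_paralogons(shuffled, verdicts)
    assert [p.member_regions for p in a] == [p.member_regions for p in b]


def test_zero_rearrangement_simulation_has_zero_calls(
    noiseless_sim, species_tree, windows
):
    """No false positives: without rearrangements neither fusion timing
    nor block comparison emits a call."""
    verdicts = _verdicts(noiseless_sim, species_tree, windows)
    table = _table(noiseless_sim)
    paralogons = assemble_paralogons(table, verdicts)
    assert infer_fusion_timing(
        paralogons, verdicts, noiseless_sim.genomes, species_tree
    ) == []
    assert (
        infer_block_rearrangements(table, "medaka", "zebrafish", verdicts)
        == []
    )


def _planted_fusion_sim(seed, species_tree, retention=1.0, fission=False):
    planted = [
        PlantedEvent("chromosome_fusion", "teleost_crown", {},
                     before_wgd="3R")
    ]
    if fission:
        planted.append(PlantedEvent("chromosome_fission", "teleost_crown", {}))
    params = SimParams(
        n_families=8 if retention == 1.0 else 30,
        n_ancestral_chromosomes=1,
        ohnolog_retention_prob=retention,
        seed=seed,
        planted_events=planted,
    )
    return simulate_history(species_tree, params)


def test_planted_fusion_called_before_3r(species_tree, windows):
    sim = _planted_fusion_sim(11, species_tree)
    verdicts = _verdicts(sim, species_tree, windows)
    paralogons = assemble_paralogons(_table(sim), verdicts)
    calls = infer_fusion_timing(paralogons, verdicts, sim.genomes,
                                species_tree)
    assert any(
        c.kind == "fusion" and c.timing == "before_3R" for c in calls
    )


def test_planted_fusion_recovered_across_20_seeds(species_tree, windows):
    """Study conditions: one planted pre-3R fusion, 30 families, retention
    0.9 — the fusion is detected with correct timing in every run."""
    hits = 0
    for seed in range(20):
        sim = _planted_fusion_sim(seed, species_tree, retention=0.9)
        verdicts = _verdicts(sim, species_tree, windows)
        paralogons = assemble_paralogons(_table(sim), verdicts)
        calls = infer_fusion_timing(
            paralogons, verdicts, sim.genomes, species_tree
        )
        hits += any(
            c.kind == "fusion" and c.timing == "before_3R" for c in calls
        )
    assert hits == 20


def test_post_3r_exchange_not_called_before_3r(species_tree, windows):
    """A post-3R exchange between 3R-sister chromosomes co-locates a/b
    duplicates only and must not produce a before_3R fusion call."""
    params = SimParams(
        n_families=8,
        n_ancestral_chromosomes=1,
        ohnolog_retention_prob=1.0,
        seed=2,
        planted_events=[
            PlantedEvent(
                "block_translocation",
                "teleost_crown",
                {
                    "source": "A0_2Ra0_2Rb0_3R0",
                    "dest": "A0_2Ra0_2Rb0_3R1",
                    "length": 3,
                    "start": 0,
                    "at": 0,
                },
            )
        ],
    )
    sim = simulate_history(species_tree, params)
    verdicts = _verdicts(sim, species_tree, windows)
    paralogons = assemble_paralogons(_table(sim), verdicts)
    calls = infer_fusion_timing(paralogons, verdicts, sim.genomes,
                                species_tree)
    assert not any(c.timing == "before_3R" for c in calls)


def test_tetrapod_only_input_yields_no_fusion_calls(
    noiseless_sim, species_tree, windows
):
    """Genomes without 3R in their ancestry produce no fusion calls here
    (nothing is co-located)."""
    verdicts = _verdicts(noiseless_sim, species_tree, windows)
    tetrapods = {
        sp: noiseless_sim.genomes[sp] for sp in ("human", "chicken")
    }
    paralogons = assemble_paralogons(
        _table(noiseless_sim, tetrapods), verdicts
    )
    calls = infer_fusion_timing(paralogons, verdicts, tetrapods,
                                species_tree)
    assert calls == []


def test_block_translocation_recovered_exactly(species_tree, windows):
    """A planted 3-gene block translocation on the zebrafish branch is
    reported as a single call covering exactly those genes."""
    params = SimParams(
        n_families=8,
        n_ancestral_chromosomes=2,
        ohnolog_retention_prob=1.0,
        seed=5,
        planted_events=[
            PlantedEvent(
                "block_translocation",
                "zebrafish",
                {
                    "source": "A0_2Ra0_2Rb0_3R0",
                    "dest": "A1_2Ra0_2Rb0_3R0",
                    "length": 3,
                    "start": 0,
                    "at": 1,
                },
            )
        ],
    )
    sim = simulate_history(species_tree, params)
    verdicts = _verdicts(sim, species_tree, windows)
    table = _table(sim)
    calls = infer_block_rearrangements(
        table, "medaka", "zebrafish", verdicts, block_window_mb=2.0
    )
    assert len(calls) == 1
    truth_event = next(
        e for e in sim.truth if e.kind == "block_translocation"
    )
    src = truth_event.payload["source"]
    moved = sim.node_genomes  # noqa: F841 (genes derived below)
    assert sorted(calls[0].payload["genes"]) == sorted(
        ["F000_2Ra0_2Rb0_3R0", "F002_2Ra0_2Rb0_3R0", "F004_2Ra0_2Rb0_3R0"]
    )
    assert calls[0].payload["block"] is True
    # untouched sister teleosts show no calls
    assert (
        infer_block_rearrangements(
            table, "medaka", "stickleback", verdicts, block_window_mb=2.0
        )
        == []
    )


def test_scenario_round_trip_matches_truth_and_tips(species_tree, windows):
    """Noiseless planted history (pre-3R fusion + post-3R fission): the
    reconstructed scenario equals the truth log and replays to the
    simulated tip genomes."""
    sim = _planted_fusion_sim(11, species_tree, fission=True)
    verdicts = _verdicts(sim, species_tree, windows)
    paralogons = assemble_paralogons(_table(sim), verdicts)
    calls = infer_fusion_timing(paralogons, verdicts, sim.genomes,
                                species_tree)
    scenario = reconstruct_scenario(
        calls, paralogons, species_tree,
        ancestor=sim.ancestor, genomes=sim.genomes,
    )
    assert scenario.events == sim.truth.events
    tips = replay_events(scenario, sim.ancestor, species_tree)
    for sp, genome in sim.genomes.items():
        assert tips[sp] == genome


def test_empty_calls_give_wgd_only_history(species_tree):
    scenario = reconstruct_scenario([], [], species_tree)
    assert all(e.kind == "wgd" for e in scenario)
    assert [e.payload["label"] for e in scenario] == ["2R-a", "2R-b", "3R"]


def test_contradictory_timing_reported(species_tree):
    regions = (("zebrafish", "c1"),)
    calls = [
        RearrangementCall("fusion", regions, "before_3R", ("F0", "F1")),
        RearrangementCall("fusion", regions, "after_3R", ("F2", "F3")),
    ]
    with pytest.raises(ParalogonError, match="contradictory timing"):
        reconstruct_scenario(calls, [], species_tree)
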