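"""Simulator invariants: doubling, determinism, retention statistics,
rearrangement conservation laws, replay round-trips and NNI perturbation."""

import dendropy
import numpy as np
import pytest

from paralogon.errors import ConfigurationError, ParalogonError, ReplayError
from paralogon.evo_sim import (
    EventHistory,
    EvoEvent,
    PlantedEvent,
    SimParams,
    _State,
    apply_event,
    perturb_gene_tree,
    replay_events,
    simulate_history,
)
from paralogon.species_tree import SpeciesTree, WgdMarker


def two_taxon_tree(markers=()):
    return SpeciesTree.from_newick("(A:1,B:1)root;", markers)


def test_two_wgds_full_retention_quadruple():
    """Two WGDs at retention 1 exactly double genes and chromosomes twice."""
    st = two_taxon_tree(
        [WgdMarker("2R-a", "A", 0.3), WgdMarker("2R-b", "A", 0.6)]
    )
    sim = simulate_history(
        st,
        SimParams(
            n_families=1,
            n_ancestral_chromosomes=1,
            ohnolog_retention_prob=1.0,
            seed=1,
        ),
    )
    assert len(sim.genomes["A"].loci) == 4
    assert len(sim.genomes["A"].chromosomes) == 4
    assert len(sim.genomes["B"].loci) == 1


def test_same_seed_byte_identical():
    st = two_taxon_tree([WgdMarker("2R-a", "A", 0.5)])
    params = SimParams(
        n_families=20, ohnolog_retention_prob=0.7, shuffle_intensity=1.0,
        fusion_rate=0.5, fission_rate=0.5, translocation_rate=0.5, seed=42,
    )
    assert (
        simulate_history(st, params).serialize()
        == simulate_history(st, params).serialize()
    )


def test_retention_matches_binomial_expectation():
    """Mean retained copies per family after one WGD at p=0.75 lies within
    3 standard errors of the binomial expectation 2p."""
    st = two_taxon_tree([WgdMarker("2R-a", "A", 0.5)])
    n = 1000
    p = 0.75
    sim = simulate_history(
        st,
        SimParams(
            n_families=n,
            n_ancestral_chromosomes=4,
            ohnolog_retention_prob=p,
            seed=9,
        ),
    )
    per_family = {f"F{i:03d}": 0 for i in range(n)}
    for info in sim.ohnolog_map.values():
        if info["species"] == "A":
            per_family[info["family"]] += 1
    mean = sum(per_family.values()) / n
    se = np.sqrt(2 * p * (1 - p) / n)
    assert abs(mean - 2 * p) <= 3 * se


def _counts(state):
    return (
        len(state.chromosomes),
        sum(len(g) for g in state.chromosomes.values()),
    )


def test_rearrangement_conservation_laws():
    """Fusion: -1 chromosome, same genes. Fission: +1, same genes.
    Translocation: both conserved."""
    state = _State()
    state.chromosomes = {"c1": ["a", "b", "c"], "c2": ["d", "e"]}
    state.families = {g: "F" for g in "abcde"}
    apply_event(
        state,
        EvoEvent(
            "chromosome_fusion",
            "A",
            {"left": "c1", "right": "c2", "flip_right": True},
        ),
    )
    assert _counts(state) == (1, 5)
    assert state.chromosomes["c1+c2"] == ["a", "b", "c", "e", "d"]
    apply_event(
        state,
        EvoEvent("chromosome_fission", "A", {"chromosome": "c1+c2", "index": 2}),
    )
    assert _counts(state) == (2, 5)
    apply_event(
        state,
        EvoEvent(
            "block_translocation",
            "A",
            {
                "source": "c1+c2_f1",
                "start": 0,
                "length": 2,
                "dest": "c1+c2_f0",
                "at": 1,
                "invert": True,
            },
        ),
    )
    assert _counts(state) == (2, 5)
    assert state.chromosomes["c1+c2_f0"] == ["a", "e", "c", "b"]


def test_replay_errors_name_event_index():
    state_genome = _State()
    state_genome.chromosomes = {"c": ["a"]}
    state_genome.families = {"a": "F"}
    genome = state_genome.to_genome("anc")
    st = two_taxon_tree()
    history = EventHistory(
        [EvoEvent("gene_loss", "A", {"gene": "missing"})]
    )
    with pytest.raises(ReplayError, match="event 0"):
        replay_events(history, genome, st)


def test_wgd_on_missing_branch_rejected():
    with pytest.raises(ConfigurationError):
        two_taxon_tree([WgdMarker("2R-a", "nope", 0.5)])


def test_simulate_then_replay_truth_reproduces_tips(species_tree):
    """The truth log replayed from the ancestor reproduces every simulated
    tip genome exactly."""
    params = SimParams(
        n_families=10,
        n_ancestral_chromosomes=2,
        ohnolog_retention_prob=0.8,
        fusion_rate=0.3,
        fission_rate=0.3,
        translocation_rate=0.5,
        shuffle_intensity=0.5,
        seed=7,
    )
    sim = simulate_history(species_tree, params)
    tips = replay_events(sim.truth, sim.ancestor, species_tree)
    assert set(tips) == set(sim.genomes)
    for sp in tips:
        assert tips[sp] == sim.genomes[sp]


def test_empty_history_keeps_ancestor_unchanged():
    state = _State()
    state.chromosomes = {"c": ["a", "b"]}
    state.families = {"a": "F", "b": "G"}
    genome = state.to_genome("anc")
    st = two_taxon_tree()
    tips = replay_events(EventHistory(), genome, st)
    for sp in ("A", "B"):
        assert len(tips[sp].loci) == 2
        assert {l.start for l in tips[sp]} == {l.start for l in genome}


def test_extant_gene_wgd_paths_match_lineage(species_tree):
    """Every extant gene's recorded WGD path contains exactly the WGDs of
    its lineage when retention is 1 (no losses)."""
    sim = simulate_history(
        species_tree,
        SimParams(
            n_families=3,
            n_ancestral_chromosomes=1,
            ohnolog_retention_prob=1.0,
            seed=2,
        ),
    )
    for info in sim.ohnolog_map.values():
        expected = species_tree.wgd_labels_in_ancestry(info["species"])
        assert [lab for lab, _ in info["wgd_path"]] == expected


NWK6 = "((A|g1:1,B|g1:1):1,((C|g1:1,D|g1:1):1,(E|g1:1,F|g1:1):1):1);"


def test_nni_identity_and_determinism():
    assert perturb_gene_tree(NWK6, 0, 1) == NWK6
    assert perturb_gene_tree(NWK6, 3, 5) == perturb_gene_tree(NWK6, 3, 5)


def test_nni_requires_four_leaves():
    with pytest.raises(ParalogonError):
        perturb_gene_tree("(A|g1:1,(B|g1:1,C|g1:1):1);", 1, 0)


@pytest.mark.parametrize("n_nni", [1, 2, 4])
def test_nni_rf_distance_bounded(n_nni):
    """Robinson-Foulds distance after n NNI moves is at most 2n."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(
        data=NWK6, schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    out = perturb_gene_tree(NWK6, n_nni, seed=17)
    t2 = dendropy.Tree.get(
        data=out, schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    assert rf <= 2 * n_nni
    assert {l.taxon.label for l in t1.leaf_node_iter()} == {
        l.taxon.label for l in t2.leaf_node_iter()
    }


def test_planted_event_before_wgd_ordering(species_tree):
    """A planted fusion marked before 3R appears ahead of the 3R event in
    the truth log."""
    params = SimParams(
        n_families=4,
        n_ancestral_chromosomes=1,
        ohnolog_retention_prob=1.0,
        seed=0,
        planted_events=[
            PlantedEvent(
                "chromosome_fusion", "teleost_crown", {}, before_wgd="3R"
            )
        ],
    )
    sim = simulate_history(species_tree, params)
    kinds = [
        (e.kind, e.payload.get("label"))
        for e in sim.truth.on_branch("teleost_crown")
    ]
    assert kinds.index(("chromosome_fusion", None)) < kinds.index(
        ("wgd", "3R")
    )
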