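"""Reconciliation, relative dating, family verdicts and subtype calls."""

import random

import pytest

from paralogon.errors import ConfigurationError, ReconciliationError
from paralogon.tree_timing import (
    DuplicationWindow,
    GeneFamilyTree,
    assign_subtype_and_ab,
    classify_family_verdict,
    date_duplication_nodes,
    reconcile,
    validate_windows,
)
from paralogon.species_tree import SpeciesTree


def test_reconcile_textbook_cases():
    st = SpeciesTree.from_newick("(A:1,B:1)root;")
    rt = reconcile(
        GeneFamilyTree.from_newick("((A|g1:1,B|g1:1):1,(A|g2:1,B|g2:1):1);"),
        st,
    )
    root = rt.gene_tree.tree.seed_node
    assert rt.events[root] == "duplication"
    assert all(
        rt.events[c] == "speciation" for c in root.child_nodes()
    )
    rt2 = reconcile(
        GeneFamilyTree.from_newick("((A|g1:1,A|g2:1):1,B|g1:1);"), st
    )
    inner = [
        n
        for n in rt2.gene_tree.tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None
    ][0]
    assert rt2.events[inner] == "duplication"
    assert rt2.mapping[inner] == "A"


def test_unknown_leaf_species_named_in_error():
    st = SpeciesTree.from_newick("(A:1,B:1)root;")
    with pytest.raises(ReconciliationError, match="martian"):
        reconcile(
            GeneFamilyTree.from_newick("(A|g1:1,martian|g1:1);"), st
        )


def _random_gene_tree(rng, species_pool, n_leaves):
    labels = [
        f"{rng.choice(species_pool)}|g{i}" for i in range(n_leaves)
    ]
    parts = [f"{lab}:1" for lab in labels]
    while len(parts) > 1:
        i = rng.randrange(len(parts))
        a = parts.pop(i)
        j = rng.randrange(len(parts))
        b = parts.pop(j)
        parts.append(f"({a},{b}):1")
    return parts[0] + ";"


def _brute_lca(species_tree, species_set):
    """Independent LCA: intersect full root paths instead of folding."""
    paths = [
        [n.name for n in species_tree.path_to_root(sp)][::-1]
        for sp in species_set
    ]
    deepest = None
    for i in range(min(len(p) for p in paths)):
        names = {p[i] for p in paths}
        if len(names) == 1:
            deepest = names.pop()
        else:
            break
    return deepest


def test_reconciliation_equals_brute_force_lca_oracle(species_tree):
    """On random trees <= 10 leaves, node mappings and duplication labels
    match a brute-force oracle computed from full root paths of the leaf
    species sets (duplication iff the mapping equals a child's mapping;
    intersecting child species sets are the common special case)."""
    rng = random.Random(2024)
    pool = species_tree.taxa
    for _ in range(200):
        nwk = _random_gene_tree(rng, pool, rng.randint(2, 10))
        gt = GeneFamilyTree.from_newick(nwk)
        rt = reconcile(gt, species_tree)
        species_sets = {}
        for node in gt.tree.postorder_node_iter():
            if node.is_leaf():
                species_sets[node] = {gt.leaf_species[node]}
                continue
            kids = node.child_nodes()
            species_sets[node] = set().union(
                *(species_sets[k] for k in kids)
            )
            mapped = _brute_lca(species_tree, species_sets[node])
            assert rt.mapping[node] == mapped
            oracle_dup = any(
                _brute_lca(species_tree, species_sets[k]) == mapped
                for k in kids
            )
            assert (rt.events[node] == "duplication") == oracle_dup
            # intersecting child species sets always imply a duplication
            if species_sets[kids[0]] & species_sets[kids[1]]:
                assert rt.events[node] == "duplication"


def test_dating_windows(species_tree, windows):
    """2R-window and 3R-window examples: a duplication with both
    sarcopterygian and actinopterygian descendants on each side dates to
    2R; a teleost-only duplication below a basal gar lineage dates to 3R;
    a single-species duplication is lineage-specific."""
    w2, w3 = windows
    nwk = (
        "((((human|a:1,zebrafish|a:1):1,(human|b:1,zebrafish|b:1):1):1,"
        "(gar|c:1,(zebrafish|c1:1,medaka|c1:1):1):1):1,"
        "(human|d1:1,human|d2:1):1);"
    )
    gt = GeneFamilyTree.from_newick(nwk)
    rt = reconcile(gt, species_tree)
    dated = date_duplication_nodes(rt, [w2, w3])
    labels = sorted(dated.values())
    assert "2R_window" in labels  # the a/b duplication
    assert "lineage_specific" in labels  # the human d1/d2 pair
    # teleost-only duplication with gar branching basal
    nwk3 = (
        "((gar|c:1,((zebrafish|ca:1,medaka|ca:1):1,"
        "(zebrafish|cb:1,medaka|cb:1):1):1):1,human|c:1);"
    )
    rt3 = reconcile(GeneFamilyTree.from_newick(nwk3), species_tree)
    dated3 = date_duplication_nodes(rt3, [w2, w3])
    assert "3R_window" in dated3.values()


def test_overlapping_windows_rejected(species_tree):
    overlapping = [
        DuplicationWindow(
            "w1", "chordate_vertebrate_split",
            "sarcopterygian_actinopterygian_split",
        ),
        DuplicationWindow(
            "w2", "chordate_vertebrate_split", "gar_teleost_split"
        ),
    ]
    with pytest.raises(ConfigurationError):
        validate_windows(species_tree, overlapping)


def test_dating_invariant_to_subtree_leaf_order(species_tree, windows):
    """Swapping leaf order below the dated node leaves its label fixed."""
    a = "((human|a:1,zebrafish|a:1):1,(human|b:1,zebrafish|b:1):1);"
    b = "((zebrafish|b:1,human|b:1):1,(zebrafish|a:1,human|a:1):1);"
    out = []
    for nwk in (a, b):
        rt = reconcile(GeneFamilyTree.from_newick(nwk), species_tree)
        dated = date_duplication_nodes(rt, list(windows))
        out.append(dated[rt.gene_tree.tree.seed_node])
    assert out[0] == out[1] == "2R_window"


TWO_R = DuplicationWindow(
    "2R_window",
    "chordate_vertebrate_split",
    "sarcopterygian_actinopterygian_split",
)


@pytest.mark.parametrize(
    "ml_support,nj,expected",
    [
        # supported in ML, NJ agrees -> supports
        ("90", "((human|a:1,zebrafish|a:1):1,(human|b:1,zebrafish|b:1):1)88;",
         "supports_WGD"),
        # ML supports, NJ has no vertebrate duplication -> still supports
        ("90", "((human|a:1,human|b:1):1,(zebrafish|a:1,zebrafish|b:1):1);",
         "supports_WGD"),
        # duplication present but weakly supported everywhere -> consistent
        ("30", "((human|a:1,zebrafish|a:1):1,(human|b:1,zebrafish|b:1):1)20;",
         "consistent"),
    ],
)
def test_family_verdicts(species_tree, ml_support, nj, expected):
    ml = (
        f"((human|a:1,zebrafish|a:1)95:1,(human|b:1,zebrafish|b:1)95:1)"
        f"{ml_support};"
    )
    trees = [
        GeneFamilyTree.from_newick(ml, method="ML"),
        GeneFamilyTree.from_newick(nj, method="NJ"),
    ]
    verdict = classify_family_verdict(trees, species_tree, TWO_R)
    assert verdict.verdict == expected


def test_no_vertebrate_duplication_is_inconclusive(species_tree):
    gt = GeneFamilyTree.from_newick(
        "(human|a:1,(gar|a:1,zebrafish|a:1):1);"
    )
    verdict = classify_family_verdict([gt], species_tree, TWO_R)
    assert verdict.verdict == "inconclusive"


def test_mismatched_method_leaf_sets_rejected(species_tree):
    t1 = GeneFamilyTree.from_newick("(human|a:1,zebrafish|a:1);")
    t2 = GeneFamilyTree.from_newick("(human|a:1,medaka|a:1);")
    with pytest.raises(Exception, match="leaf set"):
        classify_family_verdict([t1, t2], species_tree, TWO_R)


def test_noiseless_simulation_window_recovery(noiseless_sim, species_tree,
                                              windows):
    """Every WGD duplication node of the true gene trees dates to its
    generating WGD's window."""
    w2, w3 = windows
    total = correct = 0
    for fam, nwk in noiseless_sim.gene_trees.items():
        gt = GeneFamilyTree.from_newick(nwk, family_id=fam)
        rt = reconcile(gt, species_tree)
        dated = date_duplication_nodes(rt, [w2, w3])
        for node, label in dated.items():
            tag = node.label
            if tag in ("2Ra", "2Rb"):
                total += 1
                correct += label == "2R_window"
            elif tag == "3R":
                total += 1
                correct += label == "3R_window"
    assert total > 0
    assert correct == total


# --- subtype / a-b assignment ---------------------------------------------


def test_misannotated_gene_assigned_by_clade(species_tree):
    """A zebrafish gene annotated 'sstr1a' that clusters inside the SSTR6
    clade is called SSTR6."""
    nwk = (
        "(((human|SSTR1:1,gar|SSTR1:1):1,((gar|SSTR6:1,zebrafish|sstr1a:1):1,"
        "(human|SSTR4:1,chicken|SSTR4:1):1):1):1,human|SSTR2:1);"
    )
    rt = reconcile(GeneFamilyTree.from_newick(nwk), species_tree)
    refs = {
        "SSTR1": {"human|SSTR1"},
        "SSTR6": {"gar|SSTR6"},
        "SSTR4": {"human|SSTR4"},
        "SSTR2": {"human|SSTR2"},
    }
    call = assign_subtype_and_ab(rt, refs, "zebrafish|sstr1a")
    assert (call.status, call.label) == ("assigned", "SSTR6")


def test_duplicates_in_one_clade_assigned_same_subtype(species_tree):
    """Two co-clustering teleost copies both resolve to SSTR6 (salmonid-
    style duplicate pair)."""
    nwk = (
        "(((gar|SSTR6:1,(zebrafish|x1a:1,zebrafish|x1b:1):1):1,"
        "human|SSTR1:1):1,human|SSTR2:1);"
    )
    rt = reconcile(GeneFamilyTree.from_newick(nwk), species_tree)
    refs = {"SSTR6": {"gar|SSTR6"}, "SSTR1": {"human|SSTR1"},
            "SSTR2": {"human|SSTR2"}}
    for query in ("zebrafish|x1a", "zebrafish|x1b"):
        assert assign_subtype_and_ab(rt, refs, query).label == "SSTR6"


def test_ab_polarity_follows_anchor(species_tree, windows):
    """A gene named '5c' clustering with the b-duplicates is called
    SSTR5b; polarity is set by the designated a-reference."""
    nwk = (
        "((human|SSTR5:1,((zebrafish|SSTR5a:1,medaka|SSTR5a:1):1,"
        "(zebrafish|SSTR5b:1,(medaka|5c:1,stickleback|SSTR5b:1):1):1):1):1,"
        "human|SSTR2:1);"
    )
    rt = reconcile(GeneFamilyTree.from_newick(nwk), species_tree)
    assignments = date_duplication_nodes(rt, list(windows))
    call = assign_subtype_and_ab(
        rt,
        {"SSTR5": {"human|SSTR5"}, "SSTR2": {"human|SSTR2"}},
        "medaka|5c",
        ab_window_label="3R_window",
        assignments=assignments,
        a_anchors={"SSTR5": "zebrafish|SSTR5a"},
    )
    assert call.label == "SSTR5b"


def test_basal_query_is_unassignable(species_tree):
    nwk = "((human|SSTR1:1,human|SSTR4:1):1,gar|mystery:1);"
    rt = reconcile(GeneFamilyTree.from_newick(nwk), species_tree)
    refs = {"SSTR1": {"human|SSTR1"}, "SSTR4": {"human|SSTR4"}}
    call = assign_subtype_and_ab(rt, refs, "gar|mystery")
    assert call.status == "unassignable"
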