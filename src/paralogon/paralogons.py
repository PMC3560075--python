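"""Paralogon assembly and chromosome-rearrangement inference.

A paralogon is a set of chromosome regions, within and across genomes,
descending from one ancestral region via whole-genome duplication. Regions
are linked here by *window-dated paralogy*: two regions join when at least
``min_support`` distinct gene families hold paralogs of one another, with
the separating duplication dated to the WGD window in question, on the two
regions. Evidence granularity is the chromosome.

Rearrangement timing uses the signature that distinguishes pre- from
post-3R events: when the duplicates co-located on one teleost chromosome
are 2R-generated paralogs of many families (different 2R paralogy classes),
the underlying fusion predates 3R; when only 3R a/b duplicates of a single
2R class are co-located, the co-location postdates 3R. Genomes with no 3R
in their ancestry can only yield indeterminate timing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .errors import ParalogonError
from .evo_sim import EventHistory, EvoEvent, _sanitize, _State, apply_event
from .genome_model import Genome
from .species_tree import SpeciesTree
from .synteny import FamilyLocationTable
from .tree_timing import FamilyVerdict, INCONCLUSIVE

Region = tuple[str, str]  # (species, chromosome)


@dataclass
class Paralogon:
    id: str
    member_regions: tuple[Region, ...]
    supporting_families: dict[str, dict]
    wgd_label: str

    def __post_init__(self) -> None:
        if len(self.member_regions) < 2:
            raise ParalogonError("a paralogon needs >= 2 member regions")


@dataclass
class RearrangementCall:
    kind: str  # fusion | fission | translocation
    regions: tuple[Region, ...]
    timing: str  # before_3R | after_3R | indeterminate
    evidence_families: tuple[str, ...]
    interval: tuple[str, str, float, float] | None = None
    payload: dict = field(default_factory=dict)


def _class_lookup(
    verdicts: dict[str, FamilyVerdict], window_label: str
) -> dict[tuple[str, str], tuple[str, tuple[int, ...]]]:
    """(species, gene) -> (family, window class) from verdict dating."""
    out: dict[tuple[str, str], tuple[str, tuple[int, ...]]] = {}
    for fam, verdict in verdicts.items():
        classes = verdict.classes.get(window_label, {})
        for leaf, cls in classes.items():
            species, _, gene = leaf.partition("|")
            out[(species, gene)] = (fam, tuple(cls))
    return out


def assemble_paralogons(
    table: FamilyLocationTable,
    verdicts: dict[str, FamilyVerdict],
    min_support: int = 2,
    window_label: str = "2R_window",
    cross_species: bool = True,
) -> list[Paralogon]:
    """Connected components of the region graph whose edges carry >=
    ``min_support`` families with window-dated paralogs on both sides.

    Within one genome, regions are linked by paralogy (different window
    classes of a family); across genomes, by orthology (same window class),
    so that corresponding regions of different species fall into one
    paralogon. Families with an inconclusive verdict contribute no edges.
    """
    lookup = {}
    for window in {window_label}:
        lookup = _class_lookup(
            {
                f: v
                for f, v in verdicts.items()
                if v.verdict != INCONCLUSIVE
            },
            window,
        )
    # region -> family -> set of classes
    by_region: dict[Region, dict[str, set[tuple[int, ...]]]] = {}
    for row in table.frame.itertuples(index=False):
        key = (row.species, row.gene_id)
        if key not in lookup:
            continue
        fam, cls = lookup[key]
        region = (row.species, row.chromosome)
        by_region.setdefault(region, {}).setdefault(fam, set()).add(cls)

    edges: dict[tuple[Region, Region], set[str]] = {}
    regions = sorted(by_region)
    for r1, r2 in itertools.combinations(regions, 2):
        same_species = r1[0] == r2[0]
        if not same_species and not cross_species:
            continue
        fams = set(by_region[r1]) & set(by_region[r2])
        linked = set()
        for fam in fams:
            c1, c2 = by_region[r1][fam], by_region[r2][fam]
            if same_species:
                # paralogy: some class on r1 differs from some class on r2
                if any(a != b for a in c1 for b in c2):
                    linked.add(fam)
            else:
                # orthology: a shared class on both regions
                if c1 & c2:
                    linked.add(fam)
        if len(linked) >= min_support:
            edges[(r1, r2)] = linked

    graph = nx.Graph()
    for (r1, r2), fams in edges.items():
        graph.add_edge(r1, r2, families=fams)
    out: list[Paralogon] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: c[0],
    )
    for i, comp in enumerate(components):
        support: dict[str, dict] = {}
        for r1, r2 in itertools.combinations(comp, 2):
            if graph.has_edge(r1, r2):
                for fam in graph.edges[r1, r2]["families"]:
                    info = support.setdefault(fam, {"regions": set()})
                    info["regions"].update((r1, r2))
        support = {
            fam: {"regions": tuple(sorted(info["regions"]))}
            for fam, info in sorted(support.items())
        }
        out.append(
            Paralogon(
                id=f"P{i}",
                member_regions=tuple(comp),
                supporting_families=support,
                wgd_label=window_label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# fusion timing


def infer_fusion_timing(
    paralogons: list[Paralogon],
    verdicts: dict[str, FamilyVerdict],
    genomes: dict[str, Genome],
    species_tree: SpeciesTree,
    min_support: int = 2,
    window_2r: str = "2R_window",
    window_3r: str = "3R_window",
    three_r_label: str = "3R",
) -> list[RearrangementCall]:
    """Call chromosome fusions and date them relative to 3R.

    A chromosome carrying members of >= 2 distinct 2R paralogy classes for
    >= ``min_support`` families witnesses a fusion; it is dated before_3R
    when the co-located members are 2R-generated paralogs rather than 3R
    a/b duplicates of a single class, after_3R when only a/b duplicates are
    co-located, and indeterminate on ties or in genomes without 3R.
    Conflicting family evidence is resolved by majority; chromosomes
    sharing the same per-family class signatures merge into one call.
    """
    lookup2 = _class_lookup(verdicts, window_2r)
    lookup3 = _class_lookup(verdicts, window_3r)

    chrom_evidence: dict[Region, dict] = {}
    for species, genome in genomes.items():
        for chrom in genome.chromosomes:
            fam_classes2: dict[str, set] = {}
            fam_classes3: dict[str, dict[tuple, set]] = {}
            for locus in genome.loci_on(chrom):
                key = (species, locus.gene_id)
                if key not in lookup2:
                    continue
                fam, cls2 = lookup2[key]
                cls3 = lookup3.get(key, (fam, ()))[1]
                fam_classes2.setdefault(fam, set()).add(cls2)
                fam_classes3.setdefault(fam, {}).setdefault(cls2, set()).add(
                    cls3
                )
            pre = {
                fam: frozenset(classes)
                for fam, classes in fam_classes2.items()
                if len(classes) >= 2
            }
            post = {
                fam
                for fam, by2 in fam_classes3.items()
                if fam not in pre
                and any(len(c3s) >= 2 for c3s in by2.values())
            }
            if len(pre) >= min_support or len(post) >= min_support:
                chrom_evidence[(species, chrom)] = {
                    "pre": pre,
                    "post": post,
                }

    # merge chromosomes sharing identical per-family co-location signatures
    graph = nx.Graph()
    for region in chrom_evidence:
        graph.add_node(region)
    regions = sorted(chrom_evidence)
    for r1, r2 in itertools.combinations(regions, 2):
        e1, e2 = chrom_evidence[r1], chrom_evidence[r2]
        shared = {
            fam
            for fam in set(e1["pre"]) & set(e2["pre"])
            if e1["pre"][fam] == e2["pre"][fam]
        }
        if len(shared) >= min_support:
            graph.add_edge(r1, r2)

    calls: list[RearrangementCall] = []
    for comp in sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    ):
        pre_fams: set[str] = set()
        post_fams: set[str] = set()
        has3r = False
        for region in comp:
            e = chrom_evidence[region]
            pre_fams.update(e["pre"])
            post_fams.update(e["post"])
            if species_tree.has_wgd_in_ancestry(region[0], three_r_label):
                has3r = True
        n_pre, n_post = len(pre_fams), len(post_fams)
        if max(n_pre, n_post) < min_support:
            continue
        if not has3r:
            timing = "indeterminate"
            evidence = pre_fams or post_fams
        elif n_pre >= min_support and n_pre > n_post:
            timing = "before_3R"
            evidence = pre_fams
        elif n_post >= min_support and n_post > n_pre:
            timing = "after_3R"
            evidence = post_fams
        else:
            timing = "indeterminate"
            evidence = pre_fams | post_fams
        calls.append(
            RearrangementCall(
                kind="fusion",
                regions=tuple(comp),
                timing=timing,
                evidence_families=tuple(sorted(evidence)),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# small-block rearrangements


def infer_block_rearrangements(
    table: FamilyLocationTable,
    reference_species: str,
    derived_species: str,
    verdicts: dict[str, FamilyVerdict] | None = None,
    window_labels: tuple[str, ...] = ("2R_window", "3R_window"),
    block_window_mb: float = 0.5,
    min_block_families: int = 2,
) -> list[RearrangementCall]:
    """Detect translocated gene blocks between a reference and a derived
    genome: orthology groups (same family and WGD class) whose reference
    copies share one chromosome but whose derived copies split across
    several, with contiguous runs on the derived chromosome reported as a
    single block call covering their interval."""
    species = set(table.frame["species"].unique())
    if reference_species not in species:
        raise ParalogonError(
            f"reference genome {reference_species!r} absent from table"
        )
    if derived_species not in species:
        raise ParalogonError(
            f"derived genome {derived_species!r} absent from table"
        )
    lookups = (
        [_class_lookup(verdicts, w) for w in window_labels] if verdicts else []
    )

    def group_key(sp: str, gene: str, fam: str):
        # family plus the gene's class in every dating window, so each
        # orthology group holds one copy per genome
        classes = tuple(
            lk.get((sp, gene), (fam, ()))[1] for lk in lookups
        )
        return (fam, classes)

    ref_groups: dict[tuple, set[str]] = {}
    der_groups: dict[tuple, list[tuple[str, float, str]]] = {}
    for row in table.frame.itertuples(index=False):
        key = group_key(row.species, row.gene_id, row.family_id)
        if row.species == reference_species:
            ref_groups.setdefault(key, set()).add(row.chromosome)
        elif row.species == derived_species:
            der_groups.setdefault(key, []).append(
                (row.chromosome, row.pos_mb, row.gene_id)
            )

    # cohort = orthology groups sharing one reference chromosome; their
    # derived placements reveal which genes left the block
    cohorts: dict[str, list[tuple[tuple, str, float, str]]] = {}
    cohort_counts: dict[str, dict[str, int]] = {}
    for key, placements in sorted(der_groups.items()):
        if key not in ref_groups or len(ref_groups[key]) != 1:
            continue
        ref_chrom = next(iter(ref_groups[key]))
        for chrom, pos, gene in placements:
            cohorts.setdefault(ref_chrom, []).append((key, chrom, pos, gene))
            by_ref = cohort_counts.setdefault(chrom, {})
            by_ref[ref_chrom] = by_ref.get(ref_chrom, 0) + 1

    def dominant_cohort(derived_chrom: str) -> str:
        counts = cohort_counts[derived_chrom]
        return max(sorted(counts), key=lambda r: counts[r])

    moved: dict[str, list[tuple[float, str, str, str]]] = {}
    for ref_chrom in sorted(cohorts):
        entries = cohorts[ref_chrom]
        chroms = sorted({c for _, c, _, _ in entries})
        if len(chroms) < 2:
            continue
        counts = {
            c: sum(1 for _, cc, _, _ in entries if cc == c) for c in chroms
        }
        # the in-place chromosome is the strongest one this cohort dominates
        candidates = [c for c in chroms if dominant_cohort(c) == ref_chrom]
        pool = candidates or chroms
        in_place = max(sorted(pool), key=lambda c: counts[c])
        for key, chrom, pos, gene in entries:
            if chrom != in_place:
                moved.setdefault(chrom, []).append(
                    (pos, key[0], gene, ref_chrom)
                )

    calls: list[RearrangementCall] = []
    for chrom in sorted(moved):
        entries = sorted(moved[chrom])
        clusters: list[list[tuple[float, str, str, str]]] = [[entries[0]]]
        for entry in entries[1:]:
            if entry[0] - clusters[-1][-1][0] <= block_window_mb:
                clusters[-1].append(entry)
            else:
                clusters.append([entry])
        for cluster in clusters:
            fams = tuple(sorted({fam for _, fam, _, _ in cluster}))
            ref_chroms = tuple(sorted({rc for _, _, _, rc in cluster}))
            regions = tuple(
                sorted(
                    {(derived_species, chrom)}
                    | {(reference_species, rc) for rc in ref_chroms}
                )
            )
            interval = (
                derived_species,
                chrom,
                cluster[0][0],
                cluster[-1][0],
            )
            calls.append(
                RearrangementCall(
                    kind="translocation",
                    regions=regions,
                    timing="indeterminate",
                    evidence_families=fams,
                    interval=interval,
                    payload={
                        "genes": [g for _, _, g, _ in cluster],
                        "block": len(fams) >= min_block_families,
                    },
                )
            )
    return calls


# ---------------------------------------------------------------------------
# scenario reconstruction


def _strip_wgd_suffix(gene: str, label: str) -> str | None:
    lab = _sanitize(label)
    for i in (0, 1):
        suffix = f"_{lab}{i}"
        if gene.endswith(suffix):
            return gene[: -len(suffix)]
    return None


def reconstruct_scenario(
    calls: list[RearrangementCall],
    paralogons: list[Paralogon],
    species_tree: SpeciesTree,
    ancestor: Genome | None = None,
    genomes: dict[str, Genome] | None = None,
    three_r_label: str = "3R",
) -> EventHistory:
    """Order rearrangement calls into a replayable event narrative.

    WGD events come from the species tree's markers in branch-major
    pre-order; before_3R fusions are placed on the 3R-carrying branch ahead
    of the 3R event and after_3R events behind it. When the ancestral
    genome and tip genomes are supplied (simulator truth mode, noiseless),
    event payloads — fusion partners/orientation and fission breakpoints —
    are recovered from the lineage-stable identifiers of the simulator's
    serialization, so the history replays to the observed tip genomes.
    Calls whose payloads cannot be recovered are kept as flagged, unordered
    notes rather than silently dropped.
    """
    # conflict check: one region set dated both before and after 3R
    by_regions: dict[tuple, set[str]] = {}
    for call in calls:
        by_regions.setdefault(call.regions, set()).add(call.timing)
    conflicts = [
        regions
        for regions, timings in by_regions.items()
        if {"before_3R", "after_3R"} <= timings
    ]
    if conflicts:
        raise ParalogonError(
            "contradictory timing (before and after 3R) for regions: "
            + "; ".join(map(str, conflicts))
        )

    history = EventHistory()
    history.notes = []  # type: ignore[attr-defined]

    marker3 = next(
        (m for m in species_tree.wgd_markers if m.label == three_r_label),
        None,
    )
    branch3 = marker3.above if marker3 else None
    before = [c for c in calls if c.timing == "before_3R"]
    after = [c for c in calls if c.timing == "after_3R"]
    other = [c for c in calls if c.timing == "indeterminate"]

    truth_mode = ancestor is not None and genomes is not None
    state = _State.from_genome(ancestor) if truth_mode else None

    def recover_fusions(call: RearrangementCall) -> list[EvoEvent]:
        """Map a fused observed chromosome back onto pre-3R chromosomes."""
        assert state is not None and genomes is not None and branch3
        pre_chrom_of = {
            g: c for c, genes in state.chromosomes.items() for g in genes
        }
        for species, chrom in call.regions:
            if not species_tree.has_wgd_in_ancestry(species, three_r_label):
                continue
            genome = genomes.get(species)
            if genome is None:
                continue
            stripped = []
            ok = True
            for locus in genome.loci_on(chrom):
                base = _strip_wgd_suffix(locus.gene_id, three_r_label)
                if base is None or base not in pre_chrom_of:
                    ok = False
                    break
                stripped.append(base)
            if not ok or not stripped:
                continue
            # contiguous source-chromosome segments
            segments: list[tuple[str, list[str]]] = []
            for gene in stripped:
                src = pre_chrom_of[gene]
                if segments and segments[-1][0] == src:
                    segments[-1][1].append(gene)
                else:
                    segments.append((src, [gene]))
            if len(segments) < 2:
                continue
            # every segment must cover its complete source chromosome
            complete = all(
                genes == state.chromosomes[src]
                or genes == state.chromosomes[src][::-1]
                for src, genes in segments
            )
            if not complete:
                continue
            events = []
            left_name, left_genes = segments[0]
            if left_genes != state.chromosomes[left_name]:
                continue  # left segment inverted: not representable as-is
            for src, genes in segments[1:]:
                flipped = genes == state.chromosomes[src][::-1] and (
                    genes != state.chromosomes[src]
                )
                name = f"{left_name}+{src}"
                events.append(
                    EvoEvent(
                        "chromosome_fusion",
                        branch3,
                        {
                            "left": left_name,
                            "right": src,
                            "flip_right": bool(flipped),
                            "name": name,
                        },
                    )
                )
                left_name = name
            return events
        return []

    def recover_post3r() -> list[EvoEvent]:
        """Diff expected post-3R chromosomes against observed genomes to
        recover shared fissions."""
        assert state is not None and genomes is not None and branch3
        events: list[EvoEvent] = []
        species3 = [
            sp
            for sp in sorted(genomes)
            if species_tree.has_wgd_in_ancestry(sp, three_r_label)
        ]
        if not species3:
            return events
        sp = species3[0]
        genome = genomes[sp]
        gene_chrom = {l.gene_id: l.chromosome for l in genome}
        observed = {
            c: [l.gene_id for l in genome.loci_on(c)]
            for c in genome.chromosomes
        }
        for chrom in list(state.chromosomes):
            expected = state.chromosomes[chrom]
            if not expected:
                continue
            obs_chroms = []
            for g in expected:
                oc = gene_chrom.get(g)
                if oc is None:
                    obs_chroms = None
                    break
                if not obs_chroms or obs_chroms[-1] != oc:
                    obs_chroms = obs_chroms + [oc] if obs_chroms else [oc]
            if obs_chroms is None:
                history.notes.append(  # type: ignore[attr-defined]
                    f"unresolved: genes of {chrom} missing in {sp}"
                )
                continue
            if len(obs_chroms) == 1:
                continue
            if len(obs_chroms) == 2:
                a, b = obs_chroms
                k = len(observed[a])
                if (
                    observed[a] == expected[:k]
                    and observed[b] == expected[k:]
                ):
                    events.append(
                        EvoEvent(
                            "chromosome_fission",
                            branch3,
                            {"chromosome": chrom, "index": k},
                        )
                    )
                    continue
            history.notes.append(  # type: ignore[attr-defined]
                f"unresolved rearrangement of {chrom} in {sp} "
                f"(observed on {obs_chroms})"
            )
        return events

    def on_lineage_to_3r(name: str) -> bool:
        return branch3 is not None and species_tree.is_ancestor_or_equal(
            name, branch3
        )

    for node in species_tree.preorder():
        if node.parent is None:
            continue
        for marker in species_tree.markers_on(node.name):
            if marker.label == three_r_label and truth_mode:
                for call in before:
                    for event in recover_fusions(call):
                        history.append(event)
                        apply_event(state, event, index=len(history) - 1)
            elif marker.label == three_r_label and before:
                history.notes.append(  # type: ignore[attr-defined]
                    "unordered before_3R group (no ancestral genome): "
                    + "; ".join(str(c.regions) for c in before)
                )
            event = EvoEvent("wgd", node.name, {"label": marker.label})
            history.append(event)
            if truth_mode and on_lineage_to_3r(node.name):
                apply_event(state, event, index=len(history) - 1)
        if truth_mode and branch3 == node.name:
            for event in recover_post3r():
                history.append(event)
                apply_event(state, event, index=len(history) - 1)
    for call in other + (after if not truth_mode else []):
        history.notes.append(  # type: ignore[attr-defined]
            f"unordered {call.timing} {call.kind} on {call.regions} "
            f"({len(call.evidence_families)} families)"
        )
    return history
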