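"""Genome evolution simulator and event-history replay.

Genomes evolve along a species tree under whole-genome duplication (with
per-copy ohnolog retention), gene loss, chromosome fusion/fission, block
translocation, intrachromosomal shuffling and lineage-restricted tandem
duplication. The simulator records every applied event in an
:class:`EventHistory` (the *truth log*) and maintains the true gene tree of
every family; replaying the truth log through :func:`replay_events`
reproduces the simulated tip genomes exactly, because simulation and replay
share one event-application engine.

Coordinates are re-spaced uniformly after every event (fixed 1 Mb
inter-gene spacing): the downstream inference stages use only gene order
and co-location, never exact base pairs.

Identifier conventions (relied on by scenario reconstruction in truth mode):
a WGD with label ``L`` renames chromosome ``c`` to ``c_L0``/``c_L1`` and
gene ``g`` to ``g_L0``/``g_L1``; a fusion of ``a`` and ``b`` is named
``a+b``; a fission of ``c`` yields ``c_f0``/``c_f1``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy
import numpy as np

from .errors import ConfigurationError, ParalogonError, ReplayError
from .genome_model import MB, Chromosome, GeneLocus, Genome
from .species_tree import SNode, SpeciesTree

GENE_SPACING_BP = MB
GENE_LENGTH_BP = 1_000

EVENT_KINDS = {
    "wgd",
    "gene_loss",
    "chromosome_fusion",
    "chromosome_fission",
    "block_translocation",
    "intra_shuffle",
    "lineage_duplication",
}


def _sanitize(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]", "", label)


# ---------------------------------------------------------------------------
# events


@dataclass(frozen=True)
class EvoEvent:
    """A single evolutionary event on a species-tree branch.

    ``branch`` names the child node of the branch the event applies on;
    ``payload`` holds event-specific parameters with all defaults filled in
    (canonical form), so two histories compare field by field.
    """

    kind: str
    branch: str
    payload: dict

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "branch": self.branch, "payload": self.payload},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "EvoEvent":
        obj = json.loads(line)
        return cls(obj["kind"], obj["branch"], obj["payload"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvoEvent):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.branch == other.branch
            and self.payload == other.payload
        )


class EventHistory:
    """Ordered list of events, root-to-tip within each lineage."""

    def __init__(self, events: Iterable[EvoEvent] = ()):
        self.events: list[EvoEvent] = list(events)

    def append(self, event: EvoEvent) -> None:
        self.events.append(event)

    def __iter__(self) -> Iterator[EvoEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventHistory):
            return NotImplemented
        return self.events == other.events

    def on_branch(self, branch: str) -> list[EvoEvent]:
        return [e for e in self.events if e.branch == branch]

    def to_jsonl(self) -> str:
        return "".join(e.to_json() + "\n" for e in self.events)

    @classmethod
    def from_jsonl(cls, text: str) -> "EventHistory":
        return cls(
            EvoEvent.from_json(line)
            for line in text.splitlines()
            if line.strip()
        )


@dataclass
class PlantedEvent:
    """A deterministic event injected into a simulation.

    ``before_wgd`` names a WGD label on the same branch that the event must
    precede; otherwise the event applies after all of the branch's WGDs.
    Payload entries may be the string ``"random"``; they are resolved,
    reproducibly, from the simulation's random generator and the resolved
    values are logged in the truth history.
    """

    kind: str
    branch: str
    payload: dict = field(default_factory=dict)
    before_wgd: str | None = None


# ---------------------------------------------------------------------------
# mutable genome state shared by simulation and replay


class _State:
    """Ordered chromosomes -> ordered gene-id lists, plus gene -> family."""

    def __init__(self) -> None:
        self.chromosomes: dict[str, list[str]] = {}
        self.families: dict[str, str] = {}

    def copy(self) -> "_State":
        out = _State()
        out.chromosomes = {c: list(g) for c, g in self.chromosomes.items()}
        out.families = dict(self.families)
        return out

    @classmethod
    def from_genome(cls, genome: Genome) -> "_State":
        state = cls()
        for name in genome.chromosomes:
            state.chromosomes[name] = [
                l.gene_id for l in genome.loci_on(name)
            ]
        for locus in genome:
            state.families[locus.gene_id] = locus.family_id
        return state

    def chromosome_of(self, gene: str) -> str:
        for chrom, genes in self.chromosomes.items():
            if gene in genes:
                return chrom
        raise KeyError(gene)

    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def to_genome(self, species: str) -> Genome:
        genome = Genome(species)
        for chrom, genes in self.chromosomes.items():
            length = (len(genes) + 1) * GENE_SPACING_BP
            genome.add_chromosome(Chromosome(chrom, length, placed=True))
            for i, gene in enumerate(genes):
                start = GENE_SPACING_BP // 2 + i * GENE_SPACING_BP
                genome.add_locus(
                    GeneLocus(
                        gene_id=gene,
                        family_id=self.families[gene],
                        species=species,
                        chromosome=chrom,
                        start=start,
                        end=start + GENE_LENGTH_BP,
                        strand="+",
                    )
                )
        return genome


class _Hooks:
    """Callbacks used by the simulator to grow the true gene trees."""

    def on_duplicate(self, gene: str, copies: list[str], tag: str | None,
                     depth: float) -> None:  # pragma: no cover - interface
        pass

    def on_loss(self, gene: str, depth: float) -> None:  # pragma: no cover
        pass


def apply_event(
    state: _State,
    event: EvoEvent,
    index: int | None = None,
    hooks: _Hooks | None = None,
    depth: float = 0.0,
) -> None:
    """Apply one event to ``state`` in place. Deterministic; raises
    :class:`ReplayError` naming the event index on a dangling reference."""

    def err(msg: str) -> ReplayError:
        where = f"event {index}" if index is not None else "event"
        return ReplayError(f"{where} ({event.kind} on {event.branch}): {msg}")

    p = event.payload
    if event.kind == "wgd":
        label = _sanitize(p["label"])
        new_chroms: dict[str, list[str]] = {}
        renames: dict[str, list[str]] = {}
        for chrom, genes in state.chromosomes.items():
            for i in (0, 1):
                copy_genes = [f"{g}_{label}{i}" for g in genes]
                new_chroms[f"{chrom}_{label}{i}"] = copy_genes
            for g in genes:
                renames[g] = [f"{g}_{label}0", f"{g}_{label}1"]
        state.chromosomes = new_chroms
        for old, copies in renames.items():
            fam = state.families.pop(old)
            for c in copies:
                state.families[c] = fam
            if hooks:
                hooks.on_duplicate(old, copies, p["label"], depth)
    elif event.kind == "gene_loss":
        gene = p["gene"]
        for chrom, genes in state.chromosomes.items():
            if gene in genes:
                genes.remove(gene)
                state.families.pop(gene)
                if hooks:
                    hooks.on_loss(gene, depth)
                return
        raise err(f"gene {gene!r} does not exist")
    elif event.kind == "chromosome_fusion":
        left, right = p["left"], p["right"]
        if left == right:
            raise err("cannot fuse a chromosome with itself")
        for c in (left, right):
            if c not in state.chromosomes:
                raise err(f"chromosome {c!r} does not exist")
        right_genes = state.chromosomes.pop(right)
        if p.get("flip_right", False):
            right_genes = right_genes[::-1]
        left_genes = state.chromosomes.pop(left)
        name = p.get("name") or f"{left}+{right}"
        state.chromosomes[name] = left_genes + right_genes
    elif event.kind == "chromosome_fission":
        chrom = p["chromosome"]
        if chrom not in state.chromosomes:
            raise err(f"chromosome {chrom!r} does not exist")
        genes = state.chromosomes.pop(chrom)
        k = p["index"]
        if not (0 < k < len(genes)):
            raise err(
                f"fission index {k} outside (0, {len(genes)}) on {chrom!r}"
            )
        state.chromosomes[f"{chrom}_f0"] = genes[:k]
        state.chromosomes[f"{chrom}_f1"] = genes[k:]
    elif event.kind == "block_translocation":
        src, dst = p["source"], p["dest"]
        for c in (src, dst):
            if c not in state.chromosomes:
                raise err(f"chromosome {c!r} does not exist")
        if src == dst:
            raise err("source and destination chromosomes must differ")
        genes = state.chromosomes[src]
        start, length = p["start"], p["length"]
        if length < 1 or start < 0 or start + length > len(genes):
            raise err(
                f"block [{start}, {start + length}) outside {src!r} "
                f"({len(genes)} genes)"
            )
        block = genes[start : start + length]
        del genes[start : start + length]
        if p.get("invert", False):
            block = block[::-1]
        at = p["at"]
        dest_genes = state.chromosomes[dst]
        if not (0 <= at <= len(dest_genes)):
            raise err(f"insertion point {at} outside {dst!r}")
        state.chromosomes[dst] = dest_genes[:at] + block + dest_genes[at:]
    elif event.kind == "intra_shuffle":
        chrom = p["chromosome"]
        if chrom not in state.chromosomes:
            raise err(f"chromosome {chrom!r} does not exist")
        genes = state.chromosomes[chrom]
        order = p["order"]
        if sorted(order) != list(range(len(genes))):
            raise err(f"order is not a permutation of 0..{len(genes) - 1}")
        state.chromosomes[chrom] = [genes[i] for i in order]
    elif event.kind == "lineage_duplication":
        gene = p["gene"]
        try:
            chrom = state.chromosome_of(gene)
        except KeyError:
            raise err(f"gene {gene!r} does not exist")
        n = 0
        while f"{gene}_d{n}" in state.families:
            n += 1
        new = f"{gene}_d{n}"
        genes = state.chromosomes[chrom]
        genes.insert(genes.index(gene) + 1, new)
        fam = state.families[gene]
        state.families[new] = fam
        if hooks:
            hooks.on_duplicate(gene, [gene, new], None, depth)
    else:  # pragma: no cover - guarded by EvoEvent.__post_init__
        raise err("unhandled kind")


# ---------------------------------------------------------------------------
# true gene trees


class TNode:
    __slots__ = ("parent", "children", "depth", "tag", "leaf_label", "dead")

    def __init__(self, parent: "TNode | None" = None):
        self.parent = parent
        self.children: list[TNode] = []
        self.depth: float | None = None
        self.tag: str | None = None  # WGD label for duplication nodes
        self.leaf_label: str | None = None
        self.dead = False


def _prune(node: TNode) -> TNode | None:
    """Drop dead/extinct subtrees and suppress unifurcations."""
    if node.leaf_label is not None:
        return node
    kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
    if node.dead or not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    for c in kept:
        c.parent = node
    return node


def _tnode_newick(node: TNode, parent_depth: float) -> str:
    length = (node.depth or 0.0) - parent_depth
    if node.leaf_label is not None:
        return f"{node.leaf_label}:{length:g}"
    inner = ",".join(_tnode_newick(c, node.depth or 0.0) for c in node.children)
    tag = _sanitize(node.tag) if node.tag and node.tag != "speciation" else ""
    return f"({inner}){tag}:{length:g}"


def tree_to_newick(root: TNode) -> str:
    if root.leaf_label is not None:
        return f"{root.leaf_label}:0;"
    inner = ",".join(
        _tnode_newick(c, root.depth or 0.0) for c in root.children
    )
    tag = _sanitize(root.tag) if root.tag and root.tag != "speciation" else ""
    return f"({inner}){tag};"


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimParams:
    """Simulation parameters.

    Rates are expected event counts per species-tree branch (Poisson
    sampled); ``ohnolog_retention_prob`` is the per-copy probability that a
    post-WGD gene copy survives, applied immediately after each WGD.
    """

    n_families: int = 30
    n_ancestral_chromosomes: int = 2
    ohnolog_retention_prob: float = 0.9
    fusion_rate: float = 0.0
    fission_rate: float = 0.0
    translocation_rate: float = 0.0
    translocation_block_geom_p: float = 0.5
    shuffle_intensity: float = 0.0
    lineage_duplication_rate: float = 0.0
    seed: int = 0
    planted_events: list[PlantedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ohnolog_retention_prob <= 1.0):
            raise ConfigurationError("retention probability must be in [0,1]")
        if not (0.0 < self.translocation_block_geom_p <= 1.0):
            raise ConfigurationError("geometric block parameter in (0,1]")
        for rate_name in (
            "fusion_rate",
            "fission_rate",
            "translocation_rate",
            "shuffle_intensity",
            "lineage_duplication_rate",
        ):
            if getattr(self, rate_name) < 0:
                raise ConfigurationError(f"{rate_name} must be >= 0")
        if self.n_families < 1 or self.n_ancestral_chromosomes < 1:
            raise ConfigurationError("need >= 1 family and chromosome")


@dataclass
class SimResult:
    """Everything a simulation produced: tip genomes, true gene trees
    (newick, WGD duplication nodes tagged with their labels), the truth
    event log, the ohnolog map and the ancestral genome."""

    species_tree: SpeciesTree
    params: SimParams
    genomes: dict[str, Genome]
    gene_trees: dict[str, str]
    truth: EventHistory
    ohnolog_map: dict[str, dict]
    ancestor: Genome
    node_genomes: dict[str, Genome]

    def serialize(self) -> dict[str, str]:
        """Deterministic text serialization (filename -> content)."""
        from .io_tables import genome_to_tsv

        out: dict[str, str] = {}
        for species in sorted(self.genomes):
            out[f"genome_{species}.tsv"] = genome_to_tsv(self.genomes[species])
        for family in sorted(self.gene_trees):
            out[f"tree_{family}.nwk"] = self.gene_trees[family] + "\n"
        out["truth.jsonl"] = self.truth.to_jsonl()
        out["ohnolog_map.json"] = json.dumps(self.ohnolog_map, sort_keys=True)
        return out

    def to_dir(self, path) -> None:
        import pathlib

        root = pathlib.Path(path)
        root.mkdir(parents=True, exist_ok=True)
        for name, text in self.serialize().items():
            (root / name).write_text(text)


class _TreeHooks(_Hooks):
    def __init__(self, live: dict[str, TNode], meta: dict[str, dict]):
        self.live = live
        self.meta = meta

    def on_duplicate(self, gene, copies, tag, depth) -> None:
        node = self.live.pop(gene)
        node.depth = depth
        node.tag = tag if tag is not None else "dup"
        info = self.meta.pop(gene)
        for i, copy in enumerate(copies):
            tip = TNode(parent=node)
            node.children.append(tip)
            self.live[copy] = tip
            path = list(info["wgd_path"])
            if tag is not None:
                path.append([tag, i])
            self.meta[copy] = {**info, "wgd_path": path}

    def on_loss(self, gene, depth) -> None:
        node = self.live.pop(gene)
        node.dead = True
        self.meta.pop(gene)


def _resolve_payload(
    kind: str,
    payload: dict,
    state: _State,
    rng: np.random.Generator,
    geom_p: float = 0.5,
) -> dict | None:
    """Fill 'random' placeholders / missing fields; None if inapplicable."""
    p = dict(payload)
    chroms = list(state.chromosomes)
    if kind == "chromosome_fusion":
        if len(chroms) < 2:
            return None
        left = p.get("left", "random")
        right = p.get("right", "random")
        if left == "random" or right == "random":
            i, j = rng.choice(len(chroms), size=2, replace=False)
            if left == "random":
                left = chroms[int(i)]
            if right == "random":
                right = chroms[int(j)]
        if left == right:
            return None
        p["left"], p["right"] = left, right
        p.setdefault("flip_right", False)
        p.setdefault("name", f"{left}+{right}")
    elif kind == "chromosome_fission":
        candidates = [c for c in chroms if len(state.chromosomes[c]) >= 2]
        if p.get("chromosome", "random") == "random":
            if not candidates:
                return None
            p["chromosome"] = candidates[int(rng.integers(len(candidates)))]
        if p.get("index", "random") == "random":
            n = len(state.chromosomes[p["chromosome"]])
            if n < 2:
                return None
            p["index"] = int(rng.integers(1, n))
    elif kind == "block_translocation":
        if len(chroms) < 2:
            return None
        if p.get("source", "random") == "random":
            nonempty = [c for c in chroms if state.chromosomes[c]]
            if not nonempty:
                return None
            p["source"] = nonempty[int(rng.integers(len(nonempty)))]
        if p.get("dest", "random") == "random":
            others = [c for c in chroms if c != p["source"]]
            p["dest"] = others[int(rng.integers(len(others)))]
        n_src = len(state.chromosomes[p["source"]])
        if n_src == 0:
            return None
        if p.get("length", "random") == "random":
            p["length"] = min(int(rng.geometric(geom_p)), n_src)
        if p.get("start", "random") == "random":
            p["start"] = int(rng.integers(0, n_src - p["length"] + 1))
        if p.get("at", "random") == "random":
            p["at"] = int(rng.integers(0, len(state.chromosomes[p["dest"]]) + 1))
        p.setdefault("invert", False)
    elif kind == "intra_shuffle":
        if p.get("chromosome", "random") == "random":
            candidates = [c for c in chroms if len(state.chromosomes[c]) >= 2]
            if not candidates:
                return None
            p["chromosome"] = candidates[int(rng.integers(len(candidates)))]
        if p.get("order", "random") == "random":
            n = len(state.chromosomes[p["chromosome"]])
            p["order"] = [int(x) for x in rng.permutation(n)]
    elif kind == "lineage_duplication":
        if p.get("gene", "random") == "random":
            genes = [g for c in chroms for g in state.chromosomes[c]]
            if not genes:
                return None
            p["gene"] = genes[int(rng.integers(len(genes)))]
    return p


def simulate_history(tree: SpeciesTree, params: SimParams) -> SimResult:
    """Evolve an ancestral genome along ``tree`` under ``params``.

    Deterministic given ``params.seed``. Every sampled event (including the
    per-copy retention losses that follow each WGD) is appended to the truth
    history in applied order, branch-major pre-order.
    """
    if len(tree.leaves) < 2:
        raise ConfigurationError("species tree needs >= 2 extant taxa")
    for marker in tree.wgd_markers:
        if tree.node(marker.above).length <= 0:
            raise ConfigurationError(
                f"WGD {marker.label!r} sits on a zero-length branch"
            )

    rng = np.random.default_rng(params.seed)

    # ancestral genome: families round-robin over chromosomes
    state = _State()
    n_chrom = params.n_ancestral_chromosomes
    for c in range(n_chrom):
        state.chromosomes[f"A{c}"] = []
    meta: dict[str, dict] = {}
    live: dict[str, TNode] = {}
    family_roots: dict[str, TNode] = {}
    for i in range(params.n_families):
        fam = f"F{i:03d}"
        chrom = f"A{i % n_chrom}"
        state.chromosomes[chrom].append(fam)
        state.families[fam] = fam
        root = TNode()
        family_roots[fam] = root
        live[fam] = root
        meta[fam] = {
            "family": fam,
            "wgd_path": [],
            "ancestral_chromosome": chrom,
        }

    truth = EventHistory()
    genomes: dict[str, Genome] = {}
    node_genomes: dict[str, Genome] = {}
    ohnolog_map: dict[str, dict] = {}
    ancestor = state.to_genome("ancestor")

    def emit(kind: str, branch: str, payload: dict, st: _State,
             hooks: _TreeHooks, depth: float) -> None:
        event = EvoEvent(kind, branch, payload)
        apply_event(st, event, index=len(truth), hooks=hooks, depth=depth)
        truth.append(event)

    def run_branch(node: SNode, st: _State, lv: dict, mt: dict) -> None:
        hooks = _TreeHooks(lv, mt)
        branch = node.name
        parent_depth = node.parent.depth if node.parent else 0.0
        markers = tree.markers_on(branch)
        planted = [p for p in params.planted_events if p.branch == branch]
        used: set[int] = set()

        def plant(pl: PlantedEvent, depth: float) -> None:
            payload = _resolve_payload(pl.kind, pl.payload, st, rng)
            if payload is None:
                return
            emit(pl.kind, branch, payload, st, hooks, depth)

        for marker in markers:
            depth = parent_depth + marker.position * node.length
            for i, pl in enumerate(planted):
                if i not in used and pl.before_wgd == marker.label:
                    used.add(i)
                    plant(pl, depth)
            emit("wgd", branch, {"label": marker.label}, st, hooks, depth)
            # immediate per-copy retention
            if params.ohnolog_retention_prob < 1.0:
                fresh = [
                    g
                    for genes in st.chromosomes.values()
                    for g in genes
                ]
                keep = rng.random(len(fresh)) < params.ohnolog_retention_prob
                for g, k in zip(fresh, keep):
                    if not k:
                        emit("gene_loss", branch, {"gene": g}, st, hooks, depth)
        late_depth = parent_depth + 0.9 * node.length
        for i, pl in enumerate(planted):
            if i not in used:
                if pl.before_wgd is not None:
                    raise ConfigurationError(
                        f"planted event expects WGD {pl.before_wgd!r} on "
                        f"branch {branch!r}, which carries no such marker"
                    )
                plant(pl, late_depth)
        for kind, rate in (
            ("chromosome_fusion", params.fusion_rate),
            ("chromosome_fission", params.fission_rate),
            ("block_translocation", params.translocation_rate),
            ("lineage_duplication", params.lineage_duplication_rate),
        ):
            for _ in range(int(rng.poisson(rate))):
                payload = _resolve_payload(
                    kind, {}, st, rng,
                    geom_p=params.translocation_block_geom_p,
                )
                if payload is not None:
                    emit(kind, branch, payload, st, hooks, late_depth)
        for _ in range(int(rng.poisson(params.shuffle_intensity))):
            payload = _resolve_payload("intra_shuffle", {}, st, rng)
            if payload is not None:
                emit("intra_shuffle", branch, payload, st, hooks, late_depth)

    def recurse(node: SNode, st: _State, lv: dict, mt: dict) -> None:
        if node.parent is not None:
            run_branch(node, st, lv, mt)
        node_genomes[node.name] = st.to_genome(node.name)
        if node.is_leaf:
            genomes[node.name] = st.to_genome(node.name)
            for gene, tnode in lv.items():
                tnode.leaf_label = f"{node.name}|{gene}"
                tnode.depth = node.depth
                ohnolog_map[tnode.leaf_label] = {
                    "species": node.name,
                    "gene": gene,
                    "family": mt[gene]["family"],
                    "wgd_path": mt[gene]["wgd_path"],
                    "ancestral_chromosome": mt[gene]["ancestral_chromosome"],
                }
            return
        if len(node.children) == 1:
            recurse(node.children[0], st, lv, mt)
            return
        # speciation: close current tips, open one tip per child lineage
        child_tips: list[dict[str, TNode]] = [dict() for _ in node.children]
        for gene, tnode in lv.items():
            tnode.depth = node.depth
            tnode.tag = "speciation"
            for tips in child_tips:
                tip = TNode(parent=tnode)
                tnode.children.append(tip)
                tips[gene] = tip
        for child, tips in zip(node.children, child_tips):
            recurse(child, st.copy(), tips, {g: dict(m, wgd_path=list(m["wgd_path"])) for g, m in mt.items()})

    recurse(tree.root, state, live, meta)

    gene_trees: dict[str, str] = {}
    for fam, root in family_roots.items():
        pruned = _prune(root)
        if pruned is not None:
            pruned.parent = None
            gene_trees[fam] = tree_to_newick(pruned)

    return SimResult(
        species_tree=tree,
        params=params,
        genomes=genomes,
        gene_trees=gene_trees,
        truth=truth,
        ohnolog_map=ohnolog_map,
        ancestor=ancestor,
        node_genomes=node_genomes,
    )


# ---------------------------------------------------------------------------
# replay


def _replay_states(
    history: EventHistory, ancestral: Genome, tree: SpeciesTree
) -> dict[str, _State]:
    """State at every species-tree node after applying its branch prefix."""
    indexed: dict[str, list[tuple[int, EvoEvent]]] = {}
    for i, ev in enumerate(history):
        indexed.setdefault(ev.branch, []).append((i, ev))
    known = set(tree.nodes)
    for ev in history:
        if ev.branch not in known:
            raise ReplayError(
                f"event references unknown species-tree branch {ev.branch!r}"
            )
    states: dict[str, _State] = {}

    def recurse(node: SNode, st: _State) -> None:
        if node.parent is not None:
            for i, ev in indexed.get(node.name, []):
                apply_event(st, ev, index=i)
        states[node.name] = st
        for child in node.children:
            recurse(child, st.copy())

    recurse(tree.root, _State.from_genome(ancestral))
    return states


def replay_events(
    history: EventHistory, ancestral: Genome, tree: SpeciesTree
) -> dict[str, Genome]:
    """Deterministically replay an event history from the ancestral genome,
    returning one genome per species-tree tip."""
    states = _replay_states(history, ancestral, tree)
    return {
        leaf.name: states[leaf.name].to_genome(leaf.name)
        for leaf in tree.leaves
    }


def state_at(
    history: EventHistory, ancestral: Genome, tree: SpeciesTree, node: str
) -> Genome:
    """Genome state at a named species-tree node (after the events on the
    branch above it)."""
    states = _replay_states(history, ancestral, tree)
    if node not in states:
        raise ConfigurationError(f"unknown species-tree node {node!r}")
    return states[node].to_genome(node)


# ---------------------------------------------------------------------------
# gene-tree perturbation


def perturb_gene_tree(newick: str, n_nni: int, seed: int) -> str:
    """Apply ``n_nni`` random nearest-neighbor interchanges to a rooted
    newick gene tree (leaf set preserved; same seed, same output)."""
    if n_nni < 0:
        raise ParalogonError("n_nni must be >= 0")
    tree = dendropy.Tree.get(
        data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
    )
    n_leaves = len(tree.leaf_nodes())
    if n_nni > 0 and n_leaves < 4:
        raise ParalogonError(
            f"NNI needs >= 4 leaves, tree has {n_leaves}"
        )
    if n_nni == 0:
        return newick
    rng = np.random.default_rng(seed)
    for _ in range(n_nni):
        internal = [
            nd
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
            and not nd.is_leaf()
            and len(nd.parent_node.child_nodes()) >= 2
        ]
        if not internal:
            break
        v = internal[int(rng.integers(len(internal)))]
        u = v.parent_node
        siblings = [c for c in u.child_nodes() if c is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        vchildren = v.child_nodes()
        c = vchildren[int(rng.integers(len(vchildren)))]
        u.remove_child(s)
        v.remove_child(c)
        u.add_child(c)
        v.add_child(s)
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return out
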