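"""Rooted species tree with named divergence nodes and WGD placements.

The tree is read from newick (internal node labels name the divergences,
e.g. ``gar_teleost_split``) and whole-genome duplications are placed on
branches by naming the child node of the branch that carries them. Relative
dating windows are expressed between two named nodes of this tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from io import StringIO
from typing import Iterable

import dendropy
import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class WgdMarker:
    """A whole-genome duplication on the branch *above* the named node.

    ``position`` in (0, 1) orders multiple markers along one branch and sets
    the relative depth of the duplication nodes in simulated gene trees.
    """

    label: str
    above: str
    position: float = 0.5


class SNode:
    __slots__ = ("name", "parent", "children", "length", "depth")

    def __init__(self, name: str, length: float = 1.0):
        self.name = name
        self.parent: SNode | None = None
        self.children: list[SNode] = []
        self.length = length
        self.depth = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"SNode({self.name})"


class SpeciesTree:
    """Rooted species tree with unique node names and WGD markers."""

    def __init__(self, root: SNode, wgd_markers: Iterable[WgdMarker] = ()):
        self.root = root
        self.nodes: dict[str, SNode] = {}
        self._index(root, 0.0)
        self.wgd_markers: list[WgdMarker] = []
        for marker in wgd_markers:
            self.add_wgd(marker)

    def _index(self, node: SNode, depth: float) -> None:
        node.depth = depth
        if node.name in self.nodes:
            raise ConfigurationError(f"duplicate node name {node.name!r}")
        self.nodes[node.name] = node
        for child in node.children:
            self._index(child, depth + child.length)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(
        cls, newick: str, wgd_markers: Iterable[WgdMarker] = ()
    ) -> "SpeciesTree":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
        counter = [0]

        def convert(dnode) -> SNode:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            if label is None:
                counter[0] += 1
                label = f"node{counter[0]}"
            snode = SNode(label, dnode.edge.length or 1.0)
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.parent = snode
                snode.children.append(cnode)
            return snode

        return cls(convert(dtree.seed_node), wgd_markers)

    @classmethod
    def from_config(cls, config: dict) -> "SpeciesTree":
        """Build from a mapping with keys ``newick`` and optional ``wgd``
        (list of mappings with ``label``, ``above`` and optional
        ``position``)."""
        try:
            newick = config["newick"]
        except KeyError:
            raise ConfigurationError("species tree config lacks 'newick'")
        markers = [
            WgdMarker(
                label=m["label"],
                above=m["above"],
                position=float(m.get("position", 0.5)),
            )
            for m in config.get("wgd", [])
        ]
        return cls.from_newick(newick, markers)

    @classmethod
    def from_yaml(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))

    def add_wgd(self, marker: WgdMarker) -> None:
        if marker.above not in self.nodes:
            raise ConfigurationError(
                f"WGD {marker.label!r} placed above unknown node "
                f"{marker.above!r}"
            )
        if self.nodes[marker.above] is self.root:
            raise ConfigurationError(
                f"WGD {marker.label!r} placed on the root, which has no "
                "branch above it"
            )
        if any(m.label == marker.label for m in self.wgd_markers):
            raise ConfigurationError(f"duplicate WGD label {marker.label!r}")
        if not (0.0 < marker.position < 1.0):
            raise ConfigurationError(
                f"WGD {marker.label!r}: position must lie strictly inside "
                "the branch"
            )
        self.wgd_markers.append(marker)

    # -- queries -----------------------------------------------------------
    @property
    def leaves(self) -> list[SNode]:
        out: list[SNode] = []

        def walk(node: SNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    @property
    def taxa(self) -> list[str]:
        return [leaf.name for leaf in self.leaves]

    def node(self, name: str) -> SNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise ConfigurationError(f"unknown species-tree node {name!r}")

    def path_to_root(self, name: str) -> list[SNode]:
        node: SNode | None = self.node(name)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    def is_ancestor_or_equal(self, ancestor: str, descendant: str) -> bool:
        anc = self.node(ancestor)
        return any(n is anc for n in self.path_to_root(descendant))

    def is_proper_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor != descendant and self.is_ancestor_or_equal(
            ancestor, descendant
        )

    def lca(self, names: Iterable[str]) -> SNode:
        names = list(names)
        if not names:
            raise ConfigurationError("lca of empty set")
        common: list[SNode] | None = None
        for name in names:
            path = self.path_to_root(name)[::-1]  # root .. node
            if common is None:
                common = path
            else:
                keep = 0
                for a, b in zip(common, path):
                    if a is b:
                        keep += 1
                    else:
                        break
                common = common[:keep]
        assert common
        return common[-1]

    def markers_on(self, child_name: str) -> list[WgdMarker]:
        """WGD markers on the branch above ``child_name``, oldest first."""
        out = [m for m in self.wgd_markers if m.above == child_name]
        out.sort(key=lambda m: m.position)
        return out

    def wgd_labels_in_ancestry(self, species: str) -> list[str]:
        """Labels of WGDs on the root-to-leaf path of a species."""
        path_names = {n.name for n in self.path_to_root(species)}
        return [m.label for m in self.wgd_markers if m.above in path_names]

    def has_wgd_in_ancestry(self, species: str, label: str) -> bool:
        return label in self.wgd_labels_in_ancestry(species)

    def leaves_under(self, name: str) -> list[str]:
        node = self.node(name)
        out: list[str] = []

        def walk(n: SNode) -> None:
            if n.is_leaf:
                out.append(n.name)
            for child in n.children:
                walk(child)

        walk(node)
        return out

    def preorder(self) -> list[SNode]:
        out: list[SNode] = []

        def walk(node: SNode) -> None:
            out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: SNode) -> str:
            label = _quote_label(node.name)
            if node.is_leaf:
                return f"{label}:{node.length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:g}"

        return fmt(self.root) + ";"


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|+-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def parse_newick_string(newick: str) -> dendropy.Tree:
    """Convenience dendropy parse keeping internal labels as labels."""
    return dendropy.Tree.get(
        file=StringIO(newick),
        schema="newick",
        suppress_internal_node_taxa=True,
    )
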