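"""Molecular Characteristic Trees and the MP Interrelationships Network.

A Molecular Characteristic Tree (MCT) is a single-parent, shortest-path
spanning tree of a molecular interaction network rooted at one marker
molecule: every node keeps exactly one parent, chosen among the
neighbours that preserve the shortest path to the root (at random, from
a stated seed, when several qualify).  One MCT per marker makes up a
pathway's forest.

The MP Interrelationships Network (MPIN) has one node per pathway and an
edge wherever two pathways share at least one molecule.  The shared
molecule closest to both pathways' marker roots (the *lowest common
molecule*, ties broken by id) fixes the hierarchy: if its level x̄ in
pathway x's forest is smaller than its level ȳ in pathway y's forest,
an arrow runs from y to x and x is the more specific pathway; equal
levels leave the edge undirected.
"""
from __future__ import annotations

import logging
import random
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Pathway",
    "CharacteristicTree",
    "MPINEdge",
    "PathwayNetwork",
    "build_mct",
    "mct_forest",
    "molecule_level",
    "build_mpin",
]

#: Molecular interaction networks are undirected simple graphs with
#: molecule-id nodes; self-loops are rejected on validation.
MolecularNetwork = nx.Graph


def validate_network(network: nx.Graph) -> None:
    loops = list(nx.selfloop_edges(network))
    if loops:
        raise ValueError(f"molecular network has self-loops: {loops[:3]}")


@dataclass(frozen=True)
class Pathway:
    """A molecular pathway: its molecule set and designated markers."""

    id: str
    molecules: frozenset[str]
    markers: frozenset[str]

    def __post_init__(self):
        if not self.molecules:
            raise ValueError(f"pathway {self.id!r} has no molecules")
        if not self.markers <= self.molecules:
            extra = sorted(self.markers - self.molecules)
            raise ValueError(f"pathway {self.id!r}: markers {extra} not in molecule set")


@dataclass
class CharacteristicTree:
    """Single-parent shortest-path tree rooted at a marker molecule."""

    root: str
    parent: dict[str, str] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.depth)

    def __contains__(self, molecule: str) -> bool:
        return molecule in self.depth

    def validate(self) -> None:
        if self.depth.get(self.root) != 0 or self.root in self.parent:
            raise ValueError("root must have depth 0 and no parent")
        if len(self.parent) != len(self.depth) - 1:
            raise ValueError("every non-root node needs exactly one parent")
        for node, par in self.parent.items():
            if self.depth[node] != self.depth[par] + 1:
                raise ValueError(f"depth({node}) != depth({par}) + 1")
        # ancestor walk: acyclic and rooted
        for node in self.depth:
            seen = set()
            while node != self.root:
                if node in seen:
                    raise ValueError("parent map has a cycle")
                seen.add(node)
                node = self.parent[node]

    def to_indented(self) -> str:
        children: dict[str, list[str]] = {}
        for node, par in self.parent.items():
            children.setdefault(par, []).append(node)
        lines: list[str] = []

        def rec(node: str, indent: int) -> None:
            lines.append("  " * indent + node)
            for child in sorted(children.get(node, ())):
                rec(child, indent + 1)

        rec(self.root, 0)
        return "\n".join(lines)


def build_mct(
    network: nx.Graph,
    root: str,
    seed: int | None = None,
    deterministic: bool = False,
) -> CharacteristicTree:
    """Shortest-path single-parent tree over the component of ``root``.

    Each node's parent is a neighbour one level closer to the root;
    among several minimal parents one is drawn uniformly at random from
    ``seed`` (or the lexicographically smallest with
    ``deterministic=True``).  Depths equal breadth-first distances and
    therefore do not depend on the seed.
    """
    if root not in network:
        raise ValueError(f"root molecule {root!r} not in network")
    rng = random.Random(seed)
    depth = {root: 0}
    order = [root]
    queue = deque([root])
    while queue:
        node = queue.popleft()
        for nb in sorted(network.neighbors(node)):
            if nb not in depth:
                depth[nb] = depth[node] + 1
                order.append(nb)
                queue.append(nb)
    parent: dict[str, str] = {}
    for node in order[1:]:
        candidates = sorted(
            nb for nb in network.neighbors(node) if depth.get(nb) == depth[node] - 1)
        parent[node] = candidates[0] if deterministic else rng.choice(candidates)
    tree = CharacteristicTree(root=root, parent=parent, depth=depth)
    return tree


def mct_forest(
    pathway: Pathway,
    network: nx.Graph,
    seed: int | None = None,
    deterministic: bool = False,
) -> list[CharacteristicTree]:
    """One MCT per marker of the pathway, over the pathway's subnetwork.

    Trees are built on the subgraph induced by the pathway's molecules;
    molecules unreachable from every marker are excluded (logged).
    """
    if not pathway.markers:
        raise ValueError(f"pathway {pathway.id!r} has no markers")
    missing = sorted(m for m in pathway.markers if m not in network)
    if missing:
        raise ValueError(
            f"marker {missing[0]!r} of pathway {pathway.id!r} not in network")
    sub = network.subgraph(m for m in pathway.molecules if m in network)
    rng = random.Random(seed)
    forest = []
    for marker in sorted(pathway.markers):
        forest.append(build_mct(sub, marker, seed=rng.randrange(2**31),
                                deterministic=deterministic))
    covered = set().union(*(t.nodes for t in forest))
    dropped = pathway.molecules - covered
    if dropped:
        logger.info("pathway %s: %d molecule(s) unreachable from any marker "
                    "excluded from forests: %s", pathway.id, len(dropped),
                    sorted(dropped)[:5])
    return forest


def molecule_level(molecule: str, forest: Sequence[CharacteristicTree]) -> int:
    """Hierarchical level of a molecule: minimum depth over the forest."""
    depths = [t.depth[molecule] for t in forest if molecule in t]
    if not depths:
        raise ValueError(f"molecule {molecule!r} appears in no tree of the forest")
    return min(depths)


@dataclass(frozen=True)
class MPINEdge:
    """MPIN edge between pathways ``x`` and ``y`` (x < y by id).

    ``direction`` is ``"y->x"`` when x̄ < ȳ (x more specific),
    ``"x->y"`` when x̄ > ȳ, else ``"undirected"``.  ``n_com`` is the
    lowest common molecule; it is None when no shared molecule is
    reachable in both forests, in which case the edge stays undirected.
    """

    x: str
    y: str
    shared: frozenset[str]
    n_com: str | None
    x_bar: int | None
    y_bar: int | None
    direction: str

    @property
    def arrow(self) -> tuple[str, str] | None:
        """(source, target) of the hierarchy arrow, or None if undirected."""
        if self.direction == "y->x":
            return (self.y, self.x)
        if self.direction == "x->y":
            return (self.x, self.y)
        return None

    @property
    def more_specific(self) -> str | None:
        arrow = self.arrow
        return arrow[1] if arrow else None


@dataclass
class PathwayNetwork:
    """The MPIN: pathway nodes plus shared-molecule hierarchy edges."""

    pathways: list[str]
    edges: list[MPINEdge]

    def edge(self, a: str, b: str) -> MPINEdge | None:
        x, y = min(a, b), max(a, b)
        for e in self.edges:
            if (e.x, e.y) == (x, y):
                return e
        return None

    def arrows(self) -> list[tuple[str, str]]:
        return [e.arrow for e in self.edges if e.arrow is not None]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.pathways)
        for e in self.edges:
            attrs = dict(shared=",".join(sorted(e.shared)),
                         n_com=e.n_com or "",
                         x_bar=-1 if e.x_bar is None else e.x_bar,
                         y_bar=-1 if e.y_bar is None else e.y_bar,
                         direction=e.direction)
            if e.arrow is not None:
                g.add_edge(*e.arrow, **attrs)
            else:
                g.add_edge(e.x, e.y, **attrs)
                g.add_edge(e.y, e.x, **attrs)
        return g


def build_mpin(
    pathways: Sequence[Pathway],
    network: nx.Graph,
    seed: int | None = None,
    deterministic: bool = False,
) -> PathwayNetwork:
    """Build the MPIN from pathway molecule sets and their MCT forests.

    Pathways sharing at least one molecule get an edge.  The lowest
    common molecule minimizes x̄ + ȳ over shared molecules reachable in
    both forests (ties to the lexicographically smallest id); the arrow
    follows the x̄ < ȳ rule, and x̄ = ȳ leaves the edge undirected.
    """
    if len(pathways) < 2:
        raise ValueError("build_mpin needs at least two pathways")
    ids = [p.id for p in pathways]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pathway ids")
    validate_network(network)
    by_id = {p.id: p for p in pathways}
    rng = random.Random(seed)
    forests = {pid: mct_forest(by_id[pid], network, seed=rng.randrange(2**31),
                               deterministic=deterministic)
               for pid in sorted(by_id)}

    edges: list[MPINEdge] = []
    ordered = sorted(by_id)
    for i, x in enumerate(ordered):
        for y in ordered[i + 1:]:
            shared = by_id[x].molecules & by_id[y].molecules
            if not shared:
                continue
            candidates = []
            for mol in sorted(shared):
                try:
                    xb = molecule_level(mol, forests[x])
                    yb = molecule_level(mol, forests[y])
                except ValueError:
                    continue
                candidates.append((xb + yb, mol, xb, yb))
            if candidates:
                _, n_com, x_bar, y_bar = min(candidates)
                if x_bar < y_bar:
                    direction = "y->x"
                elif x_bar > y_bar:
                    direction = "x->y"
                else:
                    direction = "undirected"
            else:
                n_com, x_bar, y_bar, direction = None, None, None, "undirected"
            edges.append(MPINEdge(x, y, frozenset(shared), n_com,
                                  x_bar, y_bar, direction))
    return PathwayNetwork(pathways=sorted(ids), edges=edges)
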