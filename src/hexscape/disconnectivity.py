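"""Superbasin analysis and disconnectivity graphs.

At a threshold energy V the minima split into superbasins: two minima share
a basin iff they are joined by a path of transition states all with energy
at most V.  Sweeping V downwards in uniform steps ``delta_e`` from ``e_top``
and recording where basins split yields the disconnectivity tree, whose
leaves are the individual minima drawn at their own energies and whose
internal nodes are the superbasins at each threshold level.  Leaves can be
coloured by heat-capacity feature contribution sets for the standard
two-colour (growing/draining) visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .database import DatabaseError, StationaryPointDatabase
from .hsa import ContributionSet

__all__ = [
    "SuperbasinPartition",
    "TreeNode",
    "DisconnectivityTree",
    "superbasin_partition",
    "build_tree",
    "colour_leaves",
    "tree_to_dict",
    "plot_tree",
]


@dataclass
class SuperbasinPartition:
    """Threshold energy plus minimum-id -> basin-label mapping.

    Labels are deterministic: each basin is labelled by its smallest member id.
    """

    threshold: float
    labels: dict[int, int]

    def basins(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for mid, lab in self.labels.items():
            out.setdefault(lab, set()).add(mid)
        return out


def superbasin_partition(db: StationaryPointDatabase, threshold: float) -> SuperbasinPartition:
    """Union of minima over TS edges with energy <= threshold."""
    if not db.minima:
        raise DatabaseError("empty database")
    g = nx.Graph()
    g.add_nodes_from(db.minima_ids)
    for ts in db.transition_states:
        if ts.energy <= threshold:
            g.add_edge(ts.min1_id, ts.min2_id)
    labels: dict[int, int] = {}
    for comp in nx.connected_components(g):
        lab = min(comp)
        for mid in comp:
            labels[mid] = lab
    return SuperbasinPartition(threshold, labels)


@dataclass(eq=False)
class TreeNode:
    """One node of the disconnectivity tree.

    Internal nodes sit at a threshold level and hold a superbasin; leaves
    are single minima at their own energies.
    """

    energy: float
    minima: frozenset[int]
    children: list["TreeNode"] = field(default_factory=list)
    minimum_id: int | None = None  # set on leaves
    colour: str = "neutral"
    x: float = 0.0  # layout coordinate, assigned at build time

    @property
    def is_leaf(self) -> bool:
        return self.minimum_id is not None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class DisconnectivityTree:
    roots: list[TreeNode]
    delta_e: float
    e_top: float
    levels: np.ndarray

    def leaves(self) -> list[TreeNode]:
        out = []
        for r in self.roots:
            out.extend(r.leaves())
        return out


def build_tree(
    db: StationaryPointDatabase, delta_e: float | None = None, e_top: float | None = None
) -> DisconnectivityTree:
    """Disconnectivity tree from threshold sweeps at uniform spacing.

    ``e_top`` defaults to just above the highest transition state;
    ``delta_e`` to (e_top - global minimum)/50.  Nodes are placed at the
    lower threshold of each split (the standard drawing convention).
    """
    if not db.minima:
        raise DatabaseError("empty database")
    e_gm = db.global_minimum.energy
    ts_energies = [ts.energy for ts in db.transition_states]
    top_ts = max(ts_energies) if ts_energies else e_gm
    if e_top is None:
        e_top = top_ts + abs(top_ts) * 1e-9 + 1e-9
    if e_top < e_gm:
        raise DatabaseError("e_top below the global minimum")
    if delta_e is None:
        delta_e = (e_top - e_gm) / 50 if e_top > e_gm else 1.0
    if delta_e <= 0:
        raise DatabaseError("delta_e must be positive")

    n_levels = int(np.floor((e_top - e_gm) / delta_e)) + 1
    levels = e_top - delta_e * np.arange(n_levels)

    energies = {m.id: m.energy for m in db.minima}

    def alive(level: float) -> set[int]:
        return {mid for mid, e in energies.items() if e <= level}

    # nodes at the top level: one per superbasin
    part = superbasin_partition(db, levels[0])
    current: dict[int, TreeNode] = {}
    for lab, members in part.basins().items():
        members = frozenset(members & alive(levels[0]))
        if members:
            current[lab] = TreeNode(levels[0], members)
    roots = sorted(current.values(), key=lambda n: min(n.minima))

    for level in levels[1:]:
        part = superbasin_partition(db, level)
        live = alive(level)
        nxt: dict[int, TreeNode] = {}
        for lab, members in part.basins().items():
            members = frozenset(members & live)
            if members:
                nxt[lab] = TreeNode(level, members)
        for parent in current.values():
            kids = [n for n in nxt.values() if n.minima <= parent.minima]
            covered = frozenset().union(*[k.minima for k in kids]) if kids else frozenset()
            # minima whose energy lies above this level terminate as leaves
            for mid in sorted(parent.minima - covered):
                parent.children.append(
                    TreeNode(energies[mid], frozenset([mid]), minimum_id=mid)
                )
            if len(kids) == 1 and kids[0].minima == parent.minima:
                # basin intact: carry the node down so its final energy is the
                # lowest threshold at which its members still interconvert
                parent.energy = level
                nxt[min(kids[0].minima)] = parent
            else:
                parent.children.extend(sorted(kids, key=lambda n: min(n.minima)))
        current = nxt

    # whatever survives the lowest level terminates as leaves
    for parent in set(current.values()):
        if parent.is_leaf:
            continue
        done = frozenset().union(
            *[frozenset([l.minimum_id]) for l in parent.leaves() if l.is_leaf] or [frozenset()]
        )
        for mid in sorted(parent.minima - done):
            parent.children.append(TreeNode(energies[mid], frozenset([mid]), minimum_id=mid))

    tree = DisconnectivityTree(roots, float(delta_e), float(e_top), levels)
    _assign_layout(tree)
    return tree


def _count_leaves(node: TreeNode) -> int:
    return 1 if node.is_leaf else sum(_count_leaves(c) for c in node.children)


def _assign_layout(tree: DisconnectivityTree) -> None:
    """x coordinates by recursive subtree-size ordering (larger subtrees first)."""
    cursor = 0.0

    def place(node: TreeNode, lo: float, hi: float) -> None:
        node.x = 0.5 * (lo + hi)
        if node.is_leaf:
            return
        kids = sorted(node.children, key=_count_leaves, reverse=True)
        total = sum(_count_leaves(k) for k in kids)
        x = lo
        for k in kids:
            w = (hi - lo) * _count_leaves(k) / total
            place(k, x, x + w)
            x += w

    for r in tree.roots:
        w = float(_count_leaves(r))
        place(r, cursor, cursor + w)
        cursor += w


def colour_leaves(
    tree: DisconnectivityTree,
    sets: list[tuple[ContributionSet, ContributionSet]],
    palette: list[tuple[str, str]] | None = None,
) -> DisconnectivityTree:
    """Label leaves by the first matching (feature, sign) class.

    ``sets`` lists (positive_set, negative_set) per feature in precedence
    order; earlier features win on overlap.  Unmatched leaves stay neutral.
    """
    if palette is None:
        palette = [("red", "blue"), ("green", "orange"), ("pink", "purple"), ("grey", "yellow")]
    leaves = {l.minimum_id: l for l in tree.leaves()}
    assignment: dict[int, str] = {}
    for k, (pos, neg) in enumerate(sets):
        cpos, cneg = palette[k % len(palette)]
        for members, colour in ((pos.members, cpos), (neg.members, cneg)):
            for mid, _ in members:
                if mid not in leaves:
                    raise DatabaseError(f"contribution set references unknown minimum {mid}")
                assignment.setdefault(mid, colour)
    for mid, leaf in leaves.items():
        leaf.colour = assignment.get(mid, "neutral")
    return tree


def tree_to_dict(tree: DisconnectivityTree) -> dict:
    """JSON-ready tree representation (schema in docs/formats.md)."""

    def node_dict(n: TreeNode) -> dict:
        d = {
            "energy": n.energy,
            "x": n.x,
            "minima": sorted(n.minima),
        }
        if n.is_leaf:
            d["minimum_id"] = n.minimum_id
            d["colour"] = n.colour
        else:
            d["children"] = [node_dict(c) for c in n.children]
        return d

    return {
        "delta_e": tree.delta_e,
        "e_top": tree.e_top,
        "n_leaves": len(tree.leaves()),
        "roots": [node_dict(r) for r in tree.roots],
    }


def plot_tree(tree: DisconnectivityTree, ax=None, colours: dict[str, str] | None = None):
    """Static matplotlib rendering: vertical branches, horizontal split bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))

    def draw(node: TreeNode, parent_energy: float | None) -> None:
        top = parent_energy if parent_energy is not None else node.energy
        col = (colours or {}).get(node.colour, node.colour if node.is_leaf else "black")
        if col == "neutral":
            col = "black"
        ax.plot([node.x, node.x], [top, node.energy], color=col, lw=0.8)
        if not node.is_leaf and node.children:
            xs = [c.x for c in node.children] + [node.x]
            ax.plot([min(xs), max(xs)], [node.energy, node.energy], color="black", lw=0.5)
            for c in node.children:
                draw(c, node.energy)

    for r in tree.roots:
        draw(r, None)
    ax.set_ylabel("energy")
    ax.set_xticks([])
    return ax
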