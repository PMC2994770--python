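"""Neighbor-Joining tree construction and tree-vs-taxonomy congruence.

The NJ implementation is the classic Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion.  Ties in Q are broken deterministically by
the lowest (row, column) index pair; negative branch-length estimates are
clamped to zero with the deficit transferred to the sibling edge so the
pair's summed length is preserved.

Congruence scoring asks, for each taxonomic group at a rank, how many of
its members fall in the group's largest "pure" bipartition — a tree edge
side containing members of the group and nobody else (unrooted semantics,
both orientations of every edge considered).  Two accounting variants are
provided: per_sample scores every sample; species_collapsed first prunes
the tree to one representative per (collapsed) species.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .alignment_io import TaxonomyTable
from .distances import DistanceMatrix
from .errors import InputError, TreeError

__all__ = [
    "nj_tree",
    "max_pure_subset",
    "congruence",
    "CongruenceReport",
    "GroupScore",
    "RANKS",
]

RANKS = ("superorder", "order", "family", "genus", "species")


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-Joining tree from a distance matrix (unrooted, binary)."""
    n = matrix.n
    if n < 3:
        raise InputError("NJ needs at least 3 taxa")
    d = np.array(matrix.values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise InputError("non-finite distance matrix entry (saturated pair?)")

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes: list[dendropy.Node] = []
    for sid in matrix.sample_ids:
        taxon = taxon_ns.new_taxon(label=sid)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    active = list(range(n))

    def _join(i_pos: int, j_pos: int, li: float, lj: float) -> dendropy.Node:
        parent = dendropy.Node()
        parent.add_child(nodes[i_pos])
        parent.add_child(nodes[j_pos])
        nodes[i_pos].edge.length = li
        nodes[j_pos].edge.length = lj
        return parent

    def _clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: lowest (row, col) in active-index order
        flat = np.argmin(q)
        bi, bj = divmod(flat, m)
        if bi > bj:
            bi, bj = bj, bi
        i, j = active[bi], active[bj]
        dij = d[i, j]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        parent = _join(i, j, li, lj)
        # distances from the new node to every other active node
        for bk in range(m):
            k = active[bk]
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - dij)
        nodes[i] = parent
        active.remove(j)

    # connect the last three nodes through one central vertex
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    center = dendropy.Node()
    for pos, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[pos])
        nodes[pos].edge.length = max(length, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _bipartition_sides(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label sets below every node (one orientation of every edge)."""
    sides = []
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        labels = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        sides.append(labels)
    return sides


def max_pure_subset(tree: dendropy.Tree, group: set[str]) -> set[str]:
    """Largest subset of ``group`` forming one pure side of a bipartition.

    Both orientations of every edge are considered; a side is pure when it
    contains no leaf outside the group.  Singleton groups trivially return
    themselves (a leaf edge is a bipartition).
    """
    leaves = _leaf_labels(tree)
    unknown = set(group) - leaves
    if unknown:
        raise TreeError(f"leaves not in tree: {sorted(unknown)}")
    if not group:
        raise InputError("empty group")
    group = set(group)
    # the trivial bipartition: a group spanning every leaf is monophyletic
    best: set[str] = set(leaves) if leaves <= group else set()
    for side in _bipartition_sides(tree):
        for oriented in (side, leaves - side):
            if oriented and oriented <= group and len(oriented) > len(best):
                best = set(oriented)
    return best


@dataclass(frozen=True)
class GroupScore:
    label: str
    n_members: int
    n_correct: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_correct / self.n_members


@dataclass
class CongruenceReport:
    rank: str
    variant: str  # "per_sample" or "species_collapsed"
    groups: list[GroupScore]

    @property
    def overall_percent(self) -> float:
        total = sum(g.n_members for g in self.groups)
        correct = sum(g.n_correct for g in self.groups)
        return 100.0 * correct / total if total else float("nan")

    def as_rows(self) -> list[dict]:
        return [
            {
                "rank": self.rank,
                "variant": self.variant,
                "group": g.label,
                "n": g.n_members,
                "correct": g.n_correct,
                "percent": g.percent,
            }
            for g in self.groups
        ]


def _score_tree(
    tree: dendropy.Tree, groups: dict[str, list[str]], rank: str, variant: str
) -> CongruenceReport:
    scores = []
    for label, members in groups.items():
        member_set = set(members)
        correct = len(max_pure_subset(tree, member_set))
        scores.append(GroupScore(label, len(member_set), correct))
    return CongruenceReport(rank, variant, scores)


def congruence(
    tree: dendropy.Tree,
    taxonomy: TaxonomyTable,
    rank: str,
    variant: str = "per_sample",
) -> CongruenceReport:
    """Score tree-vs-taxonomy congruence at one rank.

    per_sample uses every tree leaf.  species_collapsed prunes the tree to
    the first-listed sample of each collapsed species before scoring, so a
    clade of conspecific subspecies samples counts once.
    """
    leaves = _leaf_labels(tree)
    missing = [sid for sid in leaves if sid not in taxonomy.collapse_map]
    if missing:
        raise TreeError(f"tree leaves not in taxonomy: {sorted(missing)}")
    if variant not in ("per_sample", "species_collapsed"):
        raise InputError(f"unknown variant {variant!r}")

    if variant == "species_collapsed":
        seen_species: set[str] = set()
        keep: list[str] = []
        for sid in taxonomy.sample_ids:
            if sid not in leaves:
                continue
            sp = taxonomy.species_of(sid)
            if sp not in seen_species:
                seen_species.add(sp)
                keep.append(sid)
        tree = tree.extract_tree_with_taxa_labels(keep)
        leaves = set(keep)

    groups = {
        label: [sid for sid in members if sid in leaves]
        for label, members in taxonomy.groups(rank).items()
    }
    groups = {label: members for label, members in groups.items() if members}
    if not groups:
        raise InputError(f"no scoreable groups at rank {rank!r}")
    return _score_tree(tree, groups, rank, variant)
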