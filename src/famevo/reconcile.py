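"""Duplication-loss reconciliation of rooted gene trees with a species tree.

The LCA (last-common-ancestor) mapping embeds each gene-tree node at the
species-tree LCA of its descendant species; an internal gene node is a
duplication exactly when its mapping coincides with the mapping of one of
its children, otherwise a speciation.  Losses are counted along skipped
species-tree edges: an edge from gene node ``u`` to child ``v`` spanning
``d`` species-tree edges contributes ``d - 1`` losses when ``u`` is a
speciation and ``d`` when ``u`` is a duplication, each attributed to the
species branch whose subtree retained no descendant.  The LCA embedding
minimizes both the duplication and the loss count, hence also the weighted
cost ``1.5 * D + 1.0 * L`` used throughout.

Poorly supported gene-tree edges (bootstrap below a cutoff, default 90%)
can be collapsed into polytomies and re-resolved to the cheapest
reconciliation: exhaustively for polytomies of degree <= 6, greedily
beyond.  Losses on the species-tree root edge are never counted (there is
no information above the root).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import BaseTree, DatedSpeciesTree, GeneTree, TreeError, _Node

__all__ = [
    "ReconciliationResult",
    "lca_reconcile",
    "rearrange_weak_edges",
    "summarize_lineage_events",
    "brute_force_reconcile_cost",
]

DUPLICATION_COST = 1.5
LOSS_COST = 1.0


@dataclass
class ReconciliationResult:
    """Events and costs of one gene tree embedded in the species tree."""

    events: dict[int, str]  # gene-node index -> "duplication" | "speciation" | "leaf"
    node_mapping: dict[int, str]  # gene-node index -> species node key
    duplications_by_lineage: dict[str, int]
    losses_by_lineage: dict[str, int]  # species branch (node key) -> loss count
    duplication_cost: float = DUPLICATION_COST
    loss_cost: float = LOSS_COST
    species_signature: str = ""

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(self.losses_by_lineage.values())

    @property
    def cost(self) -> float:
        return self.duplication_cost * self.n_duplications + self.loss_cost * self.n_losses

    def lineage_table(self) -> pd.DataFrame:
        keys = sorted(set(self.duplications_by_lineage) | set(self.losses_by_lineage))
        return pd.DataFrame(
            {
                "lineage": keys,
                "duplications": [self.duplications_by_lineage.get(k, 0) for k in keys],
                "losses": [self.losses_by_lineage.get(k, 0) for k in keys],
            }
        )


def _species_key(node) -> str:
    if node.is_leaf:
        return node.label
    return "|".join(sorted(_tips_below(node)))


def _tips_below(node) -> list[str]:
    if node.is_leaf:
        return [node.label]
    out = []
    for c in node.children:
        out.extend(_tips_below(c))
    return out


def _topology_signature(node) -> str:
    """Canonical label-only serialization (children sorted); topology id."""
    if node.is_leaf:
        return node.label
    return "(" + ",".join(sorted(_topology_signature(c) for c in node.children)) + ")"


class _SpeciesIndex:
    """Ancestry bookkeeping for fast LCA and path queries."""

    def __init__(self, species_tree: BaseTree):
        self.tree = species_tree
        self.depth = {}
        self.parent = {}
        for node in species_tree.preorder():
            self.parent[node] = node.parent
            self.depth[node] = 0 if node.parent is None else self.depth[node.parent] + 1
        self.by_tip = {t.label: t for t in species_tree.leaves}
        self.key = {node: _species_key(node) for node in species_tree.postorder()}
        self.signature = _topology_signature(species_tree.root)

    def lca(self, a, b):
        while a is not b:
            if self.depth[a] < self.depth[b]:
                b = self.parent[b]
            elif self.depth[a] > self.depth[b]:
                a = self.parent[a]
            else:
                a, b = self.parent[a], self.parent[b]
        return a

    def distance(self, anc, desc) -> int:
        """Edges from ancestor ``anc`` down to descendant ``desc``."""
        d = self.depth[desc] - self.depth[anc]
        if d < 0:
            raise ValueError("not an ancestor/descendant pair")
        return d

    def path_down(self, anc, desc) -> list:
        """Nodes from anc to desc inclusive (anc must be an ancestor)."""
        path = [desc]
        node = desc
        while node is not anc:
            node = self.parent[node]
            if node is None:
                raise ValueError("anc is not an ancestor of desc")
            path.append(node)
        return path[::-1]

    def is_ancestor(self, anc, desc) -> bool:
        node = desc
        while node is not None:
            if node is anc:
                return True
            node = self.parent[node]
        return False


def _map_gene_tree(gene_tree: GeneTree, index: _SpeciesIndex) -> dict[int, object]:
    mapping: dict[int, object] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            sp = gene_tree.species_of(node.label)
            try:
                mapping[node.index] = index.by_tip[sp]
            except KeyError:
                raise TreeError(
                    f"gene tip {node.label!r} maps to species {sp!r} absent from the species tree"
                ) from None
        else:
            m = mapping[node.children[0].index]
            for c in node.children[1:]:
                m = index.lca(m, mapping[c.index])
            mapping[node.index] = m
    return mapping


def _count_events(gene_tree: GeneTree, index: _SpeciesIndex, mapping) -> ReconciliationResult:
    events: dict[int, str] = {}
    dup_by: dict[str, int] = {}
    loss_by: dict[str, int] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            events[node.index] = "leaf"
            continue
        m = mapping[node.index]
        is_dup = any(mapping[c.index] is m for c in node.children)
        events[node.index] = "duplication" if is_dup else "speciation"
        if is_dup:
            key = index.key[m]
            dup_by[key] = dup_by.get(key, 0) + 1
    for node in gene_tree.postorder():
        if node.is_leaf or len(node.children) < 2:
            continue
        mu = mapping[node.index]
        dup = events[node.index] == "duplication"
        for child in node.children:
            mv = mapping[child.index]
            path = index.path_down(mu, mv)
            # a loss on the branch to the unvisited sibling at each skipped node
            start = 0 if dup else 1
            for k in range(start, len(path) - 1):
                sp_node = path[k]
                nxt = path[k + 1]
                for sib in sp_node.children:
                    if sib is not nxt:
                        key = index.key[sib]
                        loss_by[key] = loss_by.get(key, 0) + 1
    return ReconciliationResult(
        events=events,
        node_mapping={i: index.key[m] for i, m in mapping.items()},
        duplications_by_lineage=dup_by,
        losses_by_lineage=loss_by,
        species_signature=index.signature,
    )


def lca_reconcile(gene_tree: GeneTree, species_tree: DatedSpeciesTree) -> ReconciliationResult:
    """Most-parsimonious (LCA) duplication-loss reconciliation."""
    index = _SpeciesIndex(species_tree)
    mapping = _map_gene_tree(gene_tree, index)
    return _count_events(gene_tree, index, mapping)


# ---------------------------------------------------------------------------
# bootstrap-threshold rearrangement
# ---------------------------------------------------------------------------

def _iter_subtree(node: _Node):
    yield node
    for c in node.children:
        yield from _iter_subtree(c)


def _collapse_weak(root: _Node, threshold: float, missing_as_full: bool) -> _Node:
    """Copy the tree, absorbing children across weakly supported edges."""

    def rebuild(node: _Node) -> _Node:
        new = _Node(label=node.label, length=node.length, support=node.support)
        for child in node.children:
            sub = rebuild(child)
            if not sub.is_leaf:
                support = sub.support
                if support is None:
                    if not missing_as_full:
                        raise TreeError(
                            "internal edge without bootstrap support; pass "
                            "missing_support_as_full=True to treat it as 100"
                        )
                    support = 100.0
                if support < threshold:
                    for g in sub.children:
                        new.add(g)
                    continue
            new.add(sub)
        return new

    return rebuild(root)


def _cherry_cost(index: _SpeciesIndex, ma, mb) -> tuple[object, float]:
    """Mapping and local DL cost of joining two mapped subtrees."""
    m = index.lca(ma, mb)
    dup = (m is ma) or (m is mb)
    losses = 0
    for mc in (ma, mb):
        d = index.distance(m, mc)
        losses += d if dup else max(0, d - 1)
    cost = (DUPLICATION_COST if dup else 0.0) + LOSS_COST * losses
    return m, cost


def _best_resolution(index: _SpeciesIndex, items: list[_Node], mappings: list[object], max_exhaustive: int = 6):
    """Cheapest binary join of a polytomy's children.

    Items are already-resolved subtrees with fixed species mappings; only
    the local topology above them is searched.  Exhaustive over all rooted
    binary shapes for <= ``max_exhaustive`` children, greedy nearest-join
    beyond.
    """

    def join(a, b):
        node = _Node()
        node.add(a[0])
        node.add(b[0])
        m, cost = _cherry_cost(index, a[1], b[1])
        return (node, m, a[2] + b[2] + cost)

    entries = [(item, m, 0.0) for item, m in zip(items, mappings)]
    if len(entries) <= max_exhaustive:
        best = None

        def search(pool):
            nonlocal best
            if len(pool) == 1:
                if best is None or pool[0][2] < best[2]:
                    best = pool[0]
                return
            if best is not None and min(e[2] for e in pool) >= best[2]:
                pass  # cannot prune safely on partial cost alone; continue
            for i, j in itertools.combinations(range(len(pool)), 2):
                merged = join(pool[i], pool[j])
                rest = [pool[k] for k in range(len(pool)) if k not in (i, j)]
                search(rest + [merged])

        search(entries)
        return best[0]
    # greedy: repeatedly merge the cheapest pair
    pool = entries
    while len(pool) > 1:
        best_pair, best_cost = None, None
        for i, j in itertools.combinations(range(len(pool)), 2):
            _, cost = _cherry_cost(index, pool[i][1], pool[j][1])
            if best_cost is None or cost < best_cost:
                best_pair, best_cost = (i, j), cost
        i, j = best_pair
        merged = join(pool[i], pool[j])
        pool = [pool[k] for k in range(len(pool)) if k not in (i, j)] + [merged]
    return pool[0][0]


def rearrange_weak_edges(
    gene_tree: GeneTree,
    species_tree: DatedSpeciesTree,
    support_threshold: float = 90.0,
    missing_support_as_full: bool = False,
    max_exhaustive: int = 6,
) -> tuple[GeneTree, ReconciliationResult]:
    """Collapse weakly supported edges and re-resolve at minimum DL cost.

    Edges with bootstrap support below ``support_threshold`` are collapsed
    into polytomies; each polytomy is re-resolved independently (its root
    mapping is invariant, so local optimization is globally valid).  The
    returned reconciliation never costs more than that of the input tree;
    with threshold 0 the tree is returned unchanged.
    """
    base = lca_reconcile(gene_tree, species_tree)
    if support_threshold <= 0:
        return gene_tree, base
    index = _SpeciesIndex(species_tree)
    collapsed = _collapse_weak(gene_tree.root, support_threshold, missing_support_as_full)
    n_before = sum(1 for _ in _iter_subtree(gene_tree.root))
    n_after = sum(1 for _ in _iter_subtree(collapsed))
    if n_before == n_after:  # nothing collapsed: identity
        return gene_tree, base

    def resolve(node: _Node) -> tuple[_Node, object]:
        if node.is_leaf:
            sp = gene_tree.species_of(node.label)
            return node, index.by_tip[sp]
        resolved = [resolve(c) for c in node.children]
        items = [r[0] for r in resolved]
        maps = [r[1] for r in resolved]
        if len(items) == 1:
            return items[0], maps[0]
        if len(items) == 2:
            new = _Node(length=node.length, support=node.support)
            new.add(items[0])
            new.add(items[1])
            m = index.lca(maps[0], maps[1])
            return new, m
        sub = _best_resolution(index, items, maps, max_exhaustive=max_exhaustive)
        sub.support = node.support
        m = maps[0]
        for mm in maps[1:]:
            m = index.lca(m, mm)
        return sub, m

    new_root, _ = resolve(collapsed)
    new_tree = GeneTree(
        new_root, species_map=gene_tree._species_map, separator=gene_tree.separator
    )
    result = lca_reconcile(new_tree, species_tree)
    if result.cost > base.cost:
        return gene_tree, base
    return new_tree, result


# ---------------------------------------------------------------------------
# cross-family summaries
# ---------------------------------------------------------------------------

def summarize_lineage_events(
    results: list[ReconciliationResult], species_tree: DatedSpeciesTree
) -> pd.DataFrame:
    """Sum duplications and losses per species lineage across families."""
    index = _SpeciesIndex(species_tree)
    expected = index.signature
    for r in results:
        if r.species_signature and r.species_signature != expected:
            raise ValueError("reconciliations come from different species trees")
    keys = [index.key[n] for n in species_tree.postorder()]
    dups = {k: 0 for k in keys}
    losses = {k: 0 for k in keys}
    for r in results:
        for k, v in r.duplications_by_lineage.items():
            dups[k] = dups.get(k, 0) + v
        for k, v in r.losses_by_lineage.items():
            losses[k] = losses.get(k, 0) + v
    return pd.DataFrame(
        {
            "lineage": keys,
            "duplications": [dups[k] for k in keys],
            "losses": [losses[k] for k in keys],
        }
    )


# ---------------------------------------------------------------------------
# brute-force oracle (exhaustive over valid embeddings)
# ---------------------------------------------------------------------------

def brute_force_reconcile_cost(
    gene_tree: GeneTree, species_tree: DatedSpeciesTree
) -> tuple[float, int, int]:
    """(min cost, D, L) over every valid gene->species node assignment.

    Exhaustive search for small instances: each internal gene node may map
    to any species node that is an ancestor-or-equal of the LCA of its
    children's mappings.  A node is a speciation only if it maps exactly to
    the LCA of its children and its children map into distinct child
    subtrees; otherwise it is a duplication.  Losses follow the same
    skipped-edge rule as :func:`lca_reconcile`.
    """
    index = _SpeciesIndex(species_tree)
    gnodes = list(gene_tree.postorder())
    internal = [n for n in gnodes if not n.is_leaf]
    tip_map = {
        n.index: index.by_tip[gene_tree.species_of(n.label)] for n in gnodes if n.is_leaf
    }
    sp_nodes = list(species_tree.postorder())
    best = (np.inf, -1, -1)
    choices = []
    for node in internal:
        # any ancestor-or-equal of the subtree LCA is admissible
        tips = [index.by_tip[gene_tree.species_of(t)] for t in _tips_below(node)]
        m = tips[0]
        for t in tips[1:]:
            m = index.lca(m, t)
        admissible = [s for s in sp_nodes if index.is_ancestor(s, m)]
        choices.append(admissible)
    for combo in itertools.product(*choices):
        mapping = dict(tip_map)
        ok = True
        for node, m in zip(internal, combo):
            mapping[node.index] = m
        for node in internal:
            for c in node.children:
                if not index.is_ancestor(mapping[node.index], mapping[c.index]):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        D = L = 0
        for node in internal:
            m = mapping[node.index]
            kids = [mapping[c.index] for c in node.children]
            lca = kids[0]
            for k in kids[1:]:
                lca = index.lca(lca, k)
            separated = (
                m is lca
                and len(node.children) == 2
                and kids[0] is not m
                and kids[1] is not m
                and index.lca(kids[0], kids[1]) is m
            )
            dup = not separated
            if dup:
                D += 1
            for k in kids:
                d = index.distance(m, k)
                L += d if dup else max(0, d - 1)
        cost = DUPLICATION_COST * D + LOSS_COST * L
        if cost < best[0]:
            best = (cost, D, L)
    return best
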