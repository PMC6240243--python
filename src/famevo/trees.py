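"""Rooted phylogenetic trees: parsing, validation, calibration.

Two tree flavours are used throughout the package:

* :class:`DatedSpeciesTree` -- a rooted, ultrametric species phylogeny whose
  branch lengths are in million years (Myr).  It is the time substrate for
  the birth-death family-size model and for duplication-loss reconciliation.
* :class:`GeneTree` -- a rooted gene phylogeny whose tips carry a mapping to
  species names and whose internal edges may carry bootstrap supports
  (percentages in [0, 100]).

Parsing is delegated to :mod:`dendropy`; these classes add validation,
node-age bookkeeping and a deterministic Newick serializer so that
write -> read round-trips are lossless.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "DatedSpeciesTree",
    "GeneTree",
    "read_newick",
]


class TreeError(ValueError):
    """Invalid tree structure or failed validation."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries the approximate character offset."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character offset {offset})"
        super().__init__(message)


def _parse_dendropy(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        offset = None
        col = getattr(exc, "column", None)
        line = getattr(exc, "line_num", None)
        if col is not None:
            offset = int(col)
            if line and line > 1:
                # offset within the failing line; report cumulative offset
                prior = newick.splitlines(keepends=True)[: line - 1]
                offset += sum(len(s) for s in prior)
        raise NewickParseError(f"malformed Newick: {exc}", offset) from exc


class _Node:
    """Lightweight rooted-tree node (internal representation)."""

    __slots__ = ("label", "length", "support", "children", "parent", "index")

    def __init__(self, label=None, length=None, support=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[_Node] = []
        self.parent: _Node | None = None
        self.index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)


def _from_dendropy(dnode, support_as_label: bool) -> _Node:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    support = None
    if dnode.child_nodes() and label is not None and support_as_label:
        try:
            support = float(label)
            label = None
        except (TypeError, ValueError):
            support = None
    node = _Node(label=label, length=dnode.edge.length, support=support)
    for child in dnode.child_nodes():
        node.add(_from_dendropy(child, support_as_label))
    return node


def _format_length(x: float) -> str:
    s = repr(float(x))
    return s


def _to_newick(node: _Node, write_supports: bool) -> str:
    if node.is_leaf:
        out = node.label or ""
    else:
        inner = ",".join(_to_newick(c, write_supports) for c in node.children)
        tag = ""
        if write_supports and node.support is not None:
            tag = _format_length(node.support) if node.support % 1 else str(int(node.support))
        elif node.label is not None:
            tag = node.label
        out = f"({inner}){tag}"
    if node.length is not None:
        out += f":{_format_length(node.length)}"
    return out


class BaseTree:
    """Shared machinery for rooted trees with branch lengths."""

    def __init__(self, root: _Node):
        self.root = root
        self._reindex()

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, **kwargs):
        """Parse a Newick string (or the contents of a file-like)."""
        dtree = _parse_dendropy(newick)
        root = _from_dendropy(dtree.seed_node, kwargs.pop("support_as_label", True))
        return cls(root, **kwargs)

    @classmethod
    def read(cls, path, **kwargs):
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kwargs)

    # -- traversal ----------------------------------------------------
    def _reindex(self) -> None:
        self._postorder: list[_Node] = []

        def visit(node):
            for c in node.children:
                visit(c)
            node.index = len(self._postorder)
            self._postorder.append(node)

        visit(self.root)

    def postorder(self) -> Sequence[_Node]:
        return self._postorder

    def preorder(self) -> list[_Node]:
        return list(reversed(self._postorder))

    @property
    def leaves(self) -> list[_Node]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    def find_tip(self, label: str) -> _Node:
        for n in self.leaves:
            if n.label == label:
                return n
        raise TreeError(f"tip {label!r} not found in tree")

    def mrca(self, labels: Iterable[str]) -> _Node:
        """Most recent common ancestor of the named tips."""
        paths = []
        for lab in labels:
            node = self.find_tip(lab)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        if not paths:
            raise TreeError("mrca of an empty tip set is undefined")
        mrca = None
        for nodes in zip(*paths):
            first = nodes[0]
            if all(n is first for n in nodes):
                mrca = first
            else:
                break
        return mrca

    # -- measures -----------------------------------------------------
    def depths(self) -> dict[_Node, float]:
        """Root-to-node path lengths (root depth 0; missing lengths = 0)."""
        out = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self._postorder if n is not self.root)

    # -- output -------------------------------------------------------
    def to_newick(self, write_supports: bool = True) -> str:
        return _to_newick(self.root, write_supports) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __len__(self) -> int:
        return len(self.leaves)


def _validate_unique_tips(tree: BaseTree) -> None:
    labels = tree.tip_labels
    if any(lab is None or lab == "" for lab in labels):
        raise TreeError("every tip must carry a label")
    seen = set()
    for lab in labels:
        if lab in seen:
            raise TreeError(f"duplicate tip label {lab!r}")
        seen.add(lab)


class DatedSpeciesTree(BaseTree):
    """Rooted ultrametric species tree with branch lengths in Myr.

    Parameters
    ----------
    root : internal node structure (use :meth:`from_newick` / :meth:`read`).
    ultrametric_rtol : relative tolerance on tip-age equality.  Inputs
        outside the tolerance are rejected by :meth:`calibrate` rather than
        silently stretched.
    """

    def __init__(self, root: _Node, ultrametric_rtol: float = 1e-6):
        super().__init__(root)
        self.ultrametric_rtol = ultrametric_rtol
        _validate_unique_tips(self)
        for node in self.postorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length on edge above {node.label or 'internal node'}")

    # -- ages ---------------------------------------------------------
    def node_ages(self) -> dict[_Node, float]:
        """Age of each node in Myr (time before present; tips ~ 0)."""
        depths = self.depths()
        height = max(depths[t] for t in self.leaves)
        return {n: height - d for n, d in depths.items()}

    def is_ultrametric(self, rtol: float | None = None) -> bool:
        rtol = self.ultrametric_rtol if rtol is None else rtol
        depths = self.depths()
        tip_depths = [depths[t] for t in self.leaves]
        height = max(tip_depths)
        if height == 0:
            return True
        return all(abs(d - height) <= rtol * height for d in tip_depths)

    def calibrate(self, tip_a: str, tip_b: str, age: float) -> "DatedSpeciesTree":
        """Rescale all branch lengths so the MRCA of two tips has a given age.

        This is how a fossil calibration is applied: one dated split pins the
        absolute time scale and every branch is multiplied by the single
        scalar that moves the split to ``age`` Myr.  Ultrametricity is
        preserved exactly (a linear rescaling cannot break it).
        """
        if not self.is_ultrametric():
            raise TreeError(
                "refusing to calibrate a non-ultrametric tree "
                f"(tip ages differ by more than rtol={self.ultrametric_rtol})"
            )
        node = self.mrca([tip_a, tip_b])
        current = self.node_ages()[node]
        if current <= 0:
            raise TreeError("MRCA age is zero; cannot set a positive calibration age")
        scale = age / current
        scaled = _copy_subtree(self.root)
        for n, orig in zip(_iter_postorder(scaled), self.postorder()):
            if orig.length is not None:
                n.length = orig.length * scale
        return DatedSpeciesTree(scaled, ultrametric_rtol=self.ultrametric_rtol)


def _copy_subtree(node: _Node) -> _Node:
    new = _Node(label=node.label, length=node.length, support=node.support)
    for c in node.children:
        new.add(_copy_subtree(c))
    return new


def _iter_postorder(node: _Node):
    for c in node.children:
        yield from _iter_postorder(c)
    yield node


class GeneTree(BaseTree):
    """Rooted gene tree whose tips map to species.

    The species of each gene copy is, by default, the prefix of the tip
    label up to ``separator`` (e.g. tip ``CRO_g3`` -> species ``CRO``);
    an explicit ``species_map`` overrides the prefix rule.  Bootstrap
    supports, when present in the Newick as internal-node labels, are
    stored per internal edge as percentages.
    """

    def __init__(
        self,
        root: _Node,
        species_map: Mapping[str, str] | None = None,
        separator: str = "_",
    ):
        super().__init__(root)
        _validate_unique_tips(self)
        self.separator = separator
        self._species_map = dict(species_map) if species_map else None
        for node in self.postorder():
            if node.support is not None and not (0 <= node.support <= 100):
                raise TreeError(f"bootstrap support {node.support} outside [0, 100]")

    def species_of(self, tip_label: str) -> str:
        if self._species_map is not None:
            try:
                return self._species_map[tip_label]
            except KeyError:
                raise TreeError(f"tip {tip_label!r} missing from the species map") from None
        return tip_label.split(self.separator, 1)[0]

    def species_labels(self) -> list[str]:
        return [self.species_of(lab) for lab in self.tip_labels]

    def validate_against(self, species_tree: DatedSpeciesTree) -> None:
        known = set(species_tree.tip_labels)
        for lab in self.tip_labels:
            sp = self.species_of(lab)
            if sp not in known:
                raise TreeError(f"gene tip {lab!r} maps to unknown species {sp!r}")

    def copy(self) -> "GeneTree":
        return GeneTree(
            _copy_subtree(self.root),
            species_map=self._species_map,
            separator=self.separator,
        )


def read_newick(path, kind: str = "species", **kwargs):
    """Read a Newick file as either a species tree or a gene tree.

    Parameters
    ----------
    kind : ``"species"`` for :class:`DatedSpeciesTree`, ``"gene"`` for
        :class:`GeneTree`.
    """
    if kind == "species":
        return DatedSpeciesTree.read(path, **kwargs)
    if kind == "gene":
        return GeneTree.read(path, **kwargs)
    raise ValueError(f"unknown tree kind {kind!r}")
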