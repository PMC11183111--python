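"""Dated phylogenies and megatree assembly.

A :class:`DatedTree` is a rooted tree with nonnegative branch lengths in
millions of years (Myr) and derived node ages (tips at age 0 when the tree
is ultrametric).  The module builds a species-level dated tree from a genus
backbone: missing genera are grafted as sisters to a named relative, species
absent from the backbone are bound at the phylogenetic midpoint of their
genus, undated nodes are smoothed by even age interpolation, and the result
is pruned to the analysis species pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

ULTRAMETRIC_TOL = 1e-6
#: age offset separating species bound to the same genus at the same midpoint
ATTACH_EPSILON = 1e-8


class MissingTaxonError(KeyError):
    """A required species or genus is absent from the tree."""


class DuplicateTaxonError(ValueError):
    """A taxon being added is already present."""


class ConstraintConflictError(ValueError):
    """Age constraints imply a descendant at least as old as its ancestor."""


@dataclass(frozen=True)
class SpeciesRecord:
    """Checklist row: a species binomial with its genus and family."""

    species: str
    genus: str
    family: str = ""

    def __post_init__(self) -> None:
        token = self.species.replace("_", " ").split()[0]
        if token != self.genus:
            raise ValueError(
                f"species {self.species!r} does not start with genus {self.genus!r}"
            )


class DatedTree:
    """Rooted dated phylogeny backed by a dendropy tree.

    Branch lengths are Myr.  Node ages are measured from the present: a
    node's age is its distance to its deepest descendant tip, so tips of an
    ultrametric tree all sit at age 0.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._refresh()

    # -- construction / io ------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "DatedTree":
        """Parse Newick from a string (if it contains ';') or a file path."""
        if ";" in source or "(" in source:
            data, kind = source, "string"
        else:
            data, kind = source, "path"
        try:
            tree = dendropy.Tree.get(
                **{kind: data},
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"Newick parse error: {exc}") from exc
        return cls(tree)

    def to_newick(self, path: str | None = None) -> str:
        s = self._tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def copy(self) -> "DatedTree":
        return DatedTree(self._tree.clone(depth=1))

    # -- basic structure ---------------------------------------------------

    def _refresh(self) -> None:
        self._metrics_cache = None  # invalidate any per-tree precomputation
        tree = self._tree
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None:
                raise ValueError("leaf without a label")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self._depths: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            bl = node.edge.length or 0.0
            if bl < -1e-12:
                raise ValueError("negative branch length")
            self._depths[node] = (self._depths[parent] + bl) if parent else 0.0
        self._max_depth = max(
            (self._depths[l] for l in tree.leaf_node_iter()), default=0.0
        )
        self._ages: dict[dendropy.Node, float] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._ages[node] = self._max_depth - self._depths[node]
            else:
                self._ages[node] = max(
                    self._ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()
                )

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [l.taxon.label for l in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def root_age(self) -> float:
        return self._ages[self._tree.seed_node]

    def node_age(self, node: dendropy.Node) -> float:
        return self._ages[node]

    @property
    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter() if e.head_node.parent_node
        )

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        depths = [self._depths[l] for l in self._tree.leaf_node_iter()]
        return (max(depths) - min(depths)) <= tol if depths else True

    def find_tip(self, label: str) -> dendropy.Node:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise MissingTaxonError(label)

    def genus_tips(self, genus: str) -> list[dendropy.Node]:
        """Tips whose binomial starts with ``genus`` (space or underscore)."""
        out = []
        for leaf in self._tree.leaf_node_iter():
            token = leaf.taxon.label.replace("_", " ").split()[0]
            if token == genus:
                out.append(leaf)
        return out

    def mrca(self, nodes: Sequence[dendropy.Node]) -> dendropy.Node:
        if len(nodes) == 1:
            return nodes[0]
        paths = []
        for node in nodes:
            path = []
            cur = node
            while cur is not None:
                path.append(cur)
                cur = cur.parent_node
            paths.append(list(reversed(path)))
        anc = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        return anc

    # -- distances ---------------------------------------------------------

    def patristic_matrix(self) -> tuple[list[str], "np.ndarray"]:
        """Labels (tree order) and the dense pairwise patristic matrix."""
        import numpy as np

        leaves = list(self._tree.leaf_node_iter())
        labels = [l.taxon.label for l in leaves]
        n = len(leaves)
        idx = {id(l): i for i, l in enumerate(leaves)}
        D = np.zeros((n, n))
        # distances via postorder accumulation of tip->node depths
        below: dict[int, list[tuple[int, float]]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = [(idx[id(node)], 0.0)]
                continue
            children = node.child_nodes()
            lists = []
            for c in children:
                lst = [(i, d + (c.edge.length or 0.0)) for i, d in below.pop(id(c))]
                lists.append(lst)
            for a in range(len(lists)):
                for b in range(a + 1, len(lists)):
                    for i, di in lists[a]:
                        for j, dj in lists[b]:
                            D[i, j] = D[j, i] = di + dj
            below[id(node)] = [x for lst in lists for x in lst]
        return labels, D


# ----------------------------------------------------------------------
# grafting / binding
# ----------------------------------------------------------------------


def _insert_node_on_stem(
    tree: DatedTree, clade: dendropy.Node, attach_age: float
) -> dendropy.Node:
    """Insert a new node on the branch above ``clade`` at ``attach_age``."""
    parent = clade.parent_node
    if parent is None:
        raise MissingTaxonError("clade has no stem branch (it is the root)")
    clade_age = tree.node_age(clade)
    parent_age = tree.node_age(parent)
    if not (clade_age < attach_age < parent_age + 1e-12):
        raise ValueError(
            f"attachment age {attach_age} outside stem interval "
            f"({clade_age}, {parent_age})"
        )
    new = dendropy.Node()
    parent.remove_child(clade)
    parent.add_child(new)
    new.add_child(clade)
    new.edge.length = parent_age - attach_age
    clade.edge.length = attach_age - clade_age
    return new


def _add_tip(
    dtree: dendropy.Tree, attach_node: dendropy.Node, label: str, length: float
) -> None:
    taxon = dtree.taxon_namespace.new_taxon(label=label)
    tip = dendropy.Node(taxon=taxon)
    tip.edge.length = length
    attach_node.add_child(tip)


def graft_missing_genus(
    tree: DatedTree, missing: str, sister: str, representative_species: str
) -> DatedTree:
    """Attach a genus absent from the backbone as sister to ``sister``.

    The representative tip attaches at the midpoint of the sister clade's
    stem branch, so the output stays ultrametric.  The sister clade is the
    most recent common ancestor of the sister genus' tips (monophyly is not
    required; a violation is logged).
    """
    if tree.genus_tips(missing):
        raise DuplicateTaxonError(f"genus {missing!r} already in tree")
    sister_tips = tree.genus_tips(sister)
    if not sister_tips:
        raise MissingTaxonError(f"sister genus {sister!r} not in tree")
    out = tree.copy()
    sister_tips = out.genus_tips(sister)
    clade = out.mrca(sister_tips)
    clade_leaf_count = sum(1 for _ in clade.leaf_iter()) if not clade.is_leaf() else 1
    if clade_leaf_count != len(sister_tips):
        logger.warning("genus %s is not monophyletic; using its MRCA clade", sister)
    attach_age = (out.node_age(clade) + out.node_age(clade.parent_node)) / 2.0
    new = _insert_node_on_stem(out, clade, attach_age)
    _add_tip(out.dendropy_tree, new, representative_species, attach_age)
    out._refresh()
    return out


def bind_species_midpoint(
    tree: DatedTree, records: Iterable[SpeciesRecord]
) -> DatedTree:
    """Bind checklist species to the tree at their genus midpoint.

    A genus with >=2 tips receives new species on its stem branch at age
    (stem age + crown age)/2; a monotypic genus at half its stem-to-tip
    branch.  Several species bound to one genus form a pectinate series at
    that age, successive attachments offset downward by a fixed epsilon so
    nodes stay strictly ordered.  Species already in the tree are skipped
    with a warning.
    """
    out = tree.copy()
    present = set(out.tip_labels)
    by_genus: dict[str, list[SpeciesRecord]] = {}
    for rec in records:
        if rec.species in present:
            logger.warning("species %s already in tree; skipping", rec.species)
            continue
        by_genus.setdefault(rec.genus, []).append(rec)
    for genus, recs in by_genus.items():
        tips = out.genus_tips(genus)
        if not tips:
            raise MissingTaxonError(
                f"genus {genus!r} absent from tree; graft it before binding"
            )
        crown = out.mrca(tips)
        stem_parent = crown.parent_node
        if stem_parent is None:
            raise MissingTaxonError(f"genus {genus!r} clade is the whole tree")
        crown_age = out.node_age(crown)
        stem_age = out.node_age(stem_parent)
        attach_age = (stem_age + crown_age) / 2.0
        below = crown
        for i, rec in enumerate(sorted(recs, key=lambda r: r.species)):
            age_i = attach_age - i * ATTACH_EPSILON
            new = _insert_node_on_stem(out, below, age_i)
            _add_tip(out.dendropy_tree, new, rec.species, age_i)
            out._refresh()
            below = new.child_nodes()[0]  # original clade stays lowest
    out._refresh()
    return out


# ----------------------------------------------------------------------
# BLADJ-style smoothing
# ----------------------------------------------------------------------


def bladj_smooth(
    tree: DatedTree, constraints: Mapping[str, float]
) -> DatedTree:
    """Assign ages to undated internal nodes by even interpolation.

    ``constraints`` maps node labels (internal node labels or tip labels)
    to ages; tips are implicitly constrained to age 0.  Between a dated
    ancestor at age ``a`` and its nearest dated descendant at age ``d``
    separated by ``m`` undated nodes, node ``i`` (counting from the
    ancestor) receives age ``a - i*(a-d)/(m+1)``.  When undated nodes lie
    on several such segments, segments are resolved longest-interior-first
    (ties by older ancestor), each assignment fixing its interior nodes for
    the segments that remain.  Branch lengths are recomputed from ages.
    """
    out = tree.copy()
    dtree = out.dendropy_tree
    ages: dict[int, float] = {}
    nodes_by_id = {}
    root = dtree.seed_node
    for node in dtree.preorder_node_iter():
        nodes_by_id[id(node)] = node
        label = None
        if node.is_leaf():
            label = node.taxon.label
        elif node.label:
            label = node.label
        if label is not None and label in constraints:
            ages[id(node)] = float(constraints[label])
        elif node.is_leaf():
            ages[id(node)] = 0.0
    if id(root) not in ages:
        raise ValueError("root age must be constrained")

    def check(parent_id: int, child_id: int) -> None:
        if ages[child_id] >= ages[parent_id] - 1e-12:
            raise ConstraintConflictError(
                f"descendant age {ages[child_id]} >= ancestor age {ages[parent_id]}"
            )

    # validate dated pairs along paths
    for node in dtree.preorder_node_iter():
        if id(node) not in ages or node.parent_node is None:
            continue
        anc = node.parent_node
        while anc is not None and id(anc) not in ages:
            anc = anc.parent_node
        if anc is not None:
            check(id(anc), id(node))

    def segments() -> list[tuple[float, int, list[int], int]]:
        """(interior length, ancestor id, interior ids, descendant id) for
        every dated-ancestor -> nearest-dated-descendant path with undated
        interior."""
        segs = []
        for node in dtree.preorder_node_iter():
            if id(node) not in ages:
                continue
            # DFS down through undated nodes to nearest dated descendants
            stack = [(c, [])
                     for c in node.child_nodes()]
            while stack:
                cur, interior = stack.pop()
                if id(cur) in ages:
                    if interior:
                        segs.append((len(interior), id(node), interior, id(cur)))
                    continue
                for c in cur.child_nodes():
                    stack.append((c, interior + [id(cur)]))
        return segs

    while True:
        segs = segments()
        if not segs:
            break
        segs.sort(key=lambda s: (-s[0], -ages[s[1]], ages[s[3]]))
        m, anc_id, interior, desc_id = segs[0]
        a, d = ages[anc_id], ages[desc_id]
        step = (a - d) / (m + 1)
        for i, nid in enumerate(interior, start=1):
            ages[nid] = a - i * step

    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[id(node.parent_node)] - ages[id(node)]
            if node.edge.length < -1e-9:
                raise ConstraintConflictError(
                    "interpolated ages produced a negative branch length"
                )
            node.edge.length = max(node.edge.length, 0.0)
    out._refresh()
    return out


# ----------------------------------------------------------------------
# pruning / ages
# ----------------------------------------------------------------------


def prune_to_pool(
    tree: DatedTree, pool: Iterable[str], drop_unknown: bool = False
) -> DatedTree:
    """Minimal rooted tree on ``pool``; unary nodes collapsed, ages kept."""
    pool = set(pool)
    tips = set(tree.tip_labels)
    unknown = pool - tips
    if unknown:
        if not drop_unknown:
            raise MissingTaxonError(f"species not in tree: {sorted(unknown)}")
        logger.warning("dropping %d unknown species from pool", len(unknown))
        pool = pool & tips
    if not pool:
        raise ValueError("pool shares no species with the tree")
    out = tree.copy()
    dtree = out.dendropy_tree
    keep = [l.taxon for l in dtree.leaf_node_iter() if l.taxon.label in pool]
    dtree.retain_taxa(keep)
    dtree.purge_taxon_namespace()
    out._refresh()
    return out


def species_ages(tree: DatedTree) -> dict[str, float]:
    """Species age = its parent node's age (= terminal branch length).

    The tree must be ultrametric, so both readings coincide.
    """
    if not tree.is_ultrametric():
        raise ValueError("species ages require an ultrametric tree")
    return {
        leaf.taxon.label: leaf.edge.length or 0.0
        for leaf in tree.dendropy_tree.leaf_node_iter()
    }
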