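"""Taxonomy-based species trees, node-age calibration, and the phylogenetic
covariance matrix.

The species tree is assembled the way comparative studies without molecular
data do it: each species is grafted onto a family-level backbone topology
(bundled here: an 18-family newick consistent with APG-III relationships)
under its family and genus, producing polytomies wherever taxonomy gives no
resolution.  Branch lengths then come from a node-age table by the bladj
rule: named nodes found in the table are fixed to those ages, tips are fixed
at age zero, and every undated node is spaced evenly along the path between
the dated nodes that bracket it.  The result is ultrametric by construction.

The bundled ``node_ages.csv`` holds approximate clade ages (millions of
years) of the magnitudes used in standard angiosperm age compilations; they
set the relative depths of the tree, which is all the downstream statistics
are sensitive to.

Downstream statistics consume the tree through its covariance matrix C,
where C[i, j] is the depth (root-to-node path length) of the most recent
common ancestor of tips i and j — the variance structure implied by Brownian
motion along the tree.  Pagel's lambda transform multiplies the off-diagonal
of C by a factor in [0, 1], shrinking phylogenetic correlation toward
independence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    CalibrationConflictError,
    DomainError,
    TaxonomyLookupError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# newick and bundled-data plumbing


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree."""
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as newick with branch lengths and internal labels."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def load_family_backbone() -> dendropy.Tree:
    """The bundled 18-family backbone topology (no branch lengths)."""
    with resources.as_file(
        resources.files("precocity.data").joinpath("family_backbone.nwk")
    ) as p:
        return read_tree(p)


def read_ages(path: str | Path) -> dict[str, float]:
    """Read a clade-age CSV (columns ``clade``, ``age``) into a mapping."""
    df = pd.read_csv(path)
    for col in ("clade", "age"):
        if col not in df.columns:
            raise ValidationError(f"ages table missing column {col!r}")
    ages = dict(zip(df["clade"].astype(str), df["age"].astype(float)))
    bad = [k for k, v in ages.items() if not v > 0]
    if bad:
        raise ValidationError(f"non-positive age(s) for: {bad}")
    return ages


def load_node_ages() -> dict[str, float]:
    """The bundled clade-age table matching the backbone's node labels."""
    with resources.as_file(
        resources.files("precocity.data").joinpath("node_ages.csv")
    ) as p:
        return read_ages(p)


def _node_name(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


# ---------------------------------------------------------------------------
# taxonomy grafting


def build_taxonomy_tree(
    traits: pd.DataFrame, backbone: dendropy.Tree | None = None
) -> dendropy.Tree:
    """Graft species onto a family backbone by their taxonomy.

    Each backbone tip named after a family with k species becomes: the single
    species tip (k = 1), or an internal node (labelled with the family) whose
    children are its genera — a genus with several species becomes a labelled
    polytomy of species tips, a monotypic genus contributes its species tip
    directly.

    Families in ``traits`` with no backbone tip raise
    :class:`TaxonomyLookupError` listing them.
    """
    if backbone is None:
        backbone = load_family_backbone()
    tree = backbone.clone(depth=1)
    tns = tree.taxon_namespace

    by_family: dict[str, pd.DataFrame] = {
        fam: grp for fam, grp in traits.groupby("family")
    }
    backbone_tips = {_node_name(leaf) for leaf in tree.leaf_node_iter()}
    missing = sorted(set(by_family) - backbone_tips)
    if missing:
        raise TaxonomyLookupError(
            f"families absent from the backbone: {missing}"
        )

    for leaf in list(tree.leaf_node_iter()):
        family = _node_name(leaf)
        if family not in by_family:
            # backbone family not sampled in this study: prune below
            continue
        grp = by_family[family]
        species = list(grp["species"])
        if len(species) == 1:
            leaf.taxon = tns.require_taxon(label=species[0])
            continue
        leaf.taxon = None
        leaf.label = family
        for genus, gg in grp.groupby("genus", sort=False):
            gspecies = list(gg["species"])
            if len(gspecies) == 1:
                leaf.new_child(taxon=tns.require_taxon(label=gspecies[0]))
            else:
                gnode = leaf.new_child()
                gnode.label = genus
                for sp in gspecies:
                    gnode.new_child(taxon=tns.require_taxon(label=sp))

    # drop backbone families that carry no sampled species
    sampled = set(by_family)
    for leaf in list(tree.leaf_node_iter()):
        name = _node_name(leaf)
        if name in backbone_tips and name not in sampled:
            tree.prune_subtree(leaf, suppress_unifurcations=True)
    return tree


# ---------------------------------------------------------------------------
# bladj-style calibration


def bladj_calibrate(tree: dendropy.Tree, ages: dict[str, float]) -> dendropy.Tree:
    """Assign node ages from a table and space undated nodes evenly.

    Named nodes present in ``ages`` are fixed; tips are fixed at age 0.  Every
    undated node, visited root-to-tip, is placed by even spacing between its
    (already dated) parent and the fixed descendant that constrains it most:
    with the parent at age t_P and a fixed descendant at age t_F, d+1 edges
    below the parent, the node sits at t_P - (t_P - t_F)/(d + 1); the oldest
    such candidate wins, which keeps ages monotone down every path.  Branch
    lengths become parent age minus child age, so the output is ultrametric.

    The root must be named and dated.  A fixed node at least as old as its
    dated parent raises :class:`CalibrationConflictError` naming both.
    """
    out = tree.clone(depth=1)
    root = out.seed_node

    fixed_age: dict[int, float] = {}
    for node in out.preorder_node_iter():
        if node.is_leaf():
            fixed_age[id(node)] = 0.0
        else:
            name = _node_name(node)
            if name is not None and name in ages:
                fixed_age[id(node)] = float(ages[name])

    root_name = _node_name(root)
    if id(root) not in fixed_age:
        raise CalibrationConflictError(
            f"root node ({root_name!r}) has no entry in the ages table"
        )

    # fixed descendants (age, edge distance) of every node, tips included
    fixed_below: dict[int, list[tuple[float, int]]] = {}
    for node in out.postorder_node_iter():
        acc: list[tuple[float, int]] = []
        for child in node.child_nodes():
            if id(child) in fixed_age:
                acc.append((fixed_age[id(child)], 1))
            else:
                acc.extend((a, d + 1) for a, d in fixed_below[id(child)])
        fixed_below[id(node)] = acc

    age: dict[int, float] = {}
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            age[id(node)] = fixed_age[id(node)]
            continue
        t_parent = age[id(node.parent_node)]
        if id(node) in fixed_age:
            t = fixed_age[id(node)]
            if t >= t_parent and not node.is_leaf():
                raise CalibrationConflictError(
                    f"node {_node_name(node)!r} (age {t}) is at least as old "
                    f"as its parent {_node_name(node.parent_node)!r} "
                    f"(age {t_parent})"
                )
            age[id(node)] = t
        else:
            candidates = [
                t_parent - (t_parent - tf) / (d + 1)
                for tf, d in fixed_below[id(node)]
            ]
            age[id(node)] = max(candidates)

    for node in out.preorder_node_iter():
        node.age = age[id(node)]
        if node.parent_node is None:
            node.edge.length = 0.0
        else:
            node.edge.length = age[id(node.parent_node)] - age[id(node)]
    return out


def resolve_polytomies(tree: dendropy.Tree, seed: int = 1) -> dendropy.Tree:
    """Randomly resolve multifurcations into bifurcations (seeded).

    Inserted internal branches get length 0, so root-to-tip distances and the
    covariance matrix are unchanged; the choice of resolution is a seeded
    uniform draw and is reproducible.
    """
    out = tree.clone(depth=1)
    rng = random.Random(seed)
    out.resolve_polytomies(rng=rng)
    for edge in out.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return out


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Root-to-node path lengths (the root itself at depth 0)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            if node.edge.length is None:
                raise ValidationError(
                    f"node {_node_name(node)!r} has no branch length"
                )
            depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    depths = node_depths(tree)
    tip_depths = [d for n, d in depths.items() if n.is_leaf()]
    span = max(tip_depths) - min(tip_depths)
    return span <= rel_tol * max(tip_depths)


# ---------------------------------------------------------------------------
# covariance


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance implied by a tree.

    ``matrix[i, j]`` is the depth of the MRCA of ``taxa[i]`` and ``taxa[j]``;
    the diagonal holds root-to-tip distances (constant for an ultrametric
    tree).
    """

    matrix: np.ndarray
    taxa: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.taxa)

    def reorder(self, labels) -> "PhyloCovariance":
        """Return the covariance with rows/columns in the order of ``labels``."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise TaxonomyLookupError(f"taxa not in covariance: {missing}")
        idx = np.array([index[lab] for lab in labels])
        return PhyloCovariance(
            matrix=self.matrix[np.ix_(idx, idx)], taxa=tuple(labels)
        )


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Compute the Brownian covariance matrix of a tree's tips."""
    depths = node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    taxa = tuple(_node_name(leaf) for leaf in leaves)
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    tips_below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tips_below[id(node)] = np.array([i])
            C[i, i] = depths[node]
            continue
        child_sets = [tips_below.pop(id(c)) for c in node.child_nodes()]
        h = depths[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia, ib = child_sets[a], child_sets[b]
                C[np.ix_(ia, ib)] = h
                C[np.ix_(ib, ia)] = h
        tips_below[id(node)] = np.concatenate(child_sets)
    return PhyloCovariance(matrix=C, taxa=taxa)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: scale off-diagonal covariance by ``lam``.

    ``lam = 1`` leaves C unchanged (Brownian motion); ``lam = 0`` removes all
    phylogenetic correlation.  For ultrametric C the result stays positive
    semidefinite on the whole interval.
    """
    if not 0.0 <= lam <= 1.0:
        raise DomainError(f"lambda must lie in [0, 1], got {lam}")
    M = lam * cov.matrix
    np.fill_diagonal(M, np.diag(cov.matrix))
    return PhyloCovariance(matrix=M, taxa=cov.taxa)


def build_study_tree(
    traits: pd.DataFrame | None = None,
    backbone: dendropy.Tree | None = None,
    ages: dict[str, float] | None = None,
    seed: int = 1,
) -> dendropy.Tree:
    """Convenience: graft, calibrate and resolve in one call.

    With no arguments this produces the bundled 30-species study tree.
    """
    if traits is None:
        from .io_tables import load_study_table

        traits = load_study_table()
    tree = build_taxonomy_tree(traits, backbone)
    tree = bladj_calibrate(tree, load_node_ages() if ages is None else ages)
    return resolve_polytomies(tree, seed=seed)
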