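"""Dated phylogenies and Brownian-motion covariance structures.

Under Brownian trait evolution the covariance between two tips equals the
shared branch length from the root to their most recent common ancestor, so
a dated tree maps directly onto an error covariance for generalized least
squares. This module reads Newick trees (via dendropy), prunes them to the
analysis lineages, and builds the covariance matrix C and its unit-diagonal
correlation form R in the dataset's canonical tip order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .lineage_data import AnalysisDataset

logger = logging.getLogger("ploidypath")

#: Branch length for each arm of a duplicated-tip cherry (Myr).
DUPLICATE_TIP_EPSILON = 1e-8

#: Eigenvalue tolerance below which R is declared non-PSD.
PSD_TOL = 1e-8


class TreeError(ValueError):
    """Tree input violates a structural requirement."""


@dataclass
class CovarianceStructure:
    """Brownian shared-path covariance over analysis lineages.

    ``C[i, j]`` is the branch length shared by the root-to-tip paths of tips
    i and j (Myr); the diagonal holds root-to-tip depths. ``R`` is C
    standardized to unit diagonal using per-tip depths, so non-ultrametric
    trees are handled without assuming a common depth.
    """

    C: np.ndarray
    R: np.ndarray
    tip_order: list[str]

    @property
    def n(self) -> int:
        return len(self.tip_order)


# ---------------------------------------------------------------------------
# Tree I/O and pruning
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree with mandatory branch lengths.

    Unlabeled internal nodes and polytomies are allowed. Raises
    :class:`TreeError` for duplicate tip labels or a missing branch length
    on any root-to-tip path.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    _check_tree(tree)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same checks as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeError(f"cannot parse Newick string: {exc}") from exc
    _check_tree(tree)
    return tree


def _check_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            name = (node.taxon.label if node.taxon
                    else f"internal node above {{{', '.join(sorted(l.taxon.label for l in node.leaf_iter()))}}}")
            raise TreeError(f"missing branch length on edge to {name}")
        if node.edge.length < 0:
            raise TreeError("negative branch length in tree")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def read_tip_mapping(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``lineage_id,tip_label`` mapping lineages to tree tips."""
    mapping = {}
    with Path(path).open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or (i == 0 and line.lower().startswith("lineage_id")):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {i + 1} is not two columns")
            mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def prune_to_dataset(tree: dendropy.Tree, dataset: AnalysisDataset,
                     tip_map: dict[str, str] | None = None) -> dendropy.Tree:
    """Prune a tree down to the dataset's lineages.

    ``tip_map`` maps lineage_id to the label of its representative tip in the
    source tree; by default tips are matched by lineage_id. When two lineages
    map to the same source tip (the same genus on two archipelagos), the tip
    is split into a cherry of two near-zero branches so both lineages keep
    essentially the full shared history while C stays positive semidefinite.
    Degree-2 internal nodes left by pruning are collapsed with branch lengths
    summed, so retained root-to-tip depths are unchanged.
    """
    tip_map = tip_map or {}
    wanted = {rid: tip_map.get(rid, rid) for rid in dataset.lineage_ids}
    tree = tree.clone(depth=1)
    available = set(tip_labels(tree))
    missing = sorted(rid for rid, lab in wanted.items()
                     if lab not in available)
    if missing:
        raise TreeError(
            f"lineages with no matching tree tip: {missing}")

    # Lineages per source tip; >1 means the tip must be duplicated.
    by_tip: dict[str, list[str]] = {}
    for rid, lab in wanted.items():
        by_tip.setdefault(lab, []).append(rid)

    taxon_ns = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        lab = leaf.taxon.label
        if lab not in by_tip:
            continue
        rids = sorted(by_tip[lab])
        if len(rids) == 1:
            leaf.taxon.label = rids[0]
        else:
            logger.warning("tip %r shared by lineages %s: duplicated as a "
                           "zero-length cherry", lab, rids)
            leaf.taxon = None
            for rid in rids:
                child = leaf.new_child(edge_length=DUPLICATE_TIP_EPSILON)
                child.taxon = taxon_ns.new_taxon(label=rid)

    keep = set(wanted)
    tree.retain_taxa_with_labels(list(keep))
    tree.suppress_unifurcations()
    return tree


# ---------------------------------------------------------------------------
# Brownian covariance
# ---------------------------------------------------------------------------

def brownian_cov(tree: dendropy.Tree,
                 tip_order: list[str] | None = None) -> CovarianceStructure:
    """Shared-path covariance matrix of a dated tree.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip depths. ``R`` standardizes C to unit diagonal
    with per-tip depths. Polytomies are handled naturally by the shared-path
    definition. If R's smallest eigenvalue falls in ``[-PSD_TOL, 0)`` a
    diagonal jitter of ``PSD_TOL`` is added; anything lower is an error.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise TreeError("need at least 2 tips for a covariance structure")
    labels = [l.taxon.label for l in leaves]
    if tip_order is None:
        tip_order = labels
    else:
        if set(tip_order) != set(labels):
            raise TreeError("tip_order does not match the tree's tip set")
    index = {lab: i for i, lab in enumerate(tip_order)}
    n = len(tip_order)
    C = np.zeros((n, n))

    # Depth-first accumulation: for each internal node at depth d, every tip
    # pair split across two of its children shares exactly d of history.
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    leafsets: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[id(node)]
            leafsets[id(node)] = np.array([i])
        else:
            child_sets = [leafsets.pop(id(ch))
                          for ch in node.child_nodes()]
            d = depth[id(node)]
            if d > 0:
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        ia, ib = child_sets[a], child_sets[b]
                        C[np.ix_(ia, ib)] = d
                        C[np.ix_(ib, ia)] = d
            leafsets[id(node)] = np.concatenate(child_sets)

    depths = np.diag(C)
    if np.any(depths <= 0):
        bad = [tip_order[i] for i in np.where(depths <= 0)[0]]
        raise TreeError(f"zero-depth tips (correlation undefined): {bad}")
    scale = np.sqrt(depths)
    R = C / np.outer(scale, scale)
    np.fill_diagonal(R, 1.0)

    lam = float(np.linalg.eigvalsh(R)[0])
    if lam < -PSD_TOL:
        raise TreeError(f"correlation matrix not PSD "
                        f"(smallest eigenvalue {lam:.3g})")
    if lam < 0:
        logger.warning("correlation matrix marginally non-PSD (%.3g); "
                       "adding %g diagonal jitter", lam, PSD_TOL)
        R = R + PSD_TOL * np.eye(n)
        R = R / np.outer(np.sqrt(np.diag(R)), np.sqrt(np.diag(R)))
    return CovarianceStructure(C=C, R=R, tip_order=list(tip_order))
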