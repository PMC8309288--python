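"""Distance-based clustering of alleles by flesh-colour group.

The claim this module supports is structural, not evolutionary: alleles of the
red-flesh group are more similar to each other than to any white-flesh allele,
so a distance tree contains an internal edge splitting the leaves exactly into
the two groups.  p-distance on reference-projected columns is sufficient for
that purpose; no substitution model is fitted.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import skbio
from skbio.tree import TreeNode, nj

from .variant_analysis import PanelAlignment

logger = logging.getLogger(__name__)


class DistanceError(ValueError):
    """A pair of alleles shares no comparable alignment columns."""


class LabelError(ValueError):
    """A leaf lacks its Rf/Wf group label."""


def distance_matrix(pa: PanelAlignment) -> skbio.DistanceMatrix:
    """p-distance over reference-projected columns, gap/N columns excluded per pair.

    Insertions relative to the reference are not columns of the projection and do
    not contribute; this is a similarity summary, not an evolutionary distance.
    """
    ids, mat = pa.base_matrix()
    if len(ids) < 2:
        raise ValueError("need at least two alleles")
    n_code = ord("N")
    valid = (mat != 0) & (mat != n_code)
    k = len(ids)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise DistanceError(f"no comparable columns between {ids[i]} and {ids[j]}")
            mism = int((mat[i][both] != mat[j][both]).sum())
            dm[i, j] = dm[j, i] = mism / compared
    return skbio.DistanceMatrix(dm, ids)


def build_nj_tree(dm: skbio.DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    Taxa are processed in sorted-id order so the result does not depend on the
    input ordering of the matrix.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    raw = nj(dm, neg_as_zero=False)
    if any(n.length is not None and n.length < 0 for n in raw.traverse()):
        logger.warning("negative neighbor-joining branch lengths clamped to 0")
    return nj(dm, neg_as_zero=True)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Midpoint-rooted copy, for display only (analysis stays unrooted)."""
    return tree.copy().root_at_midpoint()


def tree_bipartitions(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf sets under each internal edge (one side of each bipartition)."""
    out = []
    for node in tree.non_tips(include_self=False):
        out.append(frozenset(leaf.name for leaf in node.tips()))
    return out


def check_group_split(tree: TreeNode, groups: Mapping[str, str]) -> tuple[bool, dict]:
    """True iff some internal edge splits the leaves exactly into Rf vs Wf."""
    leaves = [leaf.name for leaf in tree.tips()]
    unlabeled = [l for l in leaves if l not in groups or groups[l] not in ("Rf", "Wf")]
    if unlabeled:
        raise LabelError(f"leaves without Rf/Wf labels: {sorted(unlabeled)}")
    rf = frozenset(l for l in leaves if groups[l] == "Rf")
    wf = frozenset(l for l in leaves if groups[l] == "Wf")
    split = False
    for part in tree_bipartitions(tree):
        if part in (rf, wf):
            split = True
            break
    report = {
        "split": split,
        "n_rf": len(rf),
        "n_wf": len(wf),
        "rf_leaves": sorted(rf),
        "wf_leaves": sorted(wf),
    }
    return split, report


def mean_group_distances(dm: skbio.DistanceMatrix, groups: Mapping[str, str]) -> dict:
    """Mean within- and between-group p-distances (diagnostic report)."""
    ids = list(dm.ids)
    within, between = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = dm[ids[i], ids[j]]
            if groups.get(ids[i]) == groups.get(ids[j]):
                within.append(d)
            else:
                between.append(d)
    return {
        "mean_within": float(np.mean(within)) if within else float("nan"),
        "mean_between": float(np.mean(between)) if between else float("nan"),
    }
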