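"""Average-linkage clustering and hybrid dynamic branch cutting.

Module detection proceeds in two steps: UPGMA (average linkage)
agglomeration of the TOM dissimilarity, then a "hybrid" dynamic cut of
the resulting dendrogram.  Unlike a static cut at a single height, the
hybrid cut walks the merge tree below the cut height and decides per
branch whether it is a genuine cluster, from two shape quantities:

* core scatter — the average merge height inside a branch; a tight
  cluster joins its members low in the tree;
* gap — the drop between the height at which a branch attaches to the
  rest of the tree and the branch's own top merge; a distinct cluster
  hangs well below its attachment point.

The two are combined into a scale-free *relative separation*

    r = gap / (gap + (top - core scatter))
      = (attach - top) / (attach - core scatter)  in [0, 1],

the fraction of a branch's total height footprint (from its attachment
point down to its average internal merge) accounted for by clear
separation from its surroundings.  A genuine branch hangs well below its
attachment relative to its own internal spread, so r is large; an
arbitrary bipartition of a homogeneous cluster has merges reaching
almost up to the attachment, so r is near 0.  Because r is
self-normalizing, branches are detected equally well whether the
informative structure spans the dendrogram or is compressed into a thin
height sliver just under the cut height (typical for topological-overlap
dissimilarities of weakly co-expressed modules).

``deep_split`` in {0, 1, 2, 3} trades robustness for sensitivity through
the conventional core-scatter ladder {0.64, 0.73, 0.82, 0.91}: the
minimum relative separation required to *split* a join into two branches
is tau = 1 - ladder value, i.e. {0.36, 0.27, 0.18, 0.09}.  Labelling a
whole branch as one module always uses the most conservative level
(r >= 0.36), so higher deep_split only makes splits easier and the
number of detected modules is nondecreasing in deep_split.  Branches
smaller than ``min_size`` (or insufficiently separated) leave their
genes unassigned (label 0); an optional PAM-like stage then reassigns
unlabelled genes to the nearest cluster when they fall within its
radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["Dendrogram", "average_linkage", "hybrid_dynamic_cut", "DEEP_SPLIT_CORE_SCATTER"]

#: deep_split level -> core-scatter ladder; min relative separation for a
#: branch *split* = 1 - value
DEEP_SPLIT_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91}

#: minimum relative separation for labelling a whole branch as one module;
#: fixed at the most conservative ladder level (1 - 0.64) across
#: deep_split, so that deeper splitting only refines the partition
#: (module counts nondecreasing in deep_split) and loosely attached
#: noise-padded blobs never qualify wholesale
QUALIFY_SEPARATION = 0.36


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus the leaf identifiers."""

    linkage: np.ndarray  # (n-1, 4) scipy format; heights nondecreasing
    gene_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.gene_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.linkage)

    def to_merge_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.linkage[:, :3], columns=["left", "right", "height"]
        ).astype({"left": int, "right": int})


def average_linkage(dissimilarity: np.ndarray, gene_ids=None) -> Dendrogram:
    """UPGMA tree of a square symmetric dissimilarity with zero diagonal."""
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"dissimilarity must be square, got {d.shape}")
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if gene_ids is None:
        gene_ids = [str(i) for i in range(d.shape[0])]
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=z, gene_ids=list(gene_ids))


class _Subtree:
    __slots__ = ("members", "top", "sum_heights", "n_merges")

    def __init__(self, members, top, sum_heights, n_merges):
        self.members = members          # leaf indices, numpy array
        self.top = top                  # height of this node's own merge (0 for leaves)
        self.sum_heights = sum_heights  # sum of merge heights in the subtree incl. top
        self.n_merges = n_merges

    @property
    def size(self):
        return len(self.members)

    def core_scatter(self):
        return self.sum_heights / self.n_merges if self.n_merges else 0.0

    def separation(self, attach: float) -> float:
        """Relative separation r in [0, 1] w.r.t. an attachment height."""
        gap = attach - self.top
        denom = attach - self.core_scatter()
        if denom <= 0:
            return 1.0 if gap > 0 else 0.0
        return max(0.0, min(1.0, gap / denom))


def _build_subtrees(z: np.ndarray, n: int) -> list[_Subtree]:
    """Bottom-up pass collecting members and height statistics per node."""
    nodes: list[_Subtree] = [
        _Subtree(np.array([i]), 0.0, 0.0, 0) for i in range(n)
    ]
    for m in range(z.shape[0]):
        li, ri, h = int(z[m, 0]), int(z[m, 1]), float(z[m, 2])
        left, right = nodes[li], nodes[ri]
        nodes.append(
            _Subtree(
                np.concatenate([left.members, right.members]),
                h,
                left.sum_heights + right.sum_heights + h,
                left.n_merges + right.n_merges + 1,
            )
        )
    return nodes


def hybrid_dynamic_cut(
    dendrogram: Dendrogram,
    dissimilarity: np.ndarray,
    deep_split: int = 1,
    cut_height: float = 0.99,
    min_size: int = 27,
    pam_stage: bool = True,
) -> np.ndarray:
    """Assign leaves to modules by hybrid dynamic branch cutting.

    Returns an integer label per leaf: 1, 2, ... for modules (relabelled
    by decreasing size), 0 for unassigned.
    """
    if deep_split not in DEEP_SPLIT_CORE_SCATTER:
        raise ValueError(f"deep_split must be in {sorted(DEEP_SPLIT_CORE_SCATTER)}")
    if not (0.0 < cut_height <= 1.0):
        raise ValueError(f"cut_height must be in (0, 1], got {cut_height}")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    z = dendrogram.linkage
    n = dendrogram.n_leaves
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape != (n, n):
        raise ValueError("dissimilarity does not match the dendrogram's leaves")

    tau = 1.0 - DEEP_SPLIT_CORE_SCATTER[deep_split]
    nodes = _build_subtrees(z, n)
    root = 2 * n - 2 if n > 1 else 0

    labels = np.zeros(n, dtype=int)
    next_label = 1

    def distinct(node: _Subtree, attach: float) -> bool:
        return node.size >= min_size and node.separation(attach) >= tau

    def qualifies(node: _Subtree, attach: float) -> bool:
        return node.size >= min_size and node.separation(attach) >= QUALIFY_SEPARATION

    # Top-down walk.  A node spanning the cut height is transparent
    # (descend; children attach at the cut height).  A below-cut node is
    # split into its children when both are sizeable branches clearly
    # separated at the join; otherwise it is labelled whole when itself
    # distinct at its attachment, and descended into otherwise so tight
    # sub-branches can surface while loose outliers fall away unassigned.
    stack: list[tuple[int, float]] = [(root, cut_height)]
    while stack:
        idx, attach = stack.pop()
        node = nodes[idx]
        if node.size < min_size:
            continue  # members stay unassigned
        if idx < n:  # single leaf (a module only when min_size == 1)
            labels[node.members] = next_label
            next_label += 1
            continue
        merge = idx - n
        li, ri = int(z[merge, 0]), int(z[merge, 1])
        if node.top > cut_height:
            stack.append((li, cut_height))
            stack.append((ri, cut_height))
            continue
        left, right = nodes[li], nodes[ri]
        if distinct(left, node.top) and distinct(right, node.top):
            stack.append((li, node.top))
            stack.append((ri, node.top))
        elif qualifies(node, attach):
            labels[node.members] = next_label
            next_label += 1
        else:
            # not a branch at this attachment: treat the join as transparent
            # (keeps the ambient attachment while stripping chained outliers)
            stack.append((li, attach))
            stack.append((ri, attach))

    if pam_stage and next_label > 1:
        labels = _pam_assign(labels, d)

    return _relabel_by_size(labels)


def _pam_assign(labels: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Assign unlabelled leaves to the nearest cluster when inside its radius.

    A cluster's radius is the largest average dissimilarity of any member
    to its co-members; a stray leaf joins the closest cluster (by average
    dissimilarity) if it is no farther than that.
    """
    labels = labels.copy()
    cluster_ids = [c for c in np.unique(labels) if c != 0]
    if not cluster_ids:
        return labels
    unassigned = np.where(labels == 0)[0]
    members = {c: np.where(labels == c)[0] for c in cluster_ids}
    radii = {}
    for c, mem in members.items():
        if len(mem) < 2:
            radii[c] = 0.0
            continue
        sub = d[np.ix_(mem, mem)]
        avg = sub.sum(axis=1) / (len(mem) - 1)
        radii[c] = float(avg.max())
    for i in unassigned:
        best_c, best_dist = 0, np.inf
        for c, mem in members.items():
            dist = float(d[i, mem].mean())
            if dist < best_dist:
                best_c, best_dist = c, dist
        if best_c != 0 and best_dist <= radii[best_c]:
            labels[i] = best_c
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber modules 1..m by decreasing size (ties by original label)."""
    out = np.zeros_like(labels)
    ids, counts = np.unique(labels[labels != 0], return_counts=True)
    order = sorted(zip(-counts, ids))
    for new, (_, old) in enumerate(order, start=1):
        out[labels == old] = new
    return out
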