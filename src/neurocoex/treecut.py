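"""Adaptive dendrogram cutting for module detection (dynamic hybrid style).

Modules are branches of an average-linkage dendrogram built on a
topological-overlap dissimilarity.  A single static cut height cannot
separate nested modules from background, so branches are found adaptively:

1. An adaptive cut height is placed at 99% of the range between the 5th
   percentile and the maximum of the merge heights; connected components
   below it form the coarse branches.
2. Each coarse branch is decomposed top-down.  At an internal node the two
   children are split apart only if each child is itself a viable cluster:
   at least ``min_cluster_size`` leaves, a core scatter (mean internal
   merge height, normalized to the cut range) at most ``max_core_scatter``,
   and a gap to the parent merge of at least ``min_gap`` of the cut range.
   If only one child is viable the other child's leaves fall back to the
   unassigned pool and decomposition continues inside the viable child.
3. A terminal branch becomes a module if it has at least
   ``min_cluster_size`` leaves and passes the core-scatter bound;
   otherwise its leaves are unassigned.
4. PAM-like rescue: each unassigned leaf joins the module with the
   smallest average dissimilarity, provided it is no farther from that
   module than the module's own most peripheral member (95th percentile of
   member-to-module average dissimilarity).

The ``deep_split`` integer (0-4) trades off sensitivity against robustness
by mapping to ``max_core_scatter`` in (0.64, 0.73, 0.82, 0.91, 0.95) with
``min_gap = (1 - max_core_scatter) * 3/4``: higher values accept more
heterogeneous cores and smaller gaps, so they split more aggressively.

A simplified static alternative (:func:`cutree_height`) cuts at a constant
height and applies only the size filter.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, to_tree

_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


def _deep_split_params(deep_split: int) -> tuple[float, float]:
    if deep_split not in range(5):
        raise ValueError("deep_split must be an integer in 0..4")
    mcs = _CORE_SCATTER[deep_split]
    return mcs, (1.0 - mcs) * 3.0 / 4.0


def cutree_hybrid(
    link: np.ndarray,
    diss: np.ndarray,
    min_cluster_size: int = 20,
    deep_split: int = 2,
    cut_height: float | None = None,
    pam_stage: bool = True,
    pam_radius_quantile: float = 0.95,
) -> np.ndarray:
    """Cluster labels from an average-linkage tree, 0 = unassigned.

    Parameters mirror the module-detection contract: *link* is a scipy
    linkage matrix over the objects of the square dissimilarity *diss*.
    Returns integer labels ordered by decreasing cluster size (1 = largest).
    Fully deterministic: ties resolve to the lowest index.
    """
    diss = np.asarray(diss, dtype=float)
    n = diss.shape[0]
    if n < min_cluster_size:
        warnings.warn(
            f"{n} objects < min_cluster_size={min_cluster_size}; all unassigned"
        )
        return np.zeros(n, dtype=int)

    heights = link[:, 2]
    ref = float(np.quantile(heights, 0.05))
    top = float(heights.max())
    if cut_height is None:
        cut_height = ref + 0.99 * (top - ref)
    scale = max(cut_height - ref, 1e-12)
    max_core_scatter, min_gap = _deep_split_params(deep_split)

    root, nodes = to_tree(link, rd=True)

    leaves_cache: dict[int, np.ndarray] = {}

    def leaves(node) -> np.ndarray:
        if node.id not in leaves_cache:
            if node.is_leaf():
                leaves_cache[node.id] = np.array([node.id])
            else:
                leaves_cache[node.id] = np.concatenate(
                    [leaves(node.left), leaves(node.right)]
                )
        return leaves_cache[node.id]

    scatter_cache: dict[int, float] = {}

    def core_scatter(node) -> float:
        """Mean internal merge height, normalized to the cut range."""
        if node.is_leaf():
            return 0.0
        if node.id not in scatter_cache:
            internal = []
            stack = [node]
            while stack:
                cur = stack.pop()
                if not cur.is_leaf():
                    internal.append(cur.dist)
                    stack.extend([cur.left, cur.right])
            mean_h = float(np.mean(internal))
            scatter_cache[node.id] = max(0.0, (mean_h - ref) / scale)
        return scatter_cache[node.id]

    def spine_of(node) -> tuple[list, object]:
        """Peel small side branches from the top: (spine records, core node).

        Each record is ``(merge height, small child, big child)``; the walk
        stops at a leaf, a junction of two large children, or two small ones.
        """
        spine = []
        cur = node
        while (
            not cur.is_leaf()
            and min(cur.left.count, cur.right.count) < min_cluster_size
            and max(cur.left.count, cur.right.count) >= min_cluster_size
        ):
            big, small = (
                (cur.left, cur.right)
                if cur.left.count >= cur.right.count
                else (cur.right, cur.left)
            )
            spine.append((cur.dist, small, big))
            cur = big
        return spine, cur

    def core_top(node) -> float:
        """Merge height of the branch core once top fringe is peeled off."""
        spine, cur = spine_of(node)
        if not spine:
            return 0.0 if node.is_leaf() else node.dist
        heights = [h for h, _s, _b in spine]
        heights.append(cur.dist if not cur.is_leaf() else ref)
        gaps = [(heights[i] - heights[i + 1]) / scale for i in range(len(heights) - 1)]
        j = int(np.argmax(gaps))
        return heights[j + 1] if gaps[j] >= min_gap else heights[0]

    def viable(node, parent_height: float) -> bool:
        if node.count < min_cluster_size:
            return False
        if core_scatter(node) > max_core_scatter:
            return False
        gap = (parent_height - core_top(node)) / scale
        return gap >= min_gap

    clusters: list[np.ndarray] = []
    unassigned: list[np.ndarray] = []

    def decompose(node) -> None:
        if node.count < min_cluster_size:
            unassigned.append(leaves(node))
            return
        if not node.is_leaf():
            left, right = node.left, node.right
            if viable(left, node.dist) and viable(right, node.dist):
                decompose(left)
                decompose(right)
                return
            # peel small side branches from the top; if the largest height
            # drop along the spine is a real gap, everything above it is
            # fringe and the subtree below is the branch core
            spine, cur = spine_of(node)
            if spine:
                heights = [h for h, _s, _b in spine]
                heights.append(cur.dist if not cur.is_leaf() else ref)
                gaps = [
                    (heights[i] - heights[i + 1]) / scale
                    for i in range(len(heights) - 1)
                ]
                j = int(np.argmax(gaps))
                if gaps[j] >= min_gap:
                    for _h, small, _b in spine[: j + 1]:
                        unassigned.append(leaves(small))
                    decompose(spine[j][2])
                    return
        if core_scatter(node) <= max_core_scatter:
            clusters.append(leaves(node))
        else:
            unassigned.append(leaves(node))

    coarse = fcluster(link, t=cut_height, criterion="distance")
    for comp in np.unique(coarse):
        members = np.flatnonzero(coarse == comp)
        if len(members) == 1:
            unassigned.append(members)
            continue
        # find the subtree spanning exactly this component
        member_set = set(members.tolist())
        node = nodes[int(members[0])]
        while node.count < len(members):
            node = _parent(nodes, link, node, n)
        if set(leaves(node).tolist()) == member_set:
            decompose(node)
        else:  # should not happen with a distance cut; be safe
            unassigned.append(members)

    labels = np.zeros(n, dtype=int)
    clusters.sort(key=lambda c: (-len(c), int(c.min())))
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab

    if pam_stage and clusters:
        labels = _pam_assign(labels, diss, pam_radius_quantile)
    return labels


def _parent(nodes, link, node, n):
    """Walk up: find the internal node having *node* as a child."""
    target = node.id
    for i, row in enumerate(link):
        if int(row[0]) == target or int(row[1]) == target:
            return nodes[n + i]
    raise RuntimeError("node has no parent")


def _pam_assign(labels: np.ndarray, diss: np.ndarray, radius_quantile: float) -> np.ndarray:
    """Assign borderline objects to the nearest cluster by average
    dissimilarity, if within that cluster's peripheral radius."""
    out = labels.copy()
    cluster_ids = [c for c in np.unique(labels) if c != 0]
    mean_to = {}
    radius = {}
    for c in cluster_ids:
        members = np.flatnonzero(labels == c)
        d = diss[:, members].mean(axis=1)
        mean_to[c] = d
        member_d = (diss[np.ix_(members, members)].sum(axis=1)) / max(len(members) - 1, 1)
        radius[c] = float(np.quantile(member_d, radius_quantile))
    for i in np.flatnonzero(labels == 0):
        best, best_d = 0, np.inf
        for c in cluster_ids:
            if mean_to[c][i] < best_d:
                best, best_d = c, mean_to[c][i]
        if best != 0 and best_d <= radius[best]:
            out[i] = best
    return out


def cutree_height(
    link: np.ndarray,
    cut_height: float,
    min_cluster_size: int = 20,
) -> np.ndarray:
    """Static cut: constant height plus minimum-size filter, 0 = unassigned."""
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = [(int((raw == c).sum()), int(np.flatnonzero(raw == c).min()), c)
             for c in np.unique(raw)]
    keep = [c for size, _first, c in sorted(sizes, key=lambda t: (-t[0], t[1]))
            if size >= min_cluster_size]
    for lab, c in enumerate(keep, start=1):
        labels[raw == c] = lab
    return labels
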