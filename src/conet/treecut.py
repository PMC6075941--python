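"""Dynamic-hybrid branch cutting of a hierarchical clustering dendrogram.

Fixed-height dendrogram cuts cannot separate nested coexpression modules and
happily promote a featureless noise blob to a "cluster". This module instead
detects branches that look like genuine clusters: a branch qualifies as a
module when it is large enough and separated from its surroundings by a
clear *relative gap* — the jump between the height at which the branch joins
the rest of the tree and the height at which its own members stopped
merging, measured relative to the branch's internal height spread. The
statistic is scale-invariant, so it behaves identically whether the
dissimilarities span (0, 1) or are compressed near 1 by a large
soft-threshold power. A featureless tree merges continuously and shows no
such jump anywhere.

The deep-split setting (0..4) maps to the minimum relative gap, from
conservative (0: few, strongly separated modules; noise stays unassigned)
to aggressive (4: many small modules). Unassigned objects can then be
adopted by the nearest accepted branch in a PAM-like pass, provided they
fall inside the branch's height envelope and sit closer to the branch than
to the rest of the network.
"""

from __future__ import annotations

import numpy as np

# deep_split 0..4 -> minimum relative gap for branch acceptance
_MIN_RELGAP = (0.25, 0.18, 0.12, 0.07, 0.03)


def _subtree_tables(link: np.ndarray, n_leaves: int):
    """Members and internal merge heights for every node.

    Leaves are 0..n-1, internal nodes n..2n-2 in scipy linkage order; a
    subtree's height list includes its own top merge.
    """
    members: list[list[int]] = [[i] for i in range(n_leaves)]
    heights: list[list[float]] = [[] for _ in range(n_leaves)]
    for k in range(n_leaves - 1):
        a, b = int(link[k, 0]), int(link[k, 1])
        members.append(members[a] + members[b])
        heights.append(heights[a] + heights[b] + [float(link[k, 2])])
    return members, heights


def relative_gap(internal_heights, attach: float) -> float:
    """Separation of a branch from its surroundings.

    (attach - top) / (attach - median internal height): 0 when the branch
    merges into the rest at the same height its own members were still
    merging (featureless continuum), approaching 1 when the branch is tight
    and joins the rest far above its internal structure.
    """
    top = max(internal_heights)
    med = float(np.median(internal_heights))
    denom = attach - med
    if denom <= 0:
        return 0.0
    return max(0.0, (attach - top) / denom)


def cut_tree_hybrid(link: np.ndarray, n_leaves: int,
                    min_cluster_size: int = 30, deep_split: int = 2,
                    diss: np.ndarray | None = None,
                    pam_stage: bool = True) -> np.ndarray:
    """Cut a scipy linkage tree into modules; label 0 = unassigned.

    Parameters
    ----------
    link : linkage matrix from :func:`scipy.cluster.hierarchy.linkage`.
    n_leaves : number of clustered objects.
    min_cluster_size : smallest branch accepted as a module.
    deep_split : 0 (conservative) .. 4 (aggressive) split sensitivity.
    diss : optional full dissimilarity matrix enabling the PAM-like
        adoption of unassigned objects.
    pam_stage : whether to run the adoption pass (needs ``diss``).

    Returns
    -------
    ndarray of int labels, 1..k in decreasing module size, 0 for unassigned.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    link = np.asarray(link, dtype=float)
    labels = np.zeros(n_leaves, dtype=int)
    if n_leaves < 2 or np.ptp(link[:, 2]) == 0:
        return labels  # no height structure to cut
    min_gap = _MIN_RELGAP[deep_split]
    members, heights = _subtree_tables(link, n_leaves)
    sizes = [len(m) for m in members]
    h_max = float(link[:, 2].max())

    root = 2 * n_leaves - 2
    parent_height, parent_node = {}, {}
    for k in range(n_leaves - 1):
        for child in (int(link[k, 0]), int(link[k, 1])):
            parent_height[child] = float(link[k, 2])
            parent_node[child] = n_leaves + k

    # every internal non-root branch large enough and separated enough is a
    # candidate module; the root has no surroundings so it never qualifies
    candidates = []
    for node in range(n_leaves, root):
        if sizes[node] < min_cluster_size:
            continue
        gap = relative_gap(heights[node], parent_height[node])
        if gap >= min_gap:
            candidates.append((gap, sizes[node], node))
    if not candidates:
        return labels

    # greedy non-overlapping selection, largest branch first: among nested
    # candidates (a module and a tight core inside it) the whole module
    # wins; a branch spanning two modules almost never qualifies because
    # its internal top merge sits at its attachment height
    candidates.sort(key=lambda c: (-c[1], -c[0], c[2]))
    taken = np.zeros(n_leaves, dtype=bool)
    accepted = []
    for _, _, node in candidates:
        idx = members[node]
        if taken[idx].any():
            continue
        taken[idx] = True
        accepted.append(node)

    # order modules by size for stable labels
    accepted = sorted(accepted, key=lambda nd: (-sizes[nd], nd))
    for lab, node in enumerate(accepted, start=1):
        labels[members[node]] = lab

    if pam_stage and diss is not None:
        diss = np.asarray(diss, dtype=float)
        # adoption envelope: the height at which the module's lineage first
        # meets another accepted module (an accepted branch may be a tight
        # core whose immediate parent merge is still inside the module)
        member_sets = [set(members[node]) for node in accepted]
        thresholds = []
        for i, node in enumerate(accepted):
            others = set().union(*(s for j, s in enumerate(member_sets)
                                   if j != i)) if len(accepted) > 1 else set()
            current, envelope = node, h_max
            while current in parent_node:
                up = parent_node[current]
                if set(members[up]) & others:
                    envelope = parent_height[current]
                    break
                current = up
            thresholds.append(envelope)
        mod_members = [np.array(members[node]) for node in accepted]
        grey = np.where(labels == 0)[0]
        for g in grey:
            dists = [diss[g, mm].mean() for mm in mod_members]
            best = int(np.argmin(dists))
            outside = np.setdiff1d(np.arange(n_leaves),
                                   np.append(mod_members[best], g))
            # adopt only genes that sit inside the branch's height envelope
            # and are closer to the module than to the rest of the network
            if (dists[best] <= thresholds[best]
                    and (outside.size == 0
                         or dists[best] < diss[g, outside].mean())):
                labels[g] = best + 1
    return labels
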