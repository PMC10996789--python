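"""Hybrid dynamic cut of an average-linkage dendrogram.

Modules are branches of the dendrogram that are simultaneously

* large enough (``min_module_size``);
* internally tight: the mean height of the merges forming the branch core
  stays at or below an absolute core-scatter ceiling;
* separated from their surroundings: the height at which the branch
  attaches to the rest of the tree exceeds the 90th percentile of its
  internal merge heights by an absolute gap (the trimmed top tolerates a
  few late-joining stragglers);
* coherent: the mean within-branch dissimilarity sits well below the mean
  over all protein pairs, measured in SDs of the pairwise dissimilarity
  distribution.  This is the scale-free check that keeps unstructured
  data unassigned — a noise dendrogram is self-similar at every height,
  so height-derived criteria alone cannot reject it.

The ``deep_split`` level in {0..4} tunes how aggressively branches are
split: the relative core-scatter ceiling is (0.64, 0.73, 0.82, 0.91,
0.95), the minimum relative gap (1 - ceiling) * 3/4 (both made absolute
on the scale between the 5th percentile of merge heights and the cut
height), and the coherence requirement loosens from 2 to 1 pairwise SDs.
A PAM-like stage then assigns leftover objects to the nearest detected
cluster by mean dissimilarity, optionally restricted to clusters in the
object's own dendrogram branch.  Objects that survive neither step are
labelled grey.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import to_tree

#: deep_split level -> relative maximum core scatter
_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


@dataclass
class _Branch:
    leaves: np.ndarray        # leaf indices
    heights: np.ndarray       # internal merge heights, ascending
    top: float                # highest internal merge (0 for singleton)
    d_sum: float              # sum of within-branch pairwise dissimilarities


def _core_size(branch_size: int, min_module_size: int) -> int:
    base = min_module_size // 2 + 1
    if base < branch_size:
        return int(base + np.sqrt(branch_size - base))
    return branch_size


def _collect(node, info: dict, d: np.ndarray) -> _Branch:
    if node.id in info:
        return info[node.id]
    if node.is_leaf():
        b = _Branch(np.array([node.id]), np.array([]), 0.0, 0.0)
    else:
        l = _collect(node.left, info, d)
        r = _collect(node.right, info, d)
        heights = np.sort(np.concatenate([l.heights, r.heights, [node.dist]]))
        cross = float(d[np.ix_(l.leaves, r.leaves)].sum())
        b = _Branch(np.concatenate([l.leaves, r.leaves]), heights, node.dist,
                    l.d_sum + r.d_sum + cross)
    info[node.id] = b
    return b


def cutree_hybrid(
    linkage: np.ndarray,
    dissimilarity: np.ndarray,
    deep_split: int = 4,
    min_module_size: int = 30,
    pam_stage: bool = True,
    pam_respects_dendro: bool = True,
    cut_height: float | None = None,
) -> np.ndarray:
    """Label dendrogram leaves with integer cluster ids (0 = unassigned).

    Parameters
    ----------
    linkage
        scipy linkage matrix from average-linkage clustering of
        ``dissimilarity``.
    dissimilarity
        The full dissimilarity matrix the tree was built from (1 - TOM).
    deep_split
        Split sensitivity level, 0 (conservative) to 4 (aggressive).
    cut_height
        Merges above this height are never inside a cluster; default is
        the maximum merge height (no cap) — branch separation is already
        enforced by the gap and coherence criteria, and with average
        linkage on fuzzy modules the last members routinely join within a
        percent of the tree top.

    Returns
    -------
    numpy.ndarray of int, cluster id per leaf; ids are 1..k ordered by
    decreasing cluster size, 0 marks unassigned (grey) objects.
    """
    if deep_split not in _CORE_SCATTER:
        raise ValueError(f"deep_split must be in 0..4, got {deep_split}")
    n = linkage.shape[0] + 1
    if n < 2:
        raise ValueError("need at least 2 objects to cut a tree")
    d = np.asarray(dissimilarity, float)
    if d.shape != (n, n):
        raise ValueError("dissimilarity shape does not match the linkage")

    heights = linkage[:, 2]
    if cut_height is None:
        cut_height = float(heights.max())
    h_low = float(np.quantile(heights, 0.05))
    span = max(cut_height - h_low, 1e-12)
    max_abs_scatter = h_low + _CORE_SCATTER[deep_split] * span
    min_abs_gap = (1.0 - _CORE_SCATTER[deep_split]) * 0.75 * span
    coherence_cut = -(2.0 - 0.25 * deep_split)  # SDs below the pairwise mean

    iu = np.triu_indices(n, k=1)
    pair_mean = float(d[iu].mean())
    pair_sd = float(d[iu].std())
    if pair_sd == 0:  # all dissimilarities equal: nothing to separate
        return np.zeros(n, dtype=int)

    root = to_tree(linkage)
    info: dict[int, _Branch] = {}
    _collect(root, info, d)

    def core_scatter(b: _Branch) -> float:
        if b.heights.size == 0:
            return 0.0
        k = _core_size(b.leaves.size, min_module_size)
        return float(b.heights[: max(k - 1, 1)].mean())

    def coherence(b: _Branch) -> float:
        m = b.leaves.size
        mean_within = b.d_sum / (m * (m - 1) / 2)
        return (mean_within - pair_mean) / pair_sd

    def qualifies(node, attach: float) -> bool:
        b = info[node.id]
        if b.leaves.size < min_module_size:
            return False
        if b.top > cut_height:
            return False
        if core_scatter(b) > max_abs_scatter:
            return False
        trimmed_top = float(np.quantile(b.heights, 0.90))
        if (attach - trimmed_top) < min_abs_gap:
            return False
        return coherence(b) <= coherence_cut

    def best_partition(node, attach: float) -> list[np.ndarray]:
        # deepest qualifying partition: sub-branches win over their union,
        # so two merged modules split as long as each side carries its own
        # qualifying branch; a branch's halves fail the gap criterion
        # (within-module merge heights are continuous), so true modules do
        # not over-split
        if node.is_leaf():
            return []
        sub = best_partition(node.left, node.dist) \
            + best_partition(node.right, node.dist)
        if sub:
            return sub
        if qualifies(node, attach):
            return [info[node.id].leaves]
        return []

    clusters = best_partition(root, attach=max(float(root.dist), cut_height) + span)

    labels = np.zeros(n, dtype=int)
    for cid, leaves in enumerate(clusters, start=1):
        labels[leaves] = cid

    if pam_stage and clusters:
        labels = _pam_assign(labels, d, root, info, cut_height,
                             pam_respects_dendro,
                             pair_mean, pair_sd, coherence_cut / 2.0)

    return _order_by_size(labels)


def _pam_assign(labels, d, root, info, cut_height, respects_dendro,
                pair_mean, pair_sd, assign_cut) -> np.ndarray:
    """Assign unlabelled objects to the nearest cluster by mean dissimilarity.

    An object is only assigned when its mean dissimilarity to the winning
    cluster sits at least ``|assign_cut|`` pairwise SDs below the all-pairs
    mean — objects no closer to the cluster than a random protein pair
    stay grey.
    """
    labels = labels.copy()
    cluster_ids = [c for c in np.unique(labels) if c != 0]
    members = {c: np.flatnonzero(labels == c) for c in cluster_ids}
    unassigned = np.flatnonzero(labels == 0)
    if unassigned.size == 0:
        return labels

    allowed: dict[int, set[int]] = {}
    if respects_dendro:
        # candidate clusters for a leaf: those inside the smallest ancestor
        # branch (height <= cut_height) that contains at least one cluster
        cluster_of_leaf = {int(i): int(labels[i])
                           for i in np.flatnonzero(labels != 0)}

        def walk(node, path):
            if node.is_leaf():
                if labels[node.id] == 0:
                    for anc in reversed(path):
                        if anc.dist > cut_height:
                            continue
                        b = info[anc.id]
                        cands = {cluster_of_leaf[int(l)] for l in b.leaves
                                 if int(l) in cluster_of_leaf}
                        if cands:
                            allowed[node.id] = cands
                            break
                return
            walk(node.left, path + [node])
            walk(node.right, path + [node])

        walk(root, [])

    for i in unassigned:
        cands = cluster_ids if not respects_dendro \
            else sorted(allowed.get(int(i), ()))
        if not cands:
            continue
        mean_d = {c: float(d[i, members[c]].mean()) for c in cands}
        best = min(mean_d, key=lambda c: (mean_d[c], c))
        if (mean_d[best] - pair_mean) / pair_sd <= assign_cut:
            labels[i] = best
    return labels


def _order_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 1..k by decreasing size (ties: smallest leaf)."""
    out = np.zeros_like(labels)
    ids = [c for c in np.unique(labels) if c != 0]
    ids.sort(key=lambda c: (-(labels == c).sum(),
                            int(np.flatnonzero(labels == c)[0])))
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out
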