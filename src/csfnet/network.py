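"""Signed weighted co-expression network construction and module detection.

The pipeline follows the standard weighted correlation-network recipe for
proteomics: biweight midcorrelation between all protein pairs, a signed
soft-threshold adjacency A_ij = ((1 + cor_ij)/2)^beta, topological overlap
smoothing, average-linkage clustering of 1 - TOM, hybrid dynamic tree cut,
eigenprotein-based module merging, and iterative kME-consistency
reassignment of module membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .containers import GREY, AbundanceMatrix, EigenproteinSet, KMETable, ModuleAssignment
from .correlation import bicor_cross, bicor_matrix, correlation_pvalue, pearson_matrix
from .treecut import cutree_hybrid

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

def signed_adjacency(cor: np.ndarray, beta: int = 12) -> np.ndarray:
    """Signed soft-threshold adjacency A_ij = ((1 + cor_ij)/2)^beta."""
    cor = np.asarray(cor, float)
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if np.nanmax(np.abs(cor)) > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adjacency: np.ndarray, denom: str = "mean") -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (L_ij + A_ij) / (D_ij + 1 - A_ij) with
    L_ij = sum_{u != i,j} A_iu A_uj, k_i = sum_{u != i} A_iu and
    D_ij = (k_i + k_j)/2 (``denom="mean"``) or min(k_i, k_j) (``"min"``).
    """
    a = np.asarray(adjacency, float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if denom not in ("mean", "min"):
        raise ValueError(f"unknown TOM denominator: {denom!r}")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0  # connectivity excluding self
    # L_ij excludes u in {i, j}; with unit diagonal (A @ A)_ij counts both
    l = a @ a - 2.0 * a  # subtract A_ii*A_ij + A_ij*A_jj
    if denom == "mean":
        d = (k[:, None] + k[None, :]) / 2.0
    else:
        d = np.minimum(k[:, None], k[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (d + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class NetworkModel:
    """Adjacency + TOM with the parameters that produced them."""

    adjacency: np.ndarray
    tom: np.ndarray
    beta: int
    tom_denom: str
    correlation: str = "bicor"


def build_network(matrix: AbundanceMatrix, beta: int = 12, tom_denom: str = "mean",
                  correlation: str = "bicor") -> NetworkModel:
    if correlation == "bicor":
        cor = bicor_matrix(matrix.values)
    elif correlation == "pearson":
        cor = pearson_matrix(matrix.values)
    else:
        raise ValueError(f"unknown correlation method: {correlation!r}")
    adj = signed_adjacency(cor, beta=beta)
    tom = topological_overlap(adj, denom=tom_denom)
    return NetworkModel(adj, tom, beta, tom_denom, correlation)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution fit (diagnostic only)."""
    k = adjacency.sum(axis=1) - 1.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return float("nan")
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    centers, freqs = [], []
    for b in range(edges.size - 1):
        mask = which == b
        if mask.any():
            centers.append(k[mask].mean())
            freqs.append(mask.mean())
    x = np.log10(np.asarray(centers) + 1e-12)
    y = np.log10(np.asarray(freqs) + 1e-12)
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


# ---------------------------------------------------------------------------
# clustering and module detection
# ---------------------------------------------------------------------------

def cluster_dendrogram(tom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage dendrogram of d = 1 - TOM.

    Returns (scipy linkage matrix, dissimilarity matrix).
    """
    tom = np.asarray(tom, float)
    n = tom.shape[0]
    if n < 2:
        raise ValueError("need at least 2 proteins to cluster")
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    linkage = average(squareform(d, checks=False))
    return linkage, d


def detect_modules(linkage: np.ndarray, dissimilarity: np.ndarray,
                   protein_ids: list[str], deep_split: int = 4,
                   min_module_size: int = 30, pam_stage: bool = True,
                   pam_respects_dendro: bool = True) -> ModuleAssignment:
    """Hybrid dynamic tree cut; labels ordered M1..Mk by size, grey unassigned."""
    labels = cutree_hybrid(
        linkage, dissimilarity, deep_split=deep_split,
        min_module_size=min_module_size, pam_stage=pam_stage,
        pam_respects_dendro=pam_respects_dendro,
    )
    mapping = {
        pid: (GREY if lab == 0 else f"M{lab}")
        for pid, lab in zip(protein_ids, labels)
    }
    return ModuleAssignment(mapping).relabel_by_size()


# ---------------------------------------------------------------------------
# eigenproteins and kME
# ---------------------------------------------------------------------------

def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _first_pc(z: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector (length n_samples) and variance explained."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pve = float(s[0] ** 2 / (s ** 2).sum())
    return vt[0], pve


def module_eigenproteins(matrix: AbundanceMatrix, assignment: ModuleAssignment,
                         exclude: dict[str, list[str]] | None = None) -> EigenproteinSet:
    """First principal component of each module's z-scored abundance.

    The eigenprotein is z-scored over samples and sign-oriented so the mean
    correlation with module member profiles is positive.  ``exclude`` maps a
    module to proteins to leave out (sensitivity analyses).
    """
    frame = matrix.to_frame()
    rows: dict[str, np.ndarray] = {}
    pves: dict[str, float] = {}
    signs: dict[str, int] = {}
    for mod in assignment.modules():
        members = assignment.members(mod)
        if exclude and mod in exclude:
            members = [p for p in members if p not in set(exclude[mod])]
        if len(members) < 2:
            raise ValueError(f"module {mod} has fewer than 2 proteins")
        sub = frame.loc[members].to_numpy(float)
        z = _zscore_rows(sub)
        e, pve = _first_pc(z)
        mean_cor = float(np.mean(z @ e) / (np.linalg.norm(e) + 1e-300))
        sign = -1 if mean_cor < 0 else 1
        e = sign * e
        e = (e - e.mean()) / e.std()
        rows[mod] = e
        pves[mod] = pve
        signs[mod] = sign
    values = pd.DataFrame(rows, index=matrix.sample_ids).T
    return EigenproteinSet(values, pd.Series(pves, name="pve"),
                           pd.Series(signs, name="sign"))


def kme_table(matrix: AbundanceMatrix, eigenproteins: EigenproteinSet,
              method: str = "bicor") -> KMETable:
    """Module-membership correlations kME_pm = cor(protein p, eigenprotein m)."""
    if list(eigenproteins.sample_ids()) != list(matrix.sample_ids):
        raise ValueError("eigenproteins were computed on different samples")
    e = eigenproteins.values.to_numpy(float)
    if method == "bicor":
        k = bicor_cross(matrix.values, e)
    elif method == "pearson":
        x = _zscore_rows(matrix.values)
        ez = _zscore_rows(e)
        k = np.clip(x @ ez.T / matrix.n_samples, -1.0, 1.0)
    else:
        raise ValueError(f"unknown kME correlation: {method!r}")
    p = correlation_pvalue(k, matrix.n_samples)
    cols = eigenproteins.module_ids()
    return KMETable(
        pd.DataFrame(k, index=matrix.protein_ids, columns=cols),
        pd.DataFrame(p, index=matrix.protein_ids, columns=cols),
    )


# ---------------------------------------------------------------------------
# module merging and kME-consistency reassignment
# ---------------------------------------------------------------------------

def merge_close_modules(matrix: AbundanceMatrix, assignment: ModuleAssignment,
                        cut_height: float = 0.07, max_iter: int = 20) -> ModuleAssignment:
    """Merge modules whose eigenproteins are closer than ``cut_height``.

    Eigenproteins are clustered on d = 1 - cor(E); groups of modules joined
    below ``cut_height`` collapse into one module.  Eigenproteins are
    recomputed and the process repeats until no pair is that close.
    """
    if cut_height <= 0:
        return assignment.relabel_by_size()
    current = assignment
    for _ in range(max_iter):
        mods = current.modules()
        if len(mods) < 2:
            break
        eig = module_eigenproteins(matrix, current)
        e = eig.values.loc[mods].to_numpy(float)
        d = 1.0 - np.corrcoef(e)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        link = average(squareform(d, checks=False))
        from scipy.cluster.hierarchy import fcluster
        groups = fcluster(link, t=cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        rename: dict[str, str] = {}
        for g in set(groups):
            members = [mods[i] for i in np.flatnonzero(groups == g)]
            target = members[0]
            for m in members:
                rename[m] = target
        current = ModuleAssignment({
            p: rename.get(m, m) for p, m in current.labels.items()
        }).relabel_by_size()
    return current.relabel_by_size()


def enforce_kme_consistency(matrix: AbundanceMatrix, assignment: ModuleAssignment,
                            p_threshold: float = 0.05, max_iter: int = 30,
                            min_module_size: int = 3,
                            method: str = "bicor") -> ModuleAssignment:
    """Iteratively reassign proteins until module membership matches kME.

    Each round recomputes eigenproteins and the kME table, then

    a. moves an assigned protein whose maximal kME points to another module
       (correlation test p < ``p_threshold``) to that module,
    b. rescues a grey protein with a significant maximal kME, and
    c. greys out an assigned protein with no significant kME anywhere.

    Significance is familywise per protein: correlation-test p-values are
    Bonferroni-scaled by the number of modules before comparison with
    ``p_threshold``, since each protein shops across every module
    eigenprotein — without this, with dozens of modules a large share of
    genuinely unassigned proteins would be rescued by chance alone.

    Stops at a fixed point or after ``max_iter`` rounds (with a warning).
    Modules shrinking below ``min_module_size`` members are dissolved to
    grey.  Final labels are renumbered by size.
    """
    current = assignment
    for it in range(max_iter):
        mods = current.modules()
        if not mods:
            break
        eig = module_eigenproteins(matrix, current)
        kme = kme_table(matrix, eig, method=method)
        k = kme.kme.to_numpy(float)
        p = np.minimum(kme.pvalues.to_numpy(float) * len(mods), 1.0)
        cols = list(kme.kme.columns)
        best_idx = np.argmax(k, axis=1)
        new_labels: dict[str, str] = {}
        changed = 0
        for i, pid in enumerate(matrix.protein_ids):
            old = current[pid]
            j = int(best_idx[i])
            best_mod, best_p = cols[j], p[i, j]
            significant_any = (p[i] < p_threshold).any()
            if old == GREY:
                new = best_mod if best_p < p_threshold else GREY
            elif not significant_any:
                new = GREY
            elif best_mod != old and best_p < p_threshold:
                new = best_mod
            else:
                new = old
            if new != old:
                changed += 1
            new_labels[pid] = new
        nxt = ModuleAssignment(new_labels)
        # dissolve modules that fell below the size floor
        sizes = nxt.sizes()
        small = [m for m, s in sizes.items() if m != GREY and s < min_module_size]
        if small:
            nxt = ModuleAssignment({
                p: (GREY if m in small else m) for p, m in nxt.labels.items()
            })
        if changed == 0:
            current = nxt
            break
        current = nxt
    else:
        log.warning("kME reassignment did not stabilise in %d iterations", max_iter)
    return current.relabel_by_size()
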