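"""Cross-cohort module validation.

Three complementary checks of whether a reference network's modules exist
in an independent cohort:

* permutation **module preservation**: density and connectivity statistics
  of each reference module evaluated in the target cohort, standardised
  against same-size random protein sets (Z_summary < 2 no evidence, 2-10
  moderate, > 10 high preservation);
* **synthetic eigenproteins**: the reference membership applied to the
  target matrix (restricted to measured, sufficiently complete proteins)
  to recompute module summary profiles, which can then be compared across
  target diagnostic groups;
* **cross-network over-representation**: Fisher tests of module membership
  overlap between two independently built networks at gene-symbol level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GREY, AbundanceMatrix, EigenproteinSet, ModuleAssignment
from .correlation import _biweight_rows
from .annotate import bh_fdr, fisher_ora

log = logging.getLogger(__name__)

#: Density statistics ask "are the module's proteins tightly co-expressed
#: in the target?"; they are computed within the module, in the target.
DENSITY_STATS = ("propVarExplained", "meanSignedKME", "meanSignedCor", "meanAdj")
#: Connectivity statistics ask "does the module occupy the same place in
#: the network?"; each correlates the module's connectivity footprint —
#: its kIM/kME/correlation/adjacency pattern over a fixed panel of probe
#: proteins — between reference and target cohorts.
CONNECTIVITY_STATS = ("cor.kIM", "cor.kME", "cor.cor", "cor.adj")


def _normalised_rows(values: np.ndarray, method: str) -> np.ndarray:
    """Rows scaled so that row_i @ row_j.T is the chosen correlation."""
    if method == "bicor":
        tilde, _ = _biweight_rows(values)
        return tilde
    z = values - values.mean(axis=1, keepdims=True)
    n = np.linalg.norm(z, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return z / n


def _first_pc_stats(sub: np.ndarray) -> tuple[np.ndarray, float]:
    z = sub - sub.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    if np.mean(z @ e) < 0:
        e = -e
    return e, float(s[0] ** 2 / (s ** 2).sum())


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x.ravel(), y.ravel())[0, 1])


def _set_statistics(idx: np.ndarray, tilde_ref: np.ndarray, tilde_tgt: np.ndarray,
                    raw_tgt: np.ndarray, beta: int, probes: np.ndarray) -> np.ndarray:
    """The 8 preservation statistics for one protein set.

    Density statistics are within-set in the target cohort; connectivity
    statistics correlate the set's footprint over the ``probes`` panel
    between cohorts.
    """
    c_tgt = np.clip(tilde_tgt[idx] @ tilde_tgt[idx].T, -1, 1)
    a_tgt = ((1 + c_tgt) / 2) ** beta
    m = len(idx)
    off = ~np.eye(m, dtype=bool)

    e_tgt, pve = _first_pc_stats(raw_tgt[idx])
    e_norm = (e_tgt - e_tgt.mean()) / (np.linalg.norm(e_tgt - e_tgt.mean()) + 1e-300)
    kme_own_tgt = np.clip(tilde_tgt[idx] @ e_norm, -1, 1)

    # set-to-probe correlation/adjacency footprints in both cohorts
    b_ref = np.clip(tilde_ref[idx] @ tilde_ref[probes].T, -1, 1)
    b_tgt = np.clip(tilde_tgt[idx] @ tilde_tgt[probes].T, -1, 1)
    ab_ref = ((1 + b_ref) / 2) ** beta
    ab_tgt = ((1 + b_tgt) / 2) ** beta
    self_pair = np.isin(probes, idx)
    keep = np.ones_like(b_ref, dtype=bool)
    keep[:, self_pair] = ~(idx[:, None] == probes[self_pair][None, :])

    # probe kIM with respect to the set, and probe kME to the set eigenprotein
    k_im_ref = ab_ref.sum(axis=0)
    k_im_tgt = ab_tgt.sum(axis=0)
    e_ref, _ = _first_pc_stats_rows(tilde_ref[idx])
    kme_ref = np.clip(tilde_ref[probes] @ e_ref, -1, 1)
    e_t_unit = e_norm / (np.linalg.norm(e_norm) + 1e-300)
    kme_tgt = np.clip(tilde_tgt[probes] @ e_t_unit, -1, 1)

    return np.array([
        pve,
        float(kme_own_tgt.mean()),
        float(c_tgt[off].mean()),
        float(a_tgt[off].mean()),
        _safe_cor(k_im_ref, k_im_tgt),
        _safe_cor(kme_ref, kme_tgt),
        _safe_cor(b_ref[keep], b_tgt[keep]),
        _safe_cor(ab_ref[keep], ab_tgt[keep]),
    ])


def _first_pc_stats_rows(rows: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of already-normalised rows, sign-oriented, unit norm."""
    u, s, vt = np.linalg.svd(rows, full_matrices=False)
    e = vt[0]
    if np.mean(rows @ e) < 0:
        e = -e
    e = e - e.mean()
    e = e / (np.linalg.norm(e) + 1e-300)
    return e, float(s[0] ** 2 / (s ** 2).sum())


@dataclass
class PreservationReport:
    """Per-module observed statistics, permutation Zs and composites."""

    table: pd.DataFrame            # module x columns (obs_*, z_*, composites)
    n_perm: int
    skipped: list[str] = field(default_factory=list)

    def z_summary(self) -> pd.Series:
        return self.table["Z_summary"]


def module_preservation(ref_matrix: AbundanceMatrix, target_matrix: AbundanceMatrix,
                        ref_assignment: ModuleAssignment, n_perm: int = 500,
                        seed: int = 0, beta: int = 12, correlation: str = "bicor",
                        min_overlap: int = 10) -> PreservationReport:
    """Permutation module-preservation Z statistics in a target cohort.

    Observed statistics are computed on the target cohort for each reference
    module (restricted to proteins measured in both cohorts); the null
    redraws same-size protein sets uniformly from the whole overlap
    (grey included, mirroring a full permutation of the module label
    vector) ``n_perm`` times.  Z = (obs - perm mean) / perm SD per
    statistic; Z_density and Z_connectivity are medians of their four
    member statistics and Z_summary is their mean.  Connectivity
    footprints are evaluated over a fixed random panel of at most 200
    probe proteins to keep the permutation loop affordable.
    """
    if n_perm < 50:
        log.warning("n_perm=%d is low; permutation SDs will be unstable", n_perm)
    overlap = [p for p in ref_matrix.protein_ids if p in set(target_matrix.protein_ids)]
    if len(overlap) < min_overlap:
        raise ValueError("cohorts share too few proteins")
    ref = ref_matrix.select_proteins(overlap)
    tgt = target_matrix.select_proteins(overlap)
    pos = {p: i for i, p in enumerate(overlap)}

    tilde_ref = _normalised_rows(ref.values, correlation)
    tilde_tgt = _normalised_rows(tgt.values, correlation)
    raw_tgt = tgt.values

    modules = ref_assignment.modules()
    member_idx: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for mod in modules:
        members = [p for p in ref_assignment.members(mod) if p in pos]
        full_size = len(ref_assignment.members(mod))
        if len(members) < min_overlap:
            skipped.append(mod)
            continue
        if len(members) < 0.5 * full_size:
            log.warning("module %s: only %d/%d members measured in target",
                        mod, len(members), full_size)
        member_idx[mod] = np.array([pos[p] for p in members])

    candidates = np.arange(len(overlap))
    rng = np.random.default_rng(seed)
    probes = np.sort(rng.choice(len(overlap), size=min(200, len(overlap)),
                                replace=False))

    stat_names = DENSITY_STATS + CONNECTIVITY_STATS
    rows = {}
    observed = {mod: _set_statistics(idx, tilde_ref, tilde_tgt, raw_tgt,
                                     beta, probes)
                for mod, idx in member_idx.items()}
    sizes = sorted({idx.size for idx in member_idx.values()})
    perm_by_size = {s: np.empty((n_perm, len(stat_names))) for s in sizes}
    for b in range(n_perm):
        for s in sizes:
            draw = rng.choice(candidates, size=s, replace=False)
            perm_by_size[s][b] = _set_statistics(draw, tilde_ref, tilde_tgt,
                                                 raw_tgt, beta, probes)

    for mod, idx in member_idx.items():
        perms = perm_by_size[idx.size]
        mu = perms.mean(axis=0)
        sd = perms.std(axis=0, ddof=1)
        z = np.full(len(stat_names), np.nan)
        good = sd > 0
        z[good] = (observed[mod][good] - mu[good]) / sd[good]
        if (~good).any():
            log.warning("module %s: %d statistic(s) dropped (zero permutation SD)",
                        mod, int((~good).sum()))
        z_density = float(np.nanmedian(z[:4]))
        z_conn = float(np.nanmedian(z[4:]))
        row = {"size": int(idx.size)}
        row.update({f"obs_{n}": observed[mod][i] for i, n in enumerate(stat_names)})
        row.update({f"Z_{n}": z[i] for i, n in enumerate(stat_names)})
        row["Z_density"] = z_density
        row["Z_connectivity"] = z_conn
        row["Z_summary"] = (z_density + z_conn) / 2.0
        rows[mod] = row

    table = pd.DataFrame(rows).T
    table.index.name = "module"
    if not table.empty:
        ranks = pd.DataFrame({
            n: (-table[f"obs_{n}"]).rank(method="average") for n in stat_names
        })
        table["median_rank"] = ranks.median(axis=1)
        table["preservation_class"] = pd.cut(
            table["Z_summary"], bins=[-np.inf, 2, 10, np.inf],
            labels=["none", "moderate", "high"],
        )
    return PreservationReport(table, n_perm, skipped)


# ---------------------------------------------------------------------------
# synthetic eigenproteins
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEigenproteinSet:
    """Reference modules re-expressed in a target cohort."""

    values: pd.DataFrame           # modules x target samples, z-scored rows
    coverage: pd.Series            # proteins used per module
    omitted: list[str]             # modules with < 2 eligible proteins


def synthetic_eigenproteins(target_matrix: AbundanceMatrix,
                            ref_assignment: ModuleAssignment,
                            missing_threshold: float = 0.75,
                            match_by: str = "protein_id") -> SyntheticEigenproteinSet:
    """First PC of each reference module within the target cohort.

    Proteins must be measured in the target (matched by shared id or by
    uppercase gene symbol, duplicates collapsed to the highest-variance
    measurement) with missing frequency below ``missing_threshold``
    (exactly complete when the threshold is 0).  Remaining missing cells
    are imputed with the protein median before z-scoring.
    """
    if match_by == "protein_id":
        target_of = {p: p for p in target_matrix.protein_ids}
    elif match_by == "gene_symbol":
        variances = np.nanvar(target_matrix.values, axis=1)
        best: dict[str, tuple[float, str]] = {}
        for i, (pid, sym) in enumerate(zip(target_matrix.protein_ids,
                                           target_matrix.gene_symbols)):
            key = sym.upper()
            if key not in best or variances[i] > best[key][0]:
                best[key] = (variances[i], pid)
        target_of = {sym: pid for sym, (_, pid) in best.items()}
    else:
        raise ValueError(f"unknown match_by: {match_by!r}")

    frame = target_matrix.to_frame()
    miss_frac = frame.isna().mean(axis=1)

    rows: dict[str, np.ndarray] = {}
    coverage: dict[str, int] = {}
    omitted: list[str] = []
    for mod in ref_assignment.modules():
        members = ref_assignment.members(mod)
        mapped = [target_of[m] for m in members if m in target_of]
        if missing_threshold == 0:
            eligible = [p for p in mapped if miss_frac[p] == 0]
        else:
            eligible = [p for p in mapped if miss_frac[p] < missing_threshold]
        if len(eligible) < 2:
            omitted.append(mod)
            log.warning("module %s omitted: %d eligible protein(s) in target",
                        mod, len(eligible))
            continue
        sub = frame.loc[eligible].to_numpy(float)
        med = np.nanmedian(sub, axis=1)
        nan_r, nan_c = np.where(np.isnan(sub))
        sub[nan_r, nan_c] = med[nan_r]
        e, _ = _first_pc_stats(sub)
        e = (e - e.mean()) / e.std()
        rows[mod] = e
        coverage[mod] = len(eligible)
    values = pd.DataFrame(rows, index=target_matrix.sample_ids).T
    return SyntheticEigenproteinSet(values, pd.Series(coverage, name="coverage"),
                                    omitted)


def compare_synthetic_eigenproteins(synth: SyntheticEigenproteinSet,
                                    metadata: pd.DataFrame,
                                    contrasts: list[tuple[str, str]],
                                    group_column: str = "group",
                                    min_n: int = 3) -> pd.DataFrame:
    """Two-sided t tests of synthetic eigenproteins between target groups.

    BH-FDR runs across modules within each contrast; the reported effect is
    the difference of group means of the z-scored eigenprotein.
    """
    md = metadata.set_index("sample_id", drop=False) \
        if metadata.index.name != "sample_id" else metadata
    samples = list(synth.values.columns)
    groups = md.loc[samples, group_column].to_numpy()
    rows = []
    for a, b in contrasts:
        mask_a, mask_b = groups == a, groups == b
        if mask_a.sum() < min_n or mask_b.sum() < min_n:
            log.warning("contrast %s vs %s skipped: group too small", a, b)
            continue
        for mod in synth.values.index:
            e = synth.values.loc[mod].to_numpy(float)
            t, p = stats.ttest_ind(e[mask_a], e[mask_b])
            rows.append({
                "module": mod, "contrast": f"{a}_vs_{b}",
                "mean_diff_z": float(e[mask_a].mean() - e[mask_b].mean()),
                "t": float(t), "p": float(p),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = np.nan
    for _, idx in df.groupby("contrast").groups.items():
        df.loc[idx, "q"] = bh_fdr(df.loc[idx, "p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# cross-network module over-representation
# ---------------------------------------------------------------------------

def cross_network_ora(assignment_a: ModuleAssignment, assignment_b: ModuleAssignment,
                      symbols_a: dict[str, str], symbols_b: dict[str, str]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fisher overlap of every module pair between two networks.

    Modules are mapped to uppercase gene symbols; the background is the
    symbol intersection of the two platforms.  Returns the long table (with
    BH q over all pairs) and the module_a x module_b -log10(q) matrix.
    """
    syms_a = {p: s.upper() for p, s in symbols_a.items()}
    syms_b = {p: s.upper() for p, s in symbols_b.items()}
    background = set(syms_a.values()) & set(syms_b.values())
    if not background:
        raise ValueError("the two networks share no gene symbols")

    def module_sets(assignment, syms):
        return {m: {syms[p] for p in assignment.members(m) if p in syms} & background
                for m in assignment.modules()}

    sets_a = module_sets(assignment_a, syms_a)
    sets_b = module_sets(assignment_b, syms_b)
    rows = []
    for ma, sa in sets_a.items():
        for mb, sb in sets_b.items():
            res = fisher_ora(sa, sb, background)
            rows.append({"module_a": ma, "module_b": mb, **res})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["neg_log10_q"] = -np.log10(np.maximum(df["q"], 1e-300))
    matrix = df.pivot(index="module_a", columns="module_b", values="neg_log10_q")
    return df, matrix
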