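"""Module annotation: gene-set over-representation, FDR control, hubs.

Over-representation uses the one-tailed Fisher exact test on the 2x2 table
of (in module) x (in set) against the measured background, at gene-symbol
level: analyte ids are collapsed to unique uppercase symbols first, so two
aptamers for one gene count once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GREY, AbundanceMatrix, GeneSetCollection, KMETable, ModuleAssignment

log = logging.getLogger(__name__)


def fisher_ora(module_members: set[str], set_members: set[str],
               background: set[str]) -> dict:
    """One-tailed (enrichment) Fisher exact test of a module against a set.

    Returns overlap count, sizes, fold enrichment, the hypergeometric
    one-tailed p, and an overrepresentation Z from the hypergeometric null
    mean and variance.
    """
    if not background:
        raise ValueError("background is empty")
    module = set(module_members) & background
    geneset = set(set_members) & background
    n = len(background)
    k = len(module)
    s = len(geneset)
    ov = len(module & geneset)
    # one-tailed p = P(X >= ov) under Hypergeom(N=n, K=s, n=k)
    p = float(stats.hypergeom.sf(ov - 1, n, s, k)) if ov > 0 else 1.0
    expected = k * s / n
    fold = (ov / k) / (s / n) if k > 0 and s > 0 else 0.0
    var = expected * (1 - s / n) * (n - k) / max(n - 1, 1)
    z = (ov - expected) / np.sqrt(var) if var > 0 else 0.0
    return {
        "overlap": ov, "module_size": k, "set_size": s, "background_size": n,
        "fold_enrichment": fold, "p": min(p, 1.0), "z": float(z),
        "expected": expected,
    }


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _module_symbols(assignment: ModuleAssignment, matrix: AbundanceMatrix) -> dict[str, set[str]]:
    sym = matrix.symbol_of()
    out: dict[str, set[str]] = {}
    for mod in assignment.modules():
        out[mod] = {sym[p].upper() for p in assignment.members(mod)}
    return out


def enrichment_table(assignment: ModuleAssignment, gene_sets: GeneSetCollection,
                     matrix: AbundanceMatrix,
                     background: set[str] | None = None) -> pd.DataFrame:
    """Fisher ORA of every module against every gene set, BH over the table."""
    if background is None:
        background = {s.upper() for s in matrix.gene_symbols}
    usable = {name: set(members) & background for name, members in gene_sets.items()}
    usable = {name: m for name, m in usable.items() if m}
    if not usable:
        raise ValueError("no gene-set symbol overlaps the background")
    mod_syms = _module_symbols(assignment, matrix)
    rows = []
    for mod, msym in mod_syms.items():
        for name, members in usable.items():
            row = fisher_ora(msym, members, background)
            row.update({"module": mod, "set_name": name})
            rows.append(row)
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    cols = ["module", "set_name", "overlap", "module_size", "set_size",
            "background_size", "fold_enrichment", "p", "q", "z"]
    return df[cols]


def celltype_enrichment(assignment: ModuleAssignment, marker_sets: GeneSetCollection,
                        matrix: AbundanceMatrix) -> pd.DataFrame:
    """Cell-type marker over-representation per module (same machinery as GO)."""
    return enrichment_table(assignment, marker_sets, matrix)


@dataclass
class HubSet:
    """Hub proteins per module: top quantile of own-module kME."""

    table: pd.DataFrame  # protein_id, module, kME_own, percentile

    def hubs(self, module: str) -> list[str]:
        sub = self.table[self.table["module"] == module]
        return sub["protein_id"].tolist()


def identify_hubs(kme: KMETable, assignment: ModuleAssignment,
                  percentile: float = 0.80) -> HubSet:
    """Rank module members by own-module kME; hubs sit at/above the cutoff.

    ``percentile=0.80`` keeps the top 20% of each module (ties at the
    threshold are all included).  Modules with < 5 members are reported but
    may yield an empty hub list.
    """
    rows = []
    for mod in assignment.modules():
        members = [p for p in assignment.members(mod) if p in kme.kme.index]
        if len(members) < 5:
            log.warning("module %s has %d members; hub call unstable", mod, len(members))
        vals = kme.kme.loc[members, mod].astype(float)
        ranks = vals.rank(method="average", pct=True)
        n_hubs = int(np.ceil((1.0 - percentile) * len(members)))
        if n_hubs == 0:
            continue
        cutoff_value = vals.nlargest(n_hubs).min()  # ties at cutoff included
        for p in members:
            if vals[p] >= cutoff_value:
                rows.append({
                    "protein_id": p, "module": mod,
                    "kME_own": float(vals[p]), "percentile": float(ranks[p]),
                })
    table = pd.DataFrame(rows, columns=["protein_id", "module", "kME_own", "percentile"])
    return HubSet(table.sort_values(["module", "kME_own"], ascending=[True, False])
                  .reset_index(drop=True))
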