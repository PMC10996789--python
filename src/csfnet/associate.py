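"""Disease associations of modules and proteins.

Group comparisons use one-way ANOVA with Tukey HSD post-hoc tests
(Tukey-Kramer on unbalanced groups) after residualising on age and sex;
severity/biomarker relationships use Spearman correlations with BH-FDR in
full-sample families (gene-stratified correlations are reported unadjusted
and flagged, as statistical power differs too much across strata);
cognitive trajectories come from a linear mixed model with random
intercepts and slopes, fit by REML, from which person-specific slopes
(fixed effect + empirical-Bayes deviation) are extracted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GREY, AbundanceMatrix, EigenproteinSet, ModuleAssignment
from .network import module_eigenproteins

log = logging.getLogger(__name__)

STATUS_ORDER = ("control", "presymptomatic", "symptomatic")


# ---------------------------------------------------------------------------
# cognition
# ---------------------------------------------------------------------------

def composite_cognition(domain_z: pd.DataFrame,
                        domain_columns: list[str] | None = None) -> pd.DataFrame:
    """Average available domain z-scores per visit into a global score.

    ``domain_z`` must carry ``subject_id`` and ``visit_time`` plus one
    column per cognitive domain.  Visits with no domain score at all are
    dropped (logged).
    """
    keys = ["subject_id", "visit_time"]
    if domain_columns is None:
        domain_columns = [c for c in domain_z.columns if c not in keys]
    if not domain_columns:
        raise ValueError("no domain columns to average")
    out = domain_z[keys].copy()
    out["global_z"] = domain_z[domain_columns].mean(axis=1, skipna=True)
    n_empty = int(out["global_z"].isna().sum())
    if n_empty:
        log.info("dropping %d visit(s) with no domain scores", n_empty)
        out = out.dropna(subset=["global_z"])
    return out.reset_index(drop=True)


@dataclass
class SlopeEstimates:
    """Per-subject annual cognitive slopes plus the model behind them."""

    slopes: pd.Series              # subject_id -> slope, z-units/year
    fixed_effects: pd.Series
    converged: bool
    n_excluded_single_visit: int
    method: str                    # "lmm" or "ols_fallback"


def fit_cognitive_slopes(cognition: pd.DataFrame, metadata: pd.DataFrame
                         ) -> SlopeEstimates:
    """Random-slope mixed model of global cognition over time.

    global_z ~ time + baseline age + sex + education, random intercept and
    slope per subject (unstructured covariance), REML.  Subjects with a
    single visit are excluded.  On non-convergence, falls back to
    per-subject least-squares slopes with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    md = metadata.drop_duplicates("subject_id").set_index("subject_id")
    df = cognition.copy()
    counts = df.groupby("subject_id")["visit_time"].count()
    singletons = counts[counts < 2].index
    n_excluded = len(singletons)
    if n_excluded:
        log.info("excluding %d single-visit subject(s) from slope model", n_excluded)
    df = df[~df["subject_id"].isin(singletons)].copy()
    if df.empty:
        raise ValueError("no subject has >= 2 visits")

    df["age_c"] = df["subject_id"].map(md["age"]).astype(float)
    df["age_c"] -= df["age_c"].mean()
    df["sex_code"] = (df["subject_id"].map(md["sex"]).astype(str)
                      .str.lower().isin(("male", "m", "1"))).astype(float)
    df["edu_c"] = df["subject_id"].map(md["education"]).astype(float)
    df["edu_c"] -= df["edu_c"].mean()

    exog = sm.add_constant(df[["visit_time", "age_c", "sex_code", "edu_c"]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(df["global_z"], exog, groups=df["subject_id"],
                            exog_re=sm.add_constant(df[["visit_time"]]))
            fit = model.fit(reml=True, method="lbfgs")
        converged = bool(fit.converged)
    except Exception:
        converged = False

    if converged:
        beta_time = float(fit.fe_params["visit_time"])
        re = fit.random_effects
        slopes = {subj: beta_time + float(eff.get("visit_time", eff.iloc[-1]))
                  for subj, eff in re.items()}
        return SlopeEstimates(pd.Series(slopes, name="slope"), fit.fe_params,
                              True, n_excluded, "lmm")

    log.warning("mixed model did not converge; using per-subject OLS slopes")
    slopes = {}
    for subj, g in df.groupby("subject_id"):
        b = np.polyfit(g["visit_time"], g["global_z"], deg=1)[0]
        slopes[subj] = float(b)
    return SlopeEstimates(pd.Series(slopes, name="slope"),
                          pd.Series(dtype=float), False, n_excluded,
                          "ols_fallback")


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def _anova_tukey(values: np.ndarray, groups: np.ndarray,
                 group_order: tuple[str, ...]) -> dict:
    """Omnibus one-way ANOVA plus Tukey HSD pairwise rows."""
    present = [g for g in group_order if (groups == g).sum() >= 3]
    samples = [values[groups == g] for g in present]
    if len(present) < 2:
        return {"F": np.nan, "p": np.nan, "pairs": [], "groups": present}
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        pairs = [{"group_a": a, "group_b": b, "diff": 0.0, "p_tukey": 1.0}
                 for i, a in enumerate(present) for b in present[i + 1:]]
        return {"F": 0.0, "p": 1.0, "pairs": pairs, "groups": present}
    f, p = stats.f_oneway(*samples)
    res = stats.tukey_hsd(*samples)
    pairs = []
    for i, a in enumerate(present):
        for j, b in enumerate(present):
            if j <= i:
                continue
            pairs.append({
                "group_a": a, "group_b": b,
                "diff": float(np.mean(values[groups == a]) - np.mean(values[groups == b])),
                "p_tukey": float(res.pvalue[i, j]),
            })
    return {"F": float(f), "p": float(p), "pairs": pairs, "groups": present}


def module_group_comparison(eigenproteins: EigenproteinSet, metadata: pd.DataFrame,
                            stratify_by_gene: bool = False,
                            adjust: tuple[str, ...] = ("age", "sex"),
                            group_column: str = "status",
                            group_order: tuple[str, ...] = STATUS_ORDER) -> pd.DataFrame:
    """ANOVA + Tukey of eigenproteins across disease-stage groups.

    Eigenproteins are residualised on the ``adjust`` covariates first.
    With ``stratify_by_gene`` the comparison runs within each gene group,
    carriers of that gene vs. all controls.
    """
    md = metadata.set_index("sample_id", drop=False) \
        if metadata.index.name != "sample_id" else metadata
    samples = eigenproteins.sample_ids()
    md = md.loc[samples]
    cov_cols = []
    for c in adjust:
        if c == "sex":
            cov_cols.append((md["sex"].astype(str).str.lower()
                             .isin(("male", "m", "1"))).to_numpy(float))
        else:
            cov_cols.append(md[c].to_numpy(float))
    covariates = np.column_stack(cov_cols) if cov_cols else None

    strata: list[tuple[str, np.ndarray]] = []
    if stratify_by_gene:
        for gene in sorted(set(md["gene_group"]) - {"control"}):
            mask = ((md["gene_group"] == gene) | (md[group_column] == "control")).to_numpy()
            strata.append((gene, mask))
    else:
        strata.append(("all", np.ones(len(md), bool)))

    rows = []
    for mod in eigenproteins.module_ids():
        e = eigenproteins.values.loc[mod].to_numpy(float)
        for stratum, mask in strata:
            y = e[mask]
            if covariates is not None:
                y = _residualize(y, covariates[mask])
            groups = md[group_column].to_numpy()[mask]
            n_groups = sum((groups == g).sum() >= 3 for g in group_order)
            if n_groups < 2:
                log.warning("stratum %s for %s has < 2 usable groups; skipped",
                            stratum, mod)
                continue
            res = _anova_tukey(y, groups, group_order)
            for pair in res["pairs"]:
                rows.append({
                    "unit": mod, "stratum": stratum,
                    "F": res["F"], "p_anova": res["p"], **pair,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait correlations
# ---------------------------------------------------------------------------

def trait_correlations(units: pd.DataFrame, metadata_traits: pd.DataFrame,
                       traits: tuple[str, ...] = ("cdr_sb", "nfl"),
                       strata: dict[str, np.ndarray] | None = None,
                       apply_fdr: bool = True, min_pairs: int = 5) -> pd.DataFrame:
    """Spearman correlation of each unit row with each trait, per stratum.

    ``units`` is units x samples (eigenproteins or protein abundance);
    ``metadata_traits`` is indexed by sample with trait columns.  BH-FDR is
    applied within each (trait, stratum) family when ``apply_fdr``; rows are
    flagged with ``fdr_applied`` either way.
    """
    from .annotate import bh_fdr

    samples = list(units.columns)
    md = metadata_traits.loc[samples]
    if strata is None:
        strata = {"full": np.ones(len(samples), bool)}
    rows = []
    for trait in traits:
        tvals = md[trait].to_numpy(float)
        for stratum, mask in strata.items():
            for unit in units.index:
                x = units.loc[unit].to_numpy(float)[mask]
                y = tvals[mask]
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < min_pairs:
                    continue
                if np.ptp(y[ok]) == 0:
                    continue
                rho, p = stats.spearmanr(x[ok], y[ok])
                rows.append({
                    "unit": unit, "trait": trait, "stratum": stratum,
                    "rho": float(rho), "p": float(p), "n": int(ok.sum()),
                })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = np.nan
    df["fdr_applied"] = apply_fdr
    if apply_fdr:
        for (_, _), idx in df.groupby(["trait", "stratum"]).groups.items():
            df.loc[idx, "q"] = bh_fdr(df.loc[idx, "p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# protein-level differential abundance
# ---------------------------------------------------------------------------

def differential_abundance(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                           assignment: ModuleAssignment | None = None,
                           gene_stratified: bool = True,
                           group_order: tuple[str, ...] = STATUS_ORDER) -> pd.DataFrame:
    """Per-protein ANOVA + Tukey across disease stages (volcano-ready).

    Each row is one protein x stratum x pairwise contrast with the mean
    log2 difference and Tukey-adjusted p; module labels are attached when an
    assignment is given, so volcano plots can be coloured by module.
    """
    md = metadata.set_index("sample_id", drop=False) \
        if metadata.index.name != "sample_id" else metadata
    md = md.loc[matrix.sample_ids]
    strata: list[tuple[str, np.ndarray]] = []
    if gene_stratified:
        for gene in sorted(set(md["gene_group"]) - {"control"}):
            mask = ((md["gene_group"] == gene) | (md["status"] == "control")).to_numpy()
            strata.append((gene, mask))
    else:
        strata.append(("all", np.ones(len(md), bool)))

    status = md["status"].to_numpy()
    rows = []
    for stratum, mask in strata:
        groups = status[mask]
        present = [g for g in group_order if (groups == g).sum() >= 3]
        if len(present) < 2:
            log.warning("stratum %s has < 2 usable groups; skipped", stratum)
            continue
        group_masks = [groups == g for g in present]
        for i, pid in enumerate(matrix.protein_ids):
            y = matrix.values[i][mask]
            samples = [y[m] for m in group_masks]
            if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
                f, p = 0.0, 1.0
                pmat = np.ones((len(present), len(present)))
            else:
                f, p = stats.f_oneway(*samples)
                pmat = stats.tukey_hsd(*samples).pvalue
            for a in range(len(present)):
                for b in range(a + 1, len(present)):
                    rows.append({
                        "protein_id": pid, "stratum": stratum,
                        "group_a": present[a], "group_b": present[b],
                        "log2_diff": float(samples[a].mean() - samples[b].mean()),
                        "F": float(f), "p_anova": float(p),
                        "p_tukey": float(pmat[a, b]),
                    })
    df = pd.DataFrame(rows)
    if assignment is not None and not df.empty:
        df["module"] = df["protein_id"].map(assignment.labels)
    return df


def module_da_proportion(da_table: pd.DataFrame, assignment: ModuleAssignment,
                         threshold: float = 0.05,
                         contrast: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-module fraction of members differentially abundant vs. controls."""
    df = da_table.copy()
    if contrast is not None:
        a, b = contrast
        df = df[(df["group_a"] == a) & (df["group_b"] == b)]
    sizes = assignment.sizes()
    rows = []
    modules = assignment.modules() + ([GREY] if GREY in sizes else [])
    for stratum in sorted(df["stratum"].unique()):
        sub = df[df["stratum"] == stratum]
        hits = sub[sub["p_tukey"] < threshold]
        hit_proteins = set(hits["protein_id"])
        for mod in modules:
            members = set(assignment.members(mod))
            frac = len(members & hit_proteins) / len(members) if members else 0.0
            rows.append({
                "module": mod, "stratum": stratum,
                "n_members": len(members),
                "fraction_da": frac,
                "ranked": mod != GREY,
            })
    return pd.DataFrame(rows)


def leave_one_out_eigenprotein(matrix: AbundanceMatrix, assignment: ModuleAssignment,
                               module: str, protein: str) -> EigenproteinSet:
    """Recompute one module's eigenprotein without a named member protein."""
    members = assignment.members(module)
    if protein not in members:
        raise ValueError(f"{protein} is not a member of {module}")
    if len(members) < 3:
        raise ValueError(f"{module} has only {len(members)} members; cannot drop one")
    return module_eigenproteins(matrix, assignment, exclude={module: [protein]})
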