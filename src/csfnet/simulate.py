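"""Synthetic multi-cohort CSF proteomics data with planted module structure.

The generator emulates the study design the pipeline targets: a discovery
cohort of mutation carriers (three gene groups, presymptomatic and
symptomatic) and noncarrier controls, measured on a single complete panel;
a same-panel replication cohort (disease vs. control); and a second-platform
cohort with restricted protein overlap and per-protein missingness.

Each module protein follows a latent-factor model

    x_pj = lambda_p * f_{m(p), j} + alpha_p * age_j + gamma_p * sex_j + eps_pj

with the module factor f_m standard normal per sample before group shifts,
loadings uniform in ``loading_range``, and background proteins pure noise
plus the covariate terms.  Every generator is a pure function of its
parameters and seed, and returns ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

GENE_GROUPS = ("C9orf72", "GRN", "MAPT")
STATUSES = ("control", "presymptomatic", "symptomatic")

#: Default per-module group shifts of the latent factor, in z units.  Keys
#: are "status" or "status:gene"; values add to the factor mean of samples
#: in that group.  The defaults plant one clearly increased and two
#: decreased disease modules plus one presymptomatic-shifted module,
#: with shifts in the 0.5-1.0 z range typical of strongly affected CSF
#: modules.
DEFAULT_GROUP_EFFECTS: dict[int, dict[str, float]] = {
    1: {"symptomatic": 1.0, "presymptomatic": 0.5},
    2: {"symptomatic": -0.85},
    3: {"symptomatic": -0.85, "presymptomatic": -0.5},
    4: {"symptomatic:MAPT": 1.0},
}


@dataclass
class TruthRecord:
    """Ground truth behind a synthetic cohort."""

    membership: dict[str, int]          # protein_id -> module index, 0 = background
    loadings: dict[str, float]          # protein_id -> lambda (module proteins)
    factors: pd.DataFrame               # modules x samples latent factors
    group_effects: dict[int, dict[str, float]]
    beta_age: pd.Series                 # per protein, abundance per year
    beta_sex: pd.Series                 # per protein, offset for sex=male
    true_slopes: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    outlier_samples: list[str] = field(default_factory=list)
    platform_overlap: list[str] = field(default_factory=list)
    missing_rates: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def module_proteins(self, module: int) -> list[str]:
        return [p for p, m in self.membership.items() if m == module]

    def n_modules(self) -> int:
        return max(self.membership.values(), default=0)

    def labels_list(self, protein_ids) -> list[int]:
        return [self.membership[p] for p in protein_ids]


def _make_metadata(n_samples: int, control_fraction: float, rng: np.random.Generator,
                   cohort: str) -> pd.DataFrame:
    """Sample roster: controls plus carriers split by gene and stage."""
    n_ctl = max(int(round(control_fraction * n_samples)), 4)
    n_car = n_samples - n_ctl
    genes = [GENE_GROUPS[i % 3] for i in range(n_car)]
    status = ["presymptomatic" if i % 2 == 0 else "symptomatic" for i in range(n_car)]
    rows = []
    for i in range(n_samples):
        if i < n_ctl:
            g, s = "control", "control"
        else:
            g, s = genes[i - n_ctl], status[i - n_ctl]
        rows.append({
            "sample_id": f"{cohort}_S{i + 1:03d}",
            "subject_id": f"{cohort}_P{i + 1:03d}",
            "cohort": cohort,
            "gene_group": g,
            "status": s,
            "age": float(rng.uniform(30.0, 75.0)),
            "sex": "female" if rng.uniform() < 0.5 else "male",
            "education": float(np.round(rng.uniform(12.0, 20.0))),
            "cdr_sb": 0.0,
            "nfl": float(np.exp(rng.normal(6.8, 0.5))),
        })
    md = pd.DataFrame(rows)
    # severity tracks stage: 0 when presymptomatic/control, positive when symptomatic
    sym = md["status"] == "symptomatic"
    md.loc[sym, "cdr_sb"] = np.round(rng.uniform(0.5, 16.0, size=int(sym.sum())) * 2) / 2
    md.loc[sym, "nfl"] = md.loc[sym, "nfl"] * np.exp(rng.uniform(0.5, 1.2, size=int(sym.sum())))
    return md


def _group_shift(effects: dict[int, dict[str, float]], module: int,
                 status: str, gene: str) -> float:
    shifts = effects.get(module, {})
    return shifts.get(f"{status}:{gene}", shifts.get(status, 0.0))


def generate_discovery_cohort(
    n_proteins: int = 800,
    n_samples: int = 140,
    module_sizes: tuple[int, ...] | None = None,
    loading_range: tuple[float, float] = (0.6, 0.9),
    noise_sd: float = 1.0,
    group_effects: dict[int, dict[str, float]] | None = None,
    age_effect_max: float = 0.03,
    sex_effect_max: float = 0.2,
    control_fraction: float = 0.25,
    min_module_size: int = 30,
    seed: int = 0,
    cohort: str = "disc",
) -> tuple[AbundanceMatrix, pd.DataFrame, TruthRecord]:
    """Simulate the discovery cohort with planted co-expression modules.

    Defaults plant 8 modules of 40-80 proteins among 800 proteins over
    140 samples with loadings 0.6-0.9 and unit noise — a desk-scale version
    of a several-thousand-protein aptamer panel.  Per-protein age slopes are
    uniform in [-age_effect_max, age_effect_max] (log2 units/year) and sex
    offsets uniform in [-sex_effect_max, sex_effect_max].
    """
    rng = np.random.default_rng(seed)
    if module_sizes is None:
        module_sizes = tuple(rng.integers(40, 81, size=8))
    module_sizes = tuple(int(s) for s in module_sizes)
    if any(s < min_module_size for s in module_sizes):
        raise ValueError(
            f"module sizes {module_sizes} below the minimum of {min_module_size}"
        )
    if sum(module_sizes) > n_proteins:
        raise ValueError("module sizes exceed the protein count")
    if group_effects is None:
        group_effects = DEFAULT_GROUP_EFFECTS
    k = len(module_sizes)

    metadata = _make_metadata(n_samples, control_fraction, rng, cohort)
    sex_code = (metadata["sex"] == "male").to_numpy(float)
    age = metadata["age"].to_numpy(float)

    protein_ids = [f"{cohort}_PR{i + 1:04d}" for i in range(n_proteins)]
    gene_symbols = [f"GENE{i + 1:04d}" for i in range(n_proteins)]

    membership: dict[str, int] = {}
    loadings: dict[str, float] = {}
    pos = 0
    for m, size in enumerate(module_sizes, start=1):
        for p in protein_ids[pos:pos + size]:
            membership[p] = m
            loadings[p] = float(rng.uniform(*loading_range))
        pos += size
    for p in protein_ids[pos:]:
        membership[p] = 0

    factors = rng.standard_normal((k, n_samples))
    for m in range(1, k + 1):
        shift = np.array([
            _group_shift(group_effects, m, s, g)
            for s, g in zip(metadata["status"], metadata["gene_group"])
        ])
        factors[m - 1] += shift
    factors_df = pd.DataFrame(
        factors, index=[f"module_{m}" for m in range(1, k + 1)],
        columns=metadata["sample_id"],
    )

    beta_age = pd.Series(rng.uniform(-age_effect_max, age_effect_max, n_proteins),
                         index=protein_ids, name="beta_age")
    beta_sex = pd.Series(rng.uniform(-sex_effect_max, sex_effect_max, n_proteins),
                         index=protein_ids, name="beta_sex")

    values = np.empty((n_proteins, n_samples))
    noise = rng.standard_normal((n_proteins, n_samples)) * noise_sd
    for i, p in enumerate(protein_ids):
        m = membership[p]
        signal = loadings[p] * factors[m - 1] if m > 0 else 0.0
        values[i] = signal + beta_age[p] * age + beta_sex[p] * sex_code + noise[i]

    matrix = AbundanceMatrix(values, protein_ids, gene_symbols,
                             metadata["sample_id"].tolist())
    # severity loosely tracks the disease-shifted module factors so
    # trait correlations have signal to find
    sym = (metadata["status"] == "symptomatic").to_numpy()
    cdr = metadata["cdr_sb"].to_numpy(float)
    cdr[sym] = np.clip(cdr[sym] + 2.0 * factors[0][sym], 0.5, 24.0)
    metadata["cdr_sb"] = np.round(cdr * 2) / 2

    truth = TruthRecord(membership, loadings, factors_df, dict(group_effects),
                        beta_age, beta_sex)
    return matrix, metadata, truth


def generate_replication_cohort(
    truth: TruthRecord,
    preserve_fraction: float = 1.0,
    n_samples: int = 70,
    groups: tuple[str, ...] = ("PSP-RS", "control"),
    noise_sd: float = 1.0,
    disease_effects: dict[int, dict[str, float]] | None = None,
    seed: int = 0,
    cohort: str = "rep",
) -> tuple[AbundanceMatrix, pd.DataFrame, TruthRecord]:
    """Simulate a same-panel replication cohort from discovery ground truth.

    A ``preserve_fraction`` of planted modules keep their loadings and gain
    fresh latent factors; the loadings of the remaining modules are
    scattered onto randomly chosen proteins outside the preserved modules,
    so the original member sets lose their co-expression.

    Samples are split evenly over ``groups``; the last group is the
    control group.  ``disease_effects`` maps module -> {group: shift in z
    units} applied to that module's latent factor in that group; the
    default shifts the first two preserved modules by +1/-1 in the first
    (disease) group only.
    """
    if not 0.0 <= preserve_fraction <= 1.0:
        raise ValueError("preserve_fraction must be in [0, 1]")
    if n_samples < 4:
        raise ValueError("n_samples must be at least 4")
    if not truth.loadings:
        raise ValueError("truth record carries no loadings")
    rng = np.random.default_rng(seed)
    k = truth.n_modules()
    n_preserved = int(round(preserve_fraction * k))
    preserved = set(range(1, n_preserved + 1))

    protein_ids = list(truth.membership)
    n_proteins = len(protein_ids)
    if disease_effects is None:
        disease_effects = {}
        if preserved:
            disease_effects[min(preserved)] = {groups[0]: 1.0}
        if len(preserved) > 1:
            disease_effects[sorted(preserved)[1]] = {groups[0]: -1.0}

    control = groups[-1]
    per_group = n_samples // len(groups)
    group_of = [groups[min(i // per_group, len(groups) - 1)]
                for i in range(n_samples)]
    rows = []
    for i, g in enumerate(group_of):
        rows.append({
            "sample_id": f"{cohort}_S{i + 1:03d}",
            "subject_id": f"{cohort}_P{i + 1:03d}",
            "cohort": cohort,
            "gene_group": g if g != control else "control",
            "status": "symptomatic" if g != control else "control",
            "group": g,
            "age": float(rng.uniform(45.0, 75.0)),
            "sex": "female" if rng.uniform() < 0.5 else "male",
            "education": float(np.round(rng.uniform(12.0, 20.0))),
            "cdr_sb": 0.0,
            "nfl": float(np.exp(rng.normal(6.8, 0.5))),
        })
    metadata = pd.DataFrame(rows)
    group_arr = metadata["group"].to_numpy()

    factors = rng.standard_normal((k, n_samples))
    for m, shifts in disease_effects.items():
        for g, shift in shifts.items():
            factors[m - 1, group_arr == g] += shift

    # re-map loadings for non-preserved modules onto random proteins
    membership = dict(truth.membership)
    loadings = dict(truth.loadings)
    scattered = [p for p, m in truth.membership.items() if m not in preserved and m != 0]
    if scattered:
        candidates = [p for p, m in truth.membership.items()
                      if m == 0 or m not in preserved]
        targets = rng.choice(candidates, size=len(scattered), replace=False)
        for p in scattered:
            membership[p] = 0
            loadings.pop(p, None)
        for p_old, p_new in zip(scattered, targets):
            membership[p_new] = truth.membership[p_old]
            loadings[p_new] = truth.loadings[p_old]

    values = rng.standard_normal((n_proteins, n_samples)) * noise_sd
    for i, p in enumerate(protein_ids):
        m = membership[p]
        if m > 0:
            values[i] += loadings[p] * factors[m - 1]

    matrix = AbundanceMatrix(values, protein_ids, [f"GENE{i + 1:04d}" for i in range(n_proteins)],
                             metadata["sample_id"].tolist())
    new_truth = TruthRecord(
        membership, loadings,
        pd.DataFrame(factors, index=[f"module_{m}" for m in range(1, k + 1)],
                     columns=metadata["sample_id"]),
        {m: dict(shifts) for m, shifts in disease_effects.items()},
        truth.beta_age * 0.0, truth.beta_sex * 0.0,
    )
    return matrix, metadata, new_truth


def make_platform_subset(matrix: AbundanceMatrix, overlap_fraction: float = 0.2,
                         missing_rate_range: tuple[float, float] = (0.0, 0.9),
                         seed: int = 0) -> tuple[AbundanceMatrix, pd.Series]:
    """Restrict to a random protein subset and inject missing-at-random cells.

    Emulates a second platform (Olink-like) that measures only a fraction of
    the panel and has per-protein missingness drawn uniformly from
    ``missing_rate_range``.  Returns the subset matrix (NaN for missing)
    and the drawn per-protein missing rates.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    lo, hi = missing_rate_range
    if not (0.0 <= lo <= hi < 1.0):
        raise ValueError("missing rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_keep = max(int(round(overlap_fraction * matrix.n_proteins)), 1)
    keep_idx = np.sort(rng.choice(matrix.n_proteins, size=n_keep, replace=False))
    keep = [matrix.protein_ids[i] for i in keep_idx]
    sub = matrix.select_proteins(keep)
    rates = rng.uniform(lo, hi, size=n_keep)
    vals = sub.values.copy()
    for i, rate in enumerate(rates):
        if rate > 0:
            mask = rng.uniform(size=sub.n_samples) < rate
            vals[i, mask] = np.nan
    out = AbundanceMatrix(vals, list(sub.protein_ids), list(sub.gene_symbols),
                          list(sub.sample_ids))
    return out, pd.Series(rates, index=keep, name="missing_rate")


def inject_outlier_samples(matrix: AbundanceMatrix, k: int, mode: str = "shuffle",
                           seed: int = 0) -> tuple[AbundanceMatrix, list[str]]:
    """Replace ``k`` samples with decorrelated values.

    ``mode="shuffle"`` permutes each chosen sample's values independently
    across proteins, destroying its correlation with every other sample
    while keeping its marginal distribution.
    """
    if k >= matrix.n_samples:
        raise ValueError("k must be smaller than the sample count")
    if mode != "shuffle":
        raise ValueError(f"unknown outlier mode: {mode!r}")
    if k == 0:
        return matrix.copy(), []
    rng = np.random.default_rng(seed)
    idx = rng.choice(matrix.n_samples, size=k, replace=False)
    vals = matrix.values.copy()
    for j in idx:
        vals[:, j] = rng.permutation(vals[:, j])
    chosen = [matrix.sample_ids[j] for j in idx]
    return AbundanceMatrix(vals, list(matrix.protein_ids),
                           list(matrix.gene_symbols), list(matrix.sample_ids)), chosen


def generate_cognition(metadata: pd.DataFrame, truth: TruthRecord,
                       slope_scale: float = -0.15, status_offsets: dict[str, float] | None = None,
                       resid_sd: float = 0.3, n_visits: int = 4,
                       visit_interval: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Simulate longitudinal global cognitive z-scores per subject.

    True annual slope per subject: ``slope_scale`` times the subject's
    module-1 latent factor plus a status offset, so cognitive decline
    tracks the first (disease-shifted) module, mirroring module/trajectory
    coupling.  Each subject gets ``n_visits`` visits at ``visit_interval``
    years with iid residual noise.  Slopes are written into
    ``truth.true_slopes``.
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    if status_offsets is None:
        status_offsets = {"control": 0.0, "presymptomatic": -0.05, "symptomatic": -0.25}
    rng = np.random.default_rng(seed)
    f1 = truth.factors.iloc[0]
    rows = []
    slopes = {}
    for _, r in metadata.iterrows():
        factor = float(f1.get(r["sample_id"], 0.0))
        slope = slope_scale * factor + status_offsets.get(r["status"], 0.0)
        intercept = float(rng.normal(0.0, 0.5))
        slopes[r["subject_id"]] = slope
        for v in range(n_visits):
            t = v * visit_interval
            rows.append({
                "subject_id": r["subject_id"],
                "visit_time": t,
                "global_z": intercept + slope * t + float(rng.normal(0.0, resid_sd)),
            })
    truth.true_slopes = pd.Series(slopes, name="true_slope")
    return pd.DataFrame(rows)
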