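"""Sample QC and covariate adjustment.

Outliers are samples whose network connectivity — the sum of their Pearson
correlations with every other sample, computed over protein-z-scored data —
falls more than ``cutoff`` SDs below the cohort mean; removal iterates until
stable.  Age and sex effects are estimated per protein by nonparametric
bootstrap regression in controls (median coefficient over B resamples) and
subtracted from every sample, cases and controls alike, after centring the
covariates at control means so adjustment does not shift the grand location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

log = logging.getLogger(__name__)


@dataclass
class ConnectivityProfile:
    """Per-sample raw connectivity k and standardised connectivity Z.k."""

    k: pd.Series
    zk: pd.Series


def sample_connectivity(matrix: AbundanceMatrix) -> ConnectivityProfile:
    """Standardised sample network connectivity.

    k_i = sum_{j != i} cor(sample_i, sample_j), Pearson over z-scored
    proteins; Z.k_i = (k_i - mean k) / SD k.  If all k are equal (SD 0),
    Z.k is all zero — the no-outlier short-circuit.
    """
    x = matrix.values
    if matrix.n_samples < 3:
        raise ValueError("sample connectivity requires at least 3 samples")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [matrix.protein_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance protein(s): {bad[:5]}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    degenerate = z.std(axis=0) <= 1e-10  # rows are z-scored, unit scale
    idx = pd.Index(matrix.sample_ids, name="sample_id")
    if degenerate.all():
        # all samples are affine copies of one shared profile: connectivity
        # is constant, so there is nothing to flag (Z.k = 0 everywhere)
        k = np.full(matrix.n_samples, float(matrix.n_samples - 1))
        return ConnectivityProfile(pd.Series(k, idx, name="k"),
                                   pd.Series(np.zeros_like(k), idx, name="Z.k"))
    if degenerate.any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(degenerate)]
        raise ValueError(f"zero-variance sample(s): {bad}")
    c = np.corrcoef(z.T)
    k = c.sum(axis=1) - 1.0
    k_sd = k.std()
    zk = np.zeros_like(k) if k_sd == 0 else (k - k.mean()) / k_sd
    return ConnectivityProfile(pd.Series(k, idx, name="k"),
                               pd.Series(zk, idx, name="Z.k"))


def remove_outliers(matrix: AbundanceMatrix, cutoff: float = 3.0,
                    iterate: bool = True, max_removed_fraction: float = 0.2
                    ) -> tuple[AbundanceMatrix, list[str]]:
    """Drop samples with Z.k < -cutoff, iterating until none remain.

    Raises if more than ``max_removed_fraction`` of samples would go —
    wholesale removal signals a data problem, not a few bad lumbar punctures.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    current = matrix
    removed: list[str] = []
    n0 = matrix.n_samples
    while True:
        prof = sample_connectivity(current)
        bad = prof.zk[prof.zk < -cutoff].index.tolist()
        if not bad:
            break
        removed.extend(bad)
        if len(removed) > max_removed_fraction * n0:
            raise ValueError(
                f"outlier removal would drop {len(removed)}/{n0} samples "
                f"(> {max_removed_fraction:.0%}); check the data or cutoff"
            )
        keep = [s for s in current.sample_ids if s not in set(bad)]
        current = current.select_samples(keep)
        if not iterate:
            break
    if removed:
        log.info("removed %d outlier sample(s): %s", len(removed), removed)
    return current, removed


@dataclass
class CovariateModel:
    """Median bootstrap regression coefficients for age and sex, per protein."""

    beta_age: pd.Series   # per protein, units of log2 abundance per year
    beta_sex: pd.Series   # per protein, offset for sex code 1 vs 0
    mean_age: float       # control mean, centring constant
    mean_sex: float       # control mean of the 0/1 sex code
    n_boot: int
    seed: int


def _sex_code(series: pd.Series) -> np.ndarray:
    s = series.astype(str).str.lower()
    mapping = {"female": 0.0, "f": 0.0, "0": 0.0, "male": 1.0, "m": 1.0, "1": 1.0}
    bad = sorted(set(s) - set(mapping))
    if bad:
        raise ValueError(f"unrecognised sex value(s): {bad}")
    return s.map(mapping).to_numpy(float)


def fit_covariate_model(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                        n_boot: int = 1000, seed: int = 0) -> CovariateModel:
    """Bootstrap OLS of abundance on centred age + sex code in controls.

    Every protein shares the same control resample within each of the
    ``n_boot`` iterations, preserving cross-protein dependence; the stored
    coefficient per protein is the median across iterations.
    """
    md = metadata.set_index("sample_id", drop=False) \
        if metadata.index.name != "sample_id" else metadata
    controls = [s for s in matrix.sample_ids
                if md.loc[s, "status"] == "control"]
    if len(controls) < 10:
        raise ValueError(f"need >= 10 control samples, have {len(controls)}")
    age = md.loc[controls, "age"].to_numpy(float)
    sex = _sex_code(md.loc[controls, "sex"])
    if np.unique(sex).size < 2:
        raise ValueError("all controls share one sex; beta_sex is inestimable")
    mean_age, mean_sex = float(age.mean()), float(sex.mean())

    y = matrix.select_samples(controls).values  # proteins x controls
    n_ctl = len(controls)
    rng = np.random.default_rng(seed)
    betas_age = np.empty((n_boot, matrix.n_proteins))
    betas_sex = np.empty((n_boot, matrix.n_proteins))
    for b in range(n_boot):
        idx = rng.integers(0, n_ctl, size=n_ctl)
        design = np.column_stack([
            np.ones(n_ctl), age[idx] - mean_age, sex[idx] - mean_sex,
        ])
        coef, *_ = np.linalg.lstsq(design, y[:, idx].T, rcond=None)
        betas_age[b] = coef[1]
        betas_sex[b] = coef[2]
    idx_p = pd.Index(matrix.protein_ids, name="protein_id")
    return CovariateModel(
        pd.Series(np.median(betas_age, axis=0), idx_p, name="beta_age"),
        pd.Series(np.median(betas_sex, axis=0), idx_p, name="beta_sex"),
        mean_age, mean_sex, n_boot, seed,
    )


def apply_adjustment(matrix: AbundanceMatrix, model: CovariateModel,
                     metadata: pd.DataFrame) -> AbundanceMatrix:
    """Subtract modelled age and sex effects from every sample.

    adjusted_pj = x_pj - beta_age_p (age_j - mean_age_ctl)
                        - beta_sex_p (sex_j - mean_sex_ctl)
    """
    if list(model.beta_age.index) != list(matrix.protein_ids):
        raise ValueError("covariate model proteins do not match the matrix")
    md = metadata.set_index("sample_id", drop=False) \
        if metadata.index.name != "sample_id" else metadata
    missing = [s for s in matrix.sample_ids if s not in md.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    age = md.loc[matrix.sample_ids, "age"]
    if age.isna().any():
        raise ValueError("sample(s) missing age")
    age = age.to_numpy(float)
    sex = _sex_code(md.loc[matrix.sample_ids, "sex"])
    ba = model.beta_age.to_numpy(float)[:, None]
    bs = model.beta_sex.to_numpy(float)[:, None]
    adjusted = matrix.values \
        - ba * (age - model.mean_age)[None, :] \
        - bs * (sex - model.mean_sex)[None, :]
    return AbundanceMatrix(adjusted, list(matrix.protein_ids),
                           list(matrix.gene_symbols), list(matrix.sample_ids))
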