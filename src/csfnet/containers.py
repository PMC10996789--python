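"""Core data containers for the co-expression pipeline.

The canonical orientation everywhere in this package is proteins x samples:
rows are analytes (aptamer/assay targets, identified by a unique ``protein_id``
and a possibly repeating ``gene_symbol``), columns are CSF samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GREY = "grey"

#: Required columns of a sample metadata table.
METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "cohort",
    "gene_group",
    "status",
    "age",
    "sex",
    "education",
    "cdr_sb",
    "nfl",
)


@dataclass
class AbundanceMatrix:
    """Log2 protein abundance, proteins x samples.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_proteins, n_samples)``.  NaN cells are
        permitted only for platform-subset data; network stages require a
        complete matrix.
    protein_ids
        Unique analyte identifiers (one per row).
    gene_symbols
        Gene symbol per analyte; may repeat (several aptamers, one gene).
    sample_ids
        Unique sample identifiers (one per column).
    """

    values: np.ndarray
    protein_ids: list[str]
    gene_symbols: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (proteins x samples)")
        n_p, n_s = self.values.shape
        if len(self.protein_ids) != n_p:
            raise ValueError(
                f"{len(self.protein_ids)} protein_ids for {n_p} matrix rows"
            )
        if len(self.gene_symbols) != n_p:
            raise ValueError(
                f"{len(self.gene_symbols)} gene_symbols for {n_p} matrix rows"
            )
        if len(self.sample_ids) != n_s:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n_s} matrix columns"
            )
        _check_unique(self.protein_ids, "protein_id")
        _check_unique(self.sample_ids, "sample_id")

    # -- basic properties -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def n_nonfinite(self) -> int:
        """Count of non-finite (NaN/inf) cells."""
        return int((~np.isfinite(self.values)).sum())

    # -- conversions ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Return a proteins x samples DataFrame (index = protein_id)."""
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            list(self.protein_ids),
            list(self.gene_symbols),
            list(self.sample_ids),
        )

    # -- subsetting -------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceMatrix(
            self.values[:, idx],
            list(self.protein_ids),
            list(self.gene_symbols),
            [self.sample_ids[i] for i in idx],
        )

    def select_proteins(self, protein_ids: Sequence[str]) -> "AbundanceMatrix":
        pos = {p: i for i, p in enumerate(self.protein_ids)}
        idx = [pos[p] for p in protein_ids]
        return AbundanceMatrix(
            self.values[idx, :],
            [self.protein_ids[i] for i in idx],
            [self.gene_symbols[i] for i in idx],
            list(self.sample_ids),
        )

    def symbol_of(self) -> Mapping[str, str]:
        return dict(zip(self.protein_ids, self.gene_symbols))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what}(s): {sorted(set(dups))}")


@dataclass
class GeneSetCollection:
    """Named gene sets (ontology terms or cell-type marker lists).

    Member symbols are uppercase-normalised and deduplicated.
    """

    sets: dict[str, list[str]]
    source: str = "ontology"

    def __post_init__(self) -> None:
        norm: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = sorted({str(m).upper() for m in members if str(m).strip()})
            norm[name] = uniq
        self.sets = norm

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


class ModuleAssignment:
    """Protein -> module label mapping with the grey (unassigned) convention.

    Module labels are ``M1..Mk`` ordered by descending module size; ties are
    broken by the lexicographically smallest member protein_id so relabelling
    is deterministic.
    """

    def __init__(self, labels: Mapping[str, str]):
        self.labels: dict[str, str] = {str(k): str(v) for k, v in labels.items()}

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, protein_id: str) -> str:
        return self.labels[protein_id]

    def modules(self) -> list[str]:
        """Non-grey module labels, in M-number order when applicable."""
        labs = {v for v in self.labels.values() if v != GREY}

        def key(lab: str):
            if lab.startswith("M") and lab[1:].isdigit():
                return (0, int(lab[1:]))
            return (1, lab)

        return sorted(labs, key=key)

    def members(self, module: str) -> list[str]:
        return [p for p, m in self.labels.items() if m == module]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.labels.values():
            out[m] = out.get(m, 0) + 1
        return out

    def grey_fraction(self) -> float:
        if not self.labels:
            return 0.0
        n_grey = sum(1 for v in self.labels.values() if v == GREY)
        return n_grey / len(self.labels)

    # -- canonical relabelling -------------------------------------------
    def relabel_by_size(self) -> "ModuleAssignment":
        """Return an equivalent assignment with labels M1..Mk by size."""
        groups: dict[str, list[str]] = {}
        for p, m in self.labels.items():
            if m != GREY:
                groups.setdefault(m, []).append(p)
        order = sorted(
            groups, key=lambda m: (-len(groups[m]), min(groups[m]))
        )
        rename = {old: f"M{i + 1}" for i, old in enumerate(order)}
        rename[GREY] = GREY
        return ModuleAssignment({p: rename[m] for p, m in self.labels.items()})

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, name="module")

    @classmethod
    def from_series(cls, s: pd.Series) -> "ModuleAssignment":
        return cls(s.to_dict())

    def __eq__(self, other) -> bool:
        return isinstance(other, ModuleAssignment) and self.labels == other.labels


@dataclass
class EigenproteinSet:
    """Module summary profiles: first PC of module abundance per sample.

    ``values`` rows (one per module) are z-scored across samples and sign
    oriented so the mean correlation with module members is positive.
    ``pve`` is the proportion of module variance the first PC explains.
    """

    values: pd.DataFrame  # modules x samples
    pve: pd.Series  # per module
    sign: pd.Series  # +1/-1 orientation applied per module

    def module_ids(self) -> list[str]:
        return list(self.values.index)

    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class KMETable:
    """Signed module-membership correlations (protein x module) with p-values."""

    kme: pd.DataFrame  # proteins x modules
    pvalues: pd.DataFrame  # same shape

    def own_module_kme(self, assignment: ModuleAssignment) -> pd.Series:
        """kME of each assigned protein to its own module (NaN for grey)."""
        out = {}
        for p in self.kme.index:
            m = assignment[p]
            out[p] = self.kme.loc[p, m] if m in self.kme.columns else np.nan
        return pd.Series(out, name="kME_own")


def validate_metadata(metadata: pd.DataFrame, matrix: AbundanceMatrix | None = None) -> pd.DataFrame:
    """Check a sample metadata table and return it indexed by sample_id."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns and c != "nfl"]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    md = metadata.copy()
    if "nfl" not in md.columns:
        md["nfl"] = np.nan
    md["sample_id"] = md["sample_id"].astype(str)
    if md["sample_id"].duplicated().any():
        dups = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in metadata: {dups}")
    if (md["cdr_sb"].dropna() < 0).any():
        raise ValueError("cdr_sb must be nonnegative")
    if matrix is not None:
        have = set(md["sample_id"])
        absent = [s for s in matrix.sample_ids if s not in have]
        if absent:
            raise ValueError(f"samples missing from metadata: {absent}")
    return md.set_index("sample_id", drop=False)
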