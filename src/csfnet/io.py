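"""Readers and writers for the plain-text formats the pipeline consumes.

Abundance matrices and metadata travel as TSV/CSV; gene sets as GMT;
run manifests as JSON.  Values round-trip at full float precision
(written with ``repr`` semantics via pandas ``float_format=None``).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, GeneSetCollection, ModuleAssignment, validate_metadata

log = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_abundance(path, orientation: str = "proteins_in_rows",
                   gene_symbols: dict[str, str] | None = None) -> AbundanceMatrix:
    """Read a delimited abundance table into the canonical orientation.

    The first column holds identifiers (protein_id or sample_id depending on
    ``orientation``); remaining columns are numeric.  An optional second
    column named ``gene_symbol`` supplies symbols when proteins are in rows;
    otherwise symbols default to the protein_id (override via the
    ``gene_symbols`` mapping).
    """
    path = Path(path)
    if orientation not in ("proteins_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    symbol_col = None
    if orientation == "proteins_in_rows" and "gene_symbol" in df.columns:
        symbol_col = df["gene_symbol"]
        df = df.drop(columns=["gene_symbol"])

    ids = [str(i) for i in df.index]
    dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate identifier(s) in {path.name}: {dup}")

    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_nan = df[col].isna() | df[col].str.strip().isin(("", "NA", "NaN", "nan"))
        bad = converted.isna() & ~raw_nan
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric cell in {path.name} at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        # exact (correctly rounded) parse so write/read round-trips bit-for-bit
        numeric[col] = df[col].mask(raw_nan, "nan").astype(float)

    if orientation == "samples_in_rows":
        numeric = numeric.T

    protein_ids = [str(i) for i in numeric.index]
    sample_ids = [str(c) for c in numeric.columns]
    if symbol_col is not None:
        symbols = [str(symbol_col.loc[p]) for p in numeric.index]
    elif gene_symbols is not None:
        symbols = [gene_symbols.get(p, p) for p in protein_ids]
    else:
        symbols = list(protein_ids)

    m = AbundanceMatrix(numeric.to_numpy(float), protein_ids, symbols, sample_ids)
    n_bad = m.n_nonfinite()
    if n_bad:
        log.warning("%s: %d non-finite cells", path.name, n_bad)
    return m


def write_abundance(matrix: AbundanceMatrix, path, with_symbols: bool = True) -> None:
    path = Path(path)
    df = matrix.to_frame()
    if with_symbols:
        df.insert(0, "gene_symbol", matrix.gene_symbols)
    df.to_csv(path, sep=_sep_for(path), index_label="protein_id",
              float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    md = pd.read_csv(path, sep=_sep_for(path))
    return validate_metadata(md)


def read_cognition(path) -> pd.DataFrame:
    """Read a longitudinal cognition table (subject_id, visit_time, global_z)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"subject_id", "visit_time", "global_z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cognition table missing columns: {sorted(missing)}")
    if (df["visit_time"] < 0).any():
        raise ValueError("visit_time must be >= 0 (years since baseline)")
    return df


def read_gmt(path, source: str = "ontology") -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member symbols."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description and at least one member"
                )
            name = fields[0]
            sets[name] = fields[2:]
    if not sets:
        log.warning("%s: empty GMT file", path.name)
    return GeneSetCollection(sets, source=source)


def write_assignment(assignment: ModuleAssignment, matrix: AbundanceMatrix,
                     path, kme_own=None, pvalue_own=None) -> None:
    sym = matrix.symbol_of()
    rows = []
    for p in matrix.protein_ids:
        rows.append({
            "protein_id": p,
            "gene_symbol": sym[p],
            "module": assignment[p],
            "kME_own": np.nan if kme_own is None else kme_own.get(p, np.nan),
            "p_own": np.nan if pvalue_own is None else pvalue_own.get(p, np.nan),
        })
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_assignment(path) -> ModuleAssignment:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    return ModuleAssignment(dict(zip(df["protein_id"], df["module"])))


def write_manifest(path, **entries) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(Path(path), "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
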