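"""Readers and writers for the pipeline's plain-text formats.

Expression travels as TSV (genes x samples, first column ``gene_id``,
header row = sample ids), sample metadata and results as TSV, behaviour
tables as CSV, gene sets as standard GMT.  Numeric result tables are
written with 6 significant digits in a fixed column order so runs diff
cleanly.  A workbook reader with a user-supplied column mapping supports
re-analysing per-bird tables distributed as XLSX.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CohortTables

__all__ = [
    "read_expression",
    "write_expression",
    "read_meta",
    "write_meta",
    "read_gmt",
    "write_cohort",
    "read_behaviour_table",
    "read_behaviour_workbook",
    "write_results_tsv",
    "read_yaml_config",
]

BEHAVIOUR_FILES = {
    "birds": "birds.csv",
    "open_field": "open_field.csv",
    "tonic_immobility": "tonic_immobility.csv",
    "dominance": "dominance_pairs.csv",
    "hormones": "hormones.csv",
}

META_COLUMNS = ["sample_id", "age", "sex", "treatment", "condition", "pool_members"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a log2 expression TSV into a genes x samples DataFrame.

    Rejects duplicate gene or sample ids, ragged rows and non-numeric
    cells, naming the offending id or line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell: {exc}") from exc
    if not np.isfinite(values).all():
        gi, si = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value for gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = "gene_id"
    return out


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata lacks columns {sorted(missing)}")
    if meta.sample_id.duplicated().any():
        dup = meta.sample_id[meta.sample_id.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    return meta


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Read a GMT gene-set file; returns (sets, descriptions) by term."""
    from gseapy.parser import read_gmt as _read

    sets = _read(str(path))
    # gseapy drops the description column; recover it for reporting
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                descriptions[parts[0]] = parts[1]
    return sets, descriptions


def write_cohort(tables: CohortTables, outdir: str | Path) -> dict[str, Path]:
    """Write the behaviour tables as CSV, one row per bird or pair."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = outdir / BEHAVIOUR_FILES[name]
        df.to_csv(p, index=False, float_format="%.6g")
        paths[name] = p
    return paths


def read_behaviour_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: lacks required columns {sorted(missing)}")
    return df


def read_behaviour_workbook(
    path: str | Path, mapping: dict[str, dict]
) -> dict[str, pd.DataFrame]:
    """Read per-bird tables from an XLSX workbook via a column mapping.

    ``mapping`` maps table names (open_field, tonic_immobility, dominance,
    hormones, birds) to ``{"sheet": name-or-index, "columns": {source ->
    canonical}}``; sheet layouts vary between datasets, so the mapping is
    supplied by the caller (typically from a YAML config) rather than
    hard-coded.
    """
    out = {}
    for table, spec in mapping.items():
        df = pd.read_excel(path, sheet_name=spec.get("sheet", 0))
        cols = spec.get("columns", {})
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(
                f"{path}: sheet for {table!r} lacks columns {sorted(missing)}"
            )
        out[table] = df[list(cols)].rename(columns=cols)
    return out


def write_results_tsv(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write the tidy results table (test, stratum, statistic, df, P)."""
    cols = ["test", "stratum", "statistic", "value", "df", "p_value"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df = df[cols]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def read_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
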