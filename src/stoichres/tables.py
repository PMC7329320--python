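"""Tabular I/O for site, abundance and standard-curve tables.

Everything is plain TSV/CSV (UTF-8, header row, dot decimal). Abundance
tables travel in long format (site_id, gene, treatment, copies_per_g); a
wide layout (one column per gene) is auto-detected on read and melted.
Floats are written with Python's shortest round-trip repr, so a
write -> read cycle is bit-exact.
"""

from __future__ import annotations

import pandas as pd

from .errors import DuplicateKeyError, TableParseError, InvalidInputError

LONG_COLUMNS = ["site_id", "gene", "treatment", "copies_per_g"]
SITE_NUMERIC = ["mat", "map", "total_c", "total_n", "total_p", "cn", "cp", "np"]


def _delimiter_for(path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def write_abundance_table(table: pd.DataFrame, path, delimiter: str | None = None) -> None:
    """Write a long-format abundance table (TSV by default, CSV for .csv)."""
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"abundance table missing columns: {missing}")
    table[LONG_COLUMNS].to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def _check_duplicates(table: pd.DataFrame) -> None:
    keys = ["site_id", "gene", "treatment"]
    dup = table.duplicated(subset=keys)
    if dup.any():
        first = table.loc[dup, keys].iloc[0]
        raise DuplicateKeyError(
            "duplicated (site, gene, treatment) key: "
            f"({first['site_id']}, {first['gene']}, {first['treatment']})")


def _numeric_or_raise(s: pd.Series, colname: str) -> pd.Series:
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based + header line
        raise TableParseError(
            f"non-numeric value {s[bad.idxmax()]!r} in column {colname!r} "
            f"at file row {row}")
    return out.astype(float)


def read_abundance_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read an abundance table, auto-detecting long vs wide layout.

    Long layout carries a ``copies_per_g`` column; any other layout is
    treated as wide, with ``site_id`` (and optionally ``treatment``)
    identifier columns and one column per gene.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    if "copies_per_g" in df.columns:
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise TableParseError(f"long abundance table missing columns: {missing}")
        df["copies_per_g"] = _numeric_or_raise(df["copies_per_g"], "copies_per_g")
        _check_duplicates(df)
        return df[LONG_COLUMNS]
    # wide layout
    if "site_id" not in df.columns:
        raise TableParseError("wide abundance table must have a 'site_id' column")
    id_vars = ["site_id"] + (["treatment"] if "treatment" in df.columns else [])
    long = df.melt(id_vars=id_vars, var_name="gene", value_name="copies_per_g")
    if "treatment" not in long.columns:
        long["treatment"] = "control"
    long["copies_per_g"] = _numeric_or_raise(long["copies_per_g"], "copies_per_g")
    _check_duplicates(long)
    return long[LONG_COLUMNS]


def to_wide(table: pd.DataFrame, treatment: str | None = None) -> pd.DataFrame:
    """Pivot a long abundance table to sites x genes (one treatment)."""
    sub = table if treatment is None else table[table["treatment"] == treatment]
    if treatment is not None and sub.empty:
        raise InvalidInputError(f"no rows for treatment {treatment!r}")
    return sub.pivot(index="site_id", columns="gene", values="copies_per_g")


def write_site_table(sites: pd.DataFrame, path, delimiter: str | None = None) -> None:
    sites.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def read_site_table(path, delimiter: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    if "site_id" not in df.columns:
        raise TableParseError("site table must have a 'site_id' column")
    missing = [c for c in SITE_NUMERIC if c not in df.columns]
    if missing:
        raise TableParseError(f"site table missing columns: {missing}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise DuplicateKeyError(f"duplicated site_id: {dup}")
    return df


def write_standard_curves(curves: dict, path, delimiter: str | None = None) -> None:
    rows = [{"gene": c.gene, "slope": c.slope, "intercept": c.intercept,
             "r2": c.r2} for c in curves.values()]
    pd.DataFrame(rows).to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def read_standard_curves(path, delimiter: str | None = None) -> dict:
    from .qpcr import StandardCurve
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    needed = ["gene", "slope", "intercept", "r2"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise TableParseError(f"standard-curve table missing columns: {missing}")
    return {row["gene"]: StandardCurve(gene=row["gene"], slope=row["slope"],
                                       intercept=row["intercept"], r2=row["r2"])
            for _, row in df.iterrows()}
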