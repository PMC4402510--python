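"""Readers and writers for the plain-text formats used throughout.

Expression matrices are TSV/CSV with a header row of sample ids and gene ids
in the first column; sparse counts may be given as MatrixMarket triplets with
sidecar row/column name files.  Gene sets use the tab-delimited GMT format.
Result tables are written as TSV with floats at six significant digits and
NaN rendered as "NA".
"""

from __future__ import annotations

import io as _io
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DesignSpec, ExpressionMatrix, GeneSetCollection

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_design",
    "read_contrasts",
    "read_gmt",
    "write_gmt",
    "write_table",
]


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path: str, kind: str = "log_intensity", allow_dup: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (or MTX for counts).

    The delimited layout is: header row of sample ids, first column gene ids,
    numeric body.  ``.mtx`` files are MatrixMarket coordinate triplets and are
    accepted only for ``kind='counts'``; row/column names are read from
    sidecar files ``<stem>.rownames.txt`` / ``<stem>.colnames.txt`` when
    present, else synthesized.

    Duplicate gene ids raise unless ``allow_dup``, which suffixes repeats
    with ``.1``, ``.2``, ...
    """
    path = str(path)
    if path.lower().endswith(".mtx"):
        if kind != "counts":
            raise ValueError("MTX input is only supported for kind='counts'")
        from scipy.io import mmread

        mat = mmread(path)
        m = np.asarray(mat.toarray() if hasattr(mat, "toarray") else mat, dtype=float)
        stem = path[: -len(".mtx")]
        gene_ids = _read_names(stem + ".rownames.txt", m.shape[0], "g")
        sample_ids = _read_names(stem + ".colnames.txt", m.shape[1], "s")
    else:
        sep = _sep_for(path)
        with open(path) as fh:
            for header_line in fh:
                if not header_line.startswith("#"):
                    break
        raw_cols = header_line.rstrip("\n").split(sep)[1:]
        if len(set(raw_cols)) != len(raw_cols):
            raise ValueError("duplicate sample ids are not supported")
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, comment="#", dtype=str)
        sample_ids = [str(c) for c in df.columns]
        gene_ids = [str(i) for i in df.index]
        body = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            raw = df[col].to_numpy()
            for i, cell in enumerate(raw):
                try:
                    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                        val = np.nan
                    elif isinstance(cell, str) and cell.strip().upper() in ("NA", "NAN", ""):
                        val = np.nan
                    else:
                        val = float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell {cell!r} at gene {gene_ids[i]!r}, sample {col!r} in {path}"
                    ) from None
                body[i, j] = val
        m = body
    if kind == "counts" and np.isnan(m).any():
        i, j = np.argwhere(np.isnan(m))[0]
        raise ValueError(
            f"missing value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}: "
            "not allowed for kind='counts'"
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids are not supported")
    if len(set(gene_ids)) != len(gene_ids):
        if not allow_dup:
            dups = pd.Series(gene_ids).value_counts()
            dups = list(dups[dups > 1].index[:5])
            raise ValueError(f"duplicate gene ids (e.g. {dups}); pass allow_dup to suffix them")
        seen: dict[str, int] = {}
        out = []
        for g in gene_ids:
            if g in seen:
                seen[g] += 1
                out.append(f"{g}.{seen[g]}")
            else:
                seen[g] = 0
                out.append(g)
        gene_ids = out
    return ExpressionMatrix(values=m, gene_ids=gene_ids, sample_ids=sample_ids, kind=kind)


def _read_names(path: str, n: int, prefix: str) -> list[str]:
    if os.path.exists(path):
        with open(path) as fh:
            names = [ln.strip() for ln in fh if ln.strip()]
        if len(names) != n:
            raise ValueError(f"{path}: expected {n} names, found {len(names)}")
        return names
    return [f"{prefix}{i+1}" for i in range(n)]


def write_matrix(m: ExpressionMatrix, path: str, float_format: str | None = None) -> None:
    """Write an expression matrix as TSV/CSV (delimiter from the extension)."""
    sep = _sep_for(path)
    df = m.to_dataframe()
    df.to_csv(path, sep=sep, index_label="id", float_format=float_format, na_rep="NA")


def read_design(path: str, targets_mode: bool = False) -> DesignSpec:
    """Read a design matrix, or build one from a two-column targets file.

    In targets mode the file has columns (sample, group); the result is a
    treatment-means design with one indicator column per group level, levels
    ordered by first appearance.  Explicit designs must be full column rank.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, comment="#")
    if targets_mode:
        if df.shape[1] < 1:
            raise ValueError("targets file needs columns (sample, group)")
        groups = [str(g) for g in df.iloc[:, 0]]
        spec = DesignSpec.from_groups(groups)
        return spec
    design = df.to_numpy(dtype=float)
    spec = DesignSpec(design=design, coef_names=[str(c) for c in df.columns])
    spec.check_full_rank()
    return spec


def read_contrasts(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a contrast matrix (rows = coefficients, columns = contrasts)."""
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, comment="#")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT gene set file.

    Layout per line: name TAB description TAB member [TAB member ...].
    Members may carry direction/weight extension tokens, e.g. ``g1,+1`` or
    ``g1,+1,0.8``.
    """
    sets: dict[str, list[str]] = {}
    directions: dict[str, dict[str, int]] = {}
    weights: dict[str, dict[str, float]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            members: list[str] = []
            for tok in fields[2:]:
                tok = tok.strip()
                if not tok:
                    continue
                parts = tok.split(",")
                gene = parts[0]
                members.append(gene)
                if len(parts) >= 2 and parts[1] != "":
                    d = int(float(parts[1]))
                    if d not in (-1, 1):
                        raise ValueError(f"{path}:{lineno}: direction must be +1/-1, got {parts[1]}")
                    directions.setdefault(name, {})[gene] = d
                if len(parts) >= 3 and parts[2] != "":
                    weights.setdefault(name, {})[gene] = float(parts[2])
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, directions=directions,
                             gene_weights=weights, descriptions=descriptions)


def write_gmt(coll: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            toks = []
            for g in members:
                tok = g
                d = coll.directions.get(name, {}).get(g)
                w = coll.gene_weights.get(name, {}).get(g)
                if d is not None or w is not None:
                    tok += f",{d if d is not None else ''}"
                    if w is not None:
                        tok += f",{w:g}"
                toks.append(tok)
            fh.write("\t".join([name, desc] + toks) + "\n")


def _format_cell(x) -> str:
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def write_table(rows: pd.DataFrame, path: str, header_comments: Sequence[str] = ()) -> None:
    """Write a result table as TSV: stable column order, floats at 6
    significant digits, NaN as "NA", deterministic row order (as given)."""
    buf = _io.StringIO()
    for c in header_comments:
        buf.write(f"# {c}\n")
    cols = list(rows.columns)
    index_name = rows.index.name or "id"
    buf.write("\t".join([index_name] + [str(c) for c in cols]) + "\n")
    for idx, row in rows.iterrows():
        buf.write("\t".join([str(idx)] + [_format_cell(row[c]) for c in cols]) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
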