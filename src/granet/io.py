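"""Readers and writers: expression matrices, networks, complex tables.

Expression matrices are TSV/CSV (first column gene id, header row of time
labels; delimiter inferred from the extension).  Networks round-trip through
weighted edge-list TSV, GraphML and SIF.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .assoc import AssociationNetwork, DirectedStrengthMatrix
from .exceptions import ValidationError
from .modules import Complex
from .preprocess import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "write_network",
    "read_network",
    "write_directed",
    "write_complexes",
]

_NETWORK_FORMATS = {".tsv": "edgelist", ".txt": "edgelist", ".graphml": "graphml", ".sif": "sif"}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x time-point matrix, validating ids and cell contents.

    Duplicate gene ids, ragged rows and non-numeric cells are reported with
    their coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed expression file {path}: {exc}") from exc
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()].astype(str)))
        raise ValidationError(f"duplicate gene id(s) in {path}: {', '.join(dupes)}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        g, t = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[g, t]
        what = "missing value" if pd.isna(cell) else f"non-numeric value {cell!r}"
        raise ValidationError(
            f"{what} for gene '{raw.index[g]}' in column '{raw.columns[t]}' of {path}"
        )
    return ExpressionMatrix(
        [str(g) for g in raw.index],
        numeric.to_numpy(dtype=float),
        [str(c) for c in raw.columns],
    )


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.time_labels)
    df.index.name = "gene"
    df.to_csv(path, sep=_sep_for(path))


def _network_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    try:
        return _NETWORK_FORMATS[path.suffix.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown network extension '{path.suffix}' "
            f"(expected one of {sorted(_NETWORK_FORMATS)})"
        ) from None


def write_network(a: AssociationNetwork, path: str | Path, fmt: str | None = None) -> None:
    """Write the positive-weight edges as edge-list TSV, GraphML or SIF."""
    path = Path(path)
    fmt = _network_format(path, fmt)
    edges = a.edges()
    if not edges:
        raise ValidationError("refusing to write an empty network")
    if fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v, w in edges:
                fh.write(f"{u}\t{v}\t{w!r}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, _ in edges:
                fh.write(f"{u}\tpp\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(a.to_graph(), path)
    else:
        raise ValidationError(f"unknown network format '{fmt}'")


def read_network(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read a network written by :func:`write_network` (SIF edges weigh 1.0)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    fmt = _network_format(path, fmt)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return g
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if fmt == "edgelist":
                if len(parts) != 3:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                    )
                try:
                    weight = float(parts[2])
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
                g.add_edge(parts[0], parts[1], weight=weight)
            else:  # sif
                if len(parts) != 3:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 'source<TAB>type<TAB>target'"
                    )
                g.add_edge(parts[0], parts[2], weight=1.0)
    return g


def write_directed(
    d: DirectedStrengthMatrix, path: str | Path, full_matrix: bool = False
) -> None:
    """Write rejected directions as (source, target, S) TSV, or the full matrix."""
    path = Path(path)
    if full_matrix:
        df = pd.DataFrame(d.values, index=d.gene_ids, columns=d.gene_ids)
        df.index.name = "target"
        df.to_csv(path, sep="\t")
        return
    with open(path, "w") as fh:
        fh.write("source\ttarget\tstatistic\n")
        for i in range(len(d.gene_ids)):
            for j in range(len(d.gene_ids)):
                s = d.values[i, j]
                if s > 0:  # entry (i, j) holds the strength of j -> i
                    fh.write(f"{d.gene_ids[j]}\t{d.gene_ids[i]}\t{s!r}\n")


def write_complexes(complexes: list[Complex], path: str | Path) -> None:
    """Complex table: rank, score, n_vertices, comma-joined vertex ids."""
    with open(Path(path), "w") as fh:
        fh.write("rank\tscore\tn_vertices\tvertices\n")
        for c in complexes:
            fh.write(f"{c.rank}\t{c.score!r}\t{c.n_vertices}\t{','.join(map(str, c.vertices))}\n")
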