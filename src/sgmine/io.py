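"""Reading and writing datasets and mining results.

Datasets travel either as a single JSON document or as a directory of 0/1
adjacency-matrix CSVs (one file per subject per group; static graphs only).
Mining results are written as TSV with a commented header block carrying the
full run configuration, so results are reproducible from the file alone.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import BETWEEN, WITHIN, Edge, GraphDataset, GraphSample, edge_sort_key
from .mining import MiningResult

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_results",
    "read_results",
    "write_reports",
]

SCHEMA_VERSION = 1


def _edge_to_list(edge: Edge) -> list[int]:
    if edge.lag is None:
        return [edge.source, edge.target]
    return [edge.source, edge.target, edge.lag]


def write_dataset(dataset: GraphDataset, path) -> None:
    """Serialize a dataset to the JSON document format."""
    doc = {
        "schema": SCHEMA_VERSION,
        "design": dataset.design,
        "n_nodes": dataset.n_nodes,
        "directed": dataset.directed,
        "has_lags": dataset.has_lags,
        "groups": [
            [
                [_edge_to_list(e) for e in sorted(g.edges, key=edge_sort_key)]
                for g in group
            ]
            for group in (dataset.group_a, dataset.group_b)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _read_json_dataset(path) -> GraphDataset:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("design", "n_nodes", "directed", "groups"):
        if key not in doc:
            raise ValueError(f"{path}: missing required field {key!r}")
    groups = doc["groups"]
    if not (isinstance(groups, list) and len(groups) == 2):
        raise ValueError(f"{path}: 'groups' must be a list of two graph arrays")
    built = []
    for gi, group in enumerate(groups):
        graphs = []
        for si, edges in enumerate(group):
            where = f"{path}: groups[{gi}][{si}]"
            for e in edges:
                if not (isinstance(e, list) and len(e) in (2, 3)):
                    raise ValueError(
                        f"{where}: edge {e!r} must be [source, target] or "
                        "[source, target, lag]"
                    )
            try:
                graphs.append(
                    GraphSample.from_iterable(
                        (tuple(e) for e in edges), directed=doc["directed"]
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{where}: {exc}") from exc
        built.append(graphs)
    try:
        return GraphDataset(
            doc["design"], doc["n_nodes"], doc["directed"],
            tuple(built[0]), tuple(built[1]),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _read_adjacency_csv(path: Path, directed: bool) -> tuple[GraphSample, int]:
    try:
        mat = pd.read_csv(path, header=None).to_numpy()
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse adjacency CSV ({exc})") from exc
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(
            f"{path}: adjacency matrix must be square, got shape {mat.shape}"
        )
    if not np.isin(mat, (0, 1)).all():
        bad = mat[~np.isin(mat, (0, 1))].flat[0]
        raise ValueError(f"{path}: non-binary adjacency entry {bad!r}")
    if not directed and not (mat == mat.T).all():
        raise ValueError(f"{path}: undirected data requires a symmetric matrix")
    srcs, tgts = np.nonzero(mat)
    edges = {(int(i), int(j)) for i, j in zip(srcs, tgts)}
    if not directed:
        edges = {(min(i, j), max(i, j)) for i, j in edges}
    return GraphSample.from_iterable(edges, directed=directed), mat.shape[0]


def _read_csv_dir(path, design: str, directed: bool) -> GraphDataset:
    root = Path(path)
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(subdirs) != 2:
        raise ValueError(
            f"{path}: expected exactly two group subdirectories, "
            f"found {[d.name for d in subdirs]}"
        )
    groups, sizes = [], set()
    for d in subdirs:
        files = sorted(d.glob("*.csv"))
        if not files:
            raise ValueError(f"{d}: no adjacency CSV files found")
        graphs = []
        for f in files:
            g, l = _read_adjacency_csv(f, directed)
            sizes.add(l)
            graphs.append(g)
        groups.append(tuple(graphs))
    if len(sizes) != 1:
        raise ValueError(
            f"{path}: adjacency matrices disagree on node count: {sorted(sizes)}"
        )
    return GraphDataset(design, sizes.pop(), directed, groups[0], groups[1])


def read_dataset(
    path,
    format: Optional[str] = None,
    design: str = BETWEEN,
    directed: bool = True,
) -> GraphDataset:
    """Load a dataset from a JSON file or a directory of adjacency CSVs.

    ``format`` is inferred from the path when omitted (directory -> csv_dir).
    For csv_dir the design and directedness must be given by the caller; the
    JSON document carries them itself.
    """
    if format is None:
        format = "csv_dir" if os.path.isdir(path) else "json"
    if format == "json":
        return _read_json_dataset(path)
    if format == "csv_dir":
        return _read_csv_dir(path, design, directed)
    raise ValueError(f"unknown dataset format {format!r}")


def format_subgraph(edges) -> str:
    """Canonical text form: ``src->tgt[@lag]`` terms joined by ``;``."""
    parts = []
    for e in sorted(edges, key=edge_sort_key):
        s = f"{e.source}->{e.target}"
        if e.lag is not None:
            s += f"@{e.lag}"
        parts.append(s)
    return ";".join(parts)


def parse_subgraph(text: str) -> tuple[Edge, ...]:
    edges = []
    for part in text.split(";"):
        arrow, _, lag = part.partition("@")
        src, _, tgt = arrow.partition("->")
        edges.append(
            Edge(int(src), int(tgt), int(lag) if lag else None)
        )
    return tuple(edges)


def _fmt_factor(factor) -> str:
    if isinstance(factor, int):
        return str(factor)
    if isinstance(factor, float) and math.isinf(factor):
        return "inf"
    return repr(factor)


def write_results(result: MiningResult, path) -> None:
    """Write significant subgraphs as TSV with a commented config header."""
    from . import __version__

    within = result.design == WITHIN
    cols = ["subgraph", "n_links", "f1", "f2"]
    if within:
        cols.append("d")
    cols += ["p_value", "min_p", "corrected_p", "significant"]
    lines = [
        f"# sgmine {__version__}",
        f"# method\t{result.method}",
        f"# design\t{result.design}",
        f"# alpha\t{result.alpha!r}",
        f"# correction_factor\t{_fmt_factor(result.correction_factor)}",
        f"# num_testable\t{result.num_testable}",
        f"# universe_size\t{result.universe_size}",
        f"# n_perm\t{result.n_perm if result.n_perm is not None else 'NA'}",
        f"# seed\t{result.seed if result.seed is not None else 'NA'}",
        f"# max_links\t{result.max_links if result.max_links is not None else 'NA'}",
        "\t".join(cols),
    ]
    for rec in result.significant:
        row = [
            format_subgraph(rec.edges),
            str(len(rec.edges)),
            str(rec.support.f1),
            str(rec.support.f2),
        ]
        if within:
            row.append(str(rec.support.d))
        row += [
            repr(rec.p_value),
            repr(rec.min_p),
            repr(rec.corrected_p),
            "yes",
        ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path) -> tuple[dict, pd.DataFrame]:
    """Parse a results TSV back into (header metadata, records table)."""
    header = {}
    rows = []
    cols = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# "):
            body = line[2:]
            if "\t" in body:
                key, _, value = body.partition("\t")
                header[key] = value
            else:
                header["software"] = body
        elif cols is None:
            cols = line.split("\t")
        elif line:
            rows.append(line.split("\t"))
    table = pd.DataFrame(rows, columns=cols)
    for col in ("p_value", "min_p", "corrected_p"):
        if col in table:
            table[col] = table[col].astype(float)
    for col in ("n_links", "f1", "f2", "d"):
        if col in table:
            table[col] = table[col].astype(int)
    return header, table


def write_reports(reports, path) -> None:
    """Write experiment reports as tidy TSV, one row per setting."""
    rows = [r.to_row() for r in reports]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
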