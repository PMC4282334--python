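"""Reading and writing the pipeline's text formats.

Adjacency lists are one line per ego, ``ego_id<TAB>alter_id,alter_id,...``
(empty alter field allowed); edge lists are CSV with columns ``from,to``.
Weight matrices travel as sparse triplet CSV (``row_id,col_id,value``) with
a comment header naming the classification and scheme, or as Matrix Market.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .network import DirectedNetwork, parse_adjacency_list, parse_edge_list
from .weights import WeightMatrix

__all__ = [
    "read_adjacency_list",
    "write_adjacency_list",
    "read_edge_list_csv",
    "write_weight_matrix_csv",
    "read_weight_matrix_csv",
    "write_weight_matrix_mtx",
    "read_weight_matrix_mtx",
]


def read_adjacency_list(path, node_ids=None, on_unknown="drop") -> DirectedNetwork:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        ego, _, alters = line.partition("\t")
        alter_ids = [a for a in alters.strip().split(",") if a]
        records.append((ego.strip(), alter_ids))
    return parse_adjacency_list(records, node_ids=node_ids, on_unknown=on_unknown)


def write_adjacency_list(net: DirectedNetwork, path) -> None:
    lines = []
    for i, ego in enumerate(net.node_ids):
        alters = ",".join(str(net.node_ids[j]) for j in np.flatnonzero(net.D[i]))
        lines.append(f"{ego}\t{alters}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list_csv(path, node_ids=None, on_unknown="drop") -> DirectedNetwork:
    df = pd.read_csv(path, dtype=str)
    if not {"from", "to"} <= set(df.columns):
        raise ValueError("edge list CSV needs columns 'from' and 'to'")
    return parse_edge_list(
        list(zip(df["from"], df["to"])), node_ids=node_ids, on_unknown=on_unknown
    )


def write_weight_matrix_csv(wm: WeightMatrix, path) -> None:
    """Sparse triplet CSV; roster comment lines preserve all-zero rows
    (network isolates) and empty columns."""
    coo = wm.W.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# classification={wm.classification_name} scheme={wm.scheme} "
                 f"kind={wm.kind}\n")
        fh.write("# rows=" + "|".join(map(str, wm.node_ids)) + "\n")
        fh.write("# cols=" + "|".join(map(str, wm.group_labels)) + "\n")
        fh.write("row_id,col_id,value\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{wm.node_ids[i]},{wm.group_labels[j]},{float(v)!r}\n")


def read_weight_matrix_csv(path) -> WeightMatrix:
    meta, rows, cols = {}, None, None
    body = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# rows="):
            rows = line[len("# rows="):].split("|")
        elif line.startswith("# cols="):
            cols = line[len("# cols="):].split("|")
        elif line.startswith("#"):
            meta = dict(kv.split("=", 1) for kv in line[1:].split())
        else:
            body.append(line)
    import io as _io

    df = pd.read_csv(_io.StringIO("\n".join(body)),
                     dtype={"row_id": str, "col_id": str})
    if rows is None:
        rows = list(dict.fromkeys(df["row_id"]))
    if cols is None:
        cols = list(dict.fromkeys(df["col_id"]))
    ri = {v: i for i, v in enumerate(rows)}
    ci = {v: i for i, v in enumerate(cols)}
    W = sp.csr_matrix(
        (df["value"].to_numpy(float),
         (df["row_id"].map(ri), df["col_id"].map(ci))),
        shape=(len(rows), len(cols)),
    )
    return WeightMatrix(
        W=W,
        scheme=meta.get("scheme", "equal"),
        kind=meta.get("kind", "multiple-membership"),
        classification_name=meta.get("classification", "unknown"),
        node_ids=tuple(rows),
        group_labels=tuple(cols),
    )


def write_weight_matrix_mtx(wm: WeightMatrix, path) -> None:
    mmwrite(str(path), wm.W)


def read_weight_matrix_mtx(path) -> sp.csr_matrix:
    return sp.csr_matrix(mmread(str(path)))
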