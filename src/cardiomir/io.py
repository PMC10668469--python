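"""Readers and writers for every table the pipeline touches.

The canonical on-disk dialect is TSV, UTF-8, "NA" for missing values.  Gene
sets use the standard GMT layout (one set per line: name, description,
members...).  Networks can be exchanged as node/edge TSV pairs or a single
GraphML document.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneSetCollection, SampleTable, TargetMap

logger = logging.getLogger(__name__)

NA = "NA"
_ANNOTATION_COLUMNS = ("subtype", "uniquely_mapped")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, subtype_column: str | None = "subtype") -> CountMatrix:
    """Read a TSV count matrix (features x samples).

    The first column holds feature ids; annotation columns named ``subtype``
    and ``uniquely_mapped`` are split off when present, every other column is
    a sample.  Counts must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=[NA])
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate feature identifier: {dup[0]!r}")
    ann_cols = [c for c in df.columns
                if c in _ANNOTATION_COLUMNS or c == subtype_column]
    ann = pd.DataFrame(index=df.index)
    if subtype_column in df.columns:
        ann["subtype"] = df[subtype_column]
    if "uniquely_mapped" in df.columns:
        ann["uniquely_mapped"] = df["uniquely_mapped"].map(
            {"True": True, "False": False, "true": True, "false": False,
             "1": True, "0": False})
    data = df.drop(columns=ann_cols)
    counts = pd.DataFrame(index=df.index, columns=data.columns, dtype=np.int64)
    for j, col in enumerate(data.columns):
        for i, raw in enumerate(data[col]):
            try:
                val = int(raw)
                if val < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: invalid count at (row {df.index[i]!r}, "
                    f"column {col!r}): {raw!r}") from None
            counts.iat[i, j] = val
    return CountMatrix(counts, ann if len(ann.columns) else None)


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       with_annotations: bool = True) -> None:
    out = cm.counts.copy()
    if with_annotations:
        out.insert(0, "uniquely_mapped", cm.annotations["uniquely_mapped"])
        out.insert(0, "subtype", cm.annotations["subtype"])
    out.to_csv(path, sep="\t", index_label="feature_id", na_rep=NA)


def filter_unique_features(cm: CountMatrix) -> CountMatrix:
    """Keep only uniquely mapped features (multi-mapped genes are removed)."""
    keep = cm.annotations["uniquely_mapped"].to_numpy(bool)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_unique_features: removed %d multi-mapped of %d features",
                    n_removed, cm.n_features)
    if keep.sum() == 0:
        logger.warning("filter_unique_features: no uniquely mapped features remain")
    return CountMatrix(cm.counts.loc[keep], cm.annotations.loc[keep])


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     keep_default_na=False, na_values=[NA])
    return SampleTable(df)


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.table.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>member...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least "
                                 f"2 tab-separated fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set id {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning("read_gmt: set %r has duplicate members (collapsed)", name)
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gsc:
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# target maps
# ---------------------------------------------------------------------------

def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column TSV of (mirna_id, mrna_id); an optional header row
    named ``mirna_id``/``mirna`` is skipped; duplicate rows are collapsed."""
    edges: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() in ("mirna_id", "mirna", "source"):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise ValueError(f"{path}: line {lineno}: expected two "
                                 f"non-empty tab-separated fields, got {row!r}")
            edge = (row[0].strip(), row[1].strip())
            if edge in edges:
                n_dup += 1
            edges.add(edge)
    if n_dup:
        logger.info("read_target_map: collapsed %d duplicate rows", n_dup)
    if not edges:
        logger.warning("read_target_map: %s contains no edges", path)
    return TargetMap(edges)


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tmrna_id\n")
        for m, g in sorted(tm.edges):
            fh.write(f"{m}\t{g}\n")


# ---------------------------------------------------------------------------
# protein abundance tables
# ---------------------------------------------------------------------------

def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Protein x sample log2 abundances; NA marks a protein not detected
    in that sample."""
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=[NA])
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate protein identifier: {dup[0]!r}")
    return df.astype(float)


def write_protein_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="protein_id", na_rep=NA,
              float_format="%.10g")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(nodes: pd.DataFrame, edges: pd.DataFrame, path: str | Path,
                  format: str = "tsv") -> list[Path]:
    """Write a network as node/edge TSV tables or one GraphML document.

    ``nodes`` must have an ``id`` column plus attribute columns (``layer``,
    ``direction``, statistics); ``edges`` must have ``source``/``target``
    columns plus attributes (``r``, ``p``).  Every edge endpoint must appear
    in the node table.
    """
    path = Path(path)
    node_ids = set(nodes["id"].astype(str))
    for col in ("source", "target"):
        if len(edges):
            unknown = set(edges[col].astype(str)) - node_ids
            if unknown:
                raise ValueError(f"edge references unknown node "
                                 f"{sorted(unknown)[0]!r}")
    if format == "tsv":
        node_path = path.with_suffix(".nodes.tsv")
        edge_path = path.with_suffix(".edges.tsv")
        nodes.to_csv(node_path, sep="\t", index=False, na_rep=NA,
                     float_format="%.10g")
        edges.to_csv(edge_path, sep="\t", index=False, na_rep=NA,
                     float_format="%.10g")
        return [node_path, edge_path]
    if format == "graphml":
        g = nx.DiGraph()
        for rec in nodes.to_dict("records"):
            nid = str(rec.pop("id"))
            g.add_node(nid, **{k: v for k, v in rec.items() if pd.notna(v)})
        for rec in edges.to_dict("records"):
            src, tgt = str(rec.pop("source")), str(rec.pop("target"))
            g.add_edge(src, tgt, **{k: v for k, v in rec.items() if pd.notna(v)})
        out = path if path.suffix == ".graphml" else path.with_suffix(".graphml")
        nx.write_graphml(g, out)
        return [out]
    raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_network` in graphml mode."""
    g = nx.read_graphml(path)
    nodes = pd.DataFrame([{"id": n, **d} for n, d in g.nodes(data=True)])
    edges = pd.DataFrame([{"source": u, "target": v, **d}
                          for u, v, d in g.edges(data=True)])
    return nodes, edges
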