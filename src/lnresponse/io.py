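"""Readers and writers for the plain-text formats the pipeline exchanges.

Bulk expression travels as a gene-by-sample TSV (genes as rows, header row of
sample identifiers), gene sets as GMT, single-cell counts as a MatrixMarket
triplet (matrix.mtx + features.tsv + barcodes.tsv, genes x cells as in
CellRanger output) or as a dense CSV for tiny fixtures, and signaling
circuits as a node-table / edge-table CSV pair.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


# ---------------------------------------------------------------------------
# expression matrices

def write_expression_tsv(expr: pd.DataFrame, path: str) -> None:
    """Write a genes x samples expression matrix as TSV."""
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index.name = "gene"
    return expr


# ---------------------------------------------------------------------------
# GMT gene sets

def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            genes = list(genes)
            fh.write("\t".join([str(name), description, *map(str, genes)]) + "\n")


def read_gmt(path: str) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# single-cell matrices

def write_mtx(adata: ad.AnnData, outdir: str) -> None:
    """Write counts as matrix.mtx (genes x cells) + features/barcodes TSV."""
    os.makedirs(outdir, exist_ok=True)
    X = adata.X
    if not scipy.sparse.issparse(X):
        X = scipy.sparse.csr_matrix(X)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(os.path.join(outdir, "cell_metadata.csv"))


def read_mtx(indir: str) -> ad.AnnData:
    """Read a MatrixMarket triplet directory back into cells x genes AnnData."""
    X = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    features = pd.read_csv(os.path.join(indir, "features.tsv"),
                           sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"),
                           sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(X=X)
    adata.var_names = features.values
    adata.obs_names = barcodes.values
    meta_path = os.path.join(indir, "cell_metadata.csv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index = meta.index.astype(str)
        adata.obs = meta.loc[adata.obs_names]
    return adata


def read_dense_csv(path: str) -> ad.AnnData:
    """Dense cells x genes CSV (barcodes as index) for tiny fixtures."""
    df = pd.read_csv(path, index_col=0)
    adata = ad.AnnData(X=df.to_numpy())
    adata.obs_names = df.index.astype(str)
    adata.var_names = df.columns.astype(str)
    return adata


# ---------------------------------------------------------------------------
# circuits

def write_circuits(circuits, nodes_path: str, edges_path: str) -> None:
    """Serialize circuits as a node table and an edge table CSV."""
    node_rows, edge_rows = [], []
    for circ in circuits:
        for node, data in circ.graph.nodes(data=True):
            node_rows.append({
                "circuit": circ.name, "node_id": node,
                "gene_list": ";".join(data["genes"]), "role": data["role"]})
        for u, v, data in circ.graph.edges(data=True):
            edge_rows.append({"circuit": circ.name, "source": u,
                              "target": v, "sign": int(data["sign"])})
    pd.DataFrame(node_rows).to_csv(nodes_path, index=False)
    pd.DataFrame(edge_rows).to_csv(edges_path, index=False)


def read_circuits(nodes_path: str, edges_path: str):
    from .druggability import CircuitGraph

    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    circuits = []
    for name, node_df in nodes.groupby("circuit", sort=False):
        edge_df = edges[edges["circuit"] == name]
        node_spec = [(r.node_id, tuple(str(r.gene_list).split(";")))
                     for r in node_df.itertuples()]
        edge_spec = [(r.source, r.target, int(r.sign))
                     for r in edge_df.itertuples()]
        circuits.append(CircuitGraph.from_tables(name, node_spec, edge_spec))
    return circuits
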