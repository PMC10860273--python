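"""Readers and writers for the external formats the pipeline touches.

Edge-list TSV for interactomes and cell-type networks, MatrixMarket
triplets plus index files for expression, GMT for gene sets, GraphML for
interchange with graph tools. Readers reject malformed input rather than
coerce it; every dropped record (self-loop, duplicate, within-set
duplicate gene) is counted in the log.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import (
    CellTypeNetwork,
    Edge,
    ExpressionDataset,
    GeneSet,
    ReferenceInteractome,
    ValidationError,
    canonical_edge,
    network_from_edges,
)

logger = logging.getLogger("ctinet")

_HEADER_TOKENS = {"genea", "geneb", "gene_a", "gene_b", "source", "target", "weight"}


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_edge_list(
    path: str | Path, has_weight: bool = False, name: str | None = None
) -> ReferenceInteractome:
    """Read an undirected edge-list TSV into a ReferenceInteractome.

    A header row is auto-detected (non-numeric weight column when
    ``has_weight``, or recognizable column names otherwise). Duplicate
    edges are deduplicated regardless of endpoint order; self-loops are
    dropped and counted.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise ValidationError(f"{path}: empty edge list")

    start = 0
    first = lines[0].rstrip("\n").split("\t")
    if has_weight and len(first) >= 3 and not _is_number(first[2]):
        start = 1
    elif any(tok.strip().lower() in _HEADER_TOKENS for tok in first[:2]):
        start = 1

    nodes: set[str] = set()
    edges: set[Edge] = set()
    weights: dict[Edge, float] = {}
    n_self_loops = 0
    n_duplicates = 0
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValidationError(f"{path}:{lineno}: malformed edge row {raw!r}")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            n_self_loops += 1
            continue
        e = canonical_edge(a, b)
        nodes.update(e)
        if e in edges:
            n_duplicates += 1
        edges.add(e)
        if has_weight:
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: expected weight column")
            try:
                w = float(fields[2])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                ) from None
            if not (np.isfinite(w) and w >= 0):
                raise ValidationError(f"{path}:{lineno}: weight {w!r} not finite and >= 0")
            weights[e] = w
    if n_self_loops or n_duplicates:
        logger.info(
            "%s: dropped %d self-loops, collapsed %d duplicate edges",
            path,
            n_self_loops,
            n_duplicates,
        )
    ref = ReferenceInteractome(
        nodes=nodes,
        edges=edges,
        prior_weight=weights if has_weight else None,
        name=name or path.stem,
    )
    return ref.validate()


def write_edge_list(ref: ReferenceInteractome, path: str | Path) -> None:
    """Write a reference interactome as TSV (geneA, geneB[, weight])."""
    path = Path(path)
    weighted = ref.prior_weight is not None
    with path.open("w") as fh:
        fh.write("geneA\tgeneB\tweight\n" if weighted else "geneA\tgeneB\n")
        for a, b in sorted(ref.edges):
            if weighted:
                fh.write(f"{a}\t{b}\t{ref.prior_weight[(a, b)]:.12g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_expression(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    metadata_path: str | Path,
) -> ExpressionDataset:
    """Read a MatrixMarket triplet (cells x genes) with index and metadata files.

    ``genes_path`` / ``cells_path`` hold one identifier per line;
    ``metadata_path`` is a TSV with columns cell_id, cell_type, sample.
    Cells present in the matrix but absent from the metadata are an
    error, not a silent drop.
    """
    mat = scipy.io.mmread(str(mtx_path))
    counts = sp.csr_matrix(mat)
    if counts.nnz and counts.data.min() < 0:
        raise ValidationError(f"{mtx_path}: negative counts")
    gene_ids = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    cell_ids = [ln.strip() for ln in Path(cells_path).read_text().splitlines() if ln.strip()]
    if counts.shape != (len(cell_ids), len(gene_ids)):
        raise ValidationError(
            f"{mtx_path}: matrix is {counts.shape}, expected "
            f"({len(cell_ids)} cells, {len(gene_ids)} genes)"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"cell_id", "cell_type", "sample"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"{metadata_path}: missing columns {sorted(required - set(meta.columns))}"
        )
    meta = meta.set_index("cell_id")
    unknown = set(cell_ids) - set(meta.index)
    if unknown:
        raise ValidationError(
            f"{metadata_path}: no metadata for cells {sorted(unknown)[:5]}"
        )
    ds = ExpressionDataset(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_type=meta["cell_type"],
        sample=meta["sample"],
    )
    return ds.validate()


def write_expression(ds: ExpressionDataset, out_dir: str | Path, prefix: str = "expr") -> dict:
    """Write the MTX triplet + metadata TSV; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / f"{prefix}.mtx",
        "genes": out_dir / f"{prefix}.genes.txt",
        "cells": out_dir / f"{prefix}.cells.txt",
        "metadata": out_dir / f"{prefix}.metadata.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), ds.counts.tocoo(), field="integer")
    paths["genes"].write_text("\n".join(ds.gene_ids) + "\n")
    paths["cells"].write_text("\n".join(ds.cell_ids) + "\n")
    meta = pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "cell_type": ds.cell_type.loc[ds.cell_ids].values,
            "sample": ds.sample.loc[ds.cell_ids].values,
        }
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, tab-separated genes)."""
    path = Path(path)
    sets: list[GeneSet] = []
    n_dups = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
        genes = [g for g in fields[2:] if g.strip()]
        uniq = set(genes)
        n_dups += len(genes) - len(uniq)
        sets.append(GeneSet(name=fields[0], description=fields[1], genes=uniq).validate())
    if n_dups:
        logger.info("%s: removed %d duplicate genes within sets", path, n_dups)
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def write_network(net: CellTypeNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write a cell-type network as TSV (geneA, geneB, weight) or GraphML.

    TSV weights are printed with 12 significant digits so a read-back
    reproduces them to well below 1e-9.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("geneA\tgeneB\tweight\n")
            for a, b in sorted(net.edges):
                fh.write(f"{a}\t{b}\t{net.weight[(a, b)]:.12g}\n")
    elif format == "graphml":
        import networkx as nx

        nx.write_graphml(net.to_networkx(), str(path))
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path: str | Path, cell_type: str | None = None) -> CellTypeNetwork:
    """Read a network TSV written by :func:`write_network`."""
    ref = read_edge_list(path, has_weight=True, name=cell_type or Path(path).stem)
    return network_from_edges(
        ref.name, [(a, b, ref.prior_weight[(a, b)]) for a, b in ref.edges]
    )
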