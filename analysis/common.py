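"""Shared set-up for the numbered analysis drivers.

The study conditions: a 10,000-gene reference interactome (mean degree
6), three cell types of 500 cells each, one planted 20-gene connected
module per cell type up-regulated 4-fold (log2FC = 2). Every driver
rebuilds the pipeline deterministically from the same seed, so the
scripts can be run independently and in any order.
"""

from __future__ import annotations

import argparse
import logging
from dataclasses import dataclass
from pathlib import Path

import ctinet as ct

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

N_GENES = 10_000
MEAN_DEGREE = 6.0
CELL_TYPES = [("A", 500), ("B", 500), ("C", 500)]
MODULE_SIZE = 20
MODULE_LOG2FC = 2.0
DEFAULT_SEED = 7


def parse_args(description: str) -> argparse.Namespace:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=DEFAULT_SEED)
    p.add_argument("--quiet", action="store_true", help="suppress progress logging")
    args = p.parse_args()
    logging.basicConfig(
        level=logging.WARNING if args.quiet else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    RESULTS.mkdir(exist_ok=True)
    return args


@dataclass
class Pipeline:
    reference: ct.ReferenceInteractome
    expr: ct.ExpressionDataset
    truth: ct.SyntheticTruth
    profile: ct.SpecificityProfile
    networks: dict[str, ct.CellTypeNetwork]  # BH q <= 0.05 (deliverable networks)
    dense: dict[str, ct.CellTypeNetwork]  # all positive-specificity edges
    module_sets: dict[str, ct.GeneSet]


def build_pipeline(seed: int) -> Pipeline:
    """Simulate and reconstruct under the standard study conditions."""
    ref = ct.generate_reference_network(N_GENES, MEAN_DEGREE, seed=seed)
    expr, truth = ct.generate_expression(
        ref,
        CELL_TYPES,
        module_size=MODULE_SIZE,
        module_log2fc=MODULE_LOG2FC,
        seed=seed + 1,
    )
    networks, profile = ct.reconstruct_all(ref, expr)
    dense_cfg = ct.RunConfig(alpha_edge_q=1.0)
    dense = {
        c: ct.reconstruct_cell_type_network(ref, profile, c, dense_cfg)
        for c in networks
    }
    sets = ct.generate_gene_sets(truth, ref, n_random=0, seed=seed + 2)
    module_sets = {s.name.removeprefix("module_"): s for s in sets}
    return Pipeline(
        reference=ref,
        expr=expr,
        truth=truth,
        profile=profile,
        networks=networks,
        dense=dense,
        module_sets=module_sets,
    )
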