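"""Simulate the study data: reference interactome, labeled UMI counts
with planted cell-type modules, and gene sets.

Writes the full dataset in its on-disk exchange formats under scratch/
(regenerable from the seed, so not part of the versioned results) and a
small summary table under results/.
"""

import json

import numpy as np
import pandas as pd

import ctinet as ct
from common import MODULE_LOG2FC, RESULTS, SCRATCH, build_pipeline, parse_args


def main() -> None:
    args = parse_args(__doc__)
    pipe = build_pipeline(args.seed)

    data_dir = SCRATCH / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    ct.write_edge_list(pipe.reference, data_dir / "reference.tsv")
    ct.write_expression(pipe.expr, data_dir, prefix="expr")
    sets = ct.generate_gene_sets(pipe.truth, pipe.reference, n_random=10, seed=args.seed + 2)
    ct.write_gmt(sets, data_dir / "gene_sets.gmt")
    (data_dir / "truth.json").write_text(
        json.dumps(
            {
                "seed": args.seed,
                "module_log2fc": MODULE_LOG2FC,
                "planted_modules": {
                    k: sorted(v) for k, v in pipe.truth.planted_modules.items()
                },
            },
            indent=2,
        )
    )

    counts = pipe.expr.counts
    libsize = np.asarray(counts.sum(axis=1)).ravel()
    labels = pipe.expr.cell_type.loc[pipe.expr.cell_ids].to_numpy()
    rows = []
    for label, module in sorted(pipe.truth.planted_modules.items()):
        mask = labels == label
        rows.append(
            {
                "cell_type": label,
                "n_cells": int(mask.sum()),
                "module_size": len(module),
                "module_internal_edges": len(pipe.truth.module_subgraph_edges[label]),
                "median_umis_per_cell": float(np.median(libsize[mask])),
            }
        )
    summary = pd.DataFrame(rows)
    out = RESULTS / "01_simulation_summary.tsv"
    summary.to_csv(out, sep="\t", index=False)

    print(
        f"Simulated {pipe.reference.n_nodes} genes / {pipe.reference.n_edges} "
        f"reference edges; {counts.shape[0]} cells in {len(rows)} cell types."
    )
    print(summary.to_string(index=False))
    print(f"Data written to {data_dir}, summary to {out}")


if __name__ == "__main__":
    main()
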