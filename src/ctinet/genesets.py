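"""Gene-set statistics on cell-type networks.

Covers the gene-set-facing analyses: local-network extraction around a
query gene, hypergeometric enrichment with Benjamini-Hochberg
correction, within-group connectivity with a uniform-subsampling
permutation null, scaled connectivity across cell types (the
deconvolution of a gene signature into cell types), and hub/neighbor
rankings by weighted degree.

Within-group connectivity is normalized per gene by default,
C(S) = (sum of weights of edges internal to S in the network) / |S in V|,
so sets with different network coverage stay comparable; ``norm`` also
accepts "sum" and "per_pair". Null gene sets are subsampled uniformly
from the network's nodes (not degree-matched) — the documented
procedure — with a degree-aware alternative left to the caller via the
returned null machinery.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import CellTypeNetwork, GeneSet, ValidationError, network_from_edges

logger = logging.getLogger("ctinet")


@dataclass
class ConnectivityResult:
    set_name: str
    cell_type: str
    n_in_network: int
    observed: float
    null_mean: float
    null_sd: float
    empirical_p: float
    z: float | None
    n_permutations: int


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size_in_universe: int
    query_size: int
    universe_size: int
    p: float
    q: float


def local_network(network: CellTypeNetwork, gene: str, radius: int = 1) -> CellTypeNetwork:
    """Induced subgraph on genes within ``radius`` hops of the query gene."""
    if gene not in network.nodes:
        close = difflib.get_close_matches(gene, sorted(network.nodes), n=3)
        raise ValidationError(
            f"gene {gene!r} not in network; nearest symbols: {close or 'none'}"
        )
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    reach = {gene}
    frontier = {gene}
    adjacency: dict[str, set[str]] = {}
    for a, b in network.edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    for _ in range(radius):
        frontier = set().union(*(adjacency.get(g, set()) for g in frontier)) - reach
        if not frontier:
            break
        reach |= frontier
    internal = [
        (a, b, network.weight[(a, b)])
        for a, b in network.edges
        if a in reach and b in reach
    ]
    return network_from_edges(
        f"{network.cell_type}:local({gene},r={radius})",
        internal,
        parent=network.parent,
        extra_nodes=reach,
    )


def hypergeometric_enrichment(
    query: GeneSet, sets: list[GeneSet], universe: set[str]
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of the query in each set.

    Query genes outside the universe are dropped with a warning; each
    tested set is intersected with the universe. q-values are BH across
    the tested sets; rows come back sorted by p.
    """
    if not universe:
        raise ValidationError("empty universe")
    q_genes = query.genes & universe
    dropped = len(query.genes) - len(q_genes)
    if dropped:
        logger.warning("enrichment query: %d genes outside the universe dropped", dropped)
    n = len(q_genes)
    big_n = len(universe)
    rows = []
    pvals = []
    for s in sets:
        members = s.genes & universe
        k = len(q_genes & members)
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if n else 1.0
        p = min(max(p, 0.0), 1.0)
        rows.append(
            EnrichmentRow(
                set_name=s.name,
                overlap=k,
                set_size_in_universe=big_k,
                query_size=n,
                universe_size=big_n,
                p=p,
                q=np.nan,
            )
        )
        pvals.append(p)
    if rows:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for row, qv in zip(rows, qvals):
            row.q = float(qv)
    return sorted(rows, key=lambda r: (r.p, r.set_name))


def _internal_weight(network: CellTypeNetwork, members: set[str]) -> float:
    return sum(w for (a, b), w in network.weight.items() if a in members and b in members)


def _normalize(total: float, n_members: int, norm: str) -> float:
    if norm == "per_gene":
        return total / n_members
    if norm == "sum":
        return total
    if norm == "per_pair":
        return total / (n_members * (n_members - 1) / 2)
    raise ValidationError(f"unknown connectivity norm {norm!r}")


def within_group_connectivity(
    network: CellTypeNetwork, gene_set: GeneSet, norm: str = "per_gene"
) -> float | None:
    """C(S): aggregate weight of edges internal to S within the network.

    Genes in S absent from the network are excluded entirely. Returns
    None (undefined) when fewer than 2 members are in the network.
    """
    members = gene_set.genes & network.nodes
    if len(members) < 2:
        return None
    return _normalize(_internal_weight(network, members), len(members), norm)


def connectivity_permutation_test(
    network: CellTypeNetwork,
    gene_set: GeneSet,
    n_permutations: int = 1000,
    seed: int = 0,
    norm: str = "per_gene",
) -> ConnectivityResult:
    """Permutation test of C(S) against uniformly subsampled null sets.

    Null sets are drawn uniformly without replacement from the
    network's nodes, matching |S in V|. The empirical p-value carries
    the +1 correction, so it is never 0.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    members = gene_set.genes & network.nodes
    if len(members) < 2:
        raise ValidationError(
            f"gene set {gene_set.name!r} has {len(members)} genes in the network; need >= 2"
        )
    rng = np.random.default_rng(seed)
    logger.info(
        "connectivity permutation test: set=%s perms=%d seed=%d",
        gene_set.name, n_permutations, seed,
    )
    node_list, u, v, w = network.edge_arrays()
    idx = {g: i for i, g in enumerate(node_list)}
    size = len(members)
    obs_vec = np.zeros(len(node_list), dtype=bool)
    obs_vec[[idx[g] for g in members]] = True
    observed = _normalize(float(w[obs_vec[u] & obs_vec[v]].sum()), size, norm)

    # all permutations at once: boolean membership matrix x edge incidence
    picks = np.argsort(rng.random((n_permutations, len(node_list))), axis=1)[:, :size]
    member_mat = np.zeros((n_permutations, len(node_list)), dtype=bool)
    np.put_along_axis(member_mat, picks, True, axis=1)
    internal = (member_mat[:, u] & member_mat[:, v]) @ w
    null = np.array([_normalize(t, size, norm) for t in internal])

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    emp_p = float((1 + np.sum(null >= observed)) / (1 + n_permutations))
    z = (observed - null_mean) / null_sd if null_sd > 0 else None
    return ConnectivityResult(
        set_name=gene_set.name,
        cell_type=network.cell_type,
        n_in_network=size,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        empirical_p=emp_p,
        z=z,
        n_permutations=n_permutations,
    )


def scaled_connectivity(
    networks: dict[str, CellTypeNetwork],
    gene_set: GeneSet,
    n_permutations: int = 1000,
    seed: int = 0,
    norm: str = "per_gene",
) -> dict[str, float]:
    """Connectivity z per cell type, centered/scaled across cell types.

    The returned vector has mean 0 and s.d. 1 across the cell types for
    which connectivity is defined; the most set-cohesive cell type
    attains the maximum.
    """
    zs = {}
    for i, (ct, net) in enumerate(sorted(networks.items())):
        members = gene_set.genes & net.nodes
        if len(members) < 2:
            logger.info("scaled_connectivity: %s undefined for %s", gene_set.name, ct)
            continue
        res = connectivity_permutation_test(
            net, gene_set, n_permutations=n_permutations, seed=seed + i, norm=norm
        )
        zs[ct] = res.z if res.z is not None else 0.0
    if len(zs) < 2:
        raise ValidationError("scaled connectivity needs >= 2 cell types with defined values")
    vals = np.array(list(zs.values()), dtype=float)
    sd = vals.std()
    scaled = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    return dict(zip(zs.keys(), scaled))


def hub_rankings(
    network: CellTypeNetwork, gene_set: GeneSet, top_n: int | None = None
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Rank set members by strength and neighbors by connection to the set.

    Members are ordered by within-network weighted degree; non-member
    neighbors by the total weight of their edges to set members. Ties
    break by gene symbol.
    """
    members = gene_set.genes & network.nodes
    if not members:
        raise ValidationError(f"gene set {gene_set.name!r} does not intersect the network")
    strengths = network.strengths()
    member_rank = sorted(
        ((g, strengths[g]) for g in members), key=lambda kv: (-kv[1], kv[0])
    )
    to_set: dict[str, float] = {}
    for (a, b), w in network.weight.items():
        if a in members and b not in members:
            to_set[b] = to_set.get(b, 0.0) + w
        elif b in members and a not in members:
            to_set[a] = to_set.get(a, 0.0) + w
    neighbor_rank = sorted(to_set.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        member_rank = member_rank[:top_n]
        neighbor_rank = neighbor_rank[:top_n]
    return member_rank, neighbor_rank
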