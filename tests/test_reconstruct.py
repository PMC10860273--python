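"""Transcriptional specificity, rank-inverse-normal map, and network
reconstruction contracts."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import norm

import ctinet as ct
from ctinet.core import ValidationError
from ctinet.reconstruct import welch_specificity


def make_dataset(counts: np.ndarray, labels: list[str]) -> ct.ExpressionDataset:
    n_cells, n_genes = counts.shape
    cells = [f"c{i}" for i in range(n_cells)]
    genes = [f"g{j}" for j in range(n_genes)]
    return ct.ExpressionDataset(
        counts=sp.csr_matrix(counts.astype(np.int64)),
        gene_ids=genes,
        cell_ids=cells,
        cell_type=pd.Series(labels, index=cells),
        sample=pd.Series(["s"] * n_cells, index=cells),
    ).validate()


class TestWelchSpecificity:
    def test_constant_gene_is_zero_everywhere(self):
        # constant library sizes keep normalized values constant too, so
        # the numerator x_ct - x_else vanishes exactly
        counts = np.ones((8, 3), dtype=int)
        counts[:, 1] = 2  # different level, still constant
        ds = make_dataset(counts, ["A"] * 4 + ["B"] * 4)
        prof = ct.compute_transcriptional_specificity(ds)
        assert prof.tranS.loc["g0"].tolist() == [0.0, 0.0]
        assert prof.tranS.loc["g1"].tolist() == [0.0, 0.0]
        assert prof.tranS.loc["g2"].tolist() == [0.0, 0.0]

    def test_welch_formula_hand_case(self):
        """means 2 vs 1, variances 1 and 1, n=100 each => 1/sqrt(0.02)."""
        rng = np.random.default_rng(0)
        a = rng.normal(2.0, 1.0, 100)
        b = rng.normal(1.0, 1.0, 100)
        # standardize the samples so the moments are exact
        a = 2.0 + (a - a.mean()) / a.std(ddof=1)
        b = 1.0 + (b - b.mean()) / b.std(ddof=1)
        x = np.concatenate([a, b])[:, None]
        tranS, n_cells, _ = welch_specificity(x, np.array(["A"] * 100 + ["B"] * 100))
        assert tranS["A"].iloc[0] == pytest.approx(1.0 / np.sqrt(0.02))
        assert tranS["B"].iloc[0] == pytest.approx(-1.0 / np.sqrt(0.02))
        assert n_cells == {"A": 100, "B": 100}

    def test_zero_variance_guard(self):
        # both groups constant, different means -> capped finite value
        x = np.array([[5.0]] * 3 + [[1.0]] * 3)
        tranS, _, _ = welch_specificity(x, np.array(["A"] * 3 + ["B"] * 3))
        assert tranS["A"].iloc[0] == 50.0
        assert tranS["B"].iloc[0] == -50.0

    def test_single_cell_type_rejected(self):
        ds = make_dataset(np.ones((4, 2), dtype=int), ["A"] * 4)
        with pytest.raises(ValidationError):
            ct.compute_transcriptional_specificity(ds)


class TestRankInverseNormal:
    def test_single_score_maps_to_zero(self):
        assert ct.rank_inverse_normal(np.array([3.7])) == pytest.approx(0.0)

    def test_four_distinct_scores_quantile_oracle(self):
        z = ct.rank_inverse_normal(np.array([0.1, 0.5, 0.7, 0.9]))
        np.testing.assert_allclose(z, norm.ppf([0.125, 0.375, 0.625, 0.875]))

    def test_monotone(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.normal(size=50))
        z = ct.rank_inverse_normal(x)
        assert np.all(np.diff(z) > 0)

    def test_all_ties_map_to_zero(self):
        z = ct.rank_inverse_normal(np.full(10, 2.0))
        np.testing.assert_allclose(z, 0.0, atol=1e-12)


class TestReconstruction:
    def test_degenerate_all_equal_specificity_gives_empty_network(self):
        # constant genes => all tranS 0 => average-rank ties => z = 0 =>
        # no positive edges retained
        ref = ct.generate_reference_network(12, 2, seed=0)
        genes = sorted(ref.nodes)
        counts = np.ones((12, len(genes)), dtype=int)
        ds = make_dataset(counts, ["A"] * 6 + ["B"] * 6)
        ds.gene_ids[:] = genes
        ds.counts = sp.csr_matrix(counts.astype(np.int64))
        prof = ct.compute_transcriptional_specificity(ds)
        net = ct.reconstruct_cell_type_network(
            ref, prof, "A", ct.RunConfig(min_cells=5)
        )
        assert net.n_edges == 0

    def test_min_cells_enforced(self, pipeline):
        with pytest.raises(ValidationError, match="minimum"):
            ct.reconstruct_cell_type_network(
                pipeline.reference, pipeline.profile, "A", ct.RunConfig(min_cells=10_000)
            )

    def test_edges_subset_of_reference(self, pipeline):
        for net in pipeline.networks.values():
            assert net.edges <= pipeline.reference.edges

    def test_genes_absent_from_reference_never_appear(self, pipeline):
        for net in pipeline.networks.values():
            assert net.nodes <= pipeline.reference.nodes

    def test_determinism(self, pipeline):
        again = ct.reconstruct_cell_type_network(
            pipeline.reference, pipeline.profile, "A"
        )
        net = pipeline.networks["A"]
        assert again.edges == net.edges
        for e in net.edges:
            assert again.weight[e] == net.weight[e]

    def test_monotonicity_in_endpoint_specificity(self):
        """Raising one gene's tranS never lowers its incident edge weights."""
        rng = np.random.default_rng(2)
        ref = ct.generate_reference_network(40, 3, seed=2)
        genes = sorted(ref.nodes)
        base_scores = {"A": pd.Series(rng.normal(size=len(genes)), index=genes)}
        gene = genes[5]
        bumped = {k: v.copy() for k, v in base_scores.items()}
        bumped["A"].loc[gene] = bumped["A"].max() + 1.0

        def net_for(scores):
            tranS = pd.DataFrame(scores)
            z = pd.DataFrame(
                {c: ct.rank_inverse_normal(tranS[c].to_numpy()) for c in tranS},
                index=tranS.index,
            )
            prof = ct.SpecificityProfile(
                tranS=tranS, z=z, n_cells={"A": 200},
                group_mean=tranS, other_mean=tranS, group_var=tranS, other_var=tranS,
            )
            return ct.reconstruct_cell_type_network(
                ref, prof, "A", ct.RunConfig(alpha_edge_q=1.0)
            )

        before = net_for(base_scores)
        after = net_for(bumped)
        incident_before = {e: w for e, w in before.weight.items() if gene in e}
        for e, w_after in after.weight.items():
            if gene in e and e in incident_before:
                assert w_after >= incident_before[e] - 1e-12

    def test_planted_module_ranks_top(self, pipeline):
        """Planted genes land in the top 2*module_size tranS ranks."""
        for label, module in pipeline.truth.planted_modules.items():
            t = pipeline.profile.tranS[label]
            top = set(t.nlargest(2 * len(module)).index)
            assert module <= top

    def test_planted_edge_recall_and_weight_separation(self, pipeline):
        """Recall of module-internal edges >= 0.8; planted edges carry more
        weight than the network background."""
        for label, net in pipeline.networks.items():
            internal = pipeline.truth.module_subgraph_edges[label]
            recall = len(internal & net.edges) / len(internal)
            assert recall >= 0.8
        for label, dense in pipeline.dense.items():
            internal = pipeline.truth.module_subgraph_edges[label]
            planted_w = [w for e, w in dense.weight.items() if e in internal]
            other_w = [w for e, w in dense.weight.items() if e not in internal]
            assert np.mean(planted_w) > np.mean(other_w)
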