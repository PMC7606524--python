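"""Pearson screen, p-values and the same-sign hub rule."""

import numpy as np
import pytest
from scipy import stats

import ncembryo as nc

from conftest import make_matrix


class TestPearsonR:
    def test_perfect_anticorrelation(self):
        assert nc.pearson_r([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_self_correlation(self):
        x = np.array([0.3, 1.7, 2.2, 5.0])
        assert nc.pearson_r(x, x) == pytest.approx(1.0)

    def test_hand_arithmetic_case(self):
        # x=(1,2,3), y=(1,2,10): cov*n = 9, |xc| = sqrt(2), |yc| = sqrt(438/9)
        expected = 9.0 / (np.sqrt(2.0) * np.sqrt(438.0 / 9.0))
        assert nc.pearson_r([1, 2, 3], [1, 2, 10]) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_missing(self):
        assert np.isnan(nc.pearson_r([1, 1, 1], [1, 2, 3]))

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x, y = rng.random(25), rng.random(25)
            assert nc.pearson_r(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-12
            )


class TestPearsonP:
    def test_zero_correlation_gives_one(self):
        assert nc.pearson_p(0.0, 10) == pytest.approx(1.0)

    def test_perfect_correlation_gives_zero(self):
        assert nc.pearson_p(1.0, 10) == 0.0
        assert nc.pearson_p(-1.0, 10) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            nc.pearson_p(0.5, 2)

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(1)
        for n in (5, 12, 40):
            x, y = rng.random(n), rng.random(n)
            r = nc.pearson_r(x, y)
            assert nc.pearson_p(r, n) == pytest.approx(
                stats.pearsonr(x, y).pvalue, rel=1e-9
            )

    def test_matches_permutation_null(self):
        """The t-transform p agrees with an empirical permutation null
        (50k draws) within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(7)
        n, draws = 20, 50_000
        x = rng.normal(size=n)
        y = 0.6 * x + 0.8 * rng.normal(size=n)
        r_obs = nc.pearson_r(x, y)
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        perms = rng.permuted(np.tile(y, (draws, 1)), axis=1)
        pc = perms - perms.mean(axis=1, keepdims=True)
        r_null = pc @ xs / np.linalg.norm(pc, axis=1)
        p_emp = float((np.abs(r_null) >= abs(r_obs)).mean())
        se = np.sqrt(max(p_emp, 1 / draws) * (1 - p_emp) / draws)
        assert abs(nc.pearson_p(r_obs, n) - p_emp) <= 3 * se + 1e-12


def _screen_matrix(data, n_ncrna):
    data = np.asarray(data, float)
    ids = [f"n{i}" if i < n_ncrna else f"g{i}" for i in range(data.shape[0])]
    genes = [
        nc.GeneRecord(gid, "lincRNA" if gid.startswith("n") else "coding", 500)
        for gid in ids
    ]
    matrix = nc.ExpressionMatrix(
        np.abs(data), ids, [f"c{j}" for j in range(data.shape[1])], "log2tpm"
    )
    return matrix, genes


class TestScreenPairs:
    def test_perfectly_correlated_partners(self):
        rng = np.random.default_rng(2)
        x = rng.random(30)
        data = np.vstack([x] + [x * s for s in (1.5, 2.0, 0.5, 3.0, 1.0)])
        matrix, genes = _screen_matrix(data, 1)
        edges = nc.screen_pairs(matrix, genes)
        assert len(edges) == 5
        assert all(e.sign == "pos" and e.r == pytest.approx(1.0) and e.p == 0.0
                   for e in edges)

    def test_r_at_gate_excluded_just_above_included(self):
        """|r| must be strictly greater than r_min."""
        rng = np.random.default_rng(3)
        n = 2000  # large n so p is far below the gate near r = 0.6
        xc = rng.normal(size=n)
        xc -= xc.mean()
        zc = rng.normal(size=n)
        zc -= zc.mean()
        zc -= zc @ xc / (xc @ xc) * xc  # orthogonalize the centered vectors
        xs = xc / np.linalg.norm(xc)
        zs = zc / np.linalg.norm(zc)
        below = 0.5999999 * xs + np.sqrt(1 - 0.5999999**2) * zs
        above = 0.6000001 * xs + np.sqrt(1 - 0.6000001**2) * zs
        data = np.vstack([xs, below, above])
        matrix, genes = _screen_matrix(data - data.min() + 0.1, 1)
        edges = nc.screen_pairs(matrix, genes)
        hit = {e.coding_id for e in edges}
        assert "g2" in hit and "g1" not in hit

    def test_constant_genes_skipped(self):
        rng = np.random.default_rng(4)
        data = np.vstack([rng.random(20), np.ones(20), rng.random(20)])
        matrix, genes = _screen_matrix(data, 2)
        edges = nc.screen_pairs(matrix, genes)  # must not raise
        assert all(e.ncrna_id != "n1" for e in edges)

    def test_wrong_kind_rejected(self):
        m = make_matrix([[1, 2, 3]], ["g0"], ["a", "b", "c"], kind="counts")
        with pytest.raises(ValueError):
            nc.screen_pairs(m, [nc.GeneRecord("g0", "coding", 100)])

    def test_equals_bruteforce_double_loop(self):
        """Vectorized screen equals a per-pair scipy recomputation."""
        cfg = nc.SimulationConfig(
            n_cells=100, seed=13, n_coding=60,
            n_ncrna_per_class={"lincRNA": 10, "snoRNA": 10},
            cell_types=[nc.CellTypeSpec("a", 0.5, 5), nc.CellTypeSpec("b", 0.5, 5)],
            ncrna_only_type=None, n_hubs_pos=2, n_hubs_neg=1, partners_per_hub=4,
            n_time_variable_genes=10, n_trend_genes=2, n_trend_ncrna=1,
        )
        _, tpm, genes, _, _ = nc.simulate(cfg)
        lg = nc.log2_tpm(tpm)
        edges = {(e.ncrna_id, e.coding_id, e.sign) for e in nc.screen_pairs(lg, genes)}
        index = {g.gene_id: g for g in genes}
        expected = set()
        for i, gi in enumerate(lg.gene_ids):
            if index[gi].biotype == "coding":
                continue
            for j, gj in enumerate(lg.gene_ids):
                if index[gj].biotype != "coding":
                    continue
                x, y = lg.values[i], lg.values[j]
                if x.std() == 0 or y.std() == 0:
                    continue
                r, p = stats.pearsonr(x, y)
                if abs(r) > 0.6 and p < 1e-5:
                    expected.add((gi, gj, "pos" if r > 0 else "neg"))
        assert edges == expected

    def test_threshold_monotonicity(self, small_sim):
        lg, genes = small_sim["log2tpm"], small_sim["genes"]
        base = {(e.ncrna_id, e.coding_id) for e in nc.screen_pairs(lg, genes)}
        stricter_r = {(e.ncrna_id, e.coding_id)
                      for e in nc.screen_pairs(lg, genes, r_min=0.7)}
        stricter_p = {(e.ncrna_id, e.coding_id)
                      for e in nc.screen_pairs(lg, genes, p_max=1e-8)}
        assert stricter_r <= base and stricter_p <= base


class TestSelectHubs:
    def _edge(self, n, g, r, p=1e-9):
        return nc.CoexpressionEdge(n, g, r, p, "pos" if r > 0 else "neg")

    def test_signs_not_pooled(self):
        edges = [self._edge("n1", f"g{i}", 0.8) for i in range(3)]
        edges += [self._edge("n1", f"h{i}", -0.8) for i in range(3)]
        (hub,) = nc.select_hubs(edges)
        assert (hub.n_pos_partners, hub.n_neg_partners) == (3, 3)
        assert not hub.passes  # 3 + 3 does not satisfy "either >= 4"

    def test_four_same_sign_passes(self):
        edges = [self._edge("n1", f"g{i}", 0.7) for i in range(4)]
        (hub,) = nc.select_hubs(edges)
        assert hub.passes

    def test_boundary_partner_removal(self):
        edges = [self._edge("n1", f"g{i}", 0.7) for i in range(4)]
        assert nc.select_hubs(edges)[0].passes
        assert not nc.select_hubs(edges[:-1])[0].passes

    def test_partner_p_gate(self):
        edges = [self._edge("n1", f"g{i}", 0.7) for i in range(3)]
        edges.append(self._edge("n1", "g3", 0.7, p=5e-5))  # above partner gate
        (hub,) = nc.select_hubs(edges, partner_p_max=1e-5)
        assert not hub.passes

    def test_min_partner_monotonicity(self):
        edges = [self._edge("n1", f"g{i}", 0.7) for i in range(5)]
        assert nc.select_hubs(edges, min_partners=5)[0].passes
        assert not nc.select_hubs(edges, min_partners=6)[0].passes

    def test_null_data_yields_no_hubs(self):
        """Independent genes: the >=4 same-sign rule at the stated gates
        admits zero hubs across 10 seeds (1000 cells each)."""
        for seed in range(10):
            cfg = nc.SimulationConfig(
                n_cells=1000, seed=200 + seed, n_coding=400,
                n_ncrna_per_class={"lincRNA": 30, "pseudogene": 50,
                                   "unknown_ncRNA": 80, "tRNA": 20},
                cell_types=[nc.CellTypeSpec("only", 1.0, n_marker_genes=0)],
                ncrna_only_type=None, n_hubs_pos=0, n_hubs_neg=0,
                n_trend_genes=0, n_trend_ncrna=0, n_time_variable_genes=50,
            )
            _, tpm, genes, _, _ = nc.simulate(cfg)
            hubs = nc.select_hubs(nc.screen_pairs(nc.log2_tpm(tpm), genes))
            assert sum(h.passes for h in hubs) == 0


class TestHubReport:
    def test_opposite_sign_sharing_flagged(self):
        edges = [
            nc.CoexpressionEdge("n1", "gA", 0.8, 1e-9, "pos"),
            nc.CoexpressionEdge("n1", "gB", 0.8, 1e-9, "pos"),
            nc.CoexpressionEdge("n2", "gA", -0.8, 1e-9, "neg"),
        ]
        hubs = [
            nc.NcRNAHub("n1", 2, 0, True, ["gA", "gB"]),
            nc.NcRNAHub("n2", 0, 1, True, ["gA"]),
        ]
        report = nc.hub_report(hubs, edges)
        assert report.iloc[0]["ncrna_id"] == "n1"  # sorted by partner count
        assert report.set_index("ncrna_id").loc["n1", "opposite_pairs"] == "gA"

    def test_empty_hub_list(self):
        assert nc.hub_report([], []).empty

    def test_partner_counts_match_edge_recount(self, small_sim):
        lg, genes = small_sim["log2tpm"], small_sim["genes"]
        edges = nc.screen_pairs(lg, genes)
        hubs = nc.select_hubs(edges)
        report = nc.hub_report(hubs, edges)
        for row in report.itertuples():
            n_pos = sum(1 for e in edges
                        if e.ncrna_id == row.ncrna_id and e.sign == "pos")
            n_neg = sum(1 for e in edges
                        if e.ncrna_id == row.ncrna_id and e.sign == "neg")
            assert (row.n_pos_partners, row.n_neg_partners) == (n_pos, n_neg)
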