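import numpy as np
import pytest

from pandanet.netio import (
    ExpressionMatrix,
    LabeledBipartiteNetwork,
    LabeledSymmetricNetwork,
    ParseError,
    build_seed_networks,
    read_expression,
    read_network,
    read_pairwise_table,
    write_network,
)


def _write(path, text):
    path.write_text(text)
    return str(path)


class TestReadPairwiseTable:
    def test_basic_parse_with_default_weight(self, tmp_path):
        p = _write(tmp_path / "e.tsv", "TF1 G1\nTF1 G2 0.5\n")
        recs = set(read_pairwise_table(p))
        assert recs == {("TF1", "G1", 1.0), ("TF1", "G2", 0.5)}

    def test_ppi_symmetrization(self, tmp_path):
        p = _write(tmp_path / "ppi.tsv", "A B\n")
        recs = set(read_pairwise_table(p, kind="ppi"))
        assert ("A", "B", 1.0) in recs and ("B", "A", 1.0) in recs

    def test_duplicates_collapse_to_max(self, tmp_path):
        p = _write(tmp_path / "e.tsv", "TF1 G1 1\nTF1 G1 0.2\n")
        assert read_pairwise_table(p) == [("TF1", "G1", 1.0)]

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path / "bad.tsv", "A B\nonlyonefield\n")
        with pytest.raises(ParseError, match="line 2"):
            read_pairwise_table(p)

    def test_bad_weight_and_empty_file(self, tmp_path):
        p = _write(tmp_path / "bad.tsv", "A B xyz\n")
        with pytest.raises(ParseError, match="not a number"):
            read_pairwise_table(p)
        with pytest.raises(ParseError, match="empty"):
            read_pairwise_table(_write(tmp_path / "empty.tsv", "\n"))

    def test_tab_and_comma_delimiters(self, tmp_path):
        for text in ("A\tB\t2\n", "A,B,2\n"):
            p = _write(tmp_path / "d.txt", text)
            assert read_pairwise_table(p) == [("A", "B", 2.0)]


class TestReadExpression:
    def test_shape_and_labels(self, tmp_path):
        p = _write(
            tmp_path / "x.tsv",
            "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t0\t0\t1\t1\ng3\t5\t4\t3\t2\n",
        )
        em = read_expression(p)
        assert em.values.shape == (3, 4)
        assert em.gene_labels == ["g1", "g2", "g3"]

    def test_single_sample_accepted_then_rejected_by_builder(self, tmp_path):
        p = _write(tmp_path / "x.tsv", "gene\ts1\ng1\t1\ng2\t2\n")
        em = read_expression(p)
        assert em.n_samples == 1
        with pytest.raises(ValueError, match="2 expression samples"):
            build_seed_networks([("T", "g1", 1), ("T", "g2", 1)], None, em)

    def test_missing_sentinel_gives_pairwise_complete_corr(self, tmp_path):
        p = _write(
            tmp_path / "x.tsv",
            "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\tNA\ng2\t2\t4\t6\t100\n",
        )
        em = read_expression(p)
        seeds = build_seed_networks(
            [("T", "g1", 1), ("T", "g2", 1)], None, em, universe="intersection"
        )
        # with the NA cell excluded, (1,2,3) vs (2,4,6) are perfectly collinear
        assert seeds.coregulation.weights[0, 1] == pytest.approx(1.0)

    def test_non_numeric_cell_and_duplicate_gene_error(self, tmp_path):
        p = _write(tmp_path / "x.tsv", "gene\ts1\ts2\ng1\t1\toops\n")
        with pytest.raises(ParseError, match="non-numeric"):
            read_expression(p)
        p2 = _write(tmp_path / "y.tsv", "gene\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_expression(p2)


class TestBuildSeedNetworks:
    def _expr(self, genes, values):
        values = np.asarray(values, dtype=float)
        samples = [f"s{k}" for k in range(values.shape[1])]
        return ExpressionMatrix(genes, samples, values)

    def test_no_ppi_gives_identity_cooperativity(self):
        prior = [("T1", "g1", 1), ("T2", "g2", 1), ("T3", "g1", 1)]
        seeds = build_seed_networks(prior, None, None)
        assert np.array_equal(seeds.cooperativity.weights, np.eye(3))

    def test_constant_gene_gets_zero_correlation(self):
        expr = self._expr(["g1", "g2"], [[1, 1, 1, 1], [1, 2, 3, 4]])
        seeds = build_seed_networks([("T", "g1", 1), ("T", "g2", 1)], None, expr)
        C = seeds.coregulation.weights
        assert C[0, 1] == 0.0 and C[0, 0] == 1.0 and C[1, 1] == 1.0

    def test_collinear_genes_correlate_perfectly(self):
        expr = self._expr(["g1", "g2"], [[1, 2, 3], [2, 4, 6]])
        seeds = build_seed_networks([("T", "g1", 1), ("T", "g2", 1)], None, expr)
        assert seeds.coregulation.weights[0, 1] == pytest.approx(1.0)

    def test_shapes_symmetry_and_diagonals(self, rng):
        tfs = [f"T{i}" for i in range(4)]
        genes = [f"g{j}" for j in range(6)]
        prior = [(t, g, 1.0) for t in tfs for g in genes if rng.random() < 0.5]
        prior += [(tfs[0], genes[0], 1.0)]
        ppi = [("T0", "T1", 1.0), ("T1", "T0", 1.0)]
        expr = self._expr(genes, rng.normal(size=(6, 5)))
        seeds = build_seed_networks(prior, ppi, expr)
        nW, nP, nC = (
            seeds.regulatory.weights,
            seeds.cooperativity.weights,
            seeds.coregulation.weights,
        )
        assert nW.shape == (4, 6) and nP.shape == (4, 4) and nC.shape == (6, 6)
        assert np.array_equal(nP, nP.T) and np.array_equal(nC, nC.T)
        assert np.all(np.diag(nP) == 1) and np.all(np.diag(nC) == 1)
        assert np.all(np.abs(nC) <= 1 + 1e-12)

    def test_intersection_vs_prior_driven_universe(self):
        prior = [("T", "g1", 1), ("T", "g2", 1), ("T", "g3", 1)]
        expr = self._expr(["g1", "g2"], [[1, 2, 3], [3, 1, 2]])
        inter = build_seed_networks(prior, None, expr, universe="intersection")
        assert inter.gene_labels == ["g1", "g2"]
        full = build_seed_networks(prior, None, expr, universe="prior-driven")
        assert full.gene_labels == ["g1", "g2", "g3"]
        # g3 has no expression: zero co-regulation evidence off-diagonal
        C = full.coregulation.weights
        assert C[2, 2] == 1.0 and C[2, 0] == 0.0 and C[2, 1] == 0.0


class TestWriteNetwork:
    @pytest.mark.parametrize("fmt", ["matrix", "edge-list"])
    def test_round_trip_bit_faithful(self, tmp_path, rng, fmt):
        net = LabeledBipartiteNetwork(
            ["Ta", "Tb"], ["g1", "g2", "g3"], rng.normal(size=(2, 3))
        )
        path = tmp_path / "net.txt"
        write_network(net, path, format=fmt)
        back = read_network(path, format=fmt)
        assert back.tf_labels == net.tf_labels
        assert back.gene_labels == net.gene_labels
        np.testing.assert_allclose(back.weights, net.weights, rtol=1e-10)

    def test_edge_list_row_count_and_order(self, tmp_path):
        net = LabeledBipartiteNetwork(["T2", "T1"], ["g2", "g1"], np.arange(4.0).reshape(2, 2))
        path = tmp_path / "net.txt"
        write_network(net, path, format="edge-list")
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert [l.split("\t")[:2] for l in lines] == [
            ["T1", "g1"], ["T1", "g2"], ["T2", "g1"], ["T2", "g2"],
        ]

    def test_symmetric_edge_list_contains_both_orientations(self, tmp_path, rng):
        M = rng.normal(size=(3, 3))
        net = LabeledSymmetricNetwork(["a", "b", "c"], (M + M.T) / 2)
        path = tmp_path / "sym.txt"
        write_network(net, path, format="edge-list")
        rows = {(f[0], f[1]): float(f[2]) for f in
                (l.split("\t") for l in path.read_text().splitlines())}
        for x in "abc":
            for y in "abc":
                assert rows[(x, y)] == rows[(y, x)]
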