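"""Network construction: adjacency/TOM formulas against brute-force oracles,
soft-threshold selection against an independent recomputation, module
detection on planted data, eigengene maximality against a dense
eigendecomposition, and the membership pruning rules."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexnet.network import (
    CoexpressionNetwork,
    adjacency,
    apply_membership_rules,
    build_network,
    cluster_and_cut,
    connectivity,
    module_eigengene,
    module_membership,
    pick_soft_threshold,
    scale_free_fit,
    tom,
)
from coexnet.synthdata import SynthConfig, generate_expression


def brute_force_tom(A):
    """Triple-loop reference implementation of topological overlap."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    a = A.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            w[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return w


def random_adjacency(rng, n):
    """Random symmetric matrix with unit diagonal and entries in [0, 1]."""
    A = rng.uniform(0, 1, (n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


class TestAdjacency:
    def test_signed_limits(self):
        # perfectly correlated, anti-correlated, and uncorrelated genes
        t = np.linspace(-1, 1, 8)
        expr = pd.DataFrame(
            [t, -t, t**2 - np.mean(t**2)],
            index=["up", "down", "sym"],
            columns=[f"s{j}" for j in range(8)],
        )
        net = adjacency(expr, beta=2.0)
        assert net.adjacency[0, 0] == pytest.approx(1.0)
        assert net.adjacency[0, 1] == pytest.approx(0.0, abs=1e-12)  # cor -1 signed
        assert net.adjacency[0, 2] == pytest.approx(0.25, abs=1e-12)  # cor 0, (0.5)^2

    def test_monotone_in_correlation(self, rng):
        expr = pd.DataFrame(rng.standard_normal((20, 15)))
        net = adjacency(expr, beta=6.0)
        corr = np.corrcoef(expr.to_numpy())
        iu = np.triu_indices(20, k=1)
        order = np.argsort(corr[iu])
        assert (np.diff(net.adjacency[iu][order]) >= -1e-12).all()

    def test_entries_bounded_and_symmetric(self, rng):
        expr = pd.DataFrame(rng.standard_normal((30, 10)))
        A = adjacency(expr, beta=9.0).adjacency
        assert ((A >= 0) & (A <= 1)).all()
        assert np.allclose(A, A.T)

    def test_zero_variance_gene_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="variance"):
            adjacency(expr, beta=2.0)


class TestConnectivity:
    def test_complete_graph(self):
        A = np.ones((5, 5))
        k = connectivity(A)
        assert np.allclose(k["kTotal"], 4.0)

    def test_isolated_nodes(self):
        assert np.allclose(connectivity(np.eye(4))["kTotal"], 0.0)

    def test_hand_summed_triangle(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.5
        A[0, 2] = A[2, 0] = 0.2
        A[1, 2] = A[2, 1] = 0.1
        k = connectivity(A)
        assert np.allclose(k["kTotal"], [0.7, 0.6, 0.3])

    def test_kin_respects_partition(self):
        A = np.ones((4, 4))
        labels = pd.Series(["a", "a", "b", "b"], index=range(4))
        k = connectivity(A, labels=labels)
        assert np.allclose(k["kIN"], 1.0)
        assert np.allclose(k["kTotal"], 3.0)


class TestTom:
    def test_isolated_perfect_pair_full_overlap(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 1.0
        w = tom(A)
        assert w[0, 1] == pytest.approx(1.0)

    def test_zero_offdiagonal_zero_overlap(self):
        w = tom(np.eye(5))
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(w[off], 0.0)

    def test_three_gene_hand_computation(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.5
        A[0, 2] = A[2, 0] = 0.2
        A[1, 2] = A[2, 1] = 0.1
        w = tom(A)
        assert w[0, 1] == pytest.approx(0.52 / 1.1, abs=1e-12)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(25):
            A = random_adjacency(rng, 8)
            assert np.allclose(tom(A), brute_force_tom(A), atol=1e-12)

    def test_bounded_and_symmetric(self, rng):
        w = tom(random_adjacency(rng, 12))
        assert ((w >= 0) & (w <= 1)).all()
        assert np.allclose(w, w.T)


class TestPickSoftThreshold:
    def test_mean_k_decreases_with_power(self, rng):
        expr = pd.DataFrame(rng.standard_normal((40, 12)))
        scan = pick_soft_threshold(expr, candidate_powers=(2, 4, 6, 8))
        assert (np.diff(scan.table["mean_k"]) < 0).all()

    def test_no_qualifying_power_returns_sentinel_with_full_table(self, rng):
        expr = pd.DataFrame(rng.standard_normal((30, 12)))
        scan = pick_soft_threshold(expr, candidate_powers=(1, 2), fit_cut=0.999)
        assert scan.selected is None
        assert len(scan.table) == 2

    def test_selection_matches_independent_regression(self, small_planted):
        """Oracle: recompute the binned log-log regression per power."""
        from scipy.stats import linregress

        _, expr, _ = small_planted
        powers = (2, 4, 6, 8, 10, 12)
        scan = pick_soft_threshold(expr, candidate_powers=powers, fit_cut=0.8)
        corr = np.corrcoef(expr.to_numpy())
        expected = None
        for beta in powers:
            A = ((1 + corr) / 2) ** beta
            k = A.sum(axis=1) - 1
            edges = np.linspace(k.min(), k.max(), 11)
            which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
            fr, mk = [], []
            for b in range(10):
                sel = k[which == b]
                if sel.size and sel.mean() > 0:
                    fr.append(sel.size / k.size)
                    mk.append(sel.mean())
            fit = linregress(np.log10(mk), np.log10(fr))
            if -np.sign(fit.slope) * fit.rvalue**2 >= 0.8:
                expected = beta
                break
        assert scan.selected == expected

    def test_degenerate_equal_connectivity_is_nan(self):
        k = np.full(50, 3.0)
        r2, slope = scale_free_fit(k)
        assert np.isnan(r2) and np.isnan(slope)


class TestClusterAndCut:
    def test_planted_modules_recovered(self, small_planted):
        _, expr, truth = small_planted
        net = adjacency(expr, beta=12.0)
        w = tom(net.adjacency)
        labels = cluster_and_cut(w, expr.index, min_module_size=30, deep_split=2)
        non_grey = labels != "grey"
        ari = adjusted_rand_score(truth.labels[non_grey], labels[non_grey])
        assert ari >= 0.9

    def test_fewer_genes_than_min_size_all_grey(self, rng):
        w = np.eye(10)
        labels = cluster_and_cut(w, pd.Index(range(10)), min_module_size=100)
        assert (labels == "grey").all()

    def test_anticorrelated_blocks_split_in_signed_network(self, rng):
        """Signed adjacency sends cor = -1 to 0, so mirrored blocks separate."""
        base = rng.standard_normal(30)
        expr = pd.DataFrame(
            np.vstack(
                [base + 0.1 * rng.standard_normal(30) for _ in range(20)]
                + [-base + 0.1 * rng.standard_normal(30) for _ in range(20)]
            )
        )
        net = adjacency(expr, beta=6.0)
        w = tom(net.adjacency)
        labels = cluster_and_cut(w, expr.index, min_module_size=10, deep_split=2)
        up = set(labels.iloc[:20].unique())
        down = set(labels.iloc[20:].unique())
        assert up.isdisjoint(down)
        assert "grey" not in up | down


class TestModuleEigengene:
    def test_single_gene_module_is_standardized_profile(self, toy_expr):
        labels = pd.Series(["a", "grey", "grey", "grey"], index=toy_expr.index)
        mes, ve = module_eigengene(toy_expr, labels)
        g = toy_expr.iloc[0]
        z = (g - g.mean()) / g.std()
        assert np.allclose(np.abs(np.corrcoef(mes["a"], z)[0, 1]), 1.0)
        assert ve["a"] == pytest.approx(1.0)

    def test_identical_genes_fully_explained(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        expr = pd.DataFrame(np.tile(profile, (5, 1)) * [[1], [2], [3], [4], [5]])
        labels = pd.Series(["m"] * 5, index=expr.index)
        mes, ve = module_eigengene(expr, labels)
        assert ve["m"] == pytest.approx(1.0)
        assert np.corrcoef(mes["m"], profile)[0, 1] == pytest.approx(1.0)

    def test_variance_explained_matches_dense_eigendecomposition(self, rng):
        """Oracle: top eigenvalue share of the gene-gene correlation matrix."""
        expr = pd.DataFrame(rng.standard_normal((20, 15)))
        labels = pd.Series(["m"] * 20, index=expr.index)
        mes, ve = module_eigengene(expr, labels)
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
        evals = np.linalg.eigvalsh(z @ z.T)
        assert ve["m"] == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_me_maximality(self, rng):
        """No unit-norm linear combination of module genes explains more
        variance than the eigengene."""
        expr = pd.DataFrame(rng.standard_normal((15, 12)))
        labels = pd.Series(["m"] * 15, index=expr.index)
        mes, ve = module_eigengene(expr, labels)
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
        me = mes["m"].to_numpy()
        me_var = np.sum((z @ me) ** 2) / np.sum(me**2)
        for _ in range(50):
            v = rng.standard_normal(12)
            assert np.sum((z @ v) ** 2) / np.sum(v**2) <= me_var + 1e-9

    def test_sign_oriented_to_mean_profile(self, rng):
        expr = pd.DataFrame(rng.standard_normal((10, 8)) + 2.0)
        labels = pd.Series(["m"] * 10, index=expr.index)
        mes, _ = module_eigengene(expr, labels)
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T
        assert np.corrcoef(mes["m"], z.mean(axis=0))[0, 1] >= 0


class TestMembershipRules:
    def _fixture(self, rng, n_strong, n_weak, kme_strong=0.95, kme_weak=0.15, n_samples=60):
        """Module whose first genes track the seed profile strongly and the
        rest barely."""
        seed_profile = rng.standard_normal(n_samples)
        rows = []
        for r, count in ((kme_strong, n_strong), (kme_weak, n_weak)):
            for _ in range(count):
                rows.append(r * seed_profile + np.sqrt(1 - r**2) * rng.standard_normal(n_samples))
        expr = pd.DataFrame(rows)
        labels = pd.Series(["m"] * len(rows), index=expr.index)
        mes, _ = module_eigengene(expr, labels)
        return expr, labels, mes

    def test_strong_module_unchanged(self, rng):
        expr, labels, mes = self._fixture(rng, n_strong=40, n_weak=0)
        new_labels, _, _ = apply_membership_rules(expr, labels, mes, min_module_size=30)
        assert (new_labels == "m").all()

    def test_weak_members_sent_to_grey(self, rng):
        expr, labels, mes = self._fixture(rng, n_strong=40, n_weak=10)
        new_labels, _, _ = apply_membership_rules(expr, labels, mes, min_module_size=30)
        kme = module_membership(expr, mes)["m"]
        assert (new_labels[kme < 0.3] == "grey").all()
        assert (new_labels[kme > 0.5] == "m").all()

    def test_module_without_core_disbanded(self, rng):
        """Top members capped below the core-kME threshold: all to grey."""
        expr, labels, mes = self._fixture(
            rng, n_strong=0, n_weak=40, kme_weak=0.38, n_samples=2000
        )
        new_labels, mes2, _ = apply_membership_rules(
            expr, labels, mes, min_module_size=100
        )
        assert (new_labels == "grey").all()
        assert mes2.shape[1] == 0


class TestBuildNetwork:
    def test_strong_modules_converge_quickly_no_grey(self):
        cfg = SynthConfig(
            n_samples=40,
            module_sizes=(60, 60),
            n_background_genes=0,
            kme_targets=0.9,
            trait_couplings={},
            preserved_modules=(),
            seed=33,
        )
        expr, _ = generate_expression(cfg)
        net, modules, info = build_network(
            expr, beta=8.0, min_module_size=30, deep_split=2
        )
        assert info["converged"]
        assert len(info["grey_per_iteration"]) <= 2
        assert (modules.labels != "grey").all()
        assert len(modules.module_names) == 2

    def test_pure_noise_terminates_without_modules(self, rng):
        expr = pd.DataFrame(
            rng.standard_normal((80, 20)),
            index=[f"g{i}" for i in range(80)],
        )
        net, modules, info = build_network(
            expr, beta=6.0, min_module_size=60, deep_split=2, max_iter=4
        )
        # noise either sheds everything or ends all-grey; no spurious module
        # should survive the membership rules at this size
        assert len(modules.module_names) <= 1

    def test_results_object_roundtrip(self, small_planted):
        _, expr, truth = small_planted
        res = CoexpressionNetwork(expr, power=10.0, min_module_size=30).fit()
        table = res.gene_table()
        assert {"module", "kTotal", "kIN", "kME_own"} <= set(table.columns)
        summary = res.summary()
        assert (summary["size"] >= 30).all()
        # adding an external gene annotation post hoc does not change stats
        before = res.summary().copy()
        _ = truth.labels.copy()
        assert res.summary().equals(before)
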