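import numpy as np
import pytest

from neurogain import connectome as cx
from neurogain.synthetic import SynthConnectomeSpec, generate_connectome
from tests.conftest import random_connectome

# ---------------------------------------------------------------------------
# loading / construction
# ---------------------------------------------------------------------------


class TestLoadConnectome:
    def test_zero_offdiagonal(self, tmp_path):
        p = tmp_path / "m.csv"
        np.savetxt(p, np.zeros((3, 3)), delimiter=",")
        M = cx.load_connectome(p)
        assert M.n == 3
        assert np.all(M.weights == 0)

    def test_npy_roundtrip(self, tmp_path):
        w = np.array([[0, 0.3], [0.3, 0]])
        p = tmp_path / "m.npy"
        np.save(p, w)
        assert np.allclose(cx.load_connectome(p).weights, w)

    def test_labels(self, tmp_path):
        np.savetxt(tmp_path / "m.csv", np.zeros((2, 2)), delimiter=",")
        (tmp_path / "labels.txt").write_text("A\nB\n")
        M = cx.load_connectome(tmp_path / "m.csv", tmp_path / "labels.txt")
        assert M.labels == ["A", "B"]

    def test_asymmetric_rejected(self, tmp_path):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        w[1, 0] = 0.7
        np.savetxt(tmp_path / "m.csv", w, delimiter=",")
        with pytest.raises(ValueError, match="symmetric"):
            cx.load_connectome(tmp_path / "m.csv")

    @pytest.mark.parametrize(
        "bad, msg",
        [
            (np.full((2, 3), 0.1), "square"),
            (-np.ones((3, 3)) + np.eye(3), "negative"),
        ],
    )
    def test_invalid_matrices(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            cx.Connectome(bad)

    def test_nan_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cx.Connectome(w)

    def test_diagonal_zeroed(self):
        w = np.ones((3, 3))
        assert np.all(np.diag(cx.Connectome(w).weights) == 0)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestNormalize:
    def test_complete_graph(self, triangle):
        Mn = cx.normalize_connectome(triangle)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(Mn.weights[off], 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_strength_one(self, seed):
        M = random_connectome(12, seed)
        Mn = cx.normalize_connectome(M)
        assert abs(Mn.weights.sum(axis=1).mean() - 1.0) < 1e-12

    def test_matches_bruteforce_divisor(self):
        M = random_connectome(10, 3)
        # independent double loop
        total = 0.0
        for i in range(10):
            for j in range(10):
                if i != j:
                    total += M.weights[i, j]
        divisor = total / 10
        Mn = cx.normalize_connectome(M)
        assert np.allclose(Mn.weights, M.weights / divisor)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cx.normalize_connectome(cx.Connectome(np.zeros((3, 3))))


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------


class TestDSPR:
    def test_preservation_contract(self):
        M = generate_connectome(SynthConnectomeSpec(n=30, n_modules=2, seed=3))
        S = cx.dspr_surrogate(M, seed=7)
        assert np.array_equal(M.degree(), S.degree())
        iu = np.triu_indices(30, 1)
        assert np.allclose(np.sort(M.weights[iu]), np.sort(S.weights[iu]))
        rel = np.abs(S.strength() - M.strength()) / M.strength()
        assert rel.max() <= 0.05
        assert np.allclose(S.weights, S.weights.T)
        assert np.all(np.diag(S.weights) == 0)

    def test_two_seeds_differ(self):
        M = generate_connectome(SynthConnectomeSpec(n=30, n_modules=2, seed=3))
        a = cx.dspr_surrogate(M, seed=1)
        b = cx.dspr_surrogate(M, seed=2)
        assert not np.allclose(a.weights, b.weights)
        assert np.array_equal(a.degree(), b.degree())

    def test_complete_homogeneous_unchanged(self):
        w = np.ones((8, 8)) - np.eye(8)
        S = cx.dspr_surrogate(cx.Connectome(w), seed=0)
        assert np.allclose(S.weights, w - np.eye(8) * 0)

    def test_too_small(self):
        with pytest.raises(ValueError):
            cx.dspr_surrogate(cx.Connectome(np.zeros((3, 3))), seed=0)


class TestFullRandomize:
    def test_multiset_preserved(self):
        M = random_connectome(10, 4)
        S = cx.full_randomize(M, seed=5)
        iu = np.triu_indices(10, 1)
        assert np.allclose(np.sort(M.weights[iu]), np.sort(S.weights[iu]))

    def test_deterministic(self):
        M = random_connectome(10, 4)
        assert np.array_equal(
            cx.full_randomize(M, seed=5).weights, cx.full_randomize(M, seed=5).weights
        )

    def test_homogeneous_unchanged(self):
        w = np.ones((6, 6)) - np.eye(6)
        assert np.allclose(cx.full_randomize(cx.Connectome(w), 1).weights, w - 0)


class TestHomogenize:
    def test_all_above(self):
        w = np.full((4, 4), 0.5) - 0.5 * np.eye(4)
        H = cx.homogenize(cx.Connectome(w))
        assert np.allclose(H.weights, np.ones((4, 4)) - np.eye(4))

    def test_boundary(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.04
        w[0, 2] = w[2, 0] = 0.05
        w[1, 2] = w[2, 1] = 0.06
        H = cx.homogenize(cx.Connectome(w))
        assert H.weights[0, 1] == 0.0
        assert H.weights[0, 2] == 1.0
        assert H.weights[1, 2] == 1.0

    def test_empty_warns(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.01
        with pytest.warns(UserWarning, match="removed all edges"):
            H = cx.homogenize(cx.Connectome(w))
        assert H.weights.sum() == 0


# ---------------------------------------------------------------------------
# node metrics
# ---------------------------------------------------------------------------


def _bruteforce_metrics(weights):
    """Independent oracle: Floyd-Warshall on 1/w lengths, triple-loop triangles."""
    n = weights.shape[0]
    INF = float("inf")
    d = [[0.0 if i == j else (1.0 / weights[i][j] if weights[i][j] > 0 else INF)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    eff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and d[i][j] < INF:
                eff[i] += 1.0 / d[i][j]
    eff /= n - 1
    tri = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for h in range(n):
                tri[i] += (weights[i][j] * weights[i][h] * weights[j][h]) ** (1 / 3)
    tri /= 2.0
    deg = (weights > 0).sum(axis=1)
    clust = np.zeros(n)
    for i in range(n):
        if deg[i] > 1:
            clust[i] = 2 * tri[i] / (deg[i] * (deg[i] - 1))
    return weights.sum(axis=1), eff, clust, tri


class TestNodeMetrics:
    def test_triangle(self, triangle):
        nm = cx.node_metrics(triangle)
        assert np.allclose(nm.strength, 2)
        assert np.allclose(nm.nodal_efficiency, 1)
        assert np.allclose(nm.clustering, 1)

    def test_path(self, path3):
        nm = cx.node_metrics(path3)
        # node a: d(a,b)=1, d(a,c)=2 -> (1 + 1/2)/2
        assert np.isclose(nm.nodal_efficiency[0], 0.75)
        assert np.allclose(nm.clustering, 0)

    @pytest.mark.parametrize("seed", range(100))
    def test_against_bruteforce(self, seed):
        n = 4 + seed % 7  # n in 4..10
        M = random_connectome(n, seed)
        nm = cx.node_metrics(M)
        s, e, c, t = _bruteforce_metrics(M.weights)
        assert np.allclose(nm.strength, s)
        assert np.allclose(nm.nodal_efficiency, e)
        assert np.allclose(nm.clustering, c)
        assert np.allclose(nm.triangle_intensity, t)


# ---------------------------------------------------------------------------
# rich club
# ---------------------------------------------------------------------------


class TestRichClub:
    def test_complete_homogeneous_phi_one(self):
        w = np.ones((8, 8)) - np.eye(8)
        rc = cx.rich_club(cx.Connectome(w), n_surrogates=10, seed=0)
        for K, phi in rc.phi.items():
            if np.isfinite(phi):
                assert np.isclose(phi, 1.0)

    def test_regular_graph_warns_empty(self):
        # 6-cycle: all degrees 2, all weights equal -> phi == 1 at every
        # admissible K, no club stands out but a result is still returned
        w = np.zeros((6, 6))
        for i in range(6):
            w[i, (i + 1) % 6] = w[(i + 1) % 6, i] = 1.0
        rc = cx.rich_club(cx.Connectome(w), n_surrogates=10, seed=0)
        assert set(rc.categories) <= {"rich_club", "feeder", "local"}

    def test_planted_toy_core(self):
        # 12 nodes: 4-node heavy complete core (degree 7), periphery with
        # degree 6 and markedly weaker weights
        rng = np.random.default_rng(42)
        n = 12
        w = np.zeros((n, n))
        for i in range(4):
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = rng.uniform(0.6, 1.0)
        for i in range(4):
            for k in range(4):
                j = 4 + (2 * i + k) % 8
                w[i, j] = w[j, i] = rng.uniform(0.1, 0.4)
        for i in range(4, n):
            for off in (1, 2):
                j = 4 + (i - 4 + off) % 8
                if w[i, j] == 0:
                    w[i, j] = w[j, i] = rng.uniform(0.05, 0.2)
        rc = cx.rich_club(cx.Connectome(w), n_surrogates=300, seed=1)
        assert rc.K_star is not None
        assert rc.phi_norm[rc.K_star] > 1.0
        assert set(rc.members) == {0, 1, 2, 3}

    def test_phi_norm_of_surrogate_near_one(self, synth90):
        # a DSPR surrogate of the graph is its own null: phi_norm ~ 1
        S = cx.dspr_surrogate(synth90, seed=11)
        rc = cx.rich_club(S, n_surrogates=50, seed=12)
        deg = S.degree()
        vals = np.array([
            v for K, v in rc.phi_norm.items()
            if np.isfinite(v) and (deg > K).sum() >= 10
        ])
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - 1.0) <= max(2 * se, 0.02)

    def test_category_counts_sum(self, synth90):
        rc = cx.rich_club(synth90, n_surrogates=30, seed=3)
        assert len(rc.categories) == synth90.n
        counts = {c: (rc.categories == c).sum() for c in ("rich_club", "feeder", "local")}
        assert sum(counts.values()) == synth90.n

    def test_phi_bounds(self, synth90):
        rc = cx.rich_club(synth90, n_surrogates=10, seed=3)
        for phi in rc.phi.values():
            if np.isfinite(phi):
                assert 0 < phi <= 1 + 1e-12


# ---------------------------------------------------------------------------
# s-core
# ---------------------------------------------------------------------------


def _in_s_core(weights, s):
    """Oracle: recursive pruning of nodes with within-core strength < s."""
    alive = np.ones(weights.shape[0], dtype=bool)
    while True:
        strength = (weights[np.ix_(alive, alive)]).sum(axis=1)
        weak = strength < s
        if not weak.any() or not alive.any():
            break
        idx = np.flatnonzero(alive)
        alive[idx[weak]] = False
        if not alive.any():
            break
    return alive


class TestSCore:
    def test_complete_homogeneous_single_level(self):
        w = np.ones((6, 6)) - np.eye(6)
        res = cx.s_core(cx.Connectome(w), cuts=(1.0, 2.0))
        assert np.allclose(res.critical_s, res.critical_s[0])

    @pytest.mark.parametrize("seed", range(10))
    def test_against_pruning_oracle(self, seed):
        M = random_connectome(6, seed)
        crit = cx.s_core(M, cuts=(0.5, 1.0)).critical_s
        eps = 1e-9
        for i in range(6):
            alive_at = _in_s_core(M.weights, crit[i] - eps)
            assert alive_at[i], f"node {i} should survive at its critical s"
            alive_above = _in_s_core(M.weights, crit[i] + 1e-6)
            assert not alive_above[i], f"node {i} should be pruned just above"

    def test_monotone_in_strength_for_homogeneous_topology(self):
        rng = np.random.default_rng(0)
        w = rng.random((8, 8))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0)
        M = cx.Connectome(w)
        res = cx.s_core(M, cuts=(1.0, 2.0))
        order = np.argsort(M.strength())
        assert np.all(np.diff(res.critical_s[order]) >= -1e-12)

    def test_categories_partition(self, synth90):
        res = cx.s_core(synth90, cuts=(10.0, 14.0))
        assert len(res.categories) == synth90.n
        assert set(res.categories) <= {"S1", "S2", "S3"}

    def test_bad_cuts(self, synth90):
        with pytest.raises(ValueError):
            cx.s_core(synth90, cuts=(2.0, 1.0))
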