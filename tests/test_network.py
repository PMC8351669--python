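"""Co-expression network: bicor, adjacency, TOM (vs O(n^3) loop oracle),
module detection on planted blocks, trait statistics, and hub genes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from agingnet import network
from agingnet.network import (
    adjacency_signed,
    bicor_matrix,
    bicor_pair,
    detect_modules,
    gene_module_stats,
    hub_genes,
    module_eigengenes,
    module_trait_association,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)


# ---------------------------------------------------------------------------
# bicor
# ---------------------------------------------------------------------------

class TestBicor:
    def test_identity_and_antisymmetry(self, rng):
        x = rng.normal(size=100)
        assert bicor_pair(x, x) == pytest.approx(1.0)
        assert bicor_pair(x, -x) == pytest.approx(-1.0)

    def test_close_to_pearson_on_clean_gaussian(self, rng):
        cov = [[1.0, 0.6], [0.6, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=500)
        b = bicor_pair(xy[:, 0], xy[:, 1])
        p = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        assert abs(b - p) < 0.05

    def test_robust_to_single_outlier(self, rng):
        cov = [[1.0, 0.9], [0.9, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        p_clean = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        b_clean = bicor_pair(xy[:, 0], xy[:, 1])
        xy[0, 0] = 30.0  # one extreme outlier
        p_dirty = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
        b_dirty = bicor_pair(xy[:, 0], xy[:, 1])
        assert abs(b_clean - b_dirty) < 0.5 * abs(p_clean - p_dirty)

    def test_affine_invariance_positive_slope(self, rng):
        X = rng.normal(size=(10, 50))
        R1 = bicor_matrix(X)
        scale = rng.uniform(0.5, 3.0, size=(10, 1))
        shift = rng.normal(size=(10, 1))
        R2 = bicor_matrix(X * scale + shift)
        assert np.allclose(R1, R2, atol=1e-10)

    def test_zero_mad_falls_back_to_pearson(self, rng):
        # > half the values tied: MAD = 0, bicor undefined, Pearson used
        x = np.array([0.0] * 30 + list(rng.normal(size=20)))
        y = rng.normal(size=50)
        got = bicor_pair(x, y)
        assert got == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_constant_gene_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            bicor_matrix(np.vstack([np.ones(10), np.arange(10.0)]))


# ---------------------------------------------------------------------------
# soft threshold / adjacency
# ---------------------------------------------------------------------------

class TestSoftThreshold:
    def test_adjacency_endpoints_and_arithmetic(self):
        r = np.array([[1.0, 1.0, -1.0, 0.0, 0.8]])
        R = np.vstack([r, r, r, r, r])  # symmetric enough for the formula
        A1 = adjacency_signed(R, 1)
        assert A1[0, 1] == 1.0 and A1[0, 2] == 0.0 and A1[0, 3] == 0.5
        A6 = adjacency_signed(R, 6)
        assert A6[0, 4] == pytest.approx(0.9**6)
        # elementwise oracle
        expect = ((1 + R) / 2) ** 6
        np.fill_diagonal(expect, 1.0)
        assert np.allclose(A6, expect)

    def test_power_law_degrees_fit_well(self):
        # constructed exact power-law degree sequence: freq(k) ~ k^-2
        ks = np.arange(1, 11, dtype=float)
        k = np.repeat(ks, np.round(5000 / ks**2).astype(int))
        assert scale_free_fit(k) > 0.95

    def test_mean_connectivity_decreases_with_power(self, rng):
        X = rng.normal(size=(60, 20))
        X[:30] += rng.normal(size=20) * 2.0
        cor = bicor_matrix(X)
        table, _ = pick_soft_threshold(cor, 20, powers=[1, 2, 4, 6, 8])
        assert (np.diff(table["mean_k"]) < 0).all()

    def test_study_powers_recorded(self):
        assert network.STUDY_POWERS == {
            "brain": 7, "heart": 7, "liver": 5, "muscle": 6, "pancreas": 7
        }

    def test_fallback_power_by_sample_count(self, rng):
        # white-noise correlations never reach the fit target -> fallback
        X = rng.normal(size=(50, 10))
        cor = bicor_matrix(X)
        with pytest.warns(UserWarning, match="falling back"):
            _, beta = pick_soft_threshold(cor, 10, powers=[1, 2])
        assert beta == 16


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

def tom_loop_oracle(A):
    """O(n^3) explicit-loop topological overlap."""
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(A0[i, u] * A0[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (L + A0[i, j]) / (min(k[i], k[j]) + 1 - A0[i, j])
    return T


class TestTOM:
    def test_matches_loop_oracle_on_random_adjacency(self, rng):
        M = rng.uniform(0, 1, size=(50, 50))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 1.0)
        assert np.allclose(tom_similarity(A), tom_loop_oracle(A), atol=1e-12)

    def test_exclusive_pair_saturates(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 1.0
        assert tom_similarity(A)[0, 1] == pytest.approx(1.0)

    def test_identical_rows_maximal(self, rng):
        M = rng.uniform(0, 0.5, size=(10, 10))
        A = (M + M.T) / 2
        A[1, :] = A[0, :]
        A[:, 1] = A[:, 0]
        A[0, 1] = A[1, 0] = 0.9
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(A)
        off = T[np.triu_indices(10, 1)]
        assert T[0, 1] == pytest.approx(off.max())

    def test_bounds_and_sample_order_invariance(self, rng):
        M = rng.uniform(0, 1, size=(30, 30))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(A)
        assert (T >= 0).all() and (T <= 1).all()
        assert np.allclose(np.diag(T), 1.0)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _planted_blocks(rng, n_block=100, n_noise=200, r=0.8, n_samples=40):
    """Three equicorrelated blocks (r within, ~0 between) plus noise genes."""
    X, truth = [], []
    for b in range(3):
        latent = rng.normal(size=n_samples)
        lam = np.sqrt(r / (1 - r))
        block = lam * latent[None, :] + rng.normal(size=(n_block, n_samples))
        X.append(block)
        truth += [b] * n_block
    X.append(rng.normal(size=(n_noise, n_samples)))
    truth += [-1] * n_noise
    X = np.vstack(X)
    genes = [f"g{i}" for i in range(X.shape[0])]
    return X, genes, np.array(truth)


@pytest.fixture(scope="module")
def blocks():
    rng = np.random.default_rng(7)
    X, genes, truth = _planted_blocks(rng)
    cor = bicor_matrix(X)
    A = adjacency_signed(cor, 6)
    tom = tom_similarity(A)
    modules = detect_modules(tom, X, genes)
    return X, genes, truth, modules


class TestModuleDetection:

    def test_three_blocks_recovered(self, blocks):
        X, genes, truth, modules = blocks
        labels = modules.labels.to_numpy()
        found = set(labels) - {network.GREY}
        assert len(found) == 3
        code = pd.Series(labels).astype("category").cat.codes
        assert adjusted_rand_score(truth, code) >= 0.8

    def test_noise_genes_predominantly_grey(self, blocks):
        _, _, truth, modules = blocks
        noise_labels = modules.labels.to_numpy()[truth == -1]
        assert np.mean(noise_labels == network.GREY) > 0.5

    def test_deterministic(self, blocks):
        X, genes, truth, modules = blocks
        cor = bicor_matrix(X)
        tom = tom_similarity(adjacency_signed(cor, 6))
        again = detect_modules(tom, X, genes)
        assert (again.labels == modules.labels).all()

    def test_correlated_eigengene_blocks_merge(self, rng):
        # two blocks driven by nearly identical latents -> one module
        latent = rng.normal(size=40)
        lam = 3.0
        b1 = lam * latent[None, :] + rng.normal(size=(60, 40)) * 0.5
        b2 = lam * (latent[None, :] + rng.normal(size=40) * 0.1) + rng.normal(size=(60, 40)) * 0.5
        X = np.vstack([b1, b2, rng.normal(size=(100, 40))])
        genes = [f"g{i}" for i in range(X.shape[0])]
        tom = tom_similarity(adjacency_signed(bicor_matrix(X), 6))
        modules = detect_modules(tom, X, genes, min_size=50, merge_height=0.15)
        block_labels = modules.labels.iloc[:120]
        non_grey = block_labels[block_labels != network.GREY]
        assert non_grey.nunique() == 1

    def test_defaults(self):
        assert network.DEFAULT_MIN_MODULE_SIZE == 50
        assert network.DEFAULT_MERGE_HEIGHT == 0.15
        assert network.DEFAULT_DEEP_SPLIT == 2


# ---------------------------------------------------------------------------
# eigengenes and trait statistics
# ---------------------------------------------------------------------------

class TestEigengenes:
    def test_identical_genes_give_their_profile(self, rng):
        profile = rng.normal(size=20)
        X = np.tile(profile, (5, 1))
        labels = pd.Series(["m"] * 5, index=[f"g{i}" for i in range(5)])
        mes = module_eigengenes(X, list(labels.index), labels)
        me = mes["m"].to_numpy()
        z = (profile - profile.mean()) / profile.std(ddof=1)
        zn = z / np.linalg.norm(z)
        assert np.allclose(np.abs(me), np.abs(zn), atol=1e-8)
        assert np.corrcoef(me, profile)[0, 1] > 0.99  # sign orientation

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(30, 15))
        labels = pd.Series(["m"] * 30, index=[f"g{i}" for i in range(30)])
        mes = module_eigengenes(X, list(labels.index), labels)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        assert np.allclose(np.abs(mes["m"]), np.abs(Vt[0]), atol=1e-8)

    def test_gene_sign_flip_leaves_trait_bicor_magnitude(self, rng):
        latent = np.linspace(-1, 1, 24) + rng.normal(scale=0.2, size=24)
        X = 2 * latent[None, :] + rng.normal(size=(20, 24)) * 0.3
        genes = [f"g{i}" for i in range(20)]
        labels = pd.Series(["m"] * 20, index=genes)
        me1 = module_eigengenes(X, genes, labels)["m"]
        me2 = module_eigengenes(-X, genes, labels)["m"]
        trait = np.arange(24.0)
        assert abs(bicor_pair(me1.to_numpy(), trait)) == pytest.approx(
            abs(bicor_pair(me2.to_numpy(), trait)), abs=1e-10
        )


class TestModuleTraitStats:
    def test_perfect_age_module_selected(self):
        age = np.arange(3.0, 28.0, 3.0)
        mes = pd.DataFrame({"M1": (age - age.mean()) / np.linalg.norm(age - age.mean())})
        out = module_trait_association(mes, pd.DataFrame({"age": age}))
        row = out.iloc[0]
        assert row["bicor"] == pytest.approx(1.0)
        assert row["p"] < 1e-9
        assert row["selected"]

    def test_t_approximation_value(self):
        # r = 0.5 with m = 30 gives t = 2.9104? no: t = r sqrt((m-2)/(1-r^2))
        t = 0.5 * np.sqrt(28 / 0.75)
        p = 2 * stats.t.sf(t, 28)
        assert t == pytest.approx(3.055, abs=1e-3)
        assert p == pytest.approx(0.0049, abs=5e-4)
        assert network._cor_test_p(0.5, 30) == pytest.approx(p)

    def test_threshold_is_on_magnitude(self, rng):
        m = 40
        noise = rng.normal(size=m)
        age = np.arange(m, dtype=float)
        base = -(age - age.mean()) / np.linalg.norm(age - age.mean())
        me = base + 0.1 * noise / np.linalg.norm(noise)
        mes = pd.DataFrame({"M1": me})
        out = module_trait_association(mes, pd.DataFrame({"age": age}))
        assert out.iloc[0]["bicor"] < -0.5
        assert out.iloc[0]["selected"]  # negative correlations count via |r|

    def test_sub_threshold_not_selected(self):
        # r = 0.49 must never be selected whatever its p-value
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = 200
            age = np.arange(m, dtype=float)
            z = (age - age.mean()) / age.std()
            e = rng.normal(size=m)
            e = e - np.polyval(np.polyfit(z, e, 1), z)  # orthogonal noise
            me = 0.49 * z / np.linalg.norm(z) * np.linalg.norm(e) + e
            r = bicor_pair(me, age)
            if abs(r) < 0.5:
                out = module_trait_association(
                    pd.DataFrame({"M1": me}), pd.DataFrame({"age": age})
                )
                assert not out.iloc[0]["selected"]

    def test_constant_trait_raises(self):
        mes = pd.DataFrame({"M1": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            module_trait_association(mes, pd.DataFrame({"sex": np.zeros(10)}))


@pytest.fixture(scope="module")
def driven_module():
    rng = np.random.default_rng(11)
    m = 36
    age = np.repeat(np.arange(3.0, 28.0, 3.0), 4)
    e = (age - age.mean()) / age.std() + rng.normal(scale=0.3, size=m)
    lam = rng.uniform(0.5, 3.0, size=50)
    X = lam[:, None] * e[None, :] + rng.normal(size=(50, m))
    genes = [f"g{i}" for i in range(50)]
    labels = pd.Series(["M1"] * 50, index=genes)
    mes = module_eigengenes(X, genes, labels)
    return X, genes, labels, mes, age, lam


class TestGeneStatsAndHubs:
    def test_mmgs_correlation_high_for_trait_driver(self, driven_module):
        X, genes, labels, mes, age, lam = driven_module
        gstats, mstats = gene_module_stats(X, genes, labels, mes, age)
        assert mstats.iloc[0]["mmgs_r"] > 0.5
        assert mstats.iloc[0]["retained"]

    def test_gs_of_unrelated_gene_near_zero(self, rng):
        m = 36
        age = np.repeat(np.arange(3.0, 28.0, 3.0), 4)
        x = rng.normal(size=m)
        gs = abs(np.corrcoef(x, age)[0, 1])
        assert gs < 0.4  # sampling noise only

    def test_hub_thresholds_strict(self):
        gstats = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "module": ["M1"] * 3,
                "MM": [0.85, 0.85, 0.79],
                "GS": [0.2, 0.25, 0.9],
            }
        )
        hubs = hub_genes(gstats)
        assert hubs["M1"] == ["b"]  # GS exactly 0.2 excluded; MM 0.79 excluded

    def test_planted_hubs_recovered(self, driven_module):
        X, genes, labels, mes, age, lam = driven_module
        gstats, _ = gene_module_stats(X, genes, labels, mes, age)
        hubs = set(hub_genes(gstats)["M1"])
        planted = {g for g, l in zip(genes, lam) if l > 2.0}
        if planted:
            assert len(hubs & planted) / len(planted) >= 0.8
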