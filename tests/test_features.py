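"""Feature extraction vs independent oracles, plus pipeline structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import worktrack as wt
from worktrack.errors import EmptyClassError, NonFiniteMatrixError, UnlabeledStreamError
from worktrack.features import BasicWindow

from conftest import random_window


# --- independent oracles ----------------------------------------------------

def brute_mean_sd(values):
    """Two-pass textbook mean / sample SD, one channel at a time."""
    n, c = values.shape
    mu = np.empty(c)
    sd = np.empty(c)
    for j in range(c):
        mu[j] = sum(values[:, j]) / n
        sd[j] = math.sqrt(sum((x - mu[j]) ** 2 for x in values[:, j]) / (n - 1))
    return mu, sd


def brute_pearson(values):
    """Explicit double loop over channel pairs."""
    n, c = values.shape
    r = np.eye(c)
    for j in range(c):
        for k in range(j + 1, c):
            xj, xk = values[:, j], values[:, k]
            mj, mk = xj.mean(), xk.mean()
            num = float(np.sum((xj - mj) * (xk - mk)))
            den = math.sqrt(float(np.sum((xj - mj) ** 2)) * float(np.sum((xk - mk) ** 2)))
            r[j, k] = r[k, j] = num / den
    return r


def power_iteration(r, iters=50_000, tol=1e-15):
    """Dominant eigenvector by power iteration on the (PSD) correlation
    matrix, shifted by I so the iteration cannot stall on a zero eigenvalue."""
    c = r.shape[0]
    shifted = r + np.eye(c)
    v = np.ones(c) / math.sqrt(c)
    for _ in range(iters):
        nxt = shifted @ v
        nxt /= np.linalg.norm(nxt)
        if np.linalg.norm(nxt - v) < tol:
            v = nxt
            break
        v = nxt
    return v


def align_sign(v):
    pivot = int(np.argmax(np.abs(np.round(v, 12))))
    return -v if v[pivot] < 0 else v


# --- window statistics ------------------------------------------------------

class TestWindowStats:
    def test_constant_channel(self):
        w = BasicWindow(np.full((100, 9), 3.5), "S", 0, 0)
        mu, sd = wt.window_stats(w)
        assert np.allclose(mu, 3.5) and np.allclose(sd, 0.0)

    def test_alternating_channel_closed_form(self):
        values = np.zeros((100, 9))
        values[:, 0] = np.tile([1.0, -1.0], 50)
        mu, sd = wt.window_stats(BasicWindow(values, "S", 0, 0))
        assert mu[0] == pytest.approx(0.0, abs=1e-15)
        assert sd[0] == pytest.approx(math.sqrt(100 / 99))

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            w = random_window(rng)
            mu, sd = wt.window_stats(w)
            bmu, bsd = brute_mean_sd(w.values)
            assert np.allclose(mu, bmu, atol=1e-12)
            assert np.allclose(sd, bsd, atol=1e-12)


class TestPearson:
    def test_identical_channels_give_all_ones(self, rng):
        col = rng.standard_normal(100)
        r = wt.pearson_correlation_matrix(np.tile(col[:, None], (1, 9)))
        assert np.allclose(r, 1.0)

    def test_anticorrelated_pair(self, rng):
        values = rng.standard_normal((100, 9))
        values[:, 3] = -values[:, 1]
        r = wt.pearson_correlation_matrix(values)
        assert r[1, 3] == pytest.approx(-1.0)

    def test_zero_variance_channel_neutral(self, rng):
        values = rng.standard_normal((100, 9))
        values[:, 4] = 2.0
        r = wt.pearson_correlation_matrix(values)
        assert r[4, 4] == 1.0
        off = np.delete(r[4], 4)
        assert np.allclose(off, 0.0)
        assert np.allclose(r, r.T)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(30):
            w = random_window(rng)
            assert np.allclose(
                wt.pearson_correlation_matrix(w), brute_pearson(w.values), atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_correlation_matrix_invariants(self, seed):
        w = random_window(np.random.default_rng(seed))
        r = wt.pearson_correlation_matrix(w)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.all(r >= -1 - 1e-12) and np.all(r <= 1 + 1e-12)
        eig = np.linalg.eigvalsh(r)
        assert eig.sum() == pytest.approx(9.0)
        assert eig.min() > -1e-9  # PSD up to tolerance


class TestMaxEigenvector:
    def test_all_ones_matrix(self):
        eps = wt.max_eigenvector(np.ones((9, 9)))
        assert np.allclose(eps, 1.0 / 3.0)

    def test_identity_gives_unit_vector(self):
        eps = wt.max_eigenvector(np.eye(9))
        assert np.linalg.norm(eps) == pytest.approx(1.0)

    def test_matches_power_iteration_and_eigen_equation(self, rng):
        for _ in range(25):
            r = wt.pearson_correlation_matrix(random_window(rng))
            eps = wt.max_eigenvector(r)
            assert np.allclose(eps, align_sign(power_iteration(r)), atol=1e-9)
            lam = float(eps @ r @ eps)
            assert np.allclose(r @ eps, lam * eps, atol=1e-9)

    def test_sign_convention(self, rng):
        r = wt.pearson_correlation_matrix(random_window(rng))
        eps = wt.max_eigenvector(r)
        assert eps[int(np.argmax(np.abs(eps)))] > 0

    def test_non_finite_raises(self):
        bad = np.eye(9)
        bad[0, 1] = np.nan
        with pytest.raises(NonFiniteMatrixError):
            wt.max_eigenvector(bad)


# --- vectors, segmentation, assembly ---------------------------------------

class TestFeatureVectors:
    def test_27_vector_layout(self, rng):
        w = random_window(rng)
        v = wt.window_feature_vector(w, cooperativity=True)
        assert v.shape == (27,)
        eps = wt.max_eigenvector(wt.pearson_correlation_matrix(w))
        mu, sd = wt.window_stats(w)
        assert np.array_equal(v[:9], eps)
        assert np.array_equal(v[9:18], mu)
        assert np.array_equal(v[18:], sd)

    def test_18_vector_is_tail_of_27(self, rng):
        w = random_window(rng)
        v27 = wt.window_feature_vector(w, cooperativity=True)
        v18 = wt.window_feature_vector(w, cooperativity=False)
        assert v18.shape == (18,)
        assert np.array_equal(v18, v27[9:])

    def test_constant_window_degenerate(self):
        w = BasicWindow(np.ones((100, 9)), "S", 0, 0)
        v = wt.window_feature_vector(w, cooperativity=True)
        assert np.allclose(v[18:], 0.0)  # sigma block
        assert np.linalg.norm(v[:9]) == pytest.approx(1.0)


class TestSegmentation:
    def test_ten_minute_stream_gives_300_windows(self):
        stream = wt.SensorStream("S", np.arange(30_000) / 50.0,
                                 np.zeros((30_000, 9)))
        windows = wt.segment_basic_windows(stream)
        assert len(windows) == 300
        assert all(w.values.shape == (100, 9) for w in windows)

    def test_partial_trailing_block_dropped(self):
        stream = wt.SensorStream("S", np.arange(250) / 50.0, np.zeros((250, 9)))
        assert len(wt.segment_basic_windows(stream)) == 2

    def test_short_stream_empty(self):
        stream = wt.SensorStream("S", np.arange(99) / 50.0, np.zeros((99, 9)))
        assert wt.segment_basic_windows(stream) == []

    def test_windows_never_cross_episode_boundary(self, small_session):
        for w in wt.segment_basic_windows(small_session):
            span = small_session.episode_ids[w.start_sample : w.start_sample + 100]
            assert len(set(span.tolist())) == 1


class TestAssembly:
    def _features(self, count, episode=0, start=0):
        return [
            wt.WindowFeatures(np.full(18, i, float), "S", start + i, (start + i) * 100,
                              "Re", episode)
            for i in range(count)
        ]

    def test_groups_of_four(self):
        mats = wt.assemble_feature_matrices(self._features(300))
        assert len(mats) == 75
        assert mats[0].values.shape == (4, 18)

    def test_remainder_dropped(self):
        assert len(wt.assemble_feature_matrices(self._features(5))) == 1

    def test_no_matrix_mixes_episodes(self):
        feats = self._features(6, episode=0) + self._features(6, episode=1, start=6)
        mats = wt.assemble_feature_matrices(feats)
        assert len(mats) == 2
        assert {m.episode_id for m in mats} == {0, 1}


class TestDataset:
    def test_per_subject_class_counts(self, small_session):
        # 1-min episodes: 30 windows -> 7 samples each, 7 episodes
        ds = wt.build_dataset([small_session])
        assert len(ds) == 49

    def test_default_protocol_counts(self, cohort12):
        ds = wt.build_dataset([cohort12[0]])
        assert ds.class_counts() == {
            "W_N": 75, "St_N": 37, "Re": 44, "Ty": 44, "Wr": 44, "Si_N": 37, "L_N": 75}

    def test_cohort_counts_scale(self, dataset27):
        counts = dataset27.class_counts()
        assert counts == {c: n * 12 for c, n in
                          {"W_N": 75, "St_N": 37, "Re": 44, "Ty": 44,
                           "Wr": 44, "Si_N": 37, "L_N": 75}.items()}

    def test_18_mode_equals_27_mode_truncated(self, dataset27, dataset18):
        assert np.array_equal(dataset18.X, dataset27.X[:, :, 9:])
        assert np.array_equal(dataset18.labels, dataset27.labels)

    def test_empty_input_empty_dataset(self):
        assert len(wt.build_dataset([])) == 0

    def test_unlabeled_stream_rejected(self):
        stream = wt.SensorStream("S", np.arange(200) / 50.0, np.zeros((200, 9)))
        with pytest.raises(UnlabeledStreamError):
            wt.build_dataset([stream])

    def test_pipeline_deterministic(self, small_session):
        a = wt.build_dataset([small_session])
        b = wt.build_dataset([small_session])
        assert np.array_equal(a.X, b.X)


class TestClassMeans:
    def test_mean_of_identical_samples(self):
        x = np.random.default_rng(0).standard_normal((4, 18))
        ds = wt.Dataset(np.stack([x, x]), np.array(["Re", "Re"], object),
                        np.array(["S", "S"], object), 18)
        assert np.allclose(wt.class_mean_matrix(ds, "Re"), x)

    def test_absent_class_raises(self, dataset18):
        ds = dataset18.subset(dataset18.labels == "Re")
        with pytest.raises(EmptyClassError):
            wt.class_mean_matrix(ds, "W_N")
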