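"""Feature catalogues, extraction, recurrence measures, forest screening."""

import math

import numpy as np
import pytest

from popai.errors import FeatureError, PopaiError
from popai.features import (
    CHANNELS,
    CRQA_STATS,
    REGISTRY_VERSION,
    MinuteWindow,
    build_registry,
    crqa_measures,
    extract_features,
    rank_features_rf,
)

FS = 10.0


def _window(data):
    return MinuteWindow(np.asarray(data, dtype=float), FS)


def _noise_window(seed=0, scale=0.05):
    rng = np.random.default_rng(seed)
    return _window(rng.standard_normal((600, 3)) * scale)


class TestRegistry:
    @pytest.mark.parametrize("set_id,size", [(1, 563), (2, 213), (3, 52)])
    def test_catalogue_sizes(self, set_id, size):
        reg = build_registry(set_id)
        assert len(reg) == size
        assert reg.version == REGISTRY_VERSION

    def test_set2_is_time_domain_subset_of_set1(self):
        s1, s2 = build_registry(1), build_registry(2)
        assert set(s2.names) <= set(s1.names)
        # set 1 minus set 2 is exactly the frequency-domain part
        extra = set(s1.names) - set(s2.names)
        assert len(extra) == 563 - 213
        assert all(("bp_" in n) or ("spec" in n) or ("freq" in n) or ("band" in n) or ("power" in n)
                   for n in extra)

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError):
            build_registry(4)


class TestExtraction:
    def test_full_vector_lengths(self):
        w = _noise_window()
        assert len(extract_features(w, 1)) == 563
        assert len(extract_features(w, 2)) == 213
        assert len(extract_features(w, 3)) == 52

    def test_constant_zero_window(self):
        f = extract_features(_window(np.zeros((600, 3))), 2)
        for ch in CHANNELS:
            assert f[f"{ch}__mean"] == 0.0
            assert f[f"{ch}__var"] == 0.0
            assert f[f"{ch}__range"] == 0.0
            assert f[f"{ch}__entropy"] == 0.0

    def test_sinusoid_dominant_frequency(self):
        t = np.arange(600) / FS
        data = np.zeros((600, 3))
        data[:, 0] = np.sin(2 * np.pi * 1.0 * t)
        f = extract_features(_window(data), 1, subset=["x__dominant_freq"])
        assert f["x__dominant_freq"] == pytest.approx(1.0)

    def test_nan_names_offending_channel(self):
        data = np.zeros((600, 3))
        data[5, 1] = np.nan
        with pytest.raises(FeatureError, match="'y'"):
            extract_features(_window(data), 2)

    def test_all_values_finite_on_noise(self):
        f = extract_features(_noise_window(3), 1)
        assert all(math.isfinite(v) for v in f.values())

    def test_correlation_features_affine_invariant(self):
        """Cross-axis correlations are invariant to per-axis affine
        scaling (documented scale consistency)."""
        w = _noise_window(5)
        scaled = _window(w.data * np.array([3.0, 0.5, 7.0]) + np.array([1.0, -2.0, 0.1]))
        sub = ["cross__corr_xy", "cross__corr_xz", "cross__corr_yz"]
        f1 = extract_features(w, 2, subset=sub)
        f2 = extract_features(scaled, 2, subset=sub)
        for k in sub:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)

    def test_subset_matches_full_extraction(self):
        w = _noise_window(9)
        full = extract_features(w, 1)
        sub = ["vm__std", "x__mean", "z__spectral_entropy", "cross__sma"]
        part = extract_features(w, 1, subset=sub)
        for k in sub:
            assert part[k] == full[k]


# ---------------------------------------------------------------------------
# recurrence quantification: independent exhaustive oracle
# ---------------------------------------------------------------------------


def _crqa_oracle(x, dim, delay, radius, min_line):
    """Naive enumeration of the recurrence matrix and all line structures;
    intentionally written with explicit loops, independent of the
    vectorized implementation."""
    n = len(x) - (dim - 1) * delay
    pts = [[x[i + j * delay] for j in range(dim)] for i in range(n)]
    dmax = 0.0
    for i in range(n):
        for j in range(n):
            d = math.dist(pts[i], pts[j])
            dmax = max(dmax, d)
    eps = radius * dmax
    R = [[math.dist(pts[i], pts[j]) <= eps for j in range(n)] for i in range(n)]
    off = sum(R[i][j] for i in range(n) for j in range(n) if i != j)
    rr = off / (n * n - n) if n > 1 else 0.0

    def runs(seq):
        out, cur = [], 0
        for v in seq:
            if v:
                cur += 1
            elif cur:
                out.append(cur)
                cur = 0
        if cur:
            out.append(cur)
        return out

    diag = []
    for o in range(1, n):
        diag += runs([R[i][i + o] for i in range(n - o)])
    diag = diag + diag  # both triangles
    diag_keep = [l for l in diag if l >= min_line]
    vert = []
    white = []
    for j in range(n):
        col = [R[i][j] for i in range(n)]
        col[j] = True
        vert += runs(col)
        col[j] = False
        white += runs([not R[i][j] if i != j else False for i in range(n)])
    vert_keep = [l for l in vert if l >= min_line]

    def entr(ls):
        if not ls:
            return 0.0
        from collections import Counter

        c = Counter(ls)
        tot = sum(c.values())
        return -sum((v / tot) * math.log(v / tot) for v in c.values())

    det = min(sum(diag_keep) / off, 1.0) if off else 0.0
    lam = min(sum(vert_keep) / off, 1.0) if off else 0.0
    return {
        "recurrence_rate": rr,
        "determinism": det,
        "diag_mean": float(np.mean(diag_keep)) if diag_keep else 0.0,
        "diag_max": float(max(diag_keep)) if diag_keep else 0.0,
        "diag_entropy": entr(diag_keep),
        "laminarity": lam,
        "trapping_time": float(np.mean(vert_keep)) if vert_keep else 0.0,
        "vert_max": float(max(vert_keep)) if vert_keep else 0.0,
        "vert_entropy": entr(vert_keep),
        "mean_rec_time": float(np.mean(white)) if white else 0.0,
        "rec_time_entropy": entr(white),
    }


class TestCRQA:
    def test_constant_signal_recurs_everywhere(self):
        m = crqa_measures(np.ones(40), embedding_dim=2, delay=1, radius=0.1)
        assert m["recurrence_rate"] == 1.0
        # the single length-1 corner diagonal falls below min_line=2
        assert m["determinism"] == pytest.approx(1.0, abs=0.01)

    def test_noise_vanishing_radius(self):
        rng = np.random.default_rng(1)
        m = crqa_measures(rng.standard_normal(60), radius=1e-12)
        assert m["recurrence_rate"] == pytest.approx(0.0)
        assert m["determinism"] == 0.0
        assert m["diag_max"] == 0.0

    def test_too_short_signal_rejected(self):
        with pytest.raises(FeatureError):
            crqa_measures(np.arange(5.0), embedding_dim=4, delay=8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize(
        "dim,delay,radius", [(2, 1, 0.5), (3, 2, 0.2), (4, 8, 0.1)]
    )
    def test_matches_exhaustive_oracle(self, seed, dim, delay, radius):
        rng = np.random.default_rng(seed)
        x = np.round(rng.standard_normal(46), 3)
        got = crqa_measures(x, embedding_dim=dim, delay=delay, radius=radius, min_line=2)
        want = _crqa_oracle(list(x), dim, delay, radius, 2)
        for key, expected in want.items():
            assert got[key] == pytest.approx(expected, abs=1e-12), key

    def test_toy_series_frozen_values(self):
        """8-sample toy series, dim 2, delay 1, radius 0.5 — values frozen
        from the exhaustive enumeration."""
        x = [0.0, 1.0, 0.0, 1.0, 0.5, 0.0, 1.0, 0.0]
        got = crqa_measures(np.array(x), embedding_dim=2, delay=1, radius=0.5)
        want = _crqa_oracle(x, 2, 1, 0.5, 2)
        assert got["recurrence_rate"] == pytest.approx(want["recurrence_rate"])
        assert got["recurrence_rate"] == pytest.approx(18 / 42)
        assert got["determinism"] == pytest.approx(want["determinism"])


class TestForestScreen:
    def test_top_100_of_563(self):
        rng = np.random.default_rng(0)
        names = build_registry(1).names
        import pandas as pd

        X = pd.DataFrame(rng.standard_normal((120, 563)), columns=list(names))
        y = rng.integers(0, 2, 120)
        kept = rank_features_rf(X, y, n_keep=100, seed=0, n_estimators=30)
        assert len(kept) == 100
        assert len(set(kept)) == 100

    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(4)
        import pandas as pd

        y = rng.integers(0, 2, 500)
        X = pd.DataFrame(rng.standard_normal((500, 10)), columns=[f"f{i}" for i in range(10)])
        X["sep"] = y * 10.0 + rng.standard_normal(500) * 0.01
        kept = rank_features_rf(X, y, n_keep=3, seed=0)
        assert kept[0] == "sep"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        import pandas as pd

        X = pd.DataFrame(rng.standard_normal((200, 30)))
        X.columns = [f"f{i}" for i in range(30)]
        y = (X["f3"] + 0.5 * X["f7"] > 0).astype(int)
        a = rank_features_rf(X, y, n_keep=10, seed=11)
        b = rank_features_rf(X, y, n_keep=10, seed=11)
        assert a == b

    def test_single_class_rejected(self):
        import pandas as pd

        X = pd.DataFrame(np.zeros((10, 3)))
        with pytest.raises(PopaiError):
            rank_features_rf(X, np.zeros(10), n_keep=2)
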