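"""Signal features for 1-minute raw-acceleration windows.

Three feature catalogues are defined over the channels x, y, z and the
vector magnitude (vm):

* **Set 1** (563): all time-domain features of Set 2 plus per-channel
  frequency-domain features (relative band powers and spectral summary
  statistics) and cross-channel spectral features;
* **Set 2** (213): per-channel time-domain statistics (moments,
  percentiles, crossings, autocorrelations, jerk statistics, rolling
  activity measures) plus cross-axis correlations; Set 2 is exactly the
  time-domain subset of Set 1;
* **Set 3** (52): recurrence-quantification measures (recurrence rate,
  determinism, line-length statistics, laminarity, trapping time,
  recurrence times) of each channel's time-delay embedding.

The catalogue composition is the registry's single source of truth; the
set sizes are enforced at registry construction. A random-forest screen
(:func:`rank_features_rf`) orders features by impurity importance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FeatureError, PopaiError
from .sensor_io import RawRecording

__all__ = [
    "MinuteWindow",
    "FeatureRegistry",
    "build_registry",
    "extract_features",
    "crqa_measures",
    "rank_features_rf",
    "REGISTRY_VERSION",
    "CHANNELS",
    "TIME_STATS",
    "FREQ_STATS",
    "CRQA_STATS",
]

REGISTRY_VERSION = "1.0"
CHANNELS = ("x", "y", "z", "vm")

EXPECTED_SIZES = {1: 563, 2: 213, 3: 52}


# ---------------------------------------------------------------------------
# window container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MinuteWindow:
    """60 s of tri-axial raw acceleration.

    ``truncated`` marks windows clipped at a recording edge (sub-minute
    events near the start/end of a recording); they are still usable.
    """

    data: np.ndarray  # (n, 3) in g
    sampling_rate: float
    truncated: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise FeatureError("window must have shape (n, 3)")
        object.__setattr__(self, "data", arr)

    @classmethod
    def from_raw(cls, raw: RawRecording, start_s: float) -> "MinuteWindow":
        """Extract the 60-s window starting at ``start_s`` (clipped to the
        recording; windows may begin before t=0 for centred sub-minute
        events)."""
        expected = int(round(60.0 * raw.sampling_rate))
        data = raw.slice_seconds(start_s, start_s + 60.0)
        return cls(data, raw.sampling_rate, truncated=len(data) < expected)

    def channels(self) -> dict[str, np.ndarray]:
        x, y, z = self.data[:, 0], self.data[:, 1], self.data[:, 2]
        return {"x": x, "y": y, "z": z, "vm": np.sqrt(x * x + y * y + z * z)}


# ---------------------------------------------------------------------------
# per-channel time-domain statistics (52 names)
# ---------------------------------------------------------------------------

_AUTOCORR_LAGS = (1, 2, 5, 10, 20, 50)

TIME_STATS: tuple[str, ...] = (
    "mean", "std", "var", "median", "min", "max", "range", "iqr", "mad",
    "rms", "energy", "skew", "kurtosis", "cv",
    "p5", "p10", "p25", "p75", "p90", "p95", "p95_minus_p5",
    "zero_crossings", "mean_crossings", "slope", "abs_mean", "abs_max",
    "entropy", "n_peaks", "crest_factor", "impulse_factor", "shape_factor",
    "margin_factor", "frac_above_mean", "longest_run_above_mean",
    *(f"autocorr_lag{l}" for l in _AUTOCORR_LAGS),
    "jerk_mean_abs", "jerk_std", "jerk_max_abs", "jerk_rms", "jerk_skew",
    "jerk_kurtosis", "jerk_zero_crossings", "turning_points",
    "mean_abs_dev", "rolling_std_mean", "rolling_std_max",
    "activity_fraction",
)

CROSS_TIME_STATS: tuple[str, ...] = (
    "corr_xy", "corr_xz", "corr_yz", "sma", "tilt_mean",
)


def _safe_div(a: float, b: float) -> float:
    return a / b if b != 0 else 0.0


def _autocorr(x: np.ndarray, lag: int) -> float:
    n = len(x)
    if lag >= n:
        return 0.0
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        return 0.0
    return float(np.dot(xc[:-lag], xc[lag:]) / denom)


def _hist_entropy(x: np.ndarray, bins: int = 16) -> float:
    if np.ptp(x) == 0:
        return 0.0
    h, _ = np.histogram(x, bins=bins)
    p = h / h.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _time_stats(x: np.ndarray, fs: float) -> dict[str, float]:
    n = len(x)
    mean = float(x.mean())
    std = float(x.std())
    mn, mx = float(x.min()), float(x.max())
    q = np.percentile(x, [5, 10, 25, 50, 75, 90, 95])
    absx = np.abs(x)
    rms = float(np.sqrt(np.mean(x * x)))
    abs_mean = float(absx.mean())
    xc = x - mean
    if std > 0:
        skew = float(np.mean(xc**3) / std**3)
        kurt = float(np.mean(xc**4) / std**4)
    else:
        skew = kurt = 0.0
    jerk = np.diff(x) * fs if n > 1 else np.zeros(1)
    jstd = float(jerk.std())
    jc = jerk - jerk.mean()
    jskew = float(np.mean(jc**3) / jstd**3) if jstd > 0 else 0.0
    jkurt = float(np.mean(jc**4) / jstd**4) if jstd > 0 else 0.0
    above = x > mean
    sec = int(round(fs))
    if sec >= 1 and n >= sec:
        nblk = n // sec
        blk_std = x[: nblk * sec].reshape(nblk, sec).std(axis=1)
    else:
        blk_std = np.array([std])
    t = np.arange(n)
    slope = float(np.polyfit(t, x, 1)[0]) * fs if n > 1 and np.ptp(x) > 0 else 0.0
    d = np.diff(x)
    sign_d = np.sign(d)
    turning = int(np.sum(sign_d[:-1] * sign_d[1:] < 0)) if len(d) > 1 else 0
    peaks = int(
        np.sum((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]) & (x[1:-1] > mean + std))
    ) if n > 2 else 0
    out = {
        "mean": mean,
        "std": std,
        "var": std**2,
        "median": float(q[3]),
        "min": mn,
        "max": mx,
        "range": mx - mn,
        "iqr": float(q[4] - q[2]),
        "mad": float(np.median(np.abs(x - q[3]))),
        "rms": rms,
        "energy": rms**2,
        "skew": skew,
        "kurtosis": kurt,
        "cv": _safe_div(std, abs(mean)),
        "p5": float(q[0]),
        "p10": float(q[1]),
        "p25": float(q[2]),
        "p75": float(q[4]),
        "p90": float(q[5]),
        "p95": float(q[6]),
        "p95_minus_p5": float(q[6] - q[0]),
        "zero_crossings": float(np.sum(np.abs(np.diff(np.sign(x))) > 0)),
        "mean_crossings": float(np.sum(np.abs(np.diff(np.sign(xc))) > 0)),
        "slope": slope,
        "abs_mean": abs_mean,
        "abs_max": float(absx.max()),
        "entropy": _hist_entropy(x),
        "n_peaks": float(peaks),
        "crest_factor": _safe_div(float(absx.max()), rms),
        "impulse_factor": _safe_div(float(absx.max()), abs_mean),
        "shape_factor": _safe_div(rms, abs_mean),
        "margin_factor": _safe_div(float(absx.max()), float(np.mean(np.sqrt(absx)) ** 2)),
        "frac_above_mean": float(above.mean()),
        "longest_run_above_mean": float(_longest_run(above)),
        "jerk_mean_abs": float(np.abs(jerk).mean()),
        "jerk_std": jstd,
        "jerk_max_abs": float(np.abs(jerk).max()),
        "jerk_rms": float(np.sqrt(np.mean(jerk * jerk))),
        "jerk_skew": jskew,
        "jerk_kurtosis": jkurt,
        "jerk_zero_crossings": float(np.sum(np.abs(np.diff(np.sign(jerk))) > 0)),
        "turning_points": float(turning),
        "mean_abs_dev": float(np.abs(xc).mean()),
        "rolling_std_mean": float(blk_std.mean()),
        "rolling_std_max": float(blk_std.max()),
        "activity_fraction": float((blk_std > 0.01).mean()),
    }
    for lag in _AUTOCORR_LAGS:
        out[f"autocorr_lag{lag}"] = _autocorr(x, lag)
    return out


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _cross_time_stats(ch: Mapping[str, np.ndarray]) -> dict[str, float]:
    x, y, z, vm = ch["x"], ch["y"], ch["z"], ch["vm"]
    with np.errstate(invalid="ignore"):
        tilt = np.arccos(np.clip(_safe_vm_ratio(x, vm), -1.0, 1.0))
    return {
        "corr_xy": _corr(x, y),
        "corr_xz": _corr(x, z),
        "corr_yz": _corr(y, z),
        "sma": float(np.mean(np.abs(x) + np.abs(y) + np.abs(z))),
        "tilt_mean": float(np.mean(tilt)),
    }


def _safe_vm_ratio(x: np.ndarray, vm: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    nz = vm > 0
    out[nz] = x[nz] / vm[nz]
    return out


# ---------------------------------------------------------------------------
# per-channel frequency-domain statistics (86 names)
# ---------------------------------------------------------------------------

N_BANDS = 70

FREQ_SUMMARIES: tuple[str, ...] = (
    "dominant_freq", "dominant_power_ratio", "second_peak_freq",
    "spectral_entropy", "spectral_centroid", "spectral_spread",
    "spectral_skewness", "spectral_kurtosis", "spectral_rolloff85",
    "spectral_rolloff95", "median_freq", "spectral_flatness",
    "power_total", "low_band_power", "mid_band_power", "high_band_power",
)

FREQ_STATS: tuple[str, ...] = tuple(
    f"bp_{i:02d}" for i in range(N_BANDS)
) + FREQ_SUMMARIES

CROSS_FREQ_STATS: tuple[str, ...] = (
    "speccorr_xy", "speccorr_xz", "speccorr_yz",
    "domfreq_diff_xy", "domfreq_diff_xz", "domfreq_diff_yz",
)


def _spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    xc = x - x.mean()
    psd = np.abs(np.fft.rfft(xc)) ** 2 / len(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return freqs[1:], psd[1:]  # drop DC


def _freq_stats(x: np.ndarray, fs: float) -> dict[str, float]:
    freqs, psd = _spectrum(x, fs)
    total = float(psd.sum())
    nyq = fs / 2.0
    out: dict[str, float] = {}
    edges = np.linspace(0.0, nyq, N_BANDS + 1)
    if total == 0 or len(freqs) == 0:
        for i in range(N_BANDS):
            out[f"bp_{i:02d}"] = 0.0
        for name in FREQ_SUMMARIES:
            out[name] = 0.0
        return out
    p = psd / total
    idx = np.clip(np.searchsorted(edges, freqs, side="right") - 1, 0, N_BANDS - 1)
    bp = np.bincount(idx, weights=p, minlength=N_BANDS)
    for i in range(N_BANDS):
        out[f"bp_{i:02d}"] = float(bp[i])
    k = int(np.argmax(psd))
    dom_f = float(freqs[k])
    psd2 = psd.copy()
    lo, hi = max(k - 1, 0), min(k + 2, len(psd))
    psd2[lo:hi] = 0.0
    second = float(freqs[int(np.argmax(psd2))]) if psd2.max() > 0 else 0.0
    centroid = float(np.sum(freqs * p))
    spread = float(np.sqrt(np.sum((freqs - centroid) ** 2 * p)))
    if spread > 0:
        sskew = float(np.sum(((freqs - centroid) / spread) ** 3 * p))
        skurt = float(np.sum(((freqs - centroid) / spread) ** 4 * p))
    else:
        sskew = skurt = 0.0
    cum = np.cumsum(p)
    out.update(
        {
            "dominant_freq": dom_f,
            "dominant_power_ratio": float(psd[k] / total),
            "second_peak_freq": second,
            "spectral_entropy": float(-(p[p > 0] * np.log(p[p > 0])).sum()),
            "spectral_centroid": centroid,
            "spectral_spread": spread,
            "spectral_skewness": sskew,
            "spectral_kurtosis": skurt,
            "spectral_rolloff85": float(freqs[int(np.searchsorted(cum, 0.85))]) if cum[-1] >= 0.85 else float(freqs[-1]),
            "spectral_rolloff95": float(freqs[min(int(np.searchsorted(cum, 0.95)), len(freqs) - 1)]),
            "median_freq": float(freqs[min(int(np.searchsorted(cum, 0.5)), len(freqs) - 1)]),
            "spectral_flatness": float(np.exp(np.mean(np.log(psd[psd > 0]))) / psd.mean()) if np.all(psd >= 0) and psd.mean() > 0 else 0.0,
            "power_total": total / len(x),
            "low_band_power": float(p[freqs <= 0.5].sum()),
            "mid_band_power": float(p[(freqs > 0.5) & (freqs <= 2.0)].sum()),
            "high_band_power": float(p[freqs > 2.0].sum()),
        }
    )
    return out


def _cross_freq_stats(ch: Mapping[str, np.ndarray], fs: float) -> dict[str, float]:
    spec = {}
    domf = {}
    for name in ("x", "y", "z"):
        freqs, psd = _spectrum(ch[name], fs)
        spec[name] = psd
        domf[name] = float(freqs[int(np.argmax(psd))]) if len(psd) and psd.max() > 0 else 0.0
    return {
        "speccorr_xy": _corr(spec["x"], spec["y"]),
        "speccorr_xz": _corr(spec["x"], spec["z"]),
        "speccorr_yz": _corr(spec["y"], spec["z"]),
        "domfreq_diff_xy": abs(domf["x"] - domf["y"]),
        "domfreq_diff_xz": abs(domf["x"] - domf["z"]),
        "domfreq_diff_yz": abs(domf["y"] - domf["z"]),
    }


# ---------------------------------------------------------------------------
# recurrence quantification (13 names per channel)
# ---------------------------------------------------------------------------

CRQA_STATS: tuple[str, ...] = (
    "recurrence_rate", "determinism", "diag_mean", "diag_max",
    "diag_entropy", "divergence", "ratio_det_rr", "laminarity",
    "trapping_time", "vert_max", "vert_entropy", "mean_rec_time",
    "rec_time_entropy",
)


def _line_lengths_diag(R: np.ndarray) -> list[int]:
    """Lengths of diagonal recurrent lines, excluding the main diagonal."""
    n = R.shape[0]
    lengths: list[int] = []
    for off in range(1, n):
        diag = np.diagonal(R, offset=off)
        lengths.extend(_run_lengths(diag))
    # symmetric matrix: count both triangles like the full-matrix convention
    return lengths + list(lengths)


def _run_lengths(mask: np.ndarray) -> list[int]:
    out = []
    cur = 0
    for v in mask:
        if v:
            cur += 1
        elif cur:
            out.append(cur)
            cur = 0
    if cur:
        out.append(cur)
    return out


def _vertical_lengths(R: np.ndarray, recurrent: bool) -> list[int]:
    n = R.shape[0]
    out: list[int] = []
    for j in range(n):
        col = R[:, j].copy()
        col[j] = True  # trivial self-recurrence: never counts as white
        out.extend(_run_lengths(col if recurrent else ~col))
    return out


def _entropy_of_lengths(lengths: Sequence[int]) -> float:
    if not lengths:
        return 0.0
    vals, counts = np.unique(np.asarray(lengths), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def crqa_measures(
    signal: np.ndarray,
    embedding_dim: int = 4,
    delay: int = 8,
    radius: float = 0.1,
    min_line: int = 2,
) -> dict[str, float]:
    """Recurrence-quantification measures of a time-delay embedded signal.

    ``radius`` is a fraction of the maximum pairwise distance in the
    embedded space (so a constant signal, where that maximum is 0, recurs
    everywhere and has recurrence rate 1). The main diagonal (trivial
    self-recurrence) is excluded from the recurrence rate and all line
    structures. Degenerate cases are given defined fallbacks: with no
    recurrent point off the diagonal, determinism, laminarity, line
    statistics and entropies are 0, as is the divergence.
    """
    x = np.asarray(signal, dtype=float)
    n_emb = len(x) - (embedding_dim - 1) * delay
    if n_emb < 2:
        raise FeatureError(
            f"signal of length {len(x)} too short for dim={embedding_dim}, "
            f"delay={delay}"
        )
    emb = np.column_stack([x[i * delay : i * delay + n_emb] for i in range(embedding_dim)])
    d2 = np.sum((emb[:, None, :] - emb[None, :, :]) ** 2, axis=-1)
    dist = np.sqrt(np.maximum(d2, 0.0))
    eps = radius * float(dist.max())
    R = dist <= eps
    n = n_emb
    off_diag = R.sum() - n  # main diagonal always recurs
    denom = n * n - n
    rr = float(off_diag / denom) if denom else 0.0

    diag_lengths = [l for l in _line_lengths_diag(R) if l >= min_line]
    vert_rec = [l for l in _vertical_lengths(R, recurrent=True) if l >= min_line]
    white = _vertical_lengths(R, recurrent=False)

    diag_points = sum(diag_lengths)
    det = _safe_div(diag_points, off_diag) if off_diag > 0 else 0.0
    lmax = max(diag_lengths) if diag_lengths else 0
    vert_points = sum(vert_rec)
    lam = _safe_div(vert_points, R.sum() - n) if off_diag > 0 else 0.0
    return {
        "recurrence_rate": rr,
        "determinism": float(min(det, 1.0)),
        "diag_mean": float(np.mean(diag_lengths)) if diag_lengths else 0.0,
        "diag_max": float(lmax),
        "diag_entropy": _entropy_of_lengths(diag_lengths),
        "divergence": _safe_div(1.0, lmax),
        "ratio_det_rr": _safe_div(det, rr),
        "laminarity": float(min(lam, 1.0)),
        "trapping_time": float(np.mean(vert_rec)) if vert_rec else 0.0,
        "vert_max": float(max(vert_rec)) if vert_rec else 0.0,
        "vert_entropy": _entropy_of_lengths(vert_rec),
        "mean_rec_time": float(np.mean(white)) if white else 0.0,
        "rec_time_entropy": _entropy_of_lengths(white),
    }


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered catalogue of feature names for one feature set."""

    set_id: int
    names: tuple[str, ...]
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        expected = EXPECTED_SIZES[self.set_id]
        if len(self.names) != expected:
            raise FeatureError(
                f"feature set {self.set_id} has {len(self.names)} features, "
                f"expected {expected}"
            )
        if len(set(self.names)) != len(self.names):
            raise FeatureError("duplicate feature names in registry")

    def __len__(self) -> int:
        return len(self.names)


def _set2_names() -> tuple[str, ...]:
    names = [f"{ch}__{st}" for ch in CHANNELS for st in TIME_STATS]
    names += [f"cross__{st}" for st in CROSS_TIME_STATS]
    return tuple(names)


def _set1_names() -> tuple[str, ...]:
    names = list(_set2_names())
    names += [f"{ch}__{st}" for ch in CHANNELS for st in FREQ_STATS]
    names += [f"cross__{st}" for st in CROSS_FREQ_STATS]
    return tuple(names)


def _set3_names() -> tuple[str, ...]:
    return tuple(f"{ch}__crqa_{st}" for ch in CHANNELS for st in CRQA_STATS)


def build_registry(set_id: int) -> FeatureRegistry:
    """Build the registry for feature set 1, 2 or 3 (sizes 563/213/52)."""
    builders = {1: _set1_names, 2: _set2_names, 3: _set3_names}
    if set_id not in builders:
        raise ValueError(f"unknown feature set {set_id}")
    return FeatureRegistry(set_id=set_id, names=builders[set_id]())


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

_CRQA_TARGET_POINTS = 120  # embed on a decimated signal to bound the matrix


def extract_features(
    window: MinuteWindow,
    set_id: int = 1,
    subset: Sequence[str] | None = None,
    crqa_params: dict | None = None,
) -> dict[str, float]:
    """Compute the feature vector of one window.

    With ``subset`` only the named features are returned (in that order);
    feature groups not needed by the subset are skipped, which is how
    inference on a trained model with few selected features stays fast.
    NaNs in the signal raise :class:`FeatureError` naming the channel.
    """
    ch = window.channels()
    for name, sig in ch.items():
        if np.any(~np.isfinite(sig)):
            raise FeatureError(f"non-finite samples in channel {name!r}")
    registry = build_registry(set_id)
    wanted = list(subset) if subset is not None else list(registry.names)
    unknown = set(wanted) - set(registry.names)
    if unknown:
        raise FeatureError(f"features not in set {set_id}: {sorted(unknown)}")

    need_time = any("__" in w and w.split("__")[1] in TIME_STATS for w in wanted)
    need_cross_t = any(w.startswith("cross__") and w[7:] in CROSS_TIME_STATS for w in wanted)
    need_freq = any(w.split("__")[1] in FREQ_STATS for w in wanted if not w.startswith("cross__"))
    need_cross_f = any(w.startswith("cross__") and w[7:] in CROSS_FREQ_STATS for w in wanted)
    need_crqa = any("__crqa_" in w for w in wanted)

    ch_wanted = {w.split("__")[0] for w in wanted if not w.startswith("cross__")}
    use_channels = [c for c in CHANNELS if c in ch_wanted or subset is None]

    values: dict[str, float] = {}
    fs = window.sampling_rate
    if need_time:
        for cname in use_channels:
            for k, v in _time_stats(ch[cname], fs).items():
                values[f"{cname}__{k}"] = v
    if need_cross_t:
        for k, v in _cross_time_stats(ch).items():
            values[f"cross__{k}"] = v
    if need_freq:
        for cname in use_channels:
            for k, v in _freq_stats(ch[cname], fs).items():
                values[f"{cname}__{k}"] = v
    if need_cross_f:
        for k, v in _cross_freq_stats(ch, fs).items():
            values[f"cross__{k}"] = v
    if need_crqa:
        params = dict(embedding_dim=4, delay=8, radius=0.1, min_line=2)
        if crqa_params:
            params.update(crqa_params)
        for cname in use_channels:
            sig = ch[cname]
            stride = max(1, int(np.ceil(len(sig) / _CRQA_TARGET_POINTS)))
            for k, v in crqa_measures(sig[::stride], **params).items():
                values[f"{cname}__crqa_{k}"] = v
    out = {name: values[name] for name in wanted}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise FeatureError(f"non-finite feature values: {bad}")
    return out


def extract_feature_matrix(
    windows: Iterable[MinuteWindow],
    set_id: int = 1,
    subset: Sequence[str] | None = None,
) -> "pd.DataFrame":
    import pandas as pd

    rows = [extract_features(w, set_id=set_id, subset=subset) for w in windows]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-forest screening
# ---------------------------------------------------------------------------


def rank_features_rf(
    feature_matrix,
    labels,
    n_keep: int = 100,
    seed: int = 0,
    n_estimators: int = 200,
) -> list[str]:
    """Order features by impurity importance of a seeded random forest and
    return the top ``n_keep`` names.

    Ties are broken by column order, so the result is deterministic for a
    given seed.
    """
    import pandas as pd
    from sklearn.ensemble import RandomForestClassifier

    X = pd.DataFrame(feature_matrix)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise PopaiError("feature ranking needs at least two classes")
    if n_keep > X.shape[1]:
        raise ValueError(f"n_keep={n_keep} exceeds {X.shape[1]} features")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), y)
    imp = rf.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return [X.columns[i] for i in order[:n_keep]]
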