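"""Windowed feature extraction: 15 features per axis, 45 per window.

Features are computed on non-overlapping 2-s windows (100 samples at 50 Hz)
taken inside approximately stationary segments. Per axis, in frozen order:

==== =========================================
 0   standard deviation
 1-4 band power in 0.3-2, 4-8, 8-12, 0.2-14 Hz
 5-12 dominant-peak frequency and height in the same four bands
       (freq, height per band, band-major order)
 13  sample entropy (m=2, r=0.2*SD)
 14  spectral entropy (0.2-25 Hz, DC excluded, normalized to [0, 1])
==== =========================================

The three axis blocks are concatenated x, y, z. Spectral quantities use a
single Hann-tapered periodogram per window (0.5 Hz bin resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import RawRecording, label_windows, AnnotationTrack
from .preprocess import SegmentBoundaries

RATE_HZ = 50.0
WINDOW_S = 2.0
WINDOW_N = int(WINDOW_S * RATE_HZ)  # 100 samples

BANDS = ((0.3, 2.0), (4.0, 8.0), (8.0, 12.0), (0.2, 14.0))
SPECTRAL_ENTROPY_BAND = (0.2, 25.0)

_PER_AXIS = (
    ["sd"]
    + [f"bp_{lo:g}_{hi:g}" for lo, hi in BANDS]
    + [x for lo, hi in BANDS for x in (f"pf_{lo:g}_{hi:g}", f"ph_{lo:g}_{hi:g}")]
    + ["sampen", "spec_ent"]
)
FEATURE_NAMES = tuple(f"{ax}_{name}" for ax in "xyz" for name in _PER_AXIS)
assert len(FEATURE_NAMES) == 45


# ---------------------------------------------------------------------------
# windowing


def window_segments(rec: RawRecording, segments: SegmentBoundaries) -> pd.DataFrame:
    """Tile each stationary segment with contiguous non-overlapping 2-s
    windows from the segment start; trailing partial windows are dropped."""
    rows = []
    for seg_id, (s, e) in enumerate(segments.segments):
        k = int(np.floor((e - s) / WINDOW_S + 1e-9))
        for i in range(k):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "start": s + i * WINDOW_S,
                    "end": s + (i + 1) * WINDOW_S,
                    "segment_id": seg_id,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "start", "end", "segment_id"])


# ---------------------------------------------------------------------------
# spectral primitives


def _periodogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    freqs, psd = sps.periodogram(x, fs=RATE_HZ, window="hann", scaling="density")
    return freqs, psd


def band_power(
    x: np.ndarray, band: tuple[float, float], _psd: tuple | None = None
) -> float:
    """Integral of the Hann-tapered one-sided periodogram over ``band``."""
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band lo {lo} >= hi {hi}")
    if not (0 < lo and hi <= RATE_HZ / 2):
        raise ValueError(f"band {band} outside (0, {RATE_HZ / 2}] Hz")
    freqs, psd = _psd if _psd is not None else _periodogram(np.asarray(x, float))
    df = freqs[1] - freqs[0]
    # half-open bins [lo, hi): adjacent printed bands (e.g. 4-8 and 8-12 Hz)
    # stay disjoint, so sub-band powers nest within the wide band
    mask = (freqs >= lo) & (freqs < hi)
    return float(np.sum(psd[mask]) * df)


def dominant_peak(
    x: np.ndarray, band: tuple[float, float], _psd: tuple | None = None
) -> tuple[float, float]:
    """Frequency and PSD height of the maximum periodogram bin inside
    ``band``; ties break toward the lower frequency. A flat-zero spectrum
    reports the lowest bin in the band with height 0."""
    lo, hi = band
    freqs, psd = _psd if _psd is not None else _periodogram(np.asarray(x, float))
    mask = (freqs >= lo) & (freqs < hi)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no periodogram bins")
    sub = psd[mask]
    i = int(np.argmax(sub))  # argmax returns the first (lowest-frequency) tie
    return float(freqs[mask][i]), float(sub[i])


def spectral_entropy_from_psd(psd: np.ndarray) -> float:
    """Normalized Shannon entropy of a PSD vector treated as a probability
    mass over bins; 0 for a degenerate (single-bin or all-zero) spectrum,
    1 for an exactly uniform one."""
    psd = np.asarray(psd, dtype=float)
    total = psd.sum()
    if len(psd) < 2 or total <= 0:
        return 0.0
    p = psd / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(psd)))


def spectral_entropy(x: np.ndarray, _psd: tuple | None = None) -> float:
    """Spectral entropy of the window over 0.2-25 Hz, DC excluded."""
    freqs, psd = _psd if _psd is not None else _periodogram(np.asarray(x, float))
    lo, hi = SPECTRAL_ENTROPY_BAND
    mask = (freqs >= lo) & (freqs < hi)
    return spectral_entropy_from_psd(psd[mask])


# ---------------------------------------------------------------------------
# sample entropy


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) with Chebyshev distance, self-matches excluded.

    Conventions for degenerate windows: a constant window (SD = 0) returns 0;
    if there are template matches at length m but none at m+1, the capped
    value ``-log(2 / ((N - m - 1) * (N - m)))`` (the smallest resolvable
    conditional probability) is returned; if there are no matches at length m
    at all, 0 is returned.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = float(np.std(x))
    # exact-range check: float round-off makes std of a constant window
    # slightly positive, which would count every template as a match
    if sd == 0.0 or np.ptp(x) == 0.0 or n <= m + 1:
        return 0.0
    if r is None:
        r = 0.2 * sd

    def _count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        iu = np.triu_indices(len(emb), k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = _count(m)
    a = _count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float(-np.log(2.0 / ((n - m - 1) * (n - m))))
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# per-window feature vector


def extract_features(window: np.ndarray) -> np.ndarray:
    """45-vector for one (100, 3) window: 15 features per axis, axes x,y,z."""
    window = np.asarray(window, dtype=float)
    if window.shape != (WINDOW_N, 3):
        raise ValueError(f"window must have shape ({WINDOW_N}, 3), got {window.shape}")
    out = np.empty(45)
    j = 0
    for ax in range(3):
        x = window[:, ax]
        psd = _periodogram(x)
        out[j] = np.std(x)
        j += 1
        for band in BANDS:
            out[j] = band_power(x, band, _psd=psd)
            j += 1
        for band in BANDS:
            f, h = dominant_peak(x, band, _psd=psd)
            out[j], out[j + 1] = f, h
            j += 2
        out[j] = sample_entropy(x)
        out[j + 1] = spectral_entropy(x, _psd=psd)
        j += 2
    return out


# ---------------------------------------------------------------------------
# feature tables


@dataclass
class FeatureTable:
    """Per-window feature matrix plus metadata.

    ``frame`` holds the meta columns (subject_id, start, end, segment_id,
    label, sub_class, prototype, excluded) followed by the 45 feature
    columns. ``normalization`` is ``"raw"`` or ``"zscored"``; z-scored tables
    carry the (mean, sd) used so held-out data can be transformed with
    training statistics.
    """

    frame: pd.DataFrame
    normalization: str = "raw"
    stats: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:3]}...")
        X = self.frame[list(FEATURE_NAMES)].to_numpy()
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return (self.frame["label"] == "tremor").to_numpy(dtype=int)

    def select(self, mask) -> "FeatureTable":
        return FeatureTable(
            self.frame.loc[mask].reset_index(drop=True),
            normalization=self.normalization,
            stats=self.stats,
        )


def featurize_recording(
    rec50: RawRecording,
    segments: SegmentBoundaries,
    track: AnnotationTrack | None = None,
) -> pd.DataFrame:
    """Window a detrended 50 Hz recording, extract features and (optionally)
    attach window labels from the annotation track."""
    windows = window_segments(rec50, segments)
    if track is not None:
        windows = label_windows(windows, track)
    feats = np.empty((len(windows), 45))
    for i, (s, e) in enumerate(zip(windows["start"], windows["end"])):
        i0 = int(round(s * RATE_HZ))
        feats[i] = extract_features(rec50.acc[i0 : i0 + WINDOW_N])
    for j, name in enumerate(FEATURE_NAMES):
        windows[name] = feats[:, j]
    return windows


def build_feature_table(cohort, lam: float = 10_000.0, **seg_kwargs) -> FeatureTable:
    """End-to-end preprocessing + feature extraction for a whole cohort.

    Windows without a majority class label are dropped (``excluded`` flag);
    the returned table is raw (not normalized).
    """
    from .preprocess import preprocess_recording

    frames = []
    for rec, track in cohort:
        rec50, segments = preprocess_recording(rec, lam=lam, **seg_kwargs)
        df = featurize_recording(rec50, segments, track)
        frames.append(df)
    frame = pd.concat(frames, ignore_index=True)
    frame = frame.loc[~frame["excluded"]].reset_index(drop=True)
    return FeatureTable(frame)


def zscore_fit_apply(
    table: FeatureTable, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> FeatureTable:
    """Z-score the 45 feature columns.

    With ``stats=None`` the mean/SD are fitted on the table's own rows;
    otherwise the provided (mean, sd) — e.g. from the training fold — are
    applied. Zero-SD columns are centred and passed through with sd treated
    as 1.
    """
    X = table.X
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
    else:
        mean, sd = (np.asarray(a, dtype=float) for a in stats)
        if mean.shape != (45,) or sd.shape != (45,):
            raise ValueError("stats must be two length-45 vectors")
    safe_sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / safe_sd
    frame = table.frame.copy()
    frame[list(FEATURE_NAMES)] = Z
    return FeatureTable(frame, normalization="zscored", stats=(mean, sd))
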