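"""Fixed 15-dimensional feature vector for 5-s ECoG chunks.

The canonical set covers amplitude, waveform shape and spectral content:
coastline (line length), variance, skewness, excess kurtosis, RMS,
peak-to-peak, zero-crossing count, 95th percentile of |x|, power in six
frequency bands (1–4, 4–8, 8–12, 12–30, 30–70, 70–120 Hz) and normalized
spectral entropy.  The set is pluggable (``FeatureConfig``) so an alternative
feature list can be substituted without touching the classifier.

Spectral estimates use Welch averaging with 1-s Hann segments at 50% overlap,
which is stable on 5-s chunks at 256 Hz.  Degenerate-moment convention: the
skewness, kurtosis and spectral entropy of a constant chunk are 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .ecog_io import ChunkIndex, EcogRecording

__all__ = [
    "FEATURE_NAMES",
    "CANONICAL_BANDS",
    "FeatureConfig",
    "coastline",
    "band_power",
    "spectral_entropy",
    "extract_features",
    "extract_matrix",
]

CANONICAL_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 30.0),
    (30.0, 70.0),
    (70.0, 120.0),
)

FEATURE_NAMES: tuple[str, ...] = (
    "coastline",
    "variance",
    "skewness",
    "excess_kurtosis",
    "rms",
    "peak_to_peak",
    "zero_crossings",
    "abs_amplitude_p95",
    "power_1_4",
    "power_4_8",
    "power_8_12",
    "power_12_30",
    "power_30_70",
    "power_70_120",
    "spectral_entropy",
)


@dataclass
class FeatureConfig:
    """Pluggable feature set; the default is the canonical 15-feature list."""

    bands: tuple[tuple[float, float], ...] = CANONICAL_BANDS
    welch_segment_s: float = 1.0
    welch_overlap: float = 0.5
    names: tuple[str, ...] = FEATURE_NAMES


def coastline(x: np.ndarray) -> float:
    """Line length: sum of absolute successive sample differences (µV)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("coastline needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def _welch(x: np.ndarray, fs: float, cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(x.size, int(round(cfg.welch_segment_s * fs)))
    noverlap = int(round(cfg.welch_overlap * nperseg))
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)


def band_power(
    x: np.ndarray, fs: float, lo: float, hi: float, cfg: FeatureConfig | None = None
) -> float:
    """Integrated periodogram power over the half-open band [lo, hi) in µV²."""
    if not (0 <= lo < hi <= fs / 2):
        raise ValueError(f"invalid band [{lo}, {hi}) for fs = {fs}")
    cfg = cfg or FeatureConfig()
    f, psd = _welch(np.asarray(x, dtype=float), fs, cfg)
    df = f[1] - f[0]
    sel = (f >= lo) & (f < hi)
    return float(np.sum(psd[sel]) * df)


def spectral_entropy(x: np.ndarray, fs: float, cfg: FeatureConfig | None = None) -> float:
    """Shannon entropy of the normalized Welch PSD, scaled to [0, 1]."""
    cfg = cfg or FeatureConfig()
    _, psd = _welch(np.asarray(x, dtype=float), fs, cfg)
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd[psd > 0] / total
    if p.size <= 1:
        return 0.0
    return float(-(p * np.log(p)).sum() / np.log(psd.size))


def extract_features(
    chunk: np.ndarray, fs: float, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """Map one chunk to the ordered 15-vector of features.

    Zero-crossing count is taken on the mean-subtracted signal so it reflects
    waveform oscillation rather than DC offset.  All entries are finite for
    any finite input.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(chunk, dtype=float)
    if x.size < 2:
        raise ValueError("chunk too short")
    if not np.all(np.isfinite(x)):
        raise ValueError("chunk contains non-finite samples")
    var = float(np.var(x))
    constant = var == 0.0
    centered = x - x.mean()
    sign = np.sign(centered)
    sign[sign == 0] = 1
    zc = float(np.sum(sign[:-1] != sign[1:]))
    f, psd = _welch(x, fs, cfg)
    df = f[1] - f[0]
    powers = [
        float(np.sum(psd[(f >= lo) & (f < hi)]) * df) for lo, hi in cfg.bands
    ]
    total = psd.sum()
    if total > 0:
        p = psd[psd > 0] / total
        ent = float(-(p * np.log(p)).sum() / np.log(psd.size)) if p.size > 1 else 0.0
    else:
        ent = 0.0
    vec = np.array(
        [
            coastline(x),
            var,
            0.0 if constant else float(stats.skew(x)),
            0.0 if constant else float(stats.kurtosis(x)),
            float(np.sqrt(np.mean(x**2))),
            float(np.ptp(x)),
            zc,
            float(np.percentile(np.abs(x), 95)),
            *powers,
            ent,
        ]
    )
    if vec.size != len(cfg.names):
        raise ValueError(
            f"feature vector length {vec.size} != {len(cfg.names)} names"
        )
    return vec


def extract_matrix(
    rec: EcogRecording, idx: ChunkIndex, cfg: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature matrix: one row per chunk, columns in canonical order."""
    cfg = cfg or FeatureConfig()
    rows = [
        extract_features(rec.samples[i0:i1], rec.fs, cfg) for i0, i1 in idx.windows
    ]
    mat = np.vstack(rows) if rows else np.empty((0, len(cfg.names)))
    return pd.DataFrame(mat, columns=list(cfg.names))
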