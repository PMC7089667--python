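"""Semi-automated seizure detector: random forest + HMM smoothing.

Training: each labeled 5-s chunk of the library is mapped to its feature
vector, z-scored with statistics computed on the training library, and fed
to a random-forest classifier (100 trees, class-balanced weights).
Session-grouped cross-validation produces out-of-fold chunk predictions,
from which a two-state hidden Markov model is estimated: the hidden states
are the human annotations, the emissions are the classifier's discrete
predicted labels.  Transition, emission and initial probabilities come from
add-one-smoothed counts — zero counts would otherwise forbid ever entering
or leaving the ictal state.

Detection: classifier labels for consecutive chunks are smoothed with the
forward-backward algorithm (per-step scaled, safe for million-chunk
sequences); chunks with posterior P(ictal) >= threshold become candidate
ictal chunks, maximal runs are merged into events (also across gaps of at
most one chunk), and events can be exported for manual review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .ecog_io import (
    ICTAL,
    INTERICTAL,
    AnnotationSet,
    ChunkIndex,
    EcogRecording,
    SeizureLibrary,
    chunk_recording,
    label_chunks,
)
from .features import FeatureConfig, extract_matrix

__all__ = [
    "HmmParameters",
    "ClassifierModel",
    "DetectionResult",
    "DetectionMetrics",
    "train_classifier",
    "estimate_hmm",
    "fit_detector",
    "forward_backward",
    "detect",
    "evaluate",
    "export_for_review",
    "import_review",
    "ReviewFormatError",
]


@dataclass
class HmmParameters:
    """Two-state HMM: A (transitions per chunk step), B (emissions), pi.

    State/observation order: 0 = interictal, 1 = ictal.
    ``B[s, o]`` is P(classifier outputs o | true state s).
    """

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.A.shape != (2, 2) or self.B.shape != (2, 2) or self.pi.shape != (2,):
            raise ValueError("expected 2x2 A, 2x2 B and length-2 pi")
        for name, mat in (("A", self.A), ("B", self.B)):
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"rows of {name} must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-12):
            raise ValueError("pi must sum to 1")


def estimate_hmm(
    label_sequences: list[np.ndarray],
    prediction_sequences: list[np.ndarray],
    smoothing: float = 1.0,
) -> HmmParameters:
    """Estimate HMM parameters from annotations and cross-validated predictions.

    ``label_sequences`` are the per-session true (human) chunk labels;
    ``prediction_sequences`` the aligned out-of-fold classifier predictions.
    A comes from transition counts of the true-label sequences, B from the
    confusion counts P(predicted | true), pi from state frequencies — all
    with additive (add-``smoothing``) regularization.
    """
    if not label_sequences or all(len(s) == 0 for s in label_sequences):
        raise ValueError("empty label sequences")
    if len(label_sequences) != len(prediction_sequences):
        raise ValueError("label and prediction sequences must align")
    trans = np.full((2, 2), float(smoothing))
    emit = np.full((2, 2), float(smoothing))
    occ = np.full(2, float(smoothing))
    for lab, pred in zip(label_sequences, prediction_sequences):
        lab = np.asarray(lab, dtype=int)
        pred = np.asarray(pred, dtype=int)
        if lab.shape != pred.shape:
            raise ValueError("label/prediction sequence length mismatch")
        for s in (lab, pred):
            if s.size and not np.isin(s, (0, 1)).all():
                raise ValueError("labels must be 0 (interictal) or 1 (ictal)")
        np.add.at(trans, (lab[:-1], lab[1:]), 1.0)
        np.add.at(emit, (lab, pred), 1.0)
        np.add.at(occ, lab, 1.0)
    if smoothing == 0 and (
        (trans.sum(axis=1) == 0).any() or (emit.sum(axis=1) == 0).any()
    ):
        raise ValueError("zero counts for some state; use smoothing > 0")
    return HmmParameters(
        A=trans / trans.sum(axis=1, keepdims=True),
        B=emit / emit.sum(axis=1, keepdims=True),
        pi=occ / occ.sum(),
    )


def forward_backward(obs: np.ndarray, hmm: HmmParameters) -> np.ndarray:
    """Posterior state marginals gamma[t, s] = P(state_t = s | obs).

    Scaled forward-backward recursion: each forward step is normalized and the
    backward pass reuses the scale factors, so sequences of 10^6 chunks run
    without underflow.  ``obs`` are the discrete classifier labels {0, 1}.
    """
    obs = np.asarray(obs, dtype=int)
    if obs.ndim != 1 or obs.size < 1:
        raise ValueError("obs must be a non-empty 1-D label sequence")
    if not np.isin(obs, (0, 1)).all():
        raise ValueError("observations must be 0 or 1")
    n = obs.size
    A, B, pi = hmm.A, hmm.B, hmm.pi
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    a = pi * B[:, obs[0]]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ A) * B[:, obs[t]]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (A @ (B[:, obs[t + 1]] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


@dataclass
class ClassifierModel:
    """Fitted chunk classifier plus the preprocessing it was trained with."""

    forest: RandomForestClassifier
    feature_mean: np.ndarray
    feature_std: np.ndarray
    feature_config: FeatureConfig
    chunk_s: float
    fs: float
    seed: int
    cv_fold_count: int

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feature_mean) / self.feature_std

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.forest.predict(self.transform(features))


def _library_features(lib: SeizureLibrary, cfg: FeatureConfig) -> np.ndarray:
    if lib.feature_matrix is None:
        mats = [
            extract_matrix(rec, idx, cfg).to_numpy()
            for rec, idx in zip(lib.recordings, lib.chunk_indices)
        ]
        lib.feature_matrix = np.vstack(mats)
    return lib.feature_matrix


def train_classifier(
    lib: SeizureLibrary,
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    feature_config: FeatureConfig | None = None,
) -> tuple[ClassifierModel, np.ndarray]:
    """Fit the random forest and produce out-of-fold chunk predictions.

    Cross-validation folds are grouped by session so neighboring chunks of
    one recording never straddle a train/test split.  The returned
    predictions are aligned with ``lib.all_labels()``.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    cfg = feature_config or FeatureConfig()
    y = lib.all_labels().astype(int)
    if np.unique(y).size < 2:
        raise ValueError("library must contain both ictal and interictal chunks")
    X = _library_features(lib, cfg)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xz = (X - mean) / std
    groups = lib.session_index_per_chunk()

    cv_pred = np.empty_like(y)
    n_groups = np.unique(groups).size
    folds = min(cv_folds, n_groups)
    if folds >= 2:
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(Xz, y, groups)
    else:
        warnings.warn(
            "single session in library; falling back to stratified chunk folds",
            stacklevel=2,
        )
        folds = min(cv_folds, np.bincount(y).min())
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(Xz, y)
    for train_i, test_i in split:
        f = RandomForestClassifier(
            n_estimators=n_estimators,
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
        f.fit(Xz[train_i], y[train_i])
        cv_pred[test_i] = f.predict(Xz[test_i])

    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(Xz, y)
    model = ClassifierModel(
        forest=forest,
        feature_mean=mean,
        feature_std=std,
        feature_config=cfg,
        chunk_s=lib.chunk_s,
        fs=lib.recordings[0].fs if lib.recordings else 256.0,
        seed=seed,
        cv_fold_count=folds,
    )
    return model, cv_pred


def fit_detector(
    lib: SeizureLibrary,
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    smoothing: float = 1.0,
    feature_config: FeatureConfig | None = None,
) -> tuple[ClassifierModel, HmmParameters]:
    """Train the classifier and parameterize the HMM in one pass."""
    model, cv_pred = train_classifier(
        lib, cv_folds=cv_folds, seed=seed, n_estimators=n_estimators,
        feature_config=feature_config,
    )
    seq_true, seq_pred = [], []
    pos = 0
    for lbl in lib.chunk_labels:
        seq_true.append(lbl.astype(int))
        seq_pred.append(cv_pred[pos : pos + lbl.size])
        pos += lbl.size
    hmm = estimate_hmm(seq_true, seq_pred, smoothing=smoothing)
    return model, hmm


@dataclass
class DetectionResult:
    """Per-chunk posteriors, smoothed labels and assembled events."""

    gamma_ictal: np.ndarray
    raw_labels: np.ndarray
    smoothed_labels: np.ndarray
    events: list[tuple[float, float]]
    threshold: float
    chunk_s: float


def _runs_to_events(
    labels: np.ndarray, chunk_s: float, merge_gap_chunks: int
) -> list[tuple[float, float]]:
    """Maximal runs of ictal chunks, merged across short interictal gaps."""
    idx = np.flatnonzero(labels == 1)
    if idx.size == 0:
        return []
    events: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i - events[-1][1] <= merge_gap_chunks + 1:
            events[-1][1] = i
        else:
            events.append([i, i])
    return [(a * chunk_s, (b + 1) * chunk_s) for a, b in events]


def detect(
    rec: EcogRecording,
    model: ClassifierModel,
    hmm: HmmParameters,
    threshold: float = 0.5,
    merge_gap_chunks: int = 1,
) -> DetectionResult:
    """Run the full pipeline on one recording.

    Chunks -> features -> z-score -> classifier labels -> forward-backward
    posteriors -> chunks with P(ictal) >= threshold -> events (consecutive
    ictal chunks, merged across gaps of at most ``merge_gap_chunks``).
    """
    if abs(rec.fs - model.fs) > 1e-9:
        raise ValueError(
            f"recording fs {rec.fs} differs from training fs {model.fs}"
        )
    idx = chunk_recording(rec, model.chunk_s)
    feats = extract_matrix(rec, idx, model.feature_config).to_numpy()
    raw = model.predict(feats)
    gamma = forward_backward(raw, hmm)
    smoothed = (gamma[:, 1] >= threshold).astype(int)
    events = _runs_to_events(smoothed, model.chunk_s, merge_gap_chunks)
    return DetectionResult(
        gamma_ictal=gamma[:, 1],
        raw_labels=raw,
        smoothed_labels=smoothed,
        events=events,
        threshold=threshold,
        chunk_s=model.chunk_s,
    )


@dataclass
class DetectionMetrics:
    """Seizure-level and chunk-level detection performance."""

    n_true: int
    n_detected_true: int
    n_false_positive_events: int
    sensitivity: float | None
    false_negative_rate: float | None
    false_positives_per_day: float
    chunk_confusion: np.ndarray | None = None


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and a[1] > b[0]


def evaluate(
    detections: DetectionResult | list[tuple[float, float]],
    truth: AnnotationSet,
    total_duration_s: float,
) -> DetectionMetrics:
    """Score detections against ground truth on the same time base.

    A true seizure counts as detected iff any detected event overlaps it;
    the false-negative rate is missed/true (None when there are no true
    seizures); a detected event overlapping no true seizure is a false
    positive, reported per day of recording.
    """
    if isinstance(detections, DetectionResult):
        events = detections.events
    else:
        events = list(detections)
    true_events = truth.ictal_intervals()
    detected_true = sum(
        1 for t in true_events if any(_overlaps(t, d) for d in events)
    )
    fp = sum(1 for d in events if not any(_overlaps(t, d) for t in true_events))
    n_true = len(true_events)
    days = total_duration_s / 86400.0
    confusion = None
    if isinstance(detections, DetectionResult):
        n = detections.smoothed_labels.size
        idx = ChunkIndex(
            chunk_s=detections.chunk_s,
            fs=1.0 / detections.chunk_s,
            windows=[(i, i + 1) for i in range(n)],
        )
        true_chunks = label_chunks(idx, truth)
        confusion = np.zeros((2, 2), dtype=int)
        np.add.at(confusion, (true_chunks, detections.smoothed_labels), 1)
    return DetectionMetrics(
        n_true=n_true,
        n_detected_true=detected_true,
        n_false_positive_events=fp,
        sensitivity=(detected_true / n_true) if n_true else None,
        false_negative_rate=((n_true - detected_true) / n_true) if n_true else None,
        false_positives_per_day=fp / days if days > 0 else 0.0,
        chunk_confusion=confusion,
    )


# ---------------------------------------------------------------------------
# Manual review round trip


class ReviewFormatError(ValueError):
    """Malformed edit in a reviewer table, reported with its line number."""


_TRUE = {"yes", "y", "true", "1"}
_FALSE = {"no", "n", "false", "0"}


def export_for_review(result: DetectionResult, path: str | Path) -> pd.DataFrame:
    """Write candidate events with posterior statistics to an editable CSV.

    Reviewers set ``accept`` to yes/no and may override boundaries in the
    ``new_start_s`` / ``new_end_s`` columns (any resolution; human overrides
    win over the chunk grid).
    """
    rows = []
    for k, (s, e) in enumerate(result.events):
        i0 = int(round(s / result.chunk_s))
        i1 = int(round(e / result.chunk_s))
        g = result.gamma_ictal[i0:i1]
        rows.append(
            {
                "event_id": k,
                "start_s": s,
                "end_s": e,
                "gamma_mean": float(g.mean()) if g.size else np.nan,
                "gamma_max": float(g.max()) if g.size else np.nan,
                "accept": "yes",
                "new_start_s": "",
                "new_end_s": "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "event_id", "start_s", "end_s", "gamma_mean", "gamma_max",
            "accept", "new_start_s", "new_end_s",
        ],
    )
    df.to_csv(path, index=False)
    return df


def import_review(path: str | Path) -> AnnotationSet:
    """Re-import an edited reviewer table as a verified annotation set."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    intervals: list[tuple[float, float, str]] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        accept = str(row.get("accept", "")).strip().lower()
        if accept in _FALSE:
            continue
        if accept not in _TRUE:
            raise ReviewFormatError(f"line {line}: unparseable accept {accept!r}")
        try:
            s = float(row["new_start_s"]) if row["new_start_s"].strip() else float(row["start_s"])
            e = float(row["new_end_s"]) if row["new_end_s"].strip() else float(row["end_s"])
        except (KeyError, ValueError) as err:
            raise ReviewFormatError(f"line {line}: bad boundary value ({err})") from err
        if e <= s:
            raise ReviewFormatError(f"line {line}: end {e} <= start {s}")
        intervals.append((s, e, ICTAL))
    return AnnotationSet(intervals=intervals, provenance="verified")
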