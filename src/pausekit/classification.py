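"""Segment-level classification, subject-level majority voting, ensembling.

Classifiers are trained on fixed-length 4 s segments (each inheriting
its subject's diagnosis label -- the standard multiple-instance
assumption), then a subject's label is the majority vote over its
segment predictions.  The ensemble pools segment votes from several
feature streams (pause sequence, ComParE, eGeMAPS) into a single vote
set before the majority is taken, so streams contribute proportionally
to their segment counts.  Ties break toward AD (1): in a screening
context sensitivity is preferred, and the rule is explicit and
configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import evaluation
from .audio_io import AudioSignal, CorpusManifest, preprocess, read_wav
from .features import FeatureSet, extract_features
from .pause_encoding import DEFAULT_SEGMENT_DURATION, encode, segment
from .vad import VadModel, fit_default_model, run_vad

__all__ = [
    "Stream",
    "ClassifierKind",
    "SegmentPrediction",
    "SubjectPrediction",
    "train_classifier",
    "majority_vote",
    "predict_subject",
    "ensemble_predict",
    "run_experiment",
    "ExperimentResult",
]

TIE_BREAK_LABEL = 1  # exact vote ties resolve to AD


class Stream(str, Enum):
    VAD_PAUSE = "vad"
    COMPARE_2013 = "compare"
    EGEMAPS = "egemaps"


class ClassifierKind(str, Enum):
    LDA = "lda"
    DT = "dt"
    KNN = "knn"
    SVM = "svm"
    TB = "tb"


#: distance/margin-based classifiers get z-scored inputs; trees do not
_SCALED = {ClassifierKind.LDA, ClassifierKind.KNN, ClassifierKind.SVM}


@dataclass
class SegmentPrediction:
    subject_id: str
    segment_index: int
    predicted: int
    stream: Stream
    classifier: ClassifierKind


@dataclass
class SubjectPrediction:
    subject_id: str
    predicted: int
    vote_fraction: float  # fraction of segment votes for class 1
    n_votes: int


def _make_estimator(classifier: ClassifierKind, seed: int, n_features: int):
    if classifier is ClassifierKind.LDA:
        # shrinkage stabilises the covariance estimate for wide feature sets
        if n_features > 500:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis()
    if classifier is ClassifierKind.DT:
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if classifier is ClassifierKind.KNN:
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if classifier is ClassifierKind.SVM:
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if classifier is ClassifierKind.TB:
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=100,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier {classifier!r}")


def train_classifier(
    features: np.ndarray, labels: np.ndarray, classifier: ClassifierKind | str, seed: int = 0
):
    """Fit one segment-level classifier; deterministic given the seed.

    The five supported kinds are linear discriminant analysis, a Gini
    decision tree, 5-nearest-neighbours, a linear-kernel SVM (C=1) and a
    bag of 100 trees.  Distance/margin-based kinds are wrapped with a
    training-set z-scorer.
    """
    classifier = ClassifierKind(classifier)
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    counts = Counter(y.tolist())
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError(f"need at least 2 segments per class to train, got {dict(counts)}")
    est = _make_estimator(classifier, seed, X.shape[1])
    if classifier in _SCALED:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    est.fit(X, y)
    est.pausekit_config = {"classifier": classifier.value, "seed": seed, "scaled": classifier in _SCALED}
    return est


def majority_vote(votes: Sequence[int]) -> int:
    """Modal label of a vote sequence; an exact tie returns AD (1)."""
    votes = np.asarray(votes)
    if votes.size == 0:
        raise ValueError("majority_vote requires at least one vote")
    ones = int((votes == 1).sum())
    zeros = votes.size - ones
    if ones == zeros:
        return TIE_BREAK_LABEL
    return 1 if ones > zeros else 0


def predict_subject(model, segments: np.ndarray, subject_id: str = "") -> SubjectPrediction:
    """Predict every segment of one subject and majority-vote the label."""
    X = np.atleast_2d(np.asarray(segments, dtype=np.float64))
    preds = model.predict(X)
    return SubjectPrediction(
        subject_id=subject_id,
        predicted=majority_vote(preds),
        vote_fraction=float((preds == 1).mean()),
        n_votes=int(preds.size),
    )


def ensemble_predict(
    stream_predictions: dict[Stream | str, Sequence[int]], subject_id: str = ""
) -> SubjectPrediction:
    """Fuse feature streams by pooling all their segment votes.

    With a single stream this reduces exactly to :func:`predict_subject`
    applied to that stream's votes.
    """
    if not stream_predictions:
        raise ValueError("need at least one stream of predictions")
    pooled = np.concatenate([np.asarray(v) for v in stream_predictions.values()])
    if pooled.size == 0:
        raise ValueError("every stream must contribute at least one segment prediction")
    return SubjectPrediction(
        subject_id=subject_id,
        predicted=majority_vote(pooled),
        vote_fraction=float((pooled == 1).mean()),
        n_votes=int(pooled.size),
    )


# ---------------------------------------------------------------------------
# full experiment

ENSEMBLE_STREAM = "ensemble"


@dataclass
class ExperimentResult:
    """Prediction ledger and per-run metrics of a multi-run experiment."""

    predictions: pd.DataFrame  # run,stream,classifier,subject_id,true,predicted,vote_fraction
    metrics: pd.DataFrame  # stream,classifier,run,accuracy,precision,recall,f1
    vad_model: VadModel = None


def _load_records(corpus, base_dir: str | Path | None):
    """Yield (subject_id, preprocessed AudioSignal, label) from a corpus."""
    if hasattr(corpus, "iter_records"):
        for sid, sig, label in corpus.iter_records():
            yield sid, preprocess(sig), int(label)
        return
    if isinstance(corpus, CorpusManifest):
        base = Path(base_dir) if base_dir else Path(".")
        for row in corpus.records.itertuples():
            if pd.isna(row.label):
                continue
            yield str(row.subject_id), preprocess(read_wav(base / row.audio_path)), int(row.label)
        return
    raise TypeError(f"unsupported corpus type {type(corpus)!r}")


def _segment_audio(sig: AudioSignal, segment_duration: float) -> list[AudioSignal]:
    seg_len = int(segment_duration * sig.sample_rate)
    n_seg = sig.samples.size // seg_len
    return [
        AudioSignal(sig.samples[i * seg_len : (i + 1) * seg_len], sig.sample_rate)
        for i in range(n_seg)
    ]


def _subject_features(
    records, streams, vad_model, frame_duration, segment_duration, feature_backend
):
    """Per-subject, per-stream segment feature matrices."""
    per_stream: dict[Stream, dict[str, np.ndarray]] = {s: {} for s in streams}
    labels: dict[str, int] = {}
    for sid, sig, label in records:
        labels[sid] = label
        for stream in streams:
            if stream is Stream.VAD_PAUSE:
                seq = encode(run_vad(sig, vad_model, frame_duration), frame_duration, sid)
                per_stream[stream][sid] = segment(seq, segment_duration).segments.astype(float)
            else:
                fset = FeatureSet.COMPARE_2013 if stream is Stream.COMPARE_2013 else FeatureSet.EGEMAPS
                chunks = _segment_audio(sig, segment_duration)
                per_stream[stream][sid] = np.array(
                    [
                        extract_features(c, fset, sid, j, backend=feature_backend).values
                        for j, c in enumerate(chunks)
                    ]
                )
    return per_stream, labels


def _stratified_split(subjects, labels, test_fraction, rng):
    """Subject-disjoint split, shuffled per run, stratified by class."""
    train, test = [], []
    for cls in (0, 1):
        grp = [s for s in subjects if labels[s] == cls]
        rng.shuffle(grp)
        n_test = max(1, round(len(grp) * test_fraction))
        test.extend(grp[:n_test])
        train.extend(grp[n_test:])
    rng.shuffle(train)  # shuffled training order
    return train, test


def run_experiment(
    corpus,
    streams: Iterable[Stream | str] = (Stream.VAD_PAUSE,),
    classifiers: Iterable[ClassifierKind | str] = (ClassifierKind.TB,),
    n_runs: int = 5,
    seed: int = 0,
    *,
    base_dir: str | Path | None = None,
    frame_duration: float = 0.03,
    segment_duration: float = DEFAULT_SEGMENT_DURATION,
    test_fraction: float = 0.3,
    feature_backend: str = "auto",
    vad_model: VadModel | None = None,
) -> ExperimentResult:
    """Run the full pipeline over a labeled corpus, ``n_runs`` times.

    Each run reshuffles the subject order with a run-specific derived
    seed, splits subjects (never segments) 70/30 stratified by class,
    trains every (stream x classifier) combination on training segments
    and majority-votes subject labels on the held-out subjects.  When
    two or more streams are given, an ``"ensemble"`` pseudo-stream pools
    their segment votes per classifier.  Returns the subject-level
    prediction ledger and per-run metrics.
    """
    streams = [Stream(s) for s in streams]
    classifiers = [ClassifierKind(c) for c in classifiers]
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    records = list(_load_records(corpus, base_dir))
    if vad_model is None:
        vad_model = fit_default_model((sig for _, sig, _ in records), frame_duration)
    per_stream, labels = _subject_features(
        records, streams, vad_model, frame_duration, segment_duration, feature_backend
    )
    subjects = [sid for sid, _, _ in records]

    pred_rows, metric_rows = [], []
    for run in range(n_runs):
        run_seed = (seed * 1_000_003 + run) % (2**31)
        rng = np.random.default_rng(run_seed)
        train_ids, test_ids = _stratified_split(subjects, labels, test_fraction, rng)

        # votes[(stream, clf)][sid] -> per-segment predictions
        votes: dict[tuple, dict[str, np.ndarray]] = {}
        for stream in streams:
            X_train = np.vstack([per_stream[stream][sid] for sid in train_ids])
            y_train = np.concatenate(
                [np.full(len(per_stream[stream][sid]), labels[sid]) for sid in train_ids]
            )
            for clf in classifiers:
                model = train_classifier(X_train, y_train, clf, seed=run_seed)
                votes[(stream, clf)] = {
                    sid: model.predict(per_stream[stream][sid]) for sid in test_ids
                }

        def record(stream_name: str, clf: ClassifierKind, subject_preds: list[SubjectPrediction]):
            y_true = [labels[p.subject_id] for p in subject_preds]
            y_pred = [p.predicted for p in subject_preds]
            for p, t in zip(subject_preds, y_true):
                pred_rows.append(
                    {
                        "run": run,
                        "stream": stream_name,
                        "classifier": clf.value,
                        "subject_id": p.subject_id,
                        "true": t,
                        "predicted": p.predicted,
                        "vote_fraction": p.vote_fraction,
                    }
                )
            rep = evaluation.metrics(evaluation.confusion(y_true, y_pred))
            metric_rows.append(
                {
                    "stream": stream_name,
                    "classifier": clf.value,
                    "run": run,
                    "accuracy": rep.accuracy,
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "f1": rep.f1,
                }
            )

        for stream in streams:
            for clf in classifiers:
                subject_preds = [
                    SubjectPrediction(
                        sid,
                        majority_vote(votes[(stream, clf)][sid]),
                        float((votes[(stream, clf)][sid] == 1).mean()),
                        len(votes[(stream, clf)][sid]),
                    )
                    for sid in test_ids
                ]
                record(stream.value, clf, subject_preds)

        if len(streams) > 1:
            for clf in classifiers:
                subject_preds = [
                    ensemble_predict(
                        {s: votes[(s, clf)][sid] for s in streams}, subject_id=sid
                    )
                    for sid in test_ids
                ]
                record(ENSEMBLE_STREAM, clf, subject_preds)

    return ExperimentResult(
        predictions=pd.DataFrame(pred_rows),
        metrics=pd.DataFrame(metric_rows),
        vad_model=vad_model,
    )
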