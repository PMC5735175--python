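"""Oculomotor event classification over linear segments.

Each segment is summarised by two features: the natural log of its mean
speed (deg/s) and the Fisher transform (atanh) of the cosine of the angle
between its displacement direction and its predecessor's.  Saccades sit at
high speed; post-saccadic oscillations (PSOs) show the characteristic
near-180° direction reversals (strongly negative Fisher-cosine) right
after a saccade; fixations and pursuits occupy the slow region and are
separated mainly by speed and direction persistence.

Classification is a four-state hidden Markov model: class-conditional
emissions are full-covariance bivariate Gaussians estimated from labelled
segments (sample mean / covariance), while the transition matrix is fixed
by domain structure rather than estimated: a PSO can only follow a saccade
(or another PSO), a saccade can never directly follow a PSO, and direct
fixation↔pursuit transitions get half the within-class probability, which
gives contiguous non-saccadic stretches a labelling inertia.  Decoding is
exact Viterbi; every sample inherits its segment's class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import multivariate_normal

from .io import OUTLIER_LABELS
from .segment import Segmentation

#: canonical class order; also the deterministic tie-break order
CLASSES = ("fixation", "saccade", "pso", "pursuit")

#: clamp for mean speed before the log [deg/s]
EPS_SPEED = 1e-3
#: clamp keeping the cosine away from ±1 before atanh
EPS_COS = 1e-6
#: ridge added to near-singular class covariances
COV_RIDGE = 1e-4

MODEL_SCHEMA_VERSION = 1


def extract_features(seg: Segmentation) -> np.ndarray:
    """Per-segment feature matrix, shape (m, 2): [log_speed, fisher_cos].

    Speed is the Euclidean norm of the segment's node-to-node displacement
    divided by its duration.  The angle feature pairs each segment with its
    predecessor; the first segment, having none, gets a neutral 0.
    """
    if seg.n_segments < 1:
        raise ValueError("empty segmentation")
    disp = seg.segment_displacements()
    dur = seg.segment_durations()
    if np.any(dur <= 0):
        raise ValueError("zero-duration segment")
    speed = np.hypot(disp[:, 0], disp[:, 1]) / dur
    log_speed = np.log(np.maximum(speed, EPS_SPEED))
    m = len(disp)
    fisher = np.zeros(m)
    norms = np.hypot(disp[:, 0], disp[:, 1])
    for i in range(1, m):
        if norms[i - 1] <= 0 or norms[i] <= 0:
            fisher[i] = 0.0
            continue
        c = float(np.dot(disp[i - 1], disp[i]) / (norms[i - 1] * norms[i]))
        c = min(max(c, -1.0 + EPS_COS), 1.0 - EPS_COS)
        fisher[i] = np.arctanh(c)
    return np.column_stack([log_speed, fisher])


def build_transition_model(classes: Sequence[str] = CLASSES):
    """The fixed transition matrix and uniform initial distribution.

    Canonical four-state rows (order fixation, saccade, pso, pursuit):

    * fixation:  2/5 self, 2/5 → saccade, 1/5 → pursuit, 0 → pso
    * saccade:   uniform 1/4 over all four states
    * pso:       0 → saccade, uniform 1/3 over {fixation, pso, pursuit}
    * pursuit:   2/5 self, 2/5 → saccade, 1/5 → fixation, 0 → pso

    When a subset of classes is requested (e.g. a binary saccade/fixation
    model trained from two-class labels), the canonical matrix is restricted
    to those classes and rows renormalized.
    """
    full = {
        "fixation": {"fixation": 2 / 5, "saccade": 2 / 5, "pso": 0.0, "pursuit": 1 / 5},
        "saccade": {c: 1 / 4 for c in CLASSES},
        "pso": {"fixation": 1 / 3, "saccade": 0.0, "pso": 1 / 3, "pursuit": 1 / 3},
        "pursuit": {"fixation": 1 / 5, "saccade": 2 / 5, "pso": 0.0, "pursuit": 2 / 5},
    }
    k = len(classes)
    T = np.array([[full[a][b] for b in classes] for a in classes], dtype=float)
    rows = T.sum(axis=1, keepdims=True)
    if np.any(rows <= 0):
        raise ValueError("requested class subset leaves an absorbing-empty row")
    T = T / rows
    initial = np.full(k, 1.0 / k)
    return T, initial


@dataclass
class ClassModel:
    """Gaussian-emission HMM over segment features.

    ``classes`` is ordered (canonical: fixation, saccade, pso, pursuit);
    ``mean`` is (k, 2), ``cov`` (k, 2, 2) symmetric positive definite,
    ``transitions`` (k, k) row-stochastic, ``initial`` length k.
    """

    classes: Tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    transitions: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        k = len(self.classes)
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        for i in range(k):
            c = self.cov[i]
            if not np.allclose(c, c.T) or np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError(f"covariance of class {self.classes[i]!r} not SPD")

    def emission_logpdf(self, features: np.ndarray) -> np.ndarray:
        """(m, k) log-density of each feature vector under each class."""
        out = np.empty((len(features), len(self.classes)))
        for i in range(len(self.classes)):
            out[:, i] = multivariate_normal.logpdf(features, self.mean[i], self.cov[i])
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> Dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "classes": list(self.classes),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "transitions": self.transitions.tolist(),
            "initial": self.initial.tolist(),
            "feature_clamps": {"eps_speed": EPS_SPEED, "eps_cos": EPS_COS},
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: Dict) -> "ClassModel":
        return cls(
            tuple(d["classes"]),
            np.array(d["mean"]),
            np.array(d["cov"]),
            np.array(d["transitions"]),
            np.array(d["initial"]),
        )

    @classmethod
    def load(cls, path) -> "ClassModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def majority_label(seg: Segmentation, sample_labels: np.ndarray) -> List[Optional[str]]:
    """Label each segment by the majority vote of its samples' labels.

    Segments whose overall majority label is an outlier code ("blink" or
    "other") are excluded (``None``), so they do not enter training.  Ties
    between event classes break toward the canonical class order.
    """
    sample_labels = np.asarray(sample_labels, dtype=object)
    if len(sample_labels) != seg.n_samples:
        raise ValueError("sample labels must cover the trace")
    seg_idx = seg.segment_of_samples()
    out: List[Optional[str]] = []
    for j in range(seg.n_segments):
        labs = sample_labels[seg_idx == j]
        counts: Dict[str, int] = {}
        for l in labs:
            counts[l] = counts.get(l, 0) + 1
        top = max(counts.values())
        winners = [l for l, c in counts.items() if c == top]
        if any(w in OUTLIER_LABELS for w in winners) and not any(
            w in CLASSES for w in winners
        ):
            out.append(None)
            continue
        # outlier label tied with an event class: the event class wins
        event_winners = [w for w in winners if w in CLASSES]
        if not event_winners:
            out.append(None)
            continue
        event_winners.sort(key=CLASSES.index)
        out.append(event_winners[0])
    return out


def fit_class_distributions(
    features: np.ndarray,
    labels: Sequence[Optional[str]],
    classes: Optional[Sequence[str]] = None,
) -> ClassModel:
    """Estimate per-class Gaussian emissions from labelled segments.

    Mean and (unbiased, full 2×2) covariance per class; near-singular
    covariances are regularized by adding ``COV_RIDGE``·I.  ``classes``
    defaults to the classes present in ``labels`` (canonical order); any
    requested class with fewer than 3 labelled segments is an error.
    Transition matrix and initial distribution come from
    :func:`build_transition_model` restricted to ``classes``.
    """
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    if classes is None:
        present = {l for l in labels if l is not None}
        classes = tuple(c for c in CLASSES if c in present)
    else:
        classes = tuple(classes)
    if not classes:
        raise ValueError("no trainable classes in labels")
    k = len(classes)
    mean = np.empty((k, 2))
    cov = np.empty((k, 2, 2))
    for i, c in enumerate(classes):
        rows = features[[j for j, l in enumerate(labels) if l == c]]
        if len(rows) < 3:
            raise ValueError(f"class {c!r} has fewer than 3 labelled segments")
        mean[i] = rows.mean(axis=0)
        cv = np.cov(rows, rowvar=False, ddof=1)
        if np.min(np.linalg.eigvalsh(cv)) < COV_RIDGE:
            cv = cv + COV_RIDGE * np.eye(2)
        cov[i] = cv
    T, initial = build_transition_model(classes)
    return ClassModel(classes, mean, cov, T, initial)


def viterbi_classify(features: np.ndarray, model: ClassModel):
    """Exact maximum-likelihood class sequence (Viterbi decoding).

    Returns ``(classes, path_loglik)``.  Zero-probability transitions are
    −inf in log space and can never appear in the decoded path.  Ties break
    toward the canonical class order via first-argmax.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[None, :]
    m = len(features)
    if m < 1:
        raise ValueError("need at least one segment")
    logB = model.emission_logpdf(features)
    with np.errstate(divide="ignore"):
        logT = np.log(model.transitions)
        logpi = np.log(model.initial)
    k = len(model.classes)
    delta = logpi + logB[0]
    back = np.zeros((m, k), dtype=np.int64)
    for s in range(1, m):
        cand = delta[:, None] + logT  # (from, to)
        back[s] = np.argmax(cand, axis=0)
        delta = cand[back[s], np.arange(k)] + logB[s]
    last = int(np.argmax(delta))
    loglik = float(delta[last])
    if not np.isfinite(loglik):
        raise ValueError("all state paths are impossible under the model")
    path = np.empty(m, dtype=np.int64)
    path[-1] = last
    for s in range(m - 1, 0, -1):
        path[s - 1] = back[s, path[s]]
    return [model.classes[i] for i in path], loglik


def classify_samples(seg: Segmentation, segment_classes: Sequence[str]) -> np.ndarray:
    """Per-sample labels: every sample inherits its segment's class."""
    if len(segment_classes) != seg.n_segments:
        raise ValueError("one class per segment required")
    seg_classes = np.asarray(list(segment_classes), dtype=object)
    return seg_classes[seg.segment_of_samples()]


def classify_segmentation(seg: Segmentation, model: ClassModel):
    """Convenience: features → Viterbi → per-segment and per-sample labels."""
    feats = extract_features(seg)
    seg_classes, loglik = viterbi_classify(feats, model)
    return seg_classes, classify_samples(seg, seg_classes), loglik
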