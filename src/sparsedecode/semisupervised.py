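"""Self-training wrappers around the supervised decoders.

The main algorithm processes an ordered test stream: each volume is
coded against the *current* dictionary, classified by the
average-coefficient rule, and — when its prediction distance exceeds an
adaptive threshold — appended to the dictionary with its predicted
label.  The first test volume never updates the dictionary.  Two
reference strategies are included: naive updating (every prediction is
trusted) and random-subspace online ensembles with vote-confidence
gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import (
    LabeledDictionary,
    SolverSettings,
    fit_ldc,
    predict_ldc,
    predict_src_ave,
    score_src,
)

__all__ = [
    "SelfTrainState",
    "EnsembleConfig",
    "prediction_distance",
    "adaptive_threshold",
    "classify_stream_semisrc_ave",
    "classify_stream_naive",
    "vote_confidence",
    "classify_stream_rse",
]


@dataclass
class SelfTrainState:
    """Mutable state of one self-training pass over a test stream.

    ``distance_history`` records the prediction distance of EVERY
    processed sample, accepted or not: the adaptive threshold averages
    over all previous test samples.  ``update_log`` keeps one record per
    sample (index, predicted label, distance, threshold, accepted flag).
    """

    dictionary: LabeledDictionary
    alpha: float
    distance_history: list = field(default_factory=list)
    update_log: list = field(default_factory=list)
    n_initial_columns: int = 0

    def __post_init__(self) -> None:
        if self.n_initial_columns == 0:
            self.n_initial_columns = self.dictionary.n_samples

    @property
    def n_accepted(self) -> int:
        return self.dictionary.n_samples - self.n_initial_columns

    def log_frame(self) -> pd.DataFrame:
        """Update log as a tidy table (one row per test sample)."""
        return pd.DataFrame(
            self.update_log,
            columns=["test_index", "predicted", "distance", "threshold", "accepted"],
        )


def prediction_distance(scores, K: int | None = None) -> float:
    """Margin of the predicted class over the mean of the others.

    ``d = S_I - (sum_{j != I} S_j) / (K - 1)`` where ``I`` is the class
    with the maximal average coefficient.  Always nonnegative, since the
    predicted class attains the maximum.
    """
    averages = np.asarray(scores.averages, dtype=float)
    K = len(averages) if K is None else int(K)
    if K < 2:
        raise ValueError("prediction distance needs at least 2 classes")
    if len(averages) != K:
        raise ValueError(f"expected {K} averages, got {len(averages)}")
    i = int(np.argmax(averages))
    others = np.delete(averages, i)
    return float(averages[i] - others.sum() / (K - 1))


def adaptive_threshold(state: SelfTrainState, m: int) -> float:
    """Threshold for the m-th test sample: ``alpha * mean(d_1..d_{m-1})``.

    Defined only for ``m >= 2``; the first sample is never thresholded.
    """
    if m < 2:
        raise ValueError("threshold is undefined for the first test sample")
    history = state.distance_history[: m - 1]
    if len(history) != m - 1:
        raise ValueError(
            f"need {m - 1} recorded distances before sample {m}, "
            f"have {len(state.distance_history)}"
        )
    return float(state.alpha * np.mean(history))


def classify_stream_semisrc_ave(
    train: LabeledDictionary,
    test_stream: np.ndarray,
    alpha: float = 1.0,
    settings: SolverSettings | None = None,
):
    """Run confidence-gated self-training over an ordered test stream.

    For the m-th test volume (1-based): code it on the current
    dictionary, predict by the average-coefficient rule, compute the
    prediction distance ``d_m``; if ``m > 1`` and ``d_m`` strictly
    exceeds ``alpha * mean(d_1..d_{m-1})`` the volume is appended to the
    dictionary under its predicted label.  ``d_m`` enters the history
    either way.

    Returns ``(predictions, state)``; the input dictionary is not
    modified.
    """
    settings = settings or SolverSettings()
    state = SelfTrainState(dictionary=train.copy(), alpha=float(alpha))
    test_stream = np.asarray(test_stream, dtype=float)
    predictions = []
    for m, y in enumerate(test_stream, start=1):
        scores = score_src(state.dictionary, y, settings)
        label = predict_src_ave(scores)
        d = prediction_distance(scores)
        if m == 1:
            threshold = np.nan
            accepted = False
        else:
            threshold = adaptive_threshold(state, m)
            accepted = d > threshold
        state.distance_history.append(d)
        if accepted:
            state.dictionary.append_sample(y, label)
        state.update_log.append((m, label, d, threshold, accepted))
        predictions.append(label)
    return np.asarray(predictions), state


def classify_stream_naive(
    train: LabeledDictionary,
    test_stream: np.ndarray,
    settings: SolverSettings | None = None,
):
    """Self-training without any confidence gate.

    Every test volume — including the first — is appended to the
    dictionary under its predicted label.  Distances are still recorded
    for diagnostics.
    """
    settings = settings or SolverSettings()
    state = SelfTrainState(dictionary=train.copy(), alpha=0.0)
    test_stream = np.asarray(test_stream, dtype=float)
    predictions = []
    for m, y in enumerate(test_stream, start=1):
        scores = score_src(state.dictionary, y, settings)
        label = predict_src_ave(scores)
        d = prediction_distance(scores)
        state.distance_history.append(d)
        state.dictionary.append_sample(y, label)
        state.update_log.append((m, label, d, 0.0, True))
        predictions.append(label)
    return np.asarray(predictions), state


@dataclass(frozen=True)
class EnsembleConfig:
    """Random-subspace ensemble layout.

    ``n_classifiers`` members each see ``subspace_size`` features drawn
    once, without replacement, from the seeded generator; the same
    subsets are reused for training and testing.
    """

    n_classifiers: int = 25
    subspace_size: int | None = None  # default ceil(n_features / 10)
    confidence_threshold: float = 0.75
    seed: int = 0

    def draw_subsets(self, n_features: int) -> list:
        M = self.subspace_size
        if M is None:
            M = int(np.ceil(n_features / 10))
        if not 0 < M < n_features:
            raise ValueError(
                f"subspace size must satisfy 0 < M < n_features={n_features}, got {M}"
            )
        rng = np.random.default_rng(self.seed)
        return [
            np.sort(rng.choice(n_features, size=M, replace=False))
            for _ in range(self.n_classifiers)
        ]


def vote_confidence(votes) -> tuple:
    """Majority label and agreeing fraction of an ensemble vote.

    Ties break to the lowest class id.  Confidence is the fraction of
    members that voted for the majority label.
    """
    votes = np.asarray(votes)
    if votes.size == 0:
        raise ValueError("empty vote sequence")
    values, counts = np.unique(votes, return_counts=True)
    # np.unique sorts ascending, argmax takes the first maximal count,
    # so ties already resolve to the lowest class id
    i = int(np.argmax(counts))
    return values[i], float(counts[i] / votes.size)


def classify_stream_rse(
    train: LabeledDictionary,
    test_stream: np.ndarray,
    config: EnsembleConfig | None = None,
    base: str = "ldc",
    settings: SolverSettings | None = None,
    ldc_shrinkage: float | None = None,
):
    """Random-subspace online ensemble over an ordered test stream.

    Each member classifies its own feature subset of every test volume;
    the majority vote is the prediction.  When the vote confidence
    strictly exceeds ``confidence_threshold``, the volume joins every
    member's training data under the voted label (LDC members refit
    exactly from the augmented set; SRC-AVE members gain a dictionary
    column).

    Returns ``(predictions, log_frame)`` with one log row per sample.
    """
    if base not in ("ldc", "src_ave"):
        raise ValueError("base must be 'ldc' or 'src_ave'")
    config = config or EnsembleConfig()
    settings = settings or SolverSettings()
    test_stream = np.asarray(test_stream, dtype=float)
    subsets = config.draw_subsets(train.n_features)

    if base == "ldc":
        # rows-as-samples views per member; refit is exact on append
        member_X = [train.A[subset].T.copy() for subset in subsets]
        member_labels = [np.asarray(train.labels).copy() for _ in subsets]
        member_models = [
            fit_ldc(X, lab, shrinkage=ldc_shrinkage)
            for X, lab in zip(member_X, member_labels)
        ]
    else:
        member_dicts = [
            LabeledDictionary(train.A[subset], train.labels) for subset in subsets
        ]

    predictions = []
    log = []
    for m, y in enumerate(test_stream, start=1):
        if base == "ldc":
            votes = [
                predict_ldc(model, y[subset])
                for model, subset in zip(member_models, subsets)
            ]
        else:
            votes = [
                predict_src_ave(score_src(d, y[subset], settings))
                for d, subset in zip(member_dicts, subsets)
            ]
        label, confidence = vote_confidence(votes)
        accepted = confidence > config.confidence_threshold
        if accepted:
            if base == "ldc":
                for i, subset in enumerate(subsets):
                    member_X[i] = np.vstack([member_X[i], y[subset]])
                    member_labels[i] = np.append(member_labels[i], label)
                    member_models[i] = fit_ldc(
                        member_X[i], member_labels[i], shrinkage=ldc_shrinkage
                    )
            else:
                for d, subset in zip(member_dicts, subsets):
                    d.append_sample(y[subset], label)
        log.append((m, label, confidence, config.confidence_threshold, accepted))
        predictions.append(label)
    log_frame = pd.DataFrame(
        log, columns=["test_index", "predicted", "confidence", "threshold", "accepted"]
    )
    return np.asarray(predictions), log_frame
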