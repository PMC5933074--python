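"""Feature selection, normalization, experiment orchestration and stats.

The decoding pathway for one dataset is fixed: compute the voxelwise
Pearson correlation between the TRAINING run and the task reference
regressor, keep the top-k voxels, apply the identical voxel set to the
test run, z-score each run internally (voxel time courses first, then
per-volume spatial patterns), restrict to task volumes, and stream the
test run in time order through the requested classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .classifiers import (
    LabeledDictionary,
    SolverSettings,
    predict_src,
    predict_src_ave,
    score_src,
)
from .semisupervised import (
    EnsembleConfig,
    classify_stream_naive,
    classify_stream_rse,
    classify_stream_semisrc_ave,
)
from .simdata import REST, Paradigm, canonical_hrf

logger = logging.getLogger(__name__)

__all__ = [
    "DecodeConfig",
    "FeatureSelection",
    "ExperimentResult",
    "CLASSIFIER_NAMES",
    "build_reference",
    "select_features",
    "normalize",
    "detrend_linear",
    "accuracy",
    "run_classifier",
    "prepare_dataset",
    "compare_classifiers",
    "sweep_alpha",
    "wilcoxon_paired",
]

CLASSIFIER_NAMES = (
    "src",
    "src_ave",
    "semisrc_ave",
    "naive_semisrc_ave",
    "rse_oldc",
    "rse_osrc_ave",
)


@dataclass
class DecodeConfig:
    """Every tunable default of the decoding pathway, in one place.

    Serializes to/from YAML for the CLI; field names mirror the config
    file keys.
    """

    k_features: int = 1000
    signed_correlation: bool = True  # rank by signed r, not |r|
    include_rest: bool = False  # classify rest volumes as their own class
    normalize_test_with_train_stats: bool = False
    alpha_same_task: float = 1.0
    alpha_cross_task: float = 0.7
    tau: float | None = None
    tau_scale: float = 0.1
    solver_tol: float = 1e-4
    solver_max_iter: int = 300
    rse_n_classifiers: int = 25
    rse_subspace_size: int | None = None
    rse_confidence_threshold: float = 0.75
    rse_seed: int = 0
    disable_updates: bool = False  # freeze all self-training (diagnostics)

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            tau=self.tau,
            tau_scale=self.tau_scale,
            tol=self.solver_tol,
            max_iter=self.solver_max_iter,
        )

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            n_classifiers=self.rse_n_classifiers,
            subspace_size=self.rse_subspace_size,
            confidence_threshold=(
                1.0 + 1e-9 if self.disable_updates else self.rse_confidence_threshold
            ),
            seed=self.rse_seed,
        )

    def alpha_for_group(self, group: int) -> float:
        return self.alpha_same_task if group == 1 else self.alpha_cross_task

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DecodeConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class FeatureSelection:
    """Voxel ranking against the task reference regressor."""

    reference: np.ndarray
    correlations: np.ndarray
    selected: np.ndarray  # ordered voxel indices, best first
    k: int


def build_reference(paradigm: Paradigm, hrf: np.ndarray | None = None) -> np.ndarray:
    """Union box-car of all task blocks convolved with the HRF."""
    if hrf is None:
        hrf = canonical_hrf(paradigm.tr_seconds)
    box = paradigm.boxcar_union()
    return np.convolve(box, hrf)[: paradigm.n_volumes]


def _pearson_columns(data: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson r of every column of ``data`` against ``reference``;
    zero-variance columns get r = 0."""
    x = data - data.mean(axis=0)
    r = reference - reference.mean()
    num = x.T @ r
    denom = np.sqrt((x**2).sum(axis=0) * (r**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    return corr


def select_features(
    train_data: np.ndarray,
    reference: np.ndarray,
    k: int = 1000,
    signed: bool = True,
) -> FeatureSelection:
    """Top-k voxels by correlation with the reference, on training data only.

    Ranking uses signed r by default (``signed=False`` ranks by |r|).
    Ties at the cut rank break to the lowest voxel index; ``k`` beyond
    the voxel count is clamped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    train_data = np.asarray(train_data, dtype=float)
    if train_data.shape[0] != len(reference):
        raise ValueError("training run and reference must have equal volume counts")
    corr = _pearson_columns(train_data, np.asarray(reference, dtype=float))
    n_voxels = corr.shape[0]
    if k > n_voxels:
        logger.warning("k=%d exceeds voxel count %d; clamping", k, n_voxels)
        k = n_voxels
    key = corr if signed else np.abs(corr)
    # stable sort on (-key, index): descending value, lowest index on ties
    order = np.lexsort((np.arange(n_voxels), -key))
    selected = order[:k]
    return FeatureSelection(
        reference=np.asarray(reference, dtype=float),
        correlations=corr,
        selected=selected,
        k=k,
    )


def _zscore_rows(data: np.ndarray) -> np.ndarray:
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, (data - mean) / sd, 0.0)
    return out


def normalize(data: np.ndarray, selected: np.ndarray | None = None) -> np.ndarray:
    """Z-score voxel time courses, then per-volume spatial patterns.

    The order is fixed: columns (voxels over time) first, rows (volumes
    over voxels) second.  Constant vectors map to zeros, never NaN.
    """
    data = np.asarray(data, dtype=float)
    if selected is not None:
        data = data[:, np.asarray(selected)]
    return _zscore_rows(_zscore_rows(data.T).T)


def detrend_linear(data: np.ndarray) -> np.ndarray:
    """Remove per-voxel intercept and linear drift (OLS)."""
    return sp_signal.detrend(np.asarray(data, dtype=float), axis=0, type="linear")


def accuracy(predictions, truth) -> float:
    """Fraction of test samples classified correctly."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if predictions.size == 0:
        raise ValueError("cannot score an empty prediction set")
    return float(np.mean(predictions == truth))


def prepare_dataset(dataset, config: DecodeConfig, task_subset=None):
    """Feature-select, normalize and task-restrict one train/test pair.

    Returns ``(train_X, train_labels, test_X, test_labels)`` with
    rows-as-volumes matrices.  Feature selection sees only the training
    run; each run is z-scored internally (set
    ``normalize_test_with_train_stats`` to reuse training voxel
    statistics for the test run instead).
    """
    hrf = canonical_hrf(dataset.train.paradigm.tr_seconds)
    reference = build_reference(dataset.train.paradigm, hrf)
    fs = select_features(
        dataset.train.data, reference, k=config.k_features, signed=config.signed_correlation
    )
    if config.normalize_test_with_train_stats:
        tr = dataset.train.data[:, fs.selected]
        te = dataset.test.data[:, fs.selected]
        mean, sd = tr.mean(axis=0), tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        train_X = _zscore_rows(((tr - mean) / sd).T).T
        test_X = _zscore_rows(((te - mean) / sd).T).T
        train_X = _zscore_rows(train_X)
        test_X = _zscore_rows(test_X)
    else:
        train_X = normalize(dataset.train.data, fs.selected)
        test_X = normalize(dataset.test.data, fs.selected)

    train_labels = dataset.train.volume_labels
    test_labels = dataset.test.volume_labels
    if task_subset is not None:
        keep = np.isin(train_labels, task_subset)
        keep_te = np.isin(test_labels, task_subset)
    elif config.include_rest:
        keep = np.ones(len(train_labels), dtype=bool)
        keep_te = np.ones(len(test_labels), dtype=bool)
    else:
        keep = train_labels != REST
        keep_te = test_labels != REST
    return (
        train_X[keep],
        train_labels[keep],
        test_X[keep_te],
        test_labels[keep_te],
    )


def run_classifier(
    name: str,
    train_X: np.ndarray,
    train_labels: np.ndarray,
    test_X: np.ndarray,
    config: DecodeConfig,
    alpha: float | None = None,
):
    """Dispatch one classifier over a prepared test stream.

    Returns ``(predictions, log)`` where ``log`` is a per-sample update
    table for the self-training methods and ``None`` otherwise.
    """
    if name not in CLASSIFIER_NAMES:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    settings = config.solver_settings()
    dictionary = LabeledDictionary(train_X.T, train_labels)

    if name in ("src", "src_ave"):
        rule = predict_src if name == "src" else predict_src_ave
        preds = [rule(score_src(dictionary, y, settings)) for y in test_X]
        return np.asarray(preds), None
    if name == "semisrc_ave":
        a = 1e12 if config.disable_updates else (
            alpha if alpha is not None else config.alpha_same_task
        )
        preds, state = classify_stream_semisrc_ave(dictionary, test_X, a, settings)
        return preds, state.log_frame()
    if name == "naive_semisrc_ave":
        preds, state = classify_stream_naive(dictionary, test_X, settings)
        return preds, state.log_frame()
    base = "ldc" if name == "rse_oldc" else "src_ave"
    preds, log = classify_stream_rse(
        dictionary, test_X, config.ensemble_config(), base=base, settings=settings
    )
    return preds, log


@dataclass
class ExperimentResult:
    """Tidy outputs of one experiment sweep."""

    accuracy: pd.DataFrame  # subject, cnr, classifier, task_subset, accuracy
    pvalues: pd.DataFrame = None  # cnr, classifier, p_value (vs semisrc_ave)
    alpha_sweep: pd.DataFrame = None
    logs: dict = field(default_factory=dict)

    def mean_accuracy(self) -> pd.DataFrame:
        """Mean accuracy per (cnr, classifier) across subjects."""
        return (
            self.accuracy.groupby(["cnr", "classifier"], sort=True)["accuracy"]
            .mean()
            .reset_index()
        )


def wilcoxon_paired(a, b, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; the exact distribution is used for up
    to ``exact_max_n`` remaining pairs, the normal approximation beyond.
    All-zero differences give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    method = "exact" if diff.size <= exact_max_n else "approx"
    try:
        res = sp_stats.wilcoxon(diff, method=method)
    except ValueError:  # ties make the exact distribution unavailable
        res = sp_stats.wilcoxon(diff, method="approx")
    return float(res.pvalue)


def compare_classifiers(
    collection,
    roster=CLASSIFIER_NAMES,
    config: DecodeConfig | None = None,
    task_subset=None,
    keep_logs: bool = False,
) -> ExperimentResult:
    """Run a classifier roster over every dataset of a collection.

    Per dataset: features from run 1, both runs normalized, task volumes
    streamed in time order through each classifier.  Self-training
    alpha follows the dataset's group (same-task vs cross-decoding
    default).  Wilcoxon signed-rank tests pair subjects at each CNR
    level between ``semisrc_ave`` and every other roster member.
    """
    config = config or DecodeConfig()
    rows = []
    logs = {}
    for ds in collection:
        train_X, train_labels, test_X, test_labels = prepare_dataset(
            ds, config, task_subset
        )
        alpha = config.alpha_for_group(ds.group)
        for name in roster:
            preds, log = run_classifier(
                name, train_X, train_labels, test_X, config, alpha=alpha
            )
            rows.append(
                {
                    "subject": ds.subject_id,
                    "cnr": ds.cnr,
                    "classifier": name,
                    "task_subset": "all" if task_subset is None else str(tuple(task_subset)),
                    "accuracy": accuracy(preds, test_labels),
                }
            )
            if keep_logs and log is not None:
                logs[(ds.subject_id, ds.cnr, name)] = log
    acc = pd.DataFrame(rows)

    pv_rows = []
    if "semisrc_ave" in roster:
        ref = acc[acc.classifier == "semisrc_ave"]
        for name in roster:
            if name == "semisrc_ave":
                continue
            other = acc[acc.classifier == name]
            for cnr in sorted(acc.cnr.unique()):
                x = ref[ref.cnr == cnr].sort_values("subject")["accuracy"].to_numpy()
                y = other[other.cnr == cnr].sort_values("subject")["accuracy"].to_numpy()
                pv_rows.append(
                    {"cnr": cnr, "classifier": name, "p_value": wilcoxon_paired(x, y)}
                )
    return ExperimentResult(
        accuracy=acc,
        pvalues=pd.DataFrame(pv_rows) if pv_rows else None,
        logs=logs,
    )


def sweep_alpha(
    collection,
    alpha_grid=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    config: DecodeConfig | None = None,
    task_subset=None,
    test_stride: int = 1,
):
    """Mean semisupervised accuracy per threshold coefficient.

    For each alpha: accuracy averaged across subjects at each CNR, then
    across CNR levels.  Returns ``(table, best_alpha)``; ties go to the
    smaller alpha.  ``test_stride > 1`` keeps every stride-th test
    volume (in time order) — a desk-scale reduction of the stream.
    """
    config = config or DecodeConfig()
    alpha_grid = tuple(alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid must be nonempty")
    if test_stride < 1:
        raise ValueError("test_stride must be >= 1")
    rows = []
    for ds in collection:
        train_X, train_labels, test_X, test_labels = prepare_dataset(
            ds, config, task_subset
        )
        test_X = test_X[::test_stride]
        test_labels = test_labels[::test_stride]
        for alpha in alpha_grid:
            preds, _ = run_classifier(
                "semisrc_ave", train_X, train_labels, test_X, config, alpha=alpha
            )
            rows.append(
                {
                    "alpha": alpha,
                    "subject": ds.subject_id,
                    "cnr": ds.cnr,
                    "accuracy": accuracy(preds, test_labels),
                }
            )
    raw = pd.DataFrame(rows)
    per_cnr = (
        raw.groupby(["alpha", "cnr"], sort=True)["accuracy"].mean().reset_index()
    )
    table = per_cnr.groupby("alpha", sort=True)["accuracy"].mean().reset_index()
    table = table.rename(columns={"accuracy": "mean_accuracy"})
    best = float(table.loc[table["mean_accuracy"].idxmax(), "alpha"])
    return table, best
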