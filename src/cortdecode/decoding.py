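"""Per-subject decoders of the 8-level stress state.

Three model families are supported: an RBF-kernel SVM classifier, support
vector regression on the numeric label (predictions clipped to [1, 8] and
used unrounded for RMSE), and a two-hidden-layer MLP classifier.  The
evaluation protocol repeats a stratified report-level 80/20 split
``n_iterations`` times (seed ``base_seed + i`` for iteration i): all block
samples from one 15 s report always land on the same side of the split,
feature ranking and standardisation use the training side only, and RMSE /
accuracy are computed on the held-out reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import wilcoxon
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.neural_network import MLPClassifier

from .surface import FeatureMatrix, select_features

__all__ = [
    "ExperimentConfig",
    "DecodingResult",
    "ComparisonResult",
    "Decoder",
    "split_by_report",
    "train_decoder",
    "rmse",
    "accuracy",
    "run_experiment",
    "optimize_feature_count",
    "compare_conditions",
]

MODEL_KINDS = ("svm", "svr", "mlp")


@dataclass(frozen=True)
class ExperimentConfig:
    """One decoding configuration (model x block size x feature count)."""

    model_kind: str = "svm"
    block_size: int = 5
    k_sub: int | None = None  # None = use all features
    n_iterations: int = 25
    test_fraction: float = 0.2
    base_seed: int = 0
    svm_c: float = 100.0
    svm_gamma: str | float = "scale"
    svr_c: float = 100.0
    svr_epsilon: float = 0.1
    mlp_hidden: tuple[int, int] = (64, 32)
    mlp_max_iter: int = 500
    mlp_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class DecodingResult:
    """Per-iteration RMSE/accuracy distributions for one configuration."""

    rmse_per_iter: np.ndarray
    accuracy_per_iter: np.ndarray
    predictions: list[np.ndarray]
    true_labels: list[np.ndarray]
    config: ExperimentConfig

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse_per_iter))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.rmse_per_iter, ddof=1)) if len(self.rmse_per_iter) > 1 else 0.0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy_per_iter))

    @property
    def sd_accuracy(self) -> float:
        return (
            float(np.std(self.accuracy_per_iter, ddof=1))
            if len(self.accuracy_per_iter) > 1
            else 0.0
        )


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    direction: str  # "A<B", "A>B" or "tie" (sign of median RMSE difference)
    median_difference: float


def split_by_report(
    samples: FeatureMatrix, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Report-level stratified train/test split.

    The unit of splitting is the report group: every block sample from a
    15 s report lands on the same side.  Within each stress level,
    ``round(n_reports * test_fraction)`` reports go to test (capped so at
    least two reports per level stay in training); a level with a single
    report goes to training with a warning.  Returns row indices.
    """
    if samples.groups is None or samples.labels is None:
        raise ValueError("samples must carry labels and report group ids")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    groups = np.asarray(samples.groups)
    labels = np.asarray(samples.labels)
    uniq, first = np.unique(groups, return_index=True)
    report_labels = labels[first]

    rng = np.random.default_rng(seed)
    test_groups: list[int] = []
    for level in np.unique(report_labels):
        g_level = uniq[report_labels == level]
        n = len(g_level)
        if n < 2:
            warnings.warn(
                f"stress level {level} has a single report; kept in training",
                stacklevel=2,
            )
            continue
        n_test = int(round(n * test_fraction))
        n_test = min(n_test, max(n - 2, 0))
        if n_test == 0:
            continue
        test_groups.extend(rng.permutation(g_level)[:n_test].tolist())

    test_mask = np.isin(groups, test_groups)
    return np.where(~test_mask)[0], np.where(test_mask)[0]


@dataclass
class Decoder:
    """A fitted model plus the prediction conventions of its family."""

    kind: str
    pipeline: Pipeline

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predictions on the 1-8 label scale (float for SVR, ints else)."""
        p = self.pipeline.predict(x)
        if self.kind == "svr":
            return np.clip(p, 1.0, 8.0)
        return p.astype(np.float64)


def train_decoder(train: FeatureMatrix, config: ExperimentConfig, seed: int = 0) -> Decoder:
    """Fit one decoder; features are standardised with training statistics.

    Raises
    ------
    ValueError
        If the training labels contain a single class.
    """
    if train.labels is None:
        raise ValueError("training FeatureMatrix has no labels")
    y = np.asarray(train.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set has a single class")
    if config.model_kind == "svm":
        model = SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma)
    elif config.model_kind == "svr":
        model = SVR(kernel="rbf", C=config.svr_c, epsilon=config.svr_epsilon)
    else:
        model = MLPClassifier(
            hidden_layer_sizes=config.mlp_hidden,
            max_iter=config.mlp_max_iter,
            alpha=config.mlp_alpha,
            random_state=seed,
        )
    pipe = Pipeline([("scale", StandardScaler()), ("model", model)])
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(train.data, y.astype(np.float64) if config.model_kind == "svr" else y)
    return Decoder(kind=config.model_kind, pipeline=pipe)


def rmse(pred, true) -> float:
    """Root mean square error between predicted and reported levels."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(true, dtype=np.float64)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and true must be non-empty and equally long")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def accuracy(pred, true) -> float:
    """Exact 8-class match fraction.

    Non-integer predictions (SVR) are rounded to the nearest integer,
    ties away from zero, then clipped to [1, 8].
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(true, dtype=np.float64)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and true must be non-empty and equally long")
    rounded = np.clip(np.copysign(np.floor(np.abs(p) + 0.5), p), 1.0, 8.0)
    return float(np.mean(rounded == t))


def _one_iteration(
    samples: FeatureMatrix, config: ExperimentConfig, seed: int
) -> tuple[float, float, np.ndarray, np.ndarray]:
    train_idx, test_idx = split_by_report(samples, config.test_fraction, seed)
    train = samples.subset_samples(train_idx)
    test = samples.subset_samples(test_idx)
    if config.k_sub is not None and config.k_sub < samples.n_features:
        cols = select_features(train, config.k_sub)
        train = train.subset_features(cols)
        test = test.subset_features(cols)
    dec = train_decoder(train, config, seed=seed)
    pred = dec.predict(test.data)
    true = np.asarray(test.labels, dtype=np.float64)
    return rmse(pred, true), accuracy(pred, true), pred, true


def run_experiment(samples: FeatureMatrix, config: ExperimentConfig) -> DecodingResult:
    """Repeat split -> select -> fit -> score for ``n_iterations``."""
    rmses, accs, preds, trues = [], [], [], []
    for i in range(config.n_iterations):
        try:
            r, a, p, t = _one_iteration(samples, config, config.base_seed + i)
        except Exception as exc:  # annotate with the iteration index
            raise RuntimeError(f"iteration {i} failed: {exc}") from exc
        rmses.append(r)
        accs.append(a)
        preds.append(p)
        trues.append(t)
    return DecodingResult(
        rmse_per_iter=np.asarray(rmses),
        accuracy_per_iter=np.asarray(accs),
        predictions=preds,
        true_labels=trues,
        config=config,
    )


def optimize_feature_count(
    samples: FeatureMatrix,
    config: ExperimentConfig,
    candidates: tuple[int, ...] = (1600, 2400, 4700),
) -> tuple[int, dict[int, DecodingResult]]:
    """Run the experiment per candidate feature count; pick the lowest
    mean RMSE (ties favour the larger count).  The seed schedule is shared
    across candidates so comparisons are paired."""
    if max(candidates) > samples.n_features:
        raise ValueError("a candidate exceeds the available feature count")
    results: dict[int, DecodingResult] = {}
    for k in candidates:
        results[k] = run_experiment(samples, replace(config, k_sub=k))
    best = min(sorted(results, reverse=True), key=lambda k: results[k].mean_rmse)
    return best, results


def compare_conditions(result_a: DecodingResult, result_b: DecodingResult) -> ComparisonResult:
    """Paired two-sided Wilcoxon signed-rank test on per-iteration RMSE.

    Requires matched iteration counts (and, for a meaningful pairing, the
    same seed schedule).  If every difference is zero the p-value is 1.0
    by convention.
    """
    a = np.asarray(result_a.rmse_per_iter, dtype=np.float64)
    b = np.asarray(result_b.rmse_per_iter, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("results must have equal n_iterations")
    d = a - b
    if np.all(d == 0.0):
        return ComparisonResult(p_value=1.0, direction="tie", median_difference=0.0)
    stat = wilcoxon(d)
    med = float(np.median(d))
    direction = "tie" if med == 0 else ("A<B" if med < 0 else "A>B")
    return ComparisonResult(
        p_value=float(stat.pvalue), direction=direction, median_difference=med
    )
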