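"""Permutation testing of decoder performance.

The null hypothesis is that the cortical features carry no information
about the reported stress level.  Labels are permuted at the report level
(all block samples of one 15 s report keep a common, permuted label) so
the permuted data retain the block structure the split respects — a
sample-level shuffle would make the null anti-conservative on temporally
autocorrelated data.  The p-value uses the add-one convention
``p = (1 + #{null <= observed}) / (1 + n_permutations)`` and is never 0.

Two analytic anchors bound where null RMSE means can live for balanced
1-8 labels: a label-independent constant prediction at 4.5 has RMSE
``sqrt(5.25) ~ 2.291`` (the constant-predictor floor), and independent
uniform guessing has RMSE ``sqrt(10.5) ~ 3.240``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import DecodingResult, ExperimentConfig, run_experiment
from .surface import FeatureMatrix

__all__ = [
    "PermutationResult",
    "permute_labels",
    "permutation_test",
    "permutation_pvalue",
    "constant_predictor_rmse",
    "uniform_guess_rmse",
]


def permutation_pvalue(observed_mean: float, null_means: np.ndarray) -> float:
    """Add-one permutation p-value (never 0; 1/(n+1) when the observed
    mean beats every null mean, 1.0 when it beats none)."""
    null_means = np.asarray(null_means, dtype=np.float64)
    if null_means.size == 0:
        raise ValueError("need at least one null replicate")
    return float((1.0 + np.sum(null_means <= observed_mean)) / (1.0 + null_means.size))


@dataclass
class PermutationResult:
    """Observed RMSE distribution vs the permuted-label null."""

    observed: DecodingResult
    null_mean_rmse: np.ndarray  # one mean RMSE per permutation replicate
    p_value: float
    overlap: bool  # False when max(observed) < min(null)

    @property
    def observed_mean_rmse(self) -> float:
        return self.observed.mean_rmse


def permute_labels(
    samples: FeatureMatrix, seed: int, within_session: bool = False
) -> FeatureMatrix:
    """Permute stress labels across reports, preserving block structure.

    The multiset of report-level labels is preserved; every block sample
    of a report receives that report's new label.  Deterministic per seed.
    With ``within_session=True`` labels are shuffled only among reports of
    the same session, preserving any between-session label imbalance.
    """
    if samples.groups is None or samples.labels is None:
        raise ValueError("samples must carry labels and report group ids")
    groups = np.asarray(samples.groups)
    labels = np.asarray(samples.labels)
    uniq, first = np.unique(groups, return_index=True)
    report_labels = labels[first]
    if len(np.unique(report_labels)) < 2:
        raise ValueError("need at least two distinct labels to permute")
    rng = np.random.default_rng(seed)
    if within_session and samples.session is not None:
        sessions = np.asarray(samples.session)[first]
        permuted = report_labels.copy()
        for s in np.unique(sessions):
            idx = np.where(sessions == s)[0]
            permuted[idx] = report_labels[idx][rng.permutation(len(idx))]
    else:
        permuted = report_labels[rng.permutation(len(uniq))]
    lut = dict(zip(uniq.tolist(), permuted.tolist()))
    new_labels = np.asarray([lut[g] for g in groups], dtype=labels.dtype)
    out = FeatureMatrix(
        data=samples.data,
        feature_ids=samples.feature_ids,
        labels=new_labels,
        groups=samples.groups,
        session=samples.session,
        run=samples.run,
        meta=dict(samples.meta),
    )
    return out


def permutation_test(
    samples: FeatureMatrix,
    config: ExperimentConfig,
    n_permutations: int = 25,
    seed: int = 0,
    observed: DecodingResult | None = None,
    null_iterations: int | None = None,
) -> PermutationResult:
    """Rebuild the null RMSE distribution under permuted labels.

    The observed result is the full experiment on true labels (or a
    precomputed one); each null replicate reruns the same experiment on a
    report-permuted copy of the labels and contributes its mean RMSE.
    ``null_iterations`` optionally runs the null replicates with fewer
    split/fit iterations than the observed arm (the replicate mean is
    noisier but unbiased), keeping large permutation runs affordable.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if observed is None:
        observed = run_experiment(samples, config)
    null_config = config
    if null_iterations is not None:
        from dataclasses import replace

        null_config = replace(config, n_iterations=null_iterations)
    null_means = np.empty(n_permutations)
    for j in range(n_permutations):
        perm = permute_labels(samples, seed=seed + j)
        null_means[j] = run_experiment(perm, null_config).mean_rmse
    p = permutation_pvalue(observed.mean_rmse, null_means)
    overlap = bool(np.max(observed.rmse_per_iter) >= np.min(null_means))
    return PermutationResult(
        observed=observed, null_mean_rmse=null_means, p_value=p, overlap=overlap
    )


def constant_predictor_rmse(levels: np.ndarray | None = None) -> float:
    """RMSE of the best label-independent constant prediction.

    For balanced levels 1..8 the optimal constant is 4.5 and the RMSE is
    ``sqrt(5.25)``: the floor for any decoder that ignores the features.
    """
    lv = np.arange(1, 9, dtype=np.float64) if levels is None else np.asarray(levels, float)
    return float(np.sqrt(np.mean((lv - lv.mean()) ** 2)))


def uniform_guess_rmse(levels: np.ndarray | None = None) -> float:
    """RMSE of guessing labels independently and uniformly from the pool.

    For balanced levels 1..8 this is ``sqrt(10.5)`` (twice the variance).
    """
    lv = np.arange(1, 9, dtype=np.float64) if levels is None else np.asarray(levels, float)
    diff = lv[:, None] - lv[None, :]
    return float(np.sqrt(np.mean(diff**2)))
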