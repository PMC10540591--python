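"""Temporal preprocessing: label alignment, normalization, nuisance
removal, optional filtering, and block averaging.

The fixed run-level order is: sample -> smooth -> (optional nuisance
regression / high-pass / Wiener deconvolution) -> percent-signal-change ->
block-average.  Every optional step is a no-op when disabled; disabling all
of them reproduces the minimal base pipeline.  Because the mean-removing
filters leave a zero-mean series, the pipeline normalises against the
per-feature temporal mean recorded *before* the optional steps (for the
base case this is identical to plain percent signal change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import LabelSchedule
from .hrf import HRFKernel
from .surface import FeatureMatrix

__all__ = [
    "NuisanceSet",
    "align_labels",
    "attach_labels",
    "percent_signal_change",
    "zscore_normalize",
    "regress_nuisance",
    "highpass_filter",
    "wiener_deconvolve",
    "block_average",
]


@dataclass(frozen=True)
class NuisanceSet:
    """Per-run nuisance regressors: (frames, regressors) matrix with names.

    Typical columns: six motion traces, an HRF-convolved button-press
    stick function, and an intercept.
    """

    regressors: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.regressors, dtype=np.float64)
        if r.ndim != 2:
            raise ValueError("regressors must be (frames, n_regressors)")
        if r.shape[1] != len(self.names):
            raise ValueError("names must match regressor columns")
        allzero = np.where(~np.any(r != 0.0, axis=0))[0]
        if len(allzero):
            bad = [self.names[i] for i in allzero]
            raise ValueError(f"all-zero regressors: {bad}")
        object.__setattr__(self, "regressors", r)

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[0]


def align_labels(
    run_frames: int, report_labels: np.ndarray, frames_per_report: int = 10
) -> np.ndarray:
    """Expand per-report labels to per-frame labels.

    Each report describes the preceding ``frames_per_report`` frames, so
    report r's label is assigned to frames
    ``[r * frames_per_report, (r+1) * frames_per_report)`` (0-based).

    Raises
    ------
    ValueError
        If ``run_frames != frames_per_report * n_reports``.
    """
    report_labels = np.asarray(report_labels)
    expected = frames_per_report * len(report_labels)
    if run_frames != expected:
        raise ValueError(
            f"frame accounting mismatch: {run_frames} frames but "
            f"{len(report_labels)} reports x {frames_per_report} frames/report "
            f"= {expected}"
        )
    return np.repeat(report_labels, frames_per_report)


def attach_labels(
    fm: FeatureMatrix, schedule: LabelSchedule, session: int, run: int
) -> FeatureMatrix:
    """Attach per-frame labels and report group ids to a per-frame matrix."""
    sub = schedule.table[
        (schedule.table.session == session) & (schedule.table.run == run)
    ].sort_values("report_index")
    labels = align_labels(
        fm.n_samples, sub["stress_level"].to_numpy(), schedule.frames_per_report
    )
    groups = np.repeat(sub["group"].to_numpy(), schedule.frames_per_report)
    return FeatureMatrix(
        data=fm.data,
        feature_ids=fm.feature_ids,
        labels=labels,
        groups=groups,
        session=np.full(fm.n_samples, session, dtype=np.int64),
        run=np.full(fm.n_samples, run, dtype=np.int64),
        meta=dict(fm.meta),
    )


def percent_signal_change(series: np.ndarray, baseline: np.ndarray | None = None) -> np.ndarray:
    """Per-feature percent signal change within a run.

    ``x_t -> 100 * (x_t / mean_t(x) - 1)``; the output has exactly zero
    temporal mean per feature.  If ``baseline`` is given (the per-feature
    temporal means recorded *before* mean-removing filters), the series is
    taken to be baseline-free deviations and is scaled as
    ``100 * x_t / baseline``.

    Raises
    ------
    ValueError
        If a feature's normalising mean is (numerically) zero, naming it.
    """
    x = np.asarray(series, dtype=np.float64)
    if baseline is None:
        m = x.mean(axis=0)
        scale = np.maximum(np.abs(x).max(axis=0), 1.0)
        bad = np.where(np.abs(m) <= 1e-12 * scale)[0]
        if len(bad):
            raise ValueError(f"zero temporal mean for feature(s) {bad.tolist()}")
        return 100.0 * (x / m - 1.0)
    m = np.asarray(baseline, dtype=np.float64)
    bad = np.where(np.abs(m) <= 1e-12 * np.maximum(np.abs(m).max(), 1.0))[0]
    if len(bad):
        raise ValueError(f"zero baseline for feature(s) {bad.tolist()}")
    return 100.0 * x / m


def zscore_normalize(series: np.ndarray) -> np.ndarray:
    """Per-feature z-scoring within a run (alternative to percent change)."""
    x = np.asarray(series, dtype=np.float64)
    sd = x.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def regress_nuisance(series: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """OLS residual of every feature on the nuisance regressors.

    Collinear regressor columns are pruned greedily (a column is kept only
    if it raises the rank, singular values below ``1e-10`` of the largest
    counting as zero); residuals are orthogonal to every kept regressor.
    The operation is idempotent.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.shape[0] != nuisance.n_frames:
        raise ValueError("series and nuisance frame counts differ")
    r = nuisance.regressors
    keep: list[int] = []
    for j in range(r.shape[1]):
        cand = r[:, keep + [j]]
        s = np.linalg.svd(cand, compute_uv=False)
        rank = int(np.sum(s > 1e-10 * s[0]))
        if rank == len(keep) + 1:
            keep.append(j)
    if not keep:
        raise ValueError("nuisance matrix is rank deficient after pruning")
    xk = r[:, keep]
    beta, *_ = np.linalg.lstsq(xk, x, rcond=None)
    return x - xk @ beta


def highpass_filter(series: np.ndarray, cutoff_hz: float = 0.01, tr_s: float = 1.5) -> np.ndarray:
    """Discrete-cosine drift removal below ``cutoff_hz``.

    Regresses out DCT-II basis functions ``cos(pi k (t + 0.5) / N)`` whose
    frequency ``k / (2 N TR)`` lies below the cutoff, including the
    constant (k = 0), and returns the residual.  Slow scanner drifts
    (linear and half-cosine trends) lie inside the removed span.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    x = np.asarray(series, dtype=np.float64)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = x.shape[0]
    k_max = int(np.ceil(2.0 * n * tr_s * cutoff_hz))  # k with freq < cutoff
    k = np.arange(max(k_max, 1))
    t = np.arange(n)
    basis = np.cos(np.pi * np.outer(t + 0.5, k) / n)
    beta, *_ = np.linalg.lstsq(basis, x, rcond=None)
    out = x - basis @ beta
    return out[:, 0] if one_d else out


def wiener_deconvolve(
    series: np.ndarray, hrf: HRFKernel, snr_param: float = 100.0
) -> np.ndarray:
    """Frequency-domain Wiener deconvolution of the HRF.

    ``Xhat(f) = X(f) H*(f) / (|H(f)|^2 + 1 / snr_param)``.  Used to undo
    the hemodynamic delay so the BOLD series re-aligns with the stimulus
    timing; output length equals input length.  As ``snr_param -> 0`` the
    output vanishes; for an impulse HRF and large ``snr_param`` the series
    is returned (numerically) unchanged.
    """
    if snr_param <= 0:
        raise ValueError("snr_param must be positive")
    x = np.asarray(series, dtype=np.float64)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = x.shape[0]
    h = hrf.samples
    nfft = int(2 ** np.ceil(np.log2(n + len(h))))
    xf = np.fft.rfft(x, n=nfft, axis=0)
    hf = np.fft.rfft(h, n=nfft)[:, None]
    out = np.fft.irfft(
        xf * np.conj(hf) / (np.abs(hf) ** 2 + 1.0 / snr_param), n=nfft, axis=0
    )[:n]
    return out[:, 0] if one_d else out


def block_average(frames: FeatureMatrix, bs: int, frames_per_report: int = 10) -> FeatureMatrix:
    """Average temporally adjacent frames within each report into samples.

    Each 15 s report window contributes ``frames_per_report`` frames; the
    last ``floor(frames_per_report / bs) * bs`` frames are kept (the
    earliest remainder frames, closest to the clip transition, are
    discarded) and averaged in non-overlapping blocks of ``bs``.  All
    block samples inherit the report's label and group id.
    """
    if not (1 <= bs <= frames_per_report):
        raise ValueError(f"block size must lie in 1..{frames_per_report}")
    if frames.groups is None or frames.labels is None:
        raise ValueError("frames must carry labels and report group ids")
    groups = np.asarray(frames.groups)
    n_blocks = frames_per_report // bs
    kept = n_blocks * bs

    out_rows, out_labels, out_groups, out_sess, out_run = [], [], [], [], []
    # preserve first-appearance order of report groups
    _, first = np.unique(groups, return_index=True)
    for g in groups[np.sort(first)]:
        idx = np.where(groups == g)[0]
        if len(idx) != frames_per_report:
            raise ValueError(
                f"report group {g} has {len(idx)} frames, expected {frames_per_report}"
            )
        tail = idx[-kept:]
        blocks = frames.data[tail].reshape(n_blocks, bs, -1).mean(axis=1)
        out_rows.append(blocks)
        out_labels.extend([frames.labels[idx[0]]] * n_blocks)
        out_groups.extend([g] * n_blocks)
        if frames.session is not None:
            out_sess.extend([frames.session[idx[0]]] * n_blocks)
        if frames.run is not None:
            out_run.extend([frames.run[idx[0]]] * n_blocks)

    meta = dict(frames.meta)
    meta["block_size"] = bs
    return FeatureMatrix(
        data=np.vstack(out_rows),
        feature_ids=frames.feature_ids,
        labels=np.asarray(out_labels),
        groups=np.asarray(out_groups),
        session=np.asarray(out_sess) if out_sess else None,
        run=np.asarray(out_run) if out_run else None,
        meta=meta,
    )
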