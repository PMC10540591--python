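"""Synthetic multisession BOLD generator with a ground-truth ordinal code.

Each of the 8 stress levels is given a smooth spatial activation pattern
over the gray-matter voxels (those within a configurable distance of the
gray--white mesh).  Patterns of adjacent levels are correlated by
``ordinal_overlap`` (a first-order autoregression across levels, built so
that the adjacent-level correlation is exact and the level-k correlation
decays like ``ordinal_overlap**k``): neighbouring levels are confusable,
distant levels are not, which is what makes RMSE a meaningful ordinal
error measure for the decoders.

The voxel signal is
``baseline * (1 + sum_l beta(v, l) * (w_l * HRF)(t))`` plus AR(1) temporal
noise everywhere, a per-run slow drift (linear + half-cosine), and
optional motion / button-press artifacts driven by the same regressors
that the nuisance-regression step removes.  The level weights ``w_l`` are
per-level boxcars except for a brief first-order lag at clip transitions
(``transition_tau_s``; 0 gives exact boxcars) modelling the inertia of the
subjective state when a new stimulus appears.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
stream seeded by ``SimulationParams.seed``; identical seeds reproduce the
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.spatial import cKDTree

import pandas as pd

from .design import LabelSchedule, SessionDesign
from .hrf import HRFKernel, double_gamma_hrf
from .mesh import CorticalMesh
from .preproc import NuisanceSet
from .volume import VolumeTimeSeries

__all__ = ["SimulationParams", "SimulatedRuns", "simulate_bold", "make_nuisance"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SimulationParams:
    """Statistical stand-in for the VR stimulus protocol.

    Amplitudes are fractional: ``effect_amplitude=0.05`` means a one-unit
    pattern activation modulates the signal by 5% of baseline.
    """

    n_levels: int = 8
    effect_amplitude: float = 0.05
    pattern_smoothness_mm: float = 6.0
    ordinal_overlap: float = 0.6
    transition_tau_s: float = 3.0
    noise_sd: float = 0.01
    ar1_coef: float = 0.4
    drift_amplitude: float = 0.01
    baseline_intensity: float = 1000.0
    voxel_size_mm: float = 2.0
    gm_thickness_mm: float = 2.0
    pad_mm: float = 6.0
    motion_artifact: float = 0.0
    button_artifact: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.ordinal_overlap < 1):
            raise ValueError("ordinal_overlap must lie in [0, 1)")
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must lie in [0, 1)")


@dataclass
class SimulatedRuns:
    """Bundle of simulated runs plus the generating ground truth."""

    runs: list[VolumeTimeSeries]
    schedule: LabelSchedule
    nuisance: list[NuisanceSet]
    beta_maps: np.ndarray  # (n_levels, X, Y, Z), includes effect_amplitude
    signal_mask: np.ndarray  # (X, Y, Z) bool
    params: SimulationParams


def _grid_geometry(mesh: CorticalMesh, params: SimulationParams):
    lo = mesh.vertices.min(axis=0) - params.pad_mm
    hi = mesh.vertices.max(axis=0) + params.pad_mm
    vs = params.voxel_size_mm
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / vs)) + 1 for i in range(3))
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * vs
    affine[:3, 3] = lo
    return shape, affine


def _level_patterns(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    mask: np.ndarray,
    params: SimulationParams,
) -> np.ndarray:
    """Smooth unit-variance patterns with exact adjacent-level correlation."""
    sigma_vox = params.pattern_smoothness_mm * _FWHM_TO_SIGMA / params.voxel_size_mm
    n_mask = int(mask.sum())

    def smooth_field() -> np.ndarray:
        g = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
        v = g[mask]
        return (v - v.mean()) / v.std()

    rho = params.ordinal_overlap
    b = np.empty((params.n_levels, n_mask))
    b[0] = smooth_field()
    for l in range(1, params.n_levels):
        g = smooth_field()
        # orthogonalise against the previous level so corr(b_l, b_{l+1}) = rho
        g = g - (g @ b[l - 1] / n_mask) * b[l - 1]
        g = g / g.std()
        b[l] = rho * b[l - 1] + np.sqrt(1.0 - rho**2) * g
        b[l] = b[l] / b[l].std()
    return b


def _level_boxcars(design: SessionDesign, run_idx: int) -> np.ndarray:
    """(n_levels, frames) indicator of which level is on screen."""
    run = design.runs[run_idx]
    frames = design.frames_per_run
    box = np.zeros((8, frames))
    f = 0
    for clip in run.clips:
        n = int(round(clip.duration_s / design.tr_s))
        box[clip.level - 1, f:f + n] = 1.0
        f += n
    return box


def _state_trajectory(design: SessionDesign, run_idx: int, tau_s: float) -> np.ndarray:
    """Continuous subjective stress state per frame.

    The state follows the on-screen clip level through a first-order lag
    with time constant ``tau_s`` (the inertia of engaging with a new
    stimulus); ``tau_s = 0`` makes the state jump with the clips.
    """
    box = _level_boxcars(design, run_idx)
    levels = np.arange(1, box.shape[0] + 1, dtype=np.float64)
    target = levels @ box  # on-screen level per frame
    if tau_s <= 0:
        return target
    alpha = 1.0 - np.exp(-design.tr_s / tau_s)
    s = np.empty_like(target)
    s[0] = target[0]
    for t in range(1, len(target)):
        s[t] = s[t - 1] + alpha * (target[t] - s[t - 1])
    return s


def _level_weights(state: np.ndarray, n_levels: int) -> np.ndarray:
    """Triangular interpolation of the state between integer-level patterns.

    An integer state activates its own pattern only; a fractional state
    mixes the two nearest patterns, so transitions traverse neighbouring
    patterns rather than jumping — the spatial counterpart of the ordinal
    code.
    """
    levels = np.arange(1, n_levels + 1, dtype=np.float64)
    return np.clip(1.0 - np.abs(state[None, :] - levels[:, None]), 0.0, None)


def _report_labels(state: np.ndarray, frames_per_report: int) -> np.ndarray:
    """The level the subject reports at each 15 s cue.

    The report is the state at the cue (the last frame of the window),
    rounded to the nearest integer level (ties away from zero).
    """
    cues = state[frames_per_report - 1::frames_per_report]
    return np.clip(np.floor(cues + 0.5), 1, 8).astype(np.int64)


def make_nuisance(
    n_frames: int,
    frames_per_report: int,
    hrf: HRFKernel,
    seed: int,
) -> NuisanceSet:
    """Motion traces, HRF-convolved button-press sticks, and an intercept.

    Six motion traces are smoothed random walks (standardised); the
    button-press regressor is a stick at the last frame of each report
    window convolved with the HRF, modelling the motor response to the
    report cue.
    """
    rng = np.random.default_rng(seed)
    motion = np.cumsum(rng.standard_normal((n_frames, 6)), axis=0)
    motion = gaussian_filter1d(motion, sigma=3.0, axis=0)
    motion = (motion - motion.mean(axis=0)) / motion.std(axis=0)

    stick = np.zeros(n_frames)
    stick[frames_per_report - 1::frames_per_report] = 1.0
    button = np.convolve(stick, hrf.samples)[:n_frames]

    names = tuple(f"motion_{i}" for i in range(6)) + ("button_press", "intercept")
    regs = np.column_stack([motion, button, np.ones(n_frames)])
    return NuisanceSet(regressors=regs, names=names)


def simulate_bold(
    mesh: CorticalMesh,
    design: SessionDesign | list[SessionDesign],
    params: SimulationParams | None = None,
    hrf: HRFKernel | None = None,
) -> SimulatedRuns:
    """Simulate HRF-convolved noisy BOLD runs for one synthetic subject.

    ``design`` may be a single session or a list of sessions; one 4D run
    (float32, 2 mm voxels by default) is produced per run per session,
    together with the ground-truth label schedule and per-run nuisance
    regressors.  Gray-matter voxels (within ``gm_thickness_mm`` of a mesh
    vertex) carry the level-specific signal; all voxels carry baseline,
    AR(1) noise and drift.
    """
    params = params or SimulationParams()
    designs = design if isinstance(design, list) else [design]
    hrf = hrf or double_gamma_hrf(tr_s=designs[0].tr_s)
    rng = np.random.default_rng(params.seed)

    shape, affine = _grid_geometry(mesh, params)
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    centers = ijk.reshape(-1, 3) * params.voxel_size_mm + affine[:3, 3]
    dist, _ = cKDTree(mesh.vertices).query(centers, k=1)
    mask = (dist <= params.gm_thickness_mm).reshape(shape)
    if not mask.any():
        raise ValueError("no voxels within gm_thickness_mm of the mesh")

    b = _level_patterns(rng, shape, mask, params) * params.effect_amplitude
    beta_maps = np.zeros((params.n_levels,) + shape)
    beta_maps[:, mask] = b

    base = params.baseline_intensity
    runs: list[VolumeTimeSeries] = []
    nuisances: list[NuisanceSet] = []
    label_rows: list[tuple[int, int, np.ndarray]] = []
    lin_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for si, sess in enumerate(designs, start=1):
        fpr = sess.frames_per_report
        for ri in range(sess.n_runs):
            frames = sess.frames_per_run
            if frames not in lin_cache:
                t = np.arange(frames)
                lin_cache[frames] = (
                    2.0 * t / (frames - 1) - 1.0,
                    np.cos(np.pi * t / (frames - 1)),
                )
            lin, halfcos = lin_cache[frames]

            state = _state_trajectory(sess, ri, params.transition_tau_s)
            box = _level_weights(state, params.n_levels)
            conv = np.stack(
                [np.convolve(box[l], hrf.samples)[:frames] for l in range(params.n_levels)]
            )
            label_rows.append((si, ri + 1, _report_labels(state, fpr)))

            data = np.full(shape + (frames,), base, dtype=np.float64)
            data[mask] += base * (b.T @ conv)

            if params.drift_amplitude > 0:
                a1 = rng.standard_normal(shape)
                a2 = rng.standard_normal(shape)
                data += (
                    base
                    * params.drift_amplitude
                    * (a1[..., None] * lin + a2[..., None] * halfcos)
                )
            else:  # keep the rng stream layout fixed across settings
                rng.standard_normal(shape)
                rng.standard_normal(shape)

            if params.noise_sd > 0:
                sd = params.noise_sd * base
                innov = np.sqrt(1.0 - params.ar1_coef**2)
                e = rng.standard_normal(shape) * sd
                data[..., 0] += e
                for t in range(1, frames):
                    e = params.ar1_coef * e + innov * rng.standard_normal(shape) * sd
                    data[..., t] += e

            nuis_seed = int(rng.integers(0, 2**31 - 1))
            nuis = make_nuisance(frames, fpr, hrf, seed=nuis_seed)
            if params.motion_artifact > 0 or params.button_artifact > 0:
                amps = np.r_[
                    np.full(6, params.motion_artifact), params.button_artifact
                ]
                loadings = rng.standard_normal(shape + (7,))
                art = loadings @ (amps[:, None] * nuis.regressors[:, :7].T)
                data += base * art
            nuisances.append(nuis)

            runs.append(
                VolumeTimeSeries(
                    data=data.astype(np.float32),
                    affine=affine,
                    tr_s=sess.tr_s,
                    session=si,
                    run=ri + 1,
                )
            )

    interval = designs[0].report_interval_s
    rows, group = [], 0
    for si, ri, labels in label_rows:
        for idx, level in enumerate(labels):
            rows.append(
                {
                    "session": si,
                    "run": ri,
                    "report_index": idx,
                    "onset": idx * interval,
                    "duration": interval,
                    "stress_level": int(level),
                    "group": group,
                }
            )
            group += 1
    schedule = LabelSchedule(
        table=pd.DataFrame(rows),
        frames_per_report=designs[0].frames_per_report,
        tr_s=designs[0].tr_s,
    )

    return SimulatedRuns(
        runs=runs,
        schedule=schedule,
        nuisance=nuisances,
        beta_maps=beta_maps,
        signal_mask=mask,
        params=params,
    )
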