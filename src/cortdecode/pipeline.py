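"""End-to-end drivers: volumes -> features -> samples -> decoders.

`extract_block_samples` is the canonical run-level pipeline with the fixed
stage order sample -> smooth -> patch-average -> (optional nuisance
regression / high-pass / Wiener) -> percent-signal-change -> block-average.
`run_ablation` reproduces the four-variant preprocessing comparison (base
case, +motion regression, +high-pass, +Wiener).  `run_pipeline` is the
configuration-driven entry point behind the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import DecodingResult, ExperimentConfig, run_experiment
from .design import LabelSchedule, make_session_design
from .hrf import HRFKernel, double_gamma_hrf
from .mesh import CorticalMesh, make_synthetic_mesh
from .preproc import (
    NuisanceSet,
    attach_labels,
    block_average,
    highpass_filter,
    percent_signal_change,
    regress_nuisance,
    wiener_deconvolve,
    zscore_normalize,
)
from .significance import permutation_test
from .simulate import SimulatedRuns, SimulationParams, simulate_bold
from .surface import (
    FeatureMatrix,
    PatchPartition,
    build_patch_partition,
    patch_features,
    sample_volume_to_surface,
    surface_smooth,
)
from .volume import VolumeTimeSeries

logger = logging.getLogger("cortdecode")

__all__ = [
    "PreprocOptions",
    "extract_block_samples",
    "simulate_subject",
    "run_ablation",
    "run_pipeline",
    "config_hash",
    "ABLATION_VARIANTS",
]


@dataclass(frozen=True)
class PreprocOptions:
    """Optional temporal steps; everything defaults to the base case."""

    motion_regression: bool = False
    highpass: bool = False
    wiener: bool = False
    highpass_cutoff_hz: float = 0.01
    wiener_snr: float = 100.0
    normalize: str = "psc"  # "psc" or "zscore"


# Four-row preprocessing comparison: steps added in succession.
ABLATION_VARIANTS: tuple[tuple[str, PreprocOptions], ...] = (
    ("none", PreprocOptions()),
    ("motion", PreprocOptions(motion_regression=True)),
    ("highpass+motion", PreprocOptions(motion_regression=True, highpass=True)),
    (
        "highpass+motion+wiener",
        PreprocOptions(motion_regression=True, highpass=True, wiener=True),
    ),
)


def extract_block_samples(
    runs: list[VolumeTimeSeries],
    mesh: CorticalMesh,
    schedule: LabelSchedule,
    *,
    fwhm_mm: float = 6.0,
    k_base: int = 5100,
    block_size: int = 5,
    options: PreprocOptions = PreprocOptions(),
    nuisance: list[NuisanceSet] | None = None,
    hrf: HRFKernel | None = None,
    partition: PatchPartition | None = None,
) -> FeatureMatrix:
    """Turn co-registered runs into labelled block-averaged samples.

    The per-feature temporal mean is recorded before the optional steps so
    percent signal change stays well defined after mean-removing filters
    (for the base case this is plain percent signal change).
    """
    if options.motion_regression and nuisance is None:
        raise ValueError("motion_regression requested but no nuisance regressors given")
    if partition is None:
        partition = build_patch_partition(mesh, k_base)
    if options.wiener and hrf is None:
        hrf = double_gamma_hrf(tr_s=runs[0].tr_s)

    per_run: list[FeatureMatrix] = []
    for i, vol in enumerate(runs):
        sts = sample_volume_to_surface(vol, mesh)
        sts = surface_smooth(sts, mesh, fwhm_mm)
        fm = patch_features(sts, partition)
        x = fm.data
        baseline = x.mean(axis=0)

        mean_removed = False
        if options.motion_regression:
            x = regress_nuisance(x, nuisance[i])
            mean_removed = True  # the intercept column demeans the series
        if options.highpass:
            x = highpass_filter(x, cutoff_hz=options.highpass_cutoff_hz, tr_s=vol.tr_s)
            mean_removed = True
        if options.wiener:
            if mean_removed:
                x = wiener_deconvolve(x, hrf, snr_param=options.wiener_snr)
            else:
                x = baseline + wiener_deconvolve(x - baseline, hrf, snr_param=options.wiener_snr)

        if options.normalize == "psc":
            x = percent_signal_change(x, baseline=baseline if mean_removed else None)
        elif options.normalize == "zscore":
            x = zscore_normalize(x)
        else:
            raise ValueError(f"unknown normalize option {options.normalize!r}")

        fm = FeatureMatrix(data=x, feature_ids=fm.feature_ids, meta=fm.meta)
        fm = attach_labels(fm, schedule, session=vol.session, run=vol.run)
        per_run.append(block_average(fm, block_size, schedule.frames_per_report))
        logger.info(
            "extract: session %d run %d -> %d samples x %d features",
            vol.session, vol.run, per_run[-1].n_samples, per_run[-1].n_features,
        )

    cat = lambda parts: None if parts[0] is None else np.concatenate(parts)
    meta = dict(per_run[0].meta)
    meta.update(
        fwhm_mm=fwhm_mm,
        k_base=k_base,
        block_size=block_size,
        preproc=asdict(options),
    )
    return FeatureMatrix(
        data=np.vstack([p.data for p in per_run]),
        feature_ids=per_run[0].feature_ids,
        labels=cat([p.labels for p in per_run]),
        groups=cat([p.groups for p in per_run]),
        session=cat([p.session for p in per_run]),
        run=cat([p.run for p in per_run]),
        meta=meta,
    )


def simulate_subject(
    subdivision_level: int = 3,
    radius_mm: float = 30.0,
    n_sessions: int = 2,
    n_runs: int = 5,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> tuple[CorticalMesh, SimulatedRuns]:
    """One synthetic subject: mesh, session designs, simulated runs.

    Session designs get distinct seeds derived from ``seed``; the
    simulation seed is taken from ``params`` (or ``seed`` if omitted).
    """
    mesh = make_synthetic_mesh(subdivision_level, radius_mm)
    designs = [make_session_design(n_runs=n_runs, seed=seed + s) for s in range(n_sessions)]
    if params is None:
        params = SimulationParams(seed=seed)
    sim = simulate_bold(mesh, designs, params)
    return mesh, sim


def run_ablation(
    runs: list[VolumeTimeSeries],
    mesh: CorticalMesh,
    schedule: LabelSchedule,
    nuisance: list[NuisanceSet],
    config: ExperimentConfig,
    *,
    fwhm_mm: float = 6.0,
    k_base: int = 5100,
    partition: PatchPartition | None = None,
    hrf: HRFKernel | None = None,
) -> pd.DataFrame:
    """Four-row preprocessing comparison for one subject (SVM/BS5 style).

    Rows: base case, +motion regression, +high-pass, +Wiener — each the
    mean (SD) RMSE over the experiment's iterations.
    """
    if partition is None:
        partition = build_patch_partition(mesh, k_base)
    rows = []
    for name, options in ABLATION_VARIANTS:
        samples = extract_block_samples(
            runs, mesh, schedule,
            fwhm_mm=fwhm_mm, k_base=k_base, block_size=config.block_size,
            options=options, nuisance=nuisance, hrf=hrf, partition=partition,
        )
        res = run_experiment(samples, config)
        rows.append(
            {
                "preprocessing": name,
                "rmse_mean": res.mean_rmse,
                "rmse_sd": res.sd_rmse,
                "accuracy_mean": res.mean_accuracy,
            }
        )
        logger.info("ablation %-24s RMSE %.3f (%.3f)", name, res.mean_rmse, res.sd_rmse)
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _result_row(res: DecodingResult) -> dict:
    c = res.config
    return {
        "model": c.model_kind,
        "block_size": c.block_size,
        "k_sub": "all" if c.k_sub is None else c.k_sub,
        "rmse_mean": res.mean_rmse,
        "rmse_sd": res.sd_rmse,
        "accuracy_mean": res.mean_accuracy,
        "accuracy_sd": res.sd_accuracy,
    }


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Configuration-driven end-to-end run; returns the summary dict.

    Recognised sections (all optional, with defaults): ``simulate``
    (synthetic subject parameters), ``features`` (fwhm_mm, k_base),
    ``preproc`` (optional-step toggles), ``experiment`` (models,
    block_sizes, k_subs, n_iterations, test_fraction), ``permutation``
    (enabled, n_permutations), and a global ``seed``.  Every artifact
    carries the configuration hash; per-grid-cell iteration results go to
    ``results.tsv`` and the summary to ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config.get("seed", 0))

    sim_cfg = dict(config.get("simulate", {}))
    feat_cfg = dict(config.get("features", {}))
    pre_cfg = dict(config.get("preproc", {}))
    exp_cfg = dict(config.get("experiment", {}))
    perm_cfg = dict(config.get("permutation", {}))

    params = SimulationParams(
        seed=seed,
        **{k: v for k, v in sim_cfg.items()
           if k in SimulationParams.__dataclass_fields__ and k != "seed"},
    )
    mesh, sim = simulate_subject(
        subdivision_level=int(sim_cfg.get("subdivision_level", 3)),
        radius_mm=float(sim_cfg.get("radius_mm", 30.0)),
        n_sessions=int(sim_cfg.get("n_sessions", 2)),
        n_runs=int(sim_cfg.get("n_runs", 2)),
        params=params,
        seed=seed,
    )
    logger.info("simulate: %d runs, grid %s", len(sim.runs), sim.runs[0].shape)

    fwhm = float(feat_cfg.get("fwhm_mm", 6.0))
    k_base = int(feat_cfg.get("k_base", 5100))
    options = PreprocOptions(**pre_cfg)
    partition = build_patch_partition(mesh, k_base)

    models = exp_cfg.get("models", ["svm"])
    block_sizes = [int(b) for b in exp_cfg.get("block_sizes", [5])]
    k_subs = exp_cfg.get("k_subs", [None])
    n_iter = int(exp_cfg.get("n_iterations", 25))
    test_fraction = float(exp_cfg.get("test_fraction", 0.2))

    samples_by_bs = {
        bs: extract_block_samples(
            sim.runs, mesh, sim.schedule,
            fwhm_mm=fwhm, k_base=k_base, block_size=bs,
            options=options, nuisance=sim.nuisance, partition=partition,
        )
        for bs in block_sizes
    }

    rows, iter_rows = [], []
    summary: dict = {"config_hash": chash, "results": []}
    for model in models:
        for bs in block_sizes:
            for k_sub in k_subs:
                cfg = ExperimentConfig(
                    model_kind=model,
                    block_size=bs,
                    k_sub=None if k_sub in (None, "all") else int(k_sub),
                    n_iterations=n_iter,
                    test_fraction=test_fraction,
                    base_seed=seed,
                )
                res = run_experiment(samples_by_bs[bs], cfg)
                rows.append(_result_row(res))
                for i, (r, a) in enumerate(
                    zip(res.rmse_per_iter, res.accuracy_per_iter)
                ):
                    iter_rows.append(
                        {**_result_row(res), "iteration": i, "rmse": r, "accuracy": a}
                    )
                logger.info(
                    "decode %s bs=%d k=%s: RMSE %.3f (%.3f)",
                    model, bs, k_sub, res.mean_rmse, res.sd_rmse,
                )
                if perm_cfg.get("enabled", False):
                    perm = permutation_test(
                        samples_by_bs[bs], cfg,
                        n_permutations=int(perm_cfg.get("n_permutations", 25)),
                        seed=seed, observed=res,
                    )
                    rows[-1].update(
                        permutation_p=perm.p_value,
                        null_rmse_mean=float(perm.null_mean_rmse.mean()),
                        null_overlap=perm.overlap,
                    )

    summary["results"] = rows
    pd.DataFrame(iter_rows).to_csv(out / "results.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
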