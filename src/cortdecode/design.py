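"""Session/run designs and the self-report label schedule.

The experimental unit is an 8-minute run in which stress-inducing clips
(levels 2-8, nominally 60 or 90 s) alternate with calming clips (level 1,
nominally 30 or 60 s).  Subjects report their stress level on a 1-8 scale
every 15 s, i.e. every 10 frames at TR = 1.5 s, and each report is taken to
describe the preceding 15 s window.  Because every clip boundary falls on a
15 s multiple, each report window lies inside exactly one clip and inherits
its level as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Clip",
    "RunDesign",
    "SessionDesign",
    "LabelSchedule",
    "make_session_design",
    "label_schedule",
]

N_LEVELS = 8


@dataclass(frozen=True)
class Clip:
    """A stimulus clip: ordinal stress level and duration in seconds."""

    level: int
    duration_s: float


@dataclass(frozen=True)
class RunDesign:
    clips: tuple[Clip, ...]

    @property
    def duration_s(self) -> float:
        return float(sum(c.duration_s for c in self.clips))

    def report_labels(self, report_interval_s: float) -> np.ndarray:
        """Stress level per report window, in report order."""
        labels = []
        for clip in self.clips:
            n = int(round(clip.duration_s / report_interval_s))
            labels.extend([clip.level] * n)
        return np.asarray(labels, dtype=np.int64)


@dataclass(frozen=True)
class SessionDesign:
    """One scanning session: an ordered list of run designs.

    Invariants (checked on construction): clip durations within each run
    sum exactly to ``run_duration_s``, every clip duration is a positive
    multiple of ``report_interval_s``, the report interval is a multiple
    of ``tr_s``, and every level is an integer in [1, 8].
    """

    runs: tuple[RunDesign, ...]
    tr_s: float = 1.5
    report_interval_s: float = 15.0
    run_duration_s: float = 480.0

    def __post_init__(self) -> None:
        if round(self.report_interval_s / self.tr_s, 9) % 1 != 0:
            raise ValueError("report_interval_s must be a multiple of tr_s")
        for ri, run in enumerate(self.runs):
            if abs(run.duration_s - self.run_duration_s) > 1e-9:
                raise ValueError(
                    f"run {ri}: clip durations sum to {run.duration_s}, "
                    f"expected {self.run_duration_s}"
                )
            for clip in run.clips:
                if not (1 <= clip.level <= N_LEVELS) or clip.level != int(clip.level):
                    raise ValueError(f"run {ri}: level {clip.level} outside 1..{N_LEVELS}")
                ratio = clip.duration_s / self.report_interval_s
                if clip.duration_s <= 0 or abs(ratio - round(ratio)) > 1e-9:
                    raise ValueError(
                        f"run {ri}: clip duration {clip.duration_s} is not a "
                        f"positive multiple of {self.report_interval_s}"
                    )

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def frames_per_report(self) -> int:
        return int(round(self.report_interval_s / self.tr_s))

    @property
    def n_reports_per_run(self) -> int:
        return int(round(self.run_duration_s / self.report_interval_s))

    @property
    def frames_per_run(self) -> int:
        return self.n_reports_per_run * self.frames_per_report


def make_session_design(
    n_runs: int = 5,
    level_pool: tuple[int, ...] = tuple(range(1, 9)),
    seed: int = 0,
    tr_s: float = 1.5,
    report_interval_s: float = 15.0,
    run_duration_s: float = 480.0,
) -> SessionDesign:
    """Randomly pack runs with alternating stress and calm clips.

    Each run starts with a stress clip (random level 2-8, duration 60 or
    90 s) and alternates with calm clips (level 1, duration 30 or 60 s),
    greedily packed until the run is exactly ``run_duration_s`` long; a
    final clip that would overrun is truncated to the remaining time
    (always a multiple of the report interval).  Stress levels are drawn
    preferentially from the not-yet-used portion of ``level_pool`` so that
    every level in the pool appears at least once across the session.

    Deterministic for a fixed ``seed``.

    Raises
    ------
    ValueError
        If the session cannot host every level in ``level_pool`` at least
        once (too few runs for the pool).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    levels = sorted(set(int(l) for l in level_pool))
    if any(l < 1 or l > N_LEVELS for l in levels):
        raise ValueError("level_pool entries must lie in 1..8")
    rng = np.random.default_rng(seed)
    unused = set(levels) - {1}

    runs = []
    for _ in range(n_runs):
        clips: list[Clip] = []
        remaining = run_duration_s
        stress_turn = True
        while remaining > 0:
            if stress_turn:
                if unused:
                    level = int(rng.choice(sorted(unused)))
                    unused.discard(level)
                else:
                    level = int(rng.integers(2, N_LEVELS + 1))
                dur = float(rng.choice([60.0, 90.0]))
            else:
                level = 1
                dur = float(rng.choice([30.0, 60.0]))
            dur = min(dur, remaining)
            clips.append(Clip(level=level, duration_s=dur))
            remaining -= dur
            stress_turn = not stress_turn
        runs.append(RunDesign(clips=tuple(clips)))

    design = SessionDesign(
        runs=tuple(runs),
        tr_s=tr_s,
        report_interval_s=report_interval_s,
        run_duration_s=run_duration_s,
    )
    present = set()
    for run in design.runs:
        present.update(c.level for c in run.clips)
    missing = set(levels) - present
    if missing:
        raise ValueError(
            f"cannot pack levels {sorted(missing)} into {n_runs} run(s); "
            "use more runs or a smaller level_pool"
        )
    return design


@dataclass(frozen=True)
class LabelSchedule:
    """Ground-truth stress reports across sessions and runs.

    ``table`` has one row per report with columns ``session`` (1-based),
    ``run`` (1-based within session), ``report_index`` (0-based within
    run), ``onset`` (s, start of the 15 s window the report describes),
    ``duration`` (s) and ``stress_level`` (1-8).  ``group`` is a globally
    unique report id used for leakage-safe splitting.
    """

    table: pd.DataFrame
    frames_per_report: int = 10
    tr_s: float = 1.5

    def __post_init__(self) -> None:
        lv = self.table["stress_level"].to_numpy()
        if not np.all((lv >= 1) & (lv <= N_LEVELS) & (lv == lv.astype(int))):
            raise ValueError("stress levels must be integers in 1..8")

    @property
    def n_reports(self) -> int:
        return len(self.table)

    def labels_for(self, session: int, run: int) -> np.ndarray:
        sub = self.table[(self.table.session == session) & (self.table.run == run)]
        sub = sub.sort_values("report_index")
        return sub["stress_level"].to_numpy(dtype=np.int64)


def label_schedule(designs: list[SessionDesign]) -> LabelSchedule:
    """Flatten per-session designs into a single report table."""
    if not designs:
        raise ValueError("need at least one session design")
    interval = designs[0].report_interval_s
    rows = []
    group = 0
    for si, design in enumerate(designs, start=1):
        for ri, run in enumerate(design.runs, start=1):
            labels = run.report_labels(design.report_interval_s)
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
    table = pd.DataFrame(rows)
    return LabelSchedule(
        table=table,
        frames_per_report=designs[0].frames_per_report,
        tr_s=designs[0].tr_s,
    )
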