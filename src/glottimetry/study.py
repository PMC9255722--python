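"""Two-period crossover study pipeline and aggregation.

Runs the full per-subject chain (segmentation → morphometry → final-30-s
window → breath cycles → greatest cycle), collects per-subject endpoints
(selected-cycle A/L Max, A/L Min and their difference), and summarizes them
the way the study reports them: per-agent and per-stage descriptive
statistics (mean, SD, 95% CI, range) plus a paired agent comparison
(paired t and Wilcoxon signed-rank on the Max−Min endpoint) and the
between-agent variability ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cycles import (
    AOverLSeries,
    CycleConfig,
    detect_breath_cycles,
    extract_final_window,
    select_greatest_cycle,
    smooth_series,
)
from .morphometry import measure_series
from .segmentation import SegmentationConfig, segment_frame
from .synthetic import Recording, load_recording

__all__ = [
    "SubjectResult",
    "GroupSummary",
    "ComparisonResult",
    "SchemaError",
    "run_subject",
    "run_study",
    "summarize_group",
    "summarize_by_stage",
    "compare_agents",
    "load_supplementary_results",
    "write_results",
    "results_to_frame",
]

ENDPOINTS = ("al_max", "al_min", "al_diff")


class SchemaError(ValueError):
    """A results table is missing required columns."""


class PairingError(ValueError):
    """A subject lacks a result under one of the two agents."""


class EmptyGroupError(ValueError):
    """Summary statistics requested for an empty group."""


@dataclass
class SubjectResult:
    """Selected-cycle outcome of one subject under one agent at one stage."""

    subject_id: str
    sex: str
    stage: int
    agent: str
    al_max: float
    al_min: float
    n_valid_frames: int = 0
    n_cycles: int = 0
    flagged: bool = False
    flag_reason: str = ""

    @property
    def al_diff(self) -> float:
        return self.al_max - self.al_min


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of one endpoint over one group of subjects."""

    endpoint: str
    n: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float
    min: float
    max: float

    @property
    def range(self) -> float:
        return self.max - self.min


@dataclass(frozen=True)
class ComparisonResult:
    """Paired propofol-vs-alfaxalone comparison of the Max−Min endpoint."""

    subject_ids: tuple[str, ...]
    paired_differences: tuple[float, ...]  # first-agent minus second-agent
    mean_difference: float
    t_statistic: float
    t_pvalue: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    variability_ratio: float  # second-agent group mean / first-agent group mean
    agent_order: tuple[str, str]


def run_subject(
    recording: Recording | str | Path,
    seg_config: SegmentationConfig | None = None,
    cycle_config: CycleConfig | None = None,
    subject_id: str = "",
    sex: str = "",
    stage: int = 0,
    agent: str = "",
    use_ground_truth: bool = False,
) -> SubjectResult:
    """Run the full pipeline on one recording.

    ``recording`` may be a directory written by
    :func:`glottimetry.synthetic.save_recording` or an in-memory
    :class:`Recording`.  With ``use_ground_truth=True`` the generator's true
    A/L series bypasses segmentation (useful for kinematics-only
    simulations).  A recording with no detectable cycles comes back flagged
    (``flagged=True``) rather than raising, so study aggregation can exclude
    it with a logged reason.
    """
    seg_config = seg_config or SegmentationConfig()
    cycle_config = cycle_config or CycleConfig()
    if not isinstance(recording, Recording):
        recording = load_recording(recording)
    subject_id = subject_id or recording.subject_id
    stage = stage or recording.stage
    agent = agent or recording.agent

    if use_ground_truth or recording.frames is None:
        gt = recording.ground_truth
        from .morphometry import FrameMeasurement

        meas = [
            FrameMeasurement(i, float(t), float(a), float(l), float(al),
                             valid=np.isfinite(al))
            for i, (t, a, l, al) in enumerate(
                zip(gt.timestamps_s, gt.area_px2, gt.length_px, gt.a_over_l_px)
            )
        ]
    else:
        masks = [
            segment_frame(frame, seg_config, frame_index=i)
            for i, frame in enumerate(recording.frames)
        ]
        meas = measure_series(masks, recording.fps)
    series = AOverLSeries(meas, recording.fps)
    window = extract_final_window(series, cycle_config.window_s)
    smoothed = smooth_series(window, cycle_config.smooth_halfwidth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cycles = detect_breath_cycles(
            smoothed, cycle_config.min_prominence_frac, raw=window
        )
    base = dict(subject_id=subject_id, sex=sex, stage=stage, agent=agent,
                n_valid_frames=window.n_valid, n_cycles=len(cycles))
    if not cycles:
        return SubjectResult(al_max=np.nan, al_min=np.nan, flagged=True,
                             flag_reason="no detectable motion", **base)
    best = select_greatest_cycle(cycles)
    return SubjectResult(al_max=best.max_a_over_l, al_min=best.min_a_over_l,
                         **base)


def run_study(
    recordings: Sequence[Recording] | None = None,
    manifest: pd.DataFrame | None = None,
    seg_config: SegmentationConfig | None = None,
    cycle_config: CycleConfig | None = None,
    use_ground_truth: bool = False,
) -> list[SubjectResult]:
    """Run every recording of a study; labels come from the manifest rows."""
    results = []
    if recordings is not None:
        rows = manifest.to_dict("records") if manifest is not None else [{}] * len(recordings)
        for rec, row in zip(recordings, rows):
            results.append(
                run_subject(
                    rec, seg_config, cycle_config,
                    subject_id=row.get("subject_id", rec.subject_id),
                    sex=row.get("sex", ""),
                    stage=int(row.get("stage", rec.stage) or 0),
                    agent=row.get("agent", rec.agent),
                    use_ground_truth=use_ground_truth,
                )
            )
    elif manifest is not None:
        for row in manifest.to_dict("records"):
            results.append(
                run_subject(
                    row["path"], seg_config, cycle_config,
                    subject_id=row["subject_id"], sex=row.get("sex", ""),
                    stage=int(row["stage"]), agent=row["agent"],
                )
            )
    else:
        raise ValueError("provide recordings and/or a manifest")
    return results


def _endpoint_values(results: Iterable[SubjectResult], endpoint: str) -> np.ndarray:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    vals = [getattr(r, endpoint) for r in results if not r.flagged]
    return np.asarray(vals, dtype=float)


def summarize_group(
    results: Iterable[SubjectResult], endpoint: str = "al_diff"
) -> GroupSummary:
    """Mean, SD (n−1), t-based 95% CI, min and max of one endpoint.

    Computation stays at full precision; rounding to the integers the study
    tables print is a report-layer concern.
    """
    vals = _endpoint_values(results, endpoint)
    n = len(vals)
    if n == 0:
        raise EmptyGroupError("no unflagged results to summarize")
    mean = float(vals.mean())
    if n == 1:
        return GroupSummary(endpoint, 1, mean, np.nan, np.nan, np.nan,
                            mean, mean)
    sd = float(vals.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return GroupSummary(endpoint, n, mean, sd, mean - half, mean + half,
                        float(vals.min()), float(vals.max()))


def summarize_by_stage(
    results: Sequence[SubjectResult],
) -> dict[tuple[int, str], dict]:
    """Stage × agent cells: endpoint summaries plus per-cell sex counts."""
    cells: dict[tuple[int, str], dict] = {}
    for r in results:
        if r.stage not in (1, 2):
            raise ValueError(f"missing or invalid stage label on {r.subject_id!r}")
    keys = sorted({(r.stage, r.agent) for r in results})
    for key in keys:
        members = [r for r in results if (r.stage, r.agent) == key]
        active = [r for r in members if not r.flagged]
        cell: dict = {
            "n": len(active),
            "sex_counts": {
                "female": sum(r.sex == "female" for r in members),
                "male": sum(r.sex == "male" for r in members),
            },
        }
        for ep in ENDPOINTS:
            cell[ep] = summarize_group(active, ep) if active else None
        cells[key] = cell
    return cells


def compare_agents(
    results: Sequence[SubjectResult],
    agents: tuple[str, str] | None = None,
) -> ComparisonResult:
    """Paired comparison of the selected-cycle Max−Min endpoint.

    Pairs each subject's two results by subject id (exactly one per agent),
    and reports the paired t-test, the Wilcoxon signed-rank test (both
    two-sided, no multiplicity correction — two pre-specified co-primary
    analyses) and the variability ratio: the second agent's group mean
    Max−Min divided by the first agent's.
    """
    active = [r for r in results if not r.flagged]
    found_agents = sorted({r.agent for r in active})
    if agents is None:
        if len(found_agents) != 2:
            raise ValueError(f"expected exactly 2 agents, found {found_agents}")
        # prefer propofol-like first so the ratio reads alfaxalone/propofol
        agents = tuple(sorted(found_agents, key=lambda a: "prop" not in a.lower()))
    a1, a2 = agents
    by_subject: dict[str, dict[str, float]] = {}
    for r in active:
        by_subject.setdefault(r.subject_id, {})[r.agent] = r.al_diff
    ids, diffs = [], []
    for sid in sorted(by_subject):
        pair = by_subject[sid]
        if a1 not in pair or a2 not in pair:
            raise PairingError(f"subject {sid!r} lacks a result for both agents")
        ids.append(sid)
        diffs.append(pair[a1] - pair[a2])
    diffs_arr = np.asarray(diffs)
    if np.allclose(diffs_arr, 0.0):
        t_stat, t_p = 0.0, 1.0
        w_stat, w_p = 0.0, 1.0
    else:
        t_stat, t_p = stats.ttest_rel(
            [by_subject[s][a1] for s in ids], [by_subject[s][a2] for s in ids]
        )
        w_stat, w_p = stats.wilcoxon(diffs_arr)
    mean1 = _endpoint_values([r for r in active if r.agent == a1], "al_diff").mean()
    mean2 = _endpoint_values([r for r in active if r.agent == a2], "al_diff").mean()
    return ComparisonResult(
        subject_ids=tuple(ids),
        paired_differences=tuple(float(d) for d in diffs),
        mean_difference=float(diffs_arr.mean()),
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        wilcoxon_statistic=float(w_stat),
        wilcoxon_pvalue=float(w_p),
        variability_ratio=float(mean2 / mean1),
        agent_order=(a1, a2),
    )


DEFAULT_COLUMNS: Mapping[str, str] = {
    "subject_id": "subject_id",
    "sex": "sex",
    "stage": "stage",
    "agent": "agent",
    "al_max": "al_max",
    "al_min": "al_min",
}


def load_supplementary_results(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SubjectResult]:
    """Read per-subject endpoint values from a delimited or spreadsheet table.

    ``column_map`` maps the canonical fields (``subject_id, sex, stage,
    agent, al_max, al_min``) to the file's column names; missing required
    columns raise :class:`SchemaError` listing all absent fields.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    required = ["subject_id", "stage", "agent", "al_max", "al_min"]
    missing = [colmap[k] for k in required if colmap[k] not in df.columns]
    if missing:
        raise SchemaError(f"table is missing required columns: {missing}")
    results = []
    for _, row in df.iterrows():
        sex_col = colmap["sex"]
        results.append(
            SubjectResult(
                subject_id=str(row[colmap["subject_id"]]),
                sex=str(row[sex_col]) if sex_col in df.columns else "",
                stage=int(row[colmap["stage"]]),
                agent=str(row[colmap["agent"]]),
                al_max=float(row[colmap["al_max"]]),
                al_min=float(row[colmap["al_min"]]),
            )
        )
    return results


def results_to_frame(results: Sequence[SubjectResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "sex": r.sex,
                "stage": r.stage,
                "agent": r.agent,
                "al_max": r.al_max,
                "al_min": r.al_min,
                "al_diff": r.al_diff,
                "n_valid_frames": r.n_valid_frames,
                "n_cycles": r.n_cycles,
                "flagged": r.flagged,
                "flag_reason": r.flag_reason,
            }
            for r in results
        ]
    )


def write_results(results: Sequence[SubjectResult], path: str | Path) -> Path:
    """Write per-subject results as CSV (round-trips with the loader)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results_to_frame(results).to_csv(path, index=False)
    return path
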