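"""End-to-end study orchestration and reproduction harness.

Runs the full chain — synthetic four-arm study -> per-video kinematics ->
syncytium summaries -> ANOVA/LSD — and compares the resulting significance
patterns with the expected ones: under isoproterenol the amplitude effect is
sub-threshold while the acceleration effect is significant; the
electromagnetic field depresses contraction, significantly so in
acceleration; the combined arm is significantly depressed in every metric.
Because any single simulated study can miss a borderline contrast, the
reproduction verdict is a majority vote over independently seeded studies,
reported together with the per-seed split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fluor as fl
from .kinematics import (
    KinematicsParams,
    analyze_trajectory_set,
    summarize_syncytium,
    summarize_video,
)
from .stats import GroupSample, lsd_pairwise, one_way_anova, significance_pattern
from .synthgen import StudyDesign, iter_study
from .trajectories import ARMS

__all__ = [
    "EXPECTED_PATTERNS",
    "FLUOR_EFFECTS",
    "run_study",
    "metric_pattern",
    "fluor_study",
    "parameter_recovery",
    "repro",
    "ReproResult",
]

# Expected direction/significance of each LSD contrast, per metric
# ('+': significant increase, '-': significant decrease, 'ns': not significant)
EXPECTED_PATTERNS: dict[str, dict[str, str]] = {
    "D": {
        "ISO - CTRL": "ns",
        "EMF - CTRL": "ns",
        "ISO+EMF - CTRL": "-",
        "ISO+EMF - ISO": "-",
    },
    "Acc": {
        "ISO - CTRL": "+",
        "EMF - CTRL": "-",
        "ISO+EMF - CTRL": "-",
        "ISO+EMF - ISO": "-",
    },
    "fold": {
        "ISO - CTRL": "+",
        "EMF - CTRL": "-",
        "ISO+EMF - CTRL": "-",
        "ISO+EMF - ISO": "-",
    },
}

# Multiplicative per-arm effects on mean MF20 intensity (0-255 scale)
FLUOR_EFFECTS: dict[str, float] = {
    "CTRL": 1.00,
    "ISO": 1.30,
    "EMF": 0.75,
    "ISO+EMF": 0.85,
}


def run_study(design: StudyDesign = StudyDesign(), seed=0,
              kin: KinematicsParams = KinematicsParams()) -> pd.DataFrame:
    """Simulate one full study and reduce it to syncytium-level summaries.

    Returns one row per syncytium: ``condition, syncytium_id, D, V, Acc,
    n_videos, n_beats``, plus the ground-truth columns of the generator draw.
    """
    videos: dict[tuple[str, int], list] = {}
    truths: dict[tuple[str, int], object] = {}
    for label, sid, minute, ts, gt in iter_study(design, seed):
        records = analyze_trajectory_set(ts, kin)
        if not records:
            continue
        videos.setdefault((label, sid), []).append(summarize_video(records))
        truths[(label, sid)] = gt
    rows = []
    for (label, sid), summaries in videos.items():
        s = summarize_syncytium(summaries, sid, label)
        gt = truths[(label, sid)]
        rows.append(
            {
                "condition": label,
                "syncytium_id": sid,
                "D": s.D_mean,
                "V": s.V_mean,
                "Acc": s.Acc_mean,
                "n_videos": s.n_videos,
                "n_beats": s.n_beats,
                "D_true": gt.D_true,
                "V_true": gt.V_true,
                "Acc_true": gt.Acc_true,
            }
        )
    return pd.DataFrame(rows)


def metric_pattern(summaries: pd.DataFrame, metric: str,
                   alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA + LSD pattern table for one metric of a study summary frame."""
    groups = [
        GroupSample(arm, summaries.loc[summaries.condition == arm, metric].to_numpy())
        for arm in ARMS
        if (summaries.condition == arm).any()
    ]
    res = one_way_anova(groups)
    comps = lsd_pairwise(res, groups, alpha)
    return significance_pattern(comps)


def _pattern_matches(table: pd.DataFrame, expected: dict[str, str]) -> dict[str, bool]:
    got = dict(zip(table.contrast, table.direction))
    return {c: got.get(c) == want for c, want in expected.items()}


def fluor_study(seed=0, n_cells: int = 20, base_mean: float = 120.0,
                rel_sd: float = 0.15, alpha: float = 0.05) -> pd.DataFrame:
    """One synthetic immunofluorescence experiment, through segmentation.

    For each arm, renders one image of ``n_cells`` cells whose mean intensity
    is the arm's multiplicative effect on ``base_mean`` with ``rel_sd``
    relative cell-to-cell scatter, segments it blindly, quantifies per-cell
    mean intensity, and normalizes everything to the control mean.
    Returns the LSD pattern table over the per-cell folds.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for arm in ARMS:
        mu = base_mean * FLUOR_EFFECTS[arm]
        img, _, _ = fl.synth_fluor_image(
            n_cells=n_cells, intensity_mean=mu, intensity_sd=rel_sd * mu,
            seed=rng.integers(2 ** 31))
        labels = fl.segment_cells(img)
        cells = fl.quantify(img, labels)
        values[arm] = np.array([c.mean_intensity for c in cells])
    ctrl_mean = values["CTRL"].mean()
    groups = [GroupSample(arm, values[arm] / ctrl_mean) for arm in ARMS]
    res = one_way_anova(groups)
    comps = lsd_pairwise(res, groups, alpha)
    return significance_pattern(comps)


def parameter_recovery(n_syncytia: int = 50, seed=0,
                       design: StudyDesign = StudyDesign(),
                       kin: KinematicsParams = KinematicsParams()
                       ) -> pd.DataFrame:
    """Recovered-vs-true contraction metrics for seeded control syncytia.

    Each syncytium contributes one video at the control condition; the
    recovered metrics are the per-beat means of the farthest-from-center
    marker, the one whose amplitude the ground truth describes.
    """
    from .synthgen import synth_trajectories
    from .tracking import place_marker_grid

    h, w = design.frame_shape
    grid = place_marker_grid(w, h, design.grid_rows, design.grid_cols,
                             design.grid_margin).positions
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    dist = np.hypot(*(grid - center).T)
    far = int(np.argmax(dist))
    ctrl = design.arms[0]
    rows = []
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_syncytia)):
        ts, gt = synth_trajectories(ctrl, design.base, grid, tuple(center),
                                    design.timebase, seed=child)
        records = [r for r in analyze_trajectory_set(ts, kin)
                   if r.marker_id == far]
        if not records:
            continue
        rows.append(
            {
                "syncytium": i,
                "D": np.mean([r.D for r in records]),
                "V": np.mean([r.V for r in records]),
                "Acc": np.mean([r.Acc for r in records]),
                "D_true": gt.D_true,
                "V_true": gt.V_true,
                "Acc_true": gt.Acc_true,
            }
        )
    df = pd.DataFrame(rows)
    for m in ("D", "V", "Acc"):
        df[f"{m}_rel_err"] = (df[m] - df[f"{m}_true"]).abs() / df[f"{m}_true"]
    return df


@dataclass
class ReproResult:
    """Majority-vote reproduction verdict over independently seeded studies."""

    n_seeds: int
    per_contrast: pd.DataFrame      # metric, contrast, expected, n_match
    patterns_pass: dict[str, bool]  # metric -> all contrasts matched by majority

    @property
    def all_pass(self) -> bool:
        return all(self.patterns_pass.values())

    def report(self) -> str:
        lines = [
            f"Reproduction over {self.n_seeds} seeded studies "
            "(majority vote per contrast)",
            "",
        ]
        for metric, ok in self.patterns_pass.items():
            lines.append(f"[{'PASS' if ok else 'FAIL'}] {metric}")
            sub = self.per_contrast[self.per_contrast.metric == metric]
            for _, r in sub.iterrows():
                lines.append(
                    f"    {r.contrast:<18} expected {r.expected:>3}  "
                    f"matched {r.n_match}/{self.n_seeds}")
        lines.append("")
        lines.append("Note: LSD comparisons are unadjusted for multiplicity "
                     "(that is the procedure's definition).")
        return "\n".join(lines)


def repro(n_seeds: int = 20, seed=0, design: StudyDesign = StudyDesign(),
          metrics: tuple[str, ...] = ("D", "Acc"),
          include_fluor: bool = True, alpha: float = 0.05) -> ReproResult:
    """Run ``n_seeds`` independent studies and vote on every expected contrast."""
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in root.spawn(n_seeds)]
    counts: dict[tuple[str, str], int] = {}
    for s in child_seeds:
        summaries = run_study(design, seed=s)
        for metric in metrics:
            table = metric_pattern(summaries, metric, alpha)
            for contrast, ok in _pattern_matches(
                    table, EXPECTED_PATTERNS[metric]).items():
                counts[(metric, contrast)] = counts.get((metric, contrast), 0) + ok
        if include_fluor:
            table = fluor_study(seed=s, alpha=alpha)
            for contrast, ok in _pattern_matches(
                    table, EXPECTED_PATTERNS["fold"]).items():
                counts[("fold", contrast)] = counts.get(("fold", contrast), 0) + ok
    rows = []
    checked = list(metrics) + (["fold"] if include_fluor else [])
    for metric in checked:
        for contrast, want in EXPECTED_PATTERNS[metric].items():
            rows.append(
                {
                    "metric": metric,
                    "contrast": contrast,
                    "expected": want,
                    "n_match": counts.get((metric, contrast), 0),
                }
            )
    per_contrast = pd.DataFrame(rows)
    passes = {
        m: bool((per_contrast[per_contrast.metric == m].n_match
                 > n_seeds / 2).all())
        for m in checked
    }
    return ReproResult(n_seeds, per_contrast, passes)
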