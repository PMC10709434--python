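"""Group-level inference, gaze analyses, and behavioral metrics.

Group tests are one-sample tests against zero over subjects.  Following
standard practice for ROI summaries, a Shapiro-Wilk normality gate (alpha
0.05) decides between a Student t-test and a Wilcoxon signed-rank test;
whole-map style analyses in this package always use the t branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

_Z_CLIP = 1.0 - 1e-6


def fisher_z(r: float) -> float:
    """Variance-stabilizing atanh transform of a correlation.

    ``|r| >= 1`` (possible for degenerate noiseless patterns) is clipped to
    ``1 - 1e-6`` in magnitude so the transform stays finite.
    """
    r = float(r)
    if abs(r) >= 1.0:
        r = np.sign(r) * _Z_CLIP
    return float(np.arctanh(r))


@dataclass
class GroupTestResult:
    n: int
    mean: float
    statistic: float
    p: float
    sided: str                  # "two" | "greater" | "less"
    test: str                   # "t" | "wilcoxon"
    shapiro_p: float | None

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def group_test(
    values, sided: str = "two", gate_normality: bool = True
) -> GroupTestResult:
    """One-sample group test of ``values`` against zero.

    With ``gate_normality``, a Shapiro-Wilk rejection at 0.05 switches to
    the Wilcoxon signed-rank test; otherwise a Student t-test is used.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("need at least 3 observations for a group test")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    if x.std() == 0:
        # degenerate constant sample: decide by the mean directly
        mean = float(x.mean())
        consistent = (
            mean != 0
            if sided == "two"
            else (mean > 0 if sided == "greater" else mean < 0)
        )
        return GroupTestResult(
            n=len(x),
            mean=mean,
            statistic=float("inf") if consistent else 0.0,
            p=0.0 if consistent else 1.0,
            sided=sided,
            test="t",
            shapiro_p=None,
        )
    shapiro_p = None
    use_wilcoxon = False
    if gate_normality and x.std() > 0:
        shapiro_p = float(sp_stats.shapiro(x).pvalue)
        use_wilcoxon = shapiro_p < 0.05
    if use_wilcoxon:
        res = sp_stats.wilcoxon(x, alternative=alternative)
        stat, p, test = float(res.statistic), float(res.pvalue), "wilcoxon"
    else:
        res = sp_stats.ttest_1samp(x, 0.0, alternative=alternative)
        stat, p, test = float(res.statistic), float(res.pvalue), "t"
    return GroupTestResult(
        n=len(x),
        mean=float(x.mean()),
        statistic=stat,
        p=p,
        sided=sided,
        test=test,
        shapiro_p=shapiro_p,
    )


def _nearest_volume(times: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(times - t)))


def _volume_at_or_after(times: np.ndarray, t: float) -> int:
    idx = int(np.searchsorted(times, t - 1e-9))
    return min(idx, len(times) - 1)


def _volume_at_or_before(times: np.ndarray, t: float) -> int:
    idx = int(np.searchsorted(times, t + 1e-9)) - 1
    return max(idx, 0)


def gaze_trial_displacements(gaze, events: pd.DataFrame) -> pd.DataFrame:
    """Per-trial gaze displacement over the morph-to-imagination interval.

    The pre-movement sample is the volume nearest the morph onset; the
    post-movement sample is the first volume at or after the imagination
    onset, which guarantees the two samples bracket the morph interval at
    this TR.  Returns columns dx, dy, ego_offset.
    """
    times = gaze.volume_times
    rows = []
    for _, t in events.iterrows():
        i0 = _nearest_volume(times, t["morph_onset"])
        i1 = _volume_at_or_after(times, t["imag_onset"])
        rows.append(
            {
                "dx": gaze.x[i1] - gaze.x[i0],
                "dy": gaze.y[i1] - gaze.y[i0],
                "ego_offset": t["ego_offset"],
            }
        )
    return pd.DataFrame(rows)


def gaze_egocentric_correlation(gaze_runs, events_runs) -> dict:
    """Correlation of trial-wise gaze displacement with egocentric angle.

    Pools trials over runs for one subject and returns Pearson r for the
    horizontal and vertical axes plus their Fisher-z values.
    """
    frames = [
        gaze_trial_displacements(g, ev) for g, ev in zip(gaze_runs, events_runs)
    ]
    d = pd.concat(frames, ignore_index=True)
    with np.errstate(invalid="ignore"):
        r_x = float(np.corrcoef(d["dx"], d["ego_offset"])[0, 1])
        r_y = float(np.corrcoef(d["dy"], d["ego_offset"])[0, 1])
    return {
        "r_horizontal": r_x,
        "r_vertical": r_y,
        "z_horizontal": fisher_z(r_x),
        "z_vertical": fisher_z(r_y),
        "n_trials": len(d),
    }


def gaze_choice_validation(
    gaze_runs, events_runs, answer_lag_s: float = 1.5
) -> dict:
    """Correlation between chosen-option side and post-question gaze change.

    The chosen side is +1 (right) or -1 (left) given the response and the
    screen side of the Yes option; the gaze change is the horizontal
    difference between the last volume at or before the question onset and
    the first volume at or after ``question onset + answer_lag_s``.
    """
    sides, dxs = [], []
    for gaze, ev in zip(gaze_runs, events_runs):
        times = gaze.volume_times
        for _, t in ev.iterrows():
            resp = t.get("response")
            if not isinstance(resp, str):
                continue
            chosen = t["yes_side"] if resp == "yes" else (
                "right" if t["yes_side"] == "left" else "left"
            )
            i0 = _volume_at_or_before(times, t["question_onset"])
            i1 = _volume_at_or_after(times, t["question_onset"] + answer_lag_s)
            sides.append(1.0 if chosen == "right" else -1.0)
            dxs.append(gaze.x[i1] - gaze.x[i0])
    r = float(np.corrcoef(sides, dxs)[0, 1])
    return {"r": r, "z": fisher_z(r), "n_trials": len(sides)}


def behavior_metrics(events: pd.DataFrame) -> pd.DataFrame:
    """Hit and false-alarm percentages per context and question type.

    Hits: P(respond yes | expected yes); false alarms: P(respond yes |
    expected no).  Invariant to trial order; bounded in [0, 100].
    """
    ev = events.dropna(subset=["response"])
    rows = []
    for (context, question), grp in ev.groupby(["context", "question"]):
        yes = grp["response"] == "yes"
        target_yes = grp["expected_answer"] == "yes"
        n_hit_base = int(target_yes.sum())
        n_fa_base = int((~target_yes).sum())
        rows.append(
            {
                "context": context,
                "question": question,
                "hit_pct": 100.0 * float((yes & target_yes).sum()) / n_hit_base
                if n_hit_base
                else np.nan,
                "fa_pct": 100.0 * float((yes & ~target_yes).sum()) / n_fa_base
                if n_fa_base
                else np.nan,
                "n_trials": len(grp),
            }
        )
    return pd.DataFrame(rows)
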