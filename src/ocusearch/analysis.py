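"""Trial exclusion, condition summaries, saccade scoring, and paired tests.

The reaction-time pipeline: for each observer and condition, incorrect
button presses are excluded first; then, with mean ``m`` and standard
deviation ``s`` computed over the correct trials' RTs *before any outlier
removal*, trials with ``rt < 0.2`` s or ``rt > m + 3 s`` are excluded in a
single pass (no re-iteration).  Condition means and SEMs are computed over
the kept pool; gaze RTs use the same pool minus trials whose gaze never
reached the target.  When raw RTs vary strongly between observers, each
observer's condition means can be normalized by that observer's baseline
mean for the matching condition family.  Two conditions sharing observers
are compared with a matched-sample (paired) two-sided t-test at p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "TrialPool",
    "ConditionSummary",
    "PairedTestResult",
    "exclude_trials",
    "build_pools",
    "summarize",
    "summarize_condition",
    "normalize_by_baseline",
    "first_saccade_error",
    "gaze_reach_rt",
    "depth_split",
    "contrast_split",
    "paired_t",
    "compare_conditions",
]

#: RTs below this (s) are excluded as anticipations.
RT_FLOOR = 0.2
#: Condition key within one observer's trial log.
CONDITION_KEYS = ["condition", "O_mag", "transient_mode"]


@dataclass
class TrialPool:
    """Kept/excluded split of one observer x condition's trials."""

    observer_id: object
    condition_key: tuple
    kept: np.ndarray  # positional indices into the input order
    excluded: list[tuple[int, str]]  # (index, reason)
    flagged_empty: bool = False

    @property
    def n_total(self) -> int:
        return len(self.kept) + len(self.excluded)


@dataclass
class ConditionSummary:
    mean_rt_button: float
    sem_rt_button: float
    mean_rt_gaze: float | None
    sem_rt_gaze: float | None
    error_rate_button: float
    error_rate_first_saccade: float | None
    n_kept: int
    normalized_rt: float | None = None


@dataclass
class PairedTestResult:
    mean_difference: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    degenerate_variance: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def exclude_trials(rts, correct) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Single-pass exclusion rule for one observer x condition pool.

    Incorrect trials are removed first.  The outlier thresholds use the mean
    and sample standard deviation of the *correct* trials' RTs computed
    before any outlier removal; a trial is an outlier if its RT is below
    :data:`RT_FLOOR` or strictly above ``m + 3 s``.

    Returns ``(kept_indices, excluded)`` where ``excluded`` is a list of
    ``(index, reason)`` with reasons ``incorrect``, ``rt_too_short`` or
    ``rt_outlier_3sd``.
    """
    rts = np.asarray(rts, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if rts.shape != correct.shape:
        raise InvalidInputError("rts and correct must have equal length")
    excluded: list[tuple[int, str]] = []
    kept: list[int] = []
    pool_rts = rts[correct]
    if pool_rts.size:
        m = pool_rts.mean()
        s = pool_rts.std(ddof=1) if pool_rts.size > 1 else 0.0
        cutoff = m + 3.0 * s
    else:
        cutoff = math.inf
    for i, (rt, ok) in enumerate(zip(rts, correct)):
        if not ok:
            excluded.append((i, "incorrect"))
        elif rt < RT_FLOOR:
            excluded.append((i, "rt_too_short"))
        elif rt > cutoff:
            excluded.append((i, "rt_outlier_3sd"))
        else:
            kept.append(i)
    return np.array(kept, dtype=int), excluded


def build_pools(df: pd.DataFrame) -> list[TrialPool]:
    """Exclusion pools for every observer x condition in a trial log."""
    pools = []
    for (obs, *key), grp in df.groupby(["observer_id"] + CONDITION_KEYS, sort=True):
        kept, excl = exclude_trials(grp["rt_button_s"].to_numpy(), grp["correct"].to_numpy())
        pools.append(
            TrialPool(
                observer_id=obs,
                condition_key=tuple(key),
                kept=kept,
                excluded=excl,
                flagged_empty=kept.size == 0,
            )
        )
    return pools


def _kept_mask(df: pd.DataFrame) -> pd.Series:
    """Boolean kept-trial mask over a trial log, per observer x condition."""

    def _mask(grp: pd.DataFrame) -> pd.Series:
        kept, _ = exclude_trials(grp["rt_button_s"].to_numpy(), grp["correct"].to_numpy())
        m = np.zeros(len(grp), dtype=bool)
        m[kept] = True
        return pd.Series(m, index=grp.index)

    grouped = df.groupby(["observer_id"] + CONDITION_KEYS, sort=False, group_keys=False)
    return grouped[["rt_button_s", "correct"]].apply(_mask)


def summarize_condition(
    rts_kept, n_incorrect: int, n_total: int, gaze_rts_kept=None,
    saccade_errors=None,
) -> ConditionSummary | None:
    """Summary statistics over one kept pool; ``None`` if the pool is empty.

    ``gaze_rts_kept`` are the kept trials' gaze-arrival RTs with NaN where
    the gaze never reached the target (those trials are dropped from the
    gaze mean only).  ``saccade_errors`` is a boolean array over classified
    first saccades.
    """
    rts_kept = np.asarray(rts_kept, dtype=float)
    if rts_kept.size == 0:
        return None
    sem = rts_kept.std(ddof=1) / math.sqrt(rts_kept.size) if rts_kept.size > 1 else 0.0
    mean_gaze = sem_gaze = None
    if gaze_rts_kept is not None:
        g = np.asarray(gaze_rts_kept, dtype=float)
        g = g[~np.isnan(g)]
        if g.size:
            mean_gaze = float(g.mean())
            sem_gaze = g.std(ddof=1) / math.sqrt(g.size) if g.size > 1 else 0.0
    sac_rate = None
    if saccade_errors is not None:
        se = np.asarray(saccade_errors, dtype=bool)
        if se.size:
            sac_rate = float(se.mean())
    return ConditionSummary(
        mean_rt_button=float(rts_kept.mean()),
        sem_rt_button=float(sem),
        mean_rt_gaze=mean_gaze,
        sem_rt_gaze=sem_gaze,
        error_rate_button=n_incorrect / n_total if n_total else 0.0,
        error_rate_first_saccade=sac_rate,
        n_kept=int(rts_kept.size),
    )


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Per observer x condition summary table from a trial log.

    Applies the exclusion rule, then reports mean/SEM button RT over the
    kept pool, mean/SEM gaze RT over the kept pool restricted to trials
    whose gaze reached the target, the button error rate over *all* trials
    of the condition, and the kept count.
    """
    kept = _kept_mask(df)
    rows = []
    for (obs, *key), grp in df.groupby(["observer_id"] + CONDITION_KEYS, sort=True):
        k = kept.loc[grp.index]
        pool = grp[k]
        gaze = None
        if "rt_gaze_s" in grp.columns:
            gaze = np.where(
                pool.get("gaze_reached_target", True), pool["rt_gaze_s"], np.nan
            )
        summary = summarize_condition(
            pool["rt_button_s"].to_numpy(),
            n_incorrect=int((~grp["correct"].astype(bool)).sum()),
            n_total=len(grp),
            gaze_rts_kept=gaze,
        )
        row = dict(zip(["observer_id"] + CONDITION_KEYS, (obs, *key)))
        if summary is None:
            row.update(n_kept=0, flagged_empty=True)
        else:
            row.update(
                mean_rt_button=summary.mean_rt_button,
                sem_rt_button=summary.sem_rt_button,
                mean_rt_gaze=summary.mean_rt_gaze,
                sem_rt_gaze=summary.sem_rt_gaze,
                error_rate_button=summary.error_rate_button,
                n_kept=summary.n_kept,
                flagged_empty=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_by_baseline(
    summary: pd.DataFrame, family_keys: tuple[str, ...] = ("O_mag", "transient_mode")
) -> pd.DataFrame:
    """Add a ``normalized_rt`` column: each observer's condition mean divided
    by that observer's baseline mean for the matching condition family.

    If a family has no baseline of its own (e.g. a design with one global
    zero-ocularity baseline), the observer's unique global baseline is used.
    The baseline's own normalized RT is exactly 1.
    """
    out = summary.copy()
    out["normalized_rt"] = np.nan
    for obs, grp in summary.groupby("observer_id"):
        base = grp[grp["condition"] == "baseline"]
        global_base = None
        if len(base) == 1:
            global_base = float(base["mean_rt_button"].iloc[0])
        base_by_family = {
            tuple(r[k] for k in family_keys): float(r["mean_rt_button"])
            for _, r in base.iterrows()
        }
        for idx, r in grp.iterrows():
            fam = tuple(r[k] for k in family_keys)
            denom = base_by_family.get(fam, global_base)
            if denom is None:
                raise InvalidInputError(
                    f"no baseline condition for observer {obs!r}, family {fam!r}"
                )
            out.loc[idx, "normalized_rt"] = r["mean_rt_button"] / denom
    return out


#: First saccades with |dx| below this (deg) are unclassified.
SACCADE_LATERAL_THRESHOLD = 0.1


def first_saccade_error(gaze, target_side: str, threshold: float = SACCADE_LATERAL_THRESHOLD):
    """Whether the first saccade went to the wrong lateral half.

    ``gaze`` is an ordered list of (t, x, y) fixation events starting at the
    central fixation.  The saccade is erroneous iff the sign of its
    horizontal displacement is opposite to the target's side.  Saccades with
    ``|dx|`` below ``threshold`` -- or absent saccades -- are unclassified
    (``None``) and excluded from the saccade error rate.
    """
    if gaze is None or len(gaze) < 2:
        return None
    dx = gaze[1][1] - gaze[0][1]
    if abs(dx) < threshold:
        return None
    went_right = dx > 0
    return went_right != (target_side == "right")


def gaze_reach_rt(gaze, target_position, reach_radius: float = 1.5):
    """Time of the first fixation within ``reach_radius`` of the target.

    Returns ``None`` if the gaze never reached the target before trial end.
    """
    tx, ty = target_position
    for t, x, y in gaze:
        if math.hypot(x - tx, y - ty) <= reach_radius:
            return t
    return None


def depth_split(trials) -> pd.Series:
    """Label each trial's target ``far`` or ``near`` relative to the array.

    The target is *far* iff its disparity-implied depth is farther than the
    median item depth of that trial's array.  Under the package convention
    ``d = x_R - x_L``, larger (more uncrossed) disparity is farther.  Exact
    median ties are labelled ``near``.  Trials whose arrays carry no
    disparity variation at all are labelled ``None`` (unlabelled).
    """
    labels = {}
    for trial in trials:
        d = trial.disparity
        if np.ptp(d) == 0:
            labels[trial.index] = None
            continue
        med = float(np.median(d))
        labels[trial.index] = "far" if d[trial.target_index] > med else "near"
    return pd.Series(labels, name="depth")


def contrast_split(trials) -> pd.Series:
    """Label each trial's target ``strong`` or ``weak`` in luminance contrast.

    The target is *strong* iff its binocular contrast sum strictly exceeds
    the trial's median C_sum over all items; ties are ``weak``.
    """
    labels = {}
    for trial in trials:
        c = trial.C_sum
        med = float(np.median(c))
        labels[trial.index] = "strong" if c[trial.target_index] > med else "weak"
    return pd.Series(labels, name="contrast")


def paired_t(a, b) -> PairedTestResult:
    """Two-sided matched-sample t-test on per-observer condition means.

    ``a`` and ``b`` are equal-length paired vectors (one entry per
    observer); ``df = n - 1``.  Degenerate cases: identical vectors give
    ``t = 0, p = 1``; constant non-zero differences are reported as ``p = 0``
    with the degenerate-variance flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InvalidInputError("paired_t needs two equal-length vectors, n >= 2")
    diff = a - b
    n = diff.size
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return PairedTestResult(0.0, 0.0, n - 1, 1.0)
        return PairedTestResult(
            float(diff.mean()),
            math.copysign(math.inf, diff[0]),
            n - 1,
            0.0,
            degenerate_variance=True,
        )
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(diff.mean()), float(t), n - 1, float(p))


def compare_conditions(
    summary: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    O_mag: float | None = None,
    transient_mode: str | None = None,
    value: str = "mean_rt_button",
) -> PairedTestResult:
    """Paired test of ``cond_a - cond_b`` on per-observer condition means.

    ``summary`` is the output of :func:`summarize`; rows are filtered to the
    requested |O| and transient mode (a condition absent from a family --
    e.g. a global baseline -- falls back to the observer's unique row of
    that condition).
    """

    def _series(cond: str) -> pd.Series:
        rows = summary[summary["condition"] == cond]
        sel = rows
        if O_mag is not None and "O_mag" in rows.columns:
            sel = sel[np.isclose(sel["O_mag"], O_mag)]
        if transient_mode is not None:
            sel = sel[sel["transient_mode"] == transient_mode]
        if sel.empty:
            sel = rows  # global-baseline fallback
        s = sel.set_index("observer_id")[value]
        if s.index.duplicated().any():
            raise InvalidInputError(
                f"condition {cond!r} is not unique per observer under the given filter"
            )
        return s

    sa, sb = _series(cond_a), _series(cond_b)
    common = sa.index.intersection(sb.index)
    return paired_t(sa.loc[common].to_numpy(), sb.loc[common].to_numpy())
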