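"""Saliency-driven synthetic observer.

Generates per-trial button presses and gaze traces from a phenomenological
priority model, so that the analysis pipeline can be exercised and effect
recovery tested without human data.  The observer is deliberately *not* a
neural circuit: it encodes the qualitative effect structure of dichoptic
search behaviour (an ocularity-contrast singleton attracts the first
saccade; capture of a non-target singleton costs a corrective saccade and
lengthens the button RT; a persistently ocularly unbalanced item among
balanced items evokes lustre-driven gaze aversion that masks its saliency).

Priority of item *i* in a trial::

    priority_i = w_ori * [tilt_i differs from the array mode]
               + w_oc  * tanh(max(0, dO_i - oc_threshold) / oc_scale)
               + w_lum * (C_sum_i - mean C_sum) / mean C_sum
               + w_near * nearness_rank_i                     (in [0, 1])
               - aversion * [unbalanced among balanced AND persistent]

where ``dO_i = |O_i - median O of the other items|`` is evaluated at t = 0,
and "persistent" means the item's ocularity is still non-zero at
``tau_percept`` seconds after onset (a transient ocularity that vanishes
before the lustre percept can form evades the aversion).  The ocularity
term saturates (tanh) so that even an eye-of-origin singleton among
opposite-eye items (dO = 2) captures the first saccade on only a minority
of trials, as human first-saccade error rates stay well below 50 % for
compact arrays.

The first saccade target is drawn by a softmax over priorities; if it is
not the target, a corrective saccade follows at cost ``t_move``.  The
button press happens ``t_decide`` after gaze settles, with multiplicative
lognormal noise; occasional premature presses at a captured distractor and
a small lapse rate generate realistic error trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidInputError
from .ocularity import STATIC, ocularity_at_time
from .stimuli import SessionSpec, TrialSpec, schedule_session

__all__ = [
    "ObserverParams",
    "BehavioralTrial",
    "PRESETS",
    "get_preset",
    "item_priority",
    "simulate_trial",
    "simulate_cohort",
    "TRIAL_LOG_COLUMNS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the synthetic observer (weights unitless, times in s)."""

    w_ori: float = 2.6  # weight of orientation contrast
    w_oc: float = 2.6  # weight of ocularity contrast
    oc_threshold: float = 0.4  # minimum ocularity contrast producing attraction
    oc_scale: float = 0.4  # saturation scale of the ocularity term
    w_lum: float = 0.5  # weight of relative luminance contrast
    w_near: float = 0.5  # near-depth bias weight
    aversion: float = 0.0  # lustre-aversion coefficient
    tau_percept: float = 0.2  # latency below which transient ocularity evades aversion
    capture_temperature: float = 0.3  # softmax temperature for first-saccade targeting
    t_saccade: float = 0.2  # mean first-saccade latency
    t_move: float = 0.3  # per-saccade travel + fixation cost
    t_decide: float = 0.15  # decision time after gaze settles
    rt_noise_sd: float = 0.12  # lognormal RT noise scale
    lapse: float = 0.02  # probability of a random button flip
    distracted_press_prob: float = 0.05  # premature press at a captured distractor
    heavy_tail_prob: float = 0.0  # heavy-tail RT mixture weight (outlier injection)
    heavy_tail_scale: float = 4.0

    def __post_init__(self) -> None:
        times = (self.tau_percept, self.t_saccade, self.t_move, self.t_decide)
        weights = (self.w_ori, self.w_oc, self.w_lum, self.w_near, self.aversion)
        if min(times) < 0 or min(weights) < 0 or self.rt_noise_sd < 0:
            raise InvalidInputError("weights and times must be >= 0")
        if not (0.0 <= self.lapse <= 0.5):
            raise InvalidInputError("lapse must be in [0, 0.5]")
        if self.capture_temperature <= 0:
            raise InvalidInputError("capture_temperature must be > 0")


#: Documented presets.  The ``paper_like_*`` presets encode the effect
#: structure reported for each experiment (movement and decision costs scale
#: with array extent and task difficulty); ``null`` removes all ocularity
#: sensitivity; the ``aversion_*`` presets pair with the static/transient
#: monocular-among-binocular session designs.
PRESETS: dict[str, ObserverParams] = {
    # E1: a 20-deg orientation contrast in a 34x46-deg array -- weak
    # orientation saliency, long saccades, slow decisions.  The aversion
    # coefficient equals the saturated ocularity-contrast term of a
    # persistent monocular singleton among balanced items (w_oc * tanh(1.5)),
    # i.e. the lustre percept fully masks that singleton's saliency.
    "paper_like_E1": ObserverParams(
        w_ori=2.0, w_oc=3.2, aversion=2.9,
        t_saccade=0.22, t_move=0.6, t_decide=0.7,
    ),
    "paper_like_E2": ObserverParams(aversion=2.4),
    "paper_like_E3": ObserverParams(t_move=0.3, t_decide=0.2, aversion=2.4),
    "paper_like_E4": ObserverParams(t_move=0.3, t_decide=0.2, aversion=2.4),
    "null": ObserverParams(w_oc=0.0, aversion=0.0),
}
PRESETS["aversion_static"] = PRESETS["paper_like_E1"]
PRESETS["aversion_transient"] = PRESETS["paper_like_E1"]


def get_preset(name: str) -> ObserverParams:
    try:
        return PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise InvalidInputError(f"unknown preset {name!r}; valid: {valid}") from None


@dataclass
class BehavioralTrial:
    """Synthetic behavioural record of one trial."""

    index: int
    rt_button: float
    button: str  # "left" | "right"
    correct: bool
    gaze: list[tuple[float, float, float]]  # (t, x, y) fixation events
    first_saccade_t: float
    first_saccade_target: int | None
    gaze_reached_target: bool
    rt_gaze: float | None  # time gaze first fixated the target, if ever

    def __post_init__(self) -> None:
        if self.rt_button <= 0:
            raise InvalidInputError("rt_button must be > 0")
        ts = [t for t, _, _ in self.gaze]
        if ts != sorted(ts) or len(set(ts)) != len(ts):
            raise InvalidInputError("gaze timestamps must be strictly increasing")


def _loo_median(values: np.ndarray) -> np.ndarray:
    """Median of the array excluding each element in turn.

    Exploits the small number of distinct values in generated trials (at
    most two ocularity levels) by removing one instance per unique value.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    s = np.sort(vals)
    out = np.empty(n)
    m = n - 1
    for v in np.unique(vals):
        rest = np.delete(s, np.searchsorted(s, v))
        med = rest[m // 2] if m % 2 else 0.5 * (rest[m // 2 - 1] + rest[m // 2])
        out[vals == v] = med
    return out


def item_priority(trial: TrialSpec, params: ObserverParams) -> np.ndarray:
    """Deterministic per-item saliency priorities for one trial."""
    O = trial.O
    n = trial.n_items
    pri = np.zeros(n)
    if trial.config.item_kind == "bar":
        tilts = np.asarray(trial.identity, dtype=float)
        uniq, counts = np.unique(tilts, return_counts=True)
        mode = uniq[np.argmax(counts)]
        pri += params.w_ori * (tilts != mode)
    dO = np.abs(O - _loo_median(O))
    pri += params.w_oc * np.tanh(
        np.maximum(0.0, dO - params.oc_threshold) / params.oc_scale
    )
    c_mean = trial.C_sum.mean()
    if c_mean > 0:
        pri += params.w_lum * (trial.C_sum - c_mean) / c_mean
    d = trial.disparity
    if np.ptp(d) > 0:
        # nearest (most crossed, d most negative) item ranks 1
        pri += params.w_near * (rankdata(-d) - 1) / (n - 1)
    else:
        pri += params.w_near * 0.5
    if params.aversion > 0:
        absO = np.abs(O)
        unbalanced = (absO - _loo_median(absO)) > 0.5
        if unbalanced.any():
            ti = trial.transient_index
            for i in np.nonzero(unbalanced)[0]:
                profile = trial.transient if i == ti else STATIC
                persists = (
                    abs(ocularity_at_time(params.tau_percept, O[i], profile)) > 1e-9
                )
                if persists:
                    pri[i] -= params.aversion
    return pri


def _capture_distribution(trial: TrialSpec, params: ObserverParams):
    """Cached (priorities, cumulative softmax weights) for a trial."""
    key = ("capture", params)
    hit = trial._cache.get(key)
    if hit is None:
        pri = item_priority(trial, params)
        if np.ptp(pri) == 0:
            logger.debug(
                "trial %d: degenerate (all-equal) priorities; uniform capture",
                trial.index,
            )
        z = np.exp((pri - pri.max()) / params.capture_temperature)
        hit = (pri, np.cumsum(z))
        trial._cache[key] = hit
    return hit


def simulate_trial(trial: TrialSpec, params: ObserverParams, rng) -> BehavioralTrial:
    """One synthetic trial: first saccade, possible correction, button press."""
    _, cum = _capture_distribution(trial, params)
    first_idx = int(np.searchsorted(cum, rng.random() * cum[-1]))
    z1, z2 = rng.normal(size=2)
    u_press, u_tail, u_lapse = rng.random(3)

    first_t = params.t_saccade * float(np.exp(params.rt_noise_sd * z1))
    pos = trial.positions
    gaze = [(0.0, 0.0, 0.0), (first_t, float(pos[first_idx, 0]), float(pos[first_idx, 1]))]
    target = trial.target_index
    premature = first_idx != target and u_press < params.distracted_press_prob
    if premature:
        # decision made at the captured distractor before any correction
        attended = first_idx
        reached = False
        rt_gaze = None
        rt = (first_t + params.t_decide) * float(np.exp(params.rt_noise_sd * z2))
    else:
        if first_idx != target:
            t_reach = first_t + params.t_move
            gaze.append((t_reach, float(pos[target, 0]), float(pos[target, 1])))
        else:
            t_reach = first_t
        attended = target
        reached = True
        rt_gaze = t_reach
        rt = (t_reach + params.t_decide) * float(np.exp(params.rt_noise_sd * z2))
    if params.heavy_tail_prob > 0 and u_tail < params.heavy_tail_prob:
        rt *= params.heavy_tail_scale
    button = "right" if pos[attended, 0] > 0 else "left"
    if u_lapse < params.lapse:
        button = "left" if button == "right" else "right"
    return BehavioralTrial(
        index=trial.index,
        rt_button=rt,
        button=button,
        correct=button == trial.target_side,
        gaze=gaze,
        first_saccade_t=first_t,
        first_saccade_target=first_idx,
        gaze_reached_target=reached,
        rt_gaze=rt_gaze,
    )


TRIAL_LOG_COLUMNS = [
    "observer_id",
    "trial",
    "condition",
    "O_mag",
    "transient_mode",
    "target_side",
    "rt_button_s",
    "button",
    "correct",
    "first_saccade_t_s",
    "first_saccade_x_deg",
    "gaze_reached_target",
    "rt_gaze_s",
]


def simulate_cohort(
    trials: list[TrialSpec] | SessionSpec,
    observers: int | list[ObserverParams],
    master_seed: int,
    params: ObserverParams | None = None,
    return_trials: bool = False,
):
    """Simulate one or more observers over a session's trial list.

    ``observers`` is either an explicit list of :class:`ObserverParams` or a
    count (each observer then uses ``params``).  One independent random
    stream per observer is spawned from ``master_seed``, so two cohorts with
    the same master seed are identical.

    Returns a trial-log :class:`pandas.DataFrame` (one row per observer and
    trial, columns :data:`TRIAL_LOG_COLUMNS`), plus a per-observer list of
    :class:`BehavioralTrial` when ``return_trials`` is set.
    """
    if isinstance(trials, SessionSpec):
        trials = schedule_session(trials)
    if isinstance(observers, int):
        if params is None:
            raise InvalidInputError("a params preset is required with an observer count")
        observers = [params] * observers
    streams = np.random.SeedSequence(master_seed).spawn(len(observers))
    rows = []
    all_records: list[list[BehavioralTrial]] = []
    for obs_id, (obs_params, ss) in enumerate(zip(observers, streams)):
        rng = np.random.default_rng(ss)
        records = []
        for trial in trials:
            b = simulate_trial(trial, obs_params, rng)
            rows.append(
                (
                    obs_id,
                    trial.index,
                    trial.condition,
                    trial.O_mag,
                    trial.cell.transient.label,
                    trial.target_side,
                    b.rt_button,
                    b.button,
                    b.correct,
                    b.first_saccade_t,
                    b.gaze[1][1],
                    b.gaze_reached_target,
                    np.nan if b.rt_gaze is None else b.rt_gaze,
                )
            )
            if return_trials:
                records.append(b)
        if return_trials:
            all_records.append(records)
    df = pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)
    if return_trials:
        return df, all_records
    return df
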