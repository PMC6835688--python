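"""End-to-end orchestration: generate -> simulate -> analyze -> report.

A run is fully specified by a :class:`RunConfig`; one master seed fans out
to a session-schedule stream and per-observer simulation streams through
``numpy.random.SeedSequence`` spawning, so any stage can be reproduced in
isolation and two runs with equal configs produce byte-identical summary
tables.  :func:`reproduce_design` returns the configuration matching each
of the built-in figure designs (experiment, condition grid, session size,
observer count and preset).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import compare_conditions, normalize_by_baseline, summarize
from .errors import ConfigurationError, InvalidInputError
from .observer import get_preset, simulate_cohort
from .render import save_stereo_pair
from .stimuli import (
    ConditionCell,
    SessionSpec,
    e1_session_cells,
    experiment_config,
    grid_rowcol,
    schedule_session,
    standard_cells,
)

__all__ = ["RunConfig", "reproduce_design", "run_pipeline", "build_session"]

logger = logging.getLogger(__name__)

_FIGURE_DESIGNS = {
    # figure_id: (experiment, cells spec, trials/cond, observers, preset, overrides)
    "F3A": ("E1", ("e1", "eye_of_origin"), 50, 4, "paper_like_E1", {}),
    "F3B": (
        "E1",
        ("e1", "eye_dominance"),
        50,
        4,
        "paper_like_E1",
        {"disparity_range": (-0.3, 0.3)},
    ),
    "F5": ("E2", ("standard",), 50, 6, "paper_like_E2", {}),
    "F6": ("E3", ("standard",), 50, 5, "paper_like_E3", {}),
    "F7A": ("E1", ("e1", "binocular_among_monocular"), 50, 4, "paper_like_E1", {}),
    "F7B": ("E1", ("e1", "monocular_among_binocular"), 50, 4, "aversion_static", {}),
    "F8": (
        "E1",
        ("e1", "monocular_among_binocular_transient"),
        50,
        4,
        "aversion_transient",
        {},
    ),
    "F9": (
        "E1",
        ("e1", "monocular_among_binocular_single", "monocular_among_binocular_single_transient"),
        50,
        4,
        "aversion_static",
        {},
    ),
    "F10": ("E4", ("standard",), 45, 9, "paper_like_E4", {}),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    figure_id: str
    experiment_id: str
    cells: tuple[ConditionCell, ...]
    trials_per_condition: int
    n_observers: int
    preset: str
    seed: int = 0
    raster: bool = False
    raster_trials: int = 4
    pixels_per_degree: float = 8.0
    write_scenes: bool = False
    normalize: str = "auto"  # "auto" | "on" | "off"
    reach_radius_deg: float = 1.5
    config_overrides: tuple = ()

    def __post_init__(self) -> None:
        if self.normalize not in ("auto", "on", "off"):
            raise ConfigurationError(f"normalize must be auto/on/off, got {self.normalize!r}")


def reproduce_design(figure_id: str, seed: int = 0, **kwargs) -> RunConfig:
    """The fully specified run configuration matching a figure's design."""
    try:
        exp, cells_spec, tpc, n_obs, preset, overrides = _FIGURE_DESIGNS[figure_id]
    except KeyError:
        valid = ", ".join(sorted(_FIGURE_DESIGNS))
        raise InvalidInputError(
            f"unknown figure id {figure_id!r}; valid ids: {valid}"
        ) from None
    if cells_spec[0] == "standard":
        cells = standard_cells(exp)
    else:
        cells = tuple(c for v in cells_spec[1:] for c in e1_session_cells(v))
    return RunConfig(
        figure_id=figure_id,
        experiment_id=exp,
        cells=cells,
        trials_per_condition=tpc,
        n_observers=n_obs,
        preset=preset,
        seed=seed,
        config_overrides=tuple(sorted(overrides.items())),
        **kwargs,
    )


def build_session(config: RunConfig, session_seed: int) -> SessionSpec:
    exp = experiment_config(config.experiment_id, **dict(config.config_overrides))
    return SessionSpec(
        config=exp,
        cells=config.cells,
        trials_per_condition=config.trials_per_condition,
        rng_seed=session_seed,
    )


def session_manifest(trials) -> pd.DataFrame:
    """One row per trial: condition, |O|, transient, placements, seed."""
    rows = []
    for t in trials:
        rc = grid_rowcol(t.config)
        srow = None if t.singleton_index is None else tuple(int(v) for v in rc[t.singleton_index])
        rows.append(
            {
                "trial": t.index,
                "condition": t.condition,
                "O_mag": t.O_mag,
                "transient_mode": t.cell.transient.label,
                "scheme": t.cell.scheme,
                "target_side": t.target_side,
                "target_grid_pos": tuple(int(v) for v in rc[t.target_index]),
                "singleton_grid_pos": srow,
                "seed": t.seed,
            }
        )
    return pd.DataFrame(rows)


def _paired_tests(summary: pd.DataFrame, value: str) -> pd.DataFrame:
    """All within-family condition contrasts available in a summary table."""
    rows = []
    fams = summary[["O_mag", "transient_mode"]].drop_duplicates()
    for _, fam in fams.iterrows():
        sel = summary[
            np.isclose(summary["O_mag"], fam["O_mag"])
            & (summary["transient_mode"] == fam["transient_mode"])
        ]
        conds = set(sel["condition"])
        contrasts = []
        if "DC" in conds:
            contrasts.append(("baseline", "DC"))
            if "DI" in conds:
                contrasts.append(("DI", "DC"))
                contrasts.append(("DI", "baseline"))
        for a, b in contrasts:
            try:
                res = compare_conditions(
                    summary, a, b,
                    O_mag=fam["O_mag"], transient_mode=fam["transient_mode"],
                    value=value,
                )
            except InvalidInputError:
                continue
            rows.append(
                {
                    "O_mag": fam["O_mag"],
                    "transient_mode": fam["transient_mode"],
                    "contrast": f"{a}-{b}",
                    "mean_difference": res.mean_difference,
                    "t": res.t_statistic,
                    "df": res.degrees_of_freedom,
                    "p": res.p_value,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)


def _plot_summary(summary: pd.DataFrame, value: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = summary.groupby(["condition", "O_mag", "transient_mode"])[value]
    means, sems = g.mean(), g.sem()
    labels = [
        f"{c}\n|O|={m:.2g}\n{tr}" if tr != "static" else f"{c}\n|O|={m:.2g}"
        for c, m, tr in means.index
    ]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(means)), 4))
    ax.bar(range(len(means)), means.to_numpy(), yerr=sems.to_numpy(), capsize=3)
    ax.set_xticks(range(len(means)))
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("mean button RT (s)" if value == "mean_rt_button" else value)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute generate -> simulate -> analyze and write the report bundle.

    Returns a dict with the output paths, the in-memory tables, and any
    flagged degeneracies (empty pools, degenerate-variance tests).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    root = np.random.SeedSequence(config.seed)
    session_seed, cohort_seed = (int(s.generate_state(1)[0] % 2**31) for s in root.spawn(2))

    stage = "generate"
    try:
        session = build_session(config, session_seed)
        trials = schedule_session(session)
        manifest = session_manifest(trials)
        manifest.to_csv(out / "session_manifest.csv", index=False)
        if config.write_scenes:
            scenes_dir = out / "scenes"
            scenes_dir.mkdir(exist_ok=True)
            for t in trials:
                (scenes_dir / f"trial{t.index:04d}.json").write_text(
                    json.dumps(t.scene_dict())
                )
        if config.raster:
            for t in trials[: config.raster_trials]:
                save_stereo_pair(
                    t, out / "raster", pixels_per_degree=config.pixels_per_degree
                )

        stage = "simulate"
        params = get_preset(config.preset)
        log = simulate_cohort(trials, config.n_observers, cohort_seed, params=params)
        log.to_csv(out / "trial_log.csv", index=False)

        stage = "analyze"
        summary = summarize(log)
        flags = []
        if summary.get("flagged_empty", pd.Series(dtype=bool)).any():
            flags.append("empty_condition_pool")
        base = summary[summary["condition"] == "baseline"]["mean_rt_button"]
        cv = float(base.std() / base.mean()) if len(base) > 1 and base.mean() > 0 else 0.0
        do_norm = config.normalize == "on" or (config.normalize == "auto" and cv > 0.25)
        value = "mean_rt_button"
        if do_norm:
            summary = normalize_by_baseline(summary)
            value = "normalized_rt"
        summary.to_csv(out / "summaries.csv", index=False)
        tests = _paired_tests(summary, value)
        tests.to_csv(out / "paired_tests.csv", index=False)
        _plot_summary(summary, value, out / "rt_by_condition.png")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (master seed {config.seed})"
        ) from exc

    run_log = {
        "figure_id": config.figure_id,
        "config": {
            k: v for k, v in asdict(config).items() if k != "cells"
        },
        "n_trials": len(trials),
        "seeds": {"master": config.seed, "session": session_seed, "cohort": cohort_seed},
        "version": __version__,
        "normalized": do_norm,
        "baseline_rt_cv": cv,
        "flags": flags,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    bundle_manifest = {
        str(p.relative_to(out)): _sha256(p) for p in files
    }
    (out / "manifest.json").write_text(json.dumps(bundle_manifest, indent=2))
    logger.info("run %s complete in %.1fs (%d flags)", config.figure_id, time.time() - t0, len(flags))
    return {
        "out_dir": out,
        "trials": trials,
        "trial_log": log,
        "summary": summary,
        "paired_tests": tests,
        "flags": flags,
        "manifest": bundle_manifest,
    }
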