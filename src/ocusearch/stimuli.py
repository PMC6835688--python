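"""Dichoptic search-array generation for Experiments 1-4.

Builds complete trials: a jittered grid of bars or letters, a target whose
placement satisfies per-experiment geometric constraints, an optional
ocularity singleton, per-item disparities, per-eye luminances, vergence
anchors, and randomly interleaved session schedules.

Coordinate convention: degrees of visual angle, origin at the array centre,
x rightward, y upward.  Grid cells are indexed (row, col), 1-based from the
top-left.  Grid spacing uses (n - 1) gaps so that the bounding box of the
item *centres* spans the stated array extent (the extent is ambiguous
between centre-span and edge-span; centre-span is chosen and recorded in
scene metadata).  Disparity sign: ``d = x_right_eye - x_left_eye``; ``d < 0``
is crossed, i.e. nearer than fixation.

The four experiments:

* E1 - bright tilted bars (22x30, 34x46 deg) on black, orientation-singleton
  search, sessions differing in dichoptic scheme (eye-of-origin, 9:1 eye
  dominance, monocular/binocular singletons, transient monocularity).
* E2 - dark +/-45 deg bars (23x23, 18.4 deg) on white, |O| in {1/5,1/3,3/5}
  crossed with baseline/DC/DI.
* E3 - dark letters, T among Ls (17x17, 18.6 deg), |O| in {1/5,1/3,1/2,3/5}
  crossed with baseline/DC.
* E4 - light letters on grey (14x14, 18.3 deg) with heterogeneous luminance
  contrasts; only the target may carry non-zero ocularity, either static or
  transient with a smooth decay.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GenerationError, InvalidInputError
from .ocularity import (
    STATIC,
    DisplayConfig,
    TransientProfile,
    ocularity_at_time,
)

__all__ = [
    "TargetPlacement",
    "ExperimentConfig",
    "ConditionCell",
    "SearchItem",
    "TrialSpec",
    "SessionSpec",
    "experiment_config",
    "make_grid",
    "grid_rowcol",
    "jitter_positions",
    "choose_target_position",
    "choose_singleton_position",
    "assign_identities",
    "assign_ocularity",
    "assign_disparity",
    "place_vergence_anchors",
    "assign_contrast_heterogeneity_e4",
    "generate_trial",
    "schedule_session",
]


@dataclass(frozen=True)
class TargetPlacement:
    """Geometric constraints on the target's grid position.

    ``mode`` selects the constraint style: ``"ring"`` (rows within a band,
    at least ``min_horizontal_units`` columns from the centre, closest to a
    circle of ``ring_radius`` grid units), ``"annulus"`` (row band plus
    bands on horizontal offset and radial distance, in grid units), or
    ``"eccentricity"`` (bands in degrees of visual angle).
    """

    mode: str
    row_band: tuple[int, int] | None = None
    ring_radius: float | None = None
    min_horizontal_units: float = 0.0
    horizontal_band_units: tuple[float, float] | None = None
    radial_band_units: tuple[float, float] | None = None
    ecc_band_deg: tuple[float, float] | None = None
    min_horizontal_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("ring", "annulus", "eccentricity"):
            raise ConfigurationError(f"unknown placement mode {self.mode!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    experiment_id: str
    rows: int
    cols: int
    extent_x: float
    extent_y: float
    item_kind: str  # "bar" | "letter"
    item_size: tuple[float, float]  # (length, width) or (height, width), deg
    bar_tilt: float  # magnitude of tilt from horizontal, deg (bars only)
    jitter_bound: float  # max positional jitter per axis, deg
    disparity_range: tuple[float, float] | None
    target_placement: TargetPlacement
    viewing_distance_cm: float
    fixation_diameter_deg: float
    fixation_duration_s: float
    anchor_style: str  # "dots+corner_disks" | "dots+frame"
    dot_size_deg: float
    corner_disk_diameter_deg: float = 0.5
    frame_scale: float = 1.1
    stroke_width_deg: float = 0.085
    trials_per_condition: int = 50
    display: DisplayConfig = field(default_factory=DisplayConfig)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("rows and cols must be >= 1")
        if self.extent_x < 0 or self.extent_y < 0:
            raise ConfigurationError("extents must be >= 0")
        if self.jitter_bound < 0:
            raise ConfigurationError("jitter_bound must be >= 0")
        if self.item_kind not in ("bar", "letter"):
            raise ConfigurationError(f"unknown item kind {self.item_kind!r}")
        if self.disparity_range is not None:
            lo, hi = self.disparity_range
            if abs(lo + hi) > 1e-12 or hi <= 0:
                raise ConfigurationError("disparity interval must be symmetric about 0")
        if self.cols == 1 and self.extent_x > 0:
            raise ConfigurationError("single-column grid cannot span a nonzero extent")
        if self.rows == 1 and self.extent_y > 0:
            raise ConfigurationError("single-row grid cannot span a nonzero extent")

    @property
    def n_items(self) -> int:
        return self.rows * self.cols

    @property
    def centre_rc(self) -> tuple[float, float]:
        return ((self.rows + 1) / 2.0, (self.cols + 1) / 2.0)


_EXPERIMENTS = {
    "E1": dict(
        rows=22, cols=30, extent_x=46.0, extent_y=34.0,
        item_kind="bar", item_size=(1.1, 0.12), bar_tilt=10.0,
        jitter_bound=0.24, disparity_range=None,
        target_placement=TargetPlacement(
            mode="eccentricity", ecc_band_deg=(13.5, 16.5), min_horizontal_deg=12.0
        ),
        viewing_distance_cm=40.0,
        fixation_diameter_deg=0.3, fixation_duration_s=1.2,
        anchor_style="dots+corner_disks", dot_size_deg=0.12,
        display=DisplayConfig(polarity="bright", L_sum=48.0, optic_attenuation=7 / 8),
    ),
    "E2": dict(
        rows=23, cols=23, extent_x=18.4, extent_y=18.4,
        item_kind="bar", item_size=(0.6, 0.085), bar_tilt=45.0,
        jitter_bound=0.05, disparity_range=(-0.21, 0.21),
        target_placement=TargetPlacement(
            mode="ring", row_band=(4, 20), ring_radius=10.0, min_horizontal_units=6.0
        ),
        viewing_distance_cm=57.0,
        fixation_diameter_deg=0.3, fixation_duration_s=1.2,
        anchor_style="dots+frame", dot_size_deg=0.17,
        display=DisplayConfig(polarity="decrement", L_bg=110.0),
    ),
    "E3": dict(
        rows=17, cols=17, extent_x=18.6, extent_y=18.6,
        item_kind="letter", item_size=(0.7, 0.7), bar_tilt=0.0,
        jitter_bound=0.064, disparity_range=(-0.21, 0.21),
        target_placement=TargetPlacement(
            mode="ring", row_band=(4, 14), ring_radius=7.0, min_horizontal_units=5.0
        ),
        viewing_distance_cm=57.0,
        fixation_diameter_deg=0.3, fixation_duration_s=1.2,
        anchor_style="dots+frame", dot_size_deg=0.17,
        display=DisplayConfig(polarity="decrement", L_bg=110.0),
    ),
    "E4": dict(
        rows=14, cols=14, extent_x=18.3, extent_y=18.3,
        item_kind="letter", item_size=(0.75, 0.75), bar_tilt=0.0,
        jitter_bound=0.077, disparity_range=(-0.21, 0.21),
        target_placement=TargetPlacement(
            mode="annulus", row_band=(4, 11),
            horizontal_band_units=(2.0, 5.0), radial_band_units=(3.0, 6.0),
        ),
        viewing_distance_cm=57.0,
        fixation_diameter_deg=0.3, fixation_duration_s=1.2,
        anchor_style="dots+frame", dot_size_deg=0.17,
        trials_per_condition=45,
        display=DisplayConfig(polarity="increment", L_o=43.0, L_1=67.0),
    ),
}


def experiment_config(experiment_id: str, **overrides) -> ExperimentConfig:
    """Return the stock configuration for E1-E4, with optional overrides."""
    try:
        kwargs = dict(_EXPERIMENTS[experiment_id])
    except KeyError:
        valid = ", ".join(sorted(_EXPERIMENTS))
        raise ConfigurationError(
            f"unknown experiment {experiment_id!r}; valid ids: {valid}"
        ) from None
    kwargs.update(overrides)
    return ExperimentConfig(experiment_id=experiment_id, **kwargs)


# ---------------------------------------------------------------------------
# geometry


@functools.lru_cache(maxsize=32)
def make_grid(config: ExperimentConfig) -> np.ndarray:
    """Regular lattice of item centres, shape (rows*cols, 2), row-major.

    Centred on the origin; the bounding box of the centres equals
    (extent_x, extent_y).  Row 1 is the top row (largest y).
    """
    dx = config.extent_x / (config.cols - 1) if config.cols > 1 else 0.0
    dy = config.extent_y / (config.rows - 1) if config.rows > 1 else 0.0
    xs = -config.extent_x / 2.0 + dx * np.arange(config.cols)
    ys = config.extent_y / 2.0 - dy * np.arange(config.rows)
    xx, yy = np.meshgrid(xs, ys)
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    grid.setflags(write=False)
    return grid


@functools.lru_cache(maxsize=32)
def grid_rowcol(config: ExperimentConfig) -> np.ndarray:
    """(rows*cols, 2) array of 1-based (row, col) indices, row-major."""
    rr, cc = np.meshgrid(
        np.arange(1, config.rows + 1), np.arange(1, config.cols + 1), indexing="ij"
    )
    rc = np.column_stack([rr.ravel(), cc.ravel()])
    rc.setflags(write=False)
    return rc


def rc_to_index(config: ExperimentConfig, row: int, col: int) -> int:
    return (row - 1) * config.cols + (col - 1)


def jitter_positions(grid: np.ndarray, config: ExperimentConfig, rng) -> np.ndarray:
    """Perturb each coordinate by an independent uniform draw in [-b, +b]."""
    if config.jitter_bound == 0.0:
        return np.array(grid, copy=True)
    return grid + rng.uniform(-config.jitter_bound, config.jitter_bound, size=grid.shape)


@functools.lru_cache(maxsize=32)
def _feasible_target_cells(config: ExperimentConfig) -> np.ndarray:
    """Enumerate all grid cells satisfying the target-placement constraints."""
    p = config.target_placement
    rc = grid_rowcol(config)
    grid = make_grid(config)
    r_c, c_c = config.centre_rc
    dr = rc[:, 0] - r_c
    dc = rc[:, 1] - c_c
    dist = np.hypot(dr, dc)
    if p.mode == "ring":
        lo, hi = p.row_band
        ok = (rc[:, 0] >= lo) & (rc[:, 0] <= hi) & (np.abs(dc) >= p.min_horizontal_units)
        if not ok.any():
            raise ConfigurationError("target placement: empty feasible set")
        gap = np.abs(dist - p.ring_radius)
        best = gap[ok].min()
        ok &= gap <= best + 1e-9
    elif p.mode == "annulus":
        lo, hi = p.row_band
        h1, h2 = p.horizontal_band_units
        a1, a2 = p.radial_band_units
        ok = (
            (rc[:, 0] >= lo) & (rc[:, 0] <= hi)
            & (np.abs(dc) >= h1) & (np.abs(dc) <= h2)
            & (dist >= a1) & (dist <= a2)
        )
    else:  # eccentricity, in degrees
        ecc = np.hypot(grid[:, 0], grid[:, 1])
        lo, hi = p.ecc_band_deg
        ok = (ecc >= lo) & (ecc <= hi) & (np.abs(grid[:, 0]) >= p.min_horizontal_deg)
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        raise ConfigurationError("target placement: empty feasible set")
    idx.setflags(write=False)
    return idx


def choose_target_position(config: ExperimentConfig, rng) -> tuple[int, int]:
    """Sample a target grid cell uniformly from the feasible set."""
    idx = _feasible_target_cells(config)
    i = idx[rng.integers(idx.size)]
    row, col = grid_rowcol(config)[i]
    return int(row), int(col)


def choose_singleton_position(
    target_rc: tuple[int, int], config: ExperimentConfig, rng, policy: str = "mirror"
) -> tuple[int, int]:
    """Place the DI singleton in the opposite lateral half of the array.

    The default ``"mirror"`` policy reflects the target cell across the
    vertical midline, guaranteeing the opposite half and matched
    eccentricity.  ``"sample"`` draws uniformly from all cells whose x
    position has the opposite sign to the target's.
    """
    row, col = target_rc
    if policy == "mirror":
        mcol = config.cols + 1 - col
        if mcol != col:
            return row, mcol
        policy = "sample"  # centre-column target: mirror degenerates
    if policy != "sample":
        raise ConfigurationError(f"unknown singleton policy {policy!r}")
    grid = make_grid(config)
    x_t = grid[rc_to_index(config, row, col), 0]
    opposite = np.nonzero(np.sign(grid[:, 0]) == -np.sign(x_t))[0]
    if opposite.size == 0:
        raise ConfigurationError("no cells in the opposite lateral half")
    i = opposite[rng.integers(opposite.size)]
    r, c = grid_rowcol(config)[i]
    return int(r), int(c)


# ---------------------------------------------------------------------------
# item attributes


def assign_identities(n: int, target_index: int, config: ExperimentConfig, rng):
    """Orientation (bars) or glyph (letters) per item.

    Bars: the background tilt is +/-``bar_tilt`` from horizontal with equal
    probability and the target gets the opposite tilt.  Letters: the target
    is 'T' among 'L's, drawn upright.
    """
    if config.item_kind == "bar":
        bg = config.bar_tilt * (1 if rng.random() < 0.5 else -1)
        tilts = np.full(n, bg, dtype=float)
        tilts[target_index] = -bg
        return tilts
    glyphs = np.full(n, "L", dtype="<U1")
    glyphs[target_index] = "T"
    return glyphs


def assign_ocularity(
    n: int,
    target_index: int,
    singleton_index: int | None,
    condition: str,
    O_mag: float,
    scheme: str,
    rng,
) -> np.ndarray:
    """Per-item initial ocularity values under a dichoptic scheme.

    Schemes
    -------
    ``sign_flip``
        All items share |O| = ``O_mag``; in DC/DI the unique item carries the
        unique *sign* of O (the unique dominant eye).  The baseline sign, and
        the unique item's sign, are drawn fresh each trial.
    ``zero_among_full``
        Background items are monocular (|O| = 1, one common random eye); the
        unique item is binocular (O = 0).
    ``full_among_zero``
        Background items are binocular (O = 0); the unique item is monocular
        with a random eye.
    ``target_only``
        All non-targets are ocularly balanced (O = 0); in DC the target gets
        O = +/-``O_mag``.  (E4 design.)
    """
    if not (0.0 <= O_mag <= 1.0):
        raise InvalidInputError(f"O magnitude must be in [0, 1]; got {O_mag}")
    unique = {"DC": target_index, "DI": singleton_index, "baseline": None}[condition]
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if scheme == "sign_flip":
        O = np.full(n, -sign * O_mag)
        if unique is not None:
            O[unique] = sign * O_mag
        return O
    if scheme == "zero_among_full":
        O = np.full(n, sign * 1.0)
        if unique is not None:
            O[unique] = 0.0
        return O
    if scheme == "full_among_zero":
        O = np.zeros(n)
        if unique is not None:
            O[unique] = sign * 1.0
        return O
    if scheme == "target_only":
        O = np.zeros(n)
        if condition == "DC":
            O[target_index] = sign * O_mag
        elif condition != "baseline":
            raise ConfigurationError("target_only scheme supports baseline and DC only")
        return O
    raise ConfigurationError(f"unknown ocularity scheme {scheme!r}")


def assign_disparity(config: ExperimentConfig, rng) -> np.ndarray:
    """Independent uniform disparity per item; border columns are pinned to 0.

    Items in the first and last grid columns always get zero disparity (they
    anchor vergence at the array edges).
    """
    n = config.n_items
    if config.disparity_range is None:
        return np.zeros(n)
    lo, hi = config.disparity_range
    d = rng.uniform(lo, hi, size=n)
    cols = grid_rowcol(config)[:, 1]
    d[(cols == 1) | (cols == config.cols)] = 0.0
    return d


def place_vergence_anchors(positions: np.ndarray, config: ExperimentConfig) -> dict:
    """Binocular, zero-disparity vergence anchors for a trial.

    A bright dot sits at the centre of mass of every 2x2 neighbourhood of
    (jittered) item positions: (rows-1)x(cols-1) dots in total.  E1 adds four
    corner disks placed one degree outside the array corners; E2-E4 instead
    add an enclosing rectangular frame ``frame_scale`` times the array extent.
    """
    pos = positions.reshape(config.rows, config.cols, 2)
    dots = (pos[:-1, :-1] + pos[:-1, 1:] + pos[1:, :-1] + pos[1:, 1:]) / 4.0
    anchors = {
        "dots": dots.reshape(-1, 2),
        "dot_size_deg": config.dot_size_deg,
    }
    if config.anchor_style == "dots+corner_disks":
        ox = config.extent_x / 2.0 + 1.0
        oy = config.extent_y / 2.0 + 1.0
        anchors["corner_disks"] = np.array(
            [[sx * ox, sy * oy] for sx in (-1, 1) for sy in (-1, 1)], dtype=float
        )
        anchors["corner_disk_diameter_deg"] = config.corner_disk_diameter_deg
    else:
        anchors["frame_extent_deg"] = (
            config.frame_scale * config.extent_x,
            config.frame_scale * config.extent_y,
        )
    return anchors


_E4_RESAMPLE_CAP = 10_000


def assign_contrast_heterogeneity_e4(
    n: int, target_index: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Heterogeneous luminance jitters and contrast sums for an E4 trial.

    Non-target jitters ``x ~ U(-0.3, 0.3)``, target ``x ~ U(-0.2, 0.2)``.
    In units of the increment scale L_1, the binocular increment sum is
    ``1 + 2x`` for a non-target and ``1 + x`` for the target, so both have
    expectation 1.  The whole-trial draw is resampled until the target's sum
    is strictly between the minimum and maximum of all items' sums.

    Returns ``(x, C_sum)`` arrays; raises :class:`GenerationError` if the
    resampling cap is exceeded.
    """
    for _ in range(_E4_RESAMPLE_CAP):
        x = rng.uniform(-0.3, 0.3, size=n)
        x[target_index] = rng.uniform(-0.2, 0.2)
        c = 1.0 + 2.0 * x
        c[target_index] = 1.0 + x[target_index]
        others = np.delete(c, target_index)
        if others.min() < c[target_index] < others.max():
            return x, c
    raise GenerationError("E4 contrast-heterogeneity resampling cap exceeded")


# ---------------------------------------------------------------------------
# trials and sessions


@dataclass(frozen=True)
class SearchItem:
    """One bar or letter, materialized from a trial's item arrays."""

    grid_pos: tuple[int, int]
    position: tuple[float, float]
    identity: float | str
    role: str  # "target" | "ocularity_singleton" | "background" | "both"
    O: float
    C_sum: float
    disparity: float
    luminance_L: float
    luminance_R: float
    transient: TransientProfile


@dataclass(frozen=True)
class ConditionCell:
    """One cell of a session's condition grid."""

    condition: str  # "baseline" | "DC" | "DI"
    O_mag: float
    transient: TransientProfile = STATIC
    scheme: str = "sign_flip"
    singleton_csum_scale: float = 1.0  # 0.5 = single-strength monocular singleton
    singleton_policy: str = "mirror"

    def __post_init__(self) -> None:
        if self.condition not in ("baseline", "DC", "DI"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")


@dataclass
class TrialSpec:
    """A fully specified dichoptic search trial (structure-of-arrays)."""

    config: ExperimentConfig
    cell: ConditionCell
    index: int
    seed: int
    target_index: int
    singleton_index: int | None
    positions: np.ndarray  # (n, 2) perceived (cyclopean) positions, deg
    identity: np.ndarray  # tilt in deg (bars) or glyph (letters)
    O: np.ndarray  # initial ocularity per item
    C_sum: np.ndarray  # binocular contrast sum per item (L_1 units for E4)
    disparity: np.ndarray  # deg, d = x_R - x_L
    lum_L: np.ndarray  # per-eye luminance at t = 0, cd/m^2
    lum_R: np.ndarray
    lum_jitter: np.ndarray | None = None  # E4 per-item x
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def condition(self) -> str:
        return self.cell.condition

    @property
    def O_mag(self) -> float:
        return self.cell.O_mag

    @property
    def transient(self) -> TransientProfile:
        return self.cell.transient

    @property
    def transient_index(self) -> int | None:
        """Index of the item whose ocularity follows the transient profile.

        Only the odd item (target in DC/target_only, singleton in DI) can be
        transient; background items are always static.
        """
        if self.cell.transient.mode == "static":
            return None
        if self.condition == "DI":
            return self.singleton_index
        if self.condition == "DC":
            return self.target_index
        return None

    @property
    def n_items(self) -> int:
        return len(self.O)

    @property
    def target_side(self) -> str:
        return "right" if self.positions[self.target_index, 0] > 0 else "left"

    def ocularity_at(self, t: float) -> np.ndarray:
        """Per-item ocularity ``t`` seconds after onset."""
        O = np.array(self.O, copy=True)
        ti = self.transient_index
        if ti is not None:
            O[ti] = ocularity_at_time(t, self.O[ti], self.cell.transient)
        return O

    def eye_luminances(self, t: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Per-eye item luminances at time ``t``, conserving each C_sum."""
        return _eye_luminances(self.config, self, self.ocularity_at(t))

    def eye_positions(self, eye: str) -> np.ndarray:
        """Item positions in one monocular image: x -/+ d/2 for left/right."""
        shift = self.disparity[:, None] / 2.0 * np.array([1.0, 0.0])
        return self.positions - shift if eye == "left" else self.positions + shift

    @property
    def anchors(self) -> dict:
        if "anchors" not in self._cache:
            self._cache["anchors"] = place_vergence_anchors(self.positions, self.config)
        return self._cache["anchors"]

    @property
    def items(self) -> list[SearchItem]:
        """Materialize per-item records (for serialization and inspection)."""
        rc = grid_rowcol(self.config)
        out = []
        for i in range(self.n_items):
            if i == self.target_index:
                role = "both" if i == self.singleton_index else "target"
            elif i == self.singleton_index:
                role = "ocularity_singleton"
            else:
                role = "background"
            transient = (
                self.cell.transient if i == self.transient_index else STATIC
            )
            out.append(
                SearchItem(
                    grid_pos=(int(rc[i, 0]), int(rc[i, 1])),
                    position=(float(self.positions[i, 0]), float(self.positions[i, 1])),
                    identity=self.identity[i].item()
                    if hasattr(self.identity[i], "item")
                    else self.identity[i],
                    role=role,
                    O=float(self.O[i]),
                    C_sum=float(self.C_sum[i]),
                    disparity=float(self.disparity[i]),
                    luminance_L=float(self.lum_L[i]),
                    luminance_R=float(self.lum_R[i]),
                    transient=transient,
                )
            )
        return out

    def scene_dict(self) -> dict:
        """JSON-serializable scene description of this trial."""
        return {
            "experiment": self.config.experiment_id,
            "trial_index": self.index,
            "seed": self.seed,
            "condition": self.condition,
            "O_mag": self.O_mag,
            "transient_mode": self.cell.transient.label,
            "scheme": self.cell.scheme,
            "target_index": self.target_index,
            "singleton_index": self.singleton_index,
            "target_side": self.target_side,
            "coordinate_convention": {
                "units": "deg",
                "origin": "array centre",
                "x": "rightward",
                "y": "upward",
                "grid_extent": "centre span",
                "disparity_sign": "d = x_right_eye - x_left_eye; d < 0 is crossed (near)",
            },
            "items": [
                {
                    "grid_pos": it.grid_pos,
                    "position": it.position,
                    "identity": it.identity,
                    "role": it.role,
                    "O": it.O,
                    "C_sum": it.C_sum,
                    "disparity": it.disparity,
                    "luminance_L": it.luminance_L,
                    "luminance_R": it.luminance_R,
                    "transient": it.transient.label,
                }
                for it in self.items
            ],
            "anchors": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.anchors.items()
            },
            "fixation": {
                "diameter_deg": self.config.fixation_diameter_deg,
                "pre_onset_duration_s": self.config.fixation_duration_s,
            },
        }


def _eye_luminances(
    config: ExperimentConfig, trial: TrialSpec, O: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    disp = config.display
    s_L = (1.0 + O) / 2.0
    s_R = 1.0 - s_L
    if disp.polarity == "bright":
        return s_L * trial.C_sum * disp.L_sum, s_R * trial.C_sum * disp.L_sum
    if disp.polarity == "decrement":
        return disp.L_bg * (1.0 - s_L), disp.L_bg * (1.0 - s_R)
    # increment (E4): the target's two-eye increments sum to L_1 * (1 + x);
    # balanced non-targets show L_o + L_1 * (0.5 + x) to both eyes.
    x = trial.lum_jitter
    lum_L = disp.L_o + disp.L_1 * (0.5 + x)
    lum_R = lum_L.copy()
    t = trial.target_index
    lum_L[t] = disp.L_o + disp.L_1 * s_L[t] * (1.0 + x[t])
    lum_R[t] = disp.L_o + disp.L_1 * s_R[t] * (1.0 + x[t])
    return lum_L, lum_R


def generate_trial(
    config: ExperimentConfig, cell: ConditionCell, seed: int, index: int = 0
) -> TrialSpec:
    """Build one complete trial; a pure function of (config, cell, seed)."""
    rng = np.random.default_rng(seed)
    n = config.n_items
    grid = make_grid(config)
    positions = jitter_positions(grid, config, rng)
    t_rc = choose_target_position(config, rng)
    target_index = rc_to_index(config, *t_rc)
    singleton_index = None
    if cell.condition == "DI":
        s_rc = choose_singleton_position(t_rc, config, rng, cell.singleton_policy)
        singleton_index = rc_to_index(config, *s_rc)
    identity = assign_identities(n, target_index, config, rng)
    O = assign_ocularity(
        n, target_index, singleton_index, cell.condition, cell.O_mag, cell.scheme, rng
    )
    disparity = assign_disparity(config, rng)
    lum_jitter = None
    if config.display.polarity == "increment":
        lum_jitter, C_sum = assign_contrast_heterogeneity_e4(n, target_index, rng)
    else:
        C_sum = np.full(n, config.display.C_sum_default)
        if cell.singleton_csum_scale != 1.0:
            odd = {"DC": target_index, "DI": singleton_index}.get(cell.condition)
            if odd is not None:
                C_sum[odd] = C_sum[odd] * cell.singleton_csum_scale
    trial = TrialSpec(
        config=config,
        cell=cell,
        index=index,
        seed=seed,
        target_index=target_index,
        singleton_index=singleton_index,
        positions=positions,
        identity=identity,
        O=O,
        C_sum=C_sum,
        disparity=disparity,
        lum_L=np.empty(0),
        lum_R=np.empty(0),
        lum_jitter=lum_jitter,
    )
    trial.lum_L, trial.lum_R = _eye_luminances(config, trial, O)
    return trial


@dataclass(frozen=True)
class SessionSpec:
    """A session: a condition grid, trial counts, and a session seed."""

    config: ExperimentConfig
    cells: tuple[ConditionCell, ...]
    trials_per_condition: int
    rng_seed: int

    @property
    def n_trials(self) -> int:
        return len(self.cells) * self.trials_per_condition


def schedule_session(session: SessionSpec) -> list[TrialSpec]:
    """Randomly interleaved trial list for a session.

    Each condition cell contributes ``trials_per_condition`` trials; the
    order is a uniform shuffle driven by the session seed, and each trial's
    own randomizations (positions, signs, jitters) come from an independent
    child seed, so the schedule is a pure function of the session spec.
    """
    root = np.random.SeedSequence(session.rng_seed)
    children = root.spawn(session.n_trials + 1)
    order_rng = np.random.default_rng(children[0])
    cell_ids = np.repeat(np.arange(len(session.cells)), session.trials_per_condition)
    order_rng.shuffle(cell_ids)
    trials = []
    for i, ci in enumerate(cell_ids):
        trial_seed = int(children[i + 1].generate_state(1)[0] % (2**31))
        trials.append(
            generate_trial(session.config, session.cells[ci], trial_seed, index=i)
        )
    return trials


def standard_cells(
    experiment_id: str,
    transient: TransientProfile = STATIC,
    scheme: str = "sign_flip",
    singleton_csum_scale: float = 1.0,
) -> tuple[ConditionCell, ...]:
    """The stock condition grids.

    E2: {1/5, 1/3, 3/5} x {baseline, DC, DI} (9 cells).
    E3: {1/5, 1/3, 1/2, 3/5} x {baseline, DC} (8 cells).
    E4: one baseline plus 9 DC cells of {1/5, 1/3, 3/5} x {static,
    smooth dT=0.1, smooth dT=0.5} (10 cells).
    E1: {baseline, DC, DI} at a single |O| (per-session scheme variants).
    """
    if experiment_id == "E2":
        return tuple(
            ConditionCell(c, m, transient, scheme, singleton_csum_scale)
            for m in (1 / 5, 1 / 3, 3 / 5)
            for c in ("baseline", "DC", "DI")
        )
    if experiment_id == "E3":
        return tuple(
            ConditionCell(c, m, transient, scheme, singleton_csum_scale)
            for m in (1 / 5, 1 / 3, 1 / 2, 3 / 5)
            for c in ("baseline", "DC")
        )
    if experiment_id == "E4":
        cells = [ConditionCell("baseline", 0.0, STATIC, "target_only")]
        for m in (1 / 5, 1 / 3, 3 / 5):
            for prof in (
                STATIC,
                TransientProfile("smooth", dT=0.1),
                TransientProfile("smooth", dT=0.5),
            ):
                cells.append(ConditionCell("DC", m, prof, "target_only"))
        return tuple(cells)
    if experiment_id == "E1":
        return tuple(
            ConditionCell(c, 1.0, transient, scheme, singleton_csum_scale)
            for c in ("baseline", "DC", "DI")
        )
    raise ConfigurationError(f"unknown experiment {experiment_id!r}")


def e1_session_cells(variant: str) -> tuple[ConditionCell, ...]:
    """Condition cells for the named E1 session variants.

    ``eye_of_origin``: all bars monocular, the singleton from the other eye.
    ``eye_dominance``: 9:1 dominance ratio (s_dom = 9 * s_other, |O| = 0.8).
    ``binocular_among_monocular``: O = 0 singleton among |O| = 1 bars.
    ``monocular_among_binocular``: |O| = 1 singleton among O = 0 bars, with
    the binocular sum held constant (double-strength monocular input).
    ``monocular_among_binocular_single``: as above but the monocular bar
    matches max(C_L, C_R) of the binocular bars (half the binocular sum).
    A ``_transient`` suffix limits the singleton's ocularity to the first
    0.15 s of the display.
    """
    transient = STATIC
    if variant.endswith("_transient"):
        transient = TransientProfile("abrupt", dT=0.15)
        variant = variant[: -len("_transient")]
    if variant == "eye_of_origin":
        return standard_cells("E1", transient, "sign_flip")
    if variant == "eye_dominance":
        return tuple(
            ConditionCell(c, 0.8, transient, "sign_flip")
            for c in ("baseline", "DC", "DI")
        )
    if variant == "binocular_among_monocular":
        return standard_cells("E1", transient, "zero_among_full")
    if variant == "monocular_among_binocular":
        return standard_cells("E1", transient, "full_among_zero")
    if variant == "monocular_among_binocular_single":
        return standard_cells("E1", transient, "full_among_zero", 0.5)
    raise ConfigurationError(f"unknown E1 session variant {variant!r}")
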