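"""Ocularity algebra, per-eye luminance mappings, and temporal profiles.

The ocularity of a dichoptic input item summarizes how its input contrast is
split between the two eyes.  Writing ``C_L`` and ``C_R`` for the input
contrasts to the left and right eye (both in [0, 1]), the relative eye
weights are ``s_L = C_L / (C_L + C_R)`` and ``s_R = 1 - s_L``, and the
ocularity value is ``O = s_L - s_R`` in [-1, 1].  ``|O| = 1`` denotes a
monocular item, ``O = 0`` an ocularly balanced one, and the sign of ``O``
names the dominant eye (positive = left).

This module also holds the display-side luminance mappings used by the
stimulus generator:

* bright bars on a black background, where a bar delivers a fixed binocular
  luminance sum split between the eyes in proportion to ``s_L : s_R``;
* luminance *decrements* (dark bars/letters on a white background), where
  the item luminance seen by an eye with weight ``s`` is ``L_bg * (1 - s)``;
* luminance *increments* on a grey background, where stroke luminance is
  ``L_o + L_1 * (0.5 + x)`` for ocularly balanced non-targets and
  ``L_o + L_1 * s * (1 + x)`` for the (possibly unbalanced) target, with a
  per-item random fluctuation ``x``.

All luminances are screen-side values in cd/m^2; any attenuation along the
optical path (goggles, stereoscope mirrors) is carried as metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "ContrastPair",
    "Ocularity",
    "DisplayConfig",
    "TransientProfile",
    "LuminanceJitter",
    "STATIC",
    "ocularity_from_contrasts",
    "contrasts_from_ocularity",
    "decrement_luminance",
    "bright_bar_luminance",
    "increment_luminance_nontarget",
    "increment_luminance_target",
    "ocularity_at_time",
    "draw_luminance_jitter",
]

#: Open jitter intervals by item role for increment displays.
JITTER_RANGES = {"nontarget": (-0.3, 0.3), "target": (-0.2, 0.2)}


@dataclass(frozen=True)
class ContrastPair:
    """Per-eye input contrasts of one item, each in [0, 1]."""

    C_L: float
    C_R: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.C_L <= 1.0 and 0.0 <= self.C_R <= 1.0):
            raise InvalidInputError(
                f"contrasts must lie in [0, 1]; got ({self.C_L}, {self.C_R})"
            )

    @property
    def total(self) -> float:
        """Binocular contrast sum ``C_L + C_R``."""
        return self.C_L + self.C_R


@dataclass(frozen=True)
class Ocularity:
    """Relative eye weights of one item; ``s_L + s_R == 1`` by construction."""

    s_L: float
    s_R: float

    def __post_init__(self) -> None:
        if abs(self.s_L + self.s_R - 1.0) > 1e-12:
            raise InvalidInputError(
                f"eye weights must sum to 1; got {self.s_L} + {self.s_R}"
            )
        if not (-1e-12 <= self.s_L <= 1.0 + 1e-12):
            raise InvalidInputError(f"s_L out of [0, 1]: {self.s_L}")

    @property
    def O(self) -> float:
        """Ocularity value ``s_L - s_R`` in [-1, 1]."""
        return self.s_L - self.s_R

    @property
    def is_monocular(self) -> bool:
        return abs(abs(self.O) - 1.0) < 1e-12

    @property
    def is_balanced(self) -> bool:
        return abs(self.O) < 1e-12


@dataclass(frozen=True)
class DisplayConfig:
    """Display polarity and luminance calibration.

    Parameters
    ----------
    polarity:
        ``"bright"`` for bright bars on black, ``"decrement"`` for dark items
        on a white background, ``"increment"`` for light letters on grey.
    L_bg:
        White background luminance for decrement displays (cd/m^2).
    L_o:
        Grey background luminance for increment displays (cd/m^2).
    L_1:
        Increment-display luminance scale (cd/m^2).
    L_sum:
        Binocular luminance sum of a full-contrast bar on a bright display
        (cd/m^2); an ocularly balanced bar then shows ``L_sum / 2`` per eye.
    C_sum_default:
        Default binocular contrast sum assigned to items.
    optic_attenuation:
        Fraction of screen luminance lost before the eye (goggles etc.);
        recorded as metadata, never applied to reported luminances.
    """

    polarity: str = "decrement"
    L_bg: float = 110.0
    L_o: float = 43.0
    L_1: float = 67.0
    L_sum: float = 48.0
    C_sum_default: float = 1.0
    optic_attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.polarity not in ("bright", "decrement", "increment"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if min(self.L_bg, self.L_o, self.L_1, self.L_sum) < 0:
            raise ConfigurationError("luminances must be >= 0")
        if not (0.0 <= self.optic_attenuation < 1.0):
            raise ConfigurationError("optic_attenuation must be in [0, 1)")

    @property
    def peak_luminance(self) -> float:
        """Largest luminance the display can show under this configuration.

        Used by the renderer to map luminance linearly onto 8-bit pixel
        values.  For increment displays the target formula peaks at
        ``L_o + 1.2 * L_1`` (``s = 1`` with the target jitter bound 0.2).
        """
        if self.polarity == "decrement":
            return self.L_bg
        if self.polarity == "bright":
            return self.L_sum
        return self.L_o + 1.2 * self.L_1


@dataclass(frozen=True)
class TransientProfile:
    """Temporal profile of an item's ocularity after stimulus onset.

    ``static`` keeps the initial ocularity throughout the trial; ``abrupt``
    removes it instantaneously at ``dT`` seconds; ``smooth`` ramps it to zero
    over ``[dT, dT + decay_window]``.  The default smooth ramp is a raised
    cosine, which is C1 at both ends of the window (a perceptible transient
    is exactly what the smooth profile exists to avoid); a ``"linear"`` ramp
    is available behind the ``ramp`` flag.  The binocular contrast sum of the
    item is unchanged at all times; only the split between eyes evolves.
    """

    mode: str = "static"
    dT: float | None = None
    decay_window: float = 0.1
    ramp: str = "cosine"

    def __post_init__(self) -> None:
        if self.mode not in ("static", "abrupt", "smooth"):
            raise ConfigurationError(f"unknown transient mode {self.mode!r}")
        if self.mode != "static":
            if self.dT is None or self.dT <= 0:
                raise ConfigurationError("dT must be > 0 for transient profiles")
        if self.mode == "smooth" and self.decay_window != 0.1:
            raise ConfigurationError("smooth decay window is fixed at 0.1 s")
        if self.ramp not in ("cosine", "linear"):
            raise ConfigurationError(f"unknown ramp {self.ramp!r}")

    @property
    def label(self) -> str:
        """Short condition label used in trial logs (e.g. ``smooth_0.1``)."""
        if self.mode == "static":
            return "static"
        return f"{self.mode}_{self.dT:g}"


STATIC = TransientProfile("static")


@dataclass(frozen=True)
class LuminanceJitter:
    """A per-item random luminance fluctuation for increment displays.

    ``x`` must lie strictly inside the open interval associated with the
    item's role: (-0.3, 0.3) for non-targets, (-0.2, 0.2) for the target.
    """

    x: float
    role: str = "nontarget"
    range_nontarget: tuple[float, float] = field(default=JITTER_RANGES["nontarget"])
    range_target: tuple[float, float] = field(default=JITTER_RANGES["target"])

    def __post_init__(self) -> None:
        if self.role not in ("nontarget", "target"):
            raise InvalidInputError(f"unknown jitter role {self.role!r}")
        lo, hi = self.bounds
        if not (lo < self.x < hi):
            raise InvalidInputError(
                f"jitter x={self.x} outside open interval ({lo}, {hi}) for role {self.role!r}"
            )

    @property
    def bounds(self) -> tuple[float, float]:
        return self.range_target if self.role == "target" else self.range_nontarget


def draw_luminance_jitter(role: str, rng) -> LuminanceJitter:
    """Draw a jitter strictly inside the open interval for ``role``.

    Open intervals are enforced by rejection sampling; boundary draws
    (measure zero, but possible in floating point) are rejected.
    """
    lo, hi = JITTER_RANGES[role]
    while True:
        x = rng.uniform(lo, hi)
        if lo < x < hi:
            return LuminanceJitter(x, role)


def ocularity_from_contrasts(pair: ContrastPair) -> Ocularity:
    """Eye weights and ocularity from a per-eye contrast pair.

    Raises :class:`InvalidInputError` for a zero-sum pair, which would
    describe an invisible item with undefined ocularity.
    """
    total = pair.total
    if total <= 0.0:
        raise InvalidInputError("C_L + C_R must be > 0 (invisible item)")
    s_L = pair.C_L / total
    return Ocularity(s_L=s_L, s_R=1.0 - s_L)


def contrasts_from_ocularity(O: float, C_sum: float) -> ContrastPair:
    """Invert the ocularity definition for a given binocular contrast sum.

    ``C_L = C_sum * (1 + O) / 2`` and ``C_R = C_sum * (1 - O) / 2``; the
    result round-trips through :func:`ocularity_from_contrasts`.
    """
    if not (-1.0 <= O <= 1.0):
        raise InvalidInputError(f"|O| must be <= 1; got {O}")
    if not (0.0 < C_sum <= 2.0):
        raise InvalidInputError(f"C_sum must be in (0, 2]; got {C_sum}")
    C_L = C_sum * (1.0 + O) / 2.0
    C_R = C_sum * (1.0 - O) / 2.0
    if C_L > 1.0 + 1e-12 or C_R > 1.0 + 1e-12:
        raise InvalidInputError(
            f"per-eye contrast out of range: ({C_L}, {C_R}) from O={O}, C_sum={C_sum}"
        )
    return ContrastPair(min(C_L, 1.0), min(C_R, 1.0))


def decrement_luminance(s: float, display: DisplayConfig) -> float:
    """Item luminance seen by an eye with weight ``s`` on a decrement display.

    The dark item is darker for the more dominant eye: ``L_bg * (1 - s)``.
    """
    if display.polarity != "decrement":
        raise ConfigurationError("decrement_luminance requires a decrement display")
    if not (0.0 <= s <= 1.0):
        raise InvalidInputError(f"eye weight out of [0, 1]: {s}")
    return display.L_bg * (1.0 - s)


def bright_bar_luminance(s: float, display: DisplayConfig, C_sum: float | None = None) -> float:
    """Per-eye luminance of a bright bar delivering ``C_sum * L_sum`` binocularly.

    An eye with weight ``s`` receives ``s * C_sum * L_sum``; the two eyes'
    luminances always sum to ``C_sum * L_sum``.
    """
    if display.polarity != "bright":
        raise ConfigurationError("bright_bar_luminance requires a bright display")
    if not (0.0 <= s <= 1.0):
        raise InvalidInputError(f"eye weight out of [0, 1]: {s}")
    if C_sum is None:
        C_sum = display.C_sum_default
    return s * C_sum * display.L_sum


def increment_luminance_nontarget(jitter: LuminanceJitter, display: DisplayConfig) -> float:
    """Monocular stroke luminance of an ocularly balanced non-target letter.

    ``L_o + L_1 * (0.5 + x)``, identical for the two eyes of the item.
    """
    if display.polarity != "increment":
        raise ConfigurationError("increment mapping requires an increment display")
    if jitter.role != "nontarget":
        raise InvalidInputError("nontarget luminance needs a nontarget-role jitter")
    return display.L_o + display.L_1 * (0.5 + jitter.x)


def increment_luminance_target(s: float, jitter: LuminanceJitter, display: DisplayConfig) -> float:
    """Monocular stroke luminance of the target letter for an eye with weight ``s``.

    ``L_o + L_1 * s * (1 + x)``; the two eyes' increments sum to
    ``L_1 * (1 + x)`` independently of the ocularity split.
    """
    if display.polarity != "increment":
        raise ConfigurationError("increment mapping requires an increment display")
    if jitter.role != "target":
        raise InvalidInputError("target luminance needs a target-role jitter")
    if not (0.0 <= s <= 1.0):
        raise InvalidInputError(f"eye weight out of [0, 1]: {s}")
    return display.L_o + display.L_1 * s * (1.0 + jitter.x)


def ocularity_at_time(t: float, O0: float, profile: TransientProfile) -> float:
    """Ocularity of an item ``t`` seconds after stimulus onset.

    Static profiles keep ``O0`` forever.  Abrupt profiles drop to zero at
    ``dT``.  Smooth profiles hold ``O0`` until ``dT``, then follow a
    continuous monotone ramp to zero over ``[dT, dT + decay_window]``.
    """
    if t < 0:
        raise InvalidInputError(f"time since onset must be >= 0; got {t}")
    if profile.mode == "static":
        return O0
    dT = profile.dT
    if profile.mode == "abrupt":
        return O0 if t < dT else 0.0
    if t <= dT:
        return O0
    end = dT + profile.decay_window
    if t >= end:
        return 0.0
    u = (t - dT) / profile.decay_window
    if profile.ramp == "linear":
        return O0 * (1.0 - u)
    return O0 * (1.0 + math.cos(math.pi * u)) / 2.0
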