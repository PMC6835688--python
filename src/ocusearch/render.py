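"""Rasterization of dichoptic trials into monocular luminance images.

Each eye's image is drawn in screen luminance (cd/m^2) and mapped linearly
onto 8-bit grey with the display's peak luminance at 255.  Bars are drawn
as rotated rectangles, letters as axis-aligned stroke glyphs ('T': top
horizontal + centred vertical stroke; 'L': left vertical + bottom
horizontal stroke).  Vergence anchors (inter-item dots, corner disks or an
enclosing frame) are binocular and zero-disparity.  Items whose ocularity
is transient are re-weighted at the requested time since onset, so a
monocular item simply vanishes from its silent eye's image.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .errors import InvalidInputError
from .stimuli import TrialSpec

__all__ = ["render_dichoptic", "save_stereo_pair"]

logger = logging.getLogger(__name__)


def _bar_polygon(cx, cy, length, width, tilt_deg):
    t = math.radians(tilt_deg)
    ux, uy = math.cos(t), math.sin(t)  # along the bar
    vx, vy = -uy, ux  # across
    hl, hw = length / 2.0, width / 2.0
    return [
        (cx + sx * hl * ux + sy * hw * vx, cy + sx * hl * uy + sy * hw * vy)
        for sx, sy in ((-1, -1), (1, -1), (1, 1), (-1, 1))
    ]


def _letter_rects(cx, cy, glyph, size, stroke):
    h = size / 2.0
    s = stroke
    if glyph == "T":
        return [
            (cx - h, cy + h - s, cx + h, cy + h),  # top bar
            (cx - s / 2, cy - h, cx + s / 2, cy + h - s),  # stem
        ]
    if glyph == "L":
        return [
            (cx - h, cy - h, cx - h + s, cy + h),  # left stem
            (cx - h + s, cy - h, cx + h, cy - h + s),  # foot
        ]
    raise InvalidInputError(f"unknown glyph {glyph!r}")


def render_dichoptic(
    trial: TrialSpec,
    t: float = 0.0,
    eye: str = "left",
    pixels_per_degree: float = 8.0,
    pad_deg: float = 2.5,
) -> np.ndarray:
    """Render one eye's view of a trial at time ``t`` since onset.

    Returns an 8-bit grayscale array; deterministic given the trial and
    raster configuration.  Items falling outside the canvas are clipped
    with a logged warning.
    """
    if eye not in ("left", "right"):
        raise InvalidInputError(f"eye must be 'left' or 'right'; got {eye!r}")
    cfg = trial.config
    ppd = float(pixels_per_degree)
    half_w = cfg.extent_x / 2.0 + pad_deg
    half_h = cfg.extent_y / 2.0 + pad_deg
    W = int(round(2 * half_w * ppd))
    H = int(round(2 * half_h * ppd))
    peak = cfg.display.peak_luminance

    def to_px(x, y):
        return ((x + half_w) * ppd, (half_h - y) * ppd)

    def level(lum):
        return int(round(255 * min(max(lum, 0.0), peak) / peak))

    bg = {"bright": 0.0, "decrement": cfg.display.L_bg, "increment": cfg.display.L_o}[
        cfg.display.polarity
    ]
    img = Image.new("L", (W, H), color=level(bg))
    draw = ImageDraw.Draw(img)

    # --- vergence anchors (binocular, zero disparity) ---
    anchors = trial.anchors
    dark_display = cfg.display.polarity == "decrement"
    dot_level = level(0.0 if dark_display else peak)
    r = anchors["dot_size_deg"] / 2.0 * ppd
    for x, y in anchors["dots"]:
        px, py = to_px(x, y)
        draw.rectangle((px - r, py - r, px + r, py + r), fill=dot_level)
    if "corner_disks" in anchors:
        rr = anchors["corner_disk_diameter_deg"] / 2.0 * ppd
        for x, y in anchors["corner_disks"]:
            px, py = to_px(x, y)
            draw.ellipse((px - rr, py - rr, px + rr, py + rr), fill=dot_level)
    if "frame_extent_deg" in anchors:
        fx, fy = anchors["frame_extent_deg"]
        x0, y0 = to_px(-fx / 2.0, fy / 2.0)
        x1, y1 = to_px(fx / 2.0, -fy / 2.0)
        frame_level = level(0.0 if dark_display else peak)
        draw.rectangle((x0, y0, x1, y1), outline=frame_level, width=max(1, int(ppd * 0.1)))

    # --- search items at their per-eye positions and luminances ---
    lum_L, lum_R = trial.eye_luminances(t)
    lums = lum_L if eye == "left" else lum_R
    positions = trial.eye_positions(eye)
    clipped = 0
    for i in range(trial.n_items):
        x, y = positions[i]
        if abs(x) > half_w or abs(y) > half_h:
            clipped += 1
            continue
        lvl = level(lums[i])
        if lvl == level(bg):
            continue  # invisible in this eye (e.g. monocular item, silent eye)
        px, py = to_px(x, y)
        if cfg.item_kind == "bar":
            length, width = cfg.item_size
            poly = _bar_polygon(x, y, length, width, float(trial.identity[i]))
            draw.polygon([to_px(qx, qy) for qx, qy in poly], fill=lvl)
        else:
            size = cfg.item_size[0]
            for x0, y0, x1, y1 in _letter_rects(x, y, trial.identity[i], size, cfg.stroke_width_deg):
                p0, p1 = to_px(x0, y1), to_px(x1, y0)
                draw.rectangle((p0[0], p0[1], p1[0], p1[1]), fill=lvl)
    if clipped:
        logger.warning("trial %d: %d items clipped outside the canvas", trial.index, clipped)
    return np.asarray(img)


def save_stereo_pair(
    trial: TrialSpec,
    out_dir,
    t: float = 0.0,
    pixels_per_degree: float = 8.0,
    side_by_side: bool = False,
) -> list[Path]:
    """Write ``trial####_L.png`` / ``trial####_R.png`` (and optionally a
    side-by-side stereogram) for one trial; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    imgs = {}
    for eye, tag in (("left", "L"), ("right", "R")):
        arr = render_dichoptic(trial, t=t, eye=eye, pixels_per_degree=pixels_per_degree)
        imgs[tag] = arr
        p = out_dir / f"trial{trial.index:04d}_{tag}.png"
        Image.fromarray(arr).save(p)
        paths.append(p)
    if side_by_side:
        pair = np.concatenate([imgs["L"], imgs["R"]], axis=1)
        p = out_dir / f"trial{trial.index:04d}_stereo.png"
        Image.fromarray(pair).save(p)
        paths.append(p)
    return paths
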