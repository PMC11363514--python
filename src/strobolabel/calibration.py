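"""Data-driven estimation of per-color HSB filter bounds.

The original workflow tuned HSB bounds interactively in a GUI that
re-filtered sample UV frames live.  Here the tuning is scriptable: the
user marks a handful of seed pixels on sample UV frames (one text line per
seed), and bounds are fit per color from the HSB values in a 3×3
neighborhood of each seed — componentwise [min, max] widened by a margin,
with hue handled on the circle via the minimal covering arc.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detection import HSBBounds, filter_color, rgb_to_hsb
from .frames import Frame

#: widen each channel interval by this fraction of its range by default;
#: seeds undersample the marker's chromatic spread
DEFAULT_MARGIN = 0.25


@dataclass(frozen=True)
class SeedSample:
    """One user-marked marker pixel: frame index, (x, y), color label."""

    frame_index: int
    x: int
    y: int
    color_name: str


def read_seed_file(path: str | Path) -> list[SeedSample]:
    """Parse a seed file: whitespace-separated ``frame_idx x y color_name``
    columns, ``#`` comments and blank lines ignored."""
    seeds = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'frame_idx x y color', got {raw!r}")
        seeds.append(SeedSample(int(parts[0]), int(parts[1]), int(parts[2]), parts[3]))
    return seeds


def minimal_covering_arc(hues_deg: np.ndarray) -> tuple[float, float]:
    """Smallest circular arc [lo, hi] (degrees, possibly wrapping through
    0°) that covers all given hues.

    Found by sorting the hues and cutting the circle at the largest gap
    between consecutive values; the arc is the complement of that gap.
    """
    h = np.sort(np.asarray(hues_deg, dtype=float) % 360.0)
    if h.size == 1:
        return float(h[0]), float(h[0])
    gaps = np.diff(h)
    wrap_gap = h[0] + 360.0 - h[-1]
    i = int(np.argmax(gaps)) if gaps.size else 0
    if gaps.size == 0 or wrap_gap >= gaps[i]:
        return float(h[0]), float(h[-1])  # cut at the wrap gap: no wrapping needed
    return float(h[i + 1]), float(h[i])  # arc wraps through 0°


def _arc_width(lo: float, hi: float) -> float:
    return (hi - lo) % 360.0 if lo != hi else 0.0


def _neighborhood_hsb(frame: Frame, x: int, y: int) -> np.ndarray:
    """HSB values of the 3×3 neighborhood of a pixel, clipped at borders."""
    h, w = frame.pixels.shape[:2]
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"seed pixel ({x}, {y}) outside frame bounds {w}×{h}")
    y0, y1 = max(y - 1, 0), min(y + 2, h)
    x0, x1 = max(x - 1, 0), min(x + 2, w)
    patch = frame.pixels[y0:y1, x0:x1]
    return rgb_to_hsb(patch).reshape(-1, 3)


def estimate_bounds(
    frames: Mapping[int, Frame] | Sequence[Frame],
    seeds: Iterable[SeedSample],
    margin: float = DEFAULT_MARGIN,
    min_seeds: int = 3,
) -> dict[str, HSBBounds]:
    """Fit per-color HSB bounds from seed-pixel neighborhoods.

    For each color the HSB samples of all 3×3 seed neighborhoods are
    pooled; saturation and brightness bounds are [min, max] widened by
    ``margin`` × range and clipped to [0, 1]; the hue interval is the
    minimal covering arc widened by ``margin`` × its width on each side
    (on the circle).  Estimation is invariant to seed order, and widening
    is monotone in ``margin``.

    Raises ``ValueError`` when a color has fewer than ``min_seeds`` seeds
    or when its seed hues span more than 180° (not color-coherent).
    """
    if margin < 0:
        raise ValueError("margin must be ≥ 0")
    frame_map: Mapping[int, Frame]
    if isinstance(frames, Mapping):
        frame_map = frames
    else:
        frame_map = {f.index: f for f in frames}

    by_color: dict[str, list[np.ndarray]] = {}
    for seed in seeds:
        if seed.frame_index not in frame_map:
            raise ValueError(f"seed references unknown frame {seed.frame_index}")
        by_color.setdefault(seed.color_name, []).append(
            _neighborhood_hsb(frame_map[seed.frame_index], seed.x, seed.y))

    out: dict[str, HSBBounds] = {}
    for color in sorted(by_color):
        chunks = by_color[color]
        if len(chunks) < min_seeds:
            raise ValueError(
                f"color {color!r} has {len(chunks)} seeds; at least {min_seeds} required")
        hsb = np.concatenate(chunks, axis=0)
        lo_h, hi_h = minimal_covering_arc(hsb[:, 0])
        width = _arc_width(lo_h, hi_h)
        if width > 180.0:
            raise ValueError(
                f"color {color!r}: seeds not color-coherent (hue arc spans {width:.1f}°)")
        pad = margin * width
        lo_h = (lo_h - pad) % 360.0
        hi_h = (hi_h + pad) % 360.0
        if _arc_width(lo_h, hi_h) >= 360.0 - 1e-9 or margin * width * 2 + width >= 360.0:
            lo_h, hi_h = 0.0, 360.0 - 1e-9  # widened arc covers the full circle

        svals, vvals = hsb[:, 1], hsb[:, 2]
        bounds_sv = []
        for vals in (svals, vvals):
            lo, hi = float(vals.min()), float(vals.max())
            pad_c = margin * (hi - lo)
            bounds_sv.append((max(lo - pad_c, 0.0), min(hi + pad_c, 1.0)))
        out[color] = HSBBounds(
            color_name=color,
            lower=(lo_h, bounds_sv[0][0], bounds_sv[1][0]),
            upper=(hi_h, bounds_sv[0][1], bounds_sv[1][1]),
        )
        # sanity: the fitted bounds must capture (almost) all evidence pixels
        inside = np.fromiter(
            (out[color].contains(*row) for row in hsb), dtype=bool, count=len(hsb))
        if inside.mean() < 0.99:
            raise ValueError(
                f"color {color!r}: fitted bounds classify only "
                f"{100 * inside.mean():.1f}% of seed-neighborhood pixels in-gamut")
    return out


def preview_filter(frame: Frame, bounds: HSBBounds) -> np.ndarray:
    """The frame with out-of-gamut pixels zeroed, for visual inspection."""
    mask = filter_color(frame.pixels, bounds)
    out = frame.pixels.copy()
    out[~mask] = 0
    return out
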