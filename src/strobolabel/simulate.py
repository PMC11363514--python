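"""Seeded synthetic stroboscopic videos with ground-truth marker tracks.

The generator emulates the recording structure of the wheel setup: frames
alternate between a dark UV exposure, on which four colored fluorescent
paw markers glow in two non-overlapping camera views (direct bottom view
and mirror side view), and a bright white-light exposure on which the
markers are invisible and only a gray mouse-like silhouette is seen.  Paw
centers follow seeded sinusoidal gait paths with distinct phases, giving
diverse poses while keeping the per-frame displacement below a stated
bound — at 720 Hz adjacent frames are ~1.4 ms apart, so real inter-frame
motion is sub-pixel.  Every frame's true marker centers are recorded in a
manifest, the oracle for all recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage import color as skcolor

PAWS = ("left_front", "right_front", "left_hind", "right_hind")
#: reference ink colors: blue LF, green RF, red LH, turquoise RH
DEFAULT_COLORS: dict[str, tuple[float, float, float]] = {
    "blue": (230.0, 0.85, 0.95),
    "green": (120.0, 0.85, 0.95),
    "red": (0.0, 0.85, 0.95),
    "turquoise": (175.0, 0.85, 0.95),
}
DEFAULT_COLOR_TO_PAW = {
    "blue": "left_front",
    "green": "right_front",
    "red": "left_hind",
    "turquoise": "right_hind",
}
#: gait phase offsets mimicking alternating footfalls
GAIT_PHASES = {"left_front": 0.0, "right_front": math.pi,
               "left_hind": math.pi / 2, "right_hind": 3 * math.pi / 2}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic recording.

    Defaults mirror the reference setup: 720×364 px at 720 Hz, four
    marker colors, two disjoint view bands (bottom band on top, mirror
    band below), UV background brightness ~0.05 and white ~0.85, and a
    gait whose per-frame displacement stays within ``displacement_bound``
    (0.5 px by default, consistent with negligible 1.4 ms motion).
    """

    width: int = 720
    height: int = 364
    n_pairs: int = 50
    frame_rate: float = 720.0
    marker_colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS))
    color_to_paw: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLOR_TO_PAW))
    marker_radius_bottom: float = 6.0
    marker_radius_side: float = 4.0
    gait_amplitude_x: float = 12.0
    gait_amplitude_y: float = 3.0
    gait_frequency_hz: float = 4.0
    displacement_bound: float = 0.5
    noise_std: float = 2.0
    uv_background_v: float = 0.05
    white_background_v: float = 0.85
    # view bands as (y0, y1) row ranges; disjoint by construction
    bottom_region: tuple[int, int] = (0, 200)
    side_region: tuple[int, int] = (210, 364)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.bottom_region[1] <= self.side_region[0]
                or self.side_region[1] <= self.bottom_region[0]):
            raise ValueError("view regions must be disjoint")
        for name, (y0, y1) in (("bottom", self.bottom_region), ("side", self.side_region)):
            r = self.marker_radius_bottom if name == "bottom" else self.marker_radius_side
            if y1 - y0 < 4 * r:
                raise ValueError(f"marker radius too large for {name} view region")
        # peak gait speed must respect the per-frame displacement bound
        # (the y sinusoid runs at twice the stride frequency)
        w = 2 * math.pi * self.gait_frequency_hz / self.frame_rate
        peak = w * math.hypot(self.gait_amplitude_x, 2 * self.gait_amplitude_y)
        if peak > self.displacement_bound:
            raise ValueError(
                f"gait peak step {peak:.3f} px/frame exceeds displacement bound "
                f"{self.displacement_bound}")

    @property
    def n_frames(self) -> int:
        return 2 * self.n_pairs

    @property
    def bodyparts(self) -> list[str]:
        return [f"{paw}_{view}" for paw in PAWS for view in ("bottom", "side")]


def _paw_anchor(cfg: GeneratorConfig, paw: str, view: str) -> tuple[float, float]:
    """Rest position of one paw in one view, spread along x."""
    order = PAWS.index(paw)
    x = cfg.width * (0.2 + 0.2 * order)
    y0, y1 = cfg.bottom_region if view == "bottom" else cfg.side_region
    y = 0.5 * (y0 + y1)
    return x, y


def true_center(cfg: GeneratorConfig, paw: str, view: str, frame_index: int) -> tuple[float, float]:
    """Ground-truth marker center of one paw/view at one frame."""
    t = frame_index / cfg.frame_rate
    phase = GAIT_PHASES[paw]
    ax, ay = _paw_anchor(cfg, paw, view)
    w = 2 * math.pi * cfg.gait_frequency_hz
    x = ax + cfg.gait_amplitude_x * math.sin(w * t + phase)
    y = ay + cfg.gait_amplitude_y * math.sin(2 * w * t + phase)
    return x, y


def _hsb_to_rgb255(hsb: tuple[float, float, float]) -> np.ndarray:
    h, s, v = hsb
    rgb = skcolor.hsv2rgb(np.array([[[h / 360.0, s, v]]]))[0, 0]
    return rgb * 255.0


def _render_marker(img: np.ndarray, cx: float, cy: float, rx: float, ry: float,
                   rgb: np.ndarray) -> None:
    """Alpha-blend an anti-aliased ellipse onto ``img`` (float RGB, 0-255)."""
    h, w = img.shape[:2]
    x0 = max(int(cx - rx) - 2, 0)
    x1 = min(int(cx + rx) + 3, w)
    y0 = max(int(cy - ry) - 2, 0)
    y1 = min(int(cy + ry) + 3, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    # normalized elliptical distance; soft 1 px edge for anti-aliasing
    d = np.hypot((xx - cx) / rx, (yy - cy) / ry)
    alpha = np.clip((1.0 - d) * min(rx, ry) + 0.5, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch[:] = patch * (1 - alpha[..., None]) + rgb * alpha[..., None]


@dataclass(frozen=True)
class Occlusion:
    """One marker suppressed on one UV frame (tests MISSING handling)."""

    frame_index: int
    bodypart: str  # "{paw}_{view}"


class SyntheticVideo:
    """Seeded frame-by-frame renderer with its ground-truth manifest."""

    def __init__(self, cfg: GeneratorConfig, occlusions: set[Occlusion] | frozenset[Occlusion] = frozenset()):
        self.cfg = cfg
        self.occlusions = set(occlusions)
        self._marker_rgb = {name: _hsb_to_rgb255(hsb)
                            for name, hsb in cfg.marker_colors.items()}

    def is_uv(self, frame_index: int) -> bool:
        return frame_index % 2 == 0  # stream starts on a UV exposure

    def _occluded(self, frame_index: int, paw: str, view: str) -> bool:
        return Occlusion(frame_index, f"{paw}_{view}") in self.occlusions

    def render(self, frame_index: int) -> np.ndarray:
        """Render one frame as H×W×3 uint8 RGB."""
        cfg = self.cfg
        rng = np.random.default_rng((cfg.seed, frame_index))
        if self.is_uv(frame_index):
            base = cfg.uv_background_v * 255.0
            img = np.full((cfg.height, cfg.width, 3), base, dtype=np.float64)
            for cname, paw in cfg.color_to_paw.items():
                rgb = self._marker_rgb[cname]
                for view in ("bottom", "side"):
                    if self._occluded(frame_index, paw, view):
                        continue
                    cx, cy = true_center(cfg, paw, view, frame_index)
                    r = cfg.marker_radius_bottom if view == "bottom" else cfg.marker_radius_side
                    # mirror view appears slightly flattened
                    ry = r if view == "bottom" else 0.8 * r
                    _render_marker(img, cx, cy, r, ry, rgb)
        else:
            base = cfg.white_background_v * 255.0
            img = np.full((cfg.height, cfg.width, 3), base, dtype=np.float64)
            # gray mouse-like silhouette covering the paw loci, no marker color
            for view in ("bottom", "side"):
                y0, y1 = cfg.bottom_region if view == "bottom" else cfg.side_region
                cy = 0.5 * (y0 + y1)
                _render_marker(img, cfg.width * 0.5, cy, cfg.width * 0.35,
                               0.3 * (y1 - y0), np.array([120.0, 120.0, 120.0]))
        if cfg.noise_std > 0:
            img += rng.normal(0.0, cfg.noise_std, img.shape)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    def manifest(self) -> pd.DataFrame:
        """Ground-truth track: one row per frame × bodypart with the true
        center and a visibility flag (False where occluded or on white
        frames, where fluorescence is invisible)."""
        rows = []
        for i in range(self.cfg.n_frames):
            uv = self.is_uv(i)
            for paw in PAWS:
                for view in ("bottom", "side"):
                    x, y = true_center(self.cfg, paw, view, i)
                    visible = uv and not self._occluded(i, paw, view)
                    rows.append({
                        "frame_index": i,
                        "modality": "uv" if uv else "white",
                        "bodypart": f"{paw}_{view}",
                        "x": x, "y": y, "visible": visible,
                    })
        return pd.DataFrame(rows)


def generate_masks(cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    """Binary view masks matching the generator's two view bands."""
    masks = {}
    for name, (y0, y1) in (("bottom", cfg.bottom_region), ("side", cfg.side_region)):
        m = np.zeros((cfg.height, cfg.width), dtype=bool)
        m[y0:y1, :] = True
        masks[name] = m
    return masks


def default_hsb_bounds(cfg: GeneratorConfig, hue_halfwidth: float = 15.0) -> dict[str, dict]:
    """Config-file color entries bracketing the generator's marker colors."""
    entries = {}
    for name, (h, s, v) in cfg.marker_colors.items():
        lo_h = (h - hue_halfwidth) % 360.0
        hi_h = (h + hue_halfwidth) % 360.0
        entries[name] = {
            "lower": [round(lo_h, 3), max(s - 0.35, 0.0), max(v - 0.35, 0.0)],
            "upper": [round(hi_h, 3), 1.0, 1.0],
            "bodypart": cfg.color_to_paw[name],
        }
    return entries


def degrade(video: SyntheticVideo, occlusions: set[Occlusion]) -> SyntheticVideo:
    """A copy of ``video`` with extra markers suppressed; an empty schedule
    returns an equivalent renderer."""
    return SyntheticVideo(video.cfg, video.occlusions | set(occlusions))


def generate_video(
    cfg: GeneratorConfig,
    out_dir: str | Path,
    occlusions: set[Occlusion] | None = None,
) -> dict[str, Path]:
    """Write frames, masks, manifest and a ready-to-use pipeline config.

    Emits ``frames/frame_{i:05d}.png`` (even indices UV, odd white),
    ``truth.csv``, ``mask_bottom.png``, ``mask_side.png`` and
    ``config.yaml``.  Deterministic: the same seed yields bit-identical
    frames and manifest.
    """
    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    video = SyntheticVideo(cfg, occlusions or set())

    for i in range(cfg.n_frames):
        iio.imwrite(frames_dir / f"frame_{i:05d}.png", video.render(i))

    manifest_path = out / "truth.csv"
    video.manifest().to_csv(manifest_path, index=False)

    mask_paths = {}
    for name, mask in generate_masks(cfg).items():
        p = out / f"mask_{name}.png"
        iio.imwrite(p, (mask * 255).astype(np.uint8))
        mask_paths[name] = p

    config = {
        "frame_rate": cfg.frame_rate,
        "parity": "auto",
        "dark_value_cutoff": 60,
        "dark_fraction_threshold": 0.5,
        "min_area": 9,
        "min_keypoints": 4,
        "scorer": "strobolabel",
        "colors": default_hsb_bounds(cfg),
        "masks": {name: str(p.name) for name, p in mask_paths.items()},
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))

    return {
        "frames": frames_dir,
        "truth": manifest_path,
        "config": config_path,
        **{f"mask_{k}": v for k, v in mask_paths.items()},
    }
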