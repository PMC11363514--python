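"""Shared fixtures: small seeded synthetic recordings."""

from __future__ import annotations

import numpy as np
import pytest

from strobolabel.detection import HSBBounds, ViewMaskSet
from strobolabel.frames import Frame, classify_all
from strobolabel.simulate import (
    GeneratorConfig,
    SyntheticVideo,
    default_hsb_bounds,
    generate_masks,
    generate_video,
)


def small_config(**overrides) -> GeneratorConfig:
    """A compact recording geometry that keeps unit tests fast."""
    params = dict(
        width=240, height=160, n_pairs=6, seed=7,
        bottom_region=(0, 90), side_region=(100, 160),
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def render_frames(video: SyntheticVideo, classify: bool = True) -> list[Frame]:
    """Materialize all frames of a synthetic video in memory."""
    cfg = video.cfg
    frames = [
        Frame(i, video.render(i), time_s=i / cfg.frame_rate)
        for i in range(cfg.n_frames)
    ]
    if classify:
        frames = list(classify_all(iter(frames)))
    return frames


def bounds_for(cfg: GeneratorConfig) -> list[HSBBounds]:
    return [
        HSBBounds(name, tuple(e["lower"]), tuple(e["upper"]))
        for name, e in default_hsb_bounds(cfg).items()
    ]


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_video(small_cfg) -> SyntheticVideo:
    return SyntheticVideo(small_cfg)


@pytest.fixture(scope="session")
def small_frames(small_video) -> list[Frame]:
    return render_frames(small_video)


@pytest.fixture(scope="session")
def small_views(small_cfg) -> ViewMaskSet:
    return ViewMaskSet(generate_masks(small_cfg))


@pytest.fixture(scope="session")
def small_bounds(small_cfg) -> list[HSBBounds]:
    return bounds_for(small_cfg)


@pytest.fixture(scope="session")
def small_video_dir(tmp_path_factory, small_cfg):
    """The small recording written to disk with masks, truth and config."""
    out = tmp_path_factory.mktemp("video")
    paths = generate_video(small_cfg, out)
    return paths


def random_binary_mask(rng: np.random.Generator, shape=(40, 40), p: float = 0.3) -> np.ndarray:
    return rng.random(shape) < p
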