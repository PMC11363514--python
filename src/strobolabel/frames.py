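"""Video demultiplexing for stroboscopic dual-illumination recordings.

A single camera records at high rate (720 Hz in the reference setup) while
UV and white LEDs flash on alternate exposures, so the stream interleaves
two modalities: dark UV frames in which only fluorescent paw markers glow,
and bright white-light frames in which the markers are invisible.  This
module reads such a stream, classifies each frame's illumination modality
from its content, and pairs every UV frame with the immediately following
white frame — the unit on which marker coordinates are transferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: value-channel cutoff (8-bit) below which a pixel counts as dark
DEFAULT_DARK_VALUE_CUTOFF = 60
#: fraction of dark pixels above which a frame is called UV
DEFAULT_DARK_FRACTION_THRESHOLD = 0.5


class Modality(Enum):
    """Illumination modality of one frame."""

    UV = "uv"
    WHITE = "white"
    UNKNOWN = "unknown"


@dataclass
class Frame:
    """One video image.

    Attributes
    ----------
    index : int
        Position in the stream, 0-based, strictly increasing.
    pixels : ndarray
        H×W×3 uint8 RGB image.
    modality : Modality
        Illumination modality; UNKNOWN until classified.
    time_s : float
        Timestamp in seconds, ``index / frame_rate``.
    dark_fraction : float or None
        Diagnostic score from :func:`classify_modality` (fraction of
        pixels below the dark-value cutoff); None until classified.
    """

    index: int
    pixels: np.ndarray
    modality: Modality = Modality.UNKNOWN
    time_s: float = 0.0
    dark_fraction: float | None = field(default=None, compare=False)


@dataclass
class FramePair:
    """A UV frame and the white frame that immediately follows it.

    The UV frame carries the visible markers; the white frame is the one
    that receives the transferred labels.  At 720 Hz the two exposures are
    only ~1.4 ms apart, so paw motion between them is negligible.
    """

    uv: Frame
    white: Frame
    dt_s: float

    def __post_init__(self) -> None:
        if self.white.index != self.uv.index + 1:
            raise ValueError(
                f"white frame {self.white.index} does not immediately follow "
                f"UV frame {self.uv.index}"
            )


def _as_rgb(img: np.ndarray) -> np.ndarray:
    """Coerce a decoded image to H×W×3 uint8."""
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def iter_frames(video_path: str | Path, frame_rate: float = 720.0) -> Iterator[Frame]:
    """Stream frames from a video file or a directory of numbered PNGs.

    A directory is read in lexicographic filename order (the generator's
    zero-padded names sort correctly); a file is handed to imageio, which
    requires a plugin able to decode the container.

    Yields frames with modality UNKNOWN, indices 0..N−1, pixel data
    unmodified.  Raises ``FileNotFoundError`` for a missing path and
    ``ValueError`` for an unreadable or empty source.
    """
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    path = Path(video_path)
    if not path.exists():
        raise FileNotFoundError(f"video source not found: {path}")

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}
        )
        if not files:
            raise ValueError(f"no image frames found in directory: {path}")
        images: Iterable[np.ndarray] = (iio.imread(f) for f in files)
    else:
        try:
            images = iio.imiter(path)
        except Exception as exc:  # imageio raises assorted plugin errors
            raise ValueError(f"cannot decode video file {path}: {exc}") from exc

    n = 0
    shape: tuple[int, ...] | None = None
    for i, img in enumerate(images):
        img = _as_rgb(img)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"frame {i} has shape {img.shape}, expected {shape}: "
                "pixel dimensions must be constant across a sequence"
            )
        yield Frame(index=i, pixels=img, time_s=i / frame_rate)
        n += 1
    if n == 0:
        raise ValueError(f"video source contains zero frames: {path}")


def read_frames(video_path: str | Path, frame_rate: float = 720.0) -> list[Frame]:
    """Read an entire stream into memory; see :func:`iter_frames`."""
    return list(iter_frames(video_path, frame_rate))


def dark_fraction(pixels: np.ndarray, dark_value_cutoff: int = DEFAULT_DARK_VALUE_CUTOFF) -> float:
    """Fraction of pixels whose value channel (max of R,G,B) is below the cutoff."""
    value = pixels.max(axis=-1)
    return float(np.mean(value < dark_value_cutoff))


def classify_modality(
    frame: Frame,
    dark_fraction_threshold: float = DEFAULT_DARK_FRACTION_THRESHOLD,
    dark_value_cutoff: int = DEFAULT_DARK_VALUE_CUTOFF,
) -> Modality:
    """Classify a frame as UV or WHITE from its brightness content.

    UV frames are dark except for small fluorescent blobs, so the fraction
    of dark pixels is near 1; white-light frames are bright throughout.
    The score is stored on ``frame.dark_fraction`` for diagnostics and the
    frame's ``modality`` field is updated in place.
    """
    if not 0.0 < dark_fraction_threshold < 1.0:
        raise ValueError("dark_fraction_threshold must lie in (0, 1)")
    score = dark_fraction(frame.pixels, dark_value_cutoff)
    frame.dark_fraction = score
    frame.modality = Modality.UV if score > dark_fraction_threshold else Modality.WHITE
    return frame.modality


def classify_all(
    frames: Iterable[Frame],
    parity: str = "auto",
    dark_fraction_threshold: float = DEFAULT_DARK_FRACTION_THRESHOLD,
    dark_value_cutoff: int = DEFAULT_DARK_VALUE_CUTOFF,
) -> Iterator[Frame]:
    """Classify every frame's modality.

    ``parity`` selects the strategy: ``auto`` infers per-frame from image
    content (robust to recordings starting on either phase and to dropped
    frames); ``uv-even`` / ``uv-odd`` force modality from index parity for
    pathological footage.  Already-classified frames are re-scored
    identically, so the operation is idempotent.
    """
    if parity not in {"auto", "uv-even", "uv-odd"}:
        raise ValueError(f"parity must be auto, uv-even or uv-odd, got {parity!r}")
    for frame in frames:
        if parity == "auto":
            classify_modality(frame, dark_fraction_threshold, dark_value_cutoff)
        else:
            uv_on_even = parity == "uv-even"
            is_even = frame.index % 2 == 0
            frame.modality = Modality.UV if (is_even == uv_on_even) else Modality.WHITE
        yield frame


@dataclass
class PairingReport:
    """Bookkeeping from :func:`pair_frames`."""

    n_frames: int = 0
    n_pairs: int = 0
    n_skipped: int = 0
    desynchronized: bool = False


def pair_frames(
    frames: Iterable[Frame],
    frame_rate: float = 720.0,
    report: PairingReport | None = None,
) -> Iterator[FramePair]:
    """Pair each UV frame with the immediately following white frame.

    Emits one pair per (UV at i, WHITE at i+1) adjacency, streaming with
    one lookahead frame in memory.  A UV frame labels only the *following*
    white frame, never the preceding one.  Frames in no such adjacency are
    skipped and counted in ``report``; if more than 5% of frames are
    skipped a strobe-desynchronization warning is logged.  Raises
    ``ValueError`` if the stream yields no pairs at all.
    """
    if report is None:
        report = PairingReport()
    dt = 1.0 / frame_rate

    prev: Frame | None = None
    prev_used = False
    n_pairs = 0
    n_frames = 0
    for frame in frames:
        n_frames += 1
        if frame.modality is Modality.UNKNOWN:
            raise ValueError(f"frame {frame.index} is unclassified; run classify_all first")
        if (
            prev is not None
            and prev.modality is Modality.UV
            and frame.modality is Modality.WHITE
            and frame.index == prev.index + 1
        ):
            n_pairs += 1
            report.n_pairs = n_pairs
            yield FramePair(uv=prev, white=frame, dt_s=dt)
            prev_used = True
            prev = frame  # a white frame can never open a new pair, but keeps the scan honest
            continue
        if prev is not None and not prev_used:
            report.n_skipped += 1
        prev = frame
        prev_used = False

    if prev is not None and not prev_used:
        report.n_skipped += 1
    report.n_frames = n_frames
    report.n_pairs = n_pairs

    if n_pairs == 0:
        raise ValueError("no alternating structure detected: zero UV→white frame pairs")
    if n_frames and report.n_skipped / n_frames > 0.05:
        report.desynchronized = True
        logger.warning(
            "%d of %d frames (%.1f%%) could not be paired; "
            "the strobe may be desynchronized",
            report.n_skipped, n_frames, 100.0 * report.n_skipped / n_frames,
        )
    return
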