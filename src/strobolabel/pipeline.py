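"""End-to-end annotation pipeline: demux → detect → transfer → export.

Realizes the automatic annotation workflow: markers detected on each UV
frame are mapped through the color→paw table and their coordinates are
transferred unchanged to the immediately following white-light frame
(~1.4 ms later, so displacement is negligible).  Optionally a diverse
subset of annotated frames is selected by k-means on downscaled images
and split into train/test sets, then everything is written in the
DeepLabCut CollectedData layout (extracted PNG frames plus a CSV with
scorer / bodyparts / coords header rows).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.color import rgb2gray
from skimage.transform import resize
from sklearn.cluster import KMeans

from .detection import (
    DEFAULT_MIN_AREA,
    DetectionStatus,
    HSBBounds,
    MarkerDetection,
    ViewMaskSet,
    detect_all,
)
from .frames import (
    DEFAULT_DARK_FRACTION_THRESHOLD,
    DEFAULT_DARK_VALUE_CUTOFF,
    Frame,
    FramePair,
    PairingReport,
    classify_all,
    iter_frames,
    pair_frames,
)

logger = logging.getLogger(__name__)

PAW_NAMES = ("left_front", "right_front", "left_hind", "right_hind")
VIEWS = ("bottom", "side")
BODYPARTS = tuple(f"{paw}_{view}" for paw in PAW_NAMES for view in VIEWS)

#: records with fewer FOUND keypoints than this are excluded from export
DEFAULT_MIN_KEYPOINTS = 4
DEFAULT_SCORER = "strobolabel"


@dataclass(frozen=True)
class ColorBodypartMap:
    """Bijective map from marker color to paw name."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        paws = list(self.entries.values())
        if sorted(paws) != sorted(PAW_NAMES):
            raise ValueError(
                f"color→paw map must cover {PAW_NAMES} exactly once each, got {paws}")

    def bodypart(self, color_name: str, view_name: str) -> str:
        if color_name not in self.entries:
            raise KeyError(f"color {color_name!r} has no paw mapping")
        return f"{self.entries[color_name]}_{view_name}"


@dataclass
class AnnotationRecord:
    """Keypoints of one white-light frame.

    ``keypoints`` maps every one of the 8 body-part names to a subpixel
    (x, y) or to None (ABSENT).  ``image_id`` is the white frame's stream
    index; ``ambiguous`` lists body parts whose detection was ambiguous.
    """

    image_id: int
    keypoints: dict[str, tuple[float, float] | None]
    ambiguous: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.keypoints) != set(BODYPARTS):
            raise ValueError("record must carry exactly the 8 canonical body-part slots")

    @property
    def n_present(self) -> int:
        return sum(v is not None for v in self.keypoints.values())


@dataclass
class Dataset:
    """Annotated records plus scorer and train/test assignment."""

    records: list[AnnotationRecord]
    scorer: str = DEFAULT_SCORER
    video_name: str = "video"
    split: dict[int, str] = field(default_factory=dict)  # image_id → "train"|"test"

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate image ids in dataset")


def transfer_labels(
    pair: FramePair,
    detections: Sequence[MarkerDetection],
    color_map: ColorBodypartMap,
) -> AnnotationRecord:
    """Transfer marker centroids from the UV frame to its white frame.

    The transfer is strict identity in coordinates: each FOUND or
    AMBIGUOUS detection's centroid becomes the keypoint
    ``{paw}_{view}`` at the same (x, y) on the white frame; MISSING
    detections leave their slot ABSENT.  Ambiguous body parts are
    recorded on the result for reporting.
    """
    keypoints: dict[str, tuple[float, float] | None] = {bp: None for bp in BODYPARTS}
    ambiguous: list[str] = []
    for det in detections:
        bp = color_map.bodypart(det.color_name, det.view_name)
        if det.status is DetectionStatus.MISSING:
            continue
        keypoints[bp] = det.centroid
        if det.status is DetectionStatus.AMBIGUOUS:
            ambiguous.append(bp)
    return AnnotationRecord(pair.white.index, keypoints, tuple(ambiguous))


def _frame_features(images: Sequence[np.ndarray], size: tuple[int, int]) -> np.ndarray:
    feats = np.empty((len(images), size[0] * size[1]))
    for i, img in enumerate(images):
        gray = rgb2gray(img)
        feats[i] = resize(gray, size, anti_aliasing=True).ravel()
    return feats


def select_frames(
    records: Sequence[AnnotationRecord],
    images: Sequence[np.ndarray],
    k: int,
    seed: int = 0,
    size: tuple[int, int] = (30, 30),
) -> list[AnnotationRecord]:
    """Select ``k`` visually diverse records by k-means on downscaled frames.

    Each white frame is converted to grayscale, downscaled (30×30 by
    default) and flattened; the feature vectors are clustered into ``k``
    groups and one record is sampled per cluster with a seeded RNG —
    at most one pick per cluster is what enforces pose diversity.  If a
    cluster ends up empty the pick is resampled from the remaining pool.
    Reproducible given the seed.
    """
    if len(records) != len(images):
        raise ValueError("records and images must correspond one-to-one")
    if k > len(records):
        raise ValueError(f"cannot select k={k} from {len(records)} records")
    if k == len(records):
        return list(records)
    feats = _frame_features(images, size)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(feats)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cluster in range(k):
        members = np.flatnonzero(labels == cluster)
        if members.size:
            chosen.append(int(rng.choice(members)))
    if len(chosen) < k:  # empty clusters: resample from the remaining pool
        pool = np.setdiff1d(np.arange(len(records)), chosen)
        extra = rng.choice(pool, size=k - len(chosen), replace=False)
        chosen.extend(int(i) for i in extra)
    chosen.sort()
    return [records[i] for i in chosen]


def split_dataset(
    records: Sequence[AnnotationRecord],
    n_train: int,
    n_test: int,
    seed: int = 0,
    scorer: str = DEFAULT_SCORER,
    video_name: str = "video",
) -> Dataset:
    """Uniform random disjoint train/test split (seeded)."""
    if n_train + n_test > len(records):
        raise ValueError(
            f"cannot split {len(records)} records into {n_train} train + {n_test} test")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    split: dict[int, str] = {}
    kept: list[AnnotationRecord] = []
    for pos, idx in enumerate(order[: n_train + n_test]):
        rec = records[idx]
        split[rec.image_id] = "train" if pos < n_train else "test"
        kept.append(rec)
    kept.sort(key=lambda r: r.image_id)
    return Dataset(records=kept, scorer=scorer, video_name=video_name, split=split)


def _image_rel_path(video_name: str, image_id: int) -> str:
    return f"labeled-data/{video_name}/img{image_id:04d}.png"


def export_dlc(
    dataset: Dataset,
    out_dir: str | Path,
    images: Mapping[int, np.ndarray],
) -> Path:
    """Write a DeepLabCut-style labeled dataset.

    White frames go to ``labeled-data/<video>/img{index:04d}.png``; the
    annotations to ``CollectedData_<scorer>.csv`` in the same directory,
    with the three header rows (scorer, bodyparts with each name twice,
    coords alternating x/y), one data row per image keyed by its relative
    path, ABSENT keypoints as empty cells, and coordinates at full float
    precision (``repr`` round-trips exactly).
    """
    out = Path(out_dir)
    img_dir = out / "labeled-data" / dataset.video_name
    img_dir.mkdir(parents=True, exist_ok=True)

    seen: set[int] = set()
    for rec in dataset.records:
        if rec.image_id in seen:
            raise ValueError(f"duplicate image id {rec.image_id}")
        seen.add(rec.image_id)
        if rec.image_id not in images:
            raise ValueError(f"no image supplied for record {rec.image_id}")
        iio.imwrite(img_dir / f"img{rec.image_id:04d}.png", images[rec.image_id])

    csv_path = img_dir / f"CollectedData_{dataset.scorer}.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [dataset.scorer] * (2 * len(BODYPARTS)))
        w.writerow(["bodyparts"] + [bp for bp in BODYPARTS for _ in ("x", "y")])
        w.writerow(["coords"] + ["x", "y"] * len(BODYPARTS))
        for rec in dataset.records:
            row: list[str] = [_image_rel_path(dataset.video_name, rec.image_id)]
            for bp in BODYPARTS:
                kp = rec.keypoints[bp]
                if kp is None:
                    row.extend(["", ""])
                else:
                    row.extend([repr(float(kp[0])), repr(float(kp[1]))])
            w.writerow(row)
    return csv_path


def read_dlc_csv(path: str | Path) -> tuple[list[AnnotationRecord], str]:
    """Parse a CollectedData CSV back into records (lossless round-trip).

    Returns the records (image ids recovered from the ``imgNNNN.png``
    file names) and the scorer name.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3 or rows[0][0] != "scorer" or rows[2][0] != "coords":
        raise ValueError(f"{path} is not a CollectedData CSV")
    scorer = rows[0][1]
    bodyparts = rows[1][1::2]
    records = []
    for row in rows[3:]:
        if not row:
            continue
        stem = Path(row[0]).stem  # imgNNNN
        image_id = int(stem.replace("img", ""))
        keypoints: dict[str, tuple[float, float] | None] = {bp: None for bp in BODYPARTS}
        for j, bp in enumerate(bodyparts):
            xs, ys = row[1 + 2 * j], row[2 + 2 * j]
            if xs != "" and ys != "":
                keypoints[bp] = (float(xs), float(ys))
        records.append(AnnotationRecord(image_id, keypoints))
    return records, scorer


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    colors: list[HSBBounds]
    color_map: ColorBodypartMap
    mask_paths: dict[str, Path]
    frame_rate: float = 720.0
    parity: str = "auto"
    dark_value_cutoff: int = DEFAULT_DARK_VALUE_CUTOFF
    dark_fraction_threshold: float = DEFAULT_DARK_FRACTION_THRESHOLD
    min_area: int = DEFAULT_MIN_AREA
    min_keypoints: int = DEFAULT_MIN_KEYPOINTS
    scorer: str = DEFAULT_SCORER

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if "colors" not in raw or not raw["colors"]:
            raise ValueError(f"config {path}: no color entries")
        colors, mapping = [], {}
        for name, entry in raw["colors"].items():
            for key in ("lower", "upper", "bodypart"):
                if key not in entry:
                    raise ValueError(f"config {path}: color {name!r} missing {key!r}")
            colors.append(HSBBounds(name, tuple(entry["lower"]), tuple(entry["upper"])))
            mapping[name] = entry["bodypart"]
        masks = {
            name: (path.parent / p if not Path(p).is_absolute() else Path(p))
            for name, p in raw.get("masks", {}).items()
        }
        if set(masks) != set(VIEWS):
            raise ValueError(f"config {path}: masks must name views {VIEWS}")
        return cls(
            colors=colors,
            color_map=ColorBodypartMap(mapping),
            mask_paths=masks,
            frame_rate=float(raw.get("frame_rate", 720.0)),
            parity=raw.get("parity", "auto"),
            dark_value_cutoff=int(raw.get("dark_value_cutoff", DEFAULT_DARK_VALUE_CUTOFF)),
            dark_fraction_threshold=float(
                raw.get("dark_fraction_threshold", DEFAULT_DARK_FRACTION_THRESHOLD)),
            min_area=int(raw.get("min_area", DEFAULT_MIN_AREA)),
            min_keypoints=int(raw.get("min_keypoints", DEFAULT_MIN_KEYPOINTS)),
            scorer=raw.get("scorer", DEFAULT_SCORER),
        )


@dataclass
class PipelineReport:
    """Machine-readable per-stage counters."""

    n_frames: int = 0
    n_pairs: int = 0
    n_skipped_frames: int = 0
    n_found: int = 0
    n_missing: int = 0
    n_ambiguous: int = 0
    n_records: int = 0
    n_excluded_sparse: int = 0
    n_exported: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def run_pipeline(
    video: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
    k: int | None = None,
    n_train: int | None = None,
    n_test: int | None = None,
    seed: int = 0,
    video_name: str | None = None,
) -> tuple[Dataset, PipelineReport]:
    """Run the full annotation pipeline and export a DLC dataset.

    Stages: demux (classify + pair) → per-pair marker detection → label
    transfer → sparse-record exclusion (fewer than ``min_keypoints``
    present) → optional k-means frame selection → optional train/test
    split → DLC export.  Writes ``report.json`` beside the dataset and
    raises ``ValueError`` if zero records survive to export.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    views = ViewMaskSet.from_files(config.mask_paths)
    report = PipelineReport()
    pairing = PairingReport()

    records: list[AnnotationRecord] = []
    white_images: dict[int, np.ndarray] = {}
    frames = classify_all(
        iter_frames(video, config.frame_rate),
        parity=config.parity,
        dark_fraction_threshold=config.dark_fraction_threshold,
        dark_value_cutoff=config.dark_value_cutoff,
    )
    for pair in pair_frames(frames, config.frame_rate, report=pairing):
        detections = detect_all(pair.uv, config.colors, views, config.min_area)
        for det in detections:
            if det.status is DetectionStatus.FOUND:
                report.n_found += 1
            elif det.status is DetectionStatus.MISSING:
                report.n_missing += 1
            else:
                report.n_ambiguous += 1
        record = transfer_labels(pair, detections, config.color_map)
        if record.n_present < config.min_keypoints:
            report.n_excluded_sparse += 1
            continue
        records.append(record)
        white_images[record.image_id] = pair.white.pixels

    report.n_frames = pairing.n_frames
    report.n_pairs = pairing.n_pairs
    report.n_skipped_frames = pairing.n_skipped
    report.n_records = len(records)
    logger.info("demux: %d frames → %d pairs (%d skipped)",
                report.n_frames, report.n_pairs, report.n_skipped_frames)

    if not records:
        (out / "report.json").write_text(report.to_json())
        raise ValueError("pipeline produced zero exportable records")

    if k is not None:
        records = select_frames(
            records, [white_images[r.image_id] for r in records], k, seed=seed)

    name = video_name or Path(video).stem or "video"
    if n_train is not None or n_test is not None:
        dataset = split_dataset(
            records, n_train or 0, n_test or 0, seed=seed,
            scorer=config.scorer, video_name=name)
    else:
        dataset = Dataset(records=list(records), scorer=config.scorer, video_name=name)

    export_dlc(dataset, out, white_images)
    report.n_exported = len(dataset.records)
    (out / "report.json").write_text(report.to_json())
    logger.info("exported %d records (%d FOUND / %d MISSING / %d AMBIGUOUS detections)",
                report.n_exported, report.n_found, report.n_missing, report.n_ambiguous)
    return dataset, report
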