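"""Keypoint annotation files and dataset pairing.

The canonical annotation format is a UTF-8 CSV with header

    image_id,ax,ay,bx,by,cx,cy,dx,dy,ex,ey,fx,fy,status[,vhs,class]

one row per image, coordinates in pixels of the stored image, floats
written with six decimals.  ``status`` distinguishes ``ground_truth``
labels, model-emitted ``coarse`` points awaiting human refinement, and
human-``verified`` points.  A JSON mirror is provided as a convenience.

Model inputs: images are resized (anisotropically, preserving the full
field of view) to a square ``input_size`` and replicated to three
channels; keypoints are rescaled identically and normalized to [0, 1] by
the source image width/height.
"""

from __future__ import annotations

import json
import logging
import pathlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError
from .geometry import KeyPointSet, classify_vhs, flatten, unflatten, vhs_score

logger = logging.getLogger("vhsnet.annotations")

COORD_COLUMNS = ["ax", "ay", "bx", "by", "cx", "cy", "dx", "dy", "ex", "ey", "fx", "fy"]
REQUIRED_COLUMNS = ["image_id"] + COORD_COLUMNS + ["status"]
VALID_STATUS = ("ground_truth", "coarse", "verified")

#: Tolerance for a stored VHS value against the score recomputed from the
#: stored keypoints before a validation warning is raised.
VHS_CONSISTENCY_TOL = 1e-4


@dataclass
class AnnotationRecord:
    """One labeled image: id, the six keypoints, and optional derived values."""

    image_id: str
    keypoints: KeyPointSet
    status: str = "ground_truth"
    vhs: float | None = None
    cls: int | None = None

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUS:
            raise FormatError(f"record {self.image_id!r}: unknown status {self.status!r}")


@dataclass
class DatasetSplit:
    """A named collection of records paired with an image directory."""

    name: str
    records: list = field(default_factory=list)
    image_dir: pathlib.Path | None = None

    def __len__(self) -> int:
        return len(self.records)

    def image_path(self, record: AnnotationRecord) -> pathlib.Path:
        return pathlib.Path(self.image_dir) / f"{record.image_id}.png"

    def validate(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"split {self.name!r} has duplicate image ids: {dup[:5]}")
        if self.image_dir is not None:
            missing = [r.image_id for r in self.records if not self.image_path(r).exists()]
            if missing:
                raise FormatError(f"split {self.name!r}: missing image files for {missing[:5]}")


def write_annotations(records: Iterable[AnnotationRecord], path) -> None:
    """Write records as the canonical CSV (6-decimal coordinates)."""
    rows = []
    for r in records:
        row = {"image_id": r.image_id}
        row.update({c: v for c, v in zip(COORD_COLUMNS, flatten(r.keypoints))})
        row["status"] = r.status
        row["vhs"] = r.vhs
        row["class"] = r.cls
        rows.append(row)
    df = pd.DataFrame(rows, columns=["image_id"] + COORD_COLUMNS + ["status", "vhs", "class"])
    df.to_csv(path, index=False, float_format="%.6f")


def write_annotations_json(records: Iterable[AnnotationRecord], path) -> None:
    """JSON convenience mirror of :func:`write_annotations`."""
    payload = [{"image_id": r.image_id,
                "keypoints": {c: float(v) for c, v in zip(COORD_COLUMNS, flatten(r.keypoints))},
                "status": r.status, "vhs": r.vhs, "class": r.cls}
               for r in records]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_annotations(path) -> list[AnnotationRecord]:
    """Read the canonical CSV; rejects malformed rows loudly.

    Raises :class:`FormatError` for missing columns, duplicate ids, or
    non-finite coordinates (naming the offending row), and issues a
    validation warning listing ids whose stored VHS disagrees with the
    score recomputed from their keypoints by more than ``1e-4``.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: not a parsable annotation CSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    dup = df["image_id"][df["image_id"].duplicated()].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate image ids {sorted(set(dup))[:5]}")

    records: list[AnnotationRecord] = []
    inconsistent: list[str] = []
    for i, row in df.iterrows():
        coords = row[COORD_COLUMNS].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise FormatError(f"{path}: row {i} (id {row['image_id']!r}) has non-finite coordinates")
        kps = unflatten(coords)
        vhs = None if "vhs" not in df.columns or pd.isna(row.get("vhs")) else float(row["vhs"])
        cls = None if "class" not in df.columns or pd.isna(row.get("class")) else int(row["class"])
        if vhs is not None and abs(vhs - vhs_score(kps)) > VHS_CONSISTENCY_TOL:
            inconsistent.append(str(row["image_id"]))
        records.append(AnnotationRecord(image_id=str(row["image_id"]), keypoints=kps,
                                        status=str(row["status"]), vhs=vhs, cls=cls))
    if inconsistent:
        warnings.warn(
            f"{path}: stored VHS inconsistent with keypoints (>{VHS_CONSISTENCY_TOL}) "
            f"for ids {inconsistent}", stacklevel=2)
    return records


def load_dataset_dir(path, name: str = "training") -> DatasetSplit:
    """Pair ``annotations.csv`` in a directory with its PNG images."""
    path = pathlib.Path(path)
    split = DatasetSplit(name=name, records=read_annotations(path / "annotations.csv"),
                         image_dir=path)
    split.validate()
    return split


def assert_disjoint(*splits: DatasetSplit) -> None:
    """Training/validation/test id sets must be pairwise disjoint."""
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            overlap = {r.image_id for r in splits[i].records} & {r.image_id for r in splits[j].records}
            if overlap:
                raise FormatError(
                    f"splits {splits[i].name!r} and {splits[j].name!r} share ids {sorted(overlap)[:5]}")


def load_split_manifest(path) -> dict[str, DatasetSplit]:
    """Load a YAML manifest mapping split names to dataset directories."""
    import yaml

    path = pathlib.Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    splits = {}
    for name, entry in spec["splits"].items():
        d = pathlib.Path(entry["path"])
        if not d.is_absolute():
            d = path.parent / d
        splits[name] = load_dataset_dir(d, name=name)
    assert_disjoint(*splits.values())
    return splits


# -- coordinate normalization ---------------------------------------------

def normalize_keypoints(kps: KeyPointSet, width: float, height: float) -> np.ndarray:
    """Pixel keypoints -> 12-vector in [0, 1] (x/width, y/height)."""
    vec = flatten(kps)
    vec[0::2] /= width
    vec[1::2] /= height
    return vec


def denormalize_keypoints(vec, width: float, height: float) -> KeyPointSet:
    """Inverse of :func:`normalize_keypoints`."""
    v = np.asarray(vec, dtype=float).copy()
    v[0::2] *= width
    v[1::2] *= height
    return unflatten(v)


def _record_class(record: AnnotationRecord) -> int:
    if record.cls is not None:
        return int(record.cls)
    vhs = record.vhs if record.vhs is not None else vhs_score(record.keypoints)
    return classify_vhs(vhs)


def load_image_rgb(path, input_size: int) -> np.ndarray:
    """Open, convert to RGB and resize to ``input_size`` square; [0,1] floats."""
    with Image.open(path) as im:
        im = im.convert("RGB").resize((input_size, input_size), Image.BILINEAR)
        return np.asarray(im, dtype=np.float32) / 255.0


def iter_model_inputs(split: DatasetSplit, input_size: int) -> Iterator[tuple]:
    """Stream ``(image array (S,S,3), normalized 12-vector, class)`` triples.

    Unreadable images are skipped with a logged warning; the skip count is
    logged at the end of the stream.
    """
    skipped = 0
    for record in split.records:
        path = split.image_path(record)
        try:
            with Image.open(path) as im:
                width, height = im.size
                arr = np.asarray(im.convert("RGB").resize((input_size, input_size),
                                                          Image.BILINEAR),
                                 dtype=np.float32) / 255.0
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable image %s: %s", path, exc)
            skipped += 1
            continue
        yield arr, normalize_keypoints(record.keypoints, width, height), _record_class(record)
    if skipped:
        logger.warning("split %r: skipped %d unreadable image(s)", split.name, skipped)


def load_model_inputs(split: DatasetSplit, input_size: int):
    """Materialize :func:`iter_model_inputs` into stacked arrays.

    Returns ``(images (N,S,S,3) float32, targets (N,12) float64, classes
    (N,) int64)``; empty splits yield empty arrays.
    """
    images, targets, classes = [], [], []
    for arr, vec, cls in iter_model_inputs(split, input_size):
        images.append(arr)
        targets.append(vec)
        classes.append(cls)
    if not images:
        return (np.zeros((0, input_size, input_size, 3), dtype=np.float32),
                np.zeros((0, 12)), np.zeros((0,), dtype=np.int64))
    return np.stack(images), np.stack(targets), np.asarray(classes, dtype=np.int64)
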