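"""Seeded generator of radiograph-like images with exact VHS ground truth.

Real lateral canine radiographs with keypoint labels are not publicly
accessible, so this module renders the minimal scene that makes the six
VHS landmarks well defined and the score controllable:

* a bright vertebral column of equal-length rounded segments laid along a
  gently curved arc, with ``E`` at the cranial edge of the fourth segment
  and ``F`` at the caudal edge of the ninth (six vertebral lengths);
* an elliptical cardiac silhouette whose major-axis endpoints are ``A``
  (carina end, near the spine) and ``B`` (apex), with the minor axis
  ``C``–``D`` meeting the major axis perpendicularly at its midpoint — so
  perpendicularity holds exactly in the ground truth;
* a smooth illumination gradient, additive Gaussian noise, and a global
  rotation + translation of the whole scene (keypoints transformed
  identically, analytically — no image resampling is involved, so the
  stored keypoints are exact).

Axis lengths are solved so that ``6 * (|AB| + |CD|) / |EF|`` equals the
requested VHS exactly, given an aspect ratio ``|CD|/|AB|`` drawn from
[0.6, 0.85].  No attempt is made at photorealism (breed variation,
effusion, exposure artifacts are out of scope); the learnability of the
task, not its visual realism, is what the generator guarantees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image
from scipy.special import expit

from . import annotations as ann
from .errors import ConfigError
from .geometry import (KeyPointSet, Point, VhsThresholds, classify_vhs,
                       vhs_score)

#: Number of vertebral segments drawn (>= 9 so F is well defined).
N_SEGMENTS = 11

#: Training-set class proportions of the emulated three-class distribution
#: (small, normal, large) — 208 : 573 : 619 out of 1400.
DEFAULT_PROPORTIONS = (208 / 1400, 573 / 1400, 619 / 1400)

DEFAULT_VHS_RANGES = ((6.5, 8.2), (8.2, 10.0), (10.0, 13.0))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic radiograph generator.

    ``image_size`` defaults to 512 px, mirroring the full-scale model input;
    :meth:`desk` gives the 96 px configuration used for CPU-scale tests.
    ``noise_sd`` is the standard deviation of additive Gaussian intensity
    noise on the [0, 1] scale; ``max_rotation`` bounds the global scene
    rotation in degrees.
    """

    image_size: int = 512
    class_proportions: tuple = DEFAULT_PROPORTIONS
    vhs_ranges: tuple = DEFAULT_VHS_RANGES
    noise_sd: float = 0.04
    max_rotation: float = 8.0
    seed: int = 0
    thresholds: VhsThresholds = field(default_factory=VhsThresholds)

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any():
            raise ConfigError(f"class_proportions must be 3 non-negative numbers, got {self.class_proportions}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(f"class_proportions must sum to 1, got sum {p.sum()!r}")
        if len(self.vhs_ranges) != 3:
            raise ConfigError("vhs_ranges must give one (lo, hi) interval per class")
        for cls, (lo, hi) in enumerate(self.vhs_ranges):
            if not lo < hi:
                raise ConfigError(f"vhs_ranges[{cls}] is empty: ({lo}, {hi})")
            eps = 1e-9 * (hi - lo)
            # interior endpoints must both fall in the class (boundaries may
            # be open, so probe just inside)
            if (classify_vhs(lo + eps, self.thresholds) != cls
                    or classify_vhs(hi - eps, self.thresholds) != cls):
                raise ConfigError(
                    f"vhs_ranges[{cls}]=({lo}, {hi}) is inconsistent with thresholds "
                    f"low={self.thresholds.low}, high={self.thresholds.high}")
        if self.image_size < 32:
            raise ConfigError(f"image_size {self.image_size} is too small to render the scene")

    @classmethod
    def desk(cls, **overrides) -> "GeneratorConfig":
        """Small, fast configuration (96 px) for CPU-scale experiments."""
        overrides.setdefault("image_size", 96)
        return cls(**overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = {"low": self.thresholds.low, "high": self.thresholds.high}
        return d


@dataclass
class SyntheticSample:
    """One generated radiograph with exact ground truth."""

    image: np.ndarray            # (H, W) float32 intensities in [0, 1]
    keypoints: KeyPointSet       # pixel coordinates in the generated image
    true_vhs: float
    true_class: int
    meta: dict


# -- scene construction ----------------------------------------------------

def _rot(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _sample_target_vhs(cfg: GeneratorConfig, rng: np.random.Generator, cls: int) -> float:
    lo, hi = cfg.vhs_ranges[cls]
    while True:
        v = rng.uniform(lo, hi)
        if classify_vhs(v, cfg.thresholds) == cls:
            return v


def generate_sample(cfg: GeneratorConfig, rng: np.random.Generator,
                    target_class: int | None = None,
                    target_vhs: float | None = None) -> SyntheticSample:
    """Render one synthetic radiograph.

    Exactly reproducible: the same ``cfg`` and generator state yield a
    bit-identical image and keypoints.  If ``target_vhs`` is given it is
    honored exactly (``vhs_score`` of the stored keypoints equals it up to
    float rounding); if only ``target_class`` is given a VHS is drawn
    uniformly from that class's range; with neither, the class is drawn
    from ``cfg.class_proportions``.
    """
    if target_vhs is not None:
        vhs_cls = classify_vhs(target_vhs, cfg.thresholds)
        if target_class is not None and target_class != vhs_cls:
            raise ConfigError(
                f"target_vhs={target_vhs} falls in class {vhs_cls}, not requested class {target_class}")
        lo, hi = cfg.vhs_ranges[vhs_cls]
        if not (lo <= target_vhs <= hi):
            raise ConfigError(
                f"target_vhs={target_vhs} outside configured range ({lo}, {hi}) for class {vhs_cls}")
        cls = vhs_cls
    else:
        if target_class is None:
            cls = int(rng.choice(3, p=np.asarray(cfg.class_proportions, dtype=float)))
        else:
            if target_class not in (0, 1, 2):
                raise ConfigError(f"target_class must be 0, 1 or 2, got {target_class}")
            cls = target_class
        target_vhs = _sample_target_vhs(cfg, rng, cls)

    S = float(cfg.image_size)
    center = np.array([0.5 * S, 0.5 * S])

    # Vertebral column: equal arc-length segments on a large circle.
    seg_len = 0.058 * S
    radius = S * rng.uniform(2.5, 4.0)
    bend = rng.choice([-1.0, 1.0])
    phi = seg_len / radius
    y_spine = 0.20 * S
    arc_center = np.array([0.5 * S, y_spine + bend * radius])
    alphas = (np.arange(N_SEGMENTS + 1) - N_SEGMENTS / 2.0) * phi
    boundaries = np.stack([arc_center[0] + radius * np.sin(alphas),
                           arc_center[1] - bend * radius * np.cos(alphas)], axis=1)

    E = boundaries[3]          # cranial edge of segment 4
    F = boundaries[9]          # caudal edge of segment 9
    ef = float(np.linalg.norm(F - E))

    # Heart ellipse solved for the requested VHS.
    aspect = rng.uniform(0.60, 0.85)
    lab = target_vhs * ef / (6.0 * (1.0 + aspect))
    lcd = aspect * lab

    # Long axis from the carina region (below the spine near segment 6)
    # pointing caudo-ventrally.
    attach = boundaries[5]
    tangent = boundaries[6] - boundaries[4]
    tangent = tangent / np.linalg.norm(tangent)
    down = np.array([-tangent[1], tangent[0]])
    if down[1] < 0:
        down = -down
    tilt = math.radians(rng.uniform(12.0, 32.0))
    u = _rot(down, tilt)                       # unit long-axis direction
    A = attach + down * (0.055 * S)
    B = A + u * lab
    M = 0.5 * (A + B)
    uperp = np.array([-u[1], u[0]])
    C = M - uperp * (0.5 * lcd)
    D = M + uperp * (0.5 * lcd)

    # Global similarity: rotation about the image center + translation.
    theta = math.radians(rng.uniform(-cfg.max_rotation, cfg.max_rotation))
    jitter = rng.uniform(-0.04 * S, 0.04 * S, size=2)

    def xform(p: np.ndarray) -> np.ndarray:
        return center + _rot(p - center, theta) + jitter

    boundaries = np.array([xform(b) for b in boundaries])
    A, B, C, D, E, F = (xform(p) for p in (A, B, C, D, E, F))
    M, u, uperp = xform(M), _rot(u, theta), _rot(uperp, theta)

    # Keep every keypoint inside the frame: recenter if the jittered scene
    # pushed any landmark into the margin.
    pts = np.array([A, B, C, D, E, F])
    margin = 3.0
    lo_shift = margin - pts.min(axis=0)
    hi_shift = (S - 1 - margin) - pts.max(axis=0)
    shift = np.clip(lo_shift, 0.0, None) + np.clip(hi_shift, None, 0.0)
    if np.any(shift != 0.0):
        boundaries = boundaries + shift
        A, B, C, D, E, F = (p + shift for p in (A, B, C, D, E, F))
        M = M + shift

    # -- rendering --------------------------------------------------------
    n = cfg.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    img = np.full((n, n), 0.12)
    gx, gy = rng.uniform(-0.08, 0.08, size=2)
    img += gx * (xx / S - 0.5) + gy * (yy / S - 0.5)

    # heart: soft-edged ellipse composited over the background field
    px = xx - M[0]
    py = yy - M[1]
    a_half, b_half = 0.5 * lab, 0.5 * lcd
    q = ((px * u[0] + py * u[1]) / a_half) ** 2 + ((px * uperp[0] + py * uperp[1]) / b_half) ** 2
    r = np.sqrt(q)
    alpha = expit((1.0 - r) * b_half / 1.2)
    img = img * (1.0 - alpha) + 0.62 * alpha

    # spine: one soft capsule per vertebral segment
    half_w = 0.30 * seg_len
    gap = 0.10 * seg_len
    for i in range(N_SEGMENTS):
        p0, p1 = boundaries[i], boundaries[i + 1]
        d01 = p1 - p0
        L = np.linalg.norm(d01)
        d01 = d01 / L
        p0s = p0 + d01 * gap
        seg = L - 2 * gap
        t = np.clip((xx - p0s[0]) * d01[0] + (yy - p0s[1]) * d01[1], 0.0, seg)
        cxp = p0s[0] + t * d01[0]
        cyp = p0s[1] + t * d01[1]
        dist = np.hypot(xx - cxp, yy - cyp)
        salpha = expit((half_w - dist) / 0.7)
        img = img * (1.0 - salpha) + 0.88 * salpha

    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    kps = KeyPointSet(*(Point(float(p[0]), float(p[1])) for p in (A, B, C, D, E, F)))
    true_vhs = vhs_score(kps)
    meta = {"seed": cfg.seed, "noise_sd": cfg.noise_sd, "rotation_deg": math.degrees(theta),
            "aspect": aspect, "target_vhs": float(target_vhs)}
    return SyntheticSample(image=img, keypoints=kps, true_vhs=float(true_vhs),
                           true_class=int(classify_vhs(true_vhs, cfg.thresholds)), meta=meta)


def image_to_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)


def generate_dataset(cfg: GeneratorConfig, n: int, out_dir) -> dict:
    """Write ``n`` samples as 8-bit PNGs plus an annotation CSV and manifest.

    Classes are drawn independently from ``cfg.class_proportions`` (a
    multinomial realization under ``cfg.seed``).  Returns the manifest
    (also written to ``manifest.yaml``): per-class counts, seed and the
    full generator configuration.
    """
    import pathlib

    import yaml

    if n < 3:
        raise ConfigError(f"a dataset needs at least 3 samples, got n={n}")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(cfg.seed)
    records = []
    counts = [0, 0, 0]
    for i in range(n):
        sample = generate_sample(cfg, rng)
        # ids carry the seed so splits generated with different seeds are
        # disjoint by construction
        image_id = f"synth{cfg.seed}_{i:05d}"
        Image.fromarray(image_to_uint8(sample.image), mode="L").save(out / f"{image_id}.png")
        records.append(ann.AnnotationRecord(
            image_id=image_id, keypoints=sample.keypoints, status="ground_truth",
            vhs=sample.true_vhs, cls=sample.true_class))
        counts[sample.true_class] += 1
    ann.write_annotations(records, out / "annotations.csv")
    manifest = {"n": n, "seed": cfg.seed, "class_counts": counts,
                "image_size": cfg.image_size, "config": cfg.to_dict()}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
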