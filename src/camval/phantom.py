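"""Synthetic chest-slice phantoms with ground-truth feature masks.

Real postmortem-CT stacks for the drowning/non-drowning task are not publicly
available, so this module generates two-class phantom case volumes that carry
the same decision-relevant structure: a mid-gray body ellipse, two dark
elliptical lung fields, and — for the positive (drowning-like) class —
bright lung findings of three kinds:

* ``consolidation``: Gaussian-blurred bright blobs inside a lung field
  (stands in for granular / ground-glass / edema-like opacity);
* ``airway_fluid``: a filled bright disk at the tracheal position, painted
  only on slices above the carina (upper half of the stack);
* ``pleural_effusion``: a bright crescent along the dorsal lung boundary.

The three categories are merged into a single truth mask because the
downstream assessment is binary and does not distinguish finding types.
Negative (non-drowning-like) cases contain no positive-feature pixels but do
carry distractors: sharp-edged "dry airway" rings (bright rim, dark lumen)
at the tracheal position and optionally inside the lungs.  Dry airways have
well-defined edges that computer vision picks up easily, which is exactly
the failure mode the assessment is meant to expose, so they are on by
default.

Intensities live on an 8-bit [0, 255] scale: lungs dark (~40-70), features
bright (~120-200), body mid-gray.  No Hounsfield physics is modelled.

Annotator simulation (:func:`simulate_annotator`) replaces the human
annotation workflow: each simulated annotator resizes the truth mask to a
target area fraction (distance-transform thresholding), jitters the
boundary with a smooth random field, and may omit whole connected
components or leave an image empty.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, ConfigurationError, PlacementError

FEATURE_KINDS = ("consolidation", "airway_fluid", "pleural_effusion")


@dataclass(frozen=True)
class FeatureParams:
    """Intensity / multiplicity / size ranges for one feature kind.

    ``size`` is expressed as a fraction of the image side so a config scales
    with resolution; ``slice_run`` is the (min, max) number of consecutive
    slices a feature instance spans, keeping findings coherent through the
    stack the way real lung findings persist across neighbouring slices.
    """

    intensity: tuple[float, float]
    count: tuple[int, int]
    size: tuple[float, float]
    slice_run: tuple[int, int]


@dataclass(frozen=True)
class LungGeometry:
    """Two elliptical lung fields, in fractional image coordinates (x, y)."""

    centers: tuple[tuple[float, float], tuple[float, float]] = (
        (0.32, 0.52),
        (0.68, 0.52),
    )
    radii: tuple[float, float] = (0.16, 0.27)  # (rx, ry) fractions
    intensity: tuple[float, float] = (45.0, 62.0)


@dataclass(frozen=True)
class DistractorParams:
    """Dry-airway ring distractors for the negative class."""

    ring_radius: tuple[float, float] = (0.04, 0.07)  # fraction of image side
    rim_intensity: tuple[float, float] = (150.0, 210.0)
    lumen_intensity: tuple[float, float] = (10.0, 25.0)
    n_lung_rings: tuple[int, int] = (0, 2)
    enabled: bool = True


def _default_features() -> Mapping[str, FeatureParams]:
    return {
        "consolidation": FeatureParams(
            intensity=(140.0, 200.0), count=(2, 4), size=(0.045, 0.09),
            slice_run=(8, 14),
        ),
        "airway_fluid": FeatureParams(
            intensity=(140.0, 200.0), count=(1, 1), size=(0.035, 0.06),
            slice_run=(8, 14),
        ),
        "pleural_effusion": FeatureParams(
            intensity=(120.0, 180.0), count=(1, 1), size=(0.04, 0.08),
            slice_run=(8, 14),
        ),
    }


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 48
    slices_per_case: int = 30
    lung_geometry: LungGeometry = field(default_factory=LungGeometry)
    feature_params: Mapping[str, FeatureParams] = field(
        default_factory=_default_features
    )
    distractor_params: DistractorParams = field(default_factory=DistractorParams)
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0 or self.slices_per_case <= 0:
            raise ConfigurationError("image_size and slices_per_case must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for (cx, cy), name in zip(self.lung_geometry.centers, ("left", "right")):
            rx, ry = self.lung_geometry.radii
            if not (0 < cx - rx and cx + rx < 1 and 0 < cy - ry and cy + ry < 1):
                raise ConfigurationError(
                    f"{name} lung field extends outside the image bounds"
                )
        for kind in FEATURE_KINDS:
            if kind not in self.feature_params:
                raise ConfigurationError(f"missing feature_params[{kind!r}]")
            fp = self.feature_params[kind]
            lo, hi = fp.count
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"bad count range for {kind}")
            if fp.size[0] <= 0 or fp.size[1] < fp.size[0]:
                raise ConfigurationError(f"bad size range for {kind}")
            if fp.slice_run[0] < 1 or fp.slice_run[1] < fp.slice_run[0]:
                raise ConfigurationError(f"bad slice_run range for {kind}")


@dataclass
class CaseVolume:
    """Ordered slice stack with label and per-slice truth masks."""

    case_id: str
    label: int  # 1 = drowning-like (positive), 0 = non-drowning-like
    slices: np.ndarray  # (n_slices, H, W) uint8
    truth_masks: np.ndarray  # (n_slices, H, W) bool

    def __post_init__(self) -> None:
        if self.slices.ndim != 3:
            raise AlignmentError("slices must be a (n, H, W) stack")
        if self.truth_masks.shape != self.slices.shape:
            raise AlignmentError("truth_masks must align with slices pixelwise")
        self.label = int(self.label)
        if self.label not in (0, 1):
            raise ConfigurationError("label must be 0 or 1")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]


@dataclass(frozen=True)
class AnnotatorProfile:
    """Behavioural parameters of one simulated annotator.

    ``area_scale`` is the multiplicative target for the annotated area
    relative to truth (0.6 reproduces a systematic under-annotator);
    ``boundary_jitter_sd`` perturbs the mask boundary in pixels;
    ``omission_prob`` drops whole disjoint components; ``empty_prob`` leaves
    an image entirely unannotated (empty annotations are permitted).
    """

    annotator_id: str
    area_scale: float = 1.0
    boundary_jitter_sd: float = 0.0
    omission_prob: float = 0.0
    empty_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_scale <= 0:
            raise ConfigurationError("area_scale must be > 0")
        if not 0 <= self.omission_prob < 1:
            raise ConfigurationError("omission_prob must be in [0, 1)")
        if not 0 <= self.empty_prob < 1:
            raise ConfigurationError("empty_prob must be in [0, 1)")
        if self.boundary_jitter_sd < 0:
            raise ConfigurationError("boundary_jitter_sd must be >= 0")


def default_profiles(seed: int = 0) -> list[AnnotatorProfile]:
    """Four annotators: three comparable, one systematic under-annotator.

    Mirrors the interobserver pattern in which one annotator's total
    annotated area is markedly smaller than the other three's.
    """
    scales = {"A1": 0.6, "A2": 1.0, "A3": 1.0, "A4": 1.0}
    return [
        AnnotatorProfile(
            annotator_id=a, area_scale=s, boundary_jitter_sd=1.0,
            omission_prob=0.05, seed=seed + i,
        )
        for i, (a, s) in enumerate(scales.items())
    ]


# ---------------------------------------------------------------------------
# drawing helpers


def _ellipse_mask(h: int, w: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _disk_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    return _ellipse_mask(h, w, cx, cy, r, r)


@dataclass
class _Blob:
    cx: float
    cy: float
    r: float
    z0: int
    z1: int  # half-open slice range


def _sample_in_lung(rng, lung_cx, lung_cy, lung_rx, lung_ry, margin) -> tuple[float, float]:
    # rejection-sample a point whose `margin`-disk stays inside the ellipse
    rx, ry = lung_rx - margin, lung_ry - margin
    if rx <= 1 or ry <= 1:
        raise PlacementError("consolidation", "lung field too small for feature size")
    for _ in range(200):
        x = rng.uniform(lung_cx - rx, lung_cx + rx)
        y = rng.uniform(lung_cy - ry, lung_cy + ry)
        if ((x - lung_cx) / rx) ** 2 + ((y - lung_cy) / ry) ** 2 <= 1.0:
            return x, y
    raise PlacementError("consolidation", "rejection sampling exhausted")


def generate_case(config: PhantomConfig, label: int, case_seed: int) -> CaseVolume:
    """Generate one phantom case volume.

    Deterministic in ``(config, label, case_seed)``: identical inputs yield
    bit-identical volumes.  Positive cases contain at least one feature
    component; negative cases contain zero positive-feature pixels.
    """
    label = int(label)
    if label not in (0, 1):
        raise ConfigurationError("label must be 0 or 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, int(case_seed), label])
    )
    n, sz = config.slices_per_case, config.image_size
    lg = config.lung_geometry
    img = np.zeros((n, sz, sz), dtype=np.float64)
    truth = np.zeros((n, sz, sz), dtype=bool)

    body_int = rng.uniform(100.0, 120.0)
    lung_int = rng.uniform(*lg.intensity)
    body = _ellipse_mask(sz, sz, 0.5 * sz, 0.55 * sz, 0.46 * sz, 0.40 * sz)

    # per-slice lung masks; lungs taper towards the stack ends
    zz = (np.arange(n) + 0.5) / n
    lung_scale = 0.82 + 0.18 * np.sin(np.pi * zz)
    lung_masks = []  # (slice, [left, right]) geometry in pixels
    lung_px = []
    for z in range(n):
        per_slice = []
        geo = []
        for (cxf, cyf) in lg.centers:
            rx = lg.radii[0] * sz * lung_scale[z]
            ry = lg.radii[1] * sz * lung_scale[z]
            cx, cy = cxf * sz, cyf * sz
            per_slice.append(_ellipse_mask(sz, sz, cx, cy, rx, ry))
            geo.append((cx, cy, rx, ry))
        lung_masks.append(per_slice)
        lung_px.append(geo)

    for z in range(n):
        sl = np.full((sz, sz), 5.0)
        sl[body] = body_int
        for lm in lung_masks[z]:
            sl[lm] = lung_int
        img[z] = sl

    trachea_cx, trachea_cy = 0.5 * sz, 0.28 * sz
    carina = n // 2  # airway features only above the carina

    def run(fp: FeatureParams, z_lo: int = 0, z_hi: int | None = None) -> tuple[int, int]:
        z_hi = n if z_hi is None else z_hi
        length = int(rng.integers(fp.slice_run[0], fp.slice_run[1] + 1))
        length = min(length, z_hi - z_lo)
        z0 = int(rng.integers(z_lo, max(z_lo + 1, z_hi - length + 1)))
        return z0, z0 + length

    def paint(shape2d: np.ndarray, z0: int, z1: int, intensity: float,
              sigma: float, is_truth: bool) -> None:
        layer = np.where(shape2d, intensity, 0.0)
        if sigma > 0:
            layer = ndimage.gaussian_filter(layer, sigma)
        for z in range(z0, z1):
            img[z] = np.maximum(img[z], layer)
            if is_truth:
                truth[z] |= shape2d

    if label == 1:
        placed: list[_Blob] = []
        fp = config.feature_params["consolidation"]
        n_blobs = int(rng.integers(fp.count[0], fp.count[1] + 1))
        for _ in range(n_blobs):
            ok = False
            for _attempt in range(500):
                # prefer the full size range, fall back to smaller blobs when
                # the lungs are crowded
                lo, hi = fp.size
                shrink = max(0.25, 1.0 - _attempt / 250.0)
                r = rng.uniform(lo, lo + (hi - lo) * shrink) * sz
                z0, z1 = run(fp)
                side = int(rng.integers(0, 2))
                # lung geometry varies per slice; use the tightest in the run
                tight = min(range(z0, z1), key=lambda z: lung_px[z][side][2])
                cx, cy, rx, ry = lung_px[tight][side]
                try:
                    bx, by = _sample_in_lung(rng, cx, cy, rx, ry, r + 1)
                except PlacementError:
                    continue
                # keep blobs separated so truth components stay disjoint
                clash = any(
                    (b.z0 - 1 < z1 and z0 < b.z1 + 1)
                    and np.hypot(b.cx - bx, b.cy - by) < b.r + r + 1.5
                    for b in placed
                )
                if not clash:
                    placed.append(_Blob(bx, by, r, z0, z1))
                    ok = True
                    break
            if not ok:
                raise PlacementError("consolidation", "no non-overlapping position found")
            blob = placed[-1]
            shape = _disk_mask(sz, sz, blob.cx, blob.cy, blob.r)
            paint(shape, blob.z0, blob.z1, rng.uniform(*fp.intensity), 1.0, True)

        fp = config.feature_params["airway_fluid"]
        for _ in range(int(rng.integers(fp.count[0], fp.count[1] + 1))):
            r = rng.uniform(*fp.size) * sz
            z0, z1 = run(fp, 0, carina)
            shape = _disk_mask(sz, sz, trachea_cx, trachea_cy, r)
            paint(shape, z0, z1, rng.uniform(*fp.intensity), 0.5, True)

        fp = config.feature_params["pleural_effusion"]
        for _ in range(int(rng.integers(fp.count[0], fp.count[1] + 1))):
            t = max(1.5, rng.uniform(*fp.size) * sz)
            z0, z1 = run(fp)
            side = int(rng.integers(0, 2))
            z_ref = (z0 + z1) // 2
            cx, cy, rx, ry = lung_px[z_ref][side]
            lung = _ellipse_mask(sz, sz, cx, cy, rx, ry)
            shifted = _ellipse_mask(sz, sz, cx, cy - t, rx, ry)
            yy = np.arange(sz)[:, None]
            crescent = lung & ~shifted & (yy >= cy)
            if not crescent.any():
                raise PlacementError("pleural_effusion", "empty crescent")
            paint(crescent, z0, z1, rng.uniform(*fp.intensity), 0.5, True)
    else:
        dp = config.distractor_params
        if dp.enabled:
            # dry airway: bright sharp rim, dark lumen, never in the truth mask
            r = rng.uniform(*dp.ring_radius) * sz
            z0, z1 = run(config.feature_params["airway_fluid"], 0, carina)
            outer = _disk_mask(sz, sz, trachea_cx, trachea_cy, r)
            inner = _disk_mask(sz, sz, trachea_cx, trachea_cy, max(r - 1.5, 1.0))
            rim_i = rng.uniform(*dp.rim_intensity)
            lum_i = rng.uniform(*dp.lumen_intensity)
            for z in range(z0, z1):
                img[z][outer & ~inner] = rim_i
                img[z][inner] = lum_i
            for _ in range(int(rng.integers(dp.n_lung_rings[0], dp.n_lung_rings[1] + 1))):
                r2 = rng.uniform(*dp.ring_radius) * sz * 0.8
                z0, z1 = run(config.feature_params["consolidation"])
                z_ref = (z0 + z1) // 2
                side = int(rng.integers(0, 2))
                cx, cy, rx, ry = lung_px[z_ref][side]
                bx, by = _sample_in_lung(rng, cx, cy, rx, ry, r2 + 1)
                outer = _disk_mask(sz, sz, bx, by, r2)
                inner = _disk_mask(sz, sz, bx, by, max(r2 - 1.5, 1.0))
                rim_i = rng.uniform(*dp.rim_intensity)
                lum_i = rng.uniform(*dp.lumen_intensity)
                for z in range(z0, z1):
                    img[z][outer & ~inner] = rim_i
                    img[z][inner] = lum_i

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    slices = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    case_id = f"case{int(case_seed):05d}{'p' if label else 'n'}"
    return CaseVolume(case_id=case_id, label=label, slices=slices, truth_masks=truth)


# ---------------------------------------------------------------------------
# annotator simulation


def _resize_to_area(mask: np.ndarray, target: float,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Grow or shrink a binary mask to exactly ~`target` pixels.

    Pixels are ranked by Euclidean distance to the opposite phase (deepest
    pixels survive a shrink; nearest background joins a grow); ties —
    pervasive in thin structures, where every pixel touches the boundary —
    are broken randomly when an rng is given, else by pixel order.
    """
    area = int(mask.sum())
    target_n = max(0, int(round(target)))
    if area == 0 or target_n == area:
        return mask.copy()
    out = np.zeros_like(mask)
    if target_n < area:
        d = ndimage.distance_transform_edt(mask)
        idx = np.flatnonzero(mask.ravel())
        score = d.ravel()[idx]
    else:
        d = ndimage.distance_transform_edt(~mask)
        idx = np.flatnonzero(~mask.ravel())
        score = -d.ravel()[idx]
    if rng is not None:
        score = score + rng.uniform(0.0, 1e-6, size=score.shape)
    order = np.argsort(-score, kind="stable")
    if target_n < area:
        out.ravel()[idx[order[:target_n]]] = True
    else:
        out |= mask
        out.ravel()[idx[order[: target_n - area]]] = True
    return out


def simulate_annotator(truth: np.ndarray, profile: AnnotatorProfile,
                       image_key: int = 0) -> np.ndarray:
    """Simulate one annotator's binary mask for one (montage-aligned) image.

    Pipeline: resize truth to ``area_scale`` x area, jitter the boundary with
    a smooth Gaussian random field of sd ``boundary_jitter_sd`` pixels, then
    drop each disjoint component with probability ``omission_prob``.  An
    empty truth yields an empty mask.  Deterministic in
    ``(profile.seed, image_key)``.
    """
    if truth.ndim != 2:
        raise AlignmentError("truth mask must be 2D")
    truth = truth.astype(bool)
    rng = np.random.default_rng(
        np.random.SeedSequence([profile.seed & 0x7FFFFFFF, int(image_key)])
    )
    if not truth.any():
        return np.zeros_like(truth)
    if profile.empty_prob > 0 and rng.uniform() < profile.empty_prob:
        return np.zeros_like(truth)

    target = profile.area_scale * truth.sum()
    mask = _resize_to_area(truth, target, rng)

    if profile.boundary_jitter_sd > 0 and mask.any() and not mask.all():
        signed = ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(~mask)
        noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 3.0)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * profile.boundary_jitter_sd
        mask = (signed + noise) > 0
        if mask.any():
            # jitter perturbs the boundary shape only; restore the area
            # target, which thin structures otherwise regain or lose wholesale
            mask = _resize_to_area(mask, target, rng)

    if profile.omission_prob > 0 and mask.any():
        labels, n_comp = ndimage.label(mask)
        keep = rng.uniform(size=n_comp) >= profile.omission_prob
        mask = np.isin(labels, np.flatnonzero(keep) + 1) & mask
    return mask
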