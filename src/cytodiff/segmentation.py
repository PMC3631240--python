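"""Automated quantification of apoptosis in CC3-stained brightfield tiles.

A DAB/haematoxylin (CC3) image contains three major pixel classes: white
background, blue (haematoxylin) nuclei, and brown (DAB) apoptotic regions.
The pipeline is:

1. convert sRGB to CIE 1976 L*a*b*;
2. three-way k-means over (L*, a*, b*) to obtain initial white/blue/brown
   masks — because blue and brown occur in widely varying shades, this
   one-shot clustering typically leaves the brown class contaminated with
   blue pixels;
3. PCA over the per-pixel Lab values; the second principal channel isolates
   the blue-vs-brown contrast;
4. maximum-entropy (Kapur) histogram thresholding of the brown class's
   channel-2 values splits the contaminated class, and the bluish side is
   reassigned;
5. morphological clean-up (fill small holes, drop small components);
6. the apoptotic index: brown pixels as a percentage of non-background
   (tissue) pixels.

Masks form an exact partition of the image at every stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from skimage import color, morphology
from sklearn.cluster import KMeans

from .errors import (
    DegenerateInputError,
    DomainError,
    FormatError,
    UndefinedIndexError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClassMasks",
    "ProjectedImage",
    "ApoptosisResult",
    "PipelineConfig",
    "rgb_to_lab",
    "initial_cluster",
    "pca_project",
    "kapur_threshold",
    "refine_brown",
    "postprocess",
    "apoptotic_index",
    "quantify_image",
    "quantify_images",
]


@dataclass
class ClassMasks:
    """Mutually exclusive, jointly exhaustive white/blue/brown pixel masks."""

    white: np.ndarray
    blue: np.ndarray
    brown: np.ndarray

    def __post_init__(self) -> None:
        for name in ("white", "blue", "brown"):
            m = getattr(self, name)
            if m.dtype != bool:
                setattr(self, name, m.astype(bool))
        if not (self.white.shape == self.blue.shape == self.brown.shape):
            raise FormatError("class masks must share one shape")
        total = self.white.astype(int) + self.blue.astype(int) + self.brown.astype(int)
        if not np.all(total == 1):
            raise FormatError("class masks must partition the image exactly")

    @property
    def shape(self) -> tuple[int, int]:
        return self.white.shape

    def copy(self) -> "ClassMasks":
        return ClassMasks(self.white.copy(), self.blue.copy(), self.brown.copy())


@dataclass(frozen=True)
class ProjectedImage:
    """PCA-decorrelated channel image.

    ``pixels`` has the source spatial shape with channels ordered by
    descending eigenvalue; ``eigenvectors`` columns are the corresponding
    orthonormal directions in (L*, a*, b*) space.
    """

    pixels: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass(frozen=True)
class ApoptosisResult:
    """Pixel bookkeeping and apoptotic index for one image."""

    br_count: int
    w_count: int
    area: int
    index: float
    image_id: str = ""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full quantification chain."""

    seed: int = 0
    min_hole_px: int = 64
    min_object_px: int = 64
    index_convention: str = "tissue"  # or "area"
    kmeans_n_init: int = 10


def _as_rgb8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    return img


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Standard sRGB (8-bit) → CIEXYZ (D65) → CIE 1976 L*a*b* conversion."""
    img = _as_rgb8(img)
    return color.rgb2lab(img.astype(np.float64) / 255.0)


def initial_cluster(lab: np.ndarray, seed: int = 0, n_init: int = 10) -> ClassMasks:
    """Three-way k-means over per-pixel (L*, a*, b*) coordinates.

    Cluster identities are assigned from the centroids: the background
    (white) cluster is the one with the smallest chroma magnitude
    sqrt(a*² + b*²) — stained tissue carries chroma while the background is
    near-achromatic; of the remaining two, the one with the larger b*
    (yellow–brown direction) is brown, the other blue.  Deterministic for a
    fixed ``seed``.
    """
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise FormatError(f"expected an H×W×3 Lab image, got shape {lab.shape}")
    flat = lab.reshape(-1, 3)
    if np.allclose(flat, flat[0], atol=1e-12):
        raise DegenerateInputError("constant image cannot be clustered into 3 classes")
    km = KMeans(n_clusters=3, n_init=n_init, random_state=seed)
    labels = km.fit_predict(flat)
    if np.unique(labels).size < 3:
        raise DegenerateInputError("k-means collapsed to fewer than 3 clusters")
    centers = km.cluster_centers_
    chroma = np.hypot(centers[:, 1], centers[:, 2])
    white_id = int(np.argmin(chroma))
    rest = [i for i in range(3) if i != white_id]
    brown_id = rest[int(np.argmax(centers[rest, 2]))]
    blue_id = next(i for i in rest if i != brown_id)
    labels = labels.reshape(lab.shape[:2])
    return ClassMasks(
        white=labels == white_id, blue=labels == blue_id, brown=labels == brown_id
    )


def pca_project(lab: np.ndarray, masks: ClassMasks | None = None) -> ProjectedImage:
    """Project per-pixel Lab values onto the eigenvectors of their covariance.

    Pixels are reshaped to an N×3 matrix (rows = pixels, columns = channels),
    the per-channel mean is subtracted, and the data are rotated onto the
    eigenvectors of the 3×3 sample covariance, ordered by descending
    eigenvalue.  Eigenvector signs are fixed deterministically: channel 1 is
    oriented along increasing L*, and channel 2 so that brown-candidate
    pixels score higher than blue-candidate ones (using ``masks`` when given,
    otherwise the b* direction as the brown/blue contrast proxy); channel 3,
    which carries essentially noise, is oriented along increasing a*.
    """
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise FormatError(f"expected an H×W×3 Lab image, got shape {lab.shape}")
    X = lab.reshape(-1, 3).astype(np.float64)
    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 1e-12):
        raise DegenerateInputError("constant image: covariance is rank 0")
    S = (Xc.T @ Xc) / max(X.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(S)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)

    # deterministic sign orientation
    if evecs[0, 0] < 0:  # channel 1 along +L*
        evecs[:, 0] *= -1
    if masks is not None and masks.brown.any() and masks.blue.any():
        p2 = Xc @ evecs[:, 1]
        flat_brown = masks.brown.reshape(-1)
        flat_blue = masks.blue.reshape(-1)
        if p2[flat_brown].mean() < p2[flat_blue].mean():
            evecs[:, 1] *= -1
    elif evecs[2, 1] < 0:  # fall back: +b* is the brown direction
        evecs[:, 1] *= -1
    if evecs[1, 2] < 0:  # channel 3 along +a*
        evecs[:, 2] *= -1

    P = (Xc @ evecs).reshape(lab.shape)
    return ProjectedImage(pixels=P, eigenvalues=evals, eigenvectors=evecs)


def _entropy_terms(p: np.ndarray) -> np.ndarray:
    """p·ln p with the 0·ln 0 → 0 limit."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def kapur_threshold(counts: Sequence[int] | np.ndarray) -> int:
    """Maximum-entropy threshold of an intensity histogram.

    Splits the histogram at level ``t`` into the distribution of intensities
    ``≤ t`` and the distribution ``> t`` (each renormalised), and returns the
    ``t`` maximising the sum of the two Shannon entropies (natural log).
    Splits leaving either side empty are excluded; ties break toward the
    lowest ``t``.  Equivalent to exhaustive search over all candidate levels.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 2:
        raise DegenerateInputError("histogram must be 1-D with at least 2 bins")
    if np.any(counts < 0):
        raise DomainError("histogram counts must be non-negative")
    if np.count_nonzero(counts) < 2:
        raise DegenerateInputError(
            "need at least 2 non-empty bins to split the histogram"
        )
    p = counts / counts.sum()
    P_low = np.cumsum(p)
    plogp = _entropy_terms(p)
    C_low = np.cumsum(plogp)
    P_high = 1.0 - P_low
    C_high = C_low[-1] - C_low

    with np.errstate(divide="ignore", invalid="ignore"):
        H_low = -C_low / P_low + np.log(P_low)
        H_high = -C_high / P_high + np.log(P_high)
    objective = H_low + H_high
    valid = (P_low > 0) & (P_high > 0)
    objective[~valid] = -np.inf
    best = np.max(objective)
    # lowest t within floating tolerance of the maximum
    return int(np.nonzero(objective >= best - 1e-12)[0][0])


def refine_brown(
    masks: ClassMasks, proj: ProjectedImage, min_separation: float = 3.0
) -> ClassMasks:
    """Split the initial brown class by entropy thresholding of channel 2.

    The brown-class pixels' channel-2 values are linearly rescaled to 8-bit
    levels, Kapur-thresholded, and the side with the lower channel-2 mean is
    reassigned to blue; the white mask is untouched and the partition is
    preserved.

    The reassignment is applied only when the split is genuinely bimodal:
    Ashman's D between the two sides, ``|μ₁−μ₂| / sqrt((s₁²+s₂²)/2)``, must
    reach ``min_separation``.  A maximum-entropy threshold of a *unimodal*
    distribution falls near its centre (empirically D ≈ 2.7 for a Gaussian
    class), so without the guard an uncontaminated brown class would lose
    roughly half its pixels; a two-component class yields D well above 3.
    Set ``min_separation=0`` to force the split.
    """
    if proj.pixels.shape[:2] != masks.shape:
        raise FormatError("masks and projection are not spatially aligned")
    out = masks.copy()
    flat_brown = masks.brown.reshape(-1)
    if not flat_brown.any():
        warnings.warn("brown class is empty; masks returned unchanged", stacklevel=2)
        return out
    ch2 = proj.pixels[..., 1].reshape(-1)
    vals = ch2[flat_brown]
    vmin, vmax = vals.min(), vals.max()
    if vmax - vmin <= 0:
        warnings.warn("brown-class channel 2 is constant; masks unchanged", stacklevel=2)
        return out
    scaled = np.rint((vals - vmin) / (vmax - vmin) * 255.0).astype(np.int64)
    hist = np.bincount(scaled, minlength=256)
    try:
        t = kapur_threshold(hist)
    except DegenerateInputError:
        warnings.warn("brown-class histogram degenerate; masks unchanged", stacklevel=2)
        return out
    low_side = scaled <= t
    if not low_side.any() or low_side.all():
        return out
    mean_low = vals[low_side].mean()
    mean_high = vals[~low_side].mean()
    # orientation contract: higher channel-2 mean side is the brown one
    reject = low_side if mean_high >= mean_low else ~low_side
    if min_separation > 0:
        s_low = vals[low_side].std()
        s_high = vals[~low_side].std()
        pooled = np.sqrt((s_low**2 + s_high**2) / 2.0)
        ashman_d = abs(mean_high - mean_low) / pooled if pooled > 0 else np.inf
        if ashman_d < min_separation:
            return out
    idx = np.nonzero(flat_brown)[0][reject]
    flat_new_brown = out.brown.reshape(-1)
    flat_new_blue = out.blue.reshape(-1)
    flat_new_brown[idx] = False
    flat_new_blue[idx] = True
    return ClassMasks(
        white=out.white,
        blue=flat_new_blue.reshape(masks.shape),
        brown=flat_new_brown.reshape(masks.shape),
    )


def postprocess(
    mask: np.ndarray, min_hole_px: int = 64, min_object_px: int = 64
) -> np.ndarray:
    """Fill holes smaller than ``min_hole_px`` and drop 8-connected
    components smaller than ``min_object_px``.  Idempotent."""
    mask = np.asarray(mask, dtype=bool)
    out = morphology.remove_small_holes(mask, max_size=min_hole_px - 1)
    out = morphology.remove_small_objects(out, max_size=min_object_px - 1, connectivity=2)
    return out


def apoptotic_index(masks: ClassMasks, convention: str = "tissue") -> ApoptosisResult:
    """Apoptotic index of one image.

    Default ``"tissue"`` convention: ``100 · Br / (Area − W)`` — brown pixels
    as a percentage of non-background tissue.  ``"area"`` convention:
    ``100 · Br / Area``.
    """
    br = int(masks.brown.sum())
    w = int(masks.white.sum())
    area = int(masks.white.size)
    if convention == "tissue":
        if area == w:
            raise UndefinedIndexError("image contains no tissue pixels")
        index = 100.0 * br / (area - w)
    elif convention == "area":
        index = 100.0 * br / area
    else:
        raise DomainError(f"unknown index convention {convention!r}")
    return ApoptosisResult(br_count=br, w_count=w, area=area, index=index)


def quantify_image(
    img: np.ndarray, config: PipelineConfig = PipelineConfig(), image_id: str = ""
) -> tuple[ApoptosisResult, ClassMasks]:
    """Full chain on one RGB image; returns the index and the final masks."""
    lab = rgb_to_lab(img)
    masks = initial_cluster(lab, seed=config.seed, n_init=config.kmeans_n_init)
    proj = pca_project(lab, masks)
    masks = refine_brown(masks, proj)
    cleaned = postprocess(masks.brown, config.min_hole_px, config.min_object_px)
    # keep the partition: pixels dropped from brown fall back to blue,
    # pixels gained (filled holes) are taken from whichever class held them
    white = masks.white & ~cleaned
    blue = ~white & ~cleaned
    masks = ClassMasks(white=white, blue=blue, brown=cleaned)
    result = apoptotic_index(masks, config.index_convention)
    return replace(result, image_id=image_id), masks


def quantify_images(
    images: Iterable[np.ndarray],
    config: PipelineConfig = PipelineConfig(),
    conditions: Sequence[str] | None = None,
) -> tuple[list[ApoptosisResult], dict[str, float]]:
    """Run the pipeline over a batch, tolerating per-image failures.

    Returns per-image results (failed images are skipped and logged) and the
    arithmetic mean index per condition (single condition ``"all"`` when no
    condition labels are given).
    """
    images = list(images)
    if not images:
        raise DomainError("empty image batch")
    if conditions is not None and len(conditions) != len(images):
        raise DomainError("conditions must match images one-to-one")
    results: list[ApoptosisResult] = []
    labels: list[str] = []
    for i, img in enumerate(images):
        cond = conditions[i] if conditions is not None else "all"
        try:
            res, _ = quantify_image(img, config, image_id=f"image_{i}")
        except Exception:  # noqa: BLE001 - batch must survive bad tiles
            logger.exception("quantification failed for image %d (%s)", i, cond)
            continue
        results.append(res)
        labels.append(cond)
    if not results:
        raise DomainError("quantification failed for every image in the batch")
    means: dict[str, float] = {}
    for cond in dict.fromkeys(labels):
        vals = [r.index for r, c in zip(results, labels) if c == cond]
        means[cond] = float(np.mean(vals))
    return results, means
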