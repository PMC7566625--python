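"""Paired-WSI preprocessing: downscaling, nuclei-mask affine registration,
technical-noise reduction, intensity normalization, and background-filtered
tiling.

The pipeline mirrors the standard preparation of spatially registered
H&E / immunofluorescence image pairs: nuclear content (hematoxylin on the
H&E side, DAPI on the IF side) anchors an affine registration estimated from
matched keypoints on binarized nuclei masks; IF intensities are median
filtered and affinely rescaled to fixed first and second moments; finally
the pair is cut into non-overlapping square tiles and mostly-background
tiles are discarded.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from scipy import ndimage
from skimage import color
from skimage.feature import SIFT, match_descriptors
from skimage.filters import threshold_otsu
from skimage.measure import ransac
from skimage.morphology import disk
from skimage.transform import AffineTransform, warp

from .datatypes import (
    DegenerateImageError,
    InvalidSpecError,
    RegistrationError,
    RegistrationModel,
    TileRecord,
)

# ITU-R 601 luma weights (classic rgb2gray behaviour)
_GRAY_W = np.array([0.299, 0.587, 0.114])

# Reinhard-style stain-normalization target: LAB channel means/stds of a
# reference well-stained H&E field (L in [0,100], a/b roughly [-128,127]).
# The values are the statistics of the reference tissue phantom, which keeps
# normalized stroma safely on the tissue side of the 8-bit-180 background
# rule used by the tiling filter.
DEFAULT_HE_TARGET = {
    "mean": (67.0, 29.0, -15.5),
    "std": (15.0, 1.85, 10.5),
}


def downscale(img: np.ndarray, factor: int = 2) -> np.ndarray:
    """Anti-aliased integer downscaling by local averaging.

    Output dims are floor(H/factor) x floor(W/factor); trailing rows/cols that
    do not fill a complete block are dropped.
    """
    if factor < 1:
        raise InvalidSpecError("downscale factor must be >= 1")
    if factor == 1:
        return img.copy()
    h, w = img.shape[:2]
    ho, wo = h // factor, w // factor
    img = img[: ho * factor, : wo * factor]
    if img.ndim == 2:
        return img.reshape(ho, factor, wo, factor).mean(axis=(1, 3))
    return img.reshape(ho, factor, wo, factor, img.shape[2]).mean(axis=(1, 3))


def nuclei_mask(img: np.ndarray, modality: str) -> np.ndarray:
    """Binary nuclei mask by Otsu thresholding (256-bin histogram).

    H&E: grayscale -> Otsu -> complement (nuclei are dark). DAPI: Otsu
    (nuclei are bright).
    """
    if modality not in ("he", "dapi"):
        raise InvalidSpecError(f"unknown modality {modality!r}")
    if modality == "he":
        if img.ndim != 3 or img.shape[2] != 3:
            raise InvalidSpecError("H&E input must be RGB")
        gray = img @ _GRAY_W
    else:
        if img.ndim != 2:
            raise InvalidSpecError("DAPI input must be single-channel")
        gray = img
    if np.ptp(gray) == 0:
        raise DegenerateImageError("constant image has no Otsu threshold")
    t = threshold_otsu(gray, nbins=256)
    if modality == "he":
        return gray <= t
    return gray > t


def register_pair(he: np.ndarray, if_img: np.ndarray, max_features: int = 10000,
                  residual_threshold: float = 3.0, max_trials: int = 2000,
                  seed: int = 0) -> RegistrationModel:
    """Estimate the affine mapping the IF (DAPI) frame onto the H&E frame.

    Scale-invariant keypoints and descriptors (SIFT) are detected on the two
    nuclei masks, capped at ``min(max_features, detected)``, matched with
    cross-checking and a Lowe ratio test, and an affine model is fit robustly
    (RANSAC, 3 px inlier threshold). Applying the returned affine to the IF
    image registers it to the H&E frame.
    """
    try:
        he_mask = nuclei_mask(he, "he")
        if_mask = nuclei_mask(if_img, "dapi")
    except DegenerateImageError as e:
        raise RegistrationError(f"degenerate input: {e}") from e

    kp, desc = [], []
    for m in (he_mask, if_mask):
        det = SIFT()
        smooth = ndimage.gaussian_filter(m.astype(float), 1.0)
        try:
            det.detect_and_extract(smooth)
        except RuntimeError as e:
            raise RegistrationError(f"no keypoints detected: {e}") from e
        kp.append(det.keypoints[:max_features])
        desc.append(det.descriptors[:max_features])
    if len(kp[0]) < 3 or len(kp[1]) < 3:
        raise RegistrationError(
            f"too few keypoints (he={len(kp[0])}, if={len(kp[1])})")

    matches = match_descriptors(desc[1], desc[0], cross_check=True, max_ratio=0.8)
    if len(matches) < 3:
        raise RegistrationError(f"only {len(matches)} descriptor matches")
    src = kp[1][matches[:, 0]][:, ::-1]  # IF keypoints, (x, y)
    dst = kp[0][matches[:, 1]][:, ::-1]  # H&E keypoints, (x, y)

    model, inliers = ransac(
        (src, dst),
        AffineTransform,
        min_samples=3,
        residual_threshold=residual_threshold,
        max_trials=max_trials,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < 3:
        raise RegistrationError(
            f"RANSAC failed ({0 if inliers is None else int(inliers.sum())} inliers "
            f"of {len(matches)} matches)")
    return RegistrationModel(
        affine=model.params[:2],
        n_matched_features=int(len(matches)),
        inlier_fraction=float(inliers.mean()),
    )


def apply_registration(if_img: np.ndarray, model: RegistrationModel) -> np.ndarray:
    """Warp the IF image into the H&E frame using the estimated affine."""
    inv = AffineTransform(matrix=np.linalg.inv(model.matrix))
    return warp(if_img, inv, order=1, cval=0.0, preserve_range=True)


def median_filter_if(if_img: np.ndarray, radius: int = 5) -> np.ndarray:
    """Median filter with a disk structuring element (reflect edges)."""
    if radius < 1:
        raise InvalidSpecError("radius must be >= 1")
    return ndimage.median_filter(if_img, footprint=disk(radius), mode="reflect")


def normalize_if(if_img: np.ndarray, target_mean: float = 0.25,
                 target_std: float = 0.125) -> np.ndarray:
    """Affine intensity rescale to fixed moments, then clip into [0, 1].

    Pre-clip mean and std match the targets exactly (float tolerance).
    """
    sd = float(np.std(if_img))
    if sd == 0.0:
        raise DegenerateImageError("zero-variance IF image cannot be normalized")
    out = (if_img - np.mean(if_img)) / sd * target_std + target_mean
    return np.clip(out, 0.0, 1.0)


def normalize_he(he: np.ndarray, target_stats: Optional[dict] = None) -> np.ndarray:
    """Stain normalization by LAB mean/std matching to a fixed reference.

    Each LAB channel is affinely mapped to the target mean/std (Reinhard-style
    color transfer); deterministic given ``target_stats``. A channel with zero
    variance is shifted to the target mean only.
    """
    if he.ndim != 3 or he.shape[2] != 3:
        raise InvalidSpecError("H&E input must be RGB")
    stats = target_stats or DEFAULT_HE_TARGET
    lab = color.rgb2lab(np.clip(he, 0.0, 1.0))
    out = np.empty_like(lab)
    for c in range(3):
        ch = lab[:, :, c]
        mu, sd = float(ch.mean()), float(ch.std())
        if sd == 0.0:
            out[:, :, c] = stats["mean"][c]
        else:
            out[:, :, c] = (ch - mu) / sd * stats["std"][c] + stats["mean"][c]
    return np.clip(color.lab2rgb(out), 0.0, 1.0)


def he_stats(he: np.ndarray) -> dict:
    """LAB channel means/stds of an RGB image (the normalize_he statistics)."""
    lab = color.rgb2lab(np.clip(he, 0.0, 1.0))
    return {
        "mean": tuple(float(lab[:, :, c].mean()) for c in range(3)),
        "std": tuple(float(lab[:, :, c].std()) for c in range(3)),
    }


def background_fraction(he_tile: np.ndarray, bg_intensity_threshold: int = 180) -> float:
    """Fraction of pixels whose 8-bit RGB intensities are ALL > threshold."""
    as8 = np.round(np.clip(he_tile, 0.0, 1.0) * 255.0).astype(np.uint8)
    return float(np.all(as8 > bg_intensity_threshold, axis=2).mean())


def tile_pair(he: np.ndarray, if_img: np.ndarray, sample_id: str = "sample",
              tile_size: int = 256, bg_intensity_threshold: int = 180,
              bg_fraction_threshold: float = 0.5) -> List[TileRecord]:
    """Cut a registered pair into non-overlapping tiles, dropping background.

    Row-major, 0-based grid of half-open windows; partial edge tiles are
    dropped. A pixel is background iff all three 8-bit channels exceed
    ``bg_intensity_threshold``; a tile is removed (together with its IF mate)
    iff its H&E background fraction is strictly greater than
    ``bg_fraction_threshold`` — the exactly-at-threshold tile is retained.
    The IF content never triggers removal.
    """
    if he.shape[:2] != if_img.shape[:2]:
        raise InvalidSpecError("H&E and IF dimensions differ")
    h, w = he.shape[:2]
    s = tile_size
    records: List[TileRecord] = []
    for r in range(h // s):
        for c in range(w // s):
            he_t = he[r * s : (r + 1) * s, c * s : (c + 1) * s]
            if_t = if_img[r * s : (r + 1) * s, c * s : (c + 1) * s]
            bf = background_fraction(he_t, bg_intensity_threshold)
            if bf > bg_fraction_threshold:
                continue
            records.append(TileRecord(he_tile=he_t, if_tile=if_t, row=r, col=c,
                                      sample_id=sample_id, background_fraction=bf))
    return records
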