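"""Seeded tissue phantoms with a known morphology-driven marker channel.

The generators emulate the data a virtual-staining study is built on: RGB
H&E-like images (dark-violet nuclei on pink stroma) paired with a
single-channel immunofluorescence (IF) image whose signal is a smoothed
indicator of planted "marker regions". Marker regions carry a higher nucleus
density than surrounding stroma, so the H&E -> IF mapping is a function of
tissue morphology rather than of absolute position — which is what makes the
translation task learnable and the phantoms useful for end-to-end tests.

Cohorts plant cluster structure across samples (distinct texture regimes), a
synthetic analog of a small, heterogeneous multi-patient study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, warp

from .datatypes import InvalidSpecError, RegisteredPair

# hematoxylin/eosin palette: violet nuclei on pink stroma. The stroma green
# channel sits clearly below the 8-bit 180 background threshold so that
# rendered tissue is never classified as bare slide by the tiling filter.
STROMA_RGB = (0.90, 0.66, 0.80)
NUCLEUS_RGB = (0.36, 0.22, 0.54)


@dataclass
class TextureParams:
    """Texture regime of one tissue class / cluster."""

    nucleus_density: float = 0.006      # nuclei per px^2 outside marker regions
    nucleus_radius: float = 3.0         # px
    marker_density_boost: float = 3.0   # density multiplier inside marker regions
    stroma_rgb: tuple = STROMA_RGB
    nucleus_rgb: tuple = NUCLEUS_RGB
    # chromatic offset of marker-region cytoplasm vs surrounding stroma
    # (epithelial/tumor cytoplasm reads more basophilic than collagenous
    # stroma); together with the density boost this makes the planted
    # H&E -> IF mapping a deterministic function of the H&E appearance
    marker_tint: tuple = (-0.06, -0.04, 0.03)
    n_marker_disks: tuple = (1, 3)      # inclusive range per tile
    marker_radius: tuple = (8.0, 16.0)  # px range


@dataclass
class PhantomSpec:
    """Specification of a single paired H&E/IF phantom."""

    height: int = 256
    width: int = 256
    texture: TextureParams = field(default_factory=TextureParams)
    marker_regions: Sequence[tuple] = ()   # (cy, cx, radius) disks
    noise_sd: float = 0.02                 # additive Gaussian sd on the IF channel
    background_level: int = 245            # 8-bit brightness of bare slide
    background_margin: int = 0             # px of bare slide around the tissue
    if_smooth_sigma: float = 2.0           # Gaussian on the marker mask

    def validate(self):
        if self.height < 1 or self.width < 1:
            raise InvalidSpecError("phantom has zero area")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        for cy, cx, r in self.marker_regions:
            if not (0 <= cy - r and cy + r < self.height and 0 <= cx - r and cx + r < self.width):
                raise InvalidSpecError(f"marker region ({cy},{cx},{r}) outside image bounds")


@dataclass
class SampleSpec:
    sample_id: str
    n_tiles: int
    cluster_id: str


@dataclass
class CohortSpec:
    """A multi-sample cohort with planted cluster structure."""

    samples: Sequence[SampleSpec] = ()
    clusters: dict = field(default_factory=dict)   # cluster_id -> TextureParams
    tile_size: int = 256
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self):
        if not self.samples:
            raise InvalidSpecError("cohort needs at least one sample")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise InvalidSpecError("duplicate sample_id in cohort")
        for s in self.samples:
            if s.n_tiles < 1:
                raise InvalidSpecError(f"sample {s.sample_id}: n_tiles must be >= 1")
            if s.cluster_id not in self.clusters:
                raise InvalidSpecError(f"sample {s.sample_id} references undefined cluster {s.cluster_id}")


def _rasterize_disks(shape, disks) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx, r in disks:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def generate_phantom_pair(spec: PhantomSpec, seed: int) -> RegisteredPair:
    """Render one registered H&E/IF phantom pair; bit-reproducible per seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    tx = spec.texture

    mask = _rasterize_disks((h, w), spec.marker_regions)

    # tissue region excludes an optional bare-slide margin
    tissue = np.ones((h, w), dtype=bool)
    m = spec.background_margin
    if m > 0:
        tissue[:] = False
        tissue[m : h - m, m : w - m] = True

    # nucleus placement: Poisson counts, higher density inside marker regions
    inside = mask & tissue
    outside = tissue & ~mask
    n_in = rng.poisson(tx.nucleus_density * tx.marker_density_boost * inside.sum())
    n_out = rng.poisson(tx.nucleus_density * outside.sum())
    centers = []
    for region, n in ((inside, n_in), (outside, n_out)):
        idx = np.flatnonzero(region)
        if idx.size and n:
            picks = rng.choice(idx, size=min(n, idx.size), replace=False)
            centers.extend(zip(*np.unravel_index(picks, (h, w))))

    he = np.empty((h, w, 3))
    stroma_tex = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 3.0)
    tint = gaussian_filter((mask & tissue).astype(float), 1.0)
    for c in range(3):
        he[:, :, c] = tx.stroma_rgb[c] + 0.04 * stroma_tex + tx.marker_tint[c] * tint
    yy, xx = np.mgrid[0:h, 0:w]
    nuc = np.zeros((h, w), dtype=bool)
    for cy, cx in centers:
        r = tx.nucleus_radius * rng.uniform(0.7, 1.3)
        ri = int(np.ceil(r))
        y0, y1 = max(0, cy - ri), min(h, cy + ri + 1)
        x0, x1 = max(0, cx - ri), min(w, cx + ri + 1)
        sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r**2
        nuc[y0:y1, x0:x1] |= sub
    for c in range(3):
        ch = he[:, :, c]
        ch[nuc] = tx.nucleus_rgb[c] + 0.03 * stroma_tex[nuc]
        ch = gaussian_filter(ch, 0.6)
        ch[~tissue] = spec.background_level / 255.0
        he[:, :, c] = ch
    np.clip(he, 0.0, 1.0, out=he)

    if_chan = gaussian_filter((mask & tissue).astype(float), spec.if_smooth_sigma)
    if spec.noise_sd > 0:
        if_chan = if_chan + rng.normal(0.0, spec.noise_sd, (h, w))
    np.clip(if_chan, 0.0, 1.0, out=if_chan)

    # DAPI-like nuclear counterstain in the IF frame: the same nuclei the
    # hematoxylin shows, which is what anchors affine registration
    dapi = gaussian_filter(nuc.astype(float), 0.8)
    if spec.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, spec.noise_sd, (h, w))
    np.clip(dapi, 0.0, 1.0, out=dapi)

    return RegisteredPair(
        he=he,
        if_chan=if_chan,
        marker_mask=mask & tissue,
        dapi=dapi,
        meta={"seed": int(seed), "n_nuclei": len(centers)},
    )


def _random_marker_disks(rng: np.random.Generator, size: int, tx: TextureParams):
    lo, hi = tx.n_marker_disks
    n = int(rng.integers(lo, hi + 1))
    disks = []
    for _ in range(n):
        r = rng.uniform(*tx.marker_radius)
        r = min(r, (size - 2) / 2 - 1)
        cy = rng.uniform(r + 1, size - r - 2)
        cx = rng.uniform(r + 1, size - r - 2)
        disks.append((cy, cx, r))
    return disks


def generate_cohort(cohort: CohortSpec):
    """Generate per-sample tile lists: [(sample_id, [RegisteredPair, ...]), ...]."""
    cohort.validate()
    out = []
    for si, s in enumerate(cohort.samples):
        tx = cohort.clusters[s.cluster_id]
        tiles = []
        for ti in range(s.n_tiles):
            ss = np.random.SeedSequence([int(cohort.seed), si, ti])
            child = np.random.default_rng(ss)
            disks = _random_marker_disks(child, cohort.tile_size, tx)
            spec = PhantomSpec(
                height=cohort.tile_size,
                width=cohort.tile_size,
                texture=tx,
                marker_regions=disks,
                noise_sd=cohort.noise_sd,
            )
            pair = generate_phantom_pair(spec, int(ss.generate_state(1)[0] % 2**31))
            pair.sample_id = s.sample_id
            pair.row, pair.col = 0, ti
            tiles.append(pair)
        out.append((s.sample_id, tiles))
    return out


def perturb_alignment(pair: RegisteredPair, affine: np.ndarray) -> RegisteredPair:
    """Resample the IF channel through a forward 2x3 affine (x, y convention).

    A point p in the original IF image lands at ``A @ [x, y, 1]`` in the
    perturbed image; the H&E member is untouched. Bilinear interpolation,
    out-of-bounds filled with 0. The planted transform is recorded so
    registration tests can compare against ground truth.
    """
    a = np.asarray(affine, dtype=float)
    if a.shape == (2, 3):
        a = np.vstack([a, [0.0, 0.0, 1.0]])
    if a.shape != (3, 3):
        raise InvalidSpecError("affine must be 2x3 or 3x3")
    if abs(np.linalg.det(a[:2, :2])) < 1e-12:
        raise InvalidSpecError("affine is not invertible")

    inv = AffineTransform(matrix=np.linalg.inv(a))
    warped_if = warp(pair.if_chan, inv, order=1, cval=0.0, preserve_range=True)
    warped_mask = None
    if pair.marker_mask is not None:
        warped_mask = warp(pair.marker_mask.astype(float), inv, order=1, cval=0.0,
                           preserve_range=True) > 0.5
    warped_dapi = None
    if pair.dapi is not None:
        warped_dapi = warp(pair.dapi, inv, order=1, cval=0.0, preserve_range=True)
    return RegisteredPair(
        he=pair.he,
        if_chan=warped_if,
        sample_id=pair.sample_id,
        row=pair.row,
        col=pair.col,
        marker_mask=warped_mask,
        dapi=warped_dapi,
        misalignment=a,
        meta=dict(pair.meta),
    )


def generate_feature_table(
    n_per_sample: Sequence[int],
    feature_means: Sequence[Sequence[float]],
    noise_sd: float,
    seed: int,
    sample_ids: Optional[Sequence[str]] = None,
):
    """Gaussian feature rows around per-sample means; a selection-stage fixture.

    Returns a :class:`shiftlab.representation.FeatureTable` with known
    cluster/representativeness structure.
    """
    from .representation import FeatureTable

    n_per_sample = list(n_per_sample)
    means = np.asarray(feature_means, dtype=float)
    if means.ndim != 2 or len(n_per_sample) != means.shape[0]:
        raise InvalidSpecError("feature_means must be one vector per sample")
    if any(n < 1 for n in n_per_sample):
        raise InvalidSpecError("all n_per_sample must be >= 1")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(len(n_per_sample))]
    rng = np.random.default_rng(seed)
    rows, sids = [], []
    for n, mu, sid in zip(n_per_sample, means, sample_ids):
        rows.append(mu + rng.normal(0.0, noise_sd, size=(n, means.shape[1])))
        sids.extend([sid] * n)
    feats = np.vstack(rows)
    tile_ids = np.array([f"t{i}" for i in range(feats.shape[0])])
    return FeatureTable(features=feats, sample_ids=np.array(sids), tile_ids=tile_ids)


def write_pair(pair: RegisteredPair, out_dir, stem: str = "phantom"):
    """Write a pair as TIFF (8-bit RGB H&E, float32 IF) plus a JSON sidecar."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    he_path = out / f"{stem}_he.tif"
    if_path = out / f"{stem}_if.tif"
    tifffile.imwrite(he_path, (np.round(pair.he * 255)).astype(np.uint8))
    tifffile.imwrite(if_path, pair.if_chan.astype(np.float32))
    sidecar = {
        "he": he_path.name,
        "if": if_path.name,
        "sample_id": pair.sample_id,
        "seed": pair.meta.get("seed"),
        "misalignment": None if pair.misalignment is None else pair.misalignment.tolist(),
    }
    if pair.dapi is not None:
        dapi_path = out / f"{stem}_dapi.tif"
        tifffile.imwrite(dapi_path, pair.dapi.astype(np.float32))
        sidecar["dapi"] = dapi_path.name
    if pair.marker_mask is not None:
        mask_path = out / f"{stem}_mask.tif"
        tifffile.imwrite(mask_path, pair.marker_mask.astype(np.uint8))
        sidecar["marker_mask"] = mask_path.name
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return he_path, if_path
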