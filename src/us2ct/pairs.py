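"""Paired-dataset construction: alignment, resampling, splits and jitter.

A training pair couples one signal-stage matrix (converted to an axial ×
lateral image over the probe's field of view) with the ground-truth CT of
the same phantom, cropped to that field of view, both resampled to a square
raster and normalized to [−1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.transform import resize

from us2ct.ct_sim import CTImage
from us2ct.phantoms import Phantom, PhantomConfig, combined_mask
from us2ct.rf_chain import StageMatrix
from us2ct.us_sim import ProbeConfig


@dataclass
class TrainingPair:
    input_image: np.ndarray    # (S, S) in [−1, 1]
    target_image: np.ndarray   # (S, S) in [−1, 1]
    phantom_id: str
    stage: str

    def __post_init__(self) -> None:
        if self.input_image.shape != self.target_image.shape:
            raise ValueError("pair members must share a shape")


@dataclass(frozen=True)
class SplitManifest:
    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train/test overlap")


def _to_pm1(image: np.ndarray) -> np.ndarray:
    """Per-image min/max mapping to [−1, 1]; constant images map to 0."""
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros_like(image, dtype=np.float64)
    return 2.0 * (image - lo) / (hi - lo) - 1.0


def fov_crop(config: PhantomConfig, probe: ProbeConfig) -> tuple[slice, slice]:
    """Pixel crop of the phantom raster covered by the probe's field of view
    (full axial depth, lateral span n_lines × pitch centred)."""
    n_ax, n_tr = config.shape
    fov_px = int(round(probe.fov / config.grid_spacing))
    c0 = (n_tr - fov_px) // 2
    return slice(0, n_ax), slice(c0, c0 + fov_px)


def stage_to_image(stage: StageMatrix, config: PhantomConfig) -> np.ndarray:
    """Orient a stage matrix as an axial × lateral image over the phantom
    depth (time samples beyond the round trip of the full depth are
    dropped; they contain only the record margin)."""
    t_depth = 2.0 * config.axial_extent * 1e-3 / stage.c_bar
    n_keep = min(int(round(t_depth / stage.dt)), stage.data.shape[1])
    return stage.data[:, :n_keep].T.copy()


def ct_fov_image(ct: CTImage, config: PhantomConfig, probe: ProbeConfig) -> np.ndarray:
    """Extract the probe field of view from a padded-square CT image."""
    if ct.phantom_region is None:
        raise ValueError("CT image lacks phantom-region metadata")
    phantom_img = ct.data[ct.phantom_region]
    rows, cols = fov_crop(config, probe)
    return phantom_img[rows, cols]


def align_and_resample(
    stage: StageMatrix,
    ct: CTImage,
    config: PhantomConfig,
    probe: ProbeConfig,
    out_size: int = 256,
) -> TrainingPair:
    """Build one co-registered input/target pair at ``out_size`` square."""
    if stage.phantom_id != getattr(ct, "phantom_id", stage.phantom_id):
        raise ValueError("stage matrix and CT image from different phantoms")
    us_img = stage_to_image(stage, config)
    ct_img = ct_fov_image(ct, config, probe)
    us_rs = resize(us_img, (out_size, out_size), order=1, anti_aliasing=False,
                   preserve_range=True)
    ct_rs = resize(ct_img, (out_size, out_size), order=1, anti_aliasing=False,
                   preserve_range=True)
    # the CT target carries an absolute windowed-density scale: map [0, 1]
    # affinely so the same tissue gets the same gray level in every phantom
    # (per-image min/max would stretch background noise to full scale)
    return TrainingPair(
        input_image=_to_pm1(us_rs),
        target_image=np.clip(2.0 * ct_rs - 1.0, -1.0, 1.0),
        phantom_id=stage.phantom_id,
        stage=stage.stage,
    )


def aligned_masks(
    phantom: Phantom,
    probe: ProbeConfig,
    out_size: int = 256,
    bg_margin_px: int = 2,
) -> dict[str, np.ndarray]:
    """Inclusion-class and background masks on the pair raster.

    Returns boolean rasters ``anechoic``, ``hyperechoic`` and ``background``
    (field minus all inclusions dilated by ``bg_margin_px`` on the output
    grid) aligned with :func:`align_and_resample` outputs.
    """
    rows, cols = fov_crop(phantom.config, probe)
    out: dict[str, np.ndarray] = {}
    union = np.zeros((out_size, out_size), dtype=bool)
    for cls in ("anechoic", "hyperechoic"):
        m = combined_mask(phantom, cls)[rows, cols]
        mr = resize(m.astype(float), (out_size, out_size), order=0,
                    preserve_range=True) > 0.5
        out[cls] = mr
        union |= mr
    out["background"] = ~binary_dilation(union, iterations=bg_margin_px) \
        if bg_margin_px > 0 else ~union
    return out


def make_split(phantom_ids, ratio: float = 0.8, seed: int = 0) -> SplitManifest:
    """Uniform random partition of unique ids at the given train ratio."""
    ids = list(phantom_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("phantom ids must be unique")
    if len(ids) < 2:
        raise ValueError("need at least 2 ids to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    train = tuple(ids[i] for i in perm[:n_train])
    test = tuple(ids[i] for i in perm[n_train:])
    return SplitManifest(train_ids=train, test_ids=test, seed=seed)


def jitter(pair: TrainingPair, rng: np.random.Generator) -> TrainingPair:
    """Random-crop-and-flip augmentation applied jointly to both members.

    Upscales by 286/256, crops back to the original size at a shared random
    offset and mirrors both images laterally with probability 1/2.  Applied
    to training samples only, after split assignment.
    """
    s = pair.input_image.shape[0]
    s2 = int(round(s * 286.0 / 256.0))
    big_in = resize(pair.input_image, (s2, s2), order=1, preserve_range=True)
    big_tg = resize(pair.target_image, (s2, s2), order=1, preserve_range=True)
    r0 = int(rng.integers(0, s2 - s + 1))
    c0 = int(rng.integers(0, s2 - s + 1))
    a = big_in[r0 : r0 + s, c0 : c0 + s]
    b = big_tg[r0 : r0 + s, c0 : c0 + s]
    if rng.random() < 0.5:
        a = a[:, ::-1]
        b = b[:, ::-1]
    return TrainingPair(
        input_image=np.clip(a, -1.0, 1.0),
        target_image=np.clip(b, -1.0, 1.0),
        phantom_id=pair.phantom_id,
        stage=pair.stage,
    )
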