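"""Image-quality metrics and test-set evaluation.

gCNR — one minus the overlap of the ROI and background pixel-intensity
histograms over shared bins — measures lesion detectability independently
of any monotone dynamic-range manipulation.  SSIM quantifies structural
agreement between generated and ground-truth CT.  Jaccard compares binary
segmentation masks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

ROI_CLASSES = ("anechoic", "hyperechoic", "none")


@dataclass(frozen=True)
class MetricRecord:
    phantom_id: str
    stage: str
    flavour: str
    metric: str            # gcnr | ssim | jaccard
    roi_class: str         # anechoic | hyperechoic | none
    value: float
    n_inclusions: int = -1


def gcnr(
    image: np.ndarray,
    roi_mask: np.ndarray,
    bg_mask: np.ndarray,
    n_bins: int = 256,
) -> float:
    """Generalized contrast-to-noise ratio: 1 − Σ_bin min(p_ROI, p_BG).

    Histograms use shared bin edges spanning the pooled intensity range of
    both regions, each normalized to unit mass.  A degenerate pooled range
    (all pixels equal) means full overlap and returns 0.
    """
    roi = np.asarray(image)[np.asarray(roi_mask, dtype=bool)]
    bg = np.asarray(image)[np.asarray(bg_mask, dtype=bool)]
    if roi.size == 0 or bg.size == 0:
        raise ValueError("gCNR requires non-empty ROI and background masks")
    if np.any(np.asarray(roi_mask, dtype=bool) & np.asarray(bg_mask, dtype=bool)):
        raise ValueError("ROI and background masks must be disjoint")
    lo = min(roi.min(), bg.min())
    hi = max(roi.max(), bg.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p_roi = np.histogram(roi, bins=edges)[0] / roi.size
    p_bg = np.histogram(bg, bins=edges)[0] / bg.size
    return float(np.clip(1.0 - np.minimum(p_roi, p_bg).sum(), 0.0, 1.0))


def ssim(image_a: np.ndarray, image_b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity with a uniform 7×7 window and the usual
    stability constants K1 = 0.01, K2 = 0.03 scaled by ``data_range``."""
    if image_a.shape != image_b.shape:
        raise ValueError("SSIM inputs must share a shape")
    return float(
        structural_similarity(
            image_a, image_b, win_size=7, gaussian_weights=False,
            data_range=data_range,
        )
    )


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Jaccard undefined for two empty masks")
    return float(np.logical_and(a, b).sum() / union)


def render_overlay(bmode: np.ndarray, stage_outputs) -> np.ndarray:
    """Mean of 6 generated images, min-max normalized, in the red channel
    over the grayscale B-mode.

    Degenerate dynamic range is handled by convention: an all-zero stack
    yields an all-zero red channel; a non-zero constant stack yields
    mid-gray 0.5.
    """
    stack = [np.asarray(s, dtype=float) for s in stage_outputs]
    if len(stack) != 6:
        raise ValueError(f"overlay expects 6 generated images, got {len(stack)}")
    for s in stack:
        if s.shape != bmode.shape:
            raise ValueError("overlay images must be co-registered with the B-mode")
    mean = np.mean(stack, axis=0)
    lo, hi = mean.min(), mean.max()
    if hi > lo:
        red = (mean - lo) / (hi - lo)
    elif hi == 0.0:
        red = np.zeros_like(mean)
    else:
        red = np.full_like(mean, 0.5)
    g_lo, g_hi = bmode.min(), bmode.max()
    gray = (bmode - g_lo) / (g_hi - g_lo) if g_hi > g_lo else np.zeros_like(bmode)
    out = np.stack([red, gray, gray], axis=-1)
    return out


def evaluate_testset(
    models_by_stage: dict,
    test_pairs: dict,
    phantom_masks: dict,
    flavour: str,
) -> list[MetricRecord]:
    """Score generated test images against ground truth.

    ``models_by_stage`` maps stage name → trained translator,
    ``test_pairs`` maps stage name → list of TrainingPair for the test
    split, ``phantom_masks`` maps phantom id → dict with ``anechoic``,
    ``hyperechoic`` and ``background`` boolean rasters on the pair grid.

    Emits, per phantom: gCNR of the B-mode input and of each stage's
    generated image for every non-empty ROI class, and SSIM of each
    generated image against its ground-truth CT (all phantoms; inclusion
    count recorded for 0-vs->0 stratification).  gCNR is skipped entirely
    for inclusion-free phantoms.
    """
    from us2ct.pix2pix import translate  # local import to avoid cycle

    records: list[MetricRecord] = []
    bmode_done: set[str] = set()
    for stage, pairs in test_pairs.items():
        if stage not in models_by_stage:
            raise KeyError(f"no model for stage {stage!r}")
        model = models_by_stage[stage]
        for pair in pairs:
            masks = phantom_masks[pair.phantom_id]
            gen = 0.5 * (translate(model, pair.input_image) + 1.0)
            target = 0.5 * (pair.target_image + 1.0)
            n_inc = int(masks["anechoic"].any()) + int(masks["hyperechoic"].any())
            records.append(
                MetricRecord(pair.phantom_id, stage, flavour, "ssim", "none",
                             ssim(gen, target), n_inc)
            )
            for cls in ("anechoic", "hyperechoic"):
                if not masks[cls].any():
                    continue
                records.append(
                    MetricRecord(pair.phantom_id, stage, flavour, "gcnr", cls,
                                 gcnr(gen, masks[cls], masks["background"]), n_inc)
                )
                if stage == "upsampling" and pair.phantom_id not in bmode_done:
                    bmode = 0.5 * (pair.input_image + 1.0)
                    records.append(
                        MetricRecord(pair.phantom_id, "bmode", flavour, "gcnr",
                                     cls, gcnr(bmode, masks[cls], masks["background"]),
                                     n_inc)
                    )
            if stage == "upsampling":
                bmode_done.add(pair.phantom_id)
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def aggregate_records(records) -> pd.DataFrame:
    """Mean ± SD tables per (flavour, metric, roi_class, stage)."""
    df = records_to_frame(records)
    out = (
        df.groupby(["flavour", "metric", "roi_class", "stage"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return out
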