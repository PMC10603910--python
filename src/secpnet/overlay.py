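"""Qualitative overlays: colour-code agreement between a predicted and a
ground-truth mask for one class on top of the grayscale slice.

Green marks true positives (predicted and labelled), red false positives
(predicted only), blue false negatives (labelled only); every coloured pixel
belongs to exactly one of the three sets, so the colour counts reconcile
with the confusion counts used by the metrics module.
"""

from __future__ import annotations

import numpy as np

__all__ = ["render_overlay", "TP_COLOR", "FP_COLOR", "FN_COLOR"]

TP_COLOR = (0, 255, 0)
FP_COLOR = (255, 0, 0)
FN_COLOR = (0, 0, 255)


def render_overlay(image, pred, truth, cls: int) -> np.ndarray:
    """RGB uint8 overlay for class ``cls``.

    ``image`` is a 2-D grayscale slice (any range; rescaled for display),
    ``pred`` and ``truth`` are integer label masks of the same shape.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3 and image.shape[0] == 1:
        image = image[0]
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if not (image.shape == pred.shape == truth.shape):
        raise ValueError(
            f"shape mismatch: image {image.shape}, pred {pred.shape}, "
            f"truth {truth.shape}"
        )
    lo, hi = image.min(), image.max()
    gray = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
    rgb = np.repeat((gray * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    p = pred == cls
    t = truth == cls
    rgb[p & t] = TP_COLOR
    rgb[p & ~t] = FP_COLOR
    rgb[~p & t] = FN_COLOR
    return rgb
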