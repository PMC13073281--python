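"""Histology-style false-color rendering of decomposed volumes.

Mimics a hematoxylin-eosin look: the soft-tissue fraction forms a pink
morphology backdrop and the lead (stain) fraction is overlaid in
purple, each channel linearly mapped from its display range to opacity
over a white background.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hex_to_rgb", "false_color_overlay", "mean_of_slices"]

TISSUE_COLOR = "#e75acc"
LEAD_COLOR = "#480f62"
TISSUE_RANGE = (0.78, 1.04)
LEAD_RANGE = (0.0, 0.013)


def hex_to_rgb(color: str) -> np.ndarray:
    c = color.lstrip("#")
    return np.array([int(c[i : i + 2], 16) / 255.0 for i in (0, 2, 4)])


def false_color_overlay(
    tissue_fraction: np.ndarray,
    lead_fraction: np.ndarray,
    tissue_range: tuple[float, float] = TISSUE_RANGE,
    lead_range: tuple[float, float] = LEAD_RANGE,
    tissue_color: str = TISSUE_COLOR,
    lead_color: str = LEAD_COLOR,
) -> np.ndarray:
    """RGB image from co-registered tissue/lead fraction slices.

    Values are clamped to their display ranges and scaled linearly to
    opacity: range minimum is fully transparent (white), range maximum
    fully saturated.  The lead overlay sits on top of the tissue
    backdrop.  Returns floats in [0, 1] of shape (H, W, 3).
    """
    t = np.asarray(tissue_fraction, dtype=float)
    s = np.asarray(lead_fraction, dtype=float)
    if t.shape != s.shape or t.ndim != 2:
        raise ValueError("slices must be co-registered 2D arrays")
    t_op = np.clip((t - tissue_range[0]) / (tissue_range[1] - tissue_range[0]), 0, 1)
    s_op = np.clip((s - lead_range[0]) / (lead_range[1] - lead_range[0]), 0, 1)
    pink = hex_to_rgb(tissue_color)
    purple = hex_to_rgb(lead_color)
    out = np.ones((*t.shape, 3))
    out = out * (1.0 - t_op[..., None]) + pink * t_op[..., None]
    out = out * (1.0 - s_op[..., None]) + purple * s_op[..., None]
    return out


def mean_of_slices(volume: np.ndarray, start: int, n: int = 4) -> np.ndarray:
    """Average ``n`` consecutive axial slices (emulates the thicker
    physical sections of conventional histology)."""
    if n < 1 or start < 0 or start + n > volume.shape[0]:
        raise ValueError("slice window outside volume")
    return np.asarray(volume[start : start + n]).mean(axis=0)
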