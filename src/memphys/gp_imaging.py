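"""Per-pixel Laurdan GP maps and high/low-order domain segmentation.

A GP map is computed from a two-channel (blue/red-edge emission) image after
scalar background subtraction of each channel.  Pixels whose corrected
channel sum is non-positive carry no signal and are marked invalid.

Domains are segmented by a single GP threshold: pixels at or above the
threshold form the high-GP (ordered, raft-like) mask, the rest the low-GP
mask, and the fractional area of the high-GP mask is the quantity of
interest.  When images from several conditions are compared, one shared
threshold must be applied to every image; the "auto" rule computes Otsu's
threshold on the pooled GP histogram of the whole comparison set, which is
a deterministic stand-in for a threshold chosen once by eye and applied to
all images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .photophysics import gp_array

__all__ = [
    "GPMap",
    "DomainMasks",
    "gp_map",
    "pooled_threshold",
    "segment_gp_domains",
    "segment_gp_set",
]


@dataclass
class GPMap:
    """Per-pixel generalized polarization with validity mask."""

    gp: np.ndarray
    valid_mask: np.ndarray
    backgrounds: tuple[float, float]  # (bg_blue, bg_red)


@dataclass
class DomainMasks:
    """High/low-GP segmentation of one map within an analysis region."""

    high_mask: np.ndarray
    low_mask: np.ndarray
    threshold: float
    fraction_high: float


def gp_map(
    img_blue: np.ndarray,
    img_red: np.ndarray,
    bg_blue: float = 0.0,
    bg_red: float = 0.0,
) -> GPMap:
    """Background-correct both channels and compute the per-pixel GP.

    Negative corrected intensities are clipped to zero; pixels where the
    corrected channel sum is zero are invalid (gp = NaN there).
    """
    img_blue = np.asarray(img_blue, dtype=float)
    img_red = np.asarray(img_red, dtype=float)
    if img_blue.shape != img_red.shape:
        raise ValueError(
            f"channel shapes differ: {img_blue.shape} vs {img_red.shape}"
        )
    if bg_blue < 0 or bg_red < 0:
        raise ValueError("backgrounds must be non-negative")
    blue = np.clip(img_blue - bg_blue, 0.0, None)
    red = np.clip(img_red - bg_red, 0.0, None)
    gp, valid = gp_array(blue, red)
    return GPMap(gp=gp, valid_mask=valid, backgrounds=(float(bg_blue), float(bg_red)))


def pooled_threshold(maps: list[GPMap], region: np.ndarray | None = None) -> float:
    """Otsu threshold on the pooled GP histogram of a comparison set.

    The same value is then applied to every image in the set (the
    shared-threshold contract).
    """
    pools = []
    for m in maps:
        mask = m.valid_mask if region is None else (m.valid_mask & region)
        pools.append(m.gp[mask])
    values = np.concatenate(pools)
    if values.size == 0:
        raise ValueError("no valid pixels to pool")
    return float(threshold_otsu(values))


def segment_gp_domains(
    gpm: GPMap,
    threshold: float | str = "auto",
    region: np.ndarray | None = None,
) -> DomainMasks:
    """Split a GP map into high- and low-GP masks at a shared threshold.

    ``region`` restricts the analysis (defaults to the valid mask).  With
    ``threshold="auto"`` Otsu's threshold is computed on this map alone; for
    multi-image comparisons compute one :func:`pooled_threshold` and pass it
    here, or use :func:`segment_gp_set`.
    """
    mask = gpm.valid_mask if region is None else (gpm.valid_mask & region)
    if not mask.any():
        raise ValueError("empty analysis region")
    if threshold == "auto":
        threshold = float(threshold_otsu(gpm.gp[mask]))
    else:
        threshold = float(threshold)
    high = mask & (gpm.gp >= threshold)
    low = mask & ~high
    n_high = int(high.sum())
    n_low = int(low.sum())
    return DomainMasks(
        high_mask=high,
        low_mask=low,
        threshold=threshold,
        fraction_high=n_high / (n_high + n_low),
    )


def segment_gp_set(
    maps: list[GPMap],
    threshold: float | str = "auto",
    region: np.ndarray | None = None,
) -> list[DomainMasks]:
    """Segment a comparison set of GP maps with one shared threshold."""
    if not maps:
        raise ValueError("empty comparison set")
    if threshold == "auto":
        threshold = pooled_threshold(maps, region)
    return [segment_gp_domains(m, threshold, region) for m in maps]
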