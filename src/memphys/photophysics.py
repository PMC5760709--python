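"""Scalar fluorometry: steady-state anisotropy and Laurdan generalized polarization.

Both quantities are intensity ratios and therefore invariant to any common
positive rescaling of their inputs (gain, labeling density, cell number).

Anisotropy is measured in the L-format: the sample is excited with vertically
polarized light and the emission is resolved into its vertical (``Ivv``) and
horizontal (``Ivh``) components.  The instrument G factor corrects for the
polarization bias of the detection path and must be supplied from an
instrument calibration; it is never estimated here.

Laurdan generalized polarization (GP) compares the blue (ordered-phase,
~435 nm) and red-edge (~500 nm) emission bands and ranges over [-1, 1]:
high GP reports a dehydrated, ordered bilayer environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnisotropyReading",
    "GPReading",
    "anisotropy",
    "generalized_polarization",
    "gp_array",
]


@dataclass(frozen=True)
class AnisotropyReading:
    """One L-format anisotropy measurement."""

    Ivv: float
    Ivh: float
    G: float
    r: float


@dataclass(frozen=True)
class GPReading:
    """One two-band Laurdan reading."""

    I_blue: float
    I_red: float
    GP: float


def anisotropy(Ivv: float, Ivh: float, G: float = 1.0) -> float:
    """Steady-state fluorescence anisotropy r = (Ivv - G*Ivh) / (Ivv + 2*G*Ivh).

    Parameters
    ----------
    Ivv, Ivh:
        Vertically / horizontally polarized emission intensities (a.u.),
        excited with vertically polarized light.  Must be non-negative.
    G:
        Instrument correction factor (sensitivity ratio of the detection
        system for vertically vs. horizontally polarized light).  Positive.

    Raises
    ------
    ValueError
        If the total intensity ``Ivv + 2*G*Ivh`` is not positive, or if the
        inputs are unphysical (negative intensities, non-positive G).
    """
    if Ivv < 0 or Ivh < 0:
        raise ValueError("intensities must be non-negative")
    if G <= 0:
        raise ValueError("G factor must be positive")
    denom = Ivv + 2.0 * G * Ivh
    if denom <= 0:
        raise ValueError("total intensity Ivv + 2*G*Ivh must be positive")
    return (Ivv - G * Ivh) / denom


def generalized_polarization(I_blue: float, I_red: float) -> float:
    """Laurdan generalized polarization GP = (I_blue - I_red) / (I_blue + I_red).

    Scalar form; use :func:`gp_array` for images, where isolated zero-sum
    pixels are masked instead of raising.

    Raises
    ------
    ValueError
        If ``I_blue + I_red`` is not positive or an intensity is negative.
    """
    if I_blue < 0 or I_red < 0:
        raise ValueError("intensities must be non-negative")
    total = I_blue + I_red
    if total <= 0:
        raise ValueError("I_blue + I_red must be positive")
    return (I_blue - I_red) / total


def gp_array(I_blue: np.ndarray, I_red: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise GP over arrays with an invalid-pixel mask.

    Returns ``(gp, valid)`` where ``valid`` is False wherever the channel sum
    is non-positive (GP undefined there; gp set to NaN).  Shapes must match.
    """
    I_blue = np.asarray(I_blue, dtype=float)
    I_red = np.asarray(I_red, dtype=float)
    if I_blue.shape != I_red.shape:
        raise ValueError(
            f"channel shapes differ: {I_blue.shape} vs {I_red.shape}"
        )
    total = I_blue + I_red
    valid = total > 0
    gp = np.full(I_blue.shape, np.nan)
    np.divide(I_blue - I_red, total, out=gp, where=valid)
    return gp, valid
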