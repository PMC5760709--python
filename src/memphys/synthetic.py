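"""Synthetic data for every analysis stage, with known ground truth.

Each simulator is the exact inverse of its analysis stage in the noiseless
limit: applying the corresponding analysis to a noiseless record recovers
the generating parameters to numerical precision.  Noise is always applied
last.  All randomness flows through an explicit integer seed; identical
(preset, seed) pairs give bit-identical output.

The named presets encode the two experimental conditions of the study this
package models — untreated macrophages ("control") and glucocerebrosidase-
inhibited, sphingolipid-enriched macrophages ("gaucher"):

==================================  =========  =========
quantity                            control    gaucher
==================================  =========  =========
FRAP immobile fraction b            0.15       0.45
median tether force (pN)            30         27
tether count mean +- SD             4.8, 2.4   11.1, 4.3
Young's modulus median / mean (Pa)  614, 1031  459, 795
high-GP area fraction               0.13       0.48
endocytosed transferrin fraction    0.60       0.30
endocytosed cholera toxin B frac.   0.40       0.40
==================================  =========  =========

Distribution shapes for unprinted spreads: tether forces are lognormal with
sigma_log = 0.3 about the preset median (positive support, median
preserved); the Young's modulus is lognormal with sigma fixed by the
median/mean pair, sigma^2 = 2 ln(mean/median), so only the two printed
moments enter; tether counts are rounded truncated normals (min 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .afm import ForceCurve, hertz_coefficient, LOAD_CAP_PN
from .frap import FrapRecord, recovery_model

__all__ = [
    "FrapParams",
    "AfmParams",
    "GPParams",
    "EndoParams",
    "ParamSet",
    "FrapTruth",
    "AfmTruth",
    "GPTruth",
    "CellFieldTruth",
    "TwoChannelImage",
    "ThreeChannelImage",
    "make_preset",
    "simulate_frap_record",
    "simulate_force_curve",
    "simulate_gp_image",
    "simulate_cell_field",
]

PRESET_NAMES = ("control", "gaucher")
LIGANDS = ("transferrin", "ctxb")


# ---------------------------------------------------------------- parameters


@dataclass(frozen=True)
class FrapParams:
    a: float  # extent of bleaching
    b: float  # immobile fraction
    tau: float  # recovery time constant, s
    noise_sd: float = 0.02  # relative intensity noise
    acq_bleach_rate: float = 0.002  # per-frame fractional loss


@dataclass(frozen=True)
class AfmParams:
    E_median: float  # Pa
    E_mean: float  # Pa
    tether_count_mean: float
    tether_count_sd: float
    tether_force_median: float  # pN
    force_noise_sd: float = 2.0  # pN
    spring_constant: float = 0.03  # N/m
    tether_force_sigma_log: float = 0.3

    @property
    def E_sigma_log(self) -> float:
        """Lognormal sigma fixed by the printed mean/median pair."""
        return math.sqrt(2.0 * math.log(self.E_mean / self.E_median))


@dataclass(frozen=True)
class GPParams:
    high_area_fraction: float
    gp_high: float = -0.55
    gp_low: float = -0.85
    domain_length_scale: float = 8.0  # px
    photon_noise: float = 0.05  # relative


@dataclass(frozen=True)
class EndoParams:
    f_endo: float
    n_cells: int = 100
    nucleus_radius: int = 10  # px
    cell_radius: int = 24  # px
    membrane_thickness: int = 5  # px
    f_cell_sd: float = 0.05  # cell-to-cell spread of the true fraction


@dataclass(frozen=True)
class ParamSet:
    preset_name: str
    frap: FrapParams
    afm: AfmParams
    gp: GPParams
    endo: EndoParams

    def __post_init__(self) -> None:
        fr, gp, en = self.frap, self.gp, self.endo
        for name, v in (
            ("frap.a", fr.a),
            ("frap.b", fr.b),
            ("gp.high_area_fraction", gp.high_area_fraction),
            ("endo.f_endo", en.f_endo),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if fr.tau <= 0:
            raise ValueError("frap.tau must be positive")
        if self.afm.E_median <= 0 or self.afm.spring_constant <= 0:
            raise ValueError("afm.E_median and spring_constant must be positive")
        if self.afm.E_mean < self.afm.E_median:
            raise ValueError("afm.E_mean must be >= E_median for a lognormal")


_PRESETS = {
    "control": dict(
        frap=dict(a=0.6, b=0.15, tau=15.0),
        afm=dict(
            E_median=614.0,
            E_mean=1031.0,
            tether_count_mean=4.8,
            tether_count_sd=2.4,
            tether_force_median=30.0,
        ),
        gp=dict(high_area_fraction=0.13),
        endo=dict(transferrin=0.60, ctxb=0.40),
    ),
    "gaucher": dict(
        frap=dict(a=0.6, b=0.45, tau=30.0),
        afm=dict(
            E_median=459.0,
            E_mean=795.0,
            tether_count_mean=11.1,
            tether_count_sd=4.3,
            tether_force_median=27.0,
        ),
        gp=dict(high_area_fraction=0.48),
        endo=dict(transferrin=0.30, ctxb=0.40),
    ),
}


def make_preset(name: str, ligand: str = "transferrin") -> ParamSet:
    """Build the fully populated parameter set for a named condition.

    ``ligand`` selects the endocytosis tracer: "transferrin" (clathrin
    pathway, 45-min condition) or "ctxb" (cholera toxin subunit B, raft
    pathway, 40-min condition).
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    if ligand not in LIGANDS:
        raise ValueError(f"unknown ligand {ligand!r}; available: {', '.join(LIGANDS)}")
    p = _PRESETS[name]
    return ParamSet(
        preset_name=name,
        frap=FrapParams(**p["frap"]),
        afm=AfmParams(**p["afm"]),
        gp=GPParams(**p["gp"]),
        endo=EndoParams(f_endo=p["endo"][ligand]),
    )


# --------------------------------------------------------------- FRAP records


@dataclass
class FrapTruth:
    a: float
    b: float
    tau: float


def simulate_frap_record(
    params: ParamSet,
    seed: int,
    n_pre: int = 10,
    n_post: int = 150,
    dt: float = 1.0,
) -> tuple[FrapRecord, FrapTruth]:
    """Simulate raw FRAP ROI traces whose double-normalized recovery is exact.

    The record is built by inverting the double-normalization: a constant
    background, a whole-membrane trace with multiplicative per-frame
    acquisition bleaching, and a bleached-ROI trace constructed so that
    applying the double normalization to the noiseless record reproduces
    the empirical recovery curve with the preset (a, b, tau) exactly.
    Relative Gaussian noise is applied last.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_pre < 1 or n_post < 10:
        raise ValueError("need n_pre >= 1 and n_post >= 10")
    fp = params.frap
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    t = np.arange(n) * dt
    decay = (1.0 - fp.acq_bleach_rate) ** np.arange(n)

    bg_level, A, B = 50.0, 800.0, 5000.0
    R = np.ones(n)
    t_post = t[n_pre:] - t[n_pre]
    R[n_pre:] = recovery_model(t_post, 1.0, fp.a, fp.b, fp.tau)

    I = bg_level + A * decay * R
    T = bg_level + B * decay
    bg = np.full(n, bg_level)
    if fp.noise_sd > 0:
        I = I * (1.0 + fp.noise_sd * rng.standard_normal(n))
        T = T * (1.0 + fp.noise_sd * rng.standard_normal(n))
        bg = bg + bg_level * fp.noise_sd * rng.standard_normal(n)
    record = FrapRecord(t=t, I=I, T=T, bg=bg, bleach_index=n_pre)
    return record, FrapTruth(a=fp.a, b=fp.b, tau=fp.tau)


# --------------------------------------------------------------- force curves


@dataclass
class AfmTruth:
    contact_point: float  # nm
    E: float  # Pa
    step_positions: np.ndarray  # nm, ascending
    step_heights: np.ndarray  # pN
    tether_count: int


@lru_cache(maxsize=None)
def _truncnorm_loc(mean: float, sd: float) -> float:
    """Location of a zero-truncated normal whose truncated mean equals ``mean``.

    Truncating at zero shifts the mean upward; the location is solved so the
    distribution still matches the printed mean (the SD stays at its printed
    value as the scale parameter).
    """

    def truncated_mean(mu: float) -> float:
        return float(stats.truncnorm.mean((0.0 - mu) / sd, np.inf, loc=mu, scale=sd))

    return float(brentq(lambda mu: truncated_mean(mu) - mean, -sd, mean + sd))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0:
        return max(mean, 0.0)
    loc = _truncnorm_loc(mean, sd)
    for _ in range(1000):
        x = rng.normal(loc, sd)
        if x >= 0:
            return x
    return 0.0


def simulate_force_curve(
    params: ParamSet,
    seed: int,
    n_points: int = 3000,
    approach_nm: float = 1500.0,
    retract_span_nm: float = 4500.0,
    tether_range_nm: tuple[float, float] = (300.0, 3800.0),
) -> tuple[dict[str, ForceCurve], AfmTruth]:
    """Simulate one extension/retraction force-curve pair.

    Extension: flat zero baseline above the contact point, then a pyramidal
    Hertz indentation F = C * E * delta^2 truncated at the 1 nN load cap;
    the per-curve modulus is drawn from the preset lognormal.  The contact
    point falls exactly on a sample of the uniform separation grid.

    Retraction: the tether count is a rounded truncated normal, step
    heights are lognormal about the preset median, rupture separations are
    uniform over ``tether_range_nm``; the force is minus the running sum of
    unruptured tether forces (adhesive forces negative) plus Gaussian noise.

    Returns ``{"extend": ..., "retract": ...}`` and the ground truth.
    """
    if n_points < 200:
        raise ValueError("need at least 200 points per segment")
    ap = params.afm
    rng = np.random.default_rng(seed)

    E = float(ap.E_median * math.exp(ap.E_sigma_log * rng.standard_normal()))
    s_c = float(rng.uniform(1500.0, 2500.0))
    C = hertz_coefficient()
    delta_max = min(math.sqrt(LOAD_CAP_PN / (C * E * 1e-6)), 3000.0)
    span = approach_nm + delta_max
    h = span / (n_points - 1)
    n_base = max(20, int(round(approach_nm / h)))
    s_ext = s_c + (n_base - np.arange(n_points)) * h
    delta = np.clip(s_c - s_ext, 0.0, None)
    f_ext = C * E * 1e-6 * delta**2

    n_teth = int(round(_truncated_normal(rng, ap.tether_count_mean, ap.tether_count_sd)))
    heights = ap.tether_force_median * np.exp(
        ap.tether_force_sigma_log * rng.standard_normal(n_teth)
    )
    positions = rng.uniform(*tether_range_nm, size=n_teth)
    order = np.argsort(positions)
    positions, heights = positions[order], heights[order]

    s_ret = np.linspace(0.0, retract_span_nm, n_points)
    f_ret = -(heights[None, :] * (s_ret[:, None] < positions[None, :])).sum(axis=1)

    if ap.force_noise_sd > 0:
        f_ext = f_ext + rng.normal(0.0, ap.force_noise_sd, n_points)
        f_ret = f_ret + rng.normal(0.0, ap.force_noise_sd, n_points)

    curves = {
        "extend": ForceCurve(
            separation=s_ext,
            force=f_ext,
            segment="extend",
            spring_constant=ap.spring_constant,
        ),
        "retract": ForceCurve(
            separation=s_ret,
            force=f_ret,
            segment="retract",
            spring_constant=ap.spring_constant,
        ),
    }
    truth = AfmTruth(
        contact_point=s_c,
        E=E,
        step_positions=positions,
        step_heights=heights,
        tether_count=n_teth,
    )
    return curves, truth


# ------------------------------------------------------------------ GP images


@dataclass
class TwoChannelImage:
    blue: np.ndarray
    red: np.ndarray
    backgrounds: tuple[float, float]  # additive background per channel


@dataclass
class GPTruth:
    domain_mask: np.ndarray
    true_fraction: float
    gp_high: float
    gp_low: float


def simulate_gp_image(
    params: ParamSet,
    seed: int,
    shape: tuple[int, int] = (512, 512),
    total_intensity: float = 1000.0,
    background: float = 50.0,
) -> tuple[TwoChannelImage, GPTruth]:
    """Simulate a two-channel Laurdan image with a known high-GP area fraction.

    The domain mask comes from a Gaussian-smoothed random field thresholded
    at the quantile that yields the preset area fraction (exact up to
    quantile ties).  Channel intensities are chosen so that the GP formula
    returns ``gp_high`` inside domains and ``gp_low`` outside; multiplicative
    photon noise is applied to the signal, then the additive background
    (recorded in the image metadata) is added to both channels.
    """
    gp = params.gp
    if not (-1.0 < gp.gp_low < 1.0 and -1.0 < gp.gp_high < 1.0):
        raise ValueError("gp_high and gp_low must lie in (-1, 1)")
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("image must be at least 64x64")
    rng = np.random.default_rng(seed)
    frac = gp.high_area_fraction
    if frac <= 0.0:
        mask = np.zeros(shape, dtype=bool)
    elif frac >= 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        fieldv = gaussian_filter(rng.standard_normal(shape), gp.domain_length_scale)
        mask = fieldv > np.quantile(fieldv, 1.0 - frac)

    gp_img = np.where(mask, gp.gp_high, gp.gp_low)
    s_blue = total_intensity * (1.0 + gp_img) / 2.0
    s_red = total_intensity * (1.0 - gp_img) / 2.0
    if gp.photon_noise > 0:
        s_blue = s_blue * (1.0 + gp.photon_noise * rng.standard_normal(shape))
        s_red = s_red * (1.0 + gp.photon_noise * rng.standard_normal(shape))
    img = TwoChannelImage(
        blue=s_blue + background,
        red=s_red + background,
        backgrounds=(background, background),
    )
    truth = GPTruth(
        domain_mask=mask,
        true_fraction=float(mask.mean()),
        gp_high=gp.gp_high,
        gp_low=gp.gp_low,
    )
    return img, truth


# ---------------------------------------------------------------- cell fields


@dataclass
class ThreeChannelImage:
    dapi: np.ndarray
    membrane: np.ndarray
    ligand: np.ndarray
    backgrounds: tuple[float, float, float]


@dataclass
class CellFieldTruth:
    f_per_cell: np.ndarray  # true intracellular fraction, by cell label - 1
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    membrane_labels: np.ndarray
    interior_labels: np.ndarray
    centers: np.ndarray  # (n, 2) row/col
    radii: np.ndarray


def simulate_cell_field(
    params: ParamSet,
    seed: int,
    shape: tuple[int, int] | None = None,
    ligand_total: float = 2.0e5,
    background: float = 20.0,
    noise_sd: float = 3.0,
) -> tuple[ThreeChannelImage, CellFieldTruth]:
    """Simulate a DAPI/membrane/ligand cell field with known per-cell fractions.

    Round cells are laid out on a jittered grid (no overlap by
    construction).  Channel 1 carries the nuclei (disks), channel 2 the
    membrane marker (a radial ridge peaking at the cell outline) and
    channel 3 the ligand: a fraction ``f`` of each cell's total signal is
    spread uniformly over the cell interior and ``1 - f`` over an inner
    band of the membrane shell, keeping one pixel clear of the segmentation
    boundary on either side so that the readout is limited by noise rather
    than by partial-volume edge pixels.  Per-cell true fractions are drawn
    around the preset ``f_endo`` with a small spread and recorded in the
    truth.
    """
    en = params.endo
    rng = np.random.default_rng(seed)
    n = en.n_cells
    mt = en.membrane_thickness
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    rmax = int(math.ceil(1.08 * en.cell_radius))
    pitch = 2 * rmax + 10
    pad = rmax + 8
    need = (pitch * (nrows - 1) + 2 * pad + 1, pitch * (ncols - 1) + 2 * pad + 1)
    if shape is None:
        shape = need
    elif shape[0] < need[0] or shape[1] < need[1]:
        raise ValueError(
            f"{n} cells of radius {en.cell_radius} px need at least {need}, got {shape}"
        )

    dapi = np.zeros(shape)
    mem = np.zeros(shape)
    lig = np.zeros(shape)
    nuc_lab = np.zeros(shape, dtype=np.int32)
    cell_lab = np.zeros(shape, dtype=np.int32)
    mem_lab = np.zeros(shape, dtype=np.int32)
    int_lab = np.zeros(shape, dtype=np.int32)
    f_cells = np.empty(n)
    centers = np.empty((n, 2))
    radii = np.empty(n)

    for i in range(n):
        row, col = divmod(i, ncols)
        cy = pad + row * pitch + rng.uniform(-2, 2)
        cx = pad + col * pitch + rng.uniform(-2, 2)
        R = en.cell_radius * rng.uniform(0.92, 1.08)
        f = float(np.clip(rng.normal(en.f_endo, en.f_cell_sd), 0.0, 1.0))
        lab = i + 1
        f_cells[i] = f
        centers[i] = (cy, cx)
        radii[i] = R

        b = int(math.ceil(R)) + 6
        y0, y1 = int(cy) - b, int(cy) + b + 1
        x0, x1 = int(cx) - b, int(cx) + b + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(yy - cy, xx - cx)

        cell = dist <= R
        interior = dist <= R - mt
        membrane = cell & ~interior
        nucleus = dist <= en.nucleus_radius
        # ligand pools keep 1 px clear of the mask boundaries
        pool_mem = (dist <= R - 1.0) & (dist >= R - mt + 1.0)
        pool_int = dist <= R - mt - 2.0

        box = (slice(y0, y1), slice(x0, x1))
        nuc_lab[box][nucleus] = lab
        cell_lab[box][cell] = lab
        mem_lab[box][membrane] = lab
        int_lab[box][interior] = lab
        dapi[box][nucleus] += 200.0
        mem[box] += 200.0 * np.exp(-((dist - R) ** 2) / (2.0 * 2.0**2))
        lig[box][pool_int] += f * ligand_total / pool_int.sum()
        lig[box][pool_mem] += (1.0 - f) * ligand_total / pool_mem.sum()

    for ch in (dapi, mem, lig):
        ch += background
        if noise_sd > 0:
            ch += rng.normal(0.0, noise_sd, shape)
        np.clip(ch, 0.0, None, out=ch)

    img = ThreeChannelImage(
        dapi=dapi,
        membrane=mem,
        ligand=lig,
        backgrounds=(background, background, background),
    )
    truth = CellFieldTruth(
        f_per_cell=f_cells,
        nucleus_labels=nuc_lab,
        cell_labels=cell_lab,
        membrane_labels=mem_lab,
        interior_labels=int_lab,
        centers=centers,
        radii=radii,
    )
    return img, truth
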