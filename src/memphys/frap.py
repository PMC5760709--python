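"""FRAP curve normalization, averaging and empirical recovery fitting.

A FRAP record holds three raw ROI intensity traces sampled at the frame
times: the bleached ROI ``I``, the whole membrane mask ``T`` and a
background ROI ``bg``.  Raw traces are double-normalized,

    R(t) = [(I(t) - bg(t)) / (I0 - bg0)] * [(T0 - bg0) / (T(t) - bg(t))],

where the "0" quantities are means over the pre-bleach frames.  The first
factor normalizes to the pre-bleach intensity; the second cancels
acquisition bleaching during recovery, which is why R is invariant to any
per-frame decay applied to both I and T.

The empirical recovery model fitted to the mean post-bleach curve is

    R(t) = R(0) - a + a * (1 - b) * (1 - exp(-t / tau)),

with ``a`` the extent of bleaching, ``b`` the immobile fraction (the part of
the bleached population that never exchanges on the experimental timescale)
and ``tau`` the empirical recovery time constant.  R(0) is fixed to the
pre-bleach mean: the model has three free parameters, and releasing the
offset degrades their identifiability.  The fitted asymptote is
R(0) - a*b.  95% confidence bounds come from the fit covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "FrapRecord",
    "NormalizedCurve",
    "FrapFit",
    "recovery_model",
    "double_normalize",
    "average_curves",
    "fit_recovery",
    "ci_overlap",
    "read_record_csv",
    "write_curve_csv",
]


@dataclass
class FrapRecord:
    """Raw ROI intensity traces of one FRAP experiment.

    ``bleach_index`` is the index of the first post-bleach frame; frames
    ``0 .. bleach_index-1`` are pre-bleach.
    """

    t: np.ndarray
    I: np.ndarray
    T: np.ndarray
    bg: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.bg = np.asarray(self.bg, dtype=float)
        n = len(self.t)
        if not (len(self.I) == len(self.T) == len(self.bg) == n):
            raise ValueError(
                "t, I, T, bg must have equal lengths; got "
                f"{n}, {len(self.I)}, {len(self.T)}, {len(self.bg)}"
            )
        if not 1 <= self.bleach_index < n:
            raise ValueError("bleach_index must satisfy 1 <= bleach_index < n")
        if np.any(self.I < 0) or np.any(self.T < 0):
            raise ValueError("I and T must be non-negative")


@dataclass
class NormalizedCurve:
    """Double-normalized recovery curve R(t), possibly an average of several."""

    t: np.ndarray
    R: np.ndarray
    bleach_index: int
    n_averaged: int = 1
    sem: np.ndarray | None = None

    @property
    def pre_bleach_mean(self) -> float:
        return float(np.mean(self.R[: self.bleach_index]))


@dataclass
class FrapFit:
    """Fitted empirical recovery parameters with 95% confidence bounds.

    ``ci95`` maps parameter name -> (lower, upper).  ``flags`` records
    degeneracies: ``"b_at_bound"`` when the immobile fraction is pinned at 0
    or 1, ``"tau_unidentifiable"`` when the mobile amplitude a*(1-b) is too
    small for the time constant to be determined.
    """

    R0: float
    a: float
    b: float
    tau: float
    ci95: dict[str, tuple[float, float]]
    residual_rms: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "R0": self.R0,
            "a": self.a,
            "b": self.b,
            "tau": self.tau,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "residual_rms": self.residual_rms,
            "flags": list(self.flags),
            "ci_method": "covariance",
        }


def recovery_model(t: np.ndarray, R0: float, a: float, b: float, tau: float) -> np.ndarray:
    """Empirical recovery curve; ``t`` measured from the bleach pulse."""
    t = np.asarray(t, dtype=float)
    return R0 - a + a * (1.0 - b) * (1.0 - np.exp(-t / tau))


def double_normalize(record: FrapRecord) -> NormalizedCurve:
    """Double-normalize a raw FRAP record.

    Pre-bleach reference intensities are means over all pre-bleach frames.
    Raises ``ValueError`` naming the first offending frame if a corrected
    denominator is non-positive.
    """
    k = record.bleach_index
    I0 = float(np.mean(record.I[:k]))
    T0 = float(np.mean(record.T[:k]))
    bg0 = float(np.mean(record.bg[:k]))
    if I0 - bg0 <= 0:
        raise ValueError("pre-bleach bleached-ROI intensity I(0)-bg(0) is non-positive")
    if T0 - bg0 <= 0:
        raise ValueError("pre-bleach membrane intensity T(0)-bg(0) is non-positive")
    T_corr = record.T - record.bg
    bad = np.flatnonzero(T_corr <= 0)
    if bad.size:
        raise ValueError(f"membrane intensity T-bg non-positive at frame {bad[0]}")
    R = (record.I - record.bg) / (I0 - bg0) * (T0 - bg0) / T_corr
    return NormalizedCurve(t=record.t.copy(), R=R, bleach_index=k)


def average_curves(
    curves: list[NormalizedCurve], resample: bool = False
) -> NormalizedCurve:
    """Pointwise mean of normalized curves, with per-point SEM.

    Curves must share the time grid and bleach index; with ``resample=True``
    later curves are linearly interpolated onto the first curve's grid.
    """
    if not curves:
        raise ValueError("cannot average an empty list of curves")
    ref = curves[0]
    rows = []
    for c in curves:
        if c.bleach_index != ref.bleach_index:
            raise ValueError("curves have differing bleach indices")
        if np.array_equal(c.t, ref.t):
            rows.append(c.R)
        elif resample:
            rows.append(np.interp(ref.t, c.t, c.R))
        else:
            raise ValueError(
                "curves are on different time grids; pass resample=True"
            )
    stack = np.asarray(rows)
    n = sum(c.n_averaged for c in curves)
    mean = stack.mean(axis=0)
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        if stack.shape[0] > 1
        else None
    )
    return NormalizedCurve(
        t=ref.t.copy(), R=mean, bleach_index=ref.bleach_index, n_averaged=n, sem=sem
    )


def fit_recovery(curve: NormalizedCurve) -> FrapFit:
    """Fit the empirical recovery model to the post-bleach part of a curve.

    R(0) is fixed to the pre-bleach mean.  Bounded trust-region least
    squares over a, b in [0, 1] and tau in (0, 10 * t_max]; the post-bleach
    time axis is shifted so t = 0 at the first post-bleach frame.
    """
    k = curve.bleach_index
    t_post = curve.t[k:] - curve.t[k]
    R_post = curve.R[k:]
    if len(t_post) < 10:
        raise ValueError("need at least 10 post-bleach points to fit")
    R0 = curve.pre_bleach_mean

    t_max = float(t_post[-1]) if t_post[-1] > 0 else 1.0
    a0 = float(np.clip(R0 - R_post[0], 1e-6, 1.0))
    b0 = 0.2
    # crude half-recovery time as tau start
    amp = R_post[-1] - R_post[0]
    if amp > 1e-12:
        half = R_post[0] + 0.5 * amp
        idx = np.argmax(R_post >= half)
        tau0 = float(np.clip(t_post[idx] / np.log(2.0), 1e-3, 10.0 * t_max))
    else:
        tau0 = t_max / 5.0

    def resid(p: np.ndarray) -> np.ndarray:
        return recovery_model(t_post, R0, p[0], p[1], p[2]) - R_post

    res = least_squares(
        resid,
        x0=[a0, b0, tau0],
        bounds=([0.0, 0.0, 1e-9], [1.0, 1.0, 10.0 * t_max]),
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not res.success:
        raise RuntimeError(f"recovery fit did not converge (last iterate {res.x})")
    a, b, tau = (float(v) for v in res.x)

    n, p = len(t_post), 3
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    JTJ = res.jac.T @ res.jac
    flags: list[str] = []
    try:
        cov = s2 * np.linalg.inv(JTJ)
        # R0 is held fixed but is itself a noisy estimate; propagate its
        # variance (pre-bleach scatter of the mean) into the parameters:
        # d(theta)/dR0 = (J^T J)^{-1} J^T 1 since d(resid)/dR0 = 1.
        k_pre = curve.bleach_index
        if k_pre >= 2:
            var_R0 = float(np.var(curve.R[:k_pre], ddof=1)) / k_pre
            dtheta = np.linalg.solve(JTJ, res.jac.T @ np.ones(n))
            cov = cov + var_R0 * np.outer(dtheta, dtheta)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    tval = stats.t.ppf(0.975, dof)
    names = ("a", "b", "tau")
    ci95 = {
        nm: (float(v - tval * s), float(v + tval * s))
        for nm, v, s in zip(names, (a, b, tau), se)
    }
    if b <= 1e-6 or b >= 1.0 - 1e-6:
        flags.append("b_at_bound")
    mobile_amp = a * (1.0 - b)
    if mobile_amp < 5.0 * np.sqrt(s2) or not np.isfinite(se[2]) or se[2] > 10.0 * tau:
        flags.append("tau_unidentifiable")
    return FrapFit(
        R0=R0,
        a=a,
        b=b,
        tau=tau,
        ci95=ci95,
        residual_rms=float(np.sqrt(s2)),
        flags=flags,
    )


def ci_overlap(fit1: FrapFit, fit2: FrapFit, param: str) -> bool:
    """True when the 95% confidence intervals of ``param`` overlap.

    Non-overlap is the significance rule used when comparing two fitted
    conditions (e.g. control vs. sphingolipid-enriched cells).
    """
    lo1, hi1 = fit1.ci95[param]
    lo2, hi2 = fit2.ci95[param]
    return lo1 <= hi2 and lo2 <= hi1


def read_record_csv(path) -> FrapRecord:
    """Read a raw FRAP record from CSV with columns t, I, T, bg, post_bleach.

    ``post_bleach`` is 0 for pre-bleach frames and 1 afterwards.
    """
    df = pd.read_csv(path)
    required = {"t", "I", "T", "bg", "post_bleach"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FRAP CSV missing columns: {sorted(missing)}")
    flags = df["post_bleach"].to_numpy().astype(int)
    post = np.flatnonzero(flags)
    if post.size == 0:
        raise ValueError("no post-bleach frames flagged")
    return FrapRecord(
        t=df["t"].to_numpy(float),
        I=df["I"].to_numpy(float),
        T=df["T"].to_numpy(float),
        bg=df["bg"].to_numpy(float),
        bleach_index=int(post[0]),
    )


def write_curve_csv(curve: NormalizedCurve, path) -> None:
    """Write a normalized curve (and SEM when averaged) to CSV."""
    data = {"t": curve.t, "R": curve.R}
    if curve.sem is not None:
        data["sem"] = curve.sem
    df = pd.DataFrame(data)
    df["post_bleach"] = (np.arange(len(curve.t)) >= curve.bleach_index).astype(int)
    df.to_csv(path, index=False)
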