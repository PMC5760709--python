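"""AFM force-curve analysis: Hertzian elasticity and membrane-tether steps.

Extension (approach) segments are analyzed for the contact point and the
Young's modulus of the cell.  The indenter is a four-sided pyramid, for
which the Hertzian contact force at indentation depth delta is

    F = [E / (1 - nu^2)] * (tan(alpha) / sqrt(2)) * delta^2

with nu the Poisson ratio (0.5 for an incompressible cell) and alpha the
face half-angle of the tip.  Units throughout: separation in nm, force in
pN, modulus in Pa (1 Pa = 1e-6 pN/nm^2).

Retraction segments are analyzed for tether-rupture steps.  When the
cantilever retracts, membrane nanotubes (tethers) pulled from the cell
detach one by one, each producing an abrupt force jump whose magnitude is
the single-tether force.  Two independent detectors are run:

* algorithm A — iterative step-function fitting: breakpoints are added
  greedily where they maximally reduce the residual variance of a
  piecewise-constant fit, while the step height at the new breakpoint
  exceeds ``k`` robust noise SDs;
* algorithm B — thresholding of a smoothed derivative with a minimum event
  separation.

The default report is the consensus: events found by both detectors within
a matching window.  Step heights are reported as magnitudes; adhesive
(tether) forces are negative on retraction by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "StepEvents",
    "HertzFit",
    "ModulusProfile",
    "TetherStats",
    "NoContactError",
    "hertz_coefficient",
    "find_contact_point",
    "fit_hertz",
    "detect_steps",
    "tether_statistics",
    "modulus_height_profile",
    "read_force_csv",
    "write_force_csv",
]

LOAD_CAP_PN = 1000.0  # 1 nN acquisition load cap


class NoContactError(ValueError):
    """Raised when an extension curve shows no super-noise deflection."""


@dataclass
class ForceCurve:
    """One segment of a force-vs-separation record."""

    separation: np.ndarray  # nm
    force: np.ndarray  # pN
    segment: str  # "extend" or "retract"
    spring_constant: float = 0.03  # N/m
    dwell_s: float = 5.0
    velocity: float = 2.0  # um/s

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.segment not in ("extend", "retract"):
            raise ValueError("segment must be 'extend' or 'retract'")
        if self.separation.shape != self.force.shape:
            raise ValueError("separation and force must have equal lengths")
        d = np.diff(self.separation)
        if not (np.all(d >= 0) or np.all(d <= 0)):
            raise ValueError("separation must be monotone within a segment")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")


@dataclass
class StepEvents:
    """Detected tether-rupture steps on one retraction segment."""

    positions: np.ndarray  # nm, ascending
    heights: np.ndarray  # pN magnitudes
    detector: str  # "algA", "algB" or "consensus"

    @property
    def n_steps(self) -> int:
        return len(self.positions)


@dataclass
class HertzFit:
    """Pyramidal-tip Hertz fit of one extension segment."""

    E: float  # Pa
    contact_point: float  # nm
    nu: float
    half_angle: float  # degrees
    fit_range: tuple[float, float]  # nm separation interval used
    residual: float  # pN RMS
    flags: list[str] = field(default_factory=list)


@dataclass
class ModulusProfile:
    """Mean Young's modulus binned by height above the substrate."""

    bin_edges: np.ndarray  # nm, length n_bins + 1
    mean_E: np.ndarray  # Pa, NaN where empty
    n_per_bin: np.ndarray


@dataclass
class TetherStats:
    """Pooled tether statistics over a set of retraction curves."""

    heights: np.ndarray  # pN, pooled over curves
    counts: np.ndarray  # steps per curve
    median_force: float
    count_mean: float
    count_sd: float
    force_histogram: pd.DataFrame
    count_histogram: pd.DataFrame


def hertz_coefficient(nu: float = 0.5, half_angle: float = 35.0) -> float:
    """Geometry factor C such that F[pN] = C * E[Pa] * 1e-6 * delta[nm]^2."""
    return np.tan(np.radians(half_angle)) / (np.sqrt(2.0) * (1.0 - nu**2))


def _chronological_extend(curve: ForceCurve) -> tuple[np.ndarray, np.ndarray]:
    """Extension arrays ordered by decreasing separation (approach order)."""
    s, f = curve.separation, curve.force
    if s[0] < s[-1]:
        s, f = s[::-1], f[::-1]
    return s, f


def _robust_noise_sd(force: np.ndarray) -> float:
    d = np.diff(force)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0)) or 1e-12


def find_contact_point(curve: ForceCurve, min_baseline: int = 20) -> float:
    """Locate the tip-sample contact point on an extension segment.

    The curve is modeled as a flat baseline followed by a quadratic contact
    region; the returned separation is the breakpoint minimizing the total
    squared error.  A constant force offset is absorbed by the baseline and
    does not move the detected point.
    """
    if curve.segment != "extend":
        raise ValueError("contact point is defined on extension segments")
    s, f = _chronological_extend(curve)
    n = len(f)
    if n < min_baseline + 5:
        raise ValueError("extension segment too short for contact detection")

    sigma = _robust_noise_sd(f)
    baseline0 = np.median(f[:min_baseline])
    if np.max(f) - baseline0 < max(5.0 * sigma, 1e-9):
        raise NoContactError("no super-threshold deflection found on extension")

    cum = np.concatenate([[0.0], np.cumsum(f)])
    cum2 = np.concatenate([[0.0], np.cumsum(f * f)])

    def sse_for(j: int) -> float:
        # baseline over [0, j), quadratic contact for samples j..n-1
        f0 = cum[j] / j
        sse_base = cum2[j] - j * f0 * f0
        delta2 = (s[j] - s[j:]) ** 2
        y = f[j:] - f0
        denom = float(delta2 @ delta2)
        c = max(float(y @ delta2) / denom, 0.0) if denom > 0 else 0.0
        r = y - c * delta2
        return sse_base + float(r @ r)

    lo, hi = min_baseline, n - 5
    stride = max(1, (hi - lo) // 256)
    coarse = list(range(lo, hi, stride))
    j_best = min(coarse, key=sse_for)
    if stride > 1:
        fine = range(max(lo, j_best - stride), min(hi, j_best + stride + 1))
        j_best = min(fine, key=sse_for)
    return float(s[j_best])


def fit_hertz(
    curve: ForceCurve,
    nu: float = 0.5,
    half_angle: float = 35.0,
    contact_point: float | None = None,
    load_cap_pN: float = LOAD_CAP_PN,
) -> HertzFit:
    """Fit the pyramidal-tip Hertz model to an extension segment.

    The fit range runs from the contact point to the load cap (mirroring
    the acquisition protocol, which stops at 1 nN).  The pre-contact
    baseline offset is subtracted before fitting, so the result is
    invariant to a constant force offset.  A negative least-squares modulus
    is clamped to zero and flagged.
    """
    if contact_point is None:
        contact_point = find_contact_point(curve)
    s, f = _chronological_extend(curve)
    pre = s > contact_point
    if np.count_nonzero(pre) < 2:
        raise ValueError("no pre-contact baseline available")
    baseline = float(np.mean(f[pre]))
    fc = f - baseline
    in_contact = (s <= contact_point) & (fc <= load_cap_pN)
    if np.count_nonzero(in_contact) < 5:
        raise ValueError("empty indentation range up to the load cap")
    delta2 = (contact_point - s[in_contact]) ** 2
    y = fc[in_contact]
    C = hertz_coefficient(nu, half_angle)
    denom = C * 1e-6 * float(delta2 @ delta2)
    E = float(y @ delta2) / denom if denom > 0 else 0.0
    flags = []
    if E < 0:
        E = 0.0
        flags.append("clamped_nonnegative")
    resid = y - C * E * 1e-6 * delta2
    rms = float(np.sqrt(np.mean(resid**2)))
    return HertzFit(
        E=E,
        contact_point=float(contact_point),
        nu=nu,
        half_angle=half_angle,
        fit_range=(float(np.min(s[in_contact])), float(contact_point)),
        residual=rms,
        flags=flags,
    )


def _seg_sse(cum: np.ndarray, cum2: np.ndarray, a: int, b: int) -> float:
    """SSE of samples [a, b) about their mean, from prefix sums."""
    n = b - a
    s = cum[b] - cum[a]
    return float(cum2[b] - cum2[a] - s * s / n)


def _steps_algA(
    f: np.ndarray, sigma: float, k: float, min_segment: int, max_steps: int = 200
) -> list[tuple[int, float]]:
    """Greedy iterative step-function fitting; returns (index, height) pairs.

    ``index`` is the first sample after the step.  Heights are recomputed
    from the final piecewise-constant fit and filtered at k*sigma.
    """
    n = len(f)
    cum = np.concatenate([[0.0], np.cumsum(f)])
    cum2 = np.concatenate([[0.0], np.cumsum(f * f)])

    def best_split(a: int, b: int) -> tuple[int, float, float] | None:
        # best breakpoint m in (a, b); returns (m, gain, height)
        if b - a < 2 * min_segment:
            return None
        ms = np.arange(a + min_segment, b - min_segment + 1)
        if ms.size == 0:
            return None
        nl = ms - a
        nr = b - ms
        sl = cum[ms] - cum[a]
        sr = cum[b] - cum[ms]
        sse = (cum2[ms] - cum2[a] - sl * sl / nl) + (cum2[b] - cum2[ms] - sr * sr / nr)
        i = int(np.argmin(sse))
        m = int(ms[i])
        gain = _seg_sse(cum, cum2, a, b) - float(sse[i])
        height = abs(sr[i] / nr[i] - sl[i] / nl[i])
        return m, gain, height

    breaks: list[int] = []
    segments = [(0, n)]
    for _ in range(max_steps):
        candidates = []
        for a, b in segments:
            c = best_split(a, b)
            if c is not None:
                candidates.append((a, b, *c))
        if not candidates:
            break
        a, b, m, gain, height = max(candidates, key=lambda c: c[3])
        if height <= k * sigma:
            break
        breaks.append(m)
        segments.remove((a, b))
        segments.extend([(a, m), (m, b)])
    breaks.sort()
    edges = [0] + breaks + [n]
    means = [
        (cum[b] - cum[a]) / (b - a) for a, b in zip(edges[:-1], edges[1:])
    ]
    events = []
    for i, m in enumerate(breaks):
        h = abs(means[i + 1] - means[i])
        if h > k * sigma:
            events.append((m, h))
    return events


def _steps_algB(
    f: np.ndarray,
    sigma: float,
    k: float,
    window: int,
    min_separation: int,
) -> list[tuple[int, float]]:
    """Smoothed-derivative thresholding; returns (index, height) pairs."""
    n = len(f)
    kernel = np.ones(window) / window
    fs = np.convolve(f, kernel, mode="same")
    d = np.empty(n)
    d.fill(0.0)
    d[window:-window] = fs[2 * window :] - fs[: -2 * window]
    score = np.abs(d)
    thr = k * sigma
    events: list[tuple[int, float]] = []
    order = np.argsort(score)[::-1]
    taken = np.zeros(n, dtype=bool)
    for i in order:
        if score[i] <= thr:
            break
        if taken[max(0, i - min_separation) : i + min_separation + 1].any():
            continue
        taken[i] = True
        lo = slice(max(0, i - 2 * window), max(0, i - window // 2) or 1)
        hi = slice(min(n - 1, i + window // 2), min(n, i + 2 * window))
        h = abs(float(np.mean(f[hi]) - np.mean(f[lo])))
        events.append((i, h))
    events.sort()
    return events


def detect_steps(
    curve: ForceCurve,
    noise_sd: float | str = "auto",
    k: float = 3.0,
    min_segment: int = 5,
    window: int = 5,
    match_window: int = 10,
    detector: str = "consensus",
) -> StepEvents:
    """Detect tether-rupture steps on a retraction segment.

    Runs the iterative step-fitting detector (A) and the smoothed-derivative
    detector (B); ``detector`` selects which event set to return
    ("algA", "algB" or "consensus").  Consensus events are those found by
    both detectors within ``match_window`` samples, reported with algorithm
    A's position and height.  ``noise_sd="auto"`` estimates the noise SD
    robustly from the median absolute deviation of the first differences.
    """
    if curve.segment != "retract":
        raise ValueError("step detection operates on retraction segments")
    s, f = curve.separation, curve.force
    if s[0] > s[-1]:  # chronological: separation increases on retraction
        s, f = s[::-1], f[::-1]
    n = len(f)
    if n < 2 * (2 * window):
        raise ValueError("retraction segment shorter than twice the smoothing window")
    sigma = _robust_noise_sd(f) if noise_sd == "auto" else float(noise_sd)
    sigma = max(sigma, 1e-12)

    ev_a = _steps_algA(f, sigma, k, min_segment)
    ev_b = _steps_algB(f, sigma, k, window, min_separation=min_segment)

    if detector == "algA":
        chosen = ev_a
    elif detector == "algB":
        chosen = ev_b
    elif detector == "consensus":
        chosen = []
        used_b: set[int] = set()
        for ia, ha in ev_a:
            best = None
            for jb, (ib, _hb) in enumerate(ev_b):
                if jb in used_b or abs(ib - ia) > match_window:
                    continue
                if best is None or abs(ib - ia) < abs(ev_b[best][0] - ia):
                    best = jb
            if best is not None:
                used_b.add(best)
                chosen.append((ia, ha))
    else:
        raise ValueError("detector must be 'algA', 'algB' or 'consensus'")

    idx = np.array([i for i, _ in chosen], dtype=int)
    heights = np.array([h for _, h in chosen], dtype=float)
    positions = s[idx] if idx.size else np.empty(0)
    order = np.argsort(positions)
    return StepEvents(
        positions=np.asarray(positions)[order],
        heights=heights[order],
        detector=detector,
    )


def tether_statistics(
    events: list[StepEvents],
    force_bin_width: float = 5.0,
    max_count: int | None = None,
) -> TetherStats:
    """Pool step events over curves: force distribution and per-curve counts."""
    if not events:
        raise ValueError("need at least one curve's events")
    heights = np.concatenate([e.heights for e in events]) if events else np.empty(0)
    counts = np.array([e.n_steps for e in events], dtype=float)
    median_force = float(np.median(heights)) if heights.size else float("nan")
    count_mean = float(np.mean(counts))
    count_sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0

    if heights.size:
        top = force_bin_width * np.ceil(heights.max() / force_bin_width)
        fedges = np.arange(0.0, top + force_bin_width, force_bin_width)
        fhist, _ = np.histogram(heights, bins=fedges)
    else:
        fedges, fhist = np.array([0.0, force_bin_width]), np.array([0])
    force_histogram = pd.DataFrame(
        {"bin_left_pN": fedges[:-1], "bin_right_pN": fedges[1:], "n": fhist}
    )
    cmax = int(max_count if max_count is not None else counts.max())
    cedges = np.arange(0, cmax + 2)
    chist, _ = np.histogram(counts, bins=cedges)
    count_histogram = pd.DataFrame({"n_tethers": cedges[:-1], "n_curves": chist})
    return TetherStats(
        heights=heights,
        counts=counts,
        median_force=median_force,
        count_mean=count_mean,
        count_sd=count_sd,
        force_histogram=force_histogram,
        count_histogram=count_histogram,
    )


def modulus_height_profile(
    fits: list[HertzFit] | np.ndarray,
    heights: np.ndarray,
    n_bins: int = 25,
) -> ModulusProfile:
    """Mean Young's modulus in equal-width height bins (25 by default).

    ``fits`` may be a list of :class:`HertzFit` or a bare modulus array.
    Empty bins are reported as NaN.
    """
    E = np.asarray(
        [f.E for f in fits]
        if len(fits) and isinstance(fits[0], HertzFit)
        else fits,
        dtype=float,
    )
    heights = np.asarray(heights, dtype=float)
    if len(E) != len(heights):
        raise ValueError("fits and heights must have equal lengths")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    lo, hi = float(heights.min()), float(heights.max())
    if lo == hi:
        raise ValueError("all heights identical; profile undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(heights, edges) - 1, 0, n_bins - 1)
    mean_E = np.full(n_bins, np.nan)
    n_per = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        n_per[b] = sel.sum()
        if n_per[b]:
            mean_E[b] = E[sel].mean()
    return ModulusProfile(bin_edges=edges, mean_E=mean_E, n_per_bin=n_per)


def write_force_csv(path, extend: ForceCurve, retract: ForceCurve) -> None:
    """Write an extension/retraction pair as a long-format CSV."""
    frames = []
    for c in (extend, retract):
        frames.append(
            pd.DataFrame(
                {
                    "segment": c.segment,
                    "separation_nm": c.separation,
                    "force_pN": c.force,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_force_csv(path, spring_constant: float = 0.03) -> dict[str, ForceCurve]:
    """Read a force-curve CSV (columns segment, separation_nm, force_pN)."""
    df = pd.read_csv(path)
    required = {"segment", "separation_nm", "force_pN"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"force CSV missing columns: {sorted(missing)}")
    out = {}
    for seg, grp in df.groupby("segment"):
        out[str(seg)] = ForceCurve(
            separation=grp["separation_nm"].to_numpy(float),
            force=grp["force_pN"].to_numpy(float),
            segment=str(seg),
            spring_constant=spring_constant,
        )
    return out
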