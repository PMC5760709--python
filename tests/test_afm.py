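"""AFM analysis: contact point, Hertz fit, step detection and statistics."""

from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest

import memphys as m
from memphys.afm import (
    ForceCurve,
    NoContactError,
    hertz_coefficient,
    read_force_csv,
    write_force_csv,
)
from memphys.synthetic import simulate_force_curve


def noiseless(params):
    return replace(params, afm=replace(params.afm, force_noise_sd=0.0))


def step_curve(n, positions, heights, noise_sd=0.0, seed=0):
    """Retraction curve: negative running sum of unruptured tether forces."""
    s = np.linspace(0.0, 4500.0, n)
    f = np.zeros(n)
    for p, h in zip(positions, heights):
        f -= h * (s < p)
    if noise_sd:
        f = f + np.random.default_rng(seed).normal(0, noise_sd, n)
    return ForceCurve(separation=s, force=f, segment="retract")


# ------------------------------------------------------------- contact point


def test_contact_point_found_within_one_sample(control):
    curves, truth = simulate_force_curve(noiseless(control), seed=7)
    ext = curves["extend"]
    spacing = abs(np.median(np.diff(ext.separation)))
    assert abs(m.find_contact_point(ext) - truth.contact_point) <= spacing + 1e-9


def test_all_zero_force_raises_no_contact():
    s = np.linspace(3000, 0, 500)
    with pytest.raises(NoContactError):
        m.find_contact_point(ForceCurve(separation=s, force=np.zeros(500), segment="extend"))


def test_constant_offset_leaves_contact_and_modulus_unchanged(control):
    curves, truth = simulate_force_curve(noiseless(control), seed=8)
    ext = curves["extend"]
    shifted = ForceCurve(separation=ext.separation, force=ext.force + 37.0, segment="extend")
    assert m.find_contact_point(shifted) == pytest.approx(m.find_contact_point(ext))
    assert m.fit_hertz(shifted).E == pytest.approx(m.fit_hertz(ext).E, rel=1e-9)


# ----------------------------------------------------------------- Hertz fit


def test_hertz_recovers_known_modulus_to_0p1_percent():
    E_true, nu, alpha = 1000.0, 0.5, 35.0
    s_c = 2000.0
    s = np.linspace(3500.0, 500.0, 2001)  # grid hits the contact point exactly
    delta = np.clip(s_c - s, 0, None)
    f = hertz_coefficient(nu, alpha) * E_true * 1e-6 * delta**2
    curve = ForceCurve(separation=s, force=f, segment="extend")
    fit = m.fit_hertz(curve, nu=nu, half_angle=alpha)
    assert fit.E == pytest.approx(E_true, rel=1e-3)
    assert fit.residual < 1e-6


def test_hertz_resampling_density_invariance(control):
    p = noiseless(control)
    fits = []
    for n_points in (1500, 3000, 6000):
        curves, _ = simulate_force_curve(p, seed=11, n_points=n_points)
        fits.append(m.fit_hertz(curves["extend"]).E)
    assert max(fits) / min(fits) - 1 < 0.01


def test_hertz_zero_force_flagged_zero():
    s = np.linspace(3000, 500, 800)
    f = np.where(s < 1500, -1e-3 * (1500 - s) ** 2 * 1e-3, 0.0)  # negative deflection
    curve = ForceCurve(separation=s, force=f, segment="extend")
    fit = m.fit_hertz(curve, contact_point=1500.0)
    assert fit.E == 0.0
    assert "clamped_nonnegative" in fit.flags


# ------------------------------------------------------------ step detection


def test_noiseless_steps_detected_exactly():
    curve = step_curve(3000, [800.0, 1900.0, 3100.0], [30.0, 30.0, 30.0])
    ev = m.detect_steps(curve, noise_sd=1e-9)
    assert ev.n_steps == 3
    assert np.allclose(ev.heights, 30.0, atol=1e-6)
    assert np.all(np.diff(ev.positions) > 0)


def test_zero_tethers_noiseless_is_flat_baseline(control):
    p = replace(
        control,
        afm=replace(control.afm, force_noise_sd=0.0, tether_count_mean=0.0, tether_count_sd=0.0),
    )
    curves, truth = simulate_force_curve(p, seed=1)
    assert truth.tether_count == 0
    assert np.all(curves["retract"].force == 0.0)


def test_simulated_noiseless_steps_match_truth(control):
    found = 0
    for seed in range(1, 11):
        curves, truth = simulate_force_curve(noiseless(control), seed=seed)
        if truth.tether_count == 0:
            continue
        if np.min(np.diff(np.concatenate([[0], truth.step_positions]))) < 30:
            continue  # skip unresolvably close ruptures
        ev = m.detect_steps(curves["retract"], noise_sd=1e-9)
        assert ev.n_steps == truth.tether_count
        assert np.allclose(ev.heights, truth.step_heights, atol=1e-6)
        found += 1
    assert found >= 5


def brute_force_steps(f, n_steps, min_segment=5):
    """Exhaustive enumeration of breakpoint sets minimizing the SSE of a
    piecewise-constant fit (independent oracle for algorithm A)."""
    n = len(f)
    cum = np.concatenate([[0.0], np.cumsum(f)])
    cum2 = np.concatenate([[0.0], np.cumsum(f * f)])

    def sse(a, b):
        s = cum[b] - cum[a]
        return cum2[b] - cum2[a] - s * s / (b - a)

    best, best_breaks = np.inf, ()
    candidates = range(min_segment, n - min_segment + 1)
    for breaks in combinations(candidates, n_steps):
        if any(b2 - b1 < min_segment for b1, b2 in zip(breaks, breaks[1:])):
            continue
        edges = (0, *breaks, n)
        total = sum(sse(a, b) for a, b in zip(edges[:-1], edges[1:]))
        if total < best:
            best, best_breaks = total, breaks
    edges = (0, *best_breaks, n)
    means = [(cum[b] - cum[a]) / (b - a) for a, b in zip(edges[:-1], edges[1:])]
    heights = [abs(m2 - m1) for m1, m2 in zip(means, means[1:])]
    return list(best_breaks), heights


@pytest.mark.parametrize(
    "positions, heights",
    [
        ([50.0], [25.0]),
        ([30.0, 70.0], [30.0, 20.0]),
        ([20.0, 45.0, 80.0], [15.0, 40.0, 25.0]),
        ([15.0, 35.0, 55.0, 75.0, 90.0], [30.0, 30.0, 30.0, 30.0, 30.0]),
    ],
)
def test_detector_matches_brute_force_oracle(positions, heights):
    """On noiseless curves the greedy detector equals exhaustive enumeration."""
    n = 110
    s = np.linspace(0.0, 4500.0, n)
    f = np.zeros(n)
    for pct, h in zip(positions, heights):
        f -= h * (np.arange(n) < pct)
    curve = ForceCurve(separation=s, force=f, segment="retract")
    ev = m.detect_steps(curve, noise_sd=1e-9, detector="algA")
    oracle_breaks, oracle_heights = brute_force_steps(f, len(positions))
    det_breaks = [int(np.searchsorted(s, p)) for p in ev.positions]
    assert det_breaks == oracle_breaks
    assert np.allclose(sorted(ev.heights), sorted(oracle_heights), atol=1e-9)


def test_false_positive_rate_on_flat_noise_below_0p05():
    rng = np.random.default_rng(42)
    total = 0
    for _ in range(100):
        f = rng.normal(0.0, 2.0, 3000)
        curve = ForceCurve(separation=np.linspace(0, 4500, 3000), force=f, segment="retract")
        total += m.detect_steps(curve).n_steps
    assert total / 100 <= 0.05


def test_recall_of_30pN_steps_in_2pN_noise_at_least_0p95():
    rng = np.random.default_rng(43)
    hits = trials = 0
    for i in range(100):
        positions = np.sort(rng.uniform(300, 3800, 3))
        if np.min(np.diff(np.concatenate([[0], positions]))) < 50:
            continue
        curve = step_curve(3000, positions, [30.0] * 3, noise_sd=2.0, seed=i)
        ev = m.detect_steps(curve)
        trials += 3
        for p in positions:
            if np.any(np.abs(ev.positions - p) < 30):
                hits += 1
    assert trials > 200
    assert hits / trials >= 0.95


def test_short_segment_rejected():
    curve = ForceCurve(separation=np.linspace(0, 10, 12), force=np.zeros(12), segment="retract")
    with pytest.raises(ValueError, match="smoothing window"):
        m.detect_steps(curve)


# ------------------------------------------------------------------ statistics


def test_tether_statistics_median_and_counts():
    ev = [
        m.StepEvents(positions=np.array([1.0, 2.0, 3.0]), heights=np.array([10.0, 20.0, 30.0]), detector="consensus"),
        m.StepEvents(positions=np.empty(0), heights=np.empty(0), detector="consensus"),
    ]
    st = m.tether_statistics(ev)
    assert st.median_force == 20.0
    assert st.count_mean == 1.5
    assert st.count_histogram["n_curves"].sum() == 2
    with pytest.raises(ValueError):
        m.tether_statistics([])


def test_modulus_profile_flat_and_two_level():
    heights = np.linspace(0, 1000, 200)
    prof = m.modulus_height_profile(np.full(200, 500.0), heights)
    assert len(prof.mean_E) == 25  # default bin count
    assert np.allclose(prof.mean_E[prof.n_per_bin > 0], 500.0)
    E = np.where(heights < 500, 1000.0, 500.0)
    prof2 = m.modulus_height_profile(E, heights, n_bins=10)
    assert np.allclose(prof2.mean_E[:4], 1000.0)
    assert np.allclose(prof2.mean_E[6:], 500.0)
    with pytest.raises(ValueError):
        m.modulus_height_profile(E, np.full(200, 5.0))


def test_force_csv_roundtrip(tmp_path, control):
    curves, _ = simulate_force_curve(control, seed=5)
    path = tmp_path / "curve.csv"
    write_force_csv(path, curves["extend"], curves["retract"])
    back = read_force_csv(path)
    assert set(back) == {"extend", "retract"}
    assert np.allclose(back["retract"].force, curves["retract"].force)
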