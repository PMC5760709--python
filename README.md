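# memphys

Analysis pipeline for plasma-membrane biophysics experiments of the kind
used to characterize sphingolipid-storage (Gaucher-type) cell models:
fluorescence recovery after photobleaching (FRAP), fluorometric anisotropy
and Laurdan generalized polarization (GP), two-photon GP imaging with
raft-domain segmentation, AFM force spectroscopy (membrane-tether steps and
Hertzian elasticity), and per-cell image quantification of endocytosis and
nuclear translocation.  A synthetic-data generator emulates every input
modality with known ground truth, so each stage is validated by parameter
recovery without any external data.

## What it computes

**FRAP** (`memphys.frap`).  Raw bleached-ROI (*I*), whole-membrane (*T*)
and background (*bg*) traces are double-normalized,

    R(t) = [(I(t) − bg(t)) / (I(0) − bg(0))] · [(T(0) − bg(0)) / (T(t) − bg(t))],

which normalizes to the pre-bleach level and cancels acquisition bleaching.
The empirical recovery model

    R(t) = R(0) − a + a (1 − b)(1 − e^(−t/τ))

is fitted to the averaged post-bleach curve: *a* is the extent of
bleaching, *b* the immobile fraction, τ the empirical recovery time
constant.  95% confidence bounds come from the fit covariance, with the
uncertainty of the pre-bleach estimate of R(0) propagated.

**Fluorometry** (`memphys.photophysics`).  L-format steady-state
anisotropy r = (Ivv − G·Ivh)/(Ivv + 2G·Ivh) and Laurdan generalized
polarization GP = (I_blue − I_red)/(I_blue + I_red).

**GP imaging** (`memphys.gp_imaging`).  Per-pixel GP maps after scalar
background correction of both channels; high/low-GP domain masks from one
shared threshold (pooled Otsu across a comparison set by default) and the
fractional area of the high-GP, raft-like phase.

**AFM** (`memphys.afm`).  Contact-point detection (flat baseline +
quadratic contact, breakpoint at minimum total squared error) and a
pyramidal-tip Hertz fit F = [E/(1 − ν²)](tan α/√2) δ² from contact to the
1 nN load cap.  Tether-rupture steps on retraction are found by two
independent detectors — iterative step-function fitting and smoothed-
derivative thresholding — and reported as their consensus; pooled
step-height and per-curve count statistics follow, along with 25-bin
modulus-vs-height profiles.

**Cell quantification** (`memphys.cell_quant`).  Wahlby-style nucleus
detection (smoothing, Otsu, h-maxima seeds, marker-controlled watershed,
fragment merging, distance-transform cluster splitting), seeded-watershed
cell partitioning on the membrane channel with the boundary ring thickened
inward as the membrane mask, and per-cell intensity fractions: endocytosed
ligand (intracellular over membrane + intracellular) and nuclear signal
fraction (nucleus over whole cell).

**Synthetic data** (`memphys.synthetic`).  `make_preset("control")` /
`make_preset("gaucher")` carry the two study conditions (immobile
fractions 0.15/0.45, median tether forces 30/27 pN, tether counts
4.8 ± 2.4 / 11.1 ± 4.3, modulus median/mean 614/1031 and 459/795 Pa,
high-GP area fractions 13%/48%, endocytosed transferrin 60%/30%, cholera
toxin B 40%).  Every simulator emits ground truth and is exactly inverted
by its analysis stage in the noiseless limit.

## Worked example

```python
import memphys as m

# FRAP: ten noisy records per condition, averaged and fitted
fits = {}
for preset in ("control", "gaucher"):
    params = m.make_preset(preset)
    curves = [
        m.double_normalize(m.simulate_frap_record(params, seed=s)[0])
        for s in range(1, 11)
    ]
    fits[preset] = m.fit_recovery(m.average_curves(curves))
for preset, fit in fits.items():
    lo, hi = fit.ci95["b"]
    print(f"{preset:8s} b = {fit.b:.3f} (95% CI {lo:.3f}-{hi:.3f}), tau = {fit.tau:.1f} s")
print(f"immobile-fraction ratio = {fits['gaucher'].b / fits['control'].b:.2f}")

# AFM: tether statistics on 200 retraction curves per condition
for preset in ("control", "gaucher"):
    params = m.make_preset(preset)
    events = [
        m.detect_steps(m.simulate_force_curve(params, seed=s)[0]["retract"])
        for s in range(1, 201)
    ]
    st = m.tether_statistics(events)
    print(f"{preset:8s} median tether force = {st.median_force:.1f} pN, "
          f"tethers/curve = {st.count_mean:.1f} +/- {st.count_sd:.1f}")
```

prints

```
control  b = 0.148 (95% CI 0.142-0.155), tau = 15.4 s
gaucher  b = 0.447 (95% CI 0.441-0.452), tau = 30.4 s
immobile-fraction ratio = 3.01
control  median tether force = 30.7 pN, tethers/curve = 4.8 +/- 2.3
gaucher  median tether force = 27.1 pN, tethers/curve = 11.2 +/- 4.3
```

The fitted immobile fraction of the sphingolipid-enriched condition is
three times the control value (restricted lateral mobility), tethers pull
at a ~10% lower force but form more than twice as often, and the non-
overlapping 95% CIs mark the difference as significant under the
CI-overlap rule.

A CLI mirrors the pipeline for file-based work, e.g.

```sh
memphys simulate --modality afm --preset control --seed 1 --out data/
memphys afm-analyze --in data/ --out results/
memphys frap-fit --in curve1.csv --in curve2.csv --out fit.json
```

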