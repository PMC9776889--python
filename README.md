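# lvtrack

Feature tracking of left-ventricular (LV) wall motion in short-axis 2D+time
cardiac MR image series.

Retrospective (ECG-gated) cine MRI merges data from several heartbeats into
one virtual cardiac cycle, so it can only show motion that repeats
identically beat after beat. Real-time (ungated) imaging resolves every
individual heartbeat and therefore also captures *short-lived* motion that
varies from cycle to cycle. `lvtrack` implements the analysis chain that
exploits this: it delineates the LV endocardial border in every frame,
tracks border points between frames by matching "feature images" built from
radial line cuts, converts the tracked (radius, angle) paths into radial
and circumferential velocity traces, and summarises them per subject.

The central quantity is the **torsion correlation (TC)**. During systole a
healthy ventricle contracts radially while twisting — clockwise in basal
slices, counter-clockwise in apical slices — and both motions recoil
together in diastole. The radial velocity v_r(t) and circumferential
velocity v_c(t) of a slice are therefore strongly correlated: positively
(r → +1) in basal slices, negatively (r → −1) in apical slices. With
Pearson correlations computed over all tracked cardiac cycles,

    TC = mean(r, basal slices) − mean(r, apical slices)  ∈ [−2, 2],

so a well-coordinated ventricle has TC near 2, and any beat-to-beat
de-synchronisation of twist against contraction — the kind of diastolic
dysfunction that a preserved ejection fraction hides — pulls TC down. A
cine-emulation mode (phase-binned averaging of all cycles into one virtual
cycle before correlating) shows why gated imaging misses this: averaging
re-aligns the randomly shifted beats.

Alongside TC the package computes diastolic peak velocities, the standard
volumetric indices (EDV, ESV, SV = EDV − ESV, EF = SV/EDV via Simpson slice
summation), cycle detection for ungated series, and a cohort statistics
layer (one-way ANOVA, Anderson–Darling normality, Pearson correlation,
box-plot quartile tables).

Because no public image data accompany the method, `lvtrack` ships a
synthetic rotating/contracting LV phantom with analytically known motion
(multi-slice, multi-cycle, textured myocardial ring, seeded cohort regimes:
`healthy`, `reduced` EF, and `decoupled` — normal EF but beat-to-beat
rotation-timing jitter). Every quantitative claim in the test suite is made
against this ground truth. See `docs/methods.md` for the model and its
limitations.

## Worked example

Simulate one healthy subject, analyse it, and print its indices:

```python
from lvtrack import phantom, pipeline

subject = phantom.generate_cohort("healthy", 1, base_seed=1)[0]
res = pipeline.analyze_subject(subject.series, label=subject.label,
                               group="healthy")
print(res.classification)
print([round(s.r_realtime, 3) for s in res.slices])
print(round(res.tc_realtime, 3), round(res.tc_cine, 3))
print(round(res.volumes.ef_pct, 1), round(100 * subject.truth_ef, 1))
```

Output:

```
['basal', 'basal', 'basal', 'apical', 'apical', 'apical']
[0.973, 0.944, 0.956, -0.961, -0.98, -0.977]
1.931 1.964
65.6 65.0
```

Reading: the three basal slices rotate clockwise and correlate positively
(r ≈ +0.95), the three apical slices counter-clockwise and negatively, so
TC ≈ 1.93 — a tightly coupled ventricle. The full-pipeline ejection
fraction (65.6%) lands within a percentage point of the phantom's geometric
truth (65.0%). A `decoupled`-regime subject keeps its EF but drops the
real-time TC (≈ 1.7–1.8 at 60 ms timing jitter) while the cine-mode TC
stays high — the contrast that motivates real-time acquisition.

The same workflow is available from the shell:

```bash
lvtrack simulate --regime healthy --subjects 10 --seed 1 --out data/
lvtrack segment  --series data/healthy_00/slice00.tif --out contours.csv
lvtrack track    --series data/healthy_00/slice00.tif --out-dir trk/
lvtrack analyze  --subject-dir data/healthy_00 --out-dir ana/
lvtrack volumes  --subject-dir data/healthy_00 --out vol.csv
lvtrack run      --seed 1 --out run/        # full pipeline + cohort stats
```

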