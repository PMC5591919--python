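# cardiokin

Video-based kinematic and dynamic analysis of spontaneously beating cardiac
syncytia, with the solenoid-pair field dosimetry of the electromagnetic
bioreactor that stimulates them, and a synthetic-data generator that makes
the whole chain testable against exact ground truth.

## The problem

Primary neonatal murine cardiomyocytes cultured as a confluent sheet fuse
into a syncytium that beats spontaneously. Its contraction strength
(inotropy) responds to β-adrenergic agonists such as isoproterenol (ISO,
10 µM) and to pulsed electromagnetic field exposure (EMF, ~3 mT at 75 Hz
from two series-driven air-cored solenoids). The contraction is quantified
from 20 s microscopy videos: ~30 software markers on an orthogonal grid are
tracked frame by frame, and each marker's displacement signal is reduced to
per-beat metrics

- **D** — maximum contraction displacement [px],
- **V** — contractility, the maximum contraction velocity [px/s],
- **Acc** — maximum contraction acceleration [px/s²],

averaged beats → markers → videos → syncytium over a 27–39 min window (five
acquisitions, one every 3 min). With n = 20 syncytia per arm (CTRL, ISO,
EMF, ISO+EMF), arms are compared by one-way ANOVA with Fisher LSD post hoc
intervals: for the difference of group means *i, j*,

    h_ij = t_{1−α/2, N−k} · sqrt(MS_within · (1/n_i + 1/n_j)),

and a contrast is significant at α = 0.05 iff |Δ_ij| > h_ij (the 95% CI
excludes zero). The characteristic finding this package reproduces on
synthetic data: single treatments shift **D** non-significantly while
shifting **Acc** (and sarcomeric MF20 immunofluorescence) significantly, and
the combined treatment is significantly depressed in every metric — because
β-adrenergic shortening of the contraction phase τ_c amplifies velocity
(∝ A/τ_c) and acceleration (∝ A/τ_c²) much more than amplitude.

No raw videos from the original experiments are public, so the package ships
a first-class generator: beats are raised-cosine displacement pulses, chosen
because their derivatives are closed-form, giving every synthetic syncytium
exact ground-truth values of D, V and Acc.

## Worked example

`examples/03_beat_metrics.py` generates one 20 s control video (30 grid
markers, 25 Hz, 0.1 px tracker noise), runs the kinematics chain and
compares the recovered metrics against the generator's closed forms:

```bash
python examples/03_beat_metrics.py
```

```
582 beats across 30 markers
video means: D = 6.28 px, V = 34.54 px/s, Acc = 416.7 px/s^2
farthest marker: D = 9.82 px (true 10.00), V = 52.34 px/s (true 52.36), Acc = 592 px/s^2 (true 548)
```

The video means sit below the farthest marker's values because contraction
amplitude grows with distance from the syncytium center; the farthest
marker, whose amplitude the ground truth describes, is recovered to a few
percent (D and V to <1%, acceleration — the hardest quantity, a second
derivative at 25 Hz — to ~8%). The `examples/` directory holds one short
script per capability (generation, tracking, beat metrics, ANOVA/LSD, field
dosimetry, fluorescence, full reproduction), each printing the numbers it
computes and a line on what they mean.

A thin CLI wraps the same pipeline:

```bash
cardiokin simulate --outdir data          # synthetic 4-arm study
cardiokin analyze data --outdir metrics   # beat metrics + summaries
cardiokin stats metrics/syncytium_summaries.csv --outdir stats
cardiokin field --outdir field            # B_Z map + dosimetry report
cardiokin repro                           # end-to-end pattern reproduction
```

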