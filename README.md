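# spindlemetrics

Quantitative 3D analysis of metaphase-spindle geometry and sister-kinetochore
dynamics from labeled point detections, with a synthetic ground-truth spindle
generator.

## The problem

During mitosis, congressed chromosomes form a metaphase plate between the two
spindle poles. Whether that plate sits at the spindle's center matters: an
off-center plate at anaphase can produce daughter cells of unequal size. This
package quantifies plate position and its dynamics from fluorescence
time-lapse or fixed-cell imaging that has already been reduced to labeled 3D
point detections (centrioles, inner/outer kinetochore markers, an
attachment-maturity marker, cortex reference points), in micrometres.

The central statistic is the **half-spindle ratio**

```
R = L1 / L2
```

where the metaphase plate is the orthogonal-least-squares plane through the
kinetochore cloud, its intersection with the pole-to-pole axis splits the
spindle into half-spindles of length `L1` and `L2`, and `L1` is on the
**reference pole** side — the pole holding the grandmother centriole
(brightest centrin signal), or, in cells with a 2:1 centriole distribution,
the 2-centriole pole. `R = 1` is a perfectly centered plate.

Around R the package provides, per cell and per cohort:

- pole clustering, reference-pole assignment, plate plane fit,
  spindle-center vs. cell-center offset, kinetochore-to-pole distances,
  pole intensity asymmetry (geometry);
- sister-pair identification (mutual nearest neighbors, gated), inter- and
  intra-kinetochore distances, axis-projected oscillation autocorrelation
  with half-period extraction (kinetics);
- classifiers: anaphase onset (sustained inter-kinetochore separation),
  spindle rotation (> 90° net XY turn), asymmetric division (daughter size
  ratio strictly > 1.2), partially unstable attachments (> 30% of pairs with
  an attachment-marker-negative kinetochore), pole minus-end asymmetry;
- cohort statistics: R-distribution summaries with the 0.85/1.15
  boundaries, anaphase-aligned median-R trajectories with bootstrap 95%
  bands, and a two-sided test battery (Welch t, Mann–Whitney U, Fisher
  exact, exact binomial, Levene, paired t).

Because raw microscopy data of this kind are rarely shareable, the package
ships a first-class synthetic generator (`spindlemetrics.simulate`) that
emits detection tables with complete ground truth — target R per cell,
centering relaxation, quasi-periodic sister oscillations, localization
noise, spindle rotation, anaphase onset, marker intensities — so every
estimator in the pipeline can be validated against a known answer.

## Worked example

```python
from spindlemetrics import SimConfig, analyze_cohort, simulate_cohort

cfg = SimConfig(n_cells=30, config_label="C21", r_true=1.2, r_sigma=0.13,
                centering_tau_s=120.0, anaphase_at_s=300.0, duration_s=300.0,
                seed=7)
cells, _ = simulate_cohort(cfg)
metrics, summary = analyze_cohort(cells)
```

Running `python examples/02_centering_trajectory.py` (the script above)
prints:

```
n = 30 cells
metaphase median R (first 3 frames): 1.236
median R at anaphase onset         : 1.019
time-to-anaphase trajectory (every 60 s):
  t =  -300.0 s   median R = 1.246   95% CI [1.196, 1.308]
  t =  -240.0 s   median R = 1.133   95% CI [1.109, 1.180]
  t =  -180.0 s   median R = 1.081   95% CI [1.062, 1.091]
  t =  -120.0 s   median R = 1.049   95% CI [1.035, 1.058]
  t =   -60.0 s   median R = 1.037   95% CI [1.027, 1.047]
  t =     0.0 s   median R = 1.020   95% CI [1.015, 1.029]
```

The cohort starts with clearly off-center plates (median R ≈ 1.24); the
plate offset relaxes toward the spindle center before anaphase, the median
approaches 1 and the bootstrap confidence band narrows as the cells
converge. The other scripts in `examples/` show single-cell R measurement
(noise-free recovery to machine precision), oscillation half-period and
intra-kinetochore δ estimation, and a two-cohort statistical comparison.

## Command line

A thin CLI wraps the library for shell use:

```sh
spindlemetrics simulate --n-cells 10 --r-true 1.12 --out-dir out --stem demo
spindlemetrics analyze out/demo_detections.csv out/demo_metadata.csv --out-dir out
spindlemetrics report out/cohort_summary.json
```

Detection tables are plain CSV with the fixed header
`cell_id,frame,time_s,channel,x_um,y_um,z_um,intensity`.

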