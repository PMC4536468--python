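"""Anaphase-aligned plate-centering trajectory of an off-center cohort.

Simulates 30 cells starting at median R = 1.2 whose plate offset relaxes
toward the spindle center (tau = 120 s) until anaphase at t = 300 s, then
reports the cross-cell median R with bootstrap 95% confidence bands on the
anaphase-aligned time axis.
"""

from spindlemetrics import SimConfig, analyze_cohort, simulate_cohort

cfg = SimConfig(n_cells=30, config_label="C21", r_true=1.2, r_sigma=0.13,
                centering_tau_s=120.0, anaphase_at_s=300.0, duration_s=300.0,
                seed=7)
cells, _ = simulate_cohort(cfg)
metrics, summary = analyze_cohort(cells)

block = summary.conditions["C21"]
print(f"n = {block['n_cells']} cells")
print(f"metaphase median R (first 3 frames): {block['median_R']:.3f}")
print(f"median R at anaphase onset         : {block['median_R_anaphase']:.3f}")
print("time-to-anaphase trajectory (every 60 s):")
for row in block["trajectory"][::8]:
    print(f"  t = {row.time_to_anaphase_s:7.1f} s   median R = {row.median_R:.3f}"
          f"   95% CI [{row.ci_lo:.3f}, {row.ci_hi:.3f}]")
# The median relaxes toward R = 1 and the confidence band narrows as cells
# converge: off-center plates center before anaphase.
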