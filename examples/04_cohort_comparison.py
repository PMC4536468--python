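"""Compare a centered (2:2) and an off-center (2:1) metaphase cohort.

Simulates both populations at realistic dispersion, summarizes their R
distributions (median, fraction outside the 0.85/1.15 boundaries) and runs
the two-sample test battery of the analysis (Mann-Whitney U, Welch t).
"""

from spindlemetrics import SimConfig, analyze_cohort, simulate_cohort

c22, _ = simulate_cohort(SimConfig(n_cells=40, config_label="C22", r_true=1.00,
                                   duration_s=30.0, seed=1))
c21, _ = simulate_cohort(SimConfig(n_cells=40, config_label="C21", r_true=1.12,
                                   duration_s=30.0, seed=2))
metrics, summary = analyze_cohort(c22 + c21)

for cond in ("C22", "C21"):
    b = summary.conditions[cond]
    print(f"{cond}: n = {b['n_cells']}  median R = {b['median_R']:.3f}  "
          f"outside [0.85, 1.15]: {100 * b['frac_outside']:.1f}%  "
          f"R > 1.15: {100 * b['frac_above_115']:.1f}%")
for t in summary.test_results:
    print(f"{t.name} ({t.comparison}): statistic = {t.statistic:.1f}, "
          f"p = {t.p_value:.2e} ({t.method or 'default'})")
# Off-center 2:1 spindles show a shifted R distribution and a large
# fraction beyond the 1.15 boundary; both tests reject equality.
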