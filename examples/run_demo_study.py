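"""Run a complete synthetic study: 18 phantoms, histology, statistics.

Generates three groups of six specimens (repair / chronic tear /
control), writes their volumes, ROI masks and stained sections to disk,
runs the whole measurement chain, and prints the group tables and
agreement statistics.
"""

import tempfile

from fivol import generate_demo_study, run_study

with tempfile.TemporaryDirectory() as tmp:
    config = generate_demo_study(tmp, seed=0, n_per_group=6)
    report = run_study(config)

    print("group tables (mean +- SD):")
    for row in report.statistics["groups"]:
        print(
            f"  {row['group']:>12}: muscle {row['muscle_mean']:8.1f} +- {row['muscle_sd']:6.1f} mm^3, "
            f"fat {row['fat_mean']:6.1f} +- {row['fat_sd']:5.1f} mm^3, "
            f"FTMP {row['ftmp_mean']:.2f} +- {row['ftmp_sd']:.2f} %"
        )
    for key in ("anova_ftmp",):
        print(f"  ANOVA on FTMP: p = {report.statistics[key]['p']:.2e}")
        for pw in report.statistics[key]["pairwise"]:
            print(f"    {pw['pair'][0]} vs {pw['pair'][1]}: adjusted p = {pw['p_adjusted']:.4f}")
    for key in ("spearman_ftmp_vs_hist_fat", "spearman_volume_vs_weight"):
        c = report.statistics[key]
        print(f"  {key}: rho = {c['rho']:.3f} (p = {c['p']:.2e}, n = {c['n']})")

# The per-group FTMP means track the generating parameters (1.8 / 2.8 /
# 0.5 %), the chronic-tear vs control contrast is significant, and the
# two measurement arms (radiologic FTMP vs histologic fat fraction) rank
# specimens nearly identically because the histologic truth was generated
# as an increasing function of the radiologic truth.
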