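"""A full in-silico replication of the three-group study design.

Generates the normal, 3-AP ataxic and riluzole + 3-AP cohorts (cell counts
and per-cell frequency statistics from the built-in group presets), analyses every
cell, and prints the group summary table and the pairwise rank tests.
"""

from pcspectra import PipelineConfig, preset, run_cohorts

report = run_cohorts(
    [preset("normal", seed=1), preset("3ap", seed=2), preset("riluzole", seed=3)],
    PipelineConfig(),
)

print("Group frequency summary (mean ± SD, Hz):")
for _, r in report["summary"].iterrows():
    print(f"  {r['cohort']:13s} {r['band']:8s} {r['mean_hz']:6.2f} ± {r['sd_hz']:5.2f}  (n={r['n']})")

print("\nPairwise rank-sum tests per band:")
for _, r in report["tests"].iterrows():
    star = "*" if r["significant"] else " "
    print(f"  {r['band']:8s} {r['cohort_a']:8s} vs {r['cohort_b']:13s} p = {r['p_value']:.4f}{star}")

print("\nSodium and calcium fundamentals drop in the ataxic (3-AP) group and")
print("return toward normal under riluzole; starred rows are significant at")
print("alpha = 0.01, mirroring the slowed firing that characterises ataxia.")
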