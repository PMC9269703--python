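"""Which feature separates the groups best? Sequential feature ranking.

Runs the greedy forward selector once per (algorithm, repetition) on the
whole-sequence describer table and tallies the feature ranked first and
second in each run.  Repetitions are cut to 5 (35 runs) for the demo; the
full protocol uses 100 (700 runs).
"""

from bendreturn import (
    EvalProtocol, build_feature_table, generate_cohort, reduced_specs,
    sfs_rank, trim_warmup,
)

recs, _ = generate_cohort(n_per_group=20, seed=42)
table = build_feature_table([trim_warmup(r) for r in recs])

ranking = sfs_rank(
    table, reduced_specs(), EvalProtocol(repetitions=5, seed=0), "forward"
)
print(f"{ranking.total_runs} selector runs ({ranking.direction})")
print(ranking.report().to_string(index=False))
print()
print("High first-place counts mark the single most discriminative feature;")
print("extremes of the flexion angular-velocity channels dominate, since")
print("the group contrast lives in peak movement velocity.")
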