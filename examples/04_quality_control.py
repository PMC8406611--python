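"""The three QC gates: depth deviation, pool uniformity, run-wise cross-check.

A query whose mean depth deviates from its pool by more than 5% is not
interpreted; a pool whose member depths spread beyond 15% CV is a poor
reference; and windows where the static-pool and run-wise-pool scores
disagree by more than 0.3 deserve suspicion.
"""

import numpy as np

from panelcnv import (
    SampleCoverage,
    SimulationConfig,
    build_runwise_pool,
    build_static_pools,
    compare_static_vs_runwise,
    percent_deviation,
    pool_uniformity,
    run_qc,
    score_sample,
    select_normals,
    select_pool,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(seed=2, sample_depth_sd=0.02))
pools = build_static_pools(select_normals(cohort.normals(), 100.0), K=8)
template = cohort.template

query = cohort.normals()[3]
pool = select_pool(query, pools)
dev = percent_deviation(query.mean_depth, pool.pool_mean_depth)
print(f"{query.sample_id}: {query.mean_depth:.1f}x vs pool {pool.pool_mean_depth:.1f}x "
      f"-> deviation {dev:.2f}% ({'pass' if dev <= 5 else 'FAIL'} at 5%)")

cv = pool_uniformity(pool)
print(f"pool {pool.pool_id} member-depth CV: {cv:.2f}% "
      f"({'pass' if cv <= 15 else 'FAIL'} at 15%)")

# run-wise cross-check: score the query against the other samples of its run
run_mates = [s for s in cohort.samples if s.run_id == query.run_id]
static_profile = score_sample(query, pool, template)
runwise = build_runwise_pool(run_mates, query.sample_id)
runwise_profile = score_sample(query, runwise, template)
delta = compare_static_vs_runwise(static_profile, runwise_profile, delta_threshold=0.3)
print(f"static vs run-wise: max |delta| {delta.max_delta:.3f} over "
      f"{delta.n_compared} windows, {delta.n_flagged} flagged at 0.3")

report = run_qc(query.mean_depth, pool, query.sample_id,
                static_profile=static_profile, runwise_profile=runwise_profile)
print(f"assembled QC report: deviation_pass={report.deviation_pass}, "
      f"pool_cv_pass={report.pool_cv_pass}")

# an over-sequenced library: 25% more depth than the pool grid covers
deep = SampleCoverage(
    "DEEP01", np.rint(query.depths * 1.25).astype(np.int64), template
)
pool_d = select_pool(deep, pools)
dev_d = percent_deviation(deep.mean_depth, pool_d.pool_mean_depth)
print(f"\nDEEP01: deviation {dev_d:.2f}% -> FAIL; the pipeline refuses to "
      "interpret this sample and escalates (updated pools, re-sequencing, or MLPA)")
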