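"""Run the three feature selectors on one data source and compare models.

CPSO searches fixed-size subsets with a bootstrap c-index fitness; NFS
grows models along the interaction network scored by likelihood-ratio
p-values; LASSO follows the penalized Cox path with cross-validated
selection near a target model size.
"""

from omicox import (
    CPSOConfig,
    LassoConfig,
    NFSConfig,
    SyntheticConfig,
    concordance_index,
    generate_cohort,
    prognostic_index,
    run_cpso,
    run_lasso,
    run_nfs,
    stratified_split,
)

cohort = generate_cohort(SyntheticConfig(n_patients=300, seed=3))
expr = cohort.matrices["EXPR"]
train_ids, test_ids = stratified_split(cohort.survival, seed=3)
train = expr.subset_patients(train_ids)
sv_train = cohort.survival.subset(train_ids)

models = {
    "CPSO": run_cpso(train, sv_train,
                     CPSOConfig(k=3, iterations=40, runs=2, swarm_size=15, bootstrap_B=5, seed=3)),
    "NFS": run_nfs(train, sv_train, cohort.network, NFSConfig(seed=3)),
    "LASSO": run_lasso(train, sv_train, LassoConfig(target_size=5, n_folds=5, seed=3)),
}

planted = set(cohort.truth.planted["EXPR"])
print("planted features:", sorted(planted))
for name, model in models.items():
    pi = prognostic_index(model.fit, expr.subset_patients(test_ids).df.T)
    c = concordance_index(pi.to_numpy(), cohort.survival.subset(test_ids))
    hits = len(planted & set(model.feature_ids))
    print(f"{name:5s} model {sorted(model.feature_ids)} | "
          f"blind-test c-index {c:.3f} | planted recovered {hits}/{len(planted)}")
# A c-index well above 0.5 on the held-out third, with planted features in
# the model, shows the selector found the true prognostic signal.
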