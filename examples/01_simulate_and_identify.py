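"""Generate a synthetic cohort and test whether predictions are individual-specific.

Builds a 60-subject cohort whose predicted FC tracks each subject's
individual covariance component with fidelity 0.8, computes the
cross-subject similarity matrix, and runs the naive and fold-constrained
permutation identifiability tests.
"""

from fcbench import (
    SyntheticSpec,
    build_similarity,
    fold_constrained_permutation_test,
    generate_cohort,
    intra_inter,
    naive_identifiability_test,
)

spec = SyntheticSpec(
    n_subjects=60, n_nodes=30, t_samples=200, n_folds=5,
    alpha=0.1, beta=0.8, seed=42,
)
cohort, truth = generate_cohort(spec)

sim = build_similarity(cohort.pfc, cohort.efc, subject_ids=cohort.subject_ids)
r_intra, r_inter = intra_inter(sim, cohort.folds)
res = naive_identifiability_test(r_intra, r_inter)
perm_p, perm_ci = fold_constrained_permutation_test(sim, cohort.folds, n_perm=2000, seed=1)

print(f"mean r_intra = {res.mean_intra:.4f}   (prediction vs own empirical FC)")
print(f"mean r_inter = {res.mean_inter:.4f}   (prediction vs others' empirical FC)")
print(f"naive one-tailed t = {res.t_statistic:.2f}, df = {res.df:.0f}, p = {res.p_value:.2e}")
print(f"Cohen's d = {res.cohen_d:.3f}")
print(f"fold-constrained permutation p = {perm_p:.4f} "
      f"(95% CI {perm_ci[0]:.4f}-{perm_ci[1]:.4f})")
print()
print("r_intra exceeding r_inter means the predictions carry subject-specific")
print("information beyond the shared group organization of FC.")
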