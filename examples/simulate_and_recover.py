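"""Generate a synthetic ICI cohort and recover its stratum-restricted effects.

Draws an RNA-seq-style cohort (n = 234) at the generator defaults, scores
every sample with the signed-KS EMT score, and shows that (a) the score
tracks the latent EMT axis, and (b) the PR-vs-PD EMT difference exists in the
PD-L1-high stratum only — the structure the generator encodes.
"""

from scipy.stats import spearmanr, ttest_ind

from emtstrat import SyntheticCohortConfig, cohort_signatures, emt_score_cohort, generate_cohort, median_split

cfg = SyntheticCohortConfig(seed=42)
matrix, cohort, truth = generate_cohort(cfg)
sig, _ = cohort_signatures(cfg)

scores = emt_score_cohort(matrix, sig).set_index("sample_id")["score"]
rho = spearmanr(scores, truth.set_index("sample_id")["latent_emt"])[0]
print(f"cohort: {matrix.n_samples} samples x {matrix.n_genes} genes")
print(f"Spearman(EMT score, latent EMT axis) = {rho:.3f}")

meta = cohort.set_index("sample_id")
pdl1_group = median_split(meta["pdl1_expr"])
for stratum in ("high", "low"):
    mask = pdl1_group == stratum
    pr = scores[mask & (meta["response"] == "PR")]
    pd_ = scores[mask & (meta["response"] == "PD")]
    t, p = ttest_ind(pr, pd_, equal_var=False)
    print(f"PD-L1-{stratum}: mean EMT score PR {pr.mean():+.3f} (n={len(pr)}), "
          f"PD {pd_.mean():+.3f} (n={len(pd_)}), Welch p = {p:.2g}")

print()
print("The score recovers the latent axis almost perfectly, and progressive")
print("disease is tied to a higher EMT score only among PD-L1-high patients —")
print("the low stratum shows no systematic difference.")
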