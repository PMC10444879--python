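"""Rater-agreement analytics on simulated expert/non-expert ratings.

Run:  python examples/04_rater_agreement.py
"""

from tapscore import CohortSpec, gen_cohort, ground_truth_table, icc, krippendorff_alpha
from tapscore.rater_analysis import agreement_vs_quality, pairwise_agreement, ratings_wide

spec = CohortSpec(n_participants=60, seed=9)
_, ratings, truth = gen_cohort(spec)

gt = ground_truth_table(ratings)
print("ground-truth provenance:", gt.provenance.value_counts().to_dict())
# 'majority': at least two of the three experts agreed; 'averaged': the
# rounded mean of the three ratings was used instead.

experts = ratings_wide(ratings, role="expert")
res = icc(experts)
print(f"expert ICC {res.estimate:.3f}  (95% CI {res.ci95[0]:.2f}-{res.ci95[1]:.2f})")
print(f"expert Krippendorff alpha (ordinal): {krippendorff_alpha(experts):.3f}")

pairs = pairwise_agreement(experts, gt.set_index('video_id')['severity'])
print("\npairwise expert agreement:")
print(pairs["pairs"][["rater_a", "rater_b", "exact_pct", "mae"]].to_string(index=False))
print("within-1-point of ground truth (%):",
      {k: round(v, 1) for k, v in pairs["within_one_pct"].items()})

quality = agreement_vs_quality(ratings)
print("\nvideos per quality group:", quality["counts"])
if quality["chi2"]:
    print(f"chi-square (majority-found x quality): "
          f"stat {quality['chi2']['statistic']:.3f}, p {quality['chi2']['p_value']:.3f}")
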