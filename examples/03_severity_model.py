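"""Train and evaluate the severity regressor on a synthetic cohort.

Leave-one-patient-out (LOPO) cross-validation: every participant's two
hand-videos are held out together, so the reported metrics describe
performance on unseen patients.

Run:  python examples/03_severity_model.py        (about a minute)
"""

import warnings

from tapscore import CohortSpec, RunConfig, cohort_feature_table, explain, lopo_cv, train
from tapscore.severity_model import global_importance

warnings.filterwarnings("ignore")

cfg = RunConfig(seed=1)
spec = CohortSpec(n_participants=40, seed=1)
table, ratings, truth = cohort_feature_table(spec, cfg)
print(f"cohort: {len(table)} hand-videos, labels 0-4 from simulated expert ratings")

cv = lopo_cv(table, seed=cfg.seed)
m = cv.metrics
print(f"LOPO  MAE {m['mae']:.3f}  PCC {m['pcc']:.3f}  accuracy {m['accuracy_pct']:.1f}%  "
      f"Spearman {m['spearman_rho']:.3f}")
# MAE is the mean absolute distance between predicted and clinician-derived
# severity (points on the 0-4 scale); PCC is the Pearson correlation.

model = train(table, seed=cfg.seed)
contribs, base = explain(model, table.head(50))
print("\ntop-5 features by mean |Shapley attribution|:")
for name, value in global_importance(contribs).head(5).items():
    print(f"  {name:<28}{value:.4f}")
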