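"""Fit and validate the OPLS-DA models before and after variable selection.

Reads the analysis bucket table from 02, scales to unit variance, screens
for Hotelling-T² outliers by PCA, fits the two-class OPLS-DA (1 orthogonal
component), validates it by stratified sevenfold cross-validation, a
100-label-permutation test and CV-ANOVA, removes unstable variables by the
|b/b_cvSE| > 1 rule, refits and revalidates on the reduced variable set,
and reports a nested-CV Q²Y in which selection is redone inside every
training fold (the unbiased counterpart of select-then-revalidate).
Writes results/model_stats.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from urimet import (
    BucketTable,
    PipelineConfig,
    cross_validate,
    cv_anova,
    flag_outliers,
    nested_cv_q2,
    oplsda_fit,
    pca_fit,
    permutation_test,
    select_variables,
    uv_scale,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--table", type=Path, default=Path("results/bucket_table.csv"))
parser.add_argument("--out", type=Path, default=Path("results/model_stats.json"))
args = parser.parse_args()

if not args.table.exists():
    raise SystemExit(f"{args.table} not found - run analysis/02_preprocess.py first")

table = BucketTable.from_csv(args.table)
y = np.asarray(table.groups)
scaled, _ = uv_scale(table)

pca = pca_fit(scaled.values, 5, sample_ids=scaled.sample_ids)
flagged = flag_outliers(pca)
print(f"PCA screen: {len(flagged)} sample(s) above the 95% T² limit: {flagged}")


def validate(X, label, seed):
    model = oplsda_fit(X, y, 1)
    cv = cross_validate(X, y, 1, 7, seed=seed)
    perm = permutation_test(X, y, 1, 100, seed=seed)
    p_anova = cv_anova(cv, y)
    print(
        f"{label}: k={X.shape[1]}  R2Y={model.r2y:.3f}  Q2Y={cv.q2y:.3f}  "
        f"perm p={perm.p_value:.3g}  CV-ANOVA p={p_anova:.3g}  "
        f"(perm intercepts R2={perm.r2_intercept:.3f}, Q2={perm.q2_intercept:.3f})"
    )
    return model, cv, perm, p_anova


full_model, full_cv, full_perm, full_anova = validate(scaled.values, "full model", args.seed)
sel = select_variables(full_model, full_cv, 1.0)
print(f"selection |b/b_cvSE| > 1: {sel.keep.sum()} of {len(sel.keep)} variables kept")
sel_model, sel_cv, sel_perm, sel_anova = validate(
    scaled.values[:, sel.keep], "selected model", args.seed + 1
)

nested = nested_cv_q2(table.values, y, PipelineConfig(seed=args.seed), seed=args.seed + 2)
print(f"nested-CV Q2Y (selection inside folds): {nested:.3f}")

stats = {
    "outliers_flagged": flagged,
    "full": {"k": int(scaled.n_buckets), "r2y": full_model.r2y, "q2y": full_cv.q2y,
             "perm_p": full_perm.p_value, "cv_anova_p": full_anova},
    "selected": {"k": int(sel.keep.sum()), "r2y": sel_model.r2y, "q2y": sel_cv.q2y,
                 "perm_p": sel_perm.p_value, "cv_anova_p": sel_anova},
    "nested_cv_q2y": nested,
}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(stats, indent=2))
print(f"wrote {args.out}")
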