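"""A/B experiment: cross-validated three-grade classification with and
without SWT enhancement preprocessing (the toolkit's headline pipeline)."""

import histoswt as hs

# 150 synthetic graded images (50 per grade); grades differ in the spectral
# slope of their texture, contaminated by class-independent high-frequency noise
spec = hs.SyntheticSpec(n_per_class=(50, 50, 50), image_size=(32, 32), seed=1)
dataset = hs.generate_graded_dataset(spec)
folds = hs.stratified_kfold(dataset, k=5, seed=1)

baseline = hs.run_classification_cv(dataset, hs.reference_classifier(),
                                    params=None, folds=folds)
enhanced = hs.run_classification_cv(dataset, hs.reference_classifier(),
                                    params=hs.REFERENCE_TUNED_PARAMS, folds=folds)

for name, report in [("no preprocessing", baseline), ("SWT enhancement", enhanced)]:
    mean, sigma = report.metrics["auc_micro"]
    mmean, msigma = report.metrics["auc_macro"]
    print(f"{name:17s}: AUC_micro {mean:.3f} +/- {sigma:.3f}   "
          f"AUC_macro {mmean:.3f} +/- {msigma:.3f}")

print()
print("Each row is a stratified 5-fold experiment: training folds are")
print("augmented 8x (originals + 7 geometric transforms), the test fold is")
print("untouched, and one-vs-rest ROC-AUC is averaged over folds (+/- is the")
print("population std across folds). Enhancement suppresses the noisy top of")
print("the spectrum while keeping the mid-frequency class texture, which is")
print("why the enhanced row scores higher on this data.")
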