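"""Stratified 5-fold splitting with training-only augmentation: the counting
arithmetic of a 322-image, three-grade dataset."""

import histoswt as hs

# class-imbalanced dataset shaped like a small clinical grading cohort
spec = hs.SyntheticSpec(n_per_class=(161, 106, 55), image_size=(16, 16), seed=1)
dataset = hs.generate_graded_dataset(spec)
folds = hs.stratified_kfold(dataset, k=5, seed=42)

print(f"dataset: {len(dataset)} images, class counts {dataset.class_counts}")
for fold in range(5):
    test = hs.build_test_set(dataset, folds, fold)
    partition = len(dataset) - len(test)
    print(f"fold {fold}: test {len(test):3d} (counts {test.class_counts}), "
          f"training partition {partition}")

fold = next(f for f in range(5)
            if len(dataset) - len(folds.fold_indices(dataset, f)) == 257)
train = hs.build_training_set(dataset, folds, fold)
augmented = sum(1 for s in train if s.transform_tag != "original")
print()
print(f"fold {fold} training set after augmentation: "
      f"{len(train) - augmented} originals + {augmented} transformed = {len(train)}")
print()
print("Each training image contributes 7 geometric variants (3 anticlockwise")
print("rotations, 2 flips, 2 flip+rotate combinations); a 257-image training")
print("partition therefore grows by 1799 new images to 2056. The test fold is")
print("never augmented, and per class the fold sizes differ by at most one.")
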