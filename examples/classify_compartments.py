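"""Compartment classification from the 38-feature electrode descriptor.

Builds the feature table on a synthetic cohort, makes a stratified 70/30
split, selects hyperparameters by 5-fold cross-validation, trains the
random-subspace kNN ensemble and the cubic-kernel SVM, and prints test-set
confusion matrices with macro precision / recall / F1 for the 4-class and the
2-class (tumoral vs non-tumoral) schemes.
"""

from ecogpipe import (PipelineConfig, SplitSpec, collapse_labels,
                      compute_feature_table, cross_validate, evaluate,
                      feature_matrix, generate_recording, make_model,
                      split_train_test)

config = PipelineConfig(seed=5)
recording, _ = generate_recording(config.synth_config())
table, _ = compute_feature_table(recording, config)

train, test = split_train_test(table, SplitSpec(train_fraction=0.7, seed=5))
X_tr, y_tr = feature_matrix(train)
X_te, y_te = feature_matrix(test)
print(f"{len(train)} training and {len(test)} test electrodes, "
      f"{X_tr.shape[1]} features\n")

for kind in ("knn_ensemble", "svm"):
    for scheme in ("4class", "2class"):
        if scheme == "2class":
            ytr, keep_tr = collapse_labels(y_tr, "tumoral_vs_nontumoral")
            yte, keep_te = collapse_labels(y_te, "tumoral_vs_nontumoral")
            Xtr, Xte = X_tr[keep_tr], X_te[keep_te]
            ytr, yte = ytr[keep_tr], yte[keep_te]
        else:
            Xtr, ytr, Xte, yte = X_tr, y_tr, X_te, y_te
        cv = cross_validate(Xtr, ytr, kind, k=5, seed=5)
        model = make_model(kind, seed=5, **cv["best_params"])
        model.fit(Xtr, ytr)
        report = evaluate(yte, model.predict(Xte), scheme=scheme)
        print(f"== {kind} / {scheme} (CV best: {cv['best_params']}) ==")
        print(report.confusion.to_string())
        print(f"macro precision {report.precision_macro:.3f}, "
              f"recall {report.recall_macro:.3f}, F1 {report.f1_macro:.3f}\n")
print("Chance level is 25% for the balanced 4-class scheme; both models sit")
print("far above it because the synthetic compartments are well separated.")
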