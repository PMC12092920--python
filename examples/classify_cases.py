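"""Classify hardest vs easiest cases with the boosted-stump model.

Builds a small planted-signal dataset (extracting features from images
takes a couple of minutes at full size, so this example uses 24 cases),
runs leave-one-out cross-validation, and prints the AUC with its DeLong
interval, the scree-selected features, and the per-feature Kruskal-Wallis
screen.
"""
from mammodiff import BoostConfig, evaluate, planted_dataset
from mammodiff.pipeline import PipelineConfig, SyntheticBlock, extract_features

ds = planted_dataset(n_cases=24, n_readers=60, seed=5)
by_case = {cid: [img for img, _ in views.values()] for cid, views in ds.images.items()}
cfg = PipelineConfig(out_dir="unused", seed=5, synthetic=SyntheticBlock())
_, X = extract_features(by_case, cfg)
y = (ds.truth.loc[X.index, "difficulty_class"] == "hardest").to_numpy(float)

report = evaluate(X, y, BoostConfig(seed=5))

print(f"LOOCV AUC = {report.auc:.3f} "
      f"(95% CI {report.auc_ci[0]:.3f}-{report.auc_ci[1]:.3f}, DeLong)")
print(f"scree-selected features: {report.selected_features}")
print(f"KW-significant features (p < 0.05): "
      f"{int(report.kw_table['significant'].sum())}/34")
print()
print("an AUC near 1 means the left-out cases are ranked almost perfectly;")
print("the scree selection should recover the two planted features,")
print("SQ_Cluster_prominence and ROI_Std_Range_all (at n = 24 the small")
print("sample makes the selection noisier than at the 140-case benchmark).")
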