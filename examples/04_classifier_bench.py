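"""Benchmark all seven classifier configurations on synthetic features.

One stratified 80/20 split is shared by every classifier; reported values
are accuracy, macro-averaged F1 over the two classes and the area under
the ROC curve on the held-out 20%.
"""

from nucleomorph import generate_dataset, run_bench
from nucleomorph.pipeline import extract_table

dataset = generate_dataset(n_per_class=50, seed=1)
table = extract_table(dataset.images, dataset.label_maps, dataset.class_labels)
reports = run_bench(table, seed=1)

print(f"{'classifier':<12}{'accuracy':>9}{'f1_macro':>9}{'auc':>7}")
for name, rep in reports.items():
    print(f"{name:<12}{rep.accuracy:>9.3f}{rep.f1_macro:>9.3f}{rep.auc:>7.3f}")
# At the default effect sizes the classes are nearly separable in feature
# space, so every classifier scores at or near 1.0 on the 20-image test
# set; values move with the seed through the split and the generator.
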