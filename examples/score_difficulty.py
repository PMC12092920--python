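"""Score reader ratings into difficulty labels and compare density groups.

Simulates a 137-reader panel over 40 normal cases, computes each case's
difficulty score (fraction of readers rating it 3-5, i.e. a false-positive
call), labels the upper/lower quartiles hardest/easiest, and runs the
Kruskal-Wallis comparison of difficulty between low-density (BI-RADS A/B)
and high-density (C/D) cases.
"""
import pandas as pd

from mammodiff import make_dataset
from mammodiff.difficulty import build_difficulty_records, density_difficulty_test

ds = make_dataset(n_cases=40, n_readers=137, seed=3, generate_images=False)
records = build_difficulty_records(ds.ratings, ds.truth["density_class"])

table = pd.DataFrame(
    [(r.case_id, r.score, r.label, r.density_group) for r in records],
    columns=["case_id", "score", "label", "density_group"],
).set_index("case_id")
print(table.round(3).head(10).to_string())
counts = table["label"].value_counts().to_dict()
print(f"\nlabel counts: {counts} (quartile rule: top 25% hardest, bottom 25% easiest)")

h, p = density_difficulty_test(records)
print(f"density comparison (low A/B vs high C/D): H = {h:.3f}, p = {p:.3f}")
print("the generator assigns density independently of difficulty, so this")
print("test should usually be non-significant.")
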