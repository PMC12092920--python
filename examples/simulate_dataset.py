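"""Generate a small synthetic reader study and write it to disk.

Builds 12 cases (balanced hardest/easiest) with four mammogram-like views
each, a 25-reader rating panel, and ground truth, then prints what was
planted. The difficulty signal lives in two texture parameters only:
blob clusters (GLCM cluster prominence) and per-block range jitter.
"""
from mammodiff import planted_dataset, write_dataset

ds = planted_dataset(n_cases=12, n_readers=25, seed=7)
out = write_dataset(ds, "scratch/example_dataset")

print(f"wrote {4 * len(ds.cases)} images for {len(ds.cases)} cases to {out}")
print(ds.truth.round(3))
print()
print("latent_difficulty is each case's true probability of a false-positive")
print("call by an unbiased reader; the rating matrix in ratings.csv realises")
print("it over the 25-reader panel.")
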