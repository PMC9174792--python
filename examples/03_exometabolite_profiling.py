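"""Utilization profiling of the packaged toy peak table.

Subtracts extraction-blank background, normalizes each metabolite to its
uninoculated-control maximum (= 100%), computes log2 fold changes, and
calls each metabolite depleted / produced / unchanged per isolate by the
rank-sum test. Finishes with Bray-Curtis clustering of the profiles.
"""

import warnings

from exomedium import (
    blank_subtract,
    cluster_profiles,
    count_significant,
    depletion_test,
    fold_change,
    isolate_mean_profiles,
    load_fixture,
    normalize,
)

table = load_fixture("toy_peaks")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = blank_subtract(table)
norm = normalize(table)
fc = fold_change(norm)
calls = depletion_test(norm, alpha=0.05)

print("log2 fold change vs uninoculated control (negative = depleted):")
print(fc.log2.round(2).to_string())
print()
print("calls (rank-sum, normal approximation, alpha = 0.05):")
print(calls.calls.to_string())
print()
print("metabolites significantly depleted per isolate:")
print(count_significant(calls).to_string())

res = cluster_profiles(isolate_mean_profiles(norm))
print()
print(f"Bray-Curtis dissimilarity iso_1 vs iso_2: "
      f"{res.distance.loc['iso_1', 'iso_2']:.3f}")
print(f"dendrogram (newick): {res.newick}")
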