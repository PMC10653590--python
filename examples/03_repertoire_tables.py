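"""Per-species repertoire tables, normalization and summary statistics.

Builds a small pre-counted species x family table (as one would ingest
from a published supplement), derives totals and fractions, normalizes
family counts to proportions with equal family weights, and prints the
column summaries.
"""
import numpy as np
import pandas as pd

from ormine import FAMILIES, normalize_families, repertoire_from_counts, table_stats

rng = np.random.default_rng(0)
species = ["agouti", "gundi", "mouse", "mole_rat", "beaver"]
counts = pd.DataFrame(
    rng.poisson([120, 15, 25, 20, 90, 60, 140, 110, 70, 55, 45, 8, 30], size=(5, 13)),
    index=species, columns=[f"fam_{f}" for f in FAMILIES],
)
counts["pseudogene"] = rng.poisson(400, size=5)

table = repertoire_from_counts(counts)
print(table[["n_func", "pseudogene", "n_total", "fraction_functional",
             "class1_fraction"]].round(3).to_string(), "\n")

norm = normalize_families(table, rescale_columns=True)
print("normalized proportions (column mean 1):")
print(norm.round(2).to_string(), "\n")

stats = table_stats(table)
print(stats[["n_func", "pseudogene", "fraction_functional"]].to_string())

# n_func sums the 13 family counts; fraction_functional is n_func over
# the full repertoire; class1_fraction is the share of the ancient
# families 51/52/55/56. Column-rescaled proportions give every family
# the same weight regardless of its absolute size.
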