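"""End-to-end meta-analysis on a synthetic study corpus.

Generates a corpus with the default study conditions (four settings,
setting-specific dose-response, greenhouse-heavy study counts), runs
normalization -> effective-stress gate -> adaptive binning -> Hampel
filtering -> gated pairwise tests, and prints the comparison table.
"""

from saltmeta import RunConfig, analyze_records, default_config, generate_corpus
from saltmeta.binning import bin_summary
from saltmeta.compare import comparisons_table

records = generate_corpus(default_config(seed=1))
print(f"generated {len(records)} observation records")

result = analyze_records(records, RunConfig(seed=1))
print("counts:", result.counts)

va = result.variables["grain_yield"]
print(f"\ngrain yield bin edges (dS/m): {[round(e, 1) for e in va.scheme.edges]}")
print(bin_summary(va.groups).round(3).to_string(index=False))

print("\npairwise setting comparisons (grain yield):")
cols = ["setting_a", "setting_b", "n_a", "n_b", "transform", "test", "p_value"]
print(comparisons_table(va.comparisons)[cols].round(5).to_string(index=False))
print("\nsmall p for field-vs-greenhouse reflects the generating truth: the "
      "field dose-response (c50=30 dS/m) is flatter than the greenhouse one "
      "(c50=12 dS/m), i.e. field crops are least affected.")
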