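"""Enumerate and execute the full multiverse of analysis variants.

The grid crosses studies x contrasts (where the group structure allows
them) x signal spaces (avg / csd / src) x approaches (two channel pairs,
cluster subtraction, standardized clusters, source clusters) x confound
control, giving 270 analyses.  Each row is judged at alpha = 0.05 and the
binomial meta-test asks whether the number of significant rows exceeds what
chance alone predicts.
"""

from faaverse import enumerate_grid, run_grid, summarize_significance
from faaverse.synth import (
    default_study_configs,
    generate_band_power,
    generate_source_surrogate,
    scaled_configs,
)

specs = enumerate_grid()
n_pairs = sum(s.approach_class == "pair" for s in specs)
print(f"Grid: {len(specs)} analyses, of which {n_pairs} single channel-pair "
      f"variants")

# Desk-scale execution: cohorts at half size, spectral shortcut datasets,
# null world (no injected effect).
configs = scaled_configs(default_study_configs(seed=3), subject_scale=0.5)
datasets = {}
for cfg in configs:
    datasets[(cfg.study_id, "avg")] = generate_band_power(cfg, "avg")
    datasets[(cfg.study_id, "csd")] = generate_band_power(cfg, "csd")
    datasets[(cfg.study_id, "src")] = generate_source_surrogate(cfg)

table = run_grid(specs, datasets, n_perm=500, n_boot=300, base_seed=3)
print(f"Executed {int((~table.skipped).sum())} rows "
      f"({int(table.significant.sum())} significant at alpha = 0.05)\n")

print("Significance counts by approach (k significant of n, binomial p):")
print(summarize_significance(table, by=["approach_class"]).to_string(index=False))
print("\nBy contrast:")
print(summarize_significance(table, by=["contrast"]).to_string(index=False))
print("\nWith no injected effect the significant fraction should hover near "
      "0.05 and every binomial p should be unremarkable; 'k_congruent' "
      "counts significant rows whose direction matches the classical "
      "left-sided FAA pattern.")
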