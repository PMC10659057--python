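"""Contiguity statistics (N50/L50, gap %) for an assembly pair.

Generates a synthetic truth genome and its derived assembly (whose edits
insert scaffold gaps and shed debris scaffolds), then compares their
contiguity: the derived assembly has more sequences, gaps at event
junctions, and a slightly lower scaffold N50.
"""

from asmcompare import (
    SimulationConfig,
    catalog_from_sequences,
    compare_stats,
    compute_stats,
    simulate,
)

sim = simulate(SimulationConfig(seed=42))
truth_cat = catalog_from_sequences(sim.truth_seqs, min_chromosome_len=1_000_000)
derived_cat = catalog_from_sequences(sim.derived_seqs, min_chromosome_len=1_000_000)

truth_stats = compute_stats(truth_cat)
derived_stats = compute_stats(derived_cat)

print(f"{'metric':<18}{'truth':>12}{'derived':>12}")
for metric, value in truth_stats.to_dict().items():
    dv = getattr(derived_stats, metric)
    print(f"{metric:<18}{value:>12}{dv:>12}" if isinstance(value, int)
          else f"{metric:<18}{value:>12.3f}{dv:>12.3f}")

report = compare_stats(truth_stats, derived_stats)
entry = report["n_scaffolds"]
print(
    f"\nscaffold count {entry['direction']} by "
    f"{abs(entry['pct_change']):.1f}% (ratio {entry['ratio']:.2f})"
)
# N50 is the length of the sequence at which the descending cumulative sum
# reaches half the assembly; L50 is how many sequences that takes.
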