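"""Simulate multi-clade branch lengths with a planted coevolving module,
convert to relative evolutionary rates, and build the integrated ERC matrix.

The printed summary shows that within-module pairs score far above the
background: the module genes share correlated rate deviations in every
clade, and the Fisher-z sum accumulates that signal across clades.
"""

from ratecov import (
    Module,
    SimulationConfig,
    build_erc_matrix,
    compute_rer,
    group_mean_erc,
    master_profile,
    significance_threshold,
    simulate_branch_tables,
)

module = tuple(f"G{i:04d}" for i in range(1, 11))
cfg = SimulationConfig(
    n_genes=200,
    species_per_clade=(62, 39, 22, 18, 17),  # mammal/vertebrate/fly/yeast/worm-sized
    modules=(Module("planted", module, rho=0.6),),
    seed=42,
)
tables, truth, trees = simulate_branch_tables(cfg)
print(f"simulated {len(tables)} clades; branches per clade:",
      [t.n_branches for t in trees])

rers = [compute_rer(t, master_profile(t)) for t in tables]
matrix = build_erc_matrix(rers)

s = matrix.summary()
print(f"scored pairs: {s['count']};  FtERC mean {s['mean']:.3f}, SD {s['sd']:.3f}")
print(f"significance threshold (mean + 2 SD): {significance_threshold(matrix):.2f}")

module_mean, n_pairs = group_mean_erc(matrix, module)
background_mean = s["mean"]
print(f"planted module mean ERC over {n_pairs} pairs: {module_mean:.2f} "
      f"(background mean {background_mean:.2f})")
# The module mean sits far above the genome-wide mean: correlated rate
# deviations in every clade add up in the integrated Fisher-z score.
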