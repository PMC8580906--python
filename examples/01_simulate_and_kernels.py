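"""Simulate two breeding panels, run marker/line QC, and build kernels.

Prints panel sizes, filter survivors, GRM summaries, and a neighbor-joining
tree over a few lines — the backbone objects every later analysis uses.
"""

import numpy as np

from omicpred.kernels import (
    compute_grm,
    filter_lines,
    filter_markers,
    impute_missing,
    neighbor_joining,
    rogers_distance,
)
from omicpred.simdata import SimConfig, simulate_genotypes

cfg = SimConfig(
    n_lines_pop1=120,
    n_lines_pop2=80,
    n_shared=12,
    n_chrom=3,
    markers_per_chrom=150,
    ld_rho=0.6,
    fst=0.15,
    miss_rate=0.03,
    seed=7,
)
diversity, elite = simulate_genotypes(cfg)
print(f"diversity panel: {diversity.n_lines} lines x {diversity.n_markers} markers")
print(f"elite panel:     {elite.n_lines} lines x {elite.n_markers} markers "
      f"({cfg.n_shared} lines shared)")

# QC mirrors the usual small-grain pipeline: MAF > 2%, site missingness
# < 60%, site heterozygosity < 10%; then line call rate > 80%, het < 10%.
filtered = filter_lines(filter_markers(diversity))
print(f"after QC: {filtered.n_lines} lines, {filtered.n_markers} markers")

complete = impute_missing(filtered, method="within_chrom_regression")
K = compute_grm(complete)
print(f"GRM: mean diagonal {np.mean(np.diag(K.matrix)):.3f} "
      "(about 1 + f for inbreeding level f)")

D = rogers_distance(complete).iloc[:8, :8]
print("neighbor-joining tree over 8 lines (Rogers' distance):")
print(neighbor_joining(D))
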