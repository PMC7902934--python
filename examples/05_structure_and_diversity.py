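"""Sample-level structure (NJ tree, bootstrap, PCA) and windowed diversity.

Simulates two moderately diverged populations, builds the allele-sharing NJ
tree with bootstrap supports, runs PCA, and computes windowed theta-pi and
Tajima's D per population.
"""

import numpy as np

from carpiscan.core_io import PopulationMap, make_windows
from carpiscan.diversity import individual_heterozygosity, window_pi, window_tajima
from carpiscan.popstruct import bootstrap_support, nj_from_table, pca
from carpiscan.synthgen import bn_genotypes

table, _ = bn_genotypes(F=0.2, n_pops=2, samples_per_pop=6, n_sites=5_000, seed=3)
popmap = PopulationMap({s: s.rsplit("_", 1)[0] for s in table.samples})

tree = nj_from_table(table)
support = bootstrap_support(table, n_reps=100, seed=9)
print("NJ tree:", tree.newick[:80], "...")
split = frozenset(s for s in table.samples if s.startswith("pop1"))
print(f"bootstrap support of the population split: {support.get(split, 0.0):.0f}")

coords, frac = pca(table)
print(f"PC1 explains {frac[0]:.1%}, PC2 {frac[1]:.1%}")

windows = make_windows({"bn_1": 5_000 * 1_000}, 50_000, 50_000)
for pop in ("pop1", "pop2"):
    pi = window_pi(table, windows, popmap, pop)["value"]
    td = window_tajima(table, windows, popmap, pop)["value"]
    het = np.mean([individual_heterozygosity(table, s)
                   for s in popmap.samples_of(pop)])
    print(f"{pop}: mean pi/bp={np.nanmean(pi):.2e}  mean Tajima's D={np.nanmean(td):+.2f}  "
          f"mean individual heterozygosity={het:.3f}")

# The population split carries full bootstrap support and PC1 separates the
# populations; per-population diversity and Tajima's D summarise the
# within-population variation the windows contain.
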