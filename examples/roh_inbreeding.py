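"""Runs of homozygosity and genomic vs pedigree inbreeding.

Detects ROHs per individual, summarizes counts and lengths per group,
computes F_ROH (fraction of the SNP-covered genome inside ROHs) and
correlates it with the pedigree coefficient of inbreeding (COI).
"""

import numpy as np

from admixbreed import FounderModel, cwd_schedule, simulate_breed
from admixbreed.containers import GeneticMap
from admixbreed.pedigree import coi_all
from admixbreed.roh import (ROHParams, detect_roh, froh_all, roh_summary,
                            shared_roh_regions)

sim = simulate_breed(FounderModel(seed=7), cwd_schedule(), GeneticMap(), seed=7)
gm = sim.genotypes

rs = detect_roh(gm, ROHParams())
summary = roh_summary(rs, dict(zip(gm.sample_ids, gm.groups)))
for _, r in summary.iterrows():
    print(f"{r['group']:12s} mean ROH count {r['mean_count']:6.1f}  "
          f"mean length {r['mean_length_kb']:7.0f} kb")
# The breed shows the longest ROHs: recent inbreeding leaves runs that
# recombination has not yet had time to break up.

fr = froh_all(rs, gm)
coi = coi_all(sim.pedigree)
breed = sim.breed_sample_ids()
x = np.array([fr[s] for s in breed])
y = np.array([coi[s] for s in breed])
r = np.corrcoef(x, y)[0, 1]
print(f"breed F_ROH mean {x.mean():.3f}, pedigree COI mean {y.mean():.3f}, "
      f"correlation r={r:.2f} (R^2={r * r:.2f})")

shared = shared_roh_regions(rs, breed)
print(f"regions inside a ROH in every breed individual: {len(shared)} "
      f"({shared.total_length() / 1e6:.1f} Mb)")
# Shared ROH regions mark candidate targets of strong selection during
# breed formation.
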