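"""Ancestry-informative-marker panels and their consolidation.

Finds SNPs fixed for opposite alleles in the two parents, keeps the 1% where
the breed least differs from one parent (wolf-like / dog-like markers),
expands hits by +-50 kb and merges them with the ancestry-fixed-block panel
into one outlier table with method provenance.
"""

import numpy as np

from admixbreed import FounderModel, cwd_schedule, simulate_breed
from admixbreed import ancestry as anc
from admixbreed.containers import GeneticMap, HaplotypeSet
from admixbreed.outliers import (aim_select, consolidate, expand_intervals,
                                 fixed_diff_sites)

sim = simulate_breed(FounderModel(seed=7), cwd_schedule(), GeneticMap(), seed=7)
gm = sim.genotypes
chrom_lengths = sim.model.chrom_lengths

fixed = fixed_diff_sites(gm)
print(f"fixed-difference SNPs between the parents: {len(fixed)}")

sel = aim_select(gm, fixed, fraction=0.1)
print(f"wolf-like SNPs: {len(sel['wolf_like'])}, "
      f"dog-like SNPs: {len(sel['dog_like'])}")

panels = {
    "fst_snp_wolf": (expand_intervals(gm, site_indices=sel["wolf_like"],
                                      chrom_lengths=chrom_lengths), "wolf_like"),
    "fst_snp_dog": (expand_intervals(gm, site_indices=sel["dog_like"],
                                     chrom_lengths=chrom_lengths), "dog_like"),
}

# add the ancestry-fixed-block panel from deconvolution
haps = sim.haplotypes
groups = {s: g for s, g in zip(gm.sample_ids, gm.groups)
          if g in ("wild_parent", "dom_parent")}
pidx = [haps.sample_ids.index(s) for s in groups]
panel_h = HaplotypeSet(
    [haps.sample_ids[i] for i in pidx], haps.sites,
    haps.haplotypes[np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in pidx]))])
ref = anc.build_reference(panel_h, groups)
breed = sim.breed_sample_ids()
bidx = [haps.sample_ids.index(s) for s in breed]
query = HaplotypeSet(
    [haps.sample_ids[i] for i in bidx], haps.sites,
    haps.haplotypes[np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in bidx]))])
track = anc.deconvolve(query, ref)
wolf_fixed, dog_fixed = anc.fixed_ancestry_blocks(track)
for name, mask, direction in (("pcadmix_wolf", wolf_fixed, "wolf_like"),
                              ("pcadmix_dog", dog_fixed, "dog_like")):
    spans = [(track.blocks.loc[k, "chrom"], track.blocks.loc[k, "start_bp"],
              track.blocks.loc[k, "end_bp"]) for k in np.flatnonzero(mask)]
    if spans:
        panels[name] = (expand_intervals(gm, block_spans=spans,
                                         chrom_lengths=chrom_lengths),
                        direction)

table = consolidate(panels)
print(f"consolidated outlier regions: {len(table)} "
      f"({int((table['direction'] == 'dog_like').sum())} dog-like, "
      f"{int((table['direction'] == 'wolf_like').sum())} wolf-like; "
      f"{int((table['n_methods'] > 1).sum())} found by multiple methods)")
print(table.head(8).to_string(index=False))
# Regions flagged by several independent methods are the strongest
# candidates for selection during breed formation; the BED-style table is
# the hand-off to downstream gene annotation.
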