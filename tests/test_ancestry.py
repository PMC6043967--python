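import numpy as np
import pandas as pd
import pytest

from admixbreed import ancestry as anc
from admixbreed.containers import GeneticMap, HaplotypeSet


def make_haps(haps, chrom=None, spacing=100_000):
    haps = np.asarray(haps, dtype=np.int8)
    n_sites = haps.shape[1]
    if chrom is None:
        chrom = ["1"] * n_sites
    pos = []
    counter = {}
    for c in chrom:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c] * spacing)
    sites = pd.DataFrame({"chrom": np.asarray(chrom, dtype=object),
                          "pos": np.asarray(pos, dtype=np.int64),
                          "allele1": "A", "allele2": "B"})
    ids = [f"s{i}" for i in range(haps.shape[0] // 2)]
    return HaplotypeSet(ids, sites, haps)


def fixed_difference_panel(n_blocks=3, block=10, n_each=4):
    """Parental panel fixed for opposite alleles at every site."""
    m = n_blocks * block
    wolves = np.ones((2 * n_each, m), dtype=np.int8)
    dogs = np.zeros((2 * n_each, m), dtype=np.int8)
    panel = make_haps(np.vstack([wolves, dogs]))
    groups = {f"s{i}": ("wild_parent" if i < n_each else "dom_parent")
              for i in range(2 * n_each)}
    return panel, groups


class TestBuildReference:
    def test_fixed_differences_are_informative(self):
        panel, groups = fixed_difference_panel()
        ref = anc.build_reference(panel, groups)
        assert ref.n_blocks == 3
        assert all(bl.informative for bl in ref.blocks)

    def test_identical_parents_uninformative(self):
        rng = np.random.default_rng(0)
        haps = np.tile(rng.integers(0, 2, size=(1, 20)).astype(np.int8), (8, 1))
        panel = make_haps(haps)
        groups = {f"s{i}": ("wild_parent" if i < 2 else "dom_parent")
                  for i in range(4)}
        ref = anc.build_reference(panel, groups)
        assert not any(bl.informative for bl in ref.blocks)

    def test_trailing_partial_block_dropped(self):
        panel, groups = fixed_difference_panel(n_blocks=2)
        # 25 sites -> 2 full blocks of 10, 5 trailing sites dropped
        panel2 = make_haps(panel.haplotypes[:, :25])
        ref = anc.build_reference(panel2, groups)
        assert ref.n_blocks == 2

    def test_informative_fraction_grows_with_divergence(self, small_model):
        from admixbreed import simulate_breed, cwd_schedule, FounderModel
        fracs = []
        for fst in (0.1, 0.5):
            model = FounderModel(
                n_sites=600, chrom_lengths={"1": 50_000_000},
                divergence_fst=fst, seed=3)
            sim = simulate_breed(model, cwd_schedule(n_generations=4),
                                 GeneticMap(), seed=3,
                                 n_ref_wolf=6, n_ref_dog=6)
            groups = {s: g for s, g in zip(sim.genotypes.sample_ids,
                                           sim.genotypes.groups)
                      if g in ("wild_parent", "dom_parent")}
            idx = [sim.haplotypes.sample_ids.index(s) for s in groups]
            rows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in idx]))
            panel = HaplotypeSet([sim.haplotypes.sample_ids[i] for i in idx],
                                 sim.haplotypes.sites,
                                 sim.haplotypes.haplotypes[rows])
            ref = anc.build_reference(panel, groups)
            fracs.append(np.mean([bl.informative for bl in ref.blocks]))
        assert fracs[0] < fracs[1]

    def test_missing_parent_rejected(self):
        panel, groups = fixed_difference_panel()
        only_wolf = {k: "wild_parent" for k in groups}
        with pytest.raises(ValueError, match="both parental"):
            anc.build_reference(panel, only_wolf)


class TestDeconvolve:
    def test_wolf_haplotype_called_wolf_with_high_posterior(self):
        panel, groups = fixed_difference_panel()
        ref = anc.build_reference(panel, groups)
        query = make_haps(np.vstack([np.ones((1, 30)), np.zeros((1, 30))]).astype(np.int8))
        track = anc.deconvolve(query, ref, smooth=False)
        assert (track.posterior_wolf[0] > 0.99).all()
        assert (track.calls[0] == "wolf").all()
        assert (track.calls[1] == "dog").all()

    def test_uninformative_block_uncalled(self):
        panel, groups = fixed_difference_panel(n_blocks=2)
        # make block 2 monomorphic across both parents
        haps = panel.haplotypes.copy()
        haps[:, 10:] = 0
        ref = anc.build_reference(make_haps(haps), groups)
        query = make_haps(np.vstack([np.ones((1, 20)), np.zeros((1, 20))]).astype(np.int8))
        track = anc.deconvolve(query, ref, smooth=False)
        assert track.posterior_wolf[0, 1] == pytest.approx(0.5)
        assert track.calls[0, 1] is None

    def test_posterior_normalization(self, deconvolved):
        _sim, _ref, track = deconvolved
        assert ((track.posterior_wolf >= 0) & (track.posterior_wolf <= 1)).all()

    def test_site_mismatch_rejected(self):
        panel, groups = fixed_difference_panel()
        ref = anc.build_reference(panel, groups)
        query = make_haps(np.ones((2, 30), dtype=np.int8), spacing=50_000)
        with pytest.raises(ValueError, match="match"):
            anc.deconvolve(query, ref)


class TestGenomeWideAncestry:
    def test_all_wolf_track_is_one(self):
        panel, groups = fixed_difference_panel()
        ref = anc.build_reference(panel, groups)
        query = make_haps(np.ones((2, 30), dtype=np.int8))
        track = anc.deconvolve(query, ref, smooth=False)
        q = anc.genome_wide_ancestry(track)
        assert q.loc["s0", "q"] == 1.0
        assert q.loc["s0", "q_weighted"] == 1.0

    def test_matches_truth_on_default_simulation(self, deconvolved):
        sim, _ref, track = deconvolved
        q = anc.genome_wide_ancestry(track)
        truth = np.array([sim.truth_q[s] for s in q.index])
        assert np.abs(q["q"].to_numpy() - truth).mean() < 0.03


class TestSupervisedQ:
    def test_pure_wolf_and_f1_limits(self, make_gm):
        m = 40
        pw = np.ones(m)
        pd_ = np.zeros(m)
        gm = make_gm(np.vstack([np.full(m, 2), np.ones(m)]).astype(np.int8),
                     groups=["breed", "breed"])
        q = anc.supervised_q(gm, pw, pd_)
        assert q["s0"] == pytest.approx(1.0, abs=1e-3)
        assert q["s1"] == pytest.approx(0.5, abs=1e-3)

    def test_matches_grid_search_oracle(self, make_gm):
        rng = np.random.default_rng(7)
        m = 20
        pw = rng.uniform(0.05, 0.95, m)
        pd_ = rng.uniform(0.05, 0.95, m)
        calls = rng.integers(0, 3, size=(1, m)).astype(np.int8)
        gm = make_gm(calls, groups=["breed"])
        qhat = anc.supervised_q(gm, pw, pd_)["s0"]
        eps = 1.0 / (2 * m + 1)
        a = np.clip(pw, eps, 1 - eps)
        b = np.clip(pd_, eps, 1 - eps)
        grid = np.linspace(0, 1, 10_001)
        d = calls[0].astype(float)
        ll = [np.sum(d * np.log(q * a + (1 - q) * b)
                     + (2 - d) * np.log(1 - q * a - (1 - q) * b))
              for q in grid]
        assert qhat == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_agrees_with_block_estimate(self, deconvolved):
        from admixbreed.stats import allele_freq
        sim, _ref, track = deconvolved
        q_blocks = anc.genome_wide_ancestry(track)["q"]
        pw = allele_freq(sim.genotypes, "wild_parent")
        pd_ = allele_freq(sim.genotypes, "dom_parent")
        q_sup = anc.supervised_q(sim.genotypes, pw, pd_,
                                 samples=list(q_blocks.index))
        assert (q_blocks - q_sup).abs().mean() < 0.05


class TestCountSwitches:
    def test_pure_haplotypes_zero(self):
        panel, groups = fixed_difference_panel()
        ref = anc.build_reference(panel, groups)
        query = make_haps(np.vstack([np.ones((1, 30)), np.zeros((1, 30))]).astype(np.int8))
        track = anc.deconvolve(query, ref, smooth=False)
        assert anc.count_switches(track)["s0"] == 0

    def test_wolf_dog_wolf_counts_two(self):
        panel, groups = fixed_difference_panel(n_blocks=3)
        ref = anc.build_reference(panel, groups)
        hap = np.concatenate([np.ones(10), np.zeros(10), np.ones(10)])
        query = make_haps(np.vstack([hap, np.zeros(30)]).astype(np.int8))
        track = anc.deconvolve(query, ref, smooth=False)
        assert anc.count_switches(track)["s0"] == 2

    def test_uncalled_blocks_are_skipped(self):
        panel, groups = fixed_difference_panel(n_blocks=3)
        haps = panel.haplotypes.copy()
        haps[:, 10:20] = 0       # middle block uninformative
        ref = anc.build_reference(make_haps(haps), groups)
        hap = np.concatenate([np.ones(10), np.zeros(10), np.ones(10)])
        query = make_haps(np.vstack([hap, np.zeros(30)]).astype(np.int8))
        track = anc.deconvolve(query, ref, smooth=False)
        # flanking called blocks are both wolf -> no switch through the gap
        assert anc.count_switches(track)["s0"] == 0

    def test_invariant_to_chromosome_order(self, deconvolved):
        _sim, _ref, track = deconvolved
        base = anc.count_switches(track)
        order = np.argsort(track.blocks["chrom"].to_numpy(), kind="stable")[::-1]
        shuffled = anc.AncestryTrack(
            hap_ids=track.hap_ids,
            blocks=track.blocks.iloc[order].reset_index(drop=True),
            posterior_wolf=track.posterior_wolf[:, order],
            calls=track.calls[:, order])
        # per-chromosome adjacency is what counts, not processing order
        assert (anc.count_switches(shuffled) == base).all()

    def test_estimates_match_truth_junctions(self, deconvolved):
        sim, _ref, track = deconvolved
        est = anc.count_switches(track)
        truth = np.array([sim.true_switches(s) for s in est.index])
        assert abs(est.to_numpy().mean() - truth.mean()) <= 0.1 * truth.mean()


class TestFixedAncestryBlocks:
    def test_single_dog_call_breaks_wolf_fixation(self):
        panel, groups = fixed_difference_panel(n_blocks=2)
        ref = anc.build_reference(panel, groups)
        haps = np.ones((4, 20), dtype=np.int8)
        haps[3, :10] = 0          # one dog haplotype in block 0
        track = anc.deconvolve(make_haps(haps), ref, smooth=False)
        wolf_fixed, dog_fixed = anc.fixed_ancestry_blocks(track)
        assert not wolf_fixed[0]
        assert wolf_fixed[1]
        assert not dog_fixed.any()

    def test_all_wolf_cohort_all_blocks_wolf_fixed(self):
        panel, groups = fixed_difference_panel(n_blocks=3)
        ref = anc.build_reference(panel, groups)
        track = anc.deconvolve(make_haps(np.ones((4, 30), dtype=np.int8)),
                               ref, smooth=False)
        wolf_fixed, _ = anc.fixed_ancestry_blocks(track)
        assert wolf_fixed.all()

    def test_dog_fixed_dominate_when_q_below_half(self, deconvolved):
        _sim, _ref, track = deconvolved
        wolf_fixed, dog_fixed = anc.fixed_ancestry_blocks(track)
        assert dog_fixed.sum() > wolf_fixed.sum()
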