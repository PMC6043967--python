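import numpy as np
import pytest

from admixbreed.containers import MISSING, GeneticMap
from admixbreed.sim import (BreedingEvent, BreedingSchedule, FounderModel,
                            cwd_schedule, inject_missingness, simulate_breed,
                            simulate_founder_freqs)
from admixbreed.stats import pairwise_fst
from tests.conftest import build_gm


class TestFounderFreqs:
    def test_zero_divergence_identity(self):
        m = FounderModel(n_sites=500, divergence_fst=0.0, seed=1)
        pw, pd_ = simulate_founder_freqs(m)
        assert np.array_equal(pw, pd_)

    def test_extreme_divergence_near_fixation(self):
        m = FounderModel(n_sites=2000, divergence_fst=0.99, seed=1)
        pw, pd_ = simulate_founder_freqs(m)
        extreme = (np.minimum(pw, 1 - pw) < 0.05) & (np.minimum(pd_, 1 - pd_) < 0.05)
        assert extreme.mean() > 0.9

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError):
            FounderModel(divergence_fst=-0.1)
        with pytest.raises(ValueError):
            FounderModel(divergence_fst=1.0)

    def test_realized_fst_near_target(self):
        """WC F_ST over 50k sites from samples of the two gene pools."""
        m = FounderModel(n_sites=10_000, divergence_fst=0.35, seed=2)
        rng = np.random.default_rng(2)
        pw, pd_ = simulate_founder_freqs(m, rng)
        n = 30
        calls = np.vstack([
            (rng.random((n, len(pw))) < pw).astype(np.int8)
            + (rng.random((n, len(pw))) < pw).astype(np.int8),
            (rng.random((n, len(pd_))) < pd_).astype(np.int8)
            + (rng.random((n, len(pd_))) < pd_).astype(np.int8),
        ])
        chrom = np.repeat([str(c) for c in range(1, 6)], m.n_sites)
        gm = build_gm(calls, groups=["wild_parent"] * n + ["dom_parent"] * n,
                      chrom=list(chrom))
        fst = pairwise_fst(gm, ["wild_parent", "dom_parent"])
        assert 0.30 <= fst.genome_wide("wild_parent", "dom_parent") <= 0.40


class TestSimulateBreed:
    def test_f1_only_schedule_half_ancestry_no_switches(self, small_model):
        sch = BreedingSchedule([BreedingEvent(0, "found_f1", 20)])
        sim = simulate_breed(small_model(1), sch, GeneticMap(), seed=1,
                             n_ref_wolf=2, n_ref_dog=2)
        for sid in sim.breed_sample_ids():
            assert sim.truth_q[sid] == pytest.approx(0.5, abs=1e-12)
            assert sim.true_switches(sid) == 0

    def test_dog_backcross_quarter_ancestry(self, small_model):
        sch = BreedingSchedule([
            BreedingEvent(0, "found_f1", 30),
            BreedingEvent(1, "dog_backcross", 30, outcross_fraction=1.0)])
        qs = []
        for seed in range(4):
            sim = simulate_breed(small_model(seed), sch, GeneticMap(),
                                 seed=seed, n_ref_wolf=2, n_ref_dog=2)
            qs += [sim.truth_q[s] for s in sim.breed_sample_ids()]
        assert np.mean(qs) == pytest.approx(0.25, abs=0.03)

    def test_segments_tile_each_chromosome(self, default_sim):
        lengths = default_sim.model.chrom_lengths
        for hap_id, segs in default_sim.truth_tracks.items():
            by_chrom = {}
            for chrom, s, e, _o in segs:
                by_chrom.setdefault(chrom, []).append((s, e))
            assert set(by_chrom) == set(lengths)
            for chrom, pieces in by_chrom.items():
                assert pieces[0][0] == 0
                assert pieces[-1][1] == lengths[chrom]
                for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
                    assert e1 == s2              # no gap, no overlap

    def test_truth_q_equals_wolf_length_fraction(self, default_sim):
        total = 2.0 * sum(default_sim.model.chrom_lengths.values())
        for sid in default_sim.breed_sample_ids()[:5]:
            wolf = sum(e - s
                       for k in (1, 2)
                       for _c, s, e, o in default_sim.truth_tracks[f"{sid}_h{k}"]
                       if o == "wolf")
            assert default_sim.truth_q[sid] == pytest.approx(wolf / total)

    def test_every_nonfounder_has_both_parents(self, default_sim):
        for rec in default_sim.pedigree.records():
            if rec.sire is None:
                assert rec.pop_label in ("wolf", "dog")
            else:
                assert rec.sire in default_sim.pedigree
                assert rec.dam in default_sim.pedigree

    def test_haplotypes_consistent_with_genotypes(self, default_sim):
        default_sim.haplotypes.check_consistent(default_sim.genotypes)

    def test_reproducible_under_fixed_seed(self, small_model):
        sch = cwd_schedule(n_generations=8, census_start=20, census_end=12)
        a = simulate_breed(small_model(5), sch, GeneticMap(), seed=5,
                           n_ref_wolf=3, n_ref_dog=3)
        b = simulate_breed(small_model(5), sch, GeneticMap(), seed=5,
                           n_ref_wolf=3, n_ref_dog=3)
        assert np.array_equal(a.genotypes.calls, b.genotypes.calls)
        assert a.truth_q == b.truth_q
        assert a.truth_tracks == b.truth_tracks

    def test_mean_truth_q_matches_pedigree_expectation(self, small_model):
        """Allele-dropping consistency: E[truth_q] = pedigree expectation."""
        from admixbreed.pedigree import expected_ancestry_fraction
        sch = cwd_schedule(n_generations=10, census_start=24, census_end=16)
        diffs = []
        for seed in range(25):
            sim = simulate_breed(small_model(seed, n_sites=50), sch,
                                 GeneticMap(), seed=seed,
                                 n_ref_wolf=2, n_ref_dog=2)
            frac = expected_ancestry_fraction(sim.pedigree, "wolf")
            ids = sim.breed_sample_ids()
            diffs.append(np.mean([sim.truth_q[s] - frac[s] for s in ids]))
        assert abs(np.mean(diffs)) < 0.02

    def test_junction_count_grows_with_generations(self, small_model):
        means = []
        for g in (1, 3, 6, 10):
            events = [BreedingEvent(0, "found_f1", 40)]
            if g > 1:
                events.append(BreedingEvent(g - 1, "closed_breeding", 40))
            sch = BreedingSchedule(events)
            counts = []
            for seed in (0, 1):
                sim = simulate_breed(small_model(seed, n_sites=50), sch,
                                     GeneticMap(), seed=seed,
                                     n_ref_wolf=2, n_ref_dog=2)
                counts += [sim.true_switches(s) for s in sim.breed_sample_ids()]
            means.append(np.mean(counts))
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            BreedingSchedule([])

    def test_schedule_must_start_with_f1(self):
        with pytest.raises(ValueError):
            BreedingSchedule([BreedingEvent(0, "closed_breeding", 10)])


class TestInjectMissingness:
    def test_rate_zero_identity(self, default_sim):
        gm = inject_missingness(default_sim.genotypes, 0.0)
        assert gm is default_sim.genotypes

    def test_binomial_bounds_at_five_percent(self, make_gm):
        rng = np.random.default_rng(0)
        gm = make_gm(rng.integers(0, 3, size=(100, 1000)).astype(np.int8))
        out = inject_missingness(gm, 0.05, seed=1)
        n_missing = int((out.calls == MISSING).sum())
        assert 4_600 <= n_missing <= 5_400     # 99% binomial bounds at 100k calls

    def test_rate_one_rejected(self, make_gm):
        with pytest.raises(ValueError):
            inject_missingness(make_gm([[0]]), 1.0)

    def test_heavy_missingness_makes_site_removable(self, make_gm):
        from admixbreed.qc import remove_missing_sites
        gm = make_gm(np.ones((40, 1), dtype=np.int8))
        out = inject_missingness(gm, 0.5, seed=3)
        assert remove_missing_sites(out).n_sites == 0


def test_default_schedule_mirrors_breed_history():
    sch = cwd_schedule()
    kinds = {e.generation: e.kind for e in sch.events}
    assert kinds[0] == "found_f1"
    assert [g for g, k in kinds.items() if k == "wolf_introgression"] == [1, 3, 5, 8]
    assert sch.sampling_year() == 2012
    assert sch.generation_time_years == 3
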