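import itertools

import numpy as np
import pytest

from admixbreed.containers import MISSING
from admixbreed.stats import (allele_freq, ibd_pihat, inbreeding_f, ld_r2,
                              observed_heterozygosity, pairwise_fst, pca)
from tests.oracles import wc_theta_site


class TestHeterozygosity:
    def test_all_het_is_one_all_hom_is_zero(self, make_gm):
        gm = make_gm([[1, 1, 1], [0, 2, 0]])
        per_sample, _ = observed_heterozygosity(gm)
        assert per_sample["s0"] == 1.0
        assert per_sample["s1"] == 0.0

    def test_group_mean_and_missing_handling(self, make_gm):
        gm = make_gm([[1, MISSING], [0, 0]], groups=["breed", "breed"])
        per_sample, per_group = observed_heterozygosity(gm)
        assert per_sample["s0"] == 1.0       # over called sites only
        assert per_group["breed"] == 0.5

    def test_no_called_sites_flagged_nan(self, make_gm):
        gm = make_gm([[MISSING, MISSING], [0, 1]])
        per_sample, _ = observed_heterozygosity(gm)
        assert np.isnan(per_sample["s0"])


class TestInbreedingF:
    def test_three_site_hand_oracle(self, make_gm):
        # freqs from the group itself; hand computation below
        gm = make_gm([[0, 1, 2], [1, 1, 1], [2, 2, 0]],
                     groups=["breed"] * 3)
        p = allele_freq(gm, "breed")
        assert np.allclose(p, [0.5, 4 / 6, 0.5])
        f = inbreeding_f(gm)
        exp_hom = sum(1 - 2 * q * (1 - q) for q in p)   # 2 * (1/2) + 5/9
        # sample s0: 2 homozygous of 3 called sites
        assert f["s0"] == pytest.approx((2 - exp_hom) / (3 - exp_hom))
        # sample s1: fully heterozygous
        assert f["s1"] == pytest.approx((0 - exp_hom) / (3 - exp_hom))

    def test_fully_homozygous_at_half_freq_is_one(self, make_gm):
        calls = np.array([[0, 2, 0, 2]] * 2 + [[2, 0, 2, 0]] * 2)
        gm = make_gm(calls, groups=["breed"] * 4)
        f = inbreeding_f(gm)
        assert np.allclose(f, 1.0)

    def test_monomorphic_sites_flagged(self, make_gm):
        gm = make_gm([[2, 2], [2, 2]], groups=["breed"] * 2)
        f = inbreeding_f(gm)
        assert f.isna().all()


class TestPairwiseFst:
    def test_fixed_opposite_alleles_give_one(self, make_gm):
        gm = make_gm([[0, 0], [0, 0], [2, 2], [2, 2]],
                     groups=["wild_parent"] * 2 + ["dom_parent"] * 2)
        fst = pairwise_fst(gm, ["wild_parent", "dom_parent"])
        assert fst.genome_wide("wild_parent", "dom_parent") == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self, make_gm):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, size=3000)
        def draw(k):
            return ((rng.random((k, p.size)) < p).astype(np.int8)
                    + (rng.random((k, p.size)) < p).astype(np.int8))
        gm = make_gm(np.vstack([draw(15), draw(15)]),
                     groups=["wild_parent"] * 15 + ["dom_parent"] * 15)
        fst = pairwise_fst(gm, ["wild_parent", "dom_parent"])
        assert abs(fst.genome_wide("wild_parent", "dom_parent")) < 0.02

    def test_one_site_toy_matches_brute_force(self, make_gm):
        # group1: AA, AA, Aa, aa ; group2: aa, aa, aa, Aa (calls count 'a')
        calls = np.array([[0], [0], [1], [2], [2], [2], [2], [1]])
        gm = make_gm(calls, groups=["wild_parent"] * 4 + ["dom_parent"] * 4)
        fst = pairwise_fst(gm, ["wild_parent", "dom_parent"])
        a, b, c = wc_theta_site([calls[:4, 0], calls[4:, 0]])
        assert fst.per_site_theta("wild_parent", "dom_parent")[0] == \
            pytest.approx(a / (a + b + c))

    def test_matrix_symmetry_and_range(self, default_sim):
        fst = pairwise_fst(default_sim.genotypes,
                           ["breed", "wild_parent", "dom_parent"])
        m = fst.matrix.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        assert (m <= 1.0).all()

    def test_exhaustive_small_instances_match_oracle(self, make_gm):
        # all 2-group assignments of <= 6 samples over random small matrices
        rng = np.random.default_rng(12)
        for trial in range(8):
            n = int(rng.integers(4, 7))
            calls = rng.integers(0, 3, size=(n, 3)).astype(np.int8)
            for split in range(2, n - 1):
                groups = ["wild_parent"] * split + ["dom_parent"] * (n - split)
                gm = make_gm(calls, groups=groups)
                fst = pairwise_fst(gm, ["wild_parent", "dom_parent"])
                theta = fst.per_site_theta("wild_parent", "dom_parent")
                for j in range(3):
                    a, b, c = wc_theta_site([calls[:split, j], calls[split:, j]])
                    if np.isnan(a) or a + b + c == 0:
                        continue
                    assert theta[j] == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_group_too_small_rejected(self, make_gm):
        gm = make_gm([[0], [1], [2]],
                     groups=["wild_parent", "dom_parent", "dom_parent"])
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_fst(gm, ["wild_parent", "dom_parent"])


class TestPca:
    def test_duplicated_clusters_separate_on_pc1(self, make_gm):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, size=300)
        b = rng.integers(0, 3, size=300)
        calls = np.array([a, a, a, b, b, b], dtype=np.int8)
        coords, frac = pca(make_gm(calls), n_components=3)
        pc1 = coords["PC1"].to_numpy()
        assert np.allclose(pc1[:3], pc1[0])
        assert np.allclose(pc1[3:], pc1[3])
        assert abs(pc1[0] - pc1[3]) > 1.0
        assert np.all(np.diff(frac) <= 1e-12)   # non-increasing
        assert frac.sum() <= 1.0 + 1e-9

    def test_breed_intermediate_between_parents(self, default_sim):
        gm = default_sim.genotypes
        coords, _ = pca(gm, n_components=2)
        means = {g: coords["PC1"][gm.groups == g].mean()
                 for g in ("breed", "wild_parent", "dom_parent")}
        lo = min(means["wild_parent"], means["dom_parent"])
        hi = max(means["wild_parent"], means["dom_parent"])
        assert lo < means["breed"] < hi

    def test_zero_variance_rejected(self, make_gm):
        gm = make_gm(np.ones((3, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            pca(gm)


class TestLdR2:
    def test_identical_and_independent_vectors(self, make_gm):
        gm = make_gm([[0, 0, 0, 1], [1, 1, 2, 1], [2, 2, 0, 1], [1, 1, 2, 1]])
        assert ld_r2(gm, 0, 1) == pytest.approx(1.0)
        assert np.isnan(ld_r2(gm, 0, 3))        # zero variance flagged

    def test_hand_computed_toy(self, make_gm):
        x = np.array([0, 1, 2, 2])
        y = np.array([1, 0, 2, 1])
        gm = make_gm(np.stack([x, y], axis=1))
        r = np.corrcoef(x, y)[0, 1]
        assert ld_r2(gm, 0, 1) == pytest.approx(r * r)

    def test_orthogonal_vectors_zero(self, make_gm):
        gm = make_gm(np.array([[0, 0], [0, 2], [2, 0], [2, 2]]))
        assert ld_r2(gm, 0, 1) == pytest.approx(0.0, abs=1e-12)


class TestIbdPihat:
    @staticmethod
    def _founder_population(rng, n, m):
        p = rng.uniform(0.1, 0.9, size=m)
        haps = rng.random((2 * n, m)) < p
        return haps.astype(np.int8)

    def test_duplicated_sample_is_one(self, make_gm):
        rng = np.random.default_rng(1)
        haps = self._founder_population(rng, 20, 2000)
        calls = haps[0::2] + haps[1::2]
        calls[1] = calls[0]                   # duplicate
        gm = make_gm(calls)
        res = ibd_pihat(gm, ("s0", "s1"))
        assert res["pi_hat"] > 0.95

    def test_unrelated_founders_near_zero(self, make_gm):
        rng = np.random.default_rng(2)
        haps = self._founder_population(rng, 30, 5000)
        gm = make_gm(haps[0::2] + haps[1::2])
        vals = [ibd_pihat(gm, (f"s{i}", f"s{i + 1}"))["pi_hat"]
                for i in range(0, 10, 2)]
        assert np.mean(vals) < 0.05

    def test_parent_offspring_and_sib_expectations(self, make_gm):
        rng = np.random.default_rng(3)
        m = 10_000
        p = rng.uniform(0.1, 0.9, size=m)

        def founder():
            return (rng.random((2, m)) < p).astype(np.int8)

        def child(pa, ma):
            return np.stack([pa[rng.integers(0, 2, m), np.arange(m)],
                             ma[rng.integers(0, 2, m), np.arange(m)]])

        parents = [founder() for _ in range(20)]
        pa, ma, pb = parents[0], parents[1], parents[2]
        kids = [child(pa, ma) for _ in range(2)]        # full sibs
        half = child(pa, pb)
        everyone = parents + kids + [half]
        calls = np.array([h.sum(axis=0) for h in everyone], dtype=np.int8)
        ids = [f"s{i}" for i in range(len(everyone))]
        gm = make_gm(calls, sample_ids=ids)
        po = ibd_pihat(gm, ("s0", "s20"))["pi_hat"]      # parent-offspring
        fs = ibd_pihat(gm, ("s20", "s21"))["pi_hat"]     # full sibs
        hs = ibd_pihat(gm, ("s20", "s22"))["pi_hat"]     # half sibs
        assert po == pytest.approx(0.5, abs=0.05)
        assert fs == pytest.approx(0.5, abs=0.05)
        assert hs == pytest.approx(0.25, abs=0.05)

    def test_low_confidence_flag(self, make_gm):
        gm = make_gm(np.array([[0, 1, 2], [2, 1, 0]]))
        res = ibd_pihat(gm, ("s0", "s1"))
        assert res["low_confidence"]


def test_breed_heterozygosity_exceeds_parental_mean(default_sim):
    """Admixture keeps breed H_o above the (inbred) parental average."""
    _, ho = observed_heterozygosity(default_sim.genotypes)
    assert ho["breed"] > 0.5 * (ho["wild_parent"] + ho["dom_parent"])
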