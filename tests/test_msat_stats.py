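"""Microsatellite statistics against hand-computed and planted oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from peony import coalsim, msat_stats, synthetic_data
from peony.datatypes import MISSING, GenotypeDataset
from peony.msat_stats import (
    DistancePair,
    allelic_richness,
    amova,
    genotype_pca,
    heterozygosities,
    linearize_fst,
    mantel,
    mantel_ibd,
    pairwise_fst,
    private_alleles,
    relative_migration,
    shared_allele_distance,
    shared_allele_nj,
    wc_theta,
)


def _ds(genos_by_pop: dict[str, list], species: dict[str, str] | None = None):
    alleles, pops, sp = [], [], []
    for pop, genos in genos_by_pop.items():
        for g in genos:
            alleles.append(g)
            pops.append(pop)
            sp.append((species or {}).get(pop, "S1"))
    return GenotypeDataset(np.array(alleles), pops, sp)


class TestHeterozygosity:
    def test_hand_example(self):
        """One locus, genotypes {(100,100), (100,102)}: H_O = 0.5 and Nei's
        unbiased H_E = (4/3)(1 - 0.75^2 - 0.25^2) = 0.5."""
        ds = _ds({"A": [[[100, 100]], [[100, 102]]]})
        rep = heterozygosities(ds)
        assert rep.loc["A", "H_O"] == pytest.approx(0.5)
        assert rep.loc["A", "H_E"] == pytest.approx(0.5)

    def test_monomorphic(self):
        ds = _ds({"A": [[[100, 100]], [[100, 100]]]})
        rep = heterozygosities(ds)
        assert rep.loc["A", "H_O"] == 0 and rep.loc["A", "H_E"] == 0

    @pytest.mark.parametrize("n", [2, 5, 11])
    def test_all_heterozygotes_closed_form(self, n):
        ds = _ds({"A": [[[100, 102]]] * n})
        rep = heterozygosities(ds)
        assert rep.loc["A", "H_O"] == pytest.approx(1.0)
        assert rep.loc["A", "H_E"] == pytest.approx(2 * n / (2 * n - 1) * 0.5)

    def test_missing_calls_excluded(self):
        ds = _ds({"A": [[[100, 102]], [[MISSING, MISSING]]]})
        rep = heterozygosities(ds)
        assert rep.loc["A", "H_O"] == pytest.approx(1.0)


class TestAllelicRichness:
    def test_fixed_locus_is_one(self):
        ds = _ds({"A": [[[100, 100]], [[100, 100]]]})
        assert allelic_richness(ds, 2)["A"] == pytest.approx(1.0)

    def test_binomial_arithmetic_example(self):
        """N=4 gene copies with counts {3, 1}, g=2:
        2 - C(1,2)/C(4,2) - C(3,2)/C(4,2) = 1.5."""
        ds = _ds({"A": [[[100, 100]], [[100, 102]]]})
        assert allelic_richness(ds, 2)["A"] == pytest.approx(1.5)

    def test_g_equal_to_sample_gives_allele_count(self):
        ds = _ds({"A": [[[100, 102]], [[104, 106]]]})
        assert allelic_richness(ds, 4)["A"] == pytest.approx(4.0)

    def test_g_below_two_rejected(self):
        ds = _ds({"A": [[[100, 102]], [[104, 106]]]})
        with pytest.raises(ValueError):
            allelic_richness(ds, 1)


class TestPrivateAlleles:
    def test_unique_and_shared(self):
        ds = _ds({
            "A": [[[100, 102]]],
            "B": [[[100, 104]]],
        })
        ap = private_alleles(ds)
        assert ap["A"] == 1  # 102 only in A
        assert ap["B"] == 1  # 104 only in B; 100 shared, not private

    def test_planted_recovery(self):
        rng = np.random.default_rng(3)
        base = rng.choice([100, 102], size=(12, 5, 2))
        ds = GenotypeDataset(base, ["A"] * 6 + ["B"] * 6, ["S"] * 12)
        ds.alleles[0, 2, 0] = 130  # plant one allele unique to A
        ap = private_alleles(ds)
        assert ap["A"] >= 1
        ds.alleles[7, 2, 0] = 130  # now shared
        assert private_alleles(ds)["A"] == ap["A"] - 1


class TestWeirCockerham:
    def test_hand_computed_toy(self):
        """2 pops x 2 individuals, frozen from an explicit evaluation of the
        variance components: theta = (1/16 + 1/16)/(2*(1/16 + 0 + 1/4)) = 0.2."""
        ds = _ds({
            "A": [[[100, 100]], [[100, 102]]],
            "B": [[[102, 102]], [[100, 102]]],
        })
        fst = pairwise_fst(ds)
        assert fst.matrix.loc["A", "B"] == pytest.approx(0.2, abs=1e-12)

    def test_independent_scalar_evaluation(self):
        """Multi-locus theta equals a direct loop transcription of the 1984
        component formulas."""
        rng = np.random.default_rng(8)
        al = rng.choice([100, 102, 104], size=(16, 4, 2))
        ds = GenotypeDataset(al, ["A"] * 8 + ["B"] * 8, ["S"] * 16)

        num = den = 0.0
        for l in range(4):
            for allele in np.unique(al[:, l, :]):
                n = np.array([8.0, 8.0])
                blocks = [al[:8, l, :], al[8:, l, :]]
                p = np.array([(b == allele).mean() for b in blocks])
                h = np.array([np.mean((b[:, 0] != b[:, 1])
                                      & ((b[:, 0] == allele) | (b[:, 1] == allele)))
                              for b in blocks])
                r, nbar = 2, 8.0
                nc = (16 - (64 + 64) / 16) / (r - 1)
                pbar = (n * p).sum() / 16
                s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
                hbar = (n * h).sum() / 16
                inner = pbar * (1 - pbar) - (r - 1) / r * s2
                a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
                b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
                c = hbar / 2
                num += a
                den += a + b + c
        expected = num / den
        got = pairwise_fst(ds).matrix.loc["A", "B"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(1)
        al = rng.choice([100, 102, 104], size=(30, 6, 2))
        ds = GenotypeDataset(np.vstack([al, al]), ["A"] * 30 + ["B"] * 30, ["S"] * 60)
        theta = pairwise_fst(ds).matrix.loc["A", "B"]
        assert theta <= 0.001

    def test_fixed_difference_is_one(self):
        ds = _ds({
            "A": [[[100, 100]]] * 4,
            "B": [[[104, 104]]] * 4,
        })
        assert pairwise_fst(ds).matrix.loc["A", "B"] == pytest.approx(1.0)


class TestAmova:
    @staticmethod
    def _direct_two_pop(d, n1, n2):
        """Independent sums-of-squares evaluation for a one-level design."""
        n = n1 + n2
        idx_all = np.arange(n)
        ssd_t = d[np.ix_(idx_all, idx_all)].sum() / (2 * n)
        ssd_w = (d[:n1, :n1].sum() / (2 * n1)) + (d[n1:, n1:].sum() / (2 * n2))
        ssd_a = ssd_t - ssd_w
        df_b, df_c = 1, n - 2
        ms_c = ssd_w / df_c
        n0 = (n - (n1**2 + n2**2) / n) / df_b
        sig_b = (ssd_a / df_b - ms_c) / n0
        return sig_b, ms_c

    def test_components_match_direct_evaluation(self):
        """One-level AMOVA on a toy two-population table equals the explicit
        Excoffier sums-of-squares computation to 1e-10."""
        rng = np.random.default_rng(4)
        d = rng.integers(0, 5, size=(9, 9)).astype(float)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        pops = np.array(["A"] * 4 + ["B"] * 5)
        res = msat_stats.amova_from_distances(d, pops, n_perm=0)
        sig_b, sig_c = self._direct_two_pop(d, 4, 5)
        assert res["raw_components"]["among_pops"] == pytest.approx(sig_b, abs=1e-10)
        assert res["raw_components"]["within_pops"] == pytest.approx(sig_c, abs=1e-10)
        phi_direct = max(sig_b, 0) / (max(sig_b, 0) + sig_c)
        assert res["phi"]["phi_ST"] == pytest.approx(phi_direct, abs=1e-10)

    def test_null_pool_has_no_structure(self):
        rng = np.random.default_rng(9)
        al = rng.choice([100, 102, 104, 106], size=(48, 6, 2))
        pops = np.repeat([f"P{i}" for i in range(6)], 8)
        sp = np.repeat(["S1", "S2", "S3"], 16)
        ds = GenotypeDataset(al, pops, sp)
        res = amova(ds, n_perm=200, seed=2)
        assert res["percent"]["among_species"] < 5
        assert res["p"]["phi_CT"] > 0.05

    def test_planted_species_divergence_dominates(self, small_three_species):
        ds = small_three_species
        # split each species into two arbitrary "populations"
        pops = np.array([f"{s}{i % 2}" for i, s in enumerate(ds.species)], dtype=object)
        ds2 = GenotypeDataset(ds.alleles, pops, ds.species)
        res = amova(ds2, n_perm=100, seed=3)
        assert res["percent"]["among_species"] > res["percent"]["among_pops_within_species"]
        assert res["p"]["phi_CT"] <= 0.05 or res["percent"]["among_species"] > 20

    def test_percentages_sum_to_100(self, small_three_species):
        res = amova(small_three_species, n_perm=0)
        assert sum(res["percent"].values()) == pytest.approx(100.0, abs=1e-9)


class TestMantel:
    def test_affine_relation_gives_r_one(self):
        m = np.abs(np.subtract.outer(np.arange(6), np.arange(6))).astype(float)
        r, p = mantel(m, 3.0 * m + 1 - np.eye(6), n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_linearization_rejects_fst_one_without_clamp(self):
        mat = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"],
                           columns=["A", "B"])
        fst = DistancePair(mat, "fst")
        with pytest.raises(ValueError, match="clamp"):
            linearize_fst(fst)
        lin = linearize_fst(fst, clamp=0.999)
        assert lin.matrix.loc["A", "B"] == pytest.approx(0.999 / 0.001)

    def test_ibd_power_on_stepping_stone(self):
        """Planted isolation by distance is detected in most replicates."""
        hits = 0
        n_rep = 10
        for s in range(n_rep):
            ds = synthetic_data.make_stepping_stone(
                n_demes=6, n_ind=10, n_loci=12, pop_size=800, m=1e-3, seed=s + 1)
            fst = pairwise_fst(ds)
            r, p = mantel_ibd(fst, ds.coords, n_perm=199, seed=s, clamp=0.999)
            hits += p <= 0.05
        assert hits >= 0.8 * n_rep

    def test_missing_coordinates_rejected(self):
        mat = pd.DataFrame(np.zeros((2, 2)), index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="missing"):
            mantel_ibd(DistancePair(mat, "fst"),
                       pd.DataFrame({"lat": [0.0], "lon": [0.0]}, index=["A"]))


class TestClusteringSurfaces:
    def test_clones_have_zero_distance(self):
        al = np.array([[[100, 102], [104, 104]]] * 2)
        ds = GenotypeDataset(al, ["A", "A"], ["S", "S"])
        d = shared_allele_distance(ds)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_nj_recovers_additive_topology(self):
        """Four genotypes built so that shared-allele distances are additive
        with ((i0,i1),(i2,i3)) structure."""
        al = np.array([
            [[1, 1], [3, 3], [5, 5], [7, 7]],
            [[1, 1], [3, 3], [5, 5], [8, 8]],
            [[2, 2], [4, 4], [6, 6], [9, 9]],
            [[2, 2], [4, 4], [6, 6], [10, 10]],
        ])
        ds = GenotypeDataset(al, ["P"] * 4, ["S"] * 4)
        newick = shared_allele_nj(ds)
        import skbio

        tree = skbio.TreeNode.read([newick])
        names = {t.name for t in tree.tips()}
        assert len(names) == 4
        # the cherry (i0, i1) must be separated from (i2, i3) by an edge
        tip0 = next(t for t in tree.tips() if t.name.startswith("i0"))
        sibs = {t.name for t in tip0.parent.tips()}
        assert sibs in ({tip0.name, next(n for n in names if n.startswith("i1"))},
                        names - {tip0.name} - {next(n for n in names if n.startswith("i1"))})

    def test_species_monophyly_in_nj_tree(self):
        """Individuals cluster by species in nearly all replicate seeds."""
        import skbio

        spec = coalsim.get_scenario(1)
        params = coalsim.ScenarioParams(nj=800, nq=800, nr=800, a1=800, a2=800,
                                        t1=6000, t2=12000, mu=5e-4)
        cfg = {"PJ": 8, "PQ": 8, "PR": 8}
        good = 0
        n_rep = 10
        for s in range(n_rep):
            ds = coalsim.simulate_scenario(spec, params, cfg, 15, seed=s + 1)
            tree = skbio.TreeNode.read([shared_allele_nj(ds)])
            species_sets = {
                sp: {f"i{j}_{p}" for j, p in enumerate(ds.pop) if p == sp}
                for sp in ("PJ", "PQ", "PR")
            }
            tips_all = {t.name for t in tree.tips()}
            splits = set()
            for node in tree.non_tips(include_self=False):
                below = frozenset(t.name for t in node.tips())
                splits.add(below)
                splits.add(frozenset(tips_all - below))
            if all(frozenset(s_) in splits for s_ in species_sets.values()):
                good += 1
        assert good >= 0.9 * n_rep

    def test_pca_separates_species(self):
        spec = coalsim.get_scenario(1)
        params = coalsim.ScenarioParams(nj=800, nq=800, nr=800, a1=800, a2=800,
                                        t1=8000, t2=16000, mu=5e-4)
        ds = coalsim.simulate_scenario(spec, params, {"PJ": 20, "PR": 20}, 15, seed=4,
                                       pop_species={"PJ": "PJ", "PR": "PR"})
        scores, var, ratio = genotype_pca(ds)
        # species separation on the leading axes
        best = 0.0
        for k in range(min(3, scores.shape[1])):
            pc = scores[:, k]
            a, b = pc[ds.species == "PJ"], pc[ds.species == "PR"]
            pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            if pooled_sd > 0:
                best = max(best, abs(a.mean() - b.mean()) / pooled_sd)
        assert best > 3.0
        assert np.all(np.diff(var) <= 1e-9)  # non-increasing
        assert ratio.sum() == pytest.approx(1.0)

    def test_pca_constant_matrix_no_crash(self):
        al = np.tile(np.array([[100, 100]]), (5, 3, 1))
        ds = GenotypeDataset(al, ["A"] * 5, ["S"] * 5)
        scores, var, _ = genotype_pca(ds)
        assert np.allclose(var, 0.0)


class TestRelativeMigration:
    def test_symmetric_island_model(self):
        ratios = []
        for s in range(8):
            ds = synthetic_data.make_island_pair(
                20, 12, pop_size=1500, m_ab=2e-3, m_ba=2e-3, mu=5e-4, seed=s + 1)
            m = relative_migration(ds)
            ratios.append(m.loc["A", "B"] / m.loc["B", "A"])
        assert 0.8 <= np.mean(ratios) <= 1.25

    def test_source_sink_asymmetry(self):
        """Moderate one-way gene flow (4Nm ~ 6 vs ~ 0.06): the sink resembles
        the hypothetical pool, so the source->sink entry is the larger one."""
        hits = 0
        n_rep = 10
        for s in range(n_rep):
            ds = synthetic_data.make_island_pair(
                20, 25, pop_size=800, m_ab=2e-3, m_ba=2e-5, mu=5e-4, seed=s + 101)
            m = relative_migration(ds)
            hits += m.loc["A", "B"] > m.loc["B", "A"]
        assert hits >= 0.8 * n_rep

    def test_scaled_to_max_one(self, small_three_species):
        m = relative_migration(small_three_species, level="species")
        assert np.nanmax(m.to_numpy()) == pytest.approx(1.0)
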