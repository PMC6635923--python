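"""ABC machinery: summary statistics, reference table, scenario choice,
parameter estimation and posterior checking (small-scale; the full
desk-scale runs live in the acceptance suite)."""

import warnings

import numpy as np
import pandas as pd
import pytest

from peony import abc_inference as abc
from peony import coalsim
from peony.abc_inference import (
    ReferenceTable,
    STAT_NAMES,
    build_reference,
    choose_scenario,
    estimate_params,
    model_check,
    summarize,
)
from peony.coalsim import PriorConfig, ScenarioParams
from peony.datatypes import GenotypeDataset

SMALL = {"PJ": 12, "PQ": 12, "PR": 12}
PARAMS = ScenarioParams(nj=1000, nq=1000, nr=1000, a1=1000, a2=1000,
                        t1=3000, t2=9000, mu=5e-4)


def _three_group_ds(blocks):
    alleles = np.concatenate(blocks)
    n = len(blocks[0])
    pops = np.repeat(["PJ", "PQ", "PR"], [len(b) for b in blocks])
    return GenotypeDataset(alleles, pops, pops.copy())


class TestSummarize:
    def test_identical_groups_have_no_divergence(self):
        rng = np.random.default_rng(0)
        block = rng.choice([100, 102, 104], size=(10, 5, 2))
        ds = _three_group_ds([block, block.copy(), block.copy()])
        s = summarize(ds)
        stats = dict(zip(STAT_NAMES, s))
        for pair in ("PJPQ", "PJPR", "PQPR"):
            # theta of duplicated samples is slightly negative, never positive
            assert stats[f"fst_{pair}"] <= 0.001
            assert stats[f"dmu2_{pair}"] == pytest.approx(0.0)

    def test_fixed_size_difference_gives_dmu2(self):
        a = np.full((6, 3, 2), 100)
        b = np.full((6, 3, 2), 104)
        ds = _three_group_ds([a, b, a.copy()])
        stats = dict(zip(STAT_NAMES, summarize(ds)))
        assert stats["dmu2_PJPQ"] == pytest.approx(16.0)
        assert stats["dmu2_PJPR"] == pytest.approx(0.0)

    def test_matches_bruteforce_per_locus(self):
        """Vectorized summary equals a naive per-locus recomputation."""
        ds = coalsim.simulate_scenario(coalsim.get_scenario(1), PARAMS, SMALL,
                                       8, seed=5)
        s = dict(zip(STAT_NAMES, summarize(ds)))
        groups = ds.group_indices("species")
        # mean number of alleles + He, naive loops
        for sp in ("PJ", "PQ", "PR"):
            nas, hes = [], []
            for l in range(ds.n_loci):
                g = ds.alleles[groups[sp], l, :]
                vals, counts = np.unique(g, return_counts=True)
                nas.append(len(vals))
                n2 = g.size
                hes.append(n2 / (n2 - 1) * (1 - ((counts / n2) ** 2).sum()))
            assert s[f"mean_alleles_{sp}"] == pytest.approx(np.mean(nas))
            assert s[f"mean_he_{sp}"] == pytest.approx(np.mean(hes))
        # (delta mu)^2, naive
        for a, b, key in (("PJ", "PQ", "dmu2_PJPQ"), ("PQ", "PR", "dmu2_PQPR")):
            vals = []
            for l in range(ds.n_loci):
                ma = ds.alleles[groups[a], l, :].mean()
                mb = ds.alleles[groups[b], l, :].mean()
                vals.append((ma - mb) ** 2)
            assert s[key] == pytest.approx(np.mean(vals))

    def test_tiny_group_rejected(self):
        a = np.full((6, 3, 2), 100)
        ds = GenotypeDataset(np.concatenate([a, a[:1], a]),
                             ["PJ"] * 6 + ["PQ"] + ["PR"] * 6,
                             ["PJ"] * 6 + ["PQ"] + ["PR"] * 6)
        with pytest.raises(ValueError, match="fewer than 2"):
            summarize(ds)


class TestReferenceTable:
    def test_row_count_and_determinism(self, prior):
        scen = {1: coalsim.get_scenario(1), 2: coalsim.get_scenario(2)}
        t1 = build_reference(scen, prior, 10, SMALL, 5, seed=3)
        t2 = build_reference(scen, prior, 10, SMALL, 5, seed=3)
        assert len(t1.frame) == 20
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_save_load_roundtrip(self, prior, tmp_path):
        scen = {1: coalsim.get_scenario(1)}
        t = build_reference(scen, prior, 5, SMALL, 4, seed=9)
        t.save(tmp_path / "ref.csv")
        back = ReferenceTable.load(tmp_path / "ref.csv")
        pd.testing.assert_frame_equal(
            back.frame, t.frame, check_dtype=False, atol=1e-12)
        assert back.provenance["seed"] == 9


def _uninformative_table(rng, n=400):
    """Statistics independent of the scenario label."""
    stats = rng.normal(0, 1, size=(n, len(STAT_NAMES)))
    frame = pd.DataFrame(stats, columns=list(STAT_NAMES))
    frame.insert(0, "scenario_id", rng.permutation(np.repeat([1, 2], n // 2)))
    for i, p in enumerate(coalsim.PARAM_NAMES):
        frame[p] = rng.uniform(10, 100, size=n)
    return ReferenceTable(frame)


class TestChooseScenario:
    def test_uninformative_table_gives_uniform_posterior(self):
        rng = np.random.default_rng(12)
        table = _uninformative_table(rng)
        obs = np.zeros(len(STAT_NAMES))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            choice = choose_scenario(obs, table, tolerance=0.25, seed=1)
        assert choice.posterior[1] == pytest.approx(0.5, abs=0.2)
        assert sum(choice.posterior.values()) == pytest.approx(1.0, abs=1e-9)

    def test_probabilities_sum_to_one_and_ci_order(self):
        rng = np.random.default_rng(5)
        table = _uninformative_table(rng)
        # make the stats informative: shift scenario 2 rows
        mask = table.frame["scenario_id"] == 2
        table.frame.loc[mask, list(STAT_NAMES)] += 3.0
        obs = np.zeros(len(STAT_NAMES))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            choice = choose_scenario(obs, table, tolerance=0.3, seed=2)
        assert sum(choice.posterior.values()) == pytest.approx(1.0, abs=1e-9)
        assert choice.best() == 1
        for sid, (lo, hi) in choice.ci95.items():
            assert lo <= choice.posterior[sid] + 1e-6
            assert hi >= choice.posterior[sid] - 1e-6

    def test_planted_truth_recovered_under_extreme_divergence(self, prior):
        """Scenarios separated in statistic space: the generating one wins."""
        scen = {1: coalsim.get_scenario(1), 2: coalsim.get_scenario(2)}
        # make the two scenarios artificially distinct through the priors:
        # build a table under very different parameter draws per scenario
        rng = np.random.default_rng(3)
        rows = []
        for sid, t2 in ((1, 20000.0), (2, 50.0)):
            spec = coalsim.get_scenario(sid)
            p = ScenarioParams(nj=1000, nq=1000, nr=1000, a1=1000, a2=1000,
                               t1=40.0 if sid == 2 else 10000.0, t2=t2, mu=5e-4)
            for r in range(60):
                a, pops, psp = coalsim.simulate_allele_array(
                    spec, p, SMALL, 6, seed=int(rng.integers(1, 2**31 - 1)))
                blocks = abc._species_blocks(pops, psp, SMALL)
                rows.append([sid, *[getattr(p, k) for k in coalsim.PARAM_NAMES],
                             *abc.summarize_alleles(a, blocks)])
        table = ReferenceTable(pd.DataFrame(
            rows, columns=["scenario_id", *coalsim.PARAM_NAMES, *STAT_NAMES]))
        p1 = ScenarioParams(nj=1000, nq=1000, nr=1000, a1=1000, a2=1000,
                            t1=10000.0, t2=20000.0, mu=5e-4)
        obs = abc.simulate_pod(coalsim.get_scenario(1), p1, SMALL, 6, seed=77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            choice = choose_scenario(obs, table, tolerance=0.3, seed=4)
        assert choice.posterior[1] > 0.5


class TestEstimateParams:
    def test_self_assignment_sanity(self, prior):
        """Using a table row's own statistics as the observation, the
        posterior median lands inside the central range of retained draws."""
        scen = {1: coalsim.get_scenario(1)}
        table = build_reference(scen, prior, 150, SMALL, 6, seed=21)
        row = table.frame.iloc[40]
        obs = row[list(STAT_NAMES)].to_numpy(dtype=float)
        est = estimate_params(obs, table, 1, prior, tolerance=0.3)
        for name in ("nj", "t2", "mu"):
            lo, hi = est.sample[name].quantile([0.05, 0.95])
            assert lo - 1e-9 <= est.quantiles.loc["median", name] <= hi + 1e-9

    def test_full_tolerance_recovers_prior(self, prior):
        """tolerance=1 with no local-linear signal: posterior ~ prior."""
        from scipy import stats as sps

        rng = np.random.default_rng(6)
        table = _uninformative_table(rng, n=600)
        obs = np.zeros(len(STAT_NAMES))
        est = estimate_params(obs, table, 1, PriorConfig(n_lo=10, n_hi=100),
                              tolerance=1.0)
        # adjusted draws still span the prior; compare against the table draws
        ks = sps.ks_2samp(est.sample["nj"],
                          table.frame.loc[table.frame.scenario_id == 1, "nj"])
        assert ks.pvalue > 0.01

    def test_quantiles_report_years(self, prior):
        scen = {1: coalsim.get_scenario(1)}
        table = build_reference(scen, prior, 60, SMALL, 4, seed=31)
        obs = table.frame.iloc[0][list(STAT_NAMES)].to_numpy(dtype=float)
        est = estimate_params(obs, table, 1, prior, tolerance=0.5)
        assert est.quantiles.loc["median", "t1_years"] == pytest.approx(
            est.quantiles.loc["median", "t1"] * 10.0)


class TestModelCheckAndErrors:
    def test_posterior_predictive_p_in_range(self, prior):
        scen = {1: coalsim.get_scenario(1)}
        table = build_reference(scen, prior, 80, SMALL, 5, seed=41)
        obs = abc.simulate_pod(coalsim.get_scenario(1), PARAMS, SMALL, 5, seed=55)
        est = estimate_params(obs, table, 1, prior, tolerance=0.3)
        p = model_check(obs, est, coalsim.get_scenario(1), SMALL, 5,
                        n_rep=30, seed=3)
        assert np.all((p.to_numpy() >= 0) & (p.to_numpy() <= 1))

    def test_gross_misfit_detected(self, prior):
        """An observation far outside the model's reach leaves at least one
        statistic in the extreme tail."""
        scen = {1: coalsim.get_scenario(1)}
        table = build_reference(scen, prior, 80, SMALL, 5, seed=43)
        obs = abc.simulate_pod(coalsim.get_scenario(1), PARAMS, SMALL, 5, seed=56)
        est = estimate_params(obs, table, 1, prior, tolerance=0.3)
        silly = obs.copy()
        silly[:3] = 40.0  # mean alleles far beyond anything simulable
        p = model_check(silly, est, coalsim.get_scenario(1), SMALL, 5,
                        n_rep=30, seed=4)
        assert p.min() < 0.05

    def test_pod_count_validated(self, prior):
        scen = {1: coalsim.get_scenario(1), 2: coalsim.get_scenario(2)}
        table = _uninformative_table(np.random.default_rng(1))
        with pytest.raises(ValueError, match="20"):
            abc.confidence_errors(table, scen, prior, SMALL, 4, 1, n_pods=5)
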