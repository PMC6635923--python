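"""Neutrality tests and mismatch-distribution demography for cpDNA groups.

Tajima's D and Fu's Fs detect departures from the constant-size neutral
coalescent; the mismatch distribution (histogram of pairwise sequence
differences) is fit with the sudden-expansion model of Rogers & Harpending
(parameters tau, theta0, theta1) and assessed by the sum of squared
deviations (SSD) and Harpending's raggedness index, with parametric
bootstrap p-values from coalescent simulation under the fitted expansion.

Sequences are compared position-wise; characters ``N`` are treated as
missing.  Groups are species-pooled individuals by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datatypes import HaplotypeTable


def group_sequences(table: HaplotypeTable, group: str | list[str]) -> list[str]:
    """Expand a (pooled) group of populations into per-individual sequences."""
    pops = [group] if isinstance(group, str) else list(group)
    pooled: list[str] = []
    for p in pops:
        for h, c in table.counts[p].items():
            pooled.extend([table.haplotypes[h]] * int(c))
    return pooled


def _seq_array(seqs: list[str]) -> np.ndarray:
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    return np.array([list(s.upper()) for s in seqs])


def pairwise_difference_counts(seqs: list[str]) -> np.ndarray:
    """Condensed vector of pairwise difference counts (missing-aware)."""
    arr = _seq_array(seqs)
    n = len(seqs)
    out = []
    for i in range(n):
        ok_i = arr[i] != "N"
        for j in range(i + 1, n):
            ok = ok_i & (arr[j] != "N")
            out.append(int(np.sum((arr[i] != arr[j]) & ok)))
    return np.array(out)


def segregating_sites(seqs: list[str]) -> int:
    arr = _seq_array(seqs)
    s = 0
    for col in arr.T:
        vals = set(col) - {"N"}
        if len(vals) > 1:
            s += 1
    return s


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(seqs: list[str]) -> float:
    """Tajima's (1989) D; returns 0 with a warning when S = 0 (undefined)."""
    n = len(seqs)
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4 sequences")
    s = segregating_sites(seqs)
    if s == 0:
        warnings.warn("no segregating sites: Tajima's D undefined, returning 0")
        return 0.0
    k = pairwise_difference_counts(seqs).mean()
    c = _tajima_constants(n)
    return float((k - s / c["a1"]) / math.sqrt(c["e1"] * s + c["e2"] * s * (s - 1)))


def tajimas_d_from_stats(n: int, s: int, mean_pairwise: float) -> float:
    """D from precomputed (n, S, mean pairwise differences)."""
    if s == 0:
        return 0.0
    c = _tajima_constants(n)
    return float(
        (mean_pairwise - s / c["a1"]) / math.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))
    )


# ---------------------------------------------------------------------------
# Fu's Fs


def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    logs = np.full(n + 1, -np.inf)
    logs[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        shifted = np.concatenate([[-np.inf], logs[:-1]])  # k-1 term
        with np.errstate(invalid="ignore"):
            new = np.logaddexp(math.log(m) + logs, shifted)
        logs = new
    return logs


def fus_fs(seqs: list[str] | None = None, *, n: int | None = None,
           k_obs: int | None = None, theta: float | None = None) -> float:
    """Fu's (1997) Fs from the Ewens sampling formula.

    ``S' = P(K >= k_obs | theta-hat, n)`` with theta-hat the mean number of
    pairwise differences and K the number of distinct haplotypes;
    ``Fs = ln(S' / (1 - S'))``.  Degenerate cases (S' of 0 or 1) are guarded
    and return +-inf with a warning.
    """
    if seqs is not None:
        if len(seqs) < 2:
            raise ValueError("Fu's Fs needs n >= 2 sequences")
        n = len(seqs)
        k_obs = len(set(seqs))
        theta = float(pairwise_difference_counts(seqs).mean())
    assert n is not None and k_obs is not None and theta is not None
    if theta <= 0 or k_obs <= 1:
        warnings.warn("S' = 1 (monomorphic or single haplotype): Fs -> +inf")
        return float("inf")
    logs = _log_stirling_first(n)
    log_theta = math.log(theta)
    log_rising = sum(math.log(theta + i) for i in range(n))
    log_pk = logs[1:] + np.arange(1, n + 1) * log_theta - log_rising
    log_sp = float(np.logaddexp.reduce(log_pk[k_obs - 1:]))
    sp = math.exp(min(log_sp, 0.0))
    if sp >= 1.0:
        warnings.warn("S' numerically 1: Fs -> -inf guarded")
        return float("-inf")
    if sp <= 0.0:
        warnings.warn("S' numerically 0: Fs -> +inf guarded")
        return float("inf")
    return float(math.log(sp / (1.0 - sp)))


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta, n) for k = 1..n (independent check for Fs)."""
    logs = _log_stirling_first(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    log_pk = logs[1:] + np.arange(1, n + 1) * math.log(theta) - log_rising
    return np.exp(log_pk)


# ---------------------------------------------------------------------------
# mismatch distribution


@dataclass
class MismatchFit:
    observed: np.ndarray  # counts per difference class 0..d_max
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    p_ssd: float | None = None
    p_raggedness: float | None = None

    @property
    def relative(self) -> np.ndarray:
        return self.observed / self.observed.sum()


def expansion_mismatch(i: np.ndarray, tau: float, theta0: float, theta1: float) -> np.ndarray:
    """Expected mismatch probabilities under the sudden-expansion model.

    ``F_i = F(i; theta1) + e^-tau sum_{j<=i} tau^j/j! [F(i-j; theta0) -
    F(i-j; theta1)]`` with ``F(i; theta) = theta^i / (1+theta)^(i+1)``, the
    equilibrium mismatch distribution.
    """
    imax = int(np.max(i))
    idx = np.arange(imax + 1)

    def f_eq(theta: float) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.exp(idx * np.log(max(theta, 1e-300)) - (idx + 1) * np.log1p(theta))

    f0 = f_eq(theta0)
    f1 = f_eq(theta1)
    log_pois = -tau + idx * np.log(max(tau, 1e-300)) - np.array(
        [math.lgamma(j + 1) for j in idx]
    )
    pois = np.exp(log_pois)
    out = np.empty(imax + 1)
    for ii in idx:
        j = np.arange(ii + 1)
        out[ii] = f1[ii] + np.sum(pois[j] * (f0[ii - j] - f1[ii - j]))
    # the sudden-expansion curve is an approximation and can dip fractionally
    # below zero in the far tail; clamp so it stays a valid frequency curve
    return np.clip(out[np.asarray(i)], 0.0, None)


def mismatch_histogram(seqs: list[str]) -> np.ndarray:
    d = pairwise_difference_counts(seqs)
    return np.bincount(d, minlength=int(d.max()) + 1 if d.size else 1)


def raggedness(rel_freq: np.ndarray) -> float:
    """Harpending's raggedness ``sum (x_{i+1} - x_i)^2`` including the step
    down to zero after the last class."""
    x = np.concatenate([rel_freq, [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def _ssd(rel_obs: np.ndarray, tau: float, theta0: float, theta1: float) -> float:
    i = np.arange(rel_obs.size)
    exp = expansion_mismatch(i, tau, theta0, theta1)
    return float(np.sum((rel_obs - exp) ** 2))


def fit_expansion(
    observed: np.ndarray, seed: int | None = None, n_restarts: int = 10
) -> tuple[float, float, float, float]:
    """Least-squares (tau, theta0, theta1) for an observed mismatch histogram.

    Bounded Nelder-Mead with seed-controlled random restarts; returns
    ``(tau, theta0, theta1, ssd)``.
    """
    rel = observed / observed.sum()
    mean_d = float(np.arange(rel.size) @ rel)
    d_hi = max(2.0 * rel.size, 4.0)
    bounds = [(0.0, 3.0 * d_hi), (0.0, d_hi), (0.0, 50.0 * d_hi)]
    rng = np.random.default_rng(seed)
    starts = [np.array([max(mean_d, 0.5), max(mean_d / 10, 0.05), max(10 * mean_d, 5.0)])]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(np.array([rng.uniform(lo, hi / 4 if hi > 4 else hi)
                                for lo, hi in bounds]))
    best = None
    for x0 in starts:
        res = minimize(
            lambda x: _ssd(rel, *x),
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau, th0, th1 = best.x
    if th1 < th0:
        warnings.warn("fitted theta1 < theta0 (contraction rather than expansion)")
    return float(tau), float(th0), float(th1), float(best.fun)


def _tree_mutation_diffs(ts, rng: np.random.Generator, rate: float = 0.5):
    """Poisson mutations on branches of a one-tree sequence (infinite sites).

    Returns ``(condensed pairwise diffs, S, k_haplotypes)``.
    """
    tree = ts.first()
    n = ts.num_samples
    times = ts.nodes_time
    node_mut = np.zeros(ts.num_nodes)
    node_mut[ts.edges_child] = rng.poisson(
        rate * (times[ts.edges_parent] - times[ts.edges_child])
    )
    parent = tree.parent_array
    cum = np.zeros(ts.num_nodes)
    for u in tree.preorder():
        cum[u] = node_mut[u] + (cum[parent[u]] if parent[u] != -1 else 0.0)
    diffs = np.empty(n * (n - 1) // 2, dtype=np.int64)
    pos = 0
    for i in range(n):
        for j in range(i + 1, n):
            m = tree.mrca(i, j)
            diffs[pos] = int(cum[i] + cum[j] - 2 * cum[m])
            pos += 1
    # identical haplotypes are exactly the zero-difference classes
    k = _count_zero_diff_classes(diffs, n)
    return diffs, int(node_mut.sum()), k


def _count_zero_diff_classes(condensed: np.ndarray, n: int) -> int:
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    pos = 0
    for i in range(n):
        for j in range(i + 1, n):
            if condensed[pos] == 0:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
            pos += 1
    return len({find(i) for i in range(n)})


def _simulate_expansion_diffs(
    n: int, tau: float, theta0: float, theta1: float, seed: int
) -> np.ndarray:
    """Pairwise-difference histogram simulated under the fitted expansion.

    Haploid coalescent with per-sequence mutation rate u = 1/2, so sizes are
    N1 = theta1 and N0 = theta0 and the expansion time is T = tau (time and
    theta both measured in units of 1/(2u) = 1 generation).
    """
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=max(theta1, 1e-3))
    dem.add_population_parameters_change(time=max(tau, 1e-9),
                                         initial_size=max(theta0, 1e-3),
                                         population="pop")
    ts = msprime.sim_ancestry(
        samples={"pop": n}, demography=dem, ploidy=1, sequence_length=1,
        random_seed=max(seed % (2**31 - 1), 1),
    )
    rng = np.random.default_rng(seed)
    d, _, _ = _tree_mutation_diffs(ts, rng)
    return np.bincount(d, minlength=int(d.max()) + 1 if d.size else 1)


def mismatch_fit(
    seqs: list[str], n_boot: int = 1000, seed: int | None = None
) -> MismatchFit:
    """Fit the sudden-expansion model and bootstrap SSD/raggedness p-values.

    ``p = (#{stat_rep >= stat_obs}) / n_boot`` with each bootstrap replicate
    simulated under the fitted (tau, theta0, theta1) and refit.
    """
    if len(seqs) < 4:
        raise ValueError("mismatch analysis needs n >= 4 sequences")
    obs = mismatch_histogram(seqs)
    tau, th0, th1, ssd = fit_expansion(obs, seed=seed)
    rag = raggedness(obs / obs.sum())
    p_ssd = p_rag = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        hits_ssd = hits_rag = 0
        n = len(seqs)
        for _ in range(n_boot):
            rep = _simulate_expansion_diffs(n, tau, th0, th1,
                                            int(rng.integers(1, 2**31 - 1)))
            rel = rep / rep.sum()
            _, _, _, ssd_rep = fit_expansion(rep, seed=int(rng.integers(1, 2**31 - 1)),
                                             n_restarts=2)
            hits_ssd += ssd_rep >= ssd
            hits_rag += raggedness(rel) >= rag
        p_ssd = (hits_ssd + 1) / (n_boot + 1)
        p_rag = (hits_rag + 1) / (n_boot + 1)
    return MismatchFit(obs, tau, th0, th1, ssd, rag, p_ssd, p_rag)


# ---------------------------------------------------------------------------
# simulated null distributions for D and Fs


def _neutral_stats(n: int, theta: float, seed: int) -> tuple[float, float, int]:
    """(mean pairwise diff, k haplotypes, S) under the neutral coalescent."""
    ts = msprime.sim_ancestry(
        samples=n, population_size=max(theta, 1e-3), ploidy=1,
        sequence_length=1, random_seed=max(seed % (2**31 - 1), 1),
    )
    rng = np.random.default_rng(seed)
    diffs, s_total, k = _tree_mutation_diffs(ts, rng)
    return float(np.mean(diffs)), float(k), s_total


def neutrality_test(seqs: list[str], n_sim: int = 1000, seed: int | None = None) -> dict:
    """Tajima's D and Fu's Fs with simulated p-values.

    p-values are ``P(stat_sim <= stat_obs)`` under the constant-size neutral
    coalescent with theta estimated from the mean pairwise differences, so
    small p flags an excess of rare variants (expansion-like signal).
    """
    d_obs = tajimas_d(seqs)
    fs_obs = fus_fs(seqs)
    theta = float(pairwise_difference_counts(seqs).mean())
    n = len(seqs)
    rng = np.random.default_rng(seed)
    d_sims, fs_sims = [], []
    for _ in range(n_sim):
        k_mean, k_hap, s = _neutral_stats(n, theta, int(rng.integers(1, 2**31 - 1)))
        d_sims.append(tajimas_d_from_stats(n, s, k_mean))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs_sims.append(fus_fs(n=n, k_obs=int(k_hap), theta=max(k_mean, 1e-9)))
    d_sims = np.array(d_sims)
    fs_sims = np.array(fs_sims)
    return {
        "D": d_obs,
        "p_D": float(np.mean(d_sims <= d_obs)),
        "Fs": fs_obs,
        "p_Fs": float(np.mean(fs_sims <= fs_obs)),
        "n_sim": n_sim,
    }


def species_report(
    table: HaplotypeTable,
    n_sim: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-species pooled neutrality and mismatch summary (D, p, Fs, p, SSD,
    p, raggedness, p)."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp, pops in table.species_pools().items():
        seqs = group_sequences(table, pops)
        if len(seqs) < 4:
            warnings.warn(f"species {sp}: fewer than 4 sequences, skipped")
            continue
        nt = neutrality_test(seqs, n_sim=n_sim, seed=int(rng.integers(1, 2**31 - 1)))
        mf = mismatch_fit(seqs, n_boot=n_boot, seed=int(rng.integers(1, 2**31 - 1)))
        rows.append({
            "species": sp, "n": len(seqs),
            "D": nt["D"], "p_D": nt["p_D"], "Fs": nt["Fs"], "p_Fs": nt["p_Fs"],
            "tau": mf.tau, "theta0": mf.theta0, "theta1": mf.theta1,
            "SSD": mf.ssd, "p_SSD": mf.p_ssd,
            "raggedness": mf.raggedness, "p_raggedness": mf.p_raggedness,
        })
    return pd.DataFrame(rows).set_index("species")
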