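"""Likelihood-free (ABC) scenario choice and parameter estimation in the
style of DIYABC: summary statistics, a simulated reference table, rejection,
polychotomous logistic-regression model choice with type I/II error
evaluation, local-linear (Beaumont) parameter adjustment and posterior
model checking.

Summary statistics (fixed ordering, 12 entries for three species groups):
per species the mean number of alleles per locus and the mean Nei unbiased
gene diversity; per species pair the Weir-Cockerham F_ST and Goldstein's
(delta mu)^2 distance (squared difference of mean allele size, averaged over
loci).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalsim
from .coalsim import PARAM_NAMES, PriorConfig, ScenarioParams, ScenarioSpec
from .datatypes import MISSING, GenotypeDataset
from .msat_stats import wc_theta_components

SPECIES_ORDER = ("PJ", "PQ", "PR")
PAIR_ORDER = (("PJ", "PQ"), ("PJ", "PR"), ("PQ", "PR"))

STAT_NAMES = (
    ["mean_alleles_" + s for s in SPECIES_ORDER]
    + ["mean_he_" + s for s in SPECIES_ORDER]
    + ["fst_" + a + b for a, b in PAIR_ORDER]
    + ["dmu2_" + a + b for a, b in PAIR_ORDER]
)


def summarize_alleles(alleles: np.ndarray, blocks: dict[str, np.ndarray]) -> np.ndarray:
    """Summary vector from a raw allele array.

    ``blocks`` maps species label -> individual indices; all three species
    must be present with >=2 individuals.
    """
    for s in SPECIES_ORDER:
        if s not in blocks or blocks[s].size < 2:
            raise ValueError(f"species group {s} absent or has fewer than 2 individuals")
    n_loci = alleles.shape[1]
    na = {s: 0.0 for s in SPECIES_ORDER}
    he = {s: 0.0 for s in SPECIES_ORDER}
    nl = {s: 0 for s in SPECIES_ORDER}
    mean_size = {s: np.full(n_loci, np.nan) for s in SPECIES_ORDER}
    fst_num = {p: 0.0 for p in PAIR_ORDER}
    fst_den = {p: 0.0 for p in PAIR_ORDER}
    for l in range(n_loci):
        genos = {}
        for s in SPECIES_ORDER:
            g = alleles[blocks[s], l, :]
            g = g[g[:, 0] != MISSING]
            genos[s] = g
        lo = min(int(g.min()) for g in genos.values() if g.size)
        hi = max(int(g.max()) for g in genos.values() if g.size)
        k = hi - lo + 1
        tables = {}
        for s, g in genos.items():
            if g.shape[0] == 0:
                continue
            n = g.shape[0]
            c = np.bincount((g - lo).ravel(), minlength=k)
            het = g[g[:, 0] != g[:, 1]]
            hc = (np.bincount((het - lo).ravel(), minlength=k) if het.size
                  else np.zeros(k))
            tables[s] = (c, hc, n)
            p2 = ((c / (2.0 * n)) ** 2).sum()
            he[s] += 2.0 * n / (2.0 * n - 1.0) * (1.0 - p2)
            na[s] += int((c > 0).sum())
            nl[s] += 1
            mean_size[s][l] = g.mean()
        for pair in PAIR_ORDER:
            a, b = pair
            if a not in tables or b not in tables:
                continue
            ac = np.vstack([tables[a][0], tables[b][0]])
            hc = np.vstack([tables[a][1], tables[b][1]])
            n = np.array([tables[a][2], tables[b][2]], dtype=float)
            s_a, s_abc = wc_theta_components(ac, hc, n)
            fst_num[pair] += s_a
            fst_den[pair] += s_abc
    out = []
    for s in SPECIES_ORDER:
        out.append(na[s] / nl[s] if nl[s] else np.nan)
    for s in SPECIES_ORDER:
        out.append(he[s] / nl[s] if nl[s] else np.nan)
    for pair in PAIR_ORDER:
        out.append(fst_num[pair] / fst_den[pair] if fst_den[pair] > 0 else 0.0)
    for a, b in PAIR_ORDER:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out.append(float(np.nanmean((mean_size[a] - mean_size[b]) ** 2)))
    return np.array(out, dtype=float)


def summarize(ds: GenotypeDataset) -> np.ndarray:
    """Summary vector for a dataset with the three species groups present."""
    blocks = ds.group_indices("species")
    return summarize_alleles(ds.alleles, blocks)


# ---------------------------------------------------------------------------
# reference table


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary-statistics) rows."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        needed = ["scenario_id", *PARAM_NAMES, *STAT_NAMES]
        missing = [c for c in needed if c not in self.frame.columns]
        if missing:
            raise ValueError(f"reference table missing columns {missing}")

    @property
    def stats(self) -> np.ndarray:
        return self.frame[list(STAT_NAMES)].to_numpy(dtype=float)

    @property
    def scenario_ids(self) -> np.ndarray:
        return self.frame["scenario_id"].to_numpy(dtype=int)

    def params(self, scenario_id: int | None = None) -> pd.DataFrame:
        f = self.frame
        if scenario_id is not None:
            f = f[f["scenario_id"] == scenario_id]
        return f[list(PARAM_NAMES)]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceTable":
        path = Path(path)
        frame = pd.read_csv(path)
        prov = {}
        side = path.with_suffix(".json")
        if side.exists():
            prov = json.loads(side.read_text())
        return cls(frame, prov)


def build_reference(
    scenarios: dict[int, ScenarioSpec],
    prior: PriorConfig,
    n_per_scenario: int,
    sample_config: dict[str, int],
    n_loci: int,
    seed: int,
    pop_species: dict[str, str] | None = None,
) -> ReferenceTable:
    """Simulate the ABC reference table: ``n_per_scenario`` draws per scenario.

    Rows with non-finite statistics are dropped (and counted in provenance).
    """
    rng = np.random.default_rng(seed)
    rows = []
    dropped = 0
    for sid, spec in scenarios.items():
        draws, _ = coalsim.draw_params(
            prior, spec, n_per_scenario, int(rng.integers(1, 2**31 - 1))
        )
        for params in draws:
            sim_seed = int(rng.integers(1, 2**31 - 1))
            alleles, pops, psp = coalsim.simulate_allele_array(
                spec, params, sample_config, n_loci, sim_seed, pop_species
            )
            blocks = _species_blocks(pops, psp, sample_config)
            stats = summarize_alleles(alleles, blocks)
            if not np.all(np.isfinite(stats)):
                dropped += 1
                continue
            rows.append([sid, *[getattr(params, k) for k in PARAM_NAMES], *stats])
    frame = pd.DataFrame(rows, columns=["scenario_id", *PARAM_NAMES, *STAT_NAMES])
    prov = {
        "seed": seed,
        "n_per_scenario": n_per_scenario,
        "n_loci": n_loci,
        "sample_config": dict(sample_config),
        "scenario_ids": sorted(scenarios),
        "prior": prior.__dict__,
        "rows_dropped": dropped,
        "stat_names": list(STAT_NAMES),
    }
    return ReferenceTable(frame, prov)


def _species_blocks(
    pops: list[str], pop_species: dict[str, str], sample_config: dict[str, int]
) -> dict[str, np.ndarray]:
    counts = [int(sample_config[p]) for p in pops]
    starts = np.concatenate([[0], np.cumsum(counts)])
    blocks: dict[str, list[np.ndarray]] = {}
    for i, p in enumerate(pops):
        blocks.setdefault(pop_species[p], []).append(np.arange(starts[i], starts[i + 1]))
    return {s: np.concatenate(v) for s, v in blocks.items()}


# ---------------------------------------------------------------------------
# rejection and model choice


def _standardize(table_stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Statistic scales for the rejection distance.

    DIYABC normalizes summary statistics by their median absolute deviation
    over the reference table, which keeps heavy-tailed statistics such as
    (delta mu)^2 from washing out the distance; the SD is the fallback for
    degenerate columns.
    """
    med = np.median(table_stats, axis=0)
    scale = np.median(np.abs(table_stats - med), axis=0)
    sd = table_stats.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, sd)
    scale[scale == 0] = 1.0
    return table_stats / scale, scale


def _retain(
    obs: np.ndarray, table_stats: np.ndarray, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the closest ``tolerance`` fraction and their distances."""
    z, sd = _standardize(table_stats)
    d = np.sqrt(((z - obs / sd) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(tolerance * len(d))), 2)
    idx = np.argsort(d, kind="stable")[:n_keep]
    return idx, d[idx]


@dataclass
class ScenarioChoice:
    posterior: dict[int, float]
    ci95: dict[int, tuple[float, float]]
    method: str
    n_retained: int

    def best(self) -> int:
        return max(self.posterior, key=self.posterior.get)


def choose_scenario(
    obs: np.ndarray,
    table: ReferenceTable,
    tolerance: float = 0.01,
    seed: int | None = None,
) -> ScenarioChoice:
    """Posterior scenario probabilities by polychotomous logistic regression.

    The closest ``tolerance`` fraction of rows (Euclidean distance on
    MAD-standardized statistics) is retained; a multinomial logistic
    regression of the scenario indicator on the statistics (centered at the
    observation) is evaluated at the observation.  95% CIs come from the
    regression's asymptotic covariance (parametric draws on the intercepts).
    Falls back to direct rejection frequencies when the retained set lacks a
    scenario or the regression is degenerate.
    """
    sids = np.unique(table.scenario_ids)
    if len(sids) < 2:
        raise ValueError("scenario choice needs >=2 scenarios in the table")
    idx, _ = _retain(obs, table.stats, tolerance)
    y = table.scenario_ids[idx]
    _, sd = _standardize(table.stats)
    x = (table.stats[idx] - obs) / sd

    present = np.unique(y)
    if len(present) < len(sids):
        warnings.warn("retained set lacks some scenario; direct-rejection fallback")
        return _rejection_choice(y, sids, idx.size)

    try:
        return _logistic_choice(x, y, sids, seed=seed, n_retained=idx.size)
    except Exception as err:  # separation / singular design
        warnings.warn(f"logistic regression failed ({err}); direct-rejection fallback")
        return _rejection_choice(y, sids, idx.size)


def _rejection_choice(y: np.ndarray, sids: np.ndarray, n: int) -> ScenarioChoice:
    post = {int(s): float(np.mean(y == s)) for s in sids}
    ci = {}
    for s, p in post.items():
        se = np.sqrt(max(p * (1 - p) / n, 0.0))
        ci[s] = (max(p - 1.96 * se, 0.0), min(p + 1.96 * se, 1.0))
    return ScenarioChoice(post, ci, "rejection", n)


def _logistic_choice(
    x: np.ndarray, y: np.ndarray, sids: np.ndarray, seed: int | None, n_retained: int
) -> ScenarioChoice:
    import statsmodels.api as sm

    classes = np.array(sorted(sids))
    y_codes = np.searchsorted(classes, y)
    exog = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(y_codes, exog)
        fit = model.fit(method="newton", maxiter=200, disp=False)
    if not np.all(np.isfinite(fit.params.to_numpy() if hasattr(fit.params, "to_numpy")
                              else np.asarray(fit.params))):
        raise RuntimeError("non-finite logistic coefficients")
    x0 = np.zeros(exog.shape[1])
    x0[0] = 1.0
    probs = np.asarray(fit.predict(x0[None, :]))[0]
    post = {int(c): float(p) for c, p in zip(classes, probs)}

    # parametric draws on the coefficient vector for CI at the observation
    cov = np.asarray(fit.cov_params())
    beta = np.asarray(fit.params).ravel(order="F")
    rng = np.random.default_rng(seed)
    try:
        draws = rng.multivariate_normal(beta, cov, size=500, method="svd")
    except np.linalg.LinAlgError:
        draws = beta[None, :] + rng.standard_normal((500, beta.size)) * np.sqrt(
            np.clip(np.diag(cov), 0, None)
        )
    k = len(classes)
    p_draws = np.empty((500, k))
    n_par = exog.shape[1]
    for i, b in enumerate(draws):
        bmat = b.reshape(k - 1, n_par).T
        eta = np.concatenate([[0.0], x0 @ bmat])
        e = np.exp(eta - eta.max())
        p_draws[i] = e / e.sum()
    ci = {
        int(c): (float(np.percentile(p_draws[:, j], 2.5)),
                 float(np.percentile(p_draws[:, j], 97.5)))
        for j, c in enumerate(classes)
    }
    return ScenarioChoice(post, ci, "mnlogit", n_retained)


# ---------------------------------------------------------------------------
# parameter estimation


@dataclass
class PosteriorEstimate:
    sample: pd.DataFrame  # adjusted parameter draws
    weights: np.ndarray  # Epanechnikov weights
    quantiles: pd.DataFrame  # rows: median, q2.5, q97.5
    adjusted: bool


def _weighted_quantile(values: np.ndarray, q: float, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    return float(np.interp(q, cw, v))


def _logit_bounded(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    eps = 1e-9 * (hi - lo)
    x = np.clip(x, lo + eps, hi - eps)
    return np.log((x - lo) / (hi - x))


def _inv_logit_bounded(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def estimate_params(
    obs: np.ndarray,
    table: ReferenceTable,
    scenario_id: int,
    prior: PriorConfig,
    tolerance: float = 0.01,
) -> PosteriorEstimate:
    """Beaumont local-linear regression adjustment of the rejection sample.

    Parameters are logit-transformed to their prior bounds, adjusted by a
    weighted (Epanechnikov) linear regression on the statistics, and
    back-transformed; quantiles are Epanechnikov-weighted.
    """
    sub = table.frame[table.frame["scenario_id"] == scenario_id]
    if len(sub) < 10:
        raise ValueError("too few reference rows for the chosen scenario")
    stats = sub[list(STAT_NAMES)].to_numpy(dtype=float)
    idx, dist = _retain(obs, stats, tolerance)
    dmax = dist.max()
    w = 1.0 - (dist / dmax) ** 2 if dmax > 0 else np.ones_like(dist)
    w = np.clip(w, 1e-12, None)
    _, sd = _standardize(stats)
    x = (stats[idx] - obs) / sd

    adjusted = True
    theta_adj = {}
    # weighted ridge solve: the retained set is small relative to the number
    # of statistics, and the observation sits at the edge of the retained
    # cloud, so an unpenalized solve extrapolates wildly in logit space
    xd = np.column_stack([np.ones(len(idx)), x])
    wmat = xd * w[:, None]
    xtwx = xd.T @ wmat
    lam = 1e-3 * np.trace(xtwx) / xtwx.shape[0]
    penalty = lam * np.eye(xtwx.shape[0])
    penalty[0, 0] = 0.0  # intercept unpenalized
    for name in PARAM_NAMES:
        lo, hi = prior.bounds_of(name)
        vals = sub[name].to_numpy(dtype=float)[idx]
        # scale parameters live on a log axis under the default prior; the
        # logit transform then acts on log-values between the log bounds
        log_scale = prior.scale_kind == "loguniform" and name != "mu"
        if log_scale:
            z = _logit_bounded(np.log(vals), math.log(lo), math.log(hi))
        else:
            z = _logit_bounded(vals, lo, hi)
        try:
            beta = np.linalg.solve(xtwx + penalty, xd.T @ (w * z))
            z_star = z - x @ beta[1:]
        except np.linalg.LinAlgError:
            warnings.warn("singular local-linear design; unadjusted rejection sample")
            z_star = z
            adjusted = False
        if log_scale:
            theta_adj[name] = np.exp(
                _inv_logit_bounded(z_star, math.log(lo), math.log(hi)))
        else:
            theta_adj[name] = _inv_logit_bounded(z_star, lo, hi)
    sample = pd.DataFrame(theta_adj)
    rows = {}
    for q, label in ((0.5, "median"), (0.025, "q2.5"), (0.975, "q97.5")):
        rows[label] = {
            name: _weighted_quantile(sample[name].to_numpy(), q, w) for name in PARAM_NAMES
        }
    quant = pd.DataFrame(rows).T[list(PARAM_NAMES)]
    for t in ("t1", "t2"):
        quant[t + "_years"] = quant[t] * coalsim.GENERATION_YEARS
    return PosteriorEstimate(sample, w, quant, adjusted)


# ---------------------------------------------------------------------------
# confidence and model checking


def simulate_pod(
    spec: ScenarioSpec,
    params: ScenarioParams,
    sample_config: dict[str, int],
    n_loci: int,
    seed: int,
    pop_species: dict[str, str] | None = None,
) -> np.ndarray:
    """Summary vector of one pseudo-observed dataset."""
    alleles, pops, psp = coalsim.simulate_allele_array(
        spec, params, sample_config, n_loci, seed, pop_species
    )
    return summarize_alleles(alleles, _species_blocks(pops, psp, sample_config))


def confidence_errors(
    table: ReferenceTable,
    scenarios: dict[int, ScenarioSpec],
    prior: PriorConfig,
    sample_config: dict[str, int],
    n_loci: int,
    chosen_scenario: int,
    n_pods: int = 20,
    tolerance: float = 0.01,
    seed: int = 0,
) -> dict[str, float]:
    """Type I / type II error of scenario choice from prior-drawn pods.

    Type I: fraction of pods simulated under the chosen scenario for which it
    does not get the highest posterior probability.  Type II: fraction of pods
    from the other scenarios that are wrongly assigned to the chosen one.
    """
    if n_pods < 20:
        raise ValueError("n_pods must be >= 20")
    rng = np.random.default_rng(seed)
    wrong_chosen = 0
    assigned_chosen = 0
    n_other = 0
    for sid, spec in scenarios.items():
        draws, _ = coalsim.draw_params(prior, spec, n_pods, int(rng.integers(1, 2**31 - 1)))
        for params in draws:
            s = simulate_pod(spec, params, sample_config, n_loci,
                             int(rng.integers(1, 2**31 - 1)))
            best = choose_scenario(s, table, tolerance,
                                   seed=int(rng.integers(1, 2**31 - 1))).best()
            if sid == chosen_scenario:
                wrong_chosen += best != chosen_scenario
            else:
                n_other += 1
                assigned_chosen += best == chosen_scenario
    out = {"type_I": wrong_chosen / n_pods}
    out["type_II"] = assigned_chosen / n_other if n_other else float("nan")
    return out


def model_check(
    obs: np.ndarray,
    posterior: PosteriorEstimate,
    spec: ScenarioSpec,
    sample_config: dict[str, int],
    n_loci: int,
    n_rep: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Posterior-predictive two-sided tail probabilities per statistic.

    Simulates ``n_rep`` datasets at parameter draws from the (weighted)
    posterior sample and reports ``min(p, 1-p) * 2`` per summary statistic
    with ``p`` the fraction of replicates <= observed.
    """
    if len(posterior.sample) == 0:
        raise ValueError("posterior sample is empty")
    rng = np.random.default_rng(seed)
    w = posterior.weights / posterior.weights.sum()
    sims = np.empty((n_rep, len(STAT_NAMES)))
    for r in range(n_rep):
        row = posterior.sample.iloc[rng.choice(len(posterior.sample), p=w)]
        params = ScenarioParams(**{k: float(row[k]) for k in PARAM_NAMES})
        sims[r] = simulate_pod(spec, params, sample_config, n_loci,
                               int(rng.integers(1, 2**31 - 1)))
    p_low = (sims <= obs).mean(axis=0)
    p = np.minimum(np.minimum(p_low, 1 - p_low) * 2, 1.0)
    return pd.Series(p, index=list(STAT_NAMES), name="posterior_predictive_p")
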