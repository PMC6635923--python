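"""Coalescent simulation of microsatellite datasets under three-species
divergence scenarios.

The demographic model is a population tree over the three peony species
PJ (*P. jishanensis*), PQ (*P. qiui*) and PR (*P. rockii*): two lineages
merge (backwards in time) at ``t1``, the remaining pair at ``t2 >= t1``.
Current diploid effective sizes are NJ, NQ, NR; the lineage ancestral to the
first merge has size A2 on ``[t1, t2)`` and the final ancestor size A1 above
``t2``.  Times are in generations (continuous), sizes are diploid N with
pairwise coalescence rate 1/(2N); a generation is taken as 10 years when
converting to calendar time.

Ancestry is simulated with msprime.  Microsatellite mutation is overlaid
in-package: mutations are Poisson on branches at per-locus rate ``mu`` and
each mutation steps the repeat count by +-1 (strict SMM) or by a geometric
number of repeats (GSM), reflecting at +-``REPEAT_BOUND`` repeats around the
ancestral state.  The overlay works directly on integer allele arrays, which
keeps the ABC reference-table loop fast, and is validated against the
Ohta-Kimura SMM equilibrium He = 1 - 1/sqrt(1 + 8 N mu).

Scenario topology table
-----------------------
Only the best-fit scenario ("PQ split from PJ at t1, PR split from PJ at t2")
and the two step-2 variants are described explicitly in the source study;
the remaining step-1 topologies are *reconstructed* as the three labeled
pair-first histories of {PJ, PQ, PR}, each in two variants differing in which
lineage is the designated ancestor at the deep split:

* variant "pair": the merged-pair lineage is the ancestor; the outgroup keeps
  its current size until ``t2``.
* variant "outgroup": the outgroup is the ancestor and carries the ancestral
  size A1 from its first event (``t1``) onward.

The two step-2 scenarios are the two variants of the ((PQ, PJ), PR) topology;
they differ in distribution exactly when A1 != NR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import msprime
import numpy as np
import tskit

from .datatypes import GenotypeDataset

SPECIES = ("PJ", "PQ", "PR")

#: Allele sizes are reported as BASE_ALLELE + net repeat displacement.
BASE_ALLELE = 100
#: Reflecting bound on the net displacement from the ancestral state.
REPEAT_BOUND = 40
#: Geometric step parameter for the optional generalized stepwise model.
GSM_P = 0.22

GENERATION_YEARS = 10.0


@dataclass(frozen=True)
class ScenarioParams:
    """One concrete draw of demographic parameters.

    Sizes are current diploid effective sizes; ``a2`` is the size of the
    ancestral population on ``[t1, t2)`` and ``a1`` the size above ``t2``;
    times are in generations and ``mu`` is the per-locus per-generation
    mutation rate.
    """

    nj: float
    nq: float
    nr: float
    a1: float
    a2: float
    t1: float
    t2: float
    mu: float
    generation_years: float = GENERATION_YEARS

    def __post_init__(self) -> None:
        for name in ("nj", "nq", "nr", "a1", "a2", "t1", "t2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if self.mu < 0:
            raise ValueError("mutation rate must be >= 0")
        if not self.t1 < self.t2:
            raise ValueError("event times must satisfy t1 < t2")

    def size_of(self, species: str) -> float:
        return {"PJ": self.nj, "PQ": self.nq, "PR": self.nr}[species]

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAM_NAMES}

    def times_in_years(self) -> dict[str, float]:
        return {
            "t1_years": self.t1 * self.generation_years,
            "t2_years": self.t2 * self.generation_years,
        }


PARAM_NAMES = ("nj", "nq", "nr", "a1", "a2", "t1", "t2", "mu")


@dataclass(frozen=True)
class ScenarioSpec:
    """A labeled divergence history: which pair merges first and which
    lineage is the designated ancestor at the deep split."""

    id: int
    pair: tuple[str, str]  # (derived, continuing) at t1
    outgroup: str
    ancestor: str  # "pair" or "outgroup"
    reconstructed: bool = True

    def __post_init__(self) -> None:
        if set(self.pair) | {self.outgroup} != set(SPECIES):
            raise ValueError("scenario must involve exactly PJ, PQ, PR")
        if self.ancestor not in ("pair", "outgroup"):
            raise ValueError("ancestor must be 'pair' or 'outgroup'")

    def describe(self) -> str:
        d, c = self.pair
        deep = (
            f"{self.outgroup} splits from the {c}-lineage at t2"
            if self.ancestor == "pair"
            else f"the {c}-lineage splits from {self.outgroup} at t2"
        )
        return f"{d} splits from {c} at t1; {deep}"


def _step1_scenarios() -> dict[int, ScenarioSpec]:
    table = {}
    sid = 1
    for pair, out in ((("PQ", "PJ"), "PR"), (("PR", "PJ"), "PQ"), (("PQ", "PR"), "PJ")):
        for anc in ("pair", "outgroup"):
            recon = not (sid in (1, 2) and pair == ("PQ", "PJ"))
            table[sid] = ScenarioSpec(sid, pair, out, anc, reconstructed=recon)
            sid += 1
    return table


#: Step 1: six candidate histories (ids 1..6).  Scenario 1 is the study's
#: best-fit history; 3-6 are reconstructed (see module docstring).
STEP1_SCENARIOS = _step1_scenarios()
#: Step 2: the two variants of the best topology (ids 1..2).
STEP2_SCENARIOS = {1: STEP1_SCENARIOS[1], 2: STEP1_SCENARIOS[2]}


def get_scenario(scenario_id: int, step: int = 2) -> ScenarioSpec:
    table = STEP1_SCENARIOS if step == 1 else STEP2_SCENARIOS
    if scenario_id not in table:
        raise ValueError(
            f"invalid scenario id {scenario_id!r} for step {step}; "
            f"valid ids: {sorted(table)}"
        )
    return table[scenario_id]


@dataclass(frozen=True)
class PriorConfig:
    """Prior bounds.  ``mu`` ~ U(1e-4, 1e-3) per the study.  Size and time
    bounds and shapes are documented assumptions (the study does not print
    them): sizes and times are scale parameters spanning four decades, so the
    default shape is log-uniform on [10, 1e5]; ``scale_kind="uniform"``
    switches to flat priors on the same bounds."""

    n_lo: float = 10.0
    n_hi: float = 1e5
    t_lo: float = 10.0
    t_hi: float = 1e5
    mu_lo: float = 1e-4
    mu_hi: float = 1e-3
    scale_kind: str = "loguniform"

    def __post_init__(self) -> None:
        for lo, hi in ((self.n_lo, self.n_hi), (self.t_lo, self.t_hi), (self.mu_lo, self.mu_hi)):
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError("prior bounds must be finite and positive with lower < upper")
        if self.scale_kind not in ("loguniform", "uniform"):
            raise ValueError("scale_kind must be 'loguniform' or 'uniform'")

    def bounds_of(self, name: str) -> tuple[float, float]:
        if name in ("nj", "nq", "nr", "a1", "a2"):
            return (self.n_lo, self.n_hi)
        if name in ("t1", "t2"):
            return (self.t_lo, self.t_hi)
        if name == "mu":
            return (self.mu_lo, self.mu_hi)
        raise KeyError(name)


def draw_params(
    prior: PriorConfig, scenario: ScenarioSpec, n: int, seed: int
) -> tuple[list[ScenarioParams], dict]:
    """Draw ``n`` i.i.d. parameter sets honoring ``t1 < t2`` by rejection.

    Returns the draws and a small log with the seed and acceptance rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def draw_scale(lo: float, hi: float, size) -> np.ndarray:
        if prior.scale_kind == "loguniform":
            return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))
        return rng.uniform(lo, hi, size=size)

    out: list[ScenarioParams] = []
    proposed = 0
    while len(out) < n:
        batch = max(n - len(out), 64)
        sizes = draw_scale(prior.n_lo, prior.n_hi, (batch, 5))
        times = draw_scale(prior.t_lo, prior.t_hi, (batch, 2))
        mus = rng.uniform(prior.mu_lo, prior.mu_hi, size=batch)
        proposed += batch
        keep = times[:, 0] < times[:, 1]
        for s, t, m in zip(sizes[keep], times[keep], mus[keep]):
            out.append(ScenarioParams(s[0], s[1], s[2], s[3], s[4], t[0], t[1], m))
            if len(out) == n:
                break
        if proposed > 64 and len(out) / proposed < 1e-3:
            raise RuntimeError(
                "prior acceptance rate below 1e-3 under the t1 < t2 constraint; "
                "revise the time prior"
            )
    log = {"seed": seed, "acceptance_rate": len(out) / proposed, "scenario_id": scenario.id}
    return out, log


# ---------------------------------------------------------------------------
# demography and simulation


def build_demography(spec: ScenarioSpec, params: ScenarioParams) -> msprime.Demography:
    """msprime demography for one scenario/parameter combination."""
    dem = msprime.Demography()
    for sp in SPECIES:
        dem.add_population(name=sp, initial_size=params.size_of(sp))
    dem.add_population(name="ANC2", initial_size=params.a2)
    dem.add_population(name="ANC1", initial_size=params.a1)
    derived, continuing = spec.pair
    dem.add_population_split(time=params.t1, derived=[derived, continuing], ancestral="ANC2")
    if spec.ancestor == "outgroup":
        # the outgroup is the ancestral population: it carries A1 from t1 on
        dem.add_population_parameters_change(
            time=params.t1, population=spec.outgroup, initial_size=params.a1
        )
    dem.add_population_split(time=params.t2, derived=["ANC2", spec.outgroup], ancestral="ANC1")
    dem.sort_events()
    return dem


def _infer_species(pop_label: str) -> str:
    for sp in SPECIES:
        if pop_label.upper().startswith(sp):
            return sp
    raise ValueError(
        f"cannot infer species for population {pop_label!r}; "
        "pass pop_species explicitly"
    )


def _fold(x: np.ndarray | int, bound: int = REPEAT_BOUND) -> np.ndarray | int:
    """Fold a free-walk displacement into [-bound, bound] (method of images),
    which reproduces the endpoint distribution of the reflected +-1 walk."""
    period = 4 * bound
    y = np.mod(np.asarray(x) + bound, period)
    y = np.where(y > 2 * bound, period - y, y) - bound
    return y


def _mutate_smm(
    ts: tskit.TreeSequence,
    mu: float,
    rng: np.random.Generator,
    model: str = "smm",
) -> np.ndarray:
    """Net repeat displacement per sample node for a single-tree sequence.

    Mutations are Poisson on branches at rate ``mu``; each mutation steps the
    state by +-1 (strict SMM) or a +-Geometric(1 - GSM_P) step (GSM).  The
    net displacement per branch is drawn in closed form (difference of up and
    down steps) and reflected into +-REPEAT_BOUND around the ancestral state
    by image folding, applied branch by branch.
    """
    n_samp = ts.num_samples
    child = ts.edges_child
    parent = ts.edges_parent
    times = ts.nodes_time
    nmut = rng.poisson(mu * (times[parent] - times[child]))
    hit = np.flatnonzero(nmut)
    if hit.size == 0:
        return np.zeros(n_samp, dtype=np.int16)
    m = nmut[hit]
    if model == "gsm":
        nets = np.array(
            [
                int((rng.geometric(1.0 - GSM_P, size=k)
                     * np.where(rng.random(k) < 0.5, 1, -1)).sum())
                for k in m
            ]
        )
    else:
        nets = 2 * rng.binomial(m, 0.5) - m
    # each mutated branch adds its net displacement to every sample below it;
    # samples below a node are one contiguous block in sample-list order, so
    # a difference array accumulates all branch contributions in O(1) each
    tree = ts.first(sample_lists=True)
    order = np.fromiter(tree.samples(), dtype=np.int64, count=n_samp)
    rank = np.empty(n_samp, dtype=np.int64)
    rank[order] = np.arange(n_samp)
    delta = np.zeros(n_samp + 1, dtype=np.int64)
    left = tree.left_sample
    right = tree.right_sample
    for e, net in zip(hit, nets):
        u = int(child[e])
        i0 = rank[left(u)]
        i1 = rank[right(u)]
        delta[i0] += net
        delta[i1 + 1] -= net
    path_sums = np.cumsum(delta[:-1])
    out = np.empty(n_samp, dtype=np.int16)
    out[order] = _fold(path_sums)
    return out


def simulate_allele_array(
    spec: ScenarioSpec,
    params: ScenarioParams,
    sample_config: dict[str, int],
    n_loci: int,
    seed: int,
    pop_species: dict[str, str] | None = None,
    mutation_model: str = "smm",
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Fast path: simulate and return the raw allele array.

    Returns ``(alleles, pop_order, pop_species)`` where ``alleles`` has shape
    ``(n_individuals, n_loci, 2)`` and individuals are grouped by population
    in ``sample_config`` order.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if mutation_model not in ("smm", "gsm"):
        raise ValueError("mutation_model must be 'smm' or 'gsm'")
    pop_species = dict(pop_species or {})
    for p in sample_config:
        pop_species.setdefault(p, _infer_species(p))
    pops = list(sample_config)
    n_ind = int(sum(sample_config.values()))
    dem = build_demography(spec, params)
    samples = [
        msprime.SampleSet(int(sample_config[p]), population=pop_species[p], ploidy=2)
        for p in pops
    ]
    rng = np.random.default_rng(seed)
    ancestry_seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=1,
        num_replicates=n_loci,
        random_seed=ancestry_seed,
    )
    alleles = np.empty((n_ind, n_loci, 2), dtype=np.int16)
    for l, ts in enumerate(reps):
        disp = _mutate_smm(ts, params.mu, rng, model=mutation_model)
        alleles[:, l, :] = BASE_ALLELE + disp.reshape(n_ind, 2)
    return alleles, pops, pop_species


def simulate_scenario(
    spec: ScenarioSpec,
    params: ScenarioParams,
    sample_config: dict[str, int],
    n_loci: int,
    seed: int,
    pop_species: dict[str, str] | None = None,
    mutation_model: str = "smm",
) -> GenotypeDataset:
    """Simulate a full microsatellite dataset under one scenario.

    ``sample_config`` maps population label -> diploid sample count; labels
    starting with a species code (PJ/PQ/PR) are assigned to that species
    unless ``pop_species`` overrides the mapping.
    """
    alleles, pops, pop_species = simulate_allele_array(
        spec, params, sample_config, n_loci, seed, pop_species, mutation_model
    )
    pop_labels = np.repeat(pops, [sample_config[p] for p in pops])
    sp_labels = np.array([pop_species[p] for p in pop_labels], dtype=object)
    return GenotypeDataset(alleles, pop_labels, sp_labels)


def simulate_single_population(
    n_ind: int, n_loci: int, pop_size: float, mu: float, seed: int,
    mutation_model: str = "smm",
) -> np.ndarray:
    """Constant-size single-population SMM simulation (validation helper).

    Returns an allele array of shape ``(n_ind, n_loci, 2)``.
    """
    rng = np.random.default_rng(seed)
    ancestry_seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(
        samples=n_ind,
        population_size=pop_size,
        sequence_length=1,
        num_replicates=n_loci,
        random_seed=ancestry_seed,
    )
    alleles = np.empty((n_ind, n_loci, 2), dtype=np.int16)
    for l, ts in enumerate(reps):
        disp = _mutate_smm(ts, mu, rng, model=mutation_model)
        alleles[:, l, :] = BASE_ALLELE + disp.reshape(n_ind, 2)
    return alleles


def ohta_kimura_he(pop_size: float, mu: float) -> float:
    """SMM equilibrium expected heterozygosity 1 - 1/sqrt(1 + 8 N mu)."""
    return 1.0 - 1.0 / np.sqrt(1.0 + 8.0 * pop_size * mu)


def params_from_dict(d: dict) -> ScenarioParams:
    return ScenarioParams(**{k: float(d[k]) for k in PARAM_NAMES})


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    return dataclasses.asdict(spec)
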