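"""Synthetic microsatellite, cpDNA and climate/occurrence datasets with
known ground truth.

Every generator is deterministic under a fixed seed and returns a truth
record alongside the data, so downstream statistics can be tested for
recovery of planted structure without any external downloads.  The default
conditions emulate the study system: three species that diverged by two
sequential splits, 22 unlinked microsatellite loci under stepwise mutation,
chloroplast haplotypes with strong population sorting and a single indel,
and climate niches with species-shifted means over a shared background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from . import coalsim
from .coalsim import ScenarioParams
from .datatypes import GenotypeDataset, NicheDataset

_BASES = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """Ground truth stored alongside a synthetic dataset."""

    scenario_id: int
    params: dict
    seed: int
    sample_sizes: dict[str, int]
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 2 for v in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 2 per population")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# microsatellites


def make_microsat_truth(
    scenario_id: int,
    params: ScenarioParams,
    sample_config: dict[str, int],
    n_loci: int = 22,
    seed: int = 0,
    step: int = 2,
    pop_species: dict[str, str] | None = None,
    coords: pd.DataFrame | None = None,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Microsatellite dataset simulated under a divergence scenario.

    ``sample_config`` maps population label -> diploid count; labels prefixed
    by a species code (PJ/PQ/PR) are assigned to that species.
    """
    spec = coalsim.get_scenario(scenario_id, step=step)
    ds = coalsim.simulate_scenario(spec, params, sample_config, n_loci, seed, pop_species)
    if coords is not None:
        ds.coords = coords
    truth = TruthRecord(scenario_id, params.as_dict(), seed, dict(sample_config),
                        extras={"step": step, "n_loci": n_loci})
    return ds, truth


def make_island_pair(
    n_ind: int = 30,
    n_loci: int = 22,
    pop_size: float = 2000.0,
    m_ab: float = 1e-3,
    m_ba: float = 1e-3,
    mu: float = 5e-4,
    seed: int = 0,
) -> GenotypeDataset:
    """Two-deme island model with (possibly asymmetric) migration.

    ``m_ab`` is the forwards-in-time migration fraction from A into B per
    generation; a source-sink asymmetry makes A the source when
    ``m_ab >> m_ba``.
    """
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=pop_size)
    dem.add_population(name="B", initial_size=pop_size)
    # msprime rates are backwards in time: lineages in B trace to A at the
    # forwards rate of A -> B migration
    dem.set_migration_rate(source="B", dest="A", rate=m_ab)
    dem.set_migration_rate(source="A", dest="B", rate=m_ba)
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples={"A": n_ind, "B": n_ind}, demography=dem, sequence_length=1,
        num_replicates=n_loci, random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    alleles = np.empty((2 * n_ind, n_loci, 2), dtype=np.int16)
    for l, ts in enumerate(reps):
        disp = coalsim._mutate_smm(ts, mu, rng)
        alleles[:, l, :] = coalsim.BASE_ALLELE + disp.reshape(2 * n_ind, 2)
    pops = np.repeat(["A", "B"], n_ind)
    return GenotypeDataset(alleles, pops, pops.copy())


def make_stepping_stone(
    n_demes: int = 8,
    n_ind: int = 12,
    n_loci: int = 15,
    pop_size: float = 1000.0,
    m: float = 2e-3,
    mu: float = 5e-4,
    seed: int = 0,
    deme_spacing_km: float = 50.0,
) -> GenotypeDataset:
    """Linear stepping-stone chain (isolation by distance planted).

    Populations sit on a line of latitude with ``deme_spacing_km`` spacing so
    geographic distance grows with deme index.
    """
    dem = msprime.Demography()
    names = [f"P{i + 1}" for i in range(n_demes)]
    for nm in names:
        dem.add_population(name=nm, initial_size=pop_size)
    for i in range(n_demes - 1):
        dem.set_migration_rate(source=names[i], dest=names[i + 1], rate=m)
        dem.set_migration_rate(source=names[i + 1], dest=names[i], rate=m)
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples={nm: n_ind for nm in names}, demography=dem, sequence_length=1,
        num_replicates=n_loci, random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    n_tot = n_demes * n_ind
    alleles = np.empty((n_tot, n_loci, 2), dtype=np.int16)
    for l, ts in enumerate(reps):
        disp = coalsim._mutate_smm(ts, mu, rng)
        alleles[:, l, :] = coalsim.BASE_ALLELE + disp.reshape(n_tot, 2)
    pops = np.repeat(names, n_ind)
    lat0 = 34.0
    km_per_deg = 111.19
    coords = pd.DataFrame(
        {"lat": lat0, "lon": 105.0 + np.arange(n_demes) * deme_spacing_km / (
            km_per_deg * np.cos(np.radians(lat0)))},
        index=names,
    )
    return GenotypeDataset(alleles, pops, pops.copy(), coords=coords)


# ---------------------------------------------------------------------------
# cpDNA


def _random_coalescent_topology(k: int, rng: np.random.Generator):
    """Random binary merge tree over k labeled tips; returns parent pointers
    (2k-1 nodes, tips 0..k-1, root = 2k-2)."""
    parent = np.full(2 * k - 1, -1, dtype=int)
    active = list(range(k))
    nxt = k
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return parent


def make_cpdna_truth(
    haplotype_counts: dict[str, dict[str, int]],
    n_sites: int = 2075,
    n_mutations: int = 37,
    include_indel: bool = True,
    seed: int = 0,
    pop_species: dict[str, str] | None = None,
    indel_length: int = 1,
) -> tuple[dict[str, str], pd.DataFrame, TruthRecord]:
    """Aligned cpDNA sequences realizing a requested haplotype count map.

    Haplotypes are generated on a random coalescent genealogy: each pendant
    branch carries at least one private substitution (guaranteeing
    distinctness), remaining mutations go to random branches, each at its own
    alignment column.  With ``include_indel`` one gap run of
    ``indel_length`` columns is assigned to one haplotype lineage.

    Returns ``(sequences, assignments, truth)`` where sequences maps
    individual id -> aligned sequence and assignments has columns
    individual/population/species/haplotype.
    """
    hap_ids = sorted({h for cmap in haplotype_counts.values() for h in cmap})
    k = len(hap_ids)
    if any(c < 1 for cmap in haplotype_counts.values() for c in cmap.values()):
        raise ValueError("haplotype counts must be >= 1")
    if n_mutations >= n_sites:
        raise ValueError("n_mutations must be < n_sites")
    if k > n_mutations and k > 1:
        raise ValueError(
            f"{k} distinct haplotypes are not achievable with {n_mutations} "
            "mutated sites (need at least one private site per haplotype)"
        )
    rng = np.random.default_rng(seed)
    base = _BASES[rng.integers(0, 4, size=n_sites)]
    cols = rng.choice(n_sites, size=min(n_mutations + indel_length, n_sites),
                      replace=False)
    mut_cols = cols[:n_mutations]
    indel_cols = cols[n_mutations:n_mutations + indel_length] if include_indel else []

    seqs = {h: base.copy() for h in hap_ids}
    if k > 1:
        parent = _random_coalescent_topology(k, rng)
        n_nodes = 2 * k - 1
        branch_of_mut = np.concatenate([
            np.arange(k),  # one private mutation per tip branch
            rng.integers(0, n_nodes - 1, size=n_mutations - k),  # root has no branch
        ])
        node_cols: dict[int, list[int]] = {}
        for col, br in zip(mut_cols, branch_of_mut):
            node_cols.setdefault(int(br), []).append(int(col))
        for i, h in enumerate(hap_ids):
            u = i
            while u != -1:
                for col in node_cols.get(u, []):
                    alt = rng.choice([b for b in "ACGT" if b != base[col]])
                    seqs[h][col] = alt
                u = parent[u]
        if include_indel:
            carrier = hap_ids[int(rng.integers(0, k))]
            for col in indel_cols:
                seqs[carrier][col] = "-"
    truth_haps = {h: "".join(s) for h, s in seqs.items()}
    if len(set(truth_haps.values())) != k:
        raise RuntimeError("haplotype construction collision")  # pragma: no cover

    sequences: dict[str, str] = {}
    rows = []
    for pop, cmap in haplotype_counts.items():
        sp = (pop_species or {}).get(pop, pop)
        i = 0
        for h, c in cmap.items():
            for _ in range(int(c)):
                i += 1
                ind = f"{pop}_{i:03d}"
                sequences[ind] = truth_haps[h]
                rows.append({"individual": ind, "population": pop,
                             "species": sp, "haplotype": h})
    assignments = pd.DataFrame(rows)
    truth = TruthRecord(
        0, {}, seed,
        {p: sum(c.values()) for p, c in haplotype_counts.items()},
        extras={"kind": "cpdna", "n_sites": n_sites, "n_mutations": n_mutations,
                "haplotypes": {p: dict(c) for p, c in haplotype_counts.items()},
                "include_indel": bool(include_indel)},
    )
    return sequences, assignments, truth


def make_star_haplotypes(
    n_satellites: int = 5,
    counts_center: int = 20,
    counts_satellite: int = 3,
    n_sites: int = 500,
    seed: int = 0,
):
    """One central haplotype with k satellites, each one step away.

    A planted-topology fixture for the haplotype network.
    """
    rng = np.random.default_rng(seed)
    base = _BASES[rng.integers(0, 4, size=n_sites)]
    cols = rng.choice(n_sites, size=n_satellites, replace=False)
    haps = {"C": "".join(base)}
    for i, col in enumerate(cols):
        s = base.copy()
        s[col] = rng.choice([b for b in "ACGT" if b != base[col]])
        haps[f"S{i + 1}"] = "".join(s)
    sequences = {}
    rows = []
    idx = 0
    for h, c in [("C", counts_center)] + [(f"S{i + 1}", counts_satellite)
                                          for i in range(n_satellites)]:
        for _ in range(c):
            idx += 1
            ind = f"P1_{idx:03d}"
            sequences[ind] = haps[h]
            rows.append({"individual": ind, "population": "P1", "species": "SP1",
                         "haplotype": h})
    return sequences, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# climate niches


def make_niche_truth(
    n_species: int = 3,
    centroid_shifts: np.ndarray | list[float] | float = 0.0,
    n_occurrences: int | list[int] = 40,
    n_background: int = 300,
    n_vars: int = 8,
    seed: int = 0,
    within_sd: float = 1.0,
    background_sd: float = 2.0,
    n_duplicate_vars: int = 0,
) -> tuple[NicheDataset, TruthRecord]:
    """Occurrence/background climate tables with species-shifted niche means.

    Species ``s`` occurrences are multivariate normal with mean
    ``centroid_shifts[s]`` along a fixed unit direction in climate space and
    isotropic SD ``within_sd``.  Background climate is drawn from a shared,
    wider distribution (SD ``background_sd``, common mean): species occupy
    distinct niches within the same available environment, so zero shift is
    an exact null for the divergence test.  Geographic coordinates cluster by
    species; background points are uniform over each species' occurrence
    bounding box inflated by 25%.

    ``n_duplicate_vars`` appends noisy copies of existing variables (r > 0.8)
    to exercise the correlation filter.
    """
    rng = np.random.default_rng(seed)
    shifts = np.broadcast_to(np.asarray(centroid_shifts, dtype=float),
                             (n_species,)).copy()
    if not np.all(np.isfinite(shifts)):
        raise ValueError("centroid shifts must be finite")
    if n_vars < 2:
        raise ValueError("need at least two climate variables")
    n_occ = np.broadcast_to(np.asarray(n_occurrences, dtype=int), (n_species,))
    direction = np.ones(n_vars) / np.sqrt(n_vars)
    var_names = [f"bio{i + 1}" for i in range(n_vars)]
    species = [f"SP{i + 1}" for i in range(n_species)]

    occ_rows, bg_rows = [], []
    for s, sp in enumerate(species):
        mean = shifts[s] * direction
        clim = rng.normal(mean, within_sd, size=(n_occ[s], n_vars))
        lat0, lon0 = 33.0 + 1.5 * s, 105.0 + 2.0 * s
        lat = lat0 + rng.normal(0, 0.5, size=n_occ[s])
        lon = lon0 + rng.normal(0, 0.5, size=n_occ[s])
        for r in range(n_occ[s]):
            occ_rows.append({"species": sp, "lat": lat[r], "lon": lon[r],
                             **dict(zip(var_names, clim[r]))})
        # geographic background: inflated bounding box of the occurrences
        lat_lo, lat_hi = lat.min(), lat.max()
        lon_lo, lon_hi = lon.min(), lon.max()
        dlat, dlon = 0.25 * (lat_hi - lat_lo), 0.25 * (lon_hi - lon_lo)
        blat = rng.uniform(lat_lo - dlat, lat_hi + dlat, size=n_background)
        blon = rng.uniform(lon_lo - dlon, lon_hi + dlon, size=n_background)
        bclim = rng.normal(0.0, background_sd, size=(n_background, n_vars))
        for r in range(n_background):
            bg_rows.append({"species": sp, "lat": blat[r], "lon": blon[r],
                            **dict(zip(var_names, bclim[r]))})
    occ = pd.DataFrame(occ_rows)
    bg = pd.DataFrame(bg_rows)
    for d in range(n_duplicate_vars):
        src = var_names[d % len(var_names)]
        new = f"{src}_dup{d + 1}"
        for df in (occ, bg):
            df[new] = df[src] + rng.normal(0, 0.05 * within_sd, size=len(df))
    all_vars = var_names + [f"{var_names[d % len(var_names)]}_dup{d + 1}"
                            for d in range(n_duplicate_vars)]
    ds = NicheDataset(occ, bg, all_vars)
    truth = TruthRecord(
        0, {}, seed, {sp: int(n) for sp, n in zip(species, n_occ)},
        extras={"kind": "niche", "shifts": shifts.tolist(), "within_sd": within_sd,
                "background_sd": background_sd, "n_vars": n_vars,
                "n_duplicate_vars": n_duplicate_vars},
    )
    return ds, truth
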