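"""Nuclear-microsatellite statistics: diversity, differentiation, AMOVA,
isolation by distance, clustering surfaces and directional relative migration.

Conventions (matching the classical estimators used in the field):

* Expected heterozygosity is Nei's unbiased gene diversity
  ``(2n/(2n-1)) * (1 - sum p_i^2)`` per locus, averaged over loci.
* F_ST is the Weir & Cockerham (1984) theta, combined across alleles and loci
  as the ratio of summed variance components.
* AMOVA follows Excoffier's sums-of-squares over pairwise distances between
  gene copies, with the allele-identity (F_ST-like) distance for nSSR data.
* Missing data are handled pairwise-complete per locus; negative variance
  components are clamped to zero post hoc and percentages renormalized.
* All permutation tests take an explicit seed and use the +1 correction
  ``p = (#{stat_perm >= stat_obs} + 1) / (n_perm + 1)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .datatypes import MISSING, GenotypeDataset

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistancePair:
    """A symmetric population x population distance matrix with a kind tag."""

    matrix: pd.DataFrame
    kind: str  # fst | linearized_fst | geographic_km | shared_allele

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(np.nan_to_num(np.diag(m)), 0):
            raise ValueError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(m - m.T)) > 1e-12:
                raise ValueError("distance matrix must be symmetric")
        if self.kind == "geographic_km" and np.nanmin(m) < 0:
            raise ValueError("geographic distances must be >= 0")

    def labels(self) -> list[str]:
        return list(self.matrix.index)

    def condensed(self) -> np.ndarray:
        m = self.matrix.to_numpy(dtype=float)
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]


# ---------------------------------------------------------------------------
# helpers


def _locus_calls(ds: GenotypeDataset, idx: np.ndarray, locus: int) -> np.ndarray:
    """Non-missing genotype rows (n, 2) for the given individuals at a locus."""
    g = ds.alleles[idx, locus, :]
    return g[g[:, 0] != MISSING]


def _allele_codes(groups: list[np.ndarray]) -> tuple[list[np.ndarray], int]:
    """Recode allele sizes in the given genotype blocks to 0..K-1."""
    pool = np.concatenate([g.ravel() for g in groups]) if groups else np.array([])
    uniq = np.unique(pool)
    lut = {int(v): i for i, v in enumerate(uniq)}
    coded = [np.vectorize(lut.__getitem__, otypes=[np.int64])(g) if g.size else g.astype(np.int64)
             for g in groups]
    return coded, len(uniq)


def wc_theta_components(
    allele_counts: np.ndarray, het_counts: np.ndarray, n_ind: np.ndarray
) -> tuple[float, float]:
    """Weir & Cockerham (1984) variance components for one locus.

    Parameters
    ----------
    allele_counts
        ``(r, K)`` gene-copy counts per population per allele.
    het_counts
        ``(r, K)`` counts of heterozygous individuals carrying each allele.
    n_ind
        ``(r,)`` individuals sampled (non-missing) per population.

    Returns ``(sum_a, sum_abc)`` over alleles; the multilocus theta is the
    ratio of these sums accumulated over loci.
    """
    keep = n_ind > 0
    allele_counts = allele_counts[keep]
    het_counts = het_counts[keep]
    n = n_ind[keep].astype(float)
    r = n.size
    if r < 2:
        return 0.0, 0.0
    nbar = n.mean()
    nsum = n.sum()
    nc = (nsum - (n**2).sum() / nsum) / (r - 1)
    if nc <= 0 or nbar <= 1:
        return 0.0, 0.0
    p = allele_counts / (2.0 * n[:, None])
    pbar = (n[:, None] * p).sum(axis=0) / nsum
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (het_counts / n[:, None] * n[:, None]).sum(axis=0) / nsum
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return float(a.sum()), float((a + b + c).sum())


def _count_tables(groups: list[np.ndarray], k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Allele-count / het-count / sample-size tables from coded genotypes."""
    r = len(groups)
    ac = np.zeros((r, k))
    hc = np.zeros((r, k))
    n = np.zeros(r)
    for i, g in enumerate(groups):
        if g.size == 0:
            continue
        n[i] = g.shape[0]
        ac[i] = np.bincount(g.ravel(), minlength=k)
        het = g[g[:, 0] != g[:, 1]]
        if het.size:
            hc[i] = np.bincount(het.ravel(), minlength=k)
    return ac, hc, n


def wc_theta(ds: GenotypeDataset, level: str = "population") -> float:
    """Multilocus Weir-Cockerham theta over all groups at the given level."""
    groups = ds.group_indices(level)
    num = den = 0.0
    for l in range(ds.n_loci):
        blocks = [_locus_calls(ds, idx, l) for idx in groups.values()]
        coded, k = _allele_codes([b for b in blocks if b.size])
        it = iter(coded)
        coded_full = [next(it) if b.size else b.astype(np.int64) for b in blocks]
        ac, hc, n = _count_tables(coded_full, k)
        a, abc = wc_theta_components(ac, hc, n)
        num += a
        den += abc
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# diversity


def heterozygosities(ds: GenotypeDataset) -> pd.DataFrame:
    """Observed and Nei-unbiased expected heterozygosity per population,
    with pooled per-species rows appended (label ``species:<name>``).

    Loci with no calls in a group are skipped for that group.
    """
    rows = []
    groups = list(ds.group_indices("population").items())
    groups += [(f"species:{s}", idx) for s, idx in ds.group_indices("species").items()]
    for label, idx in groups:
        ho, he = [], []
        for l in range(ds.n_loci):
            g = _locus_calls(ds, idx, l)
            if g.shape[0] == 0:
                warnings.warn(f"group {label}: locus {ds.loci[l]} has no calls; skipped")
                continue
            n = g.shape[0]
            ho.append(float(np.mean(g[:, 0] != g[:, 1])))
            _, counts = np.unique(g.ravel(), return_counts=True)
            p2 = ((counts / (2.0 * n)) ** 2).sum()
            he.append(2.0 * n / (2.0 * n - 1.0) * (1.0 - p2) if n > 0 else 0.0)
        rows.append({"group": label, "H_O": float(np.mean(ho)), "H_E": float(np.mean(he)),
                     "n": int(idx.size)})
    return pd.DataFrame(rows).set_index("group")


def allelic_richness(ds: GenotypeDataset, g: int | str = "auto") -> pd.Series:
    """Rarefied allelic richness per population (mean over loci).

    ``A_R(locus) = sum_alleles [1 - C(N - N_i, g) / C(N, g)]`` with ``N`` the
    gene copies sampled in the population at the locus and ``g`` the
    rarefaction size in gene copies.  ``auto`` uses the smallest ``N`` over
    all populations and loci, so every locus supports the rarefaction.
    """
    groups = ds.group_indices("population")
    sizes = []
    for idx in groups.values():
        for l in range(ds.n_loci):
            sizes.append(2 * _locus_calls(ds, idx, l).shape[0])
    if g == "auto":
        g = min(s for s in sizes if s > 0)
    g = int(g)
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2 gene copies")
    if g > min(s for s in sizes if s > 0):
        raise ValueError("g exceeds the smallest per-locus sample size")
    out = {}
    for pop, idx in groups.items():
        vals = []
        for l in range(ds.n_loci):
            geno = _locus_calls(ds, idx, l)
            if geno.shape[0] == 0:
                continue
            _, counts = np.unique(geno.ravel(), return_counts=True)
            big_n = int(counts.sum())
            denom = math.comb(big_n, g)
            ar = sum(1.0 - math.comb(big_n - int(c), g) / denom for c in counts)
            vals.append(ar)
        out[pop] = float(np.mean(vals))
    return pd.Series(out, name=f"A_R(g={g})")


def private_alleles(ds: GenotypeDataset, level: str = "population") -> pd.Series:
    """Number of alleles found in exactly one group, per group (summed over loci)."""
    groups = ds.group_indices(level)
    if len(groups) < 2:
        raise ValueError("private alleles need at least two groups")
    out = {gname: 0 for gname in groups}
    for l in range(ds.n_loci):
        present: dict[int, set[str]] = {}
        for gname, idx in groups.items():
            geno = _locus_calls(ds, idx, l)
            for a in np.unique(geno.ravel()):
                present.setdefault(int(a), set()).add(gname)
        for a, where in present.items():
            if len(where) == 1:
                out[next(iter(where))] += 1
    return pd.Series(out, name="A_P")


def fis(ds: GenotypeDataset) -> pd.Series:
    """Weir-Cockerham f (inbreeding within populations), one value per
    population from the single-population variance components."""
    out = {}
    for pop, idx in ds.group_indices("population").items():
        num = den = 0.0
        for l in range(ds.n_loci):
            geno = _locus_calls(ds, idx, l)
            n = geno.shape[0]
            if n < 2:
                continue
            _, inv, counts = np.unique(geno.ravel(), return_inverse=True, return_counts=True)
            p = counts / (2.0 * n)
            het = geno[:, 0] != geno[:, 1]
            coded = inv.reshape(n, 2)
            for a in range(p.size):
                ha = float(np.mean(het & np.any(coded == a, axis=1)))
                pa = p[a]
                # Weir & Cockerham b and c for r = 1 population
                b = n / (n - 1.0) * (pa * (1 - pa) - (2 * n - 1) / (4.0 * n) * ha)
                c = ha / 2.0
                num += b
                den += b + c
        out[pop] = num / den if den > 0 else 0.0
    return pd.Series(out, name="F_IS")


def diversity_report(ds: GenotypeDataset, g: int | str = "auto") -> pd.DataFrame:
    """Per-population H_O, H_E, A_R, A_P and F_IS with species means."""
    het = heterozygosities(ds)
    pops = ds.populations()
    rep = het.loc[pops].copy()
    rep["A_R"] = allelic_richness(ds, g)
    rep["A_P"] = private_alleles(ds, "population")
    rep["F_IS"] = fis(ds)
    rep["species"] = [ds.pop_to_species()[p] for p in pops]
    return rep


# ---------------------------------------------------------------------------
# differentiation


def pairwise_fst(ds: GenotypeDataset, level: str = "population") -> DistancePair:
    """Pairwise multilocus Weir-Cockerham theta between groups.

    Negative estimates are reported as computed (clamp only happens when
    linearizing).  A pair with no co-typed locus gets NaN and a warning.
    """
    groups = ds.group_indices(level)
    names = list(groups)
    if len(names) < 2 or any(idx.size < 2 for idx in groups.values()):
        raise ValueError("pairwise F_ST needs >=2 groups with >=2 individuals each")
    k = len(names)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            num = den = 0.0
            informative = False
            for l in range(ds.n_loci):
                gi = _locus_calls(ds, groups[names[i]], l)
                gj = _locus_calls(ds, groups[names[j]], l)
                if gi.shape[0] == 0 or gj.shape[0] == 0:
                    continue
                informative = True
                coded, ka = _allele_codes([gi, gj])
                ac, hc, n = _count_tables(coded, ka)
                a, abc = wc_theta_components(ac, hc, n)
                num += a
                den += abc
            if not informative:
                warnings.warn(f"pair ({names[i]}, {names[j]}) has no co-typed loci")
                mat[i, j] = mat[j, i] = np.nan
            else:
                mat[i, j] = mat[j, i] = num / den if den > 0 else 0.0
    return DistancePair(pd.DataFrame(mat, index=names, columns=names), "fst")


def linearize_fst(fst: DistancePair, clamp: float | None = None) -> DistancePair:
    """Slatkin-linearized F_ST/(1-F_ST); negative theta clamped to 0 first.

    An entry of exactly 1 makes the transform infinite; pass ``clamp=0.999``
    to cap such entries.
    """
    m = fst.matrix.to_numpy(dtype=float).copy()
    m = np.clip(m, 0.0, None)
    if np.any(m >= 1.0):
        if clamp is None:
            raise ValueError(
                "F_ST of 1 cannot be linearized; pass clamp=0.999 to cap such entries"
            )
        m = np.minimum(m, clamp)
    lin = m / (1.0 - m)
    np.fill_diagonal(lin, 0.0)
    return DistancePair(pd.DataFrame(lin, index=fst.labels(), columns=fst.labels()),
                        "linearized_fst")


def geographic_distances(coords: pd.DataFrame) -> DistancePair:
    """Great-circle (haversine) distances in km between populations."""
    lat = np.radians(coords["lat"].to_numpy(dtype=float))
    lon = np.radians(coords["lon"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    labels = list(coords.index)
    return DistancePair(pd.DataFrame(d, index=labels, columns=labels), "geographic_km")


def mantel_ibd(
    fst: DistancePair,
    coords: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    clamp: float | None = None,
) -> tuple[float, float]:
    """Mantel correlation between linearized F_ST and great-circle distance.

    Returns ``(r, p)`` with a one-tailed permutation p-value
    ``(#{r_perm >= r_obs} + 1)/(n_perm + 1)``.
    """
    labels = fst.labels()
    missing = [l for l in labels if l not in coords.index]
    if missing:
        raise ValueError(f"coordinates missing for populations {missing}")
    gen = linearize_fst(fst, clamp=clamp).matrix.to_numpy(dtype=float)
    geo = geographic_distances(coords.loc[labels]).matrix.to_numpy(dtype=float)
    return mantel(gen, geo, n_perm=n_perm, seed=seed)


def mantel(
    x: np.ndarray, y: np.ndarray, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Seeded one-tailed Mantel test on two symmetric matrices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(a: np.ndarray) -> float:
        v1, v2 = a[iu], y[iu]
        v1 = v1 - v1.mean()
        v2 = v2 - v2.mean()
        den = np.sqrt((v1**2).sum() * (v2**2).sum())
        return float((v1 * v2).sum() / den) if den > 0 else 0.0

    r_obs = corr(x)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(x[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# AMOVA


def _squared_allele_identity_distances(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise squared distances between gene copies (allele identity).

    Returns ``(D, owner)`` where D is (2N x 2N) counts of loci with different
    alleles (pairwise-complete) and ``owner`` maps gene copy -> individual.
    """
    n, l, _ = ds.alleles.shape
    copies = ds.alleles.transpose(0, 2, 1).reshape(2 * n, l).astype(float)
    copies[copies == MISSING] = np.nan
    diff = np.zeros((2 * n, 2 * n))
    for j in range(l):
        col = copies[:, j]
        ok = ~np.isnan(col)
        both = np.outer(ok, ok)
        neq = col[:, None] != col[None, :]
        diff += np.where(both, neq, 0.0)
    np.fill_diagonal(diff, 0.0)
    owner = np.repeat(np.arange(n), 2)
    return diff, owner


def _ssd(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * idx.size))


def _amova_components(
    d: np.ndarray, pop_of: np.ndarray, sp_of: np.ndarray | None
) -> dict:
    """Variance components from a squared-distance matrix over units.

    ``pop_of``/``sp_of`` are integer labels per unit (gene copy or individual).
    With ``sp_of=None`` a one-level (among populations / within populations)
    decomposition is returned.
    """
    n_units = d.shape[0]
    all_idx = np.arange(n_units)
    pops = np.unique(pop_of)
    ssd_total = _ssd(d, all_idx)
    ssd_wp = sum(_ssd(d, np.flatnonzero(pop_of == p)) for p in pops)
    n_p = np.array([(pop_of == p).sum() for p in pops], dtype=float)
    big_n = float(n_units)

    if sp_of is None:
        df_b = len(pops) - 1
        df_c = n_units - len(pops)
        ssd_ap = ssd_total - ssd_wp
        ms_c = ssd_wp / df_c if df_c > 0 else 0.0
        sig_c = ms_c
        if df_b == 0:
            sig_b = 0.0
        else:
            n0 = (big_n - (n_p**2).sum() / big_n) / df_b
            ms_b = ssd_ap / df_b
            sig_b = (ms_b - ms_c) / n0
        return {
            "df": {"among_pops": df_b, "within_pops": df_c},
            "SS": {"among_pops": ssd_ap, "within_pops": ssd_wp},
            "components": {"among_pops": sig_b, "within_pops": sig_c},
        }

    species = np.unique(sp_of)
    df_a = len(species) - 1
    df_b = len(pops) - len(species)
    df_c = n_units - len(pops)
    ssd_ws = sum(_ssd(d, np.flatnonzero(sp_of == s)) for s in species)
    ssd_ag = ssd_total - ssd_ws
    ssd_ap = ssd_ws - ssd_wp

    # Excoffier nested-ANOVA coefficients for unequal sizes
    n_s = np.array([(sp_of == s).sum() for s in species], dtype=float)
    sum_np2_by_s = np.array(
        [sum((pop_of[sp_of == s] == p).sum() ** 2 for p in np.unique(pop_of[sp_of == s]))
         for s in species],
        dtype=float,
    )
    n1 = (big_n - (sum_np2_by_s / n_s).sum()) / df_b if df_b > 0 else 1.0
    n2 = ((sum_np2_by_s / n_s).sum() - (n_p**2).sum() / big_n) / df_a
    n3 = (big_n - (n_s**2).sum() / big_n) / df_a

    ms_c = ssd_wp / df_c if df_c > 0 else 0.0
    ms_b = ssd_ap / df_b if df_b > 0 else 0.0
    ms_a = ssd_ag / df_a
    sig_c = ms_c
    sig_b = (ms_b - ms_c) / n1 if df_b > 0 else 0.0
    sig_a = (ms_a - ms_c - n2 * sig_b) / n3
    return {
        "df": {"among_species": df_a, "among_pops_within_species": df_b, "within_pops": df_c},
        "SS": {"among_species": ssd_ag, "among_pops_within_species": ssd_ap,
               "within_pops": ssd_wp},
        "components": {"among_species": sig_a, "among_pops_within_species": sig_b,
                       "within_pops": sig_c},
    }


def _finalize_amova(raw: dict) -> dict:
    comp = dict(raw["components"])
    clamped = {k: max(v, 0.0) for k, v in comp.items()}
    if any(v < 0 for v in comp.values()):
        warnings.warn("negative variance component clamped to zero")
    total = sum(clamped.values())
    pct = {k: (100.0 * v / total if total > 0 else 0.0) for k, v in clamped.items()}
    raw = dict(raw)
    raw["components"] = clamped
    raw["raw_components"] = comp
    raw["percent"] = pct
    keys = list(clamped)
    if len(keys) == 3:
        sa, sb, sc = (clamped[k] for k in keys)
        tot = sa + sb + sc
        raw["phi"] = {
            "phi_CT": sa / tot if tot > 0 else 0.0,
            "phi_SC": sb / (sb + sc) if (sb + sc) > 0 else 0.0,
            "phi_ST": (sa + sb) / tot if tot > 0 else 0.0,
        }
    else:
        sb, sc = (clamped[k] for k in keys)
        raw["phi"] = {"phi_ST": sb / (sb + sc) if (sb + sc) > 0 else 0.0}
    return raw


def amova_from_distances(
    d: np.ndarray,
    pop_labels: np.ndarray,
    species_labels: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    owner: np.ndarray | None = None,
) -> dict:
    """Generic AMOVA over a squared-distance matrix between units.

    ``owner`` optionally maps units to individuals (gene copies of one
    individual are permuted together).  Permutation schemes: units/individuals
    among populations overall (phi_ST), among populations within species
    (phi_SC) and whole populations among species (phi_CT).
    """
    d = np.asarray(d, dtype=float)
    pop_labels = np.asarray(pop_labels)
    pops, pop_of = np.unique(pop_labels, return_inverse=True)
    sp_of = None
    if species_labels is not None:
        _, sp_of = np.unique(np.asarray(species_labels), return_inverse=True)
    res = _finalize_amova(_amova_components(d, pop_of, sp_of))
    if n_perm <= 0:
        res["p"] = {}
        return res

    rng = np.random.default_rng(seed)
    if owner is None:
        owner = np.arange(d.shape[0])
    ind_ids, first = np.unique(owner, return_index=True)
    ind_pop = pop_of[first]
    ind_sp = sp_of[first] if sp_of is not None else None
    unit_rows = {i: np.flatnonzero(owner == i) for i in ind_ids}

    def relabel(ind_perm_pop: np.ndarray, ind_perm_sp: np.ndarray | None):
        up = np.empty(d.shape[0], dtype=int)
        us = np.empty(d.shape[0], dtype=int) if ind_perm_sp is not None else None
        for i, rows in unit_rows.items():
            up[rows] = ind_perm_pop[i]
            if us is not None:
                us[rows] = ind_perm_sp[i]
        return up, us

    obs_phi = res["phi"]
    hits = {k: 0 for k in obs_phi}
    for _ in range(n_perm):
        if sp_of is None:
            perm = rng.permutation(ind_pop)
            up, _ = relabel(perm, None)
            stat = _finalize_amova(_amova_components(d, up, None))["phi"]
            if stat["phi_ST"] >= obs_phi["phi_ST"]:
                hits["phi_ST"] += 1
        else:
            # phi_ST: individuals among populations, species structure broken
            perm_pop = rng.permutation(ind_pop)
            up, us = relabel(perm_pop, ind_sp)
            stat = _finalize_amova(_amova_components(d, up, us))["phi"]
            if stat["phi_ST"] >= obs_phi["phi_ST"]:
                hits["phi_ST"] += 1
            # phi_SC: individuals among populations within species
            perm_within = ind_pop.copy()
            for s in np.unique(ind_sp):
                rows = np.flatnonzero(ind_sp == s)
                perm_within[rows] = rng.permutation(perm_within[rows])
            up, us = relabel(perm_within, ind_sp)
            stat = _finalize_amova(_amova_components(d, up, us))["phi"]
            if stat["phi_SC"] >= obs_phi["phi_SC"]:
                hits["phi_SC"] += 1
            # phi_CT: whole populations among species
            perm_sp_of_pop = rng.permutation(
                [ind_sp[ind_pop == p][0] for p in range(len(pops))]
            )
            ind_sp_perm = np.array([perm_sp_of_pop[p] for p in ind_pop])
            up, us = relabel(ind_pop, ind_sp_perm)
            stat = _finalize_amova(_amova_components(d, up, us))["phi"]
            if stat["phi_CT"] >= obs_phi["phi_CT"]:
                hits["phi_CT"] += 1
    res["p"] = {k: (v + 1) / (n_perm + 1) for k, v in hits.items()}
    res["n_perm"] = n_perm
    return res


def amova(
    ds: GenotypeDataset,
    n_perm: int = 10000,
    seed: int | None = None,
    hierarchy: str = "species/pop",
) -> dict:
    """Hierarchical AMOVA on nSSR genotypes (allele-identity distance).

    ``hierarchy`` is ``"species/pop"`` (three level) or ``"pop"`` (one level,
    e.g. within a single species).
    """
    if hierarchy == "species/pop" and len(ds.species_list()) < 2:
        raise ValueError("three-level AMOVA needs >=2 species")
    d, owner = _squared_allele_identity_distances(ds)
    pop_units = np.repeat(ds.pop, 2)
    sp_units = np.repeat(ds.species, 2) if hierarchy == "species/pop" else None
    return amova_from_distances(d, pop_units, sp_units, n_perm=n_perm, seed=seed, owner=owner)


# ---------------------------------------------------------------------------
# clustering surfaces


def shared_allele_distance(ds: GenotypeDataset) -> pd.DataFrame:
    """1 - proportion of shared alleles, averaged over co-typed loci.

    Per locus the shared proportion is 0, 0.5 or 1 (multiset intersection of
    the two genotypes divided by 2).
    """
    a = np.sort(ds.alleles, axis=2)
    n = ds.n_individuals
    miss = a[:, :, 0] == MISSING
    dist = np.zeros((n, n))
    for i in range(n):
        b1, b2 = a[i, :, 0], a[i, :, 1]
        c1, c2 = a[:, :, 0], a[:, :, 1]
        hom_i = b1 == b2
        eq11 = c1 == b1
        eq12 = c1 == b2
        eq21 = c2 == b1
        eq22 = c2 == b2
        hom_match = np.minimum((c1 == b1).astype(int) + (c2 == b1).astype(int), 2)
        het_match = (eq11 | eq21).astype(int) + (eq12 | eq22).astype(int)
        m = np.where(hom_i[None, :], hom_match, het_match)
        ok = ~(miss | miss[i][None, :])
        share = np.where(ok, m / 2.0, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist[i] = 1.0 - np.nanmean(share, axis=1)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    ids = [f"i{j}_{p}" for j, p in enumerate(ds.pop)]
    return pd.DataFrame(dist, index=ids, columns=ids)


def shared_allele_nj(ds: GenotypeDataset) -> str:
    """Unrooted neighbor-joining tree (Newick) on shared-allele distances."""
    if ds.n_individuals < 4:
        raise ValueError("NJ tree needs >=4 individuals")
    dmat = shared_allele_distance(ds)
    dm = DistanceMatrix(dmat.to_numpy(), ids=list(dmat.index))
    tree = _skbio_nj(dm)
    return str(tree).strip()


def genotype_pca(ds: GenotypeDataset, n_components: int | None = None):
    """PCA on per-allele dosage encoding (0/1/2), column-centered.

    Missing genotypes are mean-imputed per allele column.  Returns
    ``(scores, explained_variance, explained_variance_ratio)``; score signs
    are arbitrary.
    """
    if ds.n_individuals < 3:
        raise ValueError("PCA needs >=3 individuals")
    cols = []
    for l in range(ds.n_loci):
        g = ds.alleles[:, l, :]
        obs = g[g != MISSING]
        for a in np.unique(obs):
            dose = (g == a).sum(axis=1).astype(float)
            dose[g[:, 0] == MISSING] = np.nan
            mean = np.nanmean(dose) if np.any(~np.isnan(dose)) else 0.0
            dose = np.where(np.isnan(dose), mean, dose)
            cols.append(dose)
    x = np.column_stack(cols) if cols else np.zeros((ds.n_individuals, 1))
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2 / max(ds.n_individuals - 1, 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    scores = u * s
    if n_components is not None:
        scores = scores[:, :n_components]
        var = var[:n_components]
        ratio = ratio[:n_components]
    return scores, var, ratio


# ---------------------------------------------------------------------------
# directional relative migration


def _freq_tables(ds: GenotypeDataset, level: str) -> list[dict[str, np.ndarray]]:
    """Per-locus allele-frequency vectors per group."""
    groups = ds.group_indices(level)
    out = []
    for l in range(ds.n_loci):
        blocks = {g: _locus_calls(ds, idx, l) for g, idx in groups.items()}
        coded, k = _allele_codes([b for b in blocks.values() if b.size])
        it = iter(coded)
        freqs = {}
        for g, b in blocks.items():
            if b.size:
                c = next(it)
                freqs[g] = np.bincount(c.ravel(), minlength=k) / (2.0 * b.shape[0])
            else:
                freqs[g] = np.full(k, np.nan)
        out.append(freqs)
    return out


def _pair_metric(pa: np.ndarray, pb: np.ndarray, metric: str) -> float:
    """Two-deme differentiation (unweighted) between frequency vectors."""
    hs = 1.0 - 0.5 * ((pa**2).sum() + (pb**2).sum())
    pm = (pa + pb) / 2.0
    ht = 1.0 - (pm**2).sum()
    if ht <= 0:
        return np.nan
    if metric == "gst":
        return (ht - hs) / ht
    if metric == "d":
        if hs >= 1.0:
            return np.nan
        return (ht - hs) / (1.0 - hs) * 2.0  # Jost's D, n = 2 demes
    raise ValueError("metric must be 'gst' or 'd'")


def relative_migration(
    ds: GenotypeDataset,
    metric: str = "gst",
    level: str = "population",
    n_boot: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Directional relative migration between groups (divMigrate method).

    For each ordered pair, a hypothetical pool with the average allele
    frequencies of the two groups is built; the differentiation ``d`` between
    the receiving group and the pool is converted to an Nm analogue
    ``0.25 (1/d - 1)`` and the whole matrix is scaled to a maximum of 1.
    Entry ``[a, b]`` is the relative migration from a to b.
    """
    names = list(ds.group_indices(level))
    if len(names) < 2:
        raise ValueError("relative migration needs >=2 groups")
    freqs = _freq_tables(ds, level)
    k = len(names)
    nm = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            num = den = 0.0
            for lf in freqs:
                pa, pb = lf[names[i]], lf[names[j]]
                if np.any(np.isnan(pa)) or np.any(np.isnan(pb)):
                    continue
                pool = (pa + pb) / 2.0
                d = _pair_metric(pb, pool, metric)  # receiver vs pool
                if np.isnan(d):
                    continue
                num += d
                den += 1
            if den == 0:
                warnings.warn(f"metric undefined for pair ({names[i]}, {names[j]})")
                continue
            d = num / den
            if d <= 0:
                d = 1e-6
            nm[i, j] = 0.25 * (1.0 / d - 1.0)
    mx = np.nanmax(nm)
    if mx > 0:
        nm = nm / mx
    return pd.DataFrame(nm, index=names, columns=names)
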