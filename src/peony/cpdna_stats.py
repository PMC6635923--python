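"""Chloroplast-haplotype statistics: alignment collapsing with indel
recoding, diversity, GST/NST differentiation with permutation testing,
AMOVA on haplotype distances and a minimum-spanning haplotype network.

Indels: each maximal run of alignment columns containing gaps is recoded as
one binary character (A = gap absent, T = gap present), so a multi-base
indel counts as a single difference.  Which state maps to gap presence does
not affect any statistic.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import HaplotypeTable
from .msat_stats import amova_from_distances

_VALID = set("ACGT-")


def _gap_runs(cols_with_gap: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive gap-containing columns, half-open."""
    runs = []
    start = None
    prev = None
    for c in cols_with_gap:
        if start is None:
            start = prev = c
        elif c == prev + 1:
            prev = c
        else:
            runs.append((start, prev + 1))
            start = prev = c
    if start is not None:
        runs.append((start, prev + 1))
    return runs


def recode_alignment(sequences: Mapping[str, str]) -> dict[str, str]:
    """Recode gaps: every contiguous gap run becomes one A/T character.

    Non-ACGT characters (ambiguity codes) are replaced by ``N`` and treated
    as missing when counting differences.
    """
    ids = list(sequences)
    seqs = [sequences[i].upper() for i in ids]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must all have the same length")
    arr = np.array([list(s) for s in seqs])
    bad = ~np.isin(arr, list(_VALID))
    if bad.any():
        warnings.warn("ambiguity codes treated as missing for difference counting")
        arr[bad] = "N"
    gap_cols = np.flatnonzero((arr == "-").any(axis=0))
    runs = _gap_runs(gap_cols)
    keep = np.ones(arr.shape[1], dtype=bool)
    for a, b in runs:
        keep[a:b] = False
    pieces = [arr[:, keep]]
    for a, b in runs:
        has_gap = (arr[:, a:b] == "-").any(axis=1)
        pieces.append(np.where(has_gap, "T", "A")[:, None])
    recoded = np.concatenate(pieces, axis=1)
    return {i: "".join(row) for i, row in zip(ids, recoded)}


def _pairwise_diffs(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    k = len(seqs)
    d = np.zeros((k, k))
    for i in range(k):
        ok_i = arr[i] != "N"
        for j in range(i + 1, k):
            ok = ok_i & (arr[j] != "N")
            d[i, j] = d[j, i] = int(np.sum((arr[i] != arr[j]) & ok))
    return d


def collapse_haplotypes(
    sequences: Mapping[str, str],
    assignments: pd.DataFrame,
) -> HaplotypeTable:
    """Collapse an aligned set of sequences into a haplotype table.

    ``assignments`` needs columns ``individual`` and ``population`` (and
    optionally ``species``); every sequence id must be assigned.  Haplotype
    ids are assigned H1, H2, ... in order of first appearance.
    """
    if "individual" not in assignments.columns or "population" not in assignments.columns:
        raise ValueError("assignments need 'individual' and 'population' columns")
    assigned = set(assignments["individual"])
    unassigned = set(sequences) - assigned
    if unassigned:
        raise ValueError(f"sequences without assignment: {sorted(unassigned)[:5]}")
    recoded = recode_alignment(sequences)
    hap_of: dict[str, str] = {}
    hap_seq: dict[str, str] = {}
    for ind in assignments["individual"]:
        s = recoded[ind]
        for hid, hs in hap_seq.items():
            if hs == s:
                hap_of[ind] = hid
                break
        else:
            hid = f"H{len(hap_seq) + 1}"
            hap_seq[hid] = s
            hap_of[ind] = hid
    diffs = _pairwise_diffs(list(hap_seq.values()))
    counts: dict[str, dict[str, int]] = {}
    pop_species: dict[str, str] = {}
    has_sp = "species" in assignments.columns
    for _, row in assignments.iterrows():
        pop = row["population"]
        counts.setdefault(pop, {})
        hid = hap_of[row["individual"]]
        counts[pop][hid] = counts[pop].get(hid, 0) + 1
        if has_sp:
            pop_species[pop] = row["species"]
    example = next(iter(sequences.values()))
    return HaplotypeTable(hap_seq, diffs, counts, pop_species, seq_length=len(example))


# ---------------------------------------------------------------------------
# diversity


def haplotype_diversity(counts: Mapping[str, int] | np.ndarray) -> float:
    """Nei's unbiased haplotype diversity ``n/(n-1) (1 - sum p_i^2)``.

    ``counts`` may be a haplotype -> count mapping or a count vector.
    Undefined for n < 2 (returns NaN with a warning).
    """
    c = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts,
                   dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        warnings.warn("haplotype diversity undefined for n < 2")
        return float("nan")
    p2 = ((c / n) ** 2).sum()
    return float(n / (n - 1.0) * (1.0 - p2))


def nucleotide_diversity(
    table: HaplotypeTable, group: str | list[str], seq_length: int | None = None
) -> float:
    """Mean pairwise differences per site over all individual pairs in the
    pooled populations of ``group``."""
    length = seq_length if seq_length is not None else table.seq_length
    if not length or length <= 0:
        raise ValueError("a positive sequence length is required")
    pops = [group] if isinstance(group, str) else list(group)
    pooled = table.pooled_counts(pops)
    ids = table.haplotype_ids()
    c = np.array([pooled.get(h, 0) for h in ids], dtype=float)
    n = c.sum()
    if n < 2:
        return 0.0
    total = float(c @ table.diffs @ c) / 2.0  # ordered pairs double-count
    n_pairs = n * (n - 1) / 2.0
    return total / n_pairs / length


# ---------------------------------------------------------------------------
# GST / NST (Pons & Petit)


def _pons_petit(count_mat: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """(G_ST, N_ST) from a population x haplotype count matrix and a
    haplotype distance matrix, with Pons & Petit small-sample corrections."""
    n_k = count_mat.sum(axis=1)
    keep = n_k >= 2
    count_mat = count_mat[keep]
    n_k = n_k[keep]
    k_pops = count_mat.shape[0]
    if k_pops < 2:
        raise ValueError("GST/NST need >=2 populations with n >= 2")
    x = count_mat / n_k[:, None]
    n_tilde = k_pops / (1.0 / n_k).sum()
    xbar = x.mean(axis=0)

    hs_k = n_k / (n_k - 1.0) * (1.0 - (x**2).sum(axis=1))
    hs = hs_k.mean()
    ht = 1.0 - (xbar**2).sum() + hs / (n_tilde * k_pops)

    vs_k = n_k / (n_k - 1.0) * np.einsum("ij,jk,ik->i", x, d, x)
    vs = vs_k.mean()
    vt = float(xbar @ d @ xbar) + vs / (n_tilde * k_pops)

    if ht <= 0 or vt <= 0:
        raise ValueError("total diversity is zero; differentiation undefined")
    gst = float(np.clip(1.0 - hs / ht, 0.0, 1.0))
    nst = float(np.clip(1.0 - vs / vt, 0.0, 1.0))
    return gst, nst


def gst_nst(
    table: HaplotypeTable,
    n_perm: int = 10000,
    seed: int | None = None,
    populations: list[str] | None = None,
) -> dict:
    """G_ST (frequency-only) and N_ST (distance-weighted) differentiation
    with a one-tailed permutation test of N_ST > G_ST.

    The null permutes haplotype identities in the distance matrix, which
    breaks any association between haplotype relatedness and geography while
    keeping the frequency structure (and hence G_ST) fixed.
    """
    cm = table.count_matrix()
    if populations is not None:
        cm = cm.loc[populations]
    counts = cm.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValueError("GST/NST need >=2 populations")
    d = table.diffs
    try:
        gst, nst = _pons_petit(counts, d)
    except ValueError as err:
        warnings.warn(str(err))
        return {"gst": float("nan"), "nst": float("nan"), "p": float("nan")}
    rng = np.random.default_rng(seed)
    hits = 0
    k = d.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(k)
        _, nst_p = _pons_petit(counts, d[np.ix_(perm, perm)])
        if nst_p >= nst:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return {"gst": gst, "nst": nst, "p": p, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# AMOVA on haplotype distances


def _expand_units(table: HaplotypeTable, populations: list[str] | None = None):
    """Per-individual haplotype indices and labels from the count table."""
    ids = table.haplotype_ids()
    pos = {h: i for i, h in enumerate(ids)}
    hap_idx, pops, species = [], [], []
    use = populations if populations is not None else list(table.counts)
    for p in use:
        for h, c in table.counts[p].items():
            hap_idx.extend([pos[h]] * int(c))
            pops.extend([p] * int(c))
            species.extend([table.pop_species.get(p, p)] * int(c))
    return np.array(hap_idx), np.array(pops, dtype=object), np.array(species, dtype=object)


def amova_cpdna(
    table: HaplotypeTable,
    hierarchy: str = "species/pop",
    n_perm: int = 10000,
    seed: int | None = None,
    populations: list[str] | None = None,
) -> dict:
    """Hierarchical AMOVA with inter-individual distance = haplotype
    pairwise difference count."""
    hap_idx, pops, species = _expand_units(table, populations)
    d = table.diffs[np.ix_(hap_idx, hap_idx)]
    sp = species if hierarchy == "species/pop" else None
    if sp is not None and len(set(species)) < 2:
        raise ValueError("three-level AMOVA needs >=2 species")
    return amova_from_distances(d, pops, sp, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# haplotype network


def haplotype_network(table: HaplotypeTable) -> pd.DataFrame:
    """Minimum-spanning network: all MST edges plus tied-weight alternatives.

    An edge belongs to the network iff it belongs to *some* minimum spanning
    tree, i.e. its weight equals the minimax path weight between its
    endpoints.  Returns an edge list with mutational step counts and node
    total counts attached as a DataFrame attribute ``node_sizes``.
    """
    ids = table.haplotype_ids()
    if len(ids) < 2:
        raise ValueError("a network needs >=2 haplotypes")
    g = nx.Graph()
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            g.add_edge(a, ids[j], weight=float(table.diffs[i, j]))
    mst = nx.minimum_spanning_tree(g)
    edges = []
    for a, b, data in g.edges(data=True):
        path = nx.shortest_path(mst, a, b)
        minimax = max(
            mst[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
        )
        if data["weight"] <= minimax:
            edges.append((a, b, data["weight"]))
    pooled = table.pooled_counts()
    out = pd.DataFrame(edges, columns=["h1", "h2", "steps"])
    out.attrs["node_sizes"] = {h: pooled.get(h, 0) for h in ids}
    return out


def network_to_dot(edges: pd.DataFrame) -> str:
    """Graphviz DOT rendering of a haplotype network edge list."""
    sizes = edges.attrs.get("node_sizes", {})
    lines = ["graph haplotypes {"]
    for h, s in sizes.items():
        lines.append(f'  "{h}" [width={max(0.3, 0.1 * np.sqrt(s)):.2f}, label="{h} ({s})"];')
    for _, row in edges.iterrows():
        lines.append(f'  "{row.h1}" -- "{row.h2}" [label="{int(row.steps)}"];')
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# reports


def diversity_report(table: HaplotypeTable) -> pd.DataFrame:
    """Per-population and pooled per-species Hd and pi."""
    rows = []
    for p, cmap in table.counts.items():
        n = sum(cmap.values())
        rows.append({
            "group": p, "level": "population", "n": n,
            "Hd": haplotype_diversity(cmap) if n >= 2 else float("nan"),
            "pi": nucleotide_diversity(table, p),
        })
    for sp, pops in table.species_pools().items():
        pooled = table.pooled_counts(pops)
        rows.append({
            "group": sp, "level": "species", "n": sum(pooled.values()),
            "Hd": haplotype_diversity(pooled),
            "pi": nucleotide_diversity(table, pops),
        })
    return pd.DataFrame(rows).set_index("group")
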