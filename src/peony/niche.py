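"""Climate-variable filtering, PCA reduction and the background (d_b) versus
observed (d_n) niche-divergence test between species pairs.

The test follows the background-resampling logic of multivariate niche
comparisons: on each retained PC axis the observed divergence is the absolute
difference of species occurrence centroids; the null distribution of
background divergence is built by resampling background points (with
replacement, at the occurrence sample sizes).  Divergence on an axis is
supported when d_n exceeds the upper 95% bound of the d_b null *and* d_n is
itself significant against a species-label permutation null; conservatism is
flagged when d_n falls below the background median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NicheDataset


def filter_correlated(
    table: pd.DataFrame, variables: list[str] | None = None, threshold: float = 0.8
) -> list[str]:
    """Greedy elimination of highly correlated variables.

    While any pair has |Pearson r| >= threshold, the variable with the
    largest mean absolute correlation (among those in a violating pair) is
    dropped; ties break deterministically by column order.  Constant columns
    are dropped first with a warning.
    """
    cols = list(variables) if variables is not None else list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables")
    x = table[cols].to_numpy(dtype=float)
    keep = [c for c, s in zip(cols, x.std(axis=0)) if s > 0]
    if len(keep) < len(cols):
        warnings.warn(f"constant variables dropped: {sorted(set(cols) - set(keep))}")
    while len(keep) > 1:
        c = np.abs(np.corrcoef(table[keep].to_numpy(dtype=float), rowvar=False))
        np.fill_diagonal(c, 0.0)
        if c.max() < threshold:
            break
        involved = np.flatnonzero((c >= threshold).any(axis=0))
        mean_abs = c.mean(axis=0)
        drop = involved[np.argmax(mean_abs[involved])]
        keep.pop(int(drop))
    return keep


@dataclass
class NichePCA:
    occ_scores: pd.DataFrame  # columns: species + PC1..PCk
    bg_scores: pd.DataFrame
    loadings: pd.DataFrame  # variables x PCs
    explained_ratio: np.ndarray


def niche_pca(
    ds: NicheDataset,
    species: list[str] | None = None,
    variables: list[str] | None = None,
    n_components: int | None = None,
) -> NichePCA:
    """Standardized PCA over occurrences and background points jointly.

    Per-pair analyses pass the two species; the z-scoring and rotation are
    computed on the pooled points of the selected species.
    """
    sel = species if species is not None else ds.species_list()
    variables = variables if variables is not None else list(ds.variables)
    if len(variables) < 2:
        raise ValueError("PCA needs at least two retained variables")
    occ = ds.occurrences[ds.occurrences["species"].isin(sel)]
    bg = ds.background[ds.background["species"].isin(sel)]
    x = np.vstack([occ[variables].to_numpy(float), bg[variables].to_numpy(float)])
    if x.shape[0] < len(variables):
        warnings.warn("fewer points than variables; rank-limited PCA")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2 / max(z.shape[0] - 1, 1)
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    k = n_components or min(len(variables), z.shape[0])
    scores = u[:, :k] * s[:k]
    pcs = [f"PC{i + 1}" for i in range(k)]
    occ_scores = pd.DataFrame(scores[: len(occ)], columns=pcs)
    occ_scores.insert(0, "species", occ["species"].to_numpy())
    bg_scores = pd.DataFrame(scores[len(occ):], columns=pcs)
    bg_scores.insert(0, "species", bg["species"].to_numpy())
    loadings = pd.DataFrame(vt[:k].T, index=variables, columns=pcs)
    return NichePCA(occ_scores, bg_scores, loadings, ratio[:k])


@dataclass
class DivergenceResult:
    pair: tuple[str, str]
    table: pd.DataFrame  # per-axis d_n, d_b bounds, p-values, verdict
    explained_ratio: np.ndarray
    loadings: pd.DataFrame
    geo_correlations: pd.DataFrame | None = None

    def verdicts(self) -> dict[str, str]:
        return dict(zip(self.table.index, self.table["verdict"]))


def divergence_test(
    ds: NicheDataset,
    species_a: str,
    species_b: str,
    axes: int = 2,
    n_resample: int = 1000,
    seed: int | None = None,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> DivergenceResult:
    """Background vs observed niche divergence on the leading PC axes."""
    rng = np.random.default_rng(seed)
    pca = niche_pca(ds, [species_a, species_b], variables)
    occ = pca.occ_scores
    bg = pca.bg_scores
    a_occ = occ[occ["species"] == species_a]
    b_occ = occ[occ["species"] == species_b]
    a_bg = bg[bg["species"] == species_a]
    b_bg = bg[bg["species"] == species_b]
    if len(a_occ) < 3 or len(b_occ) < 3:
        raise ValueError("each species needs >= 3 occurrences")
    if len(a_bg) == 0 or len(b_bg) == 0:
        raise ValueError("both species need background points")
    pcs = [c for c in occ.columns if c.startswith("PC")][:axes]
    rows = []
    for pc in pcs:
        xa = a_occ[pc].to_numpy(float)
        xb = b_occ[pc].to_numpy(float)
        if xa.std() == 0 and xb.std() == 0:
            warnings.warn(f"{pc}: degenerate axis variance, skipped")
            continue
        d_n = abs(xa.mean() - xb.mean())
        ba = a_bg[pc].to_numpy(float)
        bb = b_bg[pc].to_numpy(float)
        d_b = np.abs(
            ba[rng.integers(0, ba.size, size=(n_resample, xa.size))].mean(axis=1)
            - bb[rng.integers(0, bb.size, size=(n_resample, xb.size))].mean(axis=1)
        )
        hi = float(np.percentile(d_b, 95))
        # permutation significance of d_n itself
        pooled = np.concatenate([xa, xb])
        na = xa.size
        hits = 0
        for _ in range(n_resample):
            perm = rng.permutation(pooled)
            if abs(perm[:na].mean() - perm[na:].mean()) >= d_n:
                hits += 1
        p_dn = (hits + 1) / (n_resample + 1)
        if d_n > hi and p_dn <= alpha:
            verdict = "divergence"
        elif d_n < float(np.median(d_b)):
            verdict = "conservatism"
        else:
            verdict = "no divergence"
        rows.append({"axis": pc, "d_n": d_n, "d_b_lo": 0.0, "d_b_hi": hi,
                     "p_d_n": p_dn, "verdict": verdict})
    table = pd.DataFrame(rows).set_index("axis")

    geo = None
    geo_vars = [v for v in ("lat", "lon", "altitude") if v in ds.occurrences.columns]
    if geo_vars:
        occ_geo = ds.occurrences[ds.occurrences["species"].isin([species_a, species_b])]
        grows = []
        for pc in pcs:
            scores = occ[pc].to_numpy(float)
            rec = {"axis": pc}
            for gv in geo_vars:
                g = occ_geo[gv].to_numpy(float)
                if np.std(g) == 0 or np.std(scores) == 0:
                    rec[f"r_{gv}"] = np.nan
                    continue
                r, p = stats.pearsonr(scores, g)
                rec[f"r_{gv}"] = r
                rec[f"sig_{gv}"] = bool(p < 0.001)
            grows.append(rec)
        geo = pd.DataFrame(grows).set_index("axis")

    top = {
        pc: ", ".join(pca.loadings[pc].abs().sort_values(ascending=False).index[:3])
        for pc in pcs
    }
    if len(table):
        table["top_loading"] = [top[pc] for pc in table.index]
        table["pct_variance"] = [100 * pca.explained_ratio[pcs.index(pc)]
                                 for pc in table.index]
    return DivergenceResult((species_a, species_b), table, pca.explained_ratio,
                            pca.loadings, geo)
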