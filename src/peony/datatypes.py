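"""Core in-memory containers shared across the package.

The analysis operates on three kinds of data: diploid microsatellite
genotypes (allele sizes per individual x locus), chloroplast haplotypes
(a collapsed alignment with per-population counts), and climate/occurrence
tables for niche analysis.  Each container validates its own invariants on
construction so downstream statistics can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call.  Both alleles of a genotype are
#: either present or missing; a half-missing call is rejected.
MISSING = -1


@dataclass
class GenotypeDataset:
    """Diploid allele-size calls with population and species labels.

    Parameters
    ----------
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)`` holding allele
        sizes (repeat counts or bp). ``MISSING`` (-1) marks absent calls.
    pop
        Population label per individual.
    species
        Species label per individual.  Every population must map to exactly
        one species.
    loci
        Locus names, length ``n_loci``.
    coords
        Optional per-population coordinates (DataFrame indexed by population
        label with columns ``lat``/``lon`` in decimal degrees).
    """

    alleles: np.ndarray
    pop: np.ndarray
    species: np.ndarray
    loci: list[str] = field(default_factory=list)
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        self.pop = np.asarray(self.pop, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_ind, n_loci, 2)")
        n, l, _ = self.alleles.shape
        if len(self.pop) != n or len(self.species) != n:
            raise ValueError("label length does not match individual count")
        if not self.loci:
            self.loci = [f"L{i + 1}" for i in range(l)]
        if len(self.loci) != l:
            raise ValueError("locus name count does not match allele array")
        half = (self.alleles == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing genotype call (one allele missing)")
        # each population maps to one species
        mapping: dict[str, str] = {}
        for p, s in zip(self.pop, self.species):
            if mapping.setdefault(p, s) != s:
                raise ValueError(f"population {p!r} assigned to several species")
        self._pop_species = mapping

    # -- conveniences -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.pop))

    def species_list(self) -> list[str]:
        return list(dict.fromkeys(self.species))

    def pop_to_species(self) -> dict[str, str]:
        return dict(self._pop_species)

    def group_indices(self, level: str = "population") -> dict[str, np.ndarray]:
        """Individual indices per group at ``population`` or ``species`` level."""
        labels = self.pop if level == "population" else self.species
        order = list(dict.fromkeys(labels))
        return {g: np.flatnonzero(labels == g) for g in order}

    def subset(self, mask: np.ndarray) -> "GenotypeDataset":
        coords = self.coords
        return GenotypeDataset(
            self.alleles[mask], self.pop[mask], self.species[mask], list(self.loci), coords
        )


@dataclass
class HaplotypeTable:
    """Distinct cpDNA haplotypes, pairwise differences and population counts.

    ``diffs[i, j]`` counts differing characters between haplotypes i and j in
    the recoded alignment (a contiguous indel contributes one character).
    ``counts`` maps population -> haplotype id -> number of individuals.
    """

    haplotypes: dict[str, str]
    diffs: np.ndarray
    counts: dict[str, dict[str, int]]
    pop_species: dict[str, str] = field(default_factory=dict)
    seq_length: int | None = None

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)
        k = len(self.haplotypes)
        if self.diffs.shape != (k, k):
            raise ValueError("diffs shape does not match haplotype count")
        if np.any(np.diag(self.diffs) != 0):
            raise ValueError("diffs diagonal must be zero")
        if not np.allclose(self.diffs, self.diffs.T):
            raise ValueError("diffs must be symmetric")
        ids = set(self.haplotype_ids())
        for p, cmap in self.counts.items():
            unknown = set(cmap) - ids
            if unknown:
                raise ValueError(f"population {p!r} counts unknown haplotypes {unknown}")

    def haplotype_ids(self) -> list[str]:
        return list(self.haplotypes)

    def index_of(self, hid: str) -> int:
        return self.haplotype_ids().index(hid)

    def count_matrix(self) -> pd.DataFrame:
        """Population x haplotype count table (rows in input order)."""
        ids = self.haplotype_ids()
        rows = {p: [cmap.get(h, 0) for h in ids] for p, cmap in self.counts.items()}
        return pd.DataFrame.from_dict(rows, orient="index", columns=ids)

    def pooled_counts(self, populations: list[str] | None = None) -> dict[str, int]:
        pops = populations if populations is not None else list(self.counts)
        out: dict[str, int] = {}
        for p in pops:
            for h, c in self.counts[p].items():
                out[h] = out.get(h, 0) + c
        return {h: c for h, c in out.items() if c > 0}

    def species_pools(self) -> dict[str, list[str]]:
        pools: dict[str, list[str]] = {}
        for p in self.counts:
            pools.setdefault(self.pop_species.get(p, p), []).append(p)
        return pools


@dataclass
class NicheDataset:
    """Occurrence and background climate points for niche-divergence tests."""

    occurrences: pd.DataFrame  # columns: species, lat, lon, <variables...>
    background: pd.DataFrame  # columns: species, <variables...>
    variables: list[str]

    def __post_init__(self) -> None:
        for v in self.variables:
            if v not in self.occurrences.columns or v not in self.background.columns:
                raise ValueError(f"variable {v!r} missing from occurrence/background table")

    def species_list(self) -> list[str]:
        return list(dict.fromkeys(self.occurrences["species"]))

    def occ_values(self, species: str) -> np.ndarray:
        df = self.occurrences[self.occurrences["species"] == species]
        return df[self.variables].to_numpy(dtype=float)

    def bg_values(self, species: str) -> np.ndarray:
        df = self.background[self.background["species"] == species]
        return df[self.variables].to_numpy(dtype=float)
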