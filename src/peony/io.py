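"""Readers and writers for the external text formats the pipeline uses:
GenePop-dialect genotype files, FASTA alignments (via Biopython) and CSV
assignment/metadata tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import MISSING, GenotypeDataset

_ALLELE_DIGITS = 3


def write_genepop(ds: GenotypeDataset, path: str | Path, title: str = "peony dataset") -> None:
    """Write genotypes in the GenePop dialect (3-digit allele codes).

    Missing calls are written as 000000.  Population blocks follow the
    dataset's population order; individual ids embed the population label.
    """
    lines = [title]
    lines.extend(ds.loci)
    for pop, idx in ds.group_indices("population").items():
        lines.append("Pop")
        for i in idx:
            genos = []
            for l in range(ds.n_loci):
                a, b = ds.alleles[i, l]
                if a == MISSING:
                    genos.append("000000")
                else:
                    genos.append(f"{a:0{_ALLELE_DIGITS}d}{b:0{_ALLELE_DIGITS}d}")
            lines.append(f"{pop}_{i} , " + " ".join(genos))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path, pop_table: pd.DataFrame | str | Path) -> GenotypeDataset:
    """Read a GenePop-dialect file plus a population metadata table.

    ``pop_table`` (DataFrame or CSV path) must have one row per population
    block, in file order, with columns ``population`` and ``species`` and
    optionally ``lat``/``lon``.
    """
    if not isinstance(pop_table, pd.DataFrame):
        pop_table = pd.read_csv(pop_table)
    text = Path(path).read_text().strip().splitlines()
    if not text:
        raise ValueError("empty GenePop file")
    body = text[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend([x.strip() for x in body[i].split(",") if x.strip()])
        i += 1
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in body[i:]:
        if line.strip().lower() == "pop":
            current = []
            blocks.append(current)
        elif line.strip():
            if current is None:
                raise ValueError("genotype line before first Pop marker")
            current.append(line)
    if len(blocks) != len(pop_table):
        raise ValueError(
            f"{len(blocks)} population blocks but {len(pop_table)} rows in the "
            "population table"
        )
    alleles, pops, species = [], [], []
    for block, (_, meta) in zip(blocks, pop_table.iterrows()):
        for line in block:
            if "," not in line:
                raise ValueError(f"malformed genotype line: {line!r}")
            _, geno_part = line.split(",", 1)
            calls = geno_part.split()
            if len(calls) != len(loci):
                raise ValueError(
                    f"expected {len(loci)} loci, found {len(calls)}: {line!r}"
                )
            row = []
            for c in calls:
                a = int(c[:_ALLELE_DIGITS])
                b = int(c[_ALLELE_DIGITS:])
                row.append([MISSING, MISSING] if a == 0 or b == 0 else [a, b])
            alleles.append(row)
            pops.append(meta["population"])
            species.append(meta["species"])
    coords = None
    if {"lat", "lon"} <= set(pop_table.columns):
        coords = pop_table.set_index("population")[["lat", "lon"]]
    return GenotypeDataset(
        np.array(alleles, dtype=np.int32), np.array(pops, dtype=object),
        np.array(species, dtype=object), loci, coords,
    )


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"individual", "population"}
    if not needed <= set(df.columns):
        raise ValueError("assignment table needs 'individual' and 'population' columns")
    return df


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("occurrence table needs a 'species' column")
    return df
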