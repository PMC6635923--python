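"""End-to-end orchestration: simulate (or load) data, run the statistics
stages, ABC inference and the niche test from a single structured config,
with every stochastic stage seeded and recorded in a run manifest."""

from __future__ import annotations

import hashlib
import json
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    abc_inference,
    coalsim,
    cpdna_stats,
    io,
    msat_stats,
    neutrality,
    niche,
    synthetic_data,
)

#: Truth parameters used by the default synthetic run: posterior medians for
#: the current sizes, times and mutation rate; ancestral sizes from the
#: companion text estimates (the table omits them).
DEFAULT_TRUTH = dict(nj=1690, nq=4910, nr=5090, a1=5000, a2=9520,
                     t1=2430, t2=5030, mu=1.74e-4)
DEFAULT_SAMPLES = {"PJ": 255, "PQ": 118, "PR": 214}


@dataclass
class RunConfig:
    out_dir: str = "peony_run"
    seed: int = 1
    stages: dict = field(default_factory=lambda: {
        "msat": True, "cpdna": True, "neutrality": True, "abc": True, "niche": True,
    })
    # synthetic-data generation settings (used when no input paths are given)
    n_loci: int = 22
    sample_config: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    truth_params: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    scenario_id: int = 1
    step: int = 2
    # analysis settings
    n_perm_amova: int = 1000
    n_perm_mantel: int = 999
    n_perm_nst: int = 1000
    abc_n_per_scenario: int = 500
    abc_tolerance: float = 0.01
    neutrality_sims: int = 200
    mismatch_boot: int = 100
    niche_resamples: int = 1000
    # optional input paths (synthetic mode when absent)
    genotypes: str | None = None
    pop_table: str | None = None
    cpdna_fasta: str | None = None
    cpdna_assignments: str | None = None
    occurrences: str | None = None
    background: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages; returns (and writes) the run manifest.

    A failing stage is recorded in the manifest and does not corrupt the
    outputs of the others.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, status: str, seed: int | None = None, error: str | None = None):
        manifest["stages"][stage] = {"status": status, "seed": seed}
        if error:
            manifest["stages"][stage]["error"] = error

    def emit(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path)
        manifest["outputs"].append(name)

    # ---- data -------------------------------------------------------------
    params = coalsim.params_from_dict(cfg.truth_params)
    gen_seed = int(rng.integers(1, 2**31 - 1))
    if cfg.genotypes:
        ds = io.read_genepop(cfg.genotypes, cfg.pop_table)
    else:
        ds, truth = synthetic_data.make_microsat_truth(
            cfg.scenario_id, params, cfg.sample_config, cfg.n_loci,
            seed=gen_seed, step=cfg.step,
        )
        io.write_genepop(ds, out / "genotypes.genepop.txt")
        (out / "genotypes.truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
        manifest["outputs"] += ["genotypes.genepop.txt", "genotypes.truth.json"]

    if cfg.cpdna_fasta:
        seqs = io.read_fasta(cfg.cpdna_fasta)
        assign = io.read_assignments(cfg.cpdna_assignments)
    else:
        cp_seed = int(rng.integers(1, 2**31 - 1))
        counts = {
            "PJ1": {"H1": 10}, "PJ2": {"H1": 8, "H2": 4},
            "PQ1": {"H3": 9}, "PQ2": {"H3": 5, "H4": 5},
            "PR1": {"H5": 8}, "PR2": {"H5": 4, "H6": 6},
        }
        pop_species = {p: p[:2] for p in counts}
        seqs, assign, _ = synthetic_data.make_cpdna_truth(
            counts, n_sites=800, n_mutations=12, include_indel=True,
            seed=cp_seed, pop_species=pop_species,
        )
        io.write_fasta(seqs, out / "cpdna.fasta")
        assign.to_csv(out / "cpdna_assignments.csv", index=False)
        manifest["outputs"] += ["cpdna.fasta", "cpdna_assignments.csv"]

    # ---- stages -----------------------------------------------------------
    if cfg.stages.get("msat"):
        seed = int(rng.integers(1, 2**31 - 1))
        try:
            emit(msat_stats.diversity_report(ds), "msat_diversity.csv")
            fst = msat_stats.pairwise_fst(ds)
            emit(fst.matrix, "msat_pairwise_fst.csv")
            res = msat_stats.amova(ds, n_perm=cfg.n_perm_amova, seed=seed)
            emit(pd.DataFrame({
                "component": list(res["components"]),
                "variance": list(res["components"].values()),
                "percent": list(res["percent"].values()),
            }).set_index("component"), "msat_amova.csv")
            if ds.coords is not None:
                r, p = msat_stats.mantel_ibd(fst, ds.coords,
                                             n_perm=cfg.n_perm_mantel, seed=seed)
                emit(pd.DataFrame([{"r": r, "p": p}]), "msat_ibd.csv")
            scores, var, ratio = msat_stats.genotype_pca(ds, n_components=4)
            pca = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
            pca.insert(0, "species", ds.species)
            pca.insert(0, "population", ds.pop)
            emit(pca, "msat_pca_scores.csv")
            emit(msat_stats.relative_migration(ds, level="species"),
                 "msat_relative_migration.csv")
            (out / "msat_nj.nwk").write_text(msat_stats.shared_allele_nj(ds) + "\n")
            manifest["outputs"].append("msat_nj.nwk")
            record("msat", "ok", seed)
        except Exception as err:  # pragma: no cover - defensive
            record("msat", "failed", seed, f"{err}\n{traceback.format_exc()}")
    else:
        record("msat", "skipped")

    table = None
    if cfg.stages.get("cpdna"):
        seed = int(rng.integers(1, 2**31 - 1))
        try:
            table = cpdna_stats.collapse_haplotypes(seqs, assign)
            emit(table.count_matrix(), "cpdna_haplotype_counts.csv")
            emit(cpdna_stats.diversity_report(table), "cpdna_diversity.csv")
            gn = cpdna_stats.gst_nst(table, n_perm=cfg.n_perm_nst, seed=seed)
            emit(pd.DataFrame([gn]), "cpdna_gst_nst.csv")
            res = cpdna_stats.amova_cpdna(table, n_perm=cfg.n_perm_amova, seed=seed)
            emit(pd.DataFrame({
                "component": list(res["components"]),
                "variance": list(res["components"].values()),
                "percent": list(res["percent"].values()),
            }).set_index("component"), "cpdna_amova.csv")
            net = cpdna_stats.haplotype_network(table)
            emit(net, "cpdna_network_edges.csv")
            (out / "cpdna_network.dot").write_text(cpdna_stats.network_to_dot(net))
            manifest["outputs"].append("cpdna_network.dot")
            record("cpdna", "ok", seed)
        except Exception as err:  # pragma: no cover
            record("cpdna", "failed", seed, f"{err}\n{traceback.format_exc()}")
    else:
        record("cpdna", "skipped")

    if cfg.stages.get("neutrality") and table is not None:
        seed = int(rng.integers(1, 2**31 - 1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emit(neutrality.species_report(
                    table, n_sim=cfg.neutrality_sims, n_boot=cfg.mismatch_boot,
                    seed=seed), "neutrality_mismatch.csv")
            record("neutrality", "ok", seed)
        except Exception as err:  # pragma: no cover
            record("neutrality", "failed", seed, f"{err}\n{traceback.format_exc()}")
    else:
        record("neutrality", "skipped")

    if cfg.stages.get("abc"):
        seed = int(rng.integers(1, 2**31 - 1))
        try:
            prior = coalsim.PriorConfig()
            scen = dict(coalsim.STEP2_SCENARIOS if cfg.step == 2
                        else coalsim.STEP1_SCENARIOS)
            ref = abc_inference.build_reference(
                scen, prior, cfg.abc_n_per_scenario, cfg.sample_config,
                cfg.n_loci, seed=seed,
            )
            ref.save(out / "abc_reference.csv")
            manifest["outputs"] += ["abc_reference.csv", "abc_reference.json"]
            obs = abc_inference.summarize(ds)
            choice = abc_inference.choose_scenario(obs, ref, cfg.abc_tolerance, seed=seed)
            emit(pd.DataFrame({
                "scenario": list(choice.posterior),
                "posterior": list(choice.posterior.values()),
                "ci_lo": [choice.ci95[s][0] for s in choice.posterior],
                "ci_hi": [choice.ci95[s][1] for s in choice.posterior],
            }).set_index("scenario"), "abc_scenario_choice.csv")
            est = abc_inference.estimate_params(obs, ref, choice.best(), prior,
                                                cfg.abc_tolerance)
            emit(est.quantiles, "abc_posterior_quantiles.csv")
            record("abc", "ok", seed)
        except Exception as err:  # pragma: no cover
            record("abc", "failed", seed, f"{err}\n{traceback.format_exc()}")
    else:
        record("abc", "skipped")

    if cfg.stages.get("niche"):
        seed = int(rng.integers(1, 2**31 - 1))
        try:
            if cfg.occurrences:
                occ = io.read_occurrences(cfg.occurrences)
                bg = io.read_occurrences(cfg.background)
                variables = [c for c in occ.columns
                             if c not in ("species", "lat", "lon")]
                from .datatypes import NicheDataset
                nds = NicheDataset(occ, bg, variables)
            else:
                nds, _ = synthetic_data.make_niche_truth(
                    n_species=3, centroid_shifts=[0.0, 1.5, 3.0], seed=seed,
                )
            retained = niche.filter_correlated(
                pd.concat([nds.occurrences[nds.variables],
                           nds.background[nds.variables]]), nds.variables)
            species = nds.species_list()
            frames = []
            for i, a in enumerate(species):
                for b in species[i + 1:]:
                    res = niche.divergence_test(
                        nds, a, b, n_resample=cfg.niche_resamples,
                        seed=seed, variables=retained)
                    t = res.table.copy()
                    t.insert(0, "pair", f"{a}-{b}")
                    frames.append(t)
            emit(pd.concat(frames), "niche_divergence.csv")
            record("niche", "ok", seed)
        except Exception as err:  # pragma: no cover
            record("niche", "failed", seed, f"{err}\n{traceback.format_exc()}")
    else:
        record("niche", "skipped")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
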