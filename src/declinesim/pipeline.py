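"""End-to-end orchestration: simulate -> datasets -> infer -> evaluate.

All randomness flows from a master seed through stable per-stage sub-seeds
(see :func:`declinesim.demography.derive_seed`); re-running a stage with the
same manifest reproduces its artifacts, and completed stages are skipped
unless forced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coalescent import VariantTable, drop_mutations, recapitate
from .datasets import (
    DataTypeSpec,
    SamplingScheme,
    SimulatedDataset,
    apply_maf_filter,
    assemble_dataset,
    draw_samples,
    write_dataset_sfs,
    write_vcf,
)
from .demography import (
    AncestralChange,
    DemographicScenario,
    GridEntry,
    SizeTrajectory,
    derive_seed,
    enumerate_study_grid,
    life_history,
)
from .evaluation import InferenceRecord, aggregate_report
from .forward_sim import ChromosomeSpec, Pedigree, simulate_chromosome, simulate_pedigree
from .ld import bin_pairs, ld_ne_point, ld_trajectory
from .sfs_fit import classify_trend, fit_all_models, select_model

__all__ = [
    "RunManifest",
    "run_pipeline",
    "make_fixture",
    "simulate_tables",
    "load_config",
    "data_type_spec",
    "infer_dataset",
]

STAGES = ("simulate", "datasets", "infer", "evaluate")


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    stages_done: list[str]
    artifacts: dict[str, str]

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(path.read_text()))


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    _validate_config(config)
    return config


def _validate_config(config: dict) -> None:
    for key in ("Ne_H", "recent", "replicates", "schemes", "data_types", "master_seed"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    for scheme in config["schemes"]:
        if scheme not in ("contemporary", "two_sample", "serial"):
            raise ValueError(f"invalid scheme name {scheme!r} in config")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def data_type_spec(name: str, n_chromosomes: int, chromosome_length: int) -> DataTypeSpec:
    """Map a grid data-type label to a concrete spec at the configured scale."""
    if name == "WGS":
        return DataTypeSpec(kind="WGS", genome_length=n_chromosomes * chromosome_length)
    if name.startswith("RAD"):
        per_chrom = {"RAD10k": 10_000, "RAD50k": 50_000}[name] // n_chromosomes
        return DataTypeSpec(kind="RAD", loci_per_chromosome=per_chrom)
    raise ValueError(f"unknown data type {name!r}")


# ---------------------------------------------------------------------------
# Simulation stage
# ---------------------------------------------------------------------------

def simulate_tables(
    scenario: DemographicScenario,
    seed: int,
    n_chromosomes: int = 25,
    chromosome_length: int = 30_000_000,
    n_record: int = 200,
    model: str = "hudson",
    checkpoint_years: tuple[int, ...] | None = None,
) -> tuple[Pedigree, list[VariantTable]]:
    """One full simulation: pedigree, per-chromosome ancestry, mutations."""
    kwargs = {} if checkpoint_years is None else {"checkpoint_years": checkpoint_years}
    pedigree = simulate_pedigree(
        scenario, derive_seed(seed, "pedigree"), n_record=n_record, **kwargs
    )
    tables = []
    for i in range(1, n_chromosomes + 1):
        spec = ChromosomeSpec(
            index=i,
            length_bp=chromosome_length,
            recombination_rate=scenario.recombination_rate,
        )
        ancestry = simulate_chromosome(pedigree, spec, derive_seed(seed, "chrom", i))
        forest = recapitate(
            ancestry,
            scenario,
            derive_seed(seed, "recap", i),
            pedigree_checkpoints=pedigree.checkpoints,
            model=model,
        )
        tables.append(drop_mutations(forest, scenario.mutation_rate, derive_seed(seed, "mut", i)))
    return pedigree, tables


def _save_tables(path: Path, pedigree: Pedigree, tables: list[VariantTable]) -> None:
    payload = {"checkpoint_years": np.array(sorted(pedigree.checkpoints, reverse=True))}
    for year, ids in pedigree.checkpoints.items():
        payload[f"checkpoint_{year}"] = ids
    for t in tables:
        payload[f"chrom{t.chrom}_positions"] = t.positions
        payload[f"chrom{t.chrom}_dosages"] = t.dosages
        payload[f"chrom{t.chrom}_length"] = np.array([t.length_bp])
        payload[f"chrom{t.chrom}_sample_ids"] = t.sample_ids
        payload[f"chrom{t.chrom}_sample_years"] = t.sample_years
    np.savez_compressed(path, **payload)


def _load_tables(path: Path) -> tuple[dict[int, np.ndarray], list[VariantTable]]:
    data = np.load(path)
    checkpoints = {
        int(y): data[f"checkpoint_{int(y)}"] for y in data["checkpoint_years"]
    }
    chroms = sorted(
        int(k.removeprefix("chrom").removesuffix("_positions"))
        for k in data.files
        if k.endswith("_positions")
    )
    tables = []
    for ch in chroms:
        tables.append(
            VariantTable(
                chrom=ch,
                length_bp=int(data[f"chrom{ch}_length"][0]),
                positions=data[f"chrom{ch}_positions"],
                dosages=data[f"chrom{ch}_dosages"],
                sample_ids=data[f"chrom{ch}_sample_ids"],
                sample_years=data[f"chrom{ch}_sample_years"],
            )
        )
    return checkpoints, tables


# ---------------------------------------------------------------------------
# Inference stage
# ---------------------------------------------------------------------------

def infer_dataset(
    dataset: SimulatedDataset,
    entry: GridEntry,
    methods: tuple[str, ...],
    inference_config: dict | None = None,
) -> list[InferenceRecord]:
    cfg = inference_config or {}
    scenario = entry.scenario
    truth = {
        "scenario": scenario.label(),
        "true_ne_c": float(scenario.Ne_C),
        "true_ne_h": float(scenario.Ne_H),
        "declining_truth": scenario.trajectory.is_decline,
        "lambda_": scenario.trajectory.lambda_,
        "T_dec": scenario.trajectory.T_dec,
        "Ne_H": scenario.Ne_H,
        "gen_time": scenario.gen_time,
        "scheme": entry.scheme,
        "sample_size": entry.sample_size,
        "data_type": entry.data_type,
    }
    records = []
    rng = np.random.default_rng(derive_seed(entry.seed, "infer"))
    for method in methods:
        if method == "sfs":
            spectra = dataset.folded_spectra()
            fits = fit_all_models(
                spectra,
                gen_time=scenario.gen_time,
                mu=scenario.mutation_rate,
                n_starts=cfg.get("n_starts", 3),
                seed=derive_seed(entry.seed, "fit"),
                maxiter=cfg.get("maxiter", 150),
            )
            best = select_model(fits)
            records.append(
                InferenceRecord(
                    **truth,
                    method="sfs",
                    pathway="aic",
                    ne_c_hat=best.Ne_C_hat,
                    ne_h_hat=best.Ne_H_hat,
                    trend=classify_trend(best),
                )
            )
        elif method == "ld_point":
            ests = {}
            for year in (0, 120):
                g = dataset.genotypes(year)
                ests[year] = ld_ne_point(
                    g,
                    chrom=dataset.chrom,
                    maf=cfg.get("ld_point_maf", 0.05),
                )
            records.append(
                InferenceRecord(
                    **truth,
                    method="ld_point",
                    pathway="ci",
                    ne_c_hat=ests[0].point,
                    ne_h_hat=ests[120].point,
                    ne_c_ci=(ests[0].ci_low, ests[0].ci_high),
                    ne_h_ci=(ests[120].ci_low, ests[120].ci_high),
                    flags=[f for e in ests.values() for f in ([e.flag] if e.flag else [])],
                )
            )
        elif method == "ld_trajectory":
            g = dataset.genotypes(0)
            cols = np.flatnonzero(dataset.sample_years == 0)
            pairs = bin_pairs(
                g,
                dataset.positions,
                dataset.chrom,
                n_bins=cfg.get("n_bins", 400),
                hc=cfg.get("hc", 0.05),
                max_snps_per_chrom=cfg.get("max_snps_per_chrom", 50_000),
                rng=rng,
            )
            traj = ld_trajectory(
                pairs,
                resamples=cfg.get("resamples", 40),
                resample_size=cfg.get("resample_size", 50_000),
                rng=rng,
                gen_time=scenario.gen_time,
            )
            records.append(
                InferenceRecord(
                    **truth,
                    method="ld_trajectory",
                    pathway="ci",
                    ne_c_hat=traj.ne_c,
                    ne_h_hat=traj.ne_h,
                    ne_c_ci=traj.ne_c_ci,
                    ne_h_ci=traj.ne_h_ci,
                    flags=[traj.flag] if traj.flag else [],
                )
            )
        else:
            raise ValueError(f"unknown inference method {method!r}")
    return records


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(
    config: dict,
    outdir,
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> RunManifest:
    """Run the requested stages for every grid entry in the config.

    Simulations are cached per (scenario, replicate); datasets, inference
    records, and evaluation tables land under ``outdir``.
    """
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        manifest = RunManifest.load(manifest_path)
        if manifest.config_hash != config_hash(config):
            raise ValueError("outdir holds a run with a different config; use force")
    else:
        manifest = RunManifest(
            config_hash=config_hash(config),
            master_seed=config["master_seed"],
            version=__version__,
            stages_done=[],
            artifacts={},
        )

    sim_cfg = config.get("simulation", {})
    n_chrom = sim_cfg.get("n_chromosomes", 25)
    chrom_len = sim_cfg.get("chromosome_length", 30_000_000)
    n_record = sim_cfg.get("n_record", 200)
    entries = enumerate_study_grid(config)

    sims_dir = outdir / "sims"
    if "simulate" in stages:
        sims_dir.mkdir(exist_ok=True)
        for entry in entries:
            key = f"{entry.scenario.label()}_rep{entry.replicate}"
            path = sims_dir / f"{key}.npz"
            if path.exists() and not force:
                continue
            sim_seed = derive_seed(config["master_seed"], "sim", key)
            pedigree, tables = simulate_tables(
                entry.scenario, sim_seed, n_chrom, chrom_len, n_record
            )
            _save_tables(path, pedigree, tables)
            manifest.artifacts[key] = str(path)
        if "simulate" not in manifest.stages_done:
            manifest.stages_done.append("simulate")

    records: list[InferenceRecord] = []
    if {"datasets", "infer"} & set(stages):
        methods = tuple(config.get("inference", {}).get("methods", ("sfs",)))
        data_dir = outdir / "datasets"
        data_dir.mkdir(exist_ok=True)
        for entry in entries:
            key = f"{entry.scenario.label()}_rep{entry.replicate}"
            checkpoints, tables = _load_tables(sims_dir / f"{key}.npz")
            rng = np.random.default_rng(derive_seed(entry.seed, "dataset"))
            scheme = SamplingScheme(entry.scheme, entry.sample_size)
            spec = data_type_spec(entry.data_type, n_chrom, chrom_len)
            chosen = draw_samples(checkpoints, scheme, rng)
            dataset = assemble_dataset(
                tables, chosen, scheme, spec, rng,
                provenance={"entry": key, "seed": entry.seed},
            )
            maf = config.get("maf_filter")
            if maf:
                dataset = apply_maf_filter(dataset, maf)
            if "datasets" in stages and config.get("export_datasets", False):
                stem = data_dir / f"{key}_{entry.scheme}_n{entry.sample_size}_{entry.data_type}"
                write_vcf(dataset, stem.with_suffix(".vcf"))
                write_dataset_sfs(dataset, stem.with_suffix(".sfs.txt"))
            if "infer" in stages:
                records.extend(
                    infer_dataset(dataset, entry, methods, config.get("inference"))
                )
        for stage in ("datasets", "infer"):
            if stage in stages and stage not in manifest.stages_done:
                manifest.stages_done.append(stage)

    if "infer" in stages and records:
        import pandas as pd

        rows = [
            {
                "scenario": r.scenario,
                "method": r.method,
                "scheme": r.scheme,
                "sample_size": r.sample_size,
                "data_type": r.data_type,
                "ne_c_hat": r.ne_c_hat,
                "ne_h_hat": r.ne_h_hat,
                "trend": r.trend,
                "flags": ";".join(r.flags),
            }
            for r in records
        ]
        pd.DataFrame(rows).to_csv(outdir / "estimates.csv", index=False)
        manifest.artifacts["estimates"] = str(outdir / "estimates.csv")

    if "evaluate" in stages and records:
        report = aggregate_report(records)
        for name, table in report.items():
            path = outdir / f"report_{name}.csv"
            table.to_csv(path, index=False)
            manifest.artifacts[f"report_{name}"] = str(path)
        if "evaluate" not in manifest.stages_done:
            manifest.stages_done.append("evaluate")

    manifest.save(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# Tiny fixtures for tests
# ---------------------------------------------------------------------------

FIXTURE_PRESETS = {
    "constant_tiny": {"lambda": 1.0, "T_dec": None, "ancestral": "none"},
    "decline_tiny": {"lambda": 0.9, "T_dec": 20, "ancestral": "none"},
    "ancestral_tiny": {"lambda": 1.0, "T_dec": None, "ancestral": "bottleneck"},
}


def make_fixture(preset: str, outdir, seed: int = 0, n_samples: int = 20):
    """Miniature end-to-end dataset (2 x 2 Mb chromosomes, Ne = 200) on disk."""
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    p = FIXTURE_PRESETS[preset]
    scenario = DemographicScenario(
        life_history=life_history("G1"),
        trajectory=SizeTrajectory(Ne_H=200, lambda_=p["lambda"], T_dec=p["T_dec"]),
        ancestral=AncestralChange(kind=p["ancestral"]),
    )
    _, tables = simulate_tables(
        scenario, seed, n_chromosomes=2, chromosome_length=2_000_000, n_record=50
    )
    scheme = SamplingScheme("two_sample", n_samples)
    rng = np.random.default_rng(derive_seed(seed, "fixture"))
    checkpoints = {0: tables[0].sample_ids[tables[0].sample_years == 0],
                   120: tables[0].sample_ids[tables[0].sample_years == 120]}
    chosen = draw_samples(checkpoints, scheme, rng)
    dataset = assemble_dataset(
        tables, chosen, scheme,
        DataTypeSpec(kind="WGS", genome_length=4_000_000), rng,
        provenance={"preset": preset, "seed": seed},
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(dataset, outdir / f"{preset}.vcf")
    write_dataset_sfs(dataset, outdir / f"{preset}.sfs.txt")
    return dataset
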