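"""Orchestration of the 2 x 3 evolution experiment.

The design crosses two environmental patterns of interest (constant low
environment; spatial heterogeneity — constant high is available for
follow-up runs) with three signal treatments (no signal, environmental
signal, performance signal).  A plan enumerates every replicate with a
deterministically derived seed, runs are individually resumable, and the
output is a directory tree of plain TSV records plus experiment-level
summary tables.

Two scale presets are provided.  ``full`` is the full-scale configuration
(N = 10,000; 100,000 generations, half of the heterogeneous replicates
extended to 200,000; 200 replicates per cell; 50,000 redevelopments per
assay environment).  ``desk`` is a structurally identical reduction for a
single workstation (N = 100; 300 generations; 500 redevelopments) whose
per-replication mutation rates are scaled up by the same factor the
population size is scaled down (100x), keeping the population-wide
mutational input per generation at the full-scale value.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assay import summarize_experiment
from .evolution import (
    ENVIRONMENT_MODELS,
    EvolutionConfig,
    SimulationRecord,
    run_simulation,
)
from .genome import MutationRates, TREATMENTS, genotype_to_json
from .fixtures import FIXTURE_NAMES, make_fixture  # noqa: F401 — re-exported surface

RECORD_SCHEMA = "plastisim-record-1"

_PRESETS = {
    "full": dict(
        N=10_000,
        generations=100_000,
        replicates=200,
        n_found=1_000,
        n_redevelop=50_000,
        mutation_scale=1.0,
        extend_heterogeneous=True,
    ),
    "desk": dict(
        N=100,
        generations=300,
        replicates=2,
        n_found=200,
        n_redevelop=500,
        mutation_scale=100.0,
        extend_heterogeneous=False,
    ),
}

_PLAN_KEYS = {
    "scale", "treatments", "environments", "replicates", "master_seed",
    "N", "generations", "n_found", "n_redevelop", "delta_P",
    "mutation_scale", "omega",
}


@dataclass(frozen=True)
class ReplicateSpec:
    treatment: str
    environment_model: str
    index: int
    seed: int
    generations: int

    def relpath(self) -> Path:
        return Path(self.treatment) / self.environment_model / f"rep{self.index:04d}"


@dataclass(frozen=True)
class ExperimentPlan:
    scale: str
    master_seed: int
    replicates_per_cell: int
    base_config: dict
    replicates: tuple[ReplicateSpec, ...] = field(default_factory=tuple)

    def plan_hash(self) -> str:
        payload = json.dumps(
            {
                "scale": self.scale,
                "master_seed": self.master_seed,
                "base_config": self.base_config,
                "replicates": [
                    [r.treatment, r.environment_model, r.index, r.seed, r.generations]
                    for r in self.replicates
                ],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def config_for(self, rep: ReplicateSpec) -> EvolutionConfig:
        b = self.base_config
        rates = MutationRates().scaled(b["mutation_scale"])
        return EvolutionConfig(
            N=b["N"],
            generations=rep.generations,
            omega=b["omega"],
            environment_model=rep.environment_model,
            treatment=rep.treatment,
            mutation_rates=rates,
            n_found=b["n_found"],
            assay_n_redevelop=b["n_redevelop"],
            delta_P=b["delta_P"],
        )


def build_plan(config: "dict | str | Path") -> ExperimentPlan:
    """Build a fully enumerated experiment plan from a YAML file or dict.

    Unknown keys and out-of-range values raise a ``ValueError`` naming the
    offending key.  Replicate seeds derive deterministically from the
    master seed, so the same configuration always yields the same plan.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - _PLAN_KEYS
    if unknown:
        raise ValueError(f"unknown plan key(s): {sorted(unknown)}")
    scale = config.get("scale", "desk")
    if scale not in _PRESETS:
        raise ValueError(f"scale: expected one of {sorted(_PRESETS)}, got {scale!r}")
    preset = dict(_PRESETS[scale])

    treatments = tuple(config.get("treatments", TREATMENTS))
    for t in treatments:
        if t not in TREATMENTS:
            raise ValueError(f"treatments: unknown treatment {t!r}")
    environments = tuple(
        config.get("environments", ("constant_low", "spatial_heterogeneity"))
    )
    for e in environments:
        if e not in ENVIRONMENT_MODELS:
            raise ValueError(f"environments: unknown environment model {e!r}")

    def _pos_int(key, value):
        if not isinstance(value, int) or value <= 0:
            raise ValueError(f"{key}: expected a positive integer, got {value!r}")
        return value

    replicates = _pos_int("replicates", config.get("replicates", preset["replicates"]))
    master_seed = config.get("master_seed", 0)
    if not isinstance(master_seed, int) or master_seed < 0:
        raise ValueError(f"master_seed: expected a non-negative integer, got {master_seed!r}")

    base = {
        "N": _pos_int("N", config.get("N", preset["N"])),
        "generations": _pos_int("generations", config.get("generations", preset["generations"])),
        "n_found": _pos_int("n_found", config.get("n_found", preset["n_found"])),
        "n_redevelop": _pos_int("n_redevelop", config.get("n_redevelop", preset["n_redevelop"])),
        "delta_P": float(config.get("delta_P", 400.0)),
        "mutation_scale": float(config.get("mutation_scale", preset["mutation_scale"])),
        "omega": float(config.get("omega", 5e-5)),
    }
    if base["delta_P"] <= 0:
        raise ValueError(f"delta_P: must be > 0, got {base['delta_P']}")
    if base["omega"] <= 0:
        raise ValueError(f"omega: must be > 0, got {base['omega']}")

    ss = np.random.SeedSequence(master_seed)
    extend_rng = np.random.default_rng(ss.spawn(1)[0])
    reps: list[ReplicateSpec] = []
    for treatment in treatments:
        for envm in environments:
            cell_gens = np.full(replicates, base["generations"], dtype=np.int64)
            if preset["extend_heterogeneous"] and envm == "spatial_heterogeneity":
                # half of the cell's replicates, chosen from the plan seed,
                # run for twice as many generations
                chosen = extend_rng.choice(replicates, size=replicates // 2, replace=False)
                cell_gens[chosen] = 2 * base["generations"]
            for i in range(replicates):
                seed = int(
                    np.random.SeedSequence(
                        [master_seed, TREATMENTS.index(treatment),
                         ENVIRONMENT_MODELS.index(envm), i]
                    ).generate_state(1)[0] % (2**31 - 1)
                )
                reps.append(
                    ReplicateSpec(
                        treatment=treatment,
                        environment_model=envm,
                        index=i,
                        seed=seed,
                        generations=int(cell_gens[i]),
                    )
                )
    return ExperimentPlan(
        scale=scale,
        master_seed=master_seed,
        replicates_per_cell=replicates,
        base_config=base,
        replicates=tuple(reps),
    )


# ---------------------------------------------------------------------------
# record I/O (plain TSV with a header-comment block)

def write_record(rec: SimulationRecord, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gdir = outdir / "genotypes"
    gdir.mkdir(exist_ok=True)
    (gdir / "founder.json").write_text(genotype_to_json(rec.founder) + "\n")
    (gdir / "final.json").write_text(genotype_to_json(rec.final) + "\n")

    meta = {
        "schema": RECORD_SCHEMA,
        "config_hash": rec.config_hash,
        "seed": rec.seed,
        "treatment": rec.treatment,
        "environment_model": rec.environment_model,
        "founder_mean_fitness": rec.founder_mean_fitness,
        "founder_mean_low": rec.founder_mean_low,
        "founder_mean_high": rec.founder_mean_high,
        "founder_plastic": rec.founder_plastic,
        "final_mean_low": rec.final_mean_low,
        "final_mean_high": rec.final_mean_high,
        "final_plastic": rec.final_plastic,
        "final_noise": rec.final_noise,
        "final_frequency": rec.final_frequency,
        "gene_counts": rec.gene_counts,
    }
    lines = [f"# {k}\t{json.dumps(v)}" for k, v in meta.items()]
    lines.append("generation\tfrequency\tmean_fitness\tmean_phenotype\tgenotype_key_sha1")
    for s in rec.samples:
        key_digest = hashlib.sha1(s.genotype_key.encode()).hexdigest()[:12]
        (gdir / f"gen{s.generation:07d}.json").write_text(s.genotype_json + "\n")
        lines.append(
            f"{s.generation}\t{s.frequency:.6g}\t{s.mean_fitness:.6g}"
            f"\t{s.mean_phenotype:.6g}\t{key_digest}"
        )
    tmp = outdir / "record.tsv.tmp"
    tmp.write_text("\n".join(lines) + "\n")
    tmp.rename(outdir / "record.tsv")  # atomic: partial results never left behind


@dataclass
class RecordView:
    """Replicate-level metadata reloaded from a record.tsv header; quacks
    like a SimulationRecord for summarize_experiment."""

    seed: int
    config_hash: str
    treatment: str
    environment_model: str
    founder_mean_fitness: float
    founder_plastic: bool
    final_plastic: bool
    final_noise: float
    final_mean_low: float
    final_mean_high: float
    gene_counts: dict


def read_record(path: "Path | str") -> RecordView:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            key, _, raw = line[2:].rstrip("\n").partition("\t")
            meta[key] = json.loads(raw)
    if meta.get("schema") != RECORD_SCHEMA:
        raise ValueError(f"{path}: unsupported record schema {meta.get('schema')!r}")
    return RecordView(
        seed=meta["seed"],
        config_hash=meta["config_hash"],
        treatment=meta["treatment"],
        environment_model=meta["environment_model"],
        founder_mean_fitness=meta["founder_mean_fitness"],
        founder_plastic=meta["founder_plastic"],
        final_plastic=meta["final_plastic"],
        final_noise=meta["final_noise"],
        final_mean_low=meta["final_mean_low"],
        final_mean_high=meta["final_mean_high"],
        gene_counts=meta["gene_counts"],
    )


def collect_records(root: "Path | str") -> list[RecordView]:
    return [read_record(p) for p in sorted(Path(root).rglob("record.tsv"))]


def write_summary(
    records, outdir: "Path | str", expected_cells=None
) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = summarize_experiment(records, expected_cells=expected_cells)
    tables["summary"].to_csv(outdir / "summary.tsv", sep="\t", index=False)
    tests = pd.concat(
        [
            tables["welch"].assign(test="welch_noise"),
            tables["fisher"].assign(test="fisher_plasticity"),
        ],
        ignore_index=True,
    )
    tests.to_csv(outdir / "tests.tsv", sep="\t", index=False)
    return tables


def run_replicate(plan: ExperimentPlan, rep: ReplicateSpec, out_root: "Path | str") -> RecordView:
    """Run (or reload, if already complete) one replicate."""
    outdir = Path(out_root) / rep.relpath()
    record_path = outdir / "record.tsv"
    if record_path.exists():
        return read_record(record_path)
    config = plan.config_for(rep)
    rec = run_simulation(config, rep.seed)
    write_record(rec, outdir)
    return read_record(record_path)


def run_plan(
    plan: ExperimentPlan,
    out_root: "Path | str",
    parallelism: int = 1,
) -> dict[str, pd.DataFrame]:
    """Execute every replicate of a plan, resuming completed ones, then
    write summary.tsv and tests.tsv at the output root.

    Per-replicate failures are logged to ``failures.log`` and quarantined
    without aborting the rest of the plan.
    """
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    (out_root / "plan.json").write_text(
        json.dumps(
            {
                "plan_hash": plan.plan_hash(),
                "scale": plan.scale,
                "master_seed": plan.master_seed,
                "base_config": plan.base_config,
                "n_replicates": len(plan.replicates),
            },
            indent=2,
        )
        + "\n"
    )
    records: list[RecordView] = []
    failures: list[str] = []

    if parallelism > 1:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=parallelism) as ex:
            futs = {ex.submit(run_replicate, plan, rep, out_root): rep for rep in plan.replicates}
            for fut, rep in futs.items():
                try:
                    records.append(fut.result())
                except Exception as exc:  # noqa: BLE001 — quarantine, keep going
                    failures.append(f"{rep.relpath()}\t{exc!r}")
    else:
        for rep in plan.replicates:
            try:
                records.append(run_replicate(plan, rep, out_root))
            except Exception as exc:  # noqa: BLE001
                failures.append(f"{rep.relpath()}\t{exc!r}")

    if failures:
        (out_root / "failures.log").write_text("\n".join(failures) + "\n")
    cells = sorted({(r.treatment, r.environment_model) for r in plan.replicates})
    return write_summary(records, out_root, expected_cells=cells)
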