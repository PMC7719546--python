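"""Wright–Fisher evolution of a developing population.

Haploid individuals in a constant-size population reproduce clonally with
nonoverlapping generations: parents are drawn by fitness-proportional
multinomial sampling, and each offspring genome passes once through the
mutation model.  Fitness is Gaussian stabilizing selection on the phenotype
realized at the end of one stochastic development,
``w = exp(-omega * (P - Pe)^2)``, so developmental noise is directly costly.

Environments supply the optimum Pe: constant-low (1000), constant-high
(3000), or spatial heterogeneity, where every individual is assigned
independently and uniformly to one of the two environments each generation
(migration rate 0.5 between patches).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import (
    FounderDistributions,
    Genotype,
    MutationRates,
    TREATMENTS,
    genotype_key,
    genotype_to_json,
    mutate_genome,
    random_genotype,
)
from .development import RegulationParams, SignalSpec, develop_batch

ENVIRONMENT_MODELS = ("constant_low", "constant_high", "spatial_heterogeneity")

_TREATMENT_MODE = {
    "no_signal": "none",
    "environmental_signal": "environmental",
    "performance_signal": "performance",
}


def treatment_signal_mode(treatment: str) -> str:
    """Signal mode supplied during development under a treatment."""
    return _TREATMENT_MODE[treatment]


class ExtinctionError(RuntimeError):
    """Raised when every individual has fitness zero."""


class FounderSearchError(RuntimeError):
    """Raised when no founder meets the fitness window within the attempt cap."""


@dataclass(frozen=True)
class EnvironmentModel:
    """Environment assignment rule with the two optima."""

    name: str = "constant_low"
    Pe_low: float = 1000.0
    Pe_high: float = 3000.0

    def __post_init__(self) -> None:
        if self.name not in ENVIRONMENT_MODELS:
            raise ValueError(f"unknown environment model {self.name!r}")


def fitness(P, Pe: float, omega: float):
    """Gaussian stabilizing selection: w = exp(-omega (P - Pe)^2)."""
    if omega <= 0:
        raise ValueError("omega must be > 0")
    P = np.asarray(P, dtype=np.float64)
    w = np.exp(-omega * (P - Pe) ** 2)
    return float(w) if w.ndim == 0 else w


def assign_environments(N: int, model: EnvironmentModel, rng: np.random.Generator) -> np.ndarray:
    """Per-individual optimum Pe for one generation."""
    if model.name == "constant_low":
        return np.full(N, model.Pe_low)
    if model.name == "constant_high":
        return np.full(N, model.Pe_high)
    high = rng.random(N) < 0.5
    return np.where(high, model.Pe_high, model.Pe_low)


def _recombine(a: Genotype, b: Genotype, rng: np.random.Generator) -> Genotype:
    """Free recombination between two parents: each lineage (homology group
    identified by lineage_id) is inherited intact from one parent chosen by
    a fair coin flip; gene order follows the donating parents."""
    lineages = {g.lineage_id for g in a.genes} | {g.lineage_id for g in b.genes}
    take_a = {lid for lid in lineages if rng.random() < 0.5}
    genes = [g for g in a.genes if g.lineage_id in take_a]
    genes += [g for g in b.genes if g.lineage_id not in take_a]
    return Genotype(genes=tuple(genes))


def next_generation(
    pop: list[Genotype],
    fitnesses: np.ndarray,
    rates: MutationRates,
    rng: np.random.Generator,
    recombination: bool = False,
) -> list[Genotype]:
    """One Wright–Fisher step: fitness-proportional parentage, then one
    replication's worth of mutation per offspring.

    Default reproduction is clonal.  With ``recombination=True`` each
    offspring draws two parents and inherits each homologous lineage from
    one of them at random (free recombination)."""
    N = len(pop)
    w = np.asarray(fitnesses, dtype=np.float64)
    if w.shape != (N,):
        raise ValueError("fitnesses must have one entry per individual")
    total = w.sum()
    if total <= 0:
        raise ExtinctionError("all individuals have zero fitness")
    p = w / total
    if recombination:
        pa = rng.choice(N, size=N, p=p)
        pb = rng.choice(N, size=N, p=p)
        offspring = [
            _recombine(pop[i], pop[j], rng) if pop[i] is not pop[j] else pop[i]
            for i, j in zip(pa, pb)
        ]
    else:
        parents = rng.choice(N, size=N, p=p)
        offspring = [pop[i] for i in parents]
    return [mutate_genome(g, rates, rng) for g in offspring]


@dataclass(frozen=True)
class EvolutionConfig:
    N: int = 10_000
    generations: int = 100_000
    omega: float = 5e-5
    environment_model: str = "constant_low"
    treatment: str = "no_signal"
    sampling_schedule: tuple[int, ...] = ()
    mutation_rates: MutationRates = field(default_factory=MutationRates)
    regulation: RegulationParams = field(default_factory=RegulationParams)
    founder_dist: FounderDistributions = field(default_factory=FounderDistributions)
    founder_fitness_window: tuple[float, float] = (0.15, 0.25)
    n_found: int = 1_000           # developments in the founder fitness assay
    n_prescreen: int = 40          # cheap pre-assay developments per candidate
    prescreen_margin: float = 0.09 # widened window for the pre-assay
    founder_attempt_cap: int = 100_000
    assay_n_redevelop: int = 500   # redevelopments per environment for plasticity calls
    delta_P: float = 400.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.environment_model not in ENVIRONMENT_MODELS:
            raise ValueError(f"unknown environment model {self.environment_model!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def environment(self) -> EnvironmentModel:
        return EnvironmentModel(name=self.environment_model)

    @property
    def signal_mode(self) -> str:
        return treatment_signal_mode(self.treatment)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class GenerationSample:
    generation: int
    genotype_key: str
    genotype_json: str
    frequency: float
    mean_fitness: float
    mean_phenotype: float


@dataclass
class SimulationRecord:
    """Outcome of one evolutionary replicate."""

    seed: int
    config_hash: str
    treatment: str
    environment_model: str
    founder: Genotype
    founder_mean_fitness: float
    final: Genotype
    final_frequency: float
    samples: list[GenerationSample]
    # plasticity / noise assays (filled by run_simulation)
    founder_mean_low: float = float("nan")
    founder_mean_high: float = float("nan")
    founder_plastic: bool = False
    final_mean_low: float = float("nan")
    final_mean_high: float = float("nan")
    final_plastic: bool = False
    final_noise: float = float("nan")
    gene_counts: dict = field(default_factory=dict)


def mean_fitness_assay(
    g: Genotype,
    config: EvolutionConfig,
    rng: np.random.Generator,
    n: int | None = None,
) -> float:
    """Mean over n developments of per-development fitness, in the low
    environment, under the treatment's own signal mode."""
    n = n or config.n_found
    Pe = config.environment.Pe_low
    P = develop_batch(g, config.signal_mode, Pe, n, config.regulation, rng)
    return float(np.mean(fitness(P, Pe, config.omega)))


def found_population(
    config: EvolutionConfig, rng: np.random.Generator
) -> tuple[Genotype, float, list[Genotype]]:
    """Rejection-sample random genotypes until one has assayed mean fitness
    inside the founder window, assayed in the low environment; return the
    founder, its assayed mean fitness, and N clones.

    A cheap pre-assay with a widened window filters obvious rejects before
    paying for the full founder assay.
    """
    lo, hi = config.founder_fitness_window
    pre_lo = max(0.0, lo - config.prescreen_margin)
    pre_hi = min(1.0, hi + config.prescreen_margin)
    for _ in range(config.founder_attempt_cap):
        g = random_genotype(config.treatment, rng, config.founder_dist)
        quick = mean_fitness_assay(g, config, rng, n=config.n_prescreen)
        if not pre_lo < quick < pre_hi:
            continue
        full = mean_fitness_assay(g, config, rng, n=config.n_found)
        if lo < full < hi:
            return g, full, [g] * config.N
    raise FounderSearchError(
        f"no founder with mean fitness in ({lo}, {hi}) found within "
        f"{config.founder_attempt_cap} candidates"
    )


def develop_population(
    pop: list[Genotype],
    Pe_arr: np.ndarray,
    mode: str,
    params: RegulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Develop every individual once; returns realized final phenotypes.

    Individuals sharing a genotype are batched through the kernel."""
    N = len(pop)
    seeds = rng.integers(0, 2**31 - 1, size=N, dtype=np.int64)
    phen = np.empty(N, dtype=np.float64)
    # clones share the same immutable object (copy-on-write mutation), so
    # identity grouping batches the kernel without hashing genotype contents
    groups: dict[int, list[int]] = {}
    by_id: dict[int, Genotype] = {}
    for i, g in enumerate(pop):
        k = id(g)
        groups.setdefault(k, []).append(i)
        by_id[k] = g
    for k, idx in groups.items():
        idx = np.asarray(idx)
        phen[idx] = develop_batch(
            by_id[k], mode, Pe_arr[idx], params=params, seeds=seeds[idx]
        )
    return phen


def most_common_genotype(pop: list[Genotype]) -> tuple[Genotype, float]:
    """Modal genotype and its frequency; ties broken by first occurrence."""
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for i, g in enumerate(pop):
        k = genotype_key(g)
        if k not in counts:
            counts[k] = 0
            first[k] = i
        counts[k] += 1
    best = max(counts, key=lambda k: (counts[k], -first[k]))
    return pop[first[best]], counts[best] / len(pop)


def run_simulation(config: EvolutionConfig, seed: int) -> SimulationRecord:
    """Run one replicate: found, evolve, and assay the founder and the final
    most common genotype.  Deterministic given (config, seed)."""
    from . import assay as assay_mod  # deferred: assay depends only on development

    ss = np.random.SeedSequence(seed)
    rng_found, rng_env, rng_dev, rng_repro, rng_assay = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    founder, founder_fit, pop = found_population(config, rng_found)
    env = config.environment
    mode = config.signal_mode
    samples: list[GenerationSample] = []
    schedule = set(config.sampling_schedule)

    def take_sample(gen: int, pop: list[Genotype], w: np.ndarray, phen: np.ndarray) -> None:
        top, freq = most_common_genotype(pop)
        samples.append(
            GenerationSample(
                generation=gen,
                genotype_key=genotype_key(top),
                genotype_json=genotype_to_json(top, indent=None),
                frequency=freq,
                mean_fitness=float(np.mean(w)),
                mean_phenotype=float(np.mean(phen)),
            )
        )

    for gen in range(config.generations):
        Pe_arr = assign_environments(config.N, env, rng_env)
        phen = develop_population(pop, Pe_arr, mode, config.regulation, rng_dev)
        w = np.exp(-config.omega * (phen - Pe_arr) ** 2)
        if gen in schedule:
            take_sample(gen, pop, w, phen)
        pop = next_generation(pop, w, config.mutation_rates, rng_repro)

    # final census (development only for reporting means)
    Pe_arr = assign_environments(config.N, env, rng_env)
    phen = develop_population(pop, Pe_arr, mode, config.regulation, rng_dev)
    w = np.exp(-config.omega * (phen - Pe_arr) ** 2)
    take_sample(config.generations, pop, w, phen)
    final, freq = most_common_genotype(pop)

    acfg = assay_mod.AssayConfig(
        n_redevelop=config.assay_n_redevelop,
        delta_P=config.delta_P,
        Pe_low=env.Pe_low,
        Pe_high=env.Pe_high,
    )
    f_res = assay_mod.assay_genotype(founder, config.treatment, acfg, config.regulation, rng_assay)
    e_res = assay_mod.assay_genotype(final, config.treatment, acfg, config.regulation, rng_assay)

    return SimulationRecord(
        seed=seed,
        config_hash=config.config_hash(),
        treatment=config.treatment,
        environment_model=config.environment_model,
        founder=founder,
        founder_mean_fitness=founder_fit,
        final=final,
        final_frequency=freq,
        samples=samples,
        founder_mean_low=f_res.mean_low,
        founder_mean_high=f_res.mean_high,
        founder_plastic=f_res.is_plastic,
        final_mean_low=e_res.mean_low,
        final_mean_high=e_res.mean_high,
        final_plastic=e_res.is_plastic,
        final_noise=e_res.sd_low,
        gene_counts=final.gene_counts(),
    )
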