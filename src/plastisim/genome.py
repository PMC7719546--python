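"""Genotype representation and the six-type mutation model.

A genotype is an ordered list of genes of three kinds: *regulatory* genes
(transcription factors that only regulate), *phenotype* genes (transcription
factors that additionally catalyse growth of the measured trait), and
*signal-binding* genes (whose protein forms a heterodimer with the signal
molecule; the heterodimer acts as a transcription factor).  Each gene carries
a cis-regulatory region of exactly ``N_SITES`` binding sites and a coding
region.  Gene kind is immutable: mutation can duplicate, delete, or perturb
regulatory parameters, but never convert one kind into another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

N_MOTIFS = 20
N_SITES = 20

KIND_REGULATORY = "regulatory"
KIND_PHENOTYPE = "phenotype"
KIND_SIGNAL = "signal_binding"
GENE_KINDS = (KIND_REGULATORY, KIND_PHENOTYPE, KIND_SIGNAL)

TREATMENT_NONE = "no_signal"
TREATMENT_ENV = "environmental_signal"
TREATMENT_PERF = "performance_signal"
TREATMENTS = (TREATMENT_NONE, TREATMENT_ENV, TREATMENT_PERF)

SCHEMA_VERSION = "plastisim-genotype-1"


@dataclass(frozen=True)
class BindingSite:
    """One cis-regulatory binding site.

    ``motif_id`` selects which of the ``N_MOTIFS`` binding motifs this site
    displays; ``cis_effect`` is its signed regulatory weight; and
    ``affinity_mismatch`` is the implicit number of amino-acid mismatches
    between the site and a perfectly matching binding domain (0 = perfect
    affinity, larger = weaker binding).
    """

    motif_id: int
    cis_effect: float
    affinity_mismatch: int

    def __post_init__(self) -> None:
        if not 0 <= self.motif_id < N_MOTIFS:
            raise ValueError(f"motif_id {self.motif_id} outside [0, {N_MOTIFS - 1}]")
        if self.affinity_mismatch < 0:
            raise ValueError("affinity_mismatch must be >= 0")


@dataclass(frozen=True)
class CodingRegion:
    """Coding region of a gene.

    ``inherent_effect`` is the protein's regulatory effect (activator if
    positive, repressor if negative) and ``target_motif`` the single binding
    motif it recognises.  ``phenotype_effect`` (phenotype genes only) is the
    per-protein catalysis weight on trait growth; ``hill_n`` (signal-binding
    genes only) is the Hill cooperativity coefficient of signal binding.
    """

    inherent_effect: float
    target_motif: int
    phenotype_effect: float | None = None
    hill_n: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.target_motif < N_MOTIFS:
            raise ValueError(f"target_motif {self.target_motif} outside [0, {N_MOTIFS - 1}]")
        if self.phenotype_effect is not None and self.phenotype_effect <= 0:
            raise ValueError("phenotype_effect must be > 0 when present")
        if self.hill_n is not None and not 1.0 <= self.hill_n <= 5.0:
            raise ValueError("hill_n must lie in [1.0, 5.0]")


@dataclass(frozen=True)
class Gene:
    kind: str
    cis_sites: tuple[BindingSite, ...]
    coding: CodingRegion
    lineage_id: int = 0

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if len(self.cis_sites) != N_SITES:
            raise ValueError(f"gene must carry exactly {N_SITES} cis sites")
        if self.kind == KIND_PHENOTYPE and self.coding.phenotype_effect is None:
            raise ValueError("phenotype gene requires a phenotype_effect")
        if self.kind == KIND_SIGNAL and self.coding.hill_n is None:
            raise ValueError("signal-binding gene requires a hill_n")


@dataclass(frozen=True)
class Genotype:
    """Ordered, immutable collection of genes.

    Order matters for identity (two genotypes with permuted genes are
    distinct) but not for regulation, which is order-free.
    """

    genes: tuple[Gene, ...] = ()

    def count_kind(self, kind: str) -> int:
        return sum(1 for g in self.genes if g.kind == kind)

    def gene_counts(self) -> dict[str, int]:
        return {k: self.count_kind(k) for k in GENE_KINDS}

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MutationRates:
    """Per-replication mutation rates and effect-size kernels.

    Duplication is per genome; all other rates are per gene.  The four
    regulatory-effect channels perturb, respectively, the coding region's
    inherent effect, one site's affinity mismatch (a reflecting ±1 step on
    [0, max_mismatch]), the coding region's target motif (resampled among the
    other motifs), and one site's cis effect.  Additive kernels are Gaussian
    with the given standard deviations.
    """

    duplication_per_genome: float = 1e-8
    deletion_per_gene: float = 1e-7
    inherent_effect_per_gene: float = 1e-5
    affinity_per_gene: float = 1e-5
    target_motif_per_gene: float = 1e-5
    cis_effect_per_gene: float = 1e-5
    inherent_effect_sd: float = 0.1
    cis_effect_sd: float = 0.1
    max_mismatch: int = 10

    def __post_init__(self) -> None:
        for name in (
            "duplication_per_genome",
            "deletion_per_gene",
            "inherent_effect_per_gene",
            "affinity_per_gene",
            "target_motif_per_gene",
            "cis_effect_per_gene",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, factor: float) -> "MutationRates":
        """All six rates multiplied by ``factor`` (kernels unchanged)."""
        return replace(
            self,
            duplication_per_genome=self.duplication_per_genome * factor,
            deletion_per_gene=self.deletion_per_gene * factor,
            inherent_effect_per_gene=self.inherent_effect_per_gene * factor,
            affinity_per_gene=self.affinity_per_gene * factor,
            target_motif_per_gene=self.target_motif_per_gene * factor,
            cis_effect_per_gene=self.cis_effect_per_gene * factor,
        )


@dataclass(frozen=True)
class FounderDistributions:
    """Distributions used to draw founder genes.

    cis and inherent effects are standard Gaussian, affinity mismatches
    uniform on {0..affinity_max}, phenotype effects folded Gaussian
    |N(mean, sd)|, and Hill coefficients uniform on [1, 5].
    """

    cis_effect_sd: float = 1.0
    inherent_effect_sd: float = 1.0
    affinity_max: int = 5
    phenotype_effect_mean: float = 1.0
    phenotype_effect_sd: float = 0.3
    hill_n_low: float = 1.0
    hill_n_high: float = 5.0
    n_regulatory: int = 3
    n_phenotype: int = 3
    n_signal: int = 3


def _random_gene(
    kind: str, lineage_id: int, dist: FounderDistributions, rng: np.random.Generator
) -> Gene:
    sites = tuple(
        BindingSite(
            motif_id=int(rng.integers(N_MOTIFS)),
            cis_effect=float(rng.normal(0.0, dist.cis_effect_sd)),
            affinity_mismatch=int(rng.integers(dist.affinity_max + 1)),
        )
        for _ in range(N_SITES)
    )
    phenotype_effect = None
    hill_n = None
    if kind == KIND_PHENOTYPE:
        phenotype_effect = abs(float(rng.normal(dist.phenotype_effect_mean, dist.phenotype_effect_sd)))
        phenotype_effect = max(phenotype_effect, 1e-12)
    elif kind == KIND_SIGNAL:
        hill_n = float(rng.uniform(dist.hill_n_low, dist.hill_n_high))
    coding = CodingRegion(
        inherent_effect=float(rng.normal(0.0, dist.inherent_effect_sd)),
        target_motif=int(rng.integers(N_MOTIFS)),
        phenotype_effect=phenotype_effect,
        hill_n=hill_n,
    )
    return Gene(kind=kind, cis_sites=sites, coding=coding, lineage_id=lineage_id)


def random_genotype(
    treatment: str,
    rng: np.random.Generator,
    dist: FounderDistributions | None = None,
) -> Genotype:
    """Draw a random founder genotype for one treatment.

    All treatments start with 3 regulatory and 3 phenotype genes; the two
    signal treatments add 3 signal-binding genes whose Hill coefficients are
    drawn uniformly on [1, 5].
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    dist = dist or FounderDistributions()
    genes: list[Gene] = []
    lineage = 0
    for _ in range(dist.n_regulatory):
        genes.append(_random_gene(KIND_REGULATORY, lineage, dist, rng))
        lineage += 1
    for _ in range(dist.n_phenotype):
        genes.append(_random_gene(KIND_PHENOTYPE, lineage, dist, rng))
        lineage += 1
    if treatment != TREATMENT_NONE:
        for _ in range(dist.n_signal):
            genes.append(_random_gene(KIND_SIGNAL, lineage, dist, rng))
            lineage += 1
    return Genotype(genes=tuple(genes))


def _mutate_inherent(gene: Gene, rates: MutationRates, rng: np.random.Generator) -> Gene:
    coding = replace(
        gene.coding,
        inherent_effect=gene.coding.inherent_effect + float(rng.normal(0.0, rates.inherent_effect_sd)),
    )
    return replace(gene, coding=coding)


def _mutate_affinity(gene: Gene, rates: MutationRates, rng: np.random.Generator) -> Gene:
    i = int(rng.integers(N_SITES))
    site = gene.cis_sites[i]
    step = 1 if rng.random() < 0.5 else -1
    m = site.affinity_mismatch + step
    if m < 0:  # reflect at the boundaries
        m = 1
    elif m > rates.max_mismatch:
        m = rates.max_mismatch - 1
    sites = gene.cis_sites[:i] + (replace(site, affinity_mismatch=m),) + gene.cis_sites[i + 1 :]
    return replace(gene, cis_sites=sites)


def _mutate_target_motif(gene: Gene, rates: MutationRates, rng: np.random.Generator) -> Gene:
    new = int(rng.integers(N_MOTIFS - 1))
    if new >= gene.coding.target_motif:
        new += 1
    return replace(gene, coding=replace(gene.coding, target_motif=new))


def _mutate_cis(gene: Gene, rates: MutationRates, rng: np.random.Generator) -> Gene:
    i = int(rng.integers(N_SITES))
    site = gene.cis_sites[i]
    sites = (
        gene.cis_sites[:i]
        + (replace(site, cis_effect=site.cis_effect + float(rng.normal(0.0, rates.cis_effect_sd))),)
        + gene.cis_sites[i + 1 :]
    )
    return replace(gene, cis_sites=sites)


_EFFECT_CHANNELS = (
    ("inherent_effect_per_gene", _mutate_inherent),
    ("affinity_per_gene", _mutate_affinity),
    ("target_motif_per_gene", _mutate_target_motif),
    ("cis_effect_per_gene", _mutate_cis),
)


def mutate_genome(g: Genotype, rates: MutationRates, rng: np.random.Generator) -> Genotype:
    """Apply one replication's worth of mutation to a genotype.

    Event counts follow the configured per-replication rates: duplications
    Poisson per genome, every other channel Bernoulli per gene.  When no
    event occurs (the overwhelmingly common case at realistic rates) the
    input genotype object is returned unchanged — genotypes are immutable,
    so sharing is safe.  Effect mutations are applied first, then
    duplications (copying the already-mutated gene, same lineage_id,
    appended at the genome end), then deletions.
    """
    n = len(g.genes)
    n_dup = int(rng.poisson(rates.duplication_per_genome))
    if n == 0:
        return g

    events: list[tuple[int, object]] = []  # (gene index, mutator)
    for rate_name, mutator in _EFFECT_CHANNELS:
        rate = getattr(rates, rate_name)
        if rate <= 0:
            continue
        k = int(rng.binomial(n, rate))
        for idx in rng.integers(0, n, size=k):
            events.append((int(idx), mutator))

    n_del = int(rng.binomial(n, rates.deletion_per_gene)) if rates.deletion_per_gene > 0 else 0

    if not events and n_dup == 0 and n_del == 0:
        return g

    genes = list(g.genes)
    for idx, mutator in events:
        genes[idx] = mutator(genes[idx], rates, rng)
    for _ in range(n_dup):
        src = int(rng.integers(len(genes)))
        genes.append(genes[src])
    if n_del > 0:
        n_del = min(n_del, len(genes))
        doomed = set(int(i) for i in rng.choice(len(genes), size=n_del, replace=False))
        genes = [gene for i, gene in enumerate(genes) if i not in doomed]
    return Genotype(genes=tuple(genes))


# ---------------------------------------------------------------------------
# serialization

def _site_to_dict(s: BindingSite) -> dict:
    return {"motif_id": s.motif_id, "cis_effect": s.cis_effect, "affinity_mismatch": s.affinity_mismatch}


def _gene_to_dict(g: Gene) -> dict:
    c = g.coding
    coding: dict = {"inherent_effect": c.inherent_effect, "target_motif": c.target_motif}
    if c.phenotype_effect is not None:
        coding["phenotype_effect"] = c.phenotype_effect
    if c.hill_n is not None:
        coding["hill_n"] = c.hill_n
    return {
        "kind": g.kind,
        "lineage_id": g.lineage_id,
        "cis_sites": [_site_to_dict(s) for s in g.cis_sites],
        "coding": coding,
    }


def genotype_to_dict(g: Genotype) -> dict:
    return {"version": SCHEMA_VERSION, "genes": [_gene_to_dict(gene) for gene in g.genes]}


def genotype_from_dict(d: dict) -> Genotype:
    if d.get("version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported genotype schema {d.get('version')!r}")
    genes = []
    for gd in d["genes"]:
        sites = tuple(
            BindingSite(
                motif_id=int(s["motif_id"]),
                cis_effect=float(s["cis_effect"]),
                affinity_mismatch=int(s["affinity_mismatch"]),
            )
            for s in gd["cis_sites"]
        )
        cd = gd["coding"]
        coding = CodingRegion(
            inherent_effect=float(cd["inherent_effect"]),
            target_motif=int(cd["target_motif"]),
            phenotype_effect=float(cd["phenotype_effect"]) if "phenotype_effect" in cd else None,
            hill_n=float(cd["hill_n"]) if "hill_n" in cd else None,
        )
        genes.append(Gene(kind=gd["kind"], cis_sites=sites, coding=coding, lineage_id=int(gd["lineage_id"])))
    return Genotype(genes=tuple(genes))


def genotype_to_json(g: Genotype, indent: int | None = 2) -> str:
    return json.dumps(genotype_to_dict(g), indent=indent)


def genotype_from_json(text: str) -> Genotype:
    return genotype_from_dict(json.loads(text))


def _canonicalize(obj):
    if isinstance(obj, float):
        return format(obj, ".17g")
    if isinstance(obj, dict):
        return {k: _canonicalize(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_canonicalize(v) for v in obj]
    return obj


@lru_cache(maxsize=65536)
def genotype_key(g: Genotype) -> str:
    """Canonical text key: byte-stable serialization with sorted field names
    and 17-significant-digit float formatting.  Equal genotypes map to equal
    keys; any field difference (including gene order) changes the key."""
    return json.dumps(_canonicalize(genotype_to_dict(g)), sort_keys=True, separators=(",", ":"))
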