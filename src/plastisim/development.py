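"""Tau-leaping stochastic development of a single cell.

One individual develops for a fixed period ``T_dev`` (300 min).  Molecule
counts (mRNA per gene, protein per gene, basic transcription factor, signal)
are integers updated per time step ``tau`` by independent Poisson event
counts per reaction channel, clamped at zero.  The phenotype starts at zero,
never decays, and grows deterministically at a rate proportional to the
phenotype-gene protein counts weighted by their catalytic effects — so all
developmental noise propagates from expression and decay stochasticity.

Regulation: each cis site receives signed input from every protein species
whose target motif matches the site's motif.  Site occupancy is
``theta = X / (X + K0 * lambda^mismatch)``; the signed input is
``cis_effect * inherent_effect * theta``.  With A the sum of positive inputs
and R the magnitude sum of negative inputs, the transcription rate is the
Michaelis–Menten-like ``r_max * A / (1 + A + R)`` (zero without any bound
activator: a gene needs an enhancer to be expressed).  A non-evolving basic
transcription factor, supplied at a constant rate, can bootstrap expression.

Signal-binding genes act only through the heterodimer of their protein with
the signal molecule: cooperative binding gives the effective availability
``Se = S^n / (K^n + S^n)`` (Hill), and the heterodimer abundance entering
occupancy is ``Se * X_signal_gene``, with regulatory identity (target motif,
inherent effect) taken from the signal-binding gene's coding region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .genome import (
    Genotype,
    KIND_PHENOTYPE,
    KIND_SIGNAL,
    genotype_key,
)

SIGNAL_MODES = ("none", "environmental", "performance")
_MODE_CODE = {"none": 0, "environmental": 1, "performance": 2}


@dataclass(frozen=True)
class RegulationParams:
    """Kinetic and regulatory constants of the developmental model.

    Units: minutes, molecule counts, phenotype units.  Translation and both
    decay rates are fixed for all genes, so mutations act only through
    transcription.
    """

    tau: float = 0.5                 # leap step, min
    r_max: float = 5.0               # max transcription, mRNA/min
    K0: float = 100.0                # base dissociation scale, molecules
    lambda_mismatch: float = 2.0     # per-mismatch dissociation multiplier
    basic_tf_input: float = 10.0     # molecules/min
    translation_rate: float = 1.0    # proteins per mRNA per min
    mrna_decay: float = 0.2          # 1/min
    protein_decay: float = 0.05      # 1/min
    k_P: float = 0.01                # phenotype growth per protein*effect*min
    K_hill: float = 2.0e4            # Hill dissociation constant, molecules
    T_dev: float = 300.0             # development time, min
    basic_tf_motif: int = 0          # motif recognised by the basic TF

    def __post_init__(self) -> None:
        for name in (
            "tau", "r_max", "K0", "lambda_mismatch", "basic_tf_input",
            "translation_rate", "mrna_decay", "protein_decay", "k_P",
            "K_hill", "T_dev",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        steps = self.T_dev / self.tau
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("T_dev must be an integer number of tau steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.T_dev / self.tau))


@dataclass(frozen=True)
class SignalSpec:
    """Which signal (if any) is supplied, and the current environment's
    optimum Pe.  The environmental signal is input at rate Pe throughout
    development; the performance signal at rate |Pt - Pe|, recomputed each
    step; ``none`` supplies nothing, so Pe cannot influence development."""

    mode: str = "none"
    Pe: float = 1000.0

    def __post_init__(self) -> None:
        if self.mode not in SIGNAL_MODES:
            raise ValueError(f"unknown signal mode {self.mode!r}")
        if self.Pe < 0:
            raise ValueError("Pe must be >= 0")


@dataclass
class DevelopmentResult:
    final_phenotype: float
    trajectory: "np.ndarray | None" = None  # columns: t, phenotype, then per-species counts
    species: tuple[str, ...] = ()


def effective_signal(S: float, n: float, K: float) -> float:
    """Hill-equation effective signal Se = S^n / (K^n + S^n) in [0, 1)."""
    if S < 0:
        raise ValueError("S must be >= 0")
    if K <= 0:
        raise ValueError("K must be > 0")
    if S == 0:
        return 0.0
    try:
        ratio = (K / S) ** n
    except OverflowError:
        return 0.0
    return 1.0 / (1.0 + ratio)


def signal_input_rate(spec: SignalSpec, Pt: float) -> float:
    """Signal input rate (molecules/min) for the current phenotype Pt."""
    if spec.mode == "none":
        return 0.0
    if spec.mode == "environmental":
        return spec.Pe
    return abs(Pt - spec.Pe)


def site_occupancy(protein_count: float, mismatch: int, params: RegulationParams) -> float:
    """Fractional occupancy of one site by one protein species:
    theta = X / (X + K0 * lambda^mismatch)."""
    if protein_count < 0:
        raise ValueError("protein_count must be >= 0")
    K = params.K0 * params.lambda_mismatch ** mismatch
    return protein_count / (protein_count + K)


# ---------------------------------------------------------------------------
# genotype compilation: flatten the regulatory graph into edge arrays

class CompiledGenotype:
    """Flat-array view of a genotype consumed by the numba kernel.

    Source species are the per-gene proteins (index = gene index) plus the
    basic TF (index = n_genes).  Edges connect a source species to a target
    gene through one cis site; zero-weight edges are dropped.
    """

    __slots__ = (
        "n_genes", "kind", "phen_eff", "hill_n",
        "e_tgt", "e_src", "e_coeff", "e_K",
    )

    def __init__(self, g: Genotype, params: RegulationParams):
        n = len(g.genes)
        self.n_genes = n
        self.kind = np.zeros(n, dtype=np.int8)
        self.phen_eff = np.zeros(n, dtype=np.float64)
        self.hill_n = np.zeros(n, dtype=np.float64)
        src_motif = np.empty(n + 1, dtype=np.int64)
        src_effect = np.empty(n + 1, dtype=np.float64)
        for i, gene in enumerate(g.genes):
            if gene.kind == KIND_PHENOTYPE:
                self.kind[i] = 1
                self.phen_eff[i] = gene.coding.phenotype_effect
            elif gene.kind == KIND_SIGNAL:
                self.kind[i] = 2
                self.hill_n[i] = gene.coding.hill_n
            src_motif[i] = gene.coding.target_motif
            src_effect[i] = gene.coding.inherent_effect
        src_motif[n] = params.basic_tf_motif
        src_effect[n] = 1.0  # basic TF is a fixed, unit-effect activator

        tgt, src, coeff, K = [], [], [], []
        for t, gene in enumerate(g.genes):
            for site in gene.cis_sites:
                if site.cis_effect == 0.0:
                    continue
                Keff = params.K0 * params.lambda_mismatch ** site.affinity_mismatch
                for j in range(n + 1):
                    if src_motif[j] == site.motif_id and src_effect[j] != 0.0:
                        tgt.append(t)
                        src.append(j)
                        coeff.append(site.cis_effect * src_effect[j])
                        K.append(Keff)
        self.e_tgt = np.asarray(tgt, dtype=np.int64)
        self.e_src = np.asarray(src, dtype=np.int64)
        self.e_coeff = np.asarray(coeff, dtype=np.float64)
        self.e_K = np.asarray(K, dtype=np.float64)


_COMPILE_CACHE: dict[tuple[str, RegulationParams], CompiledGenotype] = {}


def compile_genotype(g: Genotype, params: RegulationParams) -> CompiledGenotype:
    key = (genotype_key(g), params)
    cg = _COMPILE_CACHE.get(key)
    if cg is None:
        if len(_COMPILE_CACHE) > 20000:
            _COMPILE_CACHE.clear()
        cg = CompiledGenotype(g, params)
        _COMPILE_CACHE[key] = cg
    return cg


# ---------------------------------------------------------------------------
# numba kernels

@numba.njit(cache=False, fastmath=True)
def _step(
    m, X, TF, S, Pt,
    kind, phen_eff, hill_n,
    e_tgt, e_src, e_coeff, e_K,
    tau, r_max, translation, mdec, pdec, basic_in, k_P, K_hill,
    mode, Pe,
    A, R, eff,
):
    n_genes = m.shape[0]
    # effective source abundances (heterodimer for signal-binding genes)
    for g in range(n_genes):
        if kind[g] == 2:
            if S > 0:
                Se = 1.0 / (1.0 + (K_hill / S) ** hill_n[g])
                eff[g] = Se * X[g]
            else:
                eff[g] = 0.0
        else:
            eff[g] = X[g]
    eff[n_genes] = TF

    for g in range(n_genes):
        A[g] = 0.0
        R[g] = 0.0
    for e in range(e_tgt.shape[0]):
        x = eff[e_src[e]]
        if x <= 0.0:
            continue
        th = x / (x + e_K[e])
        v = e_coeff[e] * th
        if v >= 0.0:
            A[e_tgt[e]] += v
        else:
            R[e_tgt[e]] -= v

    # phenotype growth from start-of-step protein counts (deterministic)
    growth = 0.0
    for g in range(n_genes):
        if phen_eff[g] > 0.0:
            growth += X[g] * phen_eff[g]
    Pt_new = Pt + tau * k_P * growth

    # Poisson event counts, all from start-of-step state
    for g in range(n_genes):
        if A[g] > 0.0:
            tr = r_max * A[g] / (1.0 + A[g] + R[g])
        else:
            tr = 0.0
        dm = 0
        if tr > 0.0:
            dm = np.random.poisson(tr * tau)
        if m[g] > 0:
            dm -= np.random.poisson(mdec * m[g] * tau)
        dX = 0
        if m[g] > 0:
            dX = np.random.poisson(translation * m[g] * tau)
        if X[g] > 0:
            dX -= np.random.poisson(pdec * X[g] * tau)
        m[g] = max(0, m[g] + dm)
        X[g] = max(0, X[g] + dX)

    dTF = np.random.poisson(basic_in * tau)
    if TF > 0:
        dTF -= np.random.poisson(pdec * TF * tau)
    TF = max(0, TF + dTF)

    if mode > 0:
        if mode == 1:
            srate = Pe
        else:
            srate = abs(Pt - Pe)
        dS = 0
        if srate > 0.0:
            dS = np.random.poisson(srate * tau)
        if S > 0:
            dS -= np.random.poisson(pdec * S * tau)
        S = max(0, S + dS)

    return TF, S, Pt_new


@numba.njit(cache=False, fastmath=True)
def _develop_one(
    seed, n_steps,
    kind, phen_eff, hill_n,
    e_tgt, e_src, e_coeff, e_K,
    tau, r_max, translation, mdec, pdec, basic_in, k_P, K_hill,
    mode, Pe,
):
    np.random.seed(seed)
    n_genes = kind.shape[0]
    m = np.zeros(n_genes, dtype=np.int64)
    X = np.zeros(n_genes, dtype=np.int64)
    A = np.zeros(n_genes, dtype=np.float64)
    R = np.zeros(n_genes, dtype=np.float64)
    eff = np.zeros(n_genes + 1, dtype=np.float64)
    TF = 0
    S = 0
    Pt = 0.0
    for _ in range(n_steps):
        TF, S, Pt = _step(
            m, X, TF, S, Pt, kind, phen_eff, hill_n,
            e_tgt, e_src, e_coeff, e_K,
            tau, r_max, translation, mdec, pdec, basic_in, k_P, K_hill,
            mode, Pe, A, R, eff,
        )
    return Pt


@numba.njit(cache=False, fastmath=True)
def _develop_many(
    seeds, n_steps,
    kind, phen_eff, hill_n,
    e_tgt, e_src, e_coeff, e_K,
    tau, r_max, translation, mdec, pdec, basic_in, k_P, K_hill,
    mode, Pe_arr,
):
    out = np.empty(seeds.shape[0], dtype=np.float64)
    for i in range(seeds.shape[0]):
        out[i] = _develop_one(
            seeds[i], n_steps, kind, phen_eff, hill_n,
            e_tgt, e_src, e_coeff, e_K,
            tau, r_max, translation, mdec, pdec, basic_in, k_P, K_hill,
            mode, Pe_arr[i],
        )
    return out


@numba.njit(cache=False, fastmath=True)
def _develop_traced(
    seed, n_steps, record_every,
    kind, phen_eff, hill_n,
    e_tgt, e_src, e_coeff, e_K,
    tau, r_max, translation, mdec, pdec, basic_in, k_P, K_hill,
    mode, Pe,
    rec,  # (n_records, 2 + n_genes*2 + 2): t, phenotype, mrna.., protein.., TF, S
):
    np.random.seed(seed)
    n_genes = kind.shape[0]
    m = np.zeros(n_genes, dtype=np.int64)
    X = np.zeros(n_genes, dtype=np.int64)
    A = np.zeros(n_genes, dtype=np.float64)
    R = np.zeros(n_genes, dtype=np.float64)
    eff = np.zeros(n_genes + 1, dtype=np.float64)
    TF = 0
    S = 0
    Pt = 0.0
    r = 0
    for step in range(n_steps):
        TF, S, Pt = _step(
            m, X, TF, S, Pt, kind, phen_eff, hill_n,
            e_tgt, e_src, e_coeff, e_K,
            tau, r_max, translation, mdec, pdec, basic_in, k_P, K_hill,
            mode, Pe, A, R, eff,
        )
        if (step + 1) % record_every == 0:
            rec[r, 0] = (step + 1) * tau
            rec[r, 1] = Pt
            for g in range(n_genes):
                rec[r, 2 + g] = m[g]
                rec[r, 2 + n_genes + g] = X[g]
            rec[r, 2 + 2 * n_genes] = TF
            rec[r, 3 + 2 * n_genes] = S
            r += 1
    return Pt


def _kernel_args(cg: CompiledGenotype, params: RegulationParams):
    return (
        cg.kind, cg.phen_eff, cg.hill_n,
        cg.e_tgt, cg.e_src, cg.e_coeff, cg.e_K,
        params.tau, params.r_max, params.translation_rate,
        params.mrna_decay, params.protein_decay,
        params.basic_tf_input, params.k_P, params.K_hill,
    )


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def develop(
    g: Genotype,
    spec: SignalSpec,
    params: RegulationParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
    record_every: int | None = None,
) -> DevelopmentResult:
    """Develop one individual for T_dev minutes; return the final phenotype.

    Randomness comes from ``rng`` (a child seed is drawn per call) or an
    explicit ``seed``.  With ``record_every = k`` the trajectory is sampled
    every k steps into ``result.trajectory``.
    """
    params = params or RegulationParams()
    if seed is None:
        if rng is None:
            raise ValueError("provide either rng or seed")
        seed = _child_seed(rng)
    cg = compile_genotype(g, params)
    mode = _MODE_CODE[spec.mode]
    if record_every is None:
        P = _develop_one(seed, params.n_steps, *_kernel_args(cg, params), mode, spec.Pe)
        return DevelopmentResult(final_phenotype=float(P))
    n_rec = params.n_steps // record_every
    rec = np.zeros((n_rec, 4 + 2 * cg.n_genes), dtype=np.float64)
    P = _develop_traced(
        seed, params.n_steps, record_every, *_kernel_args(cg, params), mode, spec.Pe, rec
    )
    species = (
        tuple(f"mrna_{i}" for i in range(cg.n_genes))
        + tuple(f"protein_{i}" for i in range(cg.n_genes))
        + ("basic_tf", "signal")
    )
    return DevelopmentResult(final_phenotype=float(P), trajectory=rec, species=species)


def develop_batch(
    g: Genotype,
    mode: str,
    Pe: "float | np.ndarray",
    n: int | None = None,
    params: RegulationParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    seeds: np.ndarray | None = None,
) -> np.ndarray:
    """Final phenotypes of ``n`` independent developments of one genotype.

    ``Pe`` may be a scalar (shared) or a per-replicate array (used by the
    evolutionary loop under spatial heterogeneity)."""
    params = params or RegulationParams()
    if seeds is None:
        if rng is None or n is None:
            raise ValueError("provide seeds, or rng and n")
        seeds = rng.integers(0, 2**31 - 1, size=n, dtype=np.int64)
    else:
        seeds = np.asarray(seeds, dtype=np.int64)
    Pe_arr = np.broadcast_to(np.asarray(Pe, dtype=np.float64), seeds.shape).copy()
    cg = compile_genotype(g, params)
    return _develop_many(
        seeds, params.n_steps, *_kernel_args(cg, params), _MODE_CODE[mode], Pe_arr
    )


def transcription_rate(
    gene_index: int,
    counts: dict,
    g: Genotype,
    params: RegulationParams,
    signal_count: float = 0.0,
) -> float:
    """Reference (pure-Python) transcription rate of one gene given explicit
    species counts — the same arithmetic as the kernel, exposed for
    inspection and testing.

    ``counts`` maps protein species to abundances: integer gene indices for
    per-gene proteins and the key ``"basic_tf"`` for the basic TF.
    Signal-binding gene abundances are converted to heterodimer
    availability via the Hill factor before computing occupancy.
    """
    A = 0.0
    R = 0.0
    target = g.genes[gene_index]
    sources: list[tuple[int, float, float]] = []  # (motif, inherent effect, abundance)
    for j, gene in enumerate(g.genes):
        x = float(counts.get(j, 0))
        if gene.kind == KIND_SIGNAL:
            x *= effective_signal(signal_count, gene.coding.hill_n, params.K_hill)
        sources.append((gene.coding.target_motif, gene.coding.inherent_effect, x))
    sources.append((params.basic_tf_motif, 1.0, float(counts.get("basic_tf", 0))))
    for site in target.cis_sites:
        for motif, effect, x in sources:
            if motif != site.motif_id:
                continue
            K = params.K0 * params.lambda_mismatch ** site.affinity_mismatch
            theta = x / (x + K) if x > 0 else 0.0
            v = site.cis_effect * effect * theta
            if v >= 0:
                A += v
            else:
                R -= v
    if A <= 0:
        return 0.0
    return params.r_max * A / (1.0 + A + R)
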