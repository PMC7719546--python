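"""Hand-built genotypes embodying the model's two plasticity mechanisms.

These small circuits are used in tests and demos:

``constitutive``
    A single phenotype gene driven to saturation by the basic transcription
    factor — a nonplastic reference whose mean phenotype sits near the low
    optimum.
``env_toggle``
    A constitutively expressed signal-binding gene whose heterodimer
    activates a dedicated phenotype gene.  The environmental signal's input
    rate is Pe, so the heterodimer is more available in the high
    environment and the circuit expresses an open-loop reaction norm.
``perf_feedback``
    The same wiring driven by the performance signal |Pt - Pe|: the
    phenotype grows while it is far from the optimum and the drive shuts
    off as the mismatch vanishes — a negative feedback loop that buffers
    developmental noise.
``open_loop_matched``
    A constitutive circuit tuned to the same mean final phenotype as
    ``perf_feedback`` in the low environment (within 2%), used as the
    noise-comparison control.

The numeric constants below were fixed once by simulating the circuits at
the default regulation parameters; they are part of the fixtures'
definitions, not tuning knobs.
"""

from __future__ import annotations

from .genome import (
    BindingSite,
    CodingRegion,
    Gene,
    Genotype,
    KIND_PHENOTYPE,
    KIND_SIGNAL,
    N_SITES,
)

FIXTURE_NAMES = ("constitutive", "env_toggle", "perf_feedback", "open_loop_matched")

_INERT_MOTIF = 19  # motif no fixture protein targets


def _sites(*active: tuple[int, float, int]) -> tuple[BindingSite, ...]:
    """Cis region with the given (motif, cis_effect, mismatch) sites, padded
    with inert zero-effect sites to the required length."""
    sites = [BindingSite(motif_id=m, cis_effect=c, affinity_mismatch=a) for m, c, a in active]
    while len(sites) < N_SITES:
        sites.append(BindingSite(motif_id=_INERT_MOTIF, cis_effect=0.0, affinity_mismatch=0))
    return tuple(sites)


def _phenotype_gene(
    drive: tuple[int, float, int], effect: float, lineage_id: int
) -> Gene:
    return Gene(
        kind=KIND_PHENOTYPE,
        cis_sites=_sites(drive),
        coding=CodingRegion(
            inherent_effect=0.0,  # regulates nothing itself
            target_motif=_INERT_MOTIF,
            phenotype_effect=effect,
        ),
        lineage_id=lineage_id,
    )


def _signal_gene(target_motif: int, hill_n: float, lineage_id: int) -> Gene:
    # constitutively expressed: strong activation by the basic TF (motif 0)
    return Gene(
        kind=KIND_SIGNAL,
        cis_sites=_sites((0, 50.0, 0)),
        coding=CodingRegion(
            inherent_effect=1.0,
            target_motif=target_motif,
            hill_n=hill_n,
        ),
        lineage_id=lineage_id,
    )


# constants fixed by simulation at the default RegulationParams
_CONSTITUTIVE_EFFECT = 0.753      # per-protein catalysis → mean phenotype ≈ 1000 (low env)
_ENV_TOGGLE_EFFECT = 3.0          # heterodimer-driven phenotype gene, env_toggle
_ENV_TOGGLE_CIS = 10.0
_ENV_TOGGLE_MISMATCH = 6          # K_eff = 100 * 2^6 = 6400: keeps occupancy quasi-linear
_ENV_TOGGLE_HILL = 4.0
_PERF_EFFECT = 2.5                # strong early drive so the loop closes within T_dev
_PERF_CIS = 10.0
_PERF_MISMATCH = 4                # K_eff = 1600
_PERF_HILL = 2.0
_OPEN_LOOP_EFFECT = 0.726         # matched to perf_feedback mean (low env) within 2%

_SIGNAL_TARGET_MOTIF = 5


def make_fixture(name: str) -> Genotype:
    """Return one of the packaged hand-built genotypes by name."""
    if name == "constitutive":
        return Genotype(genes=(_phenotype_gene((0, 50.0, 0), _CONSTITUTIVE_EFFECT, 0),))
    if name == "env_toggle":
        return Genotype(
            genes=(
                _signal_gene(_SIGNAL_TARGET_MOTIF, _ENV_TOGGLE_HILL, 0),
                _phenotype_gene(
                    (_SIGNAL_TARGET_MOTIF, _ENV_TOGGLE_CIS, _ENV_TOGGLE_MISMATCH),
                    _ENV_TOGGLE_EFFECT,
                    1,
                ),
            )
        )
    if name == "perf_feedback":
        return Genotype(
            genes=(
                _signal_gene(_SIGNAL_TARGET_MOTIF, _PERF_HILL, 0),
                _phenotype_gene(
                    (_SIGNAL_TARGET_MOTIF, _PERF_CIS, _PERF_MISMATCH),
                    _PERF_EFFECT,
                    1,
                ),
            )
        )
    if name == "open_loop_matched":
        return Genotype(genes=(_phenotype_gene((0, 50.0, 0), _OPEN_LOOP_EFFECT, 0),))
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
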