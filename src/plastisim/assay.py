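"""Reaction norms, plasticity classification, and developmental noise.

A genotype's reaction norm is the pair of mean final phenotypes over many
independent redevelopments in the low (Pe = 1000) and high (Pe = 3000)
environments, under the treatment's own signal mode.  A genotype is called
plastic when the absolute reaction-norm difference exceeds the threshold
``delta_P`` (default 400, 20% of the gap between the optima; strictly
greater).  Developmental noise is the sample standard deviation of realized
phenotypes among the low-environment redevelopments; robustness is its
inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .development import RegulationParams, develop_batch
from .genome import Genotype

if TYPE_CHECKING:  # pragma: no cover
    from .evolution import SimulationRecord

from .evolution import treatment_signal_mode


@dataclass(frozen=True)
class AssayConfig:
    n_redevelop: int = 50_000     # redevelopments per environment
    delta_P: float = 400.0        # plasticity threshold, phenotype units
    Pe_low: float = 1000.0
    Pe_high: float = 3000.0
    alternative_thresholds: tuple[float, ...] = (100.0, 200.0, 800.0)

    def __post_init__(self) -> None:
        if self.n_redevelop < 2:
            raise ValueError("n_redevelop must be >= 2")
        if self.delta_P <= 0:
            raise ValueError("delta_P must be > 0")


@dataclass
class AssayResult:
    mean_low: float
    mean_high: float
    sd_low: float
    is_plastic: bool
    n_redevelop: int


def _paired_batches(g, mode, assay, params, rng):
    """Low/high redevelopment batches sharing one seed stream per replicate
    (common random numbers).  The environment enters development only through
    the signal, so for the no-signal mode the two batches are identical and
    the estimated reaction norm is exactly flat; for signal modes pairing
    only reduces the variance of the contrast, never biases the means."""
    if rng is None:
        raise ValueError("an rng is required")
    seeds = rng.integers(0, 2**31 - 1, size=assay.n_redevelop, dtype=np.int64)
    low = develop_batch(g, mode, assay.Pe_low, params=params, seeds=seeds)
    high = develop_batch(g, mode, assay.Pe_high, params=params, seeds=seeds)
    return low, high


def reaction_norm(
    g: Genotype,
    treatment: str,
    assay: AssayConfig,
    params: RegulationParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean final phenotype in the low and high environments."""
    params = params or RegulationParams()
    mode = treatment_signal_mode(treatment)
    low, high = _paired_batches(g, mode, assay, params, rng)
    return float(np.mean(low)), float(np.mean(high))


def classify_plastic(mean_low: float, mean_high: float, delta_P: float = 400.0) -> bool:
    """Plastic iff |mean_high - mean_low| strictly exceeds delta_P."""
    if delta_P <= 0:
        raise ValueError("delta_P must be > 0")
    return abs(mean_high - mean_low) > delta_P


def developmental_noise(
    g: Genotype,
    treatment: str,
    assay: AssayConfig,
    params: RegulationParams | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Sample SD (n-1 denominator) of final phenotypes in the low environment."""
    params = params or RegulationParams()
    mode = treatment_signal_mode(treatment)
    low = develop_batch(g, mode, assay.Pe_low, assay.n_redevelop, params, rng)
    return float(np.std(low, ddof=1))


def assay_genotype(
    g: Genotype,
    treatment: str,
    assay: AssayConfig,
    params: RegulationParams | None = None,
    rng: np.random.Generator | None = None,
) -> AssayResult:
    """Full assay: reaction norm, plasticity call, and noise, sharing one set
    of low-environment redevelopments for the mean and the SD."""
    params = params or RegulationParams()
    mode = treatment_signal_mode(treatment)
    low, high = _paired_batches(g, mode, assay, params, rng)
    mean_low = float(np.mean(low))
    mean_high = float(np.mean(high))
    return AssayResult(
        mean_low=mean_low,
        mean_high=mean_high,
        sd_low=float(np.std(low, ddof=1)),
        is_plastic=classify_plastic(mean_low, mean_high, assay.delta_P),
        n_redevelop=assay.n_redevelop,
    )


# ---------------------------------------------------------------------------
# experiment-level summaries

def _cell_label(rec: "SimulationRecord") -> tuple[str, str]:
    return (rec.treatment, rec.environment_model)


def summarize_experiment(
    records: Iterable["SimulationRecord"],
    expected_cells: "Iterable[tuple[str, str]] | None" = None,
) -> dict[str, pd.DataFrame]:
    """Summary tables over a collection of replicate records.

    Returns
    -------
    dict with keys:
      ``summary`` — one row per (treatment, environment) cell: replicate
        counts, fraction plastic at the end among all replicates and among
        those whose founder was not plastic, and mean ± SE developmental
        noise split by final plasticity.  Cells with no usable replicates
        report NaN fractions explicitly rather than being dropped.
      ``welch`` — pairwise Welch two-sample t-tests on final noise between
        cells.
      ``fisher`` — pairwise Fisher exact tests on end-of-run plasticity
        counts (among initially nonplastic replicates) between cells.
    """
    records = list(records)
    cells: dict[tuple[str, str], list["SimulationRecord"]] = {}
    if expected_cells is not None:
        # declared design cells appear in the summary even when empty,
        # as explicit all-NaN rows rather than silent omissions
        for label in expected_cells:
            cells[tuple(label)] = []
    for r in records:
        cells.setdefault(_cell_label(r), []).append(r)

    rows = []
    for (treatment, envm), recs in sorted(cells.items()):
        n = len(recs)
        n_start_plastic = sum(r.founder_plastic for r in recs)
        n_end_plastic = sum(r.final_plastic for r in recs)
        nonstart = [r for r in recs if not r.founder_plastic]
        n_end_plastic_excl = sum(r.final_plastic for r in nonstart)
        noise_p = [r.final_noise for r in recs if r.final_plastic and np.isfinite(r.final_noise)]
        noise_np = [r.final_noise for r in recs if not r.final_plastic and np.isfinite(r.final_noise)]

        def mean_se(x):
            if not x:
                return float("nan"), float("nan")
            x = np.asarray(x, dtype=float)
            se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
            return float(np.mean(x)), se

        m_p, se_p = mean_se(noise_p)
        m_np, se_np = mean_se(noise_np)
        rows.append(
            {
                "treatment": treatment,
                "environment_model": envm,
                "n_replicates": n,
                "n_start_plastic": n_start_plastic,
                "n_end_plastic": n_end_plastic,
                "frac_plastic_all": n_end_plastic / n if n else float("nan"),
                "n_start_nonplastic": len(nonstart),
                "n_end_plastic_excl_start_plastic": n_end_plastic_excl,
                "frac_plastic_excl_start_plastic": (
                    n_end_plastic_excl / len(nonstart) if nonstart else float("nan")
                ),
                "noise_plastic_mean": m_p,
                "noise_plastic_se": se_p,
                "noise_nonplastic_mean": m_np,
                "noise_nonplastic_se": se_np,
            }
        )
    summary = pd.DataFrame(rows)

    welch_rows = []
    fisher_rows = []
    labels = sorted(cells)
    for a, b in combinations(labels, 2):
        xa = [r.final_noise for r in cells[a] if np.isfinite(r.final_noise)]
        xb = [r.final_noise for r in cells[b] if np.isfinite(r.final_noise)]
        if len(xa) >= 2 and len(xb) >= 2:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            # identical samples give 0/0; by convention no evidence at all
            if np.isnan(t) and np.allclose(np.mean(xa), np.mean(xb)):
                t, p = 0.0, 1.0
        else:
            t, p = float("nan"), float("nan")
        welch_rows.append(
            {"cell_a": "/".join(a), "cell_b": "/".join(b), "t": float(t), "p": float(p)}
        )

        na = [r for r in cells[a] if not r.founder_plastic]
        nb = [r for r in cells[b] if not r.founder_plastic]
        ka = sum(r.final_plastic for r in na)
        kb = sum(r.final_plastic for r in nb)
        if na and nb:
            table = [[ka, len(na) - ka], [kb, len(nb) - kb]]
            _, p = stats.fisher_exact(table)
        else:
            p = float("nan")
        fisher_rows.append(
            {
                "cell_a": "/".join(a),
                "cell_b": "/".join(b),
                "plastic_a": ka,
                "n_a": len(na),
                "plastic_b": kb,
                "n_b": len(nb),
                "p": float(p),
            }
        )

    return {
        "summary": summary,
        "welch": pd.DataFrame(welch_rows),
        "fisher": pd.DataFrame(fisher_rows),
    }
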