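"""Hill signal, occupancy, transcription arithmetic, and tau-leap dynamics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from plastisim.development import (
    RegulationParams,
    SignalSpec,
    develop,
    develop_batch,
    effective_signal,
    signal_input_rate,
    site_occupancy,
    transcription_rate,
)
from plastisim.fixtures import make_fixture
from plastisim.genome import BindingSite, CodingRegion, Gene, Genotype, N_SITES


def _pad_sites(*active):
    sites = [BindingSite(m, c, a) for m, c, a in active]
    sites += [BindingSite(19, 0.0, 0)] * (N_SITES - len(sites))
    return tuple(sites)


def _simple_gene(kind="phenotype", drive=(0, 1e9, 0), effect=1.0, inherent=0.0,
                 target=19, hill_n=None):
    return Gene(
        kind=kind,
        cis_sites=_pad_sites(drive) if drive else _pad_sites(),
        coding=CodingRegion(
            inherent_effect=inherent,
            target_motif=target,
            phenotype_effect=effect if kind == "phenotype" else None,
            hill_n=hill_n,
        ),
    )


# ---------------------------------------------------------------------------
# closed-form pieces

def test_effective_signal_closed_form():
    assert effective_signal(2e4, 3.7, 2e4) == pytest.approx(0.5)
    assert effective_signal(0.0, 2.0, 2e4) == 0.0
    assert effective_signal(3.0, 1.0, 1.0) == pytest.approx(0.75)  # S = 3K, n = 1


@given(
    n=st.floats(1.0, 5.0),
    K=st.floats(1.0, 1e6),
    s1=st.floats(0.0, 1e7),
    s2=st.floats(0.0, 1e7),
)
@settings(max_examples=200, deadline=None)
def test_effective_signal_monotone_and_bounded(n, K, s1, s2):
    lo, hi = sorted((s1, s2))
    e_lo, e_hi = effective_signal(lo, n, K), effective_signal(hi, n, K)
    assert 0.0 <= e_lo <= e_hi <= 1.0  # mathematically < 1, saturates in floats
    assert effective_signal(K, n, K) == pytest.approx(0.5)


def test_signal_input_rate_modes():
    assert signal_input_rate(SignalSpec("environmental", 3000.0), Pt=12345.0) == 3000.0
    assert signal_input_rate(SignalSpec("performance", 1000.0), Pt=1000.0) == 0.0
    assert signal_input_rate(SignalSpec("performance", 1000.0), Pt=250.0) == 750.0
    assert signal_input_rate(SignalSpec("none", 1000.0), Pt=500.0) == 0.0


def test_site_occupancy(params):
    assert site_occupancy(0, 0, params) == 0.0
    assert site_occupancy(params.K0, 0, params) == pytest.approx(0.5)
    # monotone in protein count, antitone in mismatch; vanishes at large mismatch
    assert site_occupancy(300, 0, params) > site_occupancy(100, 0, params)
    assert site_occupancy(100, 3, params) < site_occupancy(100, 1, params)
    assert site_occupancy(100, 40, params) < 1e-9


def test_transcription_rate_arithmetic(params):
    activator = _simple_gene(kind="regulatory", drive=None, inherent=2.0, target=4, effect=None)
    repressor = _simple_gene(kind="regulatory", drive=None, inherent=-1.0, target=4, effect=None)
    target = _simple_gene(kind="phenotype", drive=(4, 1.0, 0), effect=1.0)
    g = Genotype((activator, repressor, target))

    # nothing expressed without a bound activator
    assert transcription_rate(2, {0: 0, 1: 0}, g, params) == 0.0
    # no protein matches the target's motif -> zero even at high abundance
    orphan = Genotype((target,))
    assert transcription_rate(0, {0: 10_000}, orphan, params) == 0.0

    # saturation toward r_max as total activation A grows (A >> 1 + R)
    strong_target = _simple_gene(kind="phenotype", drive=(4, 1e7, 0), effect=1.0)
    g_strong = Genotype((activator, strong_target))
    lots = transcription_rate(1, {0: 10**6}, g_strong, params)
    assert lots == pytest.approx(params.r_max, rel=1e-3)

    # adding repressor occupancy strictly decreases the rate
    base = transcription_rate(2, {0: 500}, g, params)
    repressed = transcription_rate(2, {0: 500, 1: 500}, g, params)
    more_repressed = transcription_rate(2, {0: 500, 1: 2000}, g, params)
    assert repressed < base
    assert more_repressed < repressed


# ---------------------------------------------------------------------------
# tau-leap dynamics

def test_develop_without_phenotype_genes_stays_zero(params):
    reg = _simple_gene(kind="regulatory", drive=(0, 1e6, 0), inherent=1.0, target=1, effect=None)
    g = Genotype((reg,))
    res = develop(g, SignalSpec("none"), params, seed=123)
    assert res.final_phenotype == 0.0


def test_no_signal_development_is_environment_independent(params):
    """With no signal the environment has no channel into development: the
    same seed gives bitwise-identical trajectories for Pe=1000 and Pe=3000."""
    g = make_fixture("constitutive")
    a = develop(g, SignalSpec("none", 1000.0), params, seed=99, record_every=20)
    b = develop(g, SignalSpec("none", 3000.0), params, seed=99, record_every=20)
    assert a.final_phenotype == b.final_phenotype
    np.testing.assert_array_equal(a.trajectory, b.trajectory)
    # distributional check over independent replicates
    rng = np.random.default_rng(17)
    lo = develop_batch(g, "none", 1000.0, 400, params, rng)
    hi = develop_batch(g, "none", 3000.0, 400, params, rng)
    _, p = stats.ttest_ind(lo, hi, equal_var=False)
    assert p > 1e-4


def test_phenotype_monotone_and_counts_nonnegative(params):
    g = make_fixture("env_toggle")
    res = develop(g, SignalSpec("environmental", 3000.0), params, seed=5, record_every=1)
    traj = res.trajectory
    phen = traj[:, 1]
    assert np.all(np.diff(phen) >= 0)
    assert phen[-1] == res.final_phenotype
    counts = traj[:, 2:]
    assert np.all(counts >= 0)
    assert np.allclose(counts, np.round(counts))  # integer molecule counts


def _saturated_single_gene():
    # one phenotype gene driven at r_max whenever any basic TF is present
    return Genotype((_simple_gene(kind="phenotype", drive=(0, 1e9, 0), effect=1.0),))


def test_tau_leap_matches_birth_death_stationary_law(params):
    """A constitutively maxed-out gene is a linear birth-death cascade:
    stationary mRNA is Poisson(r_max/mrna_decay) and the protein mean is
    (r_max/mrna_decay)*(translation/protein_decay).  Empirical moments at
    t = T_dev must match within sampling error."""
    g = _saturated_single_gene()
    n = 1000
    m_final = np.empty(n)
    x_final = np.empty(n)
    for i in range(n):
        res = develop(g, SignalSpec("none"), params, seed=10_000 + i,
                      record_every=params.n_steps)
        m_final[i] = res.trajectory[-1, 2]
        x_final[i] = res.trajectory[-1, 3]

    m_mean = params.r_max / params.mrna_decay                      # 25
    x_mean = m_mean * params.translation_rate / params.protein_decay  # 500

    assert abs(m_final.mean() - m_mean) < 3 * np.sqrt(m_mean / n)
    # Poisson stationary law: variance equals the mean
    var = m_final.var(ddof=1)
    se_var = m_mean * np.sqrt(2 / (n - 1))
    assert abs(var - m_mean) < 3 * se_var
    # protein mean; empirical SD supplies the standard error
    assert abs(x_final.mean() - x_mean) < 3 * x_final.std(ddof=1) / np.sqrt(n)


def test_halving_tau_does_not_shift_the_mean(params):
    g = _saturated_single_gene()
    fine = dataclasses.replace(params, tau=params.tau / 2)
    rng = np.random.default_rng(31)
    a = develop_batch(g, "none", 1000.0, 800, params, rng)
    b = develop_batch(g, "none", 1000.0, 800, fine, rng)
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    assert abs(a.mean() - b.mean()) < 2 * se


def test_feedback_circuit_buffers_noise(feedback_batches):
    """The performance-signal feedback loop yields a lower SD of final
    phenotype than an open-loop circuit matched to the same mean (±2%):
    one-sided variance-ratio test at alpha = 0.01."""
    perf, open_loop = feedback_batches
    assert abs(perf.mean() - open_loop.mean()) / open_loop.mean() < 0.02
    assert perf.std(ddof=1) < open_loop.std(ddof=1)
    f = open_loop.var(ddof=1) / perf.var(ddof=1)
    p = stats.f.sf(f, len(open_loop) - 1, len(perf) - 1)
    assert p < 0.01


def test_param_validation():
    with pytest.raises(ValueError):
        RegulationParams(tau=0.7)  # 300/0.7 is not an integer step count
    with pytest.raises(ValueError):
        RegulationParams(r_max=0.0)
    with pytest.raises(ValueError):
        SignalSpec(mode="telepathic")
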